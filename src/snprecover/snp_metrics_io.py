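"""Read, validate, filter, partition, and encode per-sample SNP metrics tables.

The central container is a list of :class:`SnpMetricsRecord`, one per
sample x SNP observation from an Illumina-style array run: a normalized
total intensity ``R``, the allelic-intensity ratio ``Theta`` in [0, 1], the
per-SNP GenTrain cluster-quality score, and the Gencall genotype in
{AA, AB, BB, NC}.  Files are columnar (parquet or CSV/TSV) with columns

    sampleID, snpID, chromosome, position, Ref, Alt, R, Theta,
    GenTrain_Score, GT [, a_is_ref]

``position`` is 1-based.  ``a_is_ref`` records whether Illumina's allele
"A" corresponds to the reference allele; when the column is absent it
defaults to True with a logged warning, and downstream concordance results
should be treated as allele-convention-unverified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import RowParseError, SchemaError, UnknownSnpError

logger = logging.getLogger(__name__)

#: Fixed class order used everywhere a genotype becomes an index or one-hot.
GENOTYPE_CLASSES = ("AA", "AB", "BB")
NO_CALL = "NC"
VALID_GENOTYPES = GENOTYPE_CLASSES + (NO_CALL,)

REQUIRED_COLUMNS = (
    "sampleID", "snpID", "chromosome", "position", "Ref", "Alt",
    "R", "Theta", "GenTrain_Score", "GT",
)


@dataclass(frozen=True, order=True)
class VariantKey:
    """(chromosome, 1-based position, ref allele, alt allele).

    The join key across genotyping technologies.  Equality is exact on all
    four fields: no strand flipping or allele swapping is ever applied.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical: {self.ref_allele}")

    def __str__(self) -> str:  # chr12:40340400:G:A
        return f"{self.chromosome}:{self.position}:{self.ref_allele}:{self.alt_allele}"

    @classmethod
    def from_string(cls, s: str) -> "VariantKey":
        parts = s.split(":")
        if len(parts) != 4:
            raise ValueError(f"cannot parse variant key {s!r} as chrom:pos:ref:alt")
        return cls(parts[0], int(parts[1]), parts[2], parts[3])


@dataclass(frozen=True)
class SnpMetricsRecord:
    """One sample x SNP observation from the array.

    Numeric fields use ``None`` for missing (never 0).  ``genotype`` may be
    AA/AB/BB, NC (Gencall declined to call), or None (field missing in the
    source file).
    """

    sample_id: str
    snp_id: str
    variant: VariantKey
    r: Optional[float]
    theta: Optional[float]
    gentrain: Optional[float]
    genotype: Optional[str]
    a_is_ref: bool = True

    def __post_init__(self):
        if self.r is not None and self.r < 0:
            raise ValueError(f"R must be non-negative, got {self.r}")
        if self.theta is not None and not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"Theta must lie in [0, 1], got {self.theta}")
        if self.gentrain is not None and not (0.0 <= self.gentrain <= 1.0):
            raise ValueError(f"GenTrain score must lie in [0, 1], got {self.gentrain}")
        if self.genotype is not None and self.genotype not in VALID_GENOTYPES:
            raise ValueError(
                f"genotype must be one of {VALID_GENOTYPES} or missing, got {self.genotype!r}"
            )

    @property
    def is_complete(self) -> bool:
        """True when all four of {GenTrain, R, Theta, genotype} are present."""
        return (
            self.gentrain is not None
            and self.r is not None
            and self.theta is not None
            and self.genotype is not None
        )


@dataclass
class EncodedDataset:
    """Model-ready arrays: per-record SNP vocabulary index, (r, theta)
    features, and optional one-hot targets in fixed (AA, AB, BB) order."""

    snp_index: np.ndarray          # (n,) int
    features: np.ndarray           # (n, 2) float: columns (r, theta)
    targets: Optional[np.ndarray]  # (n, 3) one-hot float, or None
    vocabulary: dict               # snp_id -> index (bijection)

    def __len__(self) -> int:
        return len(self.snp_index)

    @property
    def inverse_vocabulary(self) -> dict:
        return {i: s for s, i in self.vocabulary.items()}


def _opt_float(value, row: int, column: str) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str):
        v = value.strip()
        if v == "" or v.upper() in ("NA", "NAN"):
            return None
        value = v
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowParseError(
            f"row {row}: cannot parse {column}={value!r} as a number", row=row
        ) from None


def _read_table(path, fmt: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "parquet" if path.suffix == ".parquet" else "csv"
    if fmt == "parquet":
        return pd.read_parquet(path)
    # CSV/TSV: delimiter auto-detected from the header line.
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype={"chromosome": str, "sampleID": str,
                                             "snpID": str, "Ref": str, "Alt": str},
                       keep_default_na=True, na_values=["NA", ""])


def read_snp_metrics(path, fmt: Optional[str] = None) -> list[SnpMetricsRecord]:
    """Read a per-sample SNP metrics table into records.

    Parameters
    ----------
    path : str or Path
        Parquet or delimited-text file with the documented columns.
    fmt : {"parquet", "csv", None}
        File format; ``None`` infers from the extension (``.parquet`` is
        parquet, anything else delimited text with the separator detected
        from the header line).

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    RowParseError
        If a numeric cell cannot be parsed (the message carries the 0-based
        row index).
    """
    df = _read_table(path, fmt)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    has_a_is_ref = "a_is_ref" in df.columns
    if not has_a_is_ref:
        logger.warning(
            "%s has no a_is_ref column; assuming Illumina allele A == ref for "
            "every SNP. Concordance results are allele-convention-unverified.",
            path,
        )

    records: list[SnpMetricsRecord] = []
    for row, tup in enumerate(df.itertuples(index=False)):
        d = tup._asdict()
        gt = d["GT"]
        if isinstance(gt, float) and math.isnan(gt):
            gt = None
        if isinstance(gt, str):
            gt = gt.strip()
            if gt == "" or gt.upper() == "NA":
                gt = None
        if gt is not None and gt not in VALID_GENOTYPES:
            raise RowParseError(
                f"row {row}: genotype {gt!r} is not one of {VALID_GENOTYPES}", row=row
            )
        try:
            pos = int(d["position"])
        except (TypeError, ValueError):
            raise RowParseError(
                f"row {row}: cannot parse position={d['position']!r}", row=row
            ) from None
        variant = VariantKey(str(d["chromosome"]), pos, str(d["Ref"]), str(d["Alt"]))
        a_is_ref = bool(d["a_is_ref"]) if has_a_is_ref else True
        records.append(
            SnpMetricsRecord(
                sample_id=str(d["sampleID"]),
                snp_id=str(d["snpID"]),
                variant=variant,
                r=_opt_float(d["R"], row, "R"),
                theta=_opt_float(d["Theta"], row, "Theta"),
                gentrain=_opt_float(d["GenTrain_Score"], row, "GenTrain_Score"),
                genotype=gt,
                a_is_ref=a_is_ref,
            )
        )
    return records


def filter_complete_records(
    records: Sequence[SnpMetricsRecord],
) -> tuple[list[SnpMetricsRecord], list[SnpMetricsRecord]]:
    """Drop records missing any of {GenTrain, R, Theta, genotype}.

    Returns ``(kept, dropped)``; their disjoint union is the input and
    order is preserved within each list.
    """
    kept, dropped = [], []
    for rec in records:
        (kept if rec.is_complete else dropped).append(rec)
    return kept, dropped


def partition_no_calls(
    records: Sequence[SnpMetricsRecord],
) -> tuple[list[SnpMetricsRecord], list[SnpMetricsRecord]]:
    """Separate no-call (NC) records from validly genotyped ones.

    Input should already be completeness-filtered.  Returns
    ``(valid, no_calls)``.
    """
    valid, no_calls = [], []
    for rec in records:
        (no_calls if rec.genotype == NO_CALL else valid).append(rec)
    return valid, no_calls


def split_train_val_test(
    records: Sequence[SnpMetricsRecord],
    fractions: tuple[float, float, float] = (0.90, 0.05, 0.05),
    seed: int = 0,
) -> tuple[list[SnpMetricsRecord], list[SnpMetricsRecord], list[SnpMetricsRecord]]:
    """Randomly split records into train/validation/test sets.

    The split is by record (sample x SNP observation), not by sample or by
    SNP: the same sample can appear in train and test at different SNPs.
    Sizes match the fractions to within one record; the same seed always
    yields the identical partition.
    """
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or any(x <= 0 for x in f):
        raise ValueError(f"fractions must be three positive reals, got {fractions}")
    if abs(sum(f) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got sum {sum(f)!r}")
    n = len(records)
    n_train = int(round(f[0] * n))
    n_val = int(round(f[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    take = lambda idx: [records[i] for i in idx]
    return (
        take(order[:n_train]),
        take(order[n_train : n_train + n_val]),
        take(order[n_train + n_val :]),
    )


def build_vocabulary(records: Sequence[SnpMetricsRecord]) -> dict:
    """snp_id -> index over the sorted distinct snp_ids (deterministic)."""
    return {s: i for i, s in enumerate(sorted({r.snp_id for r in records}))}


def encode_dataset(
    records: Sequence[SnpMetricsRecord],
    vocabulary: Optional[dict] = None,
    with_targets: bool = True,
) -> EncodedDataset:
    """Turn records into model-ready arrays.

    When ``vocabulary`` is None it is built from the sorted distinct
    snp_ids of the input; when supplied it is reused unchanged and any
    record with an unseen snp_id raises :class:`UnknownSnpError`.  Targets
    are one-hot over the fixed (AA, AB, BB) order; pass
    ``with_targets=False`` for no-call records awaiting prediction.
    """
    if vocabulary is None:
        vocabulary = build_vocabulary(records)
    else:
        unknown = [r.snp_id for r in records if r.snp_id not in vocabulary]
        if unknown:
            raise UnknownSnpError(unknown)

    n = len(records)
    snp_index = np.empty(n, dtype=np.int64)
    features = np.empty((n, 2), dtype=np.float64)
    targets = np.zeros((n, 3), dtype=np.float64) if with_targets else None
    class_to_col = {g: i for i, g in enumerate(GENOTYPE_CLASSES)}
    for i, rec in enumerate(records):
        if rec.r is None or rec.theta is None:
            raise ValueError(f"record {i} has missing R/Theta; filter first")
        snp_index[i] = vocabulary[rec.snp_id]
        features[i, 0] = rec.r
        features[i, 1] = rec.theta
        if with_targets:
            if rec.genotype not in class_to_col:
                raise ValueError(
                    f"record {i} has genotype {rec.genotype!r}; targets require AA/AB/BB"
                )
            targets[i, class_to_col[rec.genotype]] = 1.0
    return EncodedDataset(snp_index, features, targets, vocabulary)
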