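"""Parse PLINK-style additive-dosage text exports (".raw" layout).

A .raw file is whitespace-delimited text whose header begins

    FID IID PAT MAT SEX PHENOTYPE

followed by one column per variant named ``<id>_<countedAllele>`` where
``<id>`` encodes ``chrom:pos:ref:alt``.  Each dosage cell is the count
(0/1/2) of the counted allele in that sample's diploid genotype, or NA.
Only hard calls are accepted: a fractional imputed dosage like 1.2 is a
format error here, because downstream concordance compares discrete
genotypes — round at the producer, not in this reader.

PAT/MAT/SEX/PHENOTYPE are read and discarded; sample ids come from IID.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError
from .snp_metrics_io import VariantKey

RAW_HEADER_PREFIX = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


@dataclass
class DosageCallset:
    """Per-sample, per-variant counted-allele dosages for one technology.

    ``dosages`` is a float matrix (samples x variants) with values in
    {0, 1, 2} and NaN for missing.  ``counted_allele`` of each variant is
    always one of that variant's ref/alt alleles.
    """

    technology: str                       # "imputed" | "wgs" | free label
    samples: list                         # sample ids (from IID)
    variants: list                        # of (VariantKey, counted_allele)
    dosages: np.ndarray                   # (n_samples, n_variants) float

    def __post_init__(self):
        for vk, counted in self.variants:
            if counted not in (vk.ref_allele, vk.alt_allele):
                raise ValueError(
                    f"counted allele {counted!r} is neither ref nor alt of {vk}"
                )
        self.dosages = np.asarray(self.dosages, dtype=float)
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage {bad!r} is not in {{0, 1, 2}}")

    def alt_dosages(self) -> np.ndarray:
        """Dosage matrix re-expressed as copies of the ALT allele."""
        out = self.dosages.copy()
        for j, (vk, counted) in enumerate(self.variants):
            if counted == vk.ref_allele:
                out[:, j] = 2.0 - out[:, j]
        return out

    def lookup(self) -> dict:
        """{(sample_id, VariantKey): alt-allele dosage} over non-missing cells."""
        alt = self.alt_dosages()
        table = {}
        for i, sample in enumerate(self.samples):
            for j, (vk, _) in enumerate(self.variants):
                d = alt[i, j]
                if not math.isnan(d):
                    table[(sample, vk)] = int(d)
        return table


def _parse_variant_column(name: str) -> tuple[VariantKey, str]:
    if "_" not in name:
        raise FormatError(f"variant column {name!r} lacks a _countedAllele suffix")
    var_id, counted = name.rsplit("_", 1)
    parts = var_id.split(":")
    if len(parts) != 4:
        raise FormatError(
            f"variant column {name!r}: id {var_id!r} does not parse as chrom:pos:ref:alt"
        )
    chrom, pos_s, ref, alt = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise FormatError(f"variant column {name!r}: position {pos_s!r} is not an integer")
    vk = VariantKey(chrom, pos, ref, alt)
    if counted not in (ref, alt):
        raise FormatError(
            f"variant column {name!r}: counted allele {counted!r} is neither ref nor alt"
        )
    return vk, counted


def read_raw(
    path,
    technology: str = "imputed",
    variant_annotation: Optional[dict] = None,
) -> DosageCallset:
    """Read a PLINK .raw export into a :class:`DosageCallset`.

    Parameters
    ----------
    path : str or Path
        Whitespace-delimited text file with the documented header.
    technology : str
        Label stored on the callset ("imputed" or "wgs" in normal use).
    variant_annotation : dict, optional
        ``{opaque_id: VariantKey}`` mapping for files whose variant column
        ids are not ``chrom:pos:ref:alt`` (e.g. rs numbers).

    Raises
    ------
    FormatError
        Malformed header, unparseable variant column, or a dosage cell
        outside {0, 1, 2, NA}.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    header = tuple(df.columns[:6])
    if header != RAW_HEADER_PREFIX:
        raise FormatError(
            f"{path}: header must begin {' '.join(RAW_HEADER_PREFIX)}, got {' '.join(header)}"
        )
    variant_cols = list(df.columns[6:])
    variants = []
    for name in variant_cols:
        if variant_annotation is not None:
            var_id, _, counted = name.rpartition("_")
            if var_id in variant_annotation:
                vk = variant_annotation[var_id]
                if counted not in (vk.ref_allele, vk.alt_allele):
                    raise FormatError(
                        f"variant column {name!r}: counted allele {counted!r} "
                        f"is neither ref nor alt of annotated {vk}"
                    )
                variants.append((vk, counted))
                continue
        variants.append(_parse_variant_column(name))

    samples = df["IID"].tolist()
    dosages = np.full((len(samples), len(variant_cols)), np.nan)
    for j, col in enumerate(variant_cols):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            s = str(cell).strip()
            if s.upper() == "NA" or s == "":
                continue
            if s not in ("0", "1", "2", "0.0", "1.0", "2.0"):
                raise FormatError(
                    f"{path}: row {i}, column {col!r}: dosage {s!r} not in {{0, 1, 2, NA}}"
                )
            dosages[i, j] = float(s)
    return DosageCallset(technology, samples, variants, dosages)


def dosage_from_genotype(genotype: str, a_is_ref: bool, counted_allele_is_alt: bool) -> int:
    """Copies of the counted allele implied by an Illumina AA/AB/BB genotype.

    The genotype letters count Illumina's A/B probe alleles, not ref/alt:
    AA has zero copies of allele B, AB one, BB two.  ``a_is_ref`` says
    whether probe allele A is the reference allele; the B-copy count is
    then converted to copies of whichever allele the .raw file counts.
    """
    b_copies = {"AA": 0, "AB": 1, "BB": 2}.get(genotype)
    if b_copies is None:
        raise ValueError(f"genotype must be AA/AB/BB, got {genotype!r}")
    alt_copies = b_copies if a_is_ref else 2 - b_copies
    return alt_copies if counted_allele_is_alt else 2 - alt_copies


def write_raw(callset: DosageCallset, path) -> None:
    """Write a callset back to the PLINK .raw text layout (NA for missing)."""
    path = Path(path)
    cols = [f"{vk}_{counted}" for vk, counted in callset.variants]
    with open(path, "w") as fh:
        fh.write(" ".join(RAW_HEADER_PREFIX) + " " + " ".join(cols) + "\n")
        for i, sample in enumerate(callset.samples):
            row = [sample, sample, "0", "0", "0", "-9"]
            for j in range(len(cols)):
                d = callset.dosages[i, j]
                row.append("NA" if math.isnan(d) else str(int(d)))
            fh.write(" ".join(row) + "\n")
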