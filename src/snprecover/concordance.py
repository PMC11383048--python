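"""Match array genotypes to reference callsets and compute concordance.

Array calls (Gencall or neural-network predictions) are compared to
imputed and/or whole-genome-sequencing dosage callsets.  Matching is
exact: the sample id must be identical and the variant must agree on all
of chromosome, position, ref allele, and alt allele — no strand or allele
flipping.  Concordance is discrete alt-allele dosage equality (0/1/2);
no-call array genotypes and missing reference dosages never enter a
denominator.

A SNP is "high-performing" when its concordance rate with every
*available* reference technology reaches the threshold (default 90%);
a technology with no matched calls does not veto.  Recovered concordant
no-calls feed a per-SNP call-rate recalculation.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedResultError
from .plink_raw_io import DosageCallset, dosage_from_genotype
from .snp_metrics_io import GENOTYPE_CLASSES, SnpMetricsRecord, VariantKey


@dataclass
class MatchedCall:
    """One array call joined to its reference dosages.

    ``array_dosage`` and the values of ``reference_dosages`` are
    alt-allele copy counts in {0, 1, 2}; a technology missing this cell is
    simply absent from the dict.
    """

    sample_id: str
    variant: VariantKey
    array_dosage: int
    reference_dosages: dict  # technology -> dosage; at least one present

    def __post_init__(self):
        if not self.reference_dosages:
            raise ValueError("a MatchedCall needs at least one reference dosage")


@dataclass
class ConcordanceRow:
    """Per-SNP concordance against each technology plus summary statistics."""

    variant: VariantKey
    n_matched: dict = field(default_factory=dict)      # technology -> int
    n_concordant: dict = field(default_factory=dict)   # technology -> int
    rate: dict = field(default_factory=dict)           # technology -> float | None
    summary_n: int = 0
    summary_concordant: int = 0
    summary_rate: Optional[float] = None
    high_performing: Optional[bool] = None
    recovered_call_count: int = 0
    original_call_rate: Optional[float] = None
    recalculated_call_rate: Optional[float] = None
    gentrain: Optional[float] = None
    gp2_status: str = "untracked"


@dataclass
class MatchReport:
    """Matching output plus bookkeeping on what failed to match and why."""

    matched: list                      # of MatchedCall
    unmatched_variants: dict           # VariantKey -> reason string
    n_calls_in: int = 0
    n_calls_matched: int = 0


def match_calls(
    array_calls: Sequence[SnpMetricsRecord],
    callsets: Sequence[DosageCallset],
    genotypes: Optional[Sequence[str]] = None,
    allele_info: Optional[dict] = None,
) -> MatchReport:
    """Join array calls to reference callsets by exact sample + variant key.

    Parameters
    ----------
    array_calls : records
        The array observations to validate.
    callsets : DosageCallsets
        One per reference technology (technology labels must be distinct).
    genotypes : optional
        Per-record genotype overriding ``record.genotype`` — pass the
        neural-network predictions here when validating recovered
        no-calls.  AA/AB/BB only; NC records must be overridden or they
        are skipped.
    allele_info : optional
        ``{VariantKey: a_is_ref}``; defaults to each record's own flag.

    A call is emitted once per record that has at least one reference
    dosage present.  Variants that never match are reported with a reason:
    "allele mismatch" (same chrom:pos exists with different alleles),
    "no variant match", or "no sample overlap".
    """
    techs = [cs.technology for cs in callsets]
    if len(set(techs)) != len(techs):
        raise ValueError(f"duplicate technology labels: {techs}")
    lookups = {cs.technology: cs.lookup() for cs in callsets}
    ref_variants: set[VariantKey] = set()
    ref_positions: set[tuple[str, int]] = set()
    ref_samples: dict[str, set] = {}
    for cs in callsets:
        for vk, _ in cs.variants:
            ref_variants.add(vk)
            ref_positions.add((vk.chromosome, vk.position))
        ref_samples[cs.technology] = set(cs.samples)

    matched: list[MatchedCall] = []
    seen_variants: dict[VariantKey, bool] = {}
    n_in = 0
    for i, rec in enumerate(array_calls):
        gt = genotypes[i] if genotypes is not None else rec.genotype
        if gt not in GENOTYPE_CLASSES:
            continue  # NC / missing array genotypes never enter a comparison
        n_in += 1
        a_is_ref = (
            allele_info[rec.variant] if allele_info is not None else rec.a_is_ref
        )
        dosage = dosage_from_genotype(gt, a_is_ref, counted_allele_is_alt=True)
        refs = {}
        for tech, table in lookups.items():
            d = table.get((rec.sample_id, rec.variant))
            if d is not None:
                refs[tech] = d
        seen_variants.setdefault(rec.variant, False)
        if refs:
            matched.append(MatchedCall(rec.sample_id, rec.variant, dosage, refs))
            seen_variants[rec.variant] = True

    unmatched = {}
    for vk, ok in seen_variants.items():
        if ok:
            continue
        if vk not in ref_variants:
            if (vk.chromosome, vk.position) in ref_positions:
                unmatched[vk] = "allele mismatch"
            else:
                unmatched[vk] = "no variant match"
        else:
            unmatched[vk] = "no sample overlap"
    return MatchReport(matched, unmatched, n_calls_in=n_in, n_calls_matched=len(matched))


def snp_concordance(matched: Sequence[MatchedCall]) -> list[ConcordanceRow]:
    """Per-SNP concordance rates against each technology plus the summary.

    Per technology the rate is n_concordant / n_matched over calls where
    that technology has a dosage; the summary rate counts a call
    concordant if it equals *any* present reference dosage.  Rates with an
    empty denominator are reported as None, never 0.  Rows are sorted by
    chromosome then position.
    """
    rows: dict[VariantKey, ConcordanceRow] = {}
    for call in matched:
        row = rows.setdefault(call.variant, ConcordanceRow(call.variant))
        any_match = False
        for tech, d in call.reference_dosages.items():
            row.n_matched[tech] = row.n_matched.get(tech, 0) + 1
            if d == call.array_dosage:
                row.n_concordant[tech] = row.n_concordant.get(tech, 0) + 1
                any_match = True
            else:
                row.n_concordant.setdefault(tech, 0)
        row.summary_n += 1
        if any_match:
            row.summary_concordant += 1
    for row in rows.values():
        for tech, n in row.n_matched.items():
            row.rate[tech] = row.n_concordant[tech] / n if n else None
        row.summary_rate = (
            row.summary_concordant / row.summary_n if row.summary_n else None
        )
    return sorted(rows.values(), key=lambda r: _variant_sort_key(r.variant))


def _variant_sort_key(vk: VariantKey):
    m = re.match(r"(?:chr)?(\d+|X|Y|MT?)$", vk.chromosome, flags=re.IGNORECASE)
    if m:
        token = m.group(1).upper()
        num = int(token) if token.isdigit() else {"X": 23, "Y": 24, "M": 25, "MT": 25}[token]
    else:
        num = 99
    return (num, vk.chromosome, vk.position, vk.ref_allele, vk.alt_allele)


def classify_high_performing(
    rows: Sequence[ConcordanceRow], threshold: float = 0.90
) -> list[ConcordanceRow]:
    """Set ``high_performing`` per row: every available technology rate
    must reach ``threshold``; a technology with no matched calls does not
    veto, but a SNP with no rates at all is not high-performing."""
    for row in rows:
        available = [r for r in row.rate.values() if r is not None]
        row.high_performing = bool(available) and all(r >= threshold for r in available)
    return list(rows)


def recalculate_call_rate(
    original_calls: int, original_total: int, recovered_concordant: int
) -> float:
    """Call rate after folding recovered, reference-concordant no-calls in.

    ``(original_calls + recovered_concordant) / original_total``; always
    at least the original call rate and at most 1.
    """
    if original_total <= 0:
        raise ValueError("original_total must be positive")
    if not (0 <= original_calls <= original_total):
        raise ValueError("original_calls must lie in [0, original_total]")
    if not (0 <= recovered_concordant <= original_total - original_calls):
        raise ValueError(
            "recovered_concordant cannot exceed the original no-call count"
        )
    return (original_calls + recovered_concordant) / original_total


def gentrain_correlation(pairs: Sequence[tuple]) -> tuple[float, int]:
    """Pearson r between per-SNP GenTrain scores and concordance rates.

    Pairs with a missing member are dropped; returns ``(r, n_used)``.
    Raises :class:`UndefinedResultError` with fewer than 3 complete pairs
    or zero variance in either coordinate.
    """
    clean = [(g, c) for g, c in pairs if g is not None and c is not None
             and not (math.isnan(g) or math.isnan(c))]
    n = len(clean)
    if n < 3:
        raise UndefinedResultError(f"need >= 3 complete pairs, got {n}")
    x = np.array([p[0] for p in clean])
    y = np.array([p[1] for p in clean])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("zero variance in GenTrain or concordance values")
    return float(np.corrcoef(x, y)[0, 1]), n


# ---------------------------------------------------------------------------
# Mann-Whitney U (included vs excluded SNP groups)

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first group, from midranks (ties averaged)."""
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def compare_groups(
    included: Sequence[float], excluded: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two groups of summary rates.

    Returns ``(U, p)`` where U is the statistic of the *first* group
    (so {1,2,3} vs {4,5,6} gives U = 0).  With both groups of size
    ``<= exact_max_n`` the p-value is computed by full enumeration of the
    label assignments (valid under ties via midranks); otherwise the
    normal approximation with tie correction is used.
    """
    x = np.asarray(list(included), dtype=float)
    y = np.asarray(list(excluded), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 <= exact_max_n and n2 <= exact_max_n:
        combined = np.concatenate([x, y])
        idx = range(n1 + n2)
        extreme = 0
        total = 0
        obs_dev = abs(u_obs - mu)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(combined[mask], combined[~mask])
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        return float(u_obs), extreme / total

    # Normal approximation with tie correction
    combined = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return float(u_obs), 1.0  # all values tied: no evidence of difference
    z = (u_obs - mu) / math.sqrt(sigma2)
    # two-sided p via the normal survival function
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return float(u_obs), min(1.0, p)


# ---------------------------------------------------------------------------
# report assembly and export

def attach_call_rates(
    rows: Sequence[ConcordanceRow],
    original_calls: dict,
    original_totals: dict,
    recovered_concordant: dict,
) -> list[ConcordanceRow]:
    """Fill per-SNP original/recalculated call rates onto report rows.

    The three dicts map VariantKey to the original non-NC call count, the
    total sample count, and the number of recovered no-calls concordant
    with at least one reference.
    """
    for row in rows:
        vk = row.variant
        if vk not in original_totals:
            continue
        calls = original_calls.get(vk, 0)
        total = original_totals[vk]
        rec = recovered_concordant.get(vk, 0)
        rec = min(rec, total - calls)
        row.original_call_rate = calls / total if total else None
        row.recovered_call_count = rec
        row.recalculated_call_rate = recalculate_call_rate(calls, total, rec)
    return list(rows)


def report_to_tsv(rows: Sequence[ConcordanceRow], path,
                  technologies: Sequence[str] = ("imputed", "wgs")) -> None:
    """Write the per-SNP concordance report as TSV, one row per variant."""
    cols = ["chromosome", "position", "ref", "alt"]
    for tech in technologies:
        cols += [f"{tech}_n", f"{tech}_concordant", f"{tech}_rate"]
    cols += ["summary_n", "summary_concordant", "summary_rate", "high_performing",
             "recovered_call_count", "original_call_rate", "recalculated_call_rate",
             "gentrain", "gp2_status"]

    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            vals = [row.variant.chromosome, row.variant.position,
                    row.variant.ref_allele, row.variant.alt_allele]
            for tech in technologies:
                vals += [row.n_matched.get(tech, 0), row.n_concordant.get(tech, 0),
                         row.rate.get(tech)]
            vals += [row.summary_n, row.summary_concordant, row.summary_rate,
                     row.high_performing, row.recovered_call_count,
                     row.original_call_rate, row.recalculated_call_rate,
                     row.gentrain, row.gp2_status]
            fh.write("\t".join(fmt(v) for v in vals) + "\n")
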