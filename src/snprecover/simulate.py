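"""Synthetic SNP-metrics and reference-callset fixtures with known truth.

The generator emulates a multi-ancestry array experiment: samples are
drawn in ancestry strata (default 11 strata of 44 samples, 484 total),
each SNP gets a minor-allele frequency, genotypes follow Hardy-Weinberg
proportions (p^2, 2pq, q^2), and each genotype class emits (Theta, R)
points from its own cluster — Theta centroids near 0 / 0.5 / 1 for
AA / AB / BB with per-SNP jitter and Gaussian noise, R from a gamma
distribution.  The Gencall genotype equals the truth except where the
no-call mechanism fires (more likely far from a centroid or at low R),
and a GenTrain-like score decreases with cluster overlap.  A configurable
fraction of SNPs is planted as "non-clustering": all their genotypes draw
from one overlapping cloud, the failure mode the cluster-geometry flags
must catch.

Every fixture ships its generating truth (per-record genotypes, per-SNP
parameters) so downstream tests never re-infer ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .plink_raw_io import DosageCallset, dosage_from_genotype, write_raw
from .snp_metrics_io import GENOTYPE_CLASSES, NO_CALL, SnpMetricsRecord, VariantKey

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic array panel.

    The defaults describe the study conditions this package targets: 11
    ancestry strata x 44 samples, well-formed genotype clusters with Theta
    centroids 0.05 / 0.50 / 0.95 and noise sd 0.03, gamma-distributed R
    with mean 1, a 3% no-call rate concentrated on ambiguous/low-intensity
    points, and a 1% per-record field-missingness rate.
    """

    n_snps: int = 100
    n_strata: int = 11                 # ancestry stand-ins
    samples_per_stratum: int = 44
    maf_range: tuple = (0.05, 0.5)     # uniform draw per SNP
    centroid_template: tuple = (0.05, 0.50, 0.95)  # Theta for AA, AB, BB
    centroid_jitter_sd: float = 0.01   # per-SNP, per-class Theta jitter
    theta_noise_sd: float = 0.03
    r_mean: tuple = (1.0, 1.0, 1.0)    # per-class gamma mean
    r_shape: float = 200.0             # gamma shape (sd = mean/sqrt(shape))
    ancestry_offset_sd: float = 0.0    # per-stratum Theta shift; off by default
    nc_probability: float = 0.03       # marginal no-call rate
    nc_dist_midpoint: float = 0.06     # logistic midpoint on |theta - centroid|
    nc_dist_scale: float = 0.02
    nc_dist_weight: float = 4.0
    nc_low_r_floor: float = 0.4
    nc_low_r_weight: float = 4.0
    noncluster_fraction: float = 0.0   # planted non-clustering SNPs
    noncluster_cloud_sd: float = 0.15  # their single-cloud Theta sd
    missingness_rate: float = 0.01     # P(record has a metrics field blanked)
    gentrain_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for p in (self.nc_probability, self.noncluster_fraction, self.missingness_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for s in (self.centroid_jitter_sd, self.theta_noise_sd,
                  self.ancestry_offset_sd, self.gentrain_noise_sd):
            if s < 0:
                raise ValueError(f"standard deviation {s} must be >= 0")
        if self.n_snps < 1 or self.n_strata < 1 or self.samples_per_stratum < 1:
            raise ValueError("counts must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_strata * self.samples_per_stratum


@dataclass
class SimulatedPanel:
    """A generated panel plus its full bookkeeping.

    ``records`` is the observable data (what a metrics file would hold);
    ``truth_genotypes`` is the generating genotype per record (never NC);
    ``snp_params`` is a per-SNP DataFrame of generating parameters
    including planted non-clustering status.
    """

    records: list                    # of SnpMetricsRecord
    truth_genotypes: list            # of "AA"/"AB"/"BB", parallel to records
    snp_params: pd.DataFrame
    config: SimulationConfig

    @property
    def truth_lookup(self) -> dict:
        """{(sample_id, snp_id): truth genotype}."""
        return {
            (rec.sample_id, rec.snp_id): g
            for rec, g in zip(self.records, self.truth_genotypes)
        }


def _draw_variants(rng: np.random.Generator, n_snps: int) -> list[VariantKey]:
    chroms = rng.integers(1, 23, size=n_snps)
    positions = set()
    while len(positions) < n_snps:
        positions.update(rng.integers(1, 200_000_000, size=n_snps * 2).tolist())
    pos = sorted(positions)[:n_snps]
    variants = []
    for c, p in zip(chroms, pos):
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(VariantKey(f"chr{c}", int(p), str(_BASES[ref]), str(_BASES[alt])))
    return variants


def simulate_panel(config: Optional[SimulationConfig] = None) -> SimulatedPanel:
    """Generate a full synthetic panel (records + truth), deterministically.

    Per SNP: MAF ~ U(maf_range); per sample: genotype ~ HWE(p^2, 2pq, q^2)
    with q the alt-allele (allele B) frequency; (Theta, R) from the
    genotype's cluster; Gencall genotype = truth except where the no-call
    mechanism fires.  The no-call mechanism is weight-based — a logistic
    term in distance from the nearest centroid plus a low-R bonus —
    normalized so the marginal no-call rate equals ``nc_probability``.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    variants = _draw_variants(rng, cfg.n_snps)
    sample_ids = [
        f"GP2-{s:02d}-{i:04d}"
        for s in range(cfg.n_strata)
        for i in range(cfg.samples_per_stratum)
    ]
    strata = np.repeat(np.arange(cfg.n_strata), cfg.samples_per_stratum)
    stratum_offsets = (
        rng.normal(0.0, cfg.ancestry_offset_sd, size=cfg.n_strata)
        if cfg.ancestry_offset_sd > 0 else np.zeros(cfg.n_strata)
    )

    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    n_noncluster = int(round(cfg.noncluster_fraction * cfg.n_snps))
    noncluster = np.zeros(cfg.n_snps, dtype=bool)
    if n_noncluster:
        noncluster[rng.choice(cfg.n_snps, size=n_noncluster, replace=False)] = True

    template = np.asarray(cfg.centroid_template, dtype=float)
    centroids = template[None, :] + rng.normal(
        0.0, cfg.centroid_jitter_sd, size=(cfg.n_snps, 3)
    )
    centroids = np.clip(np.sort(centroids, axis=1), 0.005, 0.995)

    records: list[SnpMetricsRecord] = []
    truth: list[str] = []
    snp_rows = []
    n_samples = cfg.n_samples
    r_means = np.asarray(cfg.r_mean, dtype=float)

    for j, vk in enumerate(variants):
        snp_id = str(vk)
        q = mafs[j]
        geno_idx = rng.choice(
            3, size=n_samples, p=((1 - q) ** 2, 2 * q * (1 - q), q ** 2)
        )
        if noncluster[j]:
            theta = rng.normal(0.5, cfg.noncluster_cloud_sd, size=n_samples)
            sep = 0.0
        else:
            theta = centroids[j, geno_idx] + rng.normal(
                0.0, cfg.theta_noise_sd, size=n_samples
            )
            theta = theta + stratum_offsets[strata]
            sep = float(np.diff(centroids[j]).min())
        theta = np.clip(theta, 0.0, 1.0)
        mean_r = r_means[geno_idx]
        r = rng.gamma(cfg.r_shape, mean_r / cfg.r_shape, size=n_samples)

        # GenTrain-like score: decreasing in cluster overlap (separation in
        # noise-sd units), noisy, clipped to [0, 1].
        z = sep / max(cfg.theta_noise_sd, 1e-9)
        gentrain_base = 1.0 - math.exp(-z / 6.0)
        gentrain = np.clip(
            gentrain_base + rng.normal(0.0, cfg.gentrain_noise_sd, size=n_samples), 0, 1
        )

        # No-call weights: ambiguous Theta (far from every centroid) and low R.
        if noncluster[j]:
            dist = np.abs(theta - 0.5)
        else:
            dist = np.abs(theta[:, None] - centroids[j][None, :]).min(axis=1)
        w = (
            1.0
            + cfg.nc_dist_weight * expit((dist - cfg.nc_dist_midpoint) / cfg.nc_dist_scale)
            + cfg.nc_low_r_weight * (r < cfg.nc_low_r_floor)
        )
        p_nc = np.clip(cfg.nc_probability * w / w.mean(), 0.0, 1.0)
        is_nc = rng.random(n_samples) < p_nc

        # Field-level missingness: a fraction of records lose one of the
        # four required metrics fields.
        miss = rng.random(n_samples) < cfg.missingness_rate
        miss_field = rng.integers(0, 4, size=n_samples)

        for i in range(n_samples):
            g_true = GENOTYPE_CLASSES[geno_idx[i]]
            gt = NO_CALL if is_nc[i] else g_true
            rec_r: Optional[float] = float(r[i])
            rec_theta: Optional[float] = float(theta[i])
            rec_gentrain: Optional[float] = float(gentrain[i])
            rec_gt: Optional[str] = gt
            if miss[i]:
                f = miss_field[i]
                if f == 0:
                    rec_gentrain = None
                elif f == 1:
                    rec_r = None
                elif f == 2:
                    rec_theta = None
                else:
                    rec_gt = None
            records.append(
                SnpMetricsRecord(
                    sample_id=sample_ids[i], snp_id=snp_id, variant=vk,
                    r=rec_r, theta=rec_theta, gentrain=rec_gentrain,
                    genotype=rec_gt, a_is_ref=True,
                )
            )
            truth.append(g_true)

        snp_rows.append({
            "snp_id": snp_id, "chromosome": vk.chromosome, "position": vk.position,
            "ref": vk.ref_allele, "alt": vk.alt_allele, "maf": q,
            "centroid_AA": centroids[j, 0], "centroid_AB": centroids[j, 1],
            "centroid_BB": centroids[j, 2], "theta_noise_sd": cfg.theta_noise_sd,
            "non_clustering": bool(noncluster[j]), "gentrain_base": gentrain_base,
        })

    return SimulatedPanel(records, truth, pd.DataFrame(snp_rows), cfg)


def simulate_reference_callsets(
    panel: SimulatedPanel,
    error_rates: Optional[dict] = None,
    sample_overlap: float = 1.0,
    variant_overlap: float = 1.0,
    seed: int = 0,
) -> dict:
    """Imputed/WGS truth sets with injectable error, as DosageCallsets.

    Each technology's dosage starts from the planted truth genotype
    (alt-allele copies; the panel uses a_is_ref=True so B == alt) and is
    flipped, with its error rate, to a uniformly random *different*
    dosage — so the expected discordance against a perfect array call
    equals the error rate exactly.  Sample and variant overlap with the
    array are thinned to the given fractions.
    """
    if error_rates is None:
        error_rates = {"imputed": 0.0, "wgs": 0.0}
    for tech, e in error_rates.items():
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"{tech} error rate {e} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))

    all_samples = sorted({rec.sample_id for rec in panel.records})
    snp_params = panel.snp_params
    all_variants = [
        VariantKey(row.chromosome, int(row.position), row.ref, row.alt)
        for row in snp_params.itertuples(index=False)
    ]
    truth = panel.truth_lookup

    callsets = {}
    for tech, err in error_rates.items():
        n_s = int(round(sample_overlap * len(all_samples)))
        n_v = int(round(variant_overlap * len(all_variants)))
        s_idx = sorted(rng.choice(len(all_samples), size=n_s, replace=False))
        v_idx = sorted(rng.choice(len(all_variants), size=n_v, replace=False))
        samples = [all_samples[i] for i in s_idx]
        variants = [(all_variants[i], all_variants[i].alt_allele) for i in v_idx]
        dosages = np.full((n_s, n_v), np.nan)
        for jj, (vk, _) in enumerate(variants):
            snp_id = str(vk)
            for ii, sample in enumerate(samples):
                g = truth.get((sample, snp_id))
                if g is None:
                    continue
                d = dosage_from_genotype(g, a_is_ref=True, counted_allele_is_alt=True)
                if err > 0 and rng.random() < err:
                    d = int(rng.choice([x for x in (0, 1, 2) if x != d]))
                dosages[ii, jj] = d
        callsets[tech] = DosageCallset(tech, samples, variants, dosages)
    return callsets


def write_snp_metrics(records: Sequence[SnpMetricsRecord], path,
                      fmt: Optional[str] = None) -> None:
    """Write records to a metrics file (parquet or CSV/TSV by extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "parquet" if path.suffix == ".parquet" else (
            "tsv" if path.suffix in (".tsv", ".txt") else "csv")
    df = pd.DataFrame({
        "sampleID": [r.sample_id for r in records],
        "snpID": [r.snp_id for r in records],
        "chromosome": [r.variant.chromosome for r in records],
        "position": [r.variant.position for r in records],
        "Ref": [r.variant.ref_allele for r in records],
        "Alt": [r.variant.alt_allele for r in records],
        "R": [r.r for r in records],
        "Theta": [r.theta for r in records],
        "GenTrain_Score": [r.gentrain for r in records],
        "GT": [r.genotype for r in records],
        "a_is_ref": [r.a_is_ref for r in records],
    })
    if fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False, na_rep="NA")


__all__ = [
    "SimulationConfig", "SimulatedPanel", "simulate_panel",
    "simulate_reference_callsets", "write_snp_metrics", "write_raw",
]
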