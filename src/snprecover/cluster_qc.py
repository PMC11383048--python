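"""Per-genotype cluster geometry in (Theta, R) space and non-clustering flags.

A SNP that genotypes well on the array shows three tight clusters in the
(Theta, R) plane: homozygotes near Theta 0 and 1, heterozygotes near 0.5,
all at healthy intensity R.  Given any trusted genotype labelling of the
points (imputed genotypes in normal use, but the operations are agnostic
to the label source), this module computes each genotype class's centroid
and width and flags SNPs whose geometry makes them unsuitable for
cluster-based calling: clusters too wide, centroids too close in Theta,
or centroids at very low R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .snp_metrics_io import GENOTYPE_CLASSES, VariantKey


@dataclass
class QcThresholds:
    """Flagging thresholds (Theta is unitless in [0,1]; R in intensity units).

    Defaults reflect the geometry of a clean SNP — homozygote centroids
    near Theta 0 and 1 with cluster spread well under 0.1 — and are all
    configurable; treat them as starting points, not calibrated constants.
    """

    w_max: float = 0.10    # max cluster RMS width
    d_min: float = 0.10    # min pairwise centroid separation in Theta
    r_min: float = 0.20    # min centroid R coordinate
    n_min: int = 3         # min points per class for a trustworthy geometry


@dataclass
class ClusterGeometry:
    """Per-class centroids and widths for one SNP.

    ``centroids[g]`` is a (theta, r) pair; ``widths[g]`` is the
    root-mean-square Euclidean distance of class g's points to its
    centroid (0 for a single-point cluster).  ``theta_separations`` holds
    |centroid theta difference| for every present class pair.
    """

    n: dict = field(default_factory=dict)                  # class -> count
    centroids: dict = field(default_factory=dict)          # class -> (theta, r)
    widths: dict = field(default_factory=dict)             # class -> float
    theta_separations: dict = field(default_factory=dict)  # (g1, g2) -> float
    min_centroid_r: Optional[float] = None

    @property
    def present_classes(self) -> list:
        return [g for g in GENOTYPE_CLASSES if g in self.centroids]


@dataclass
class FlagRow:
    """Flag outcome for one SNP."""

    variant: Optional[VariantKey]
    flags: set = field(default_factory=set)
    flagged: bool = False
    geometry: Optional[ClusterGeometry] = None


def compute_geometry(
    points: Sequence[tuple],
    labels: Sequence[str],
    width_metric: str = "rms",
) -> ClusterGeometry:
    """Centroid and width of each genotype cluster.

    Parameters
    ----------
    points : sequence of (theta, r)
    labels : genotype per point, each in {AA, AB, BB}
    width_metric : {"rms", "per_axis_sd"}
        "rms" (default) is the root-mean-square Euclidean distance to the
        centroid; "per_axis_sd" instead reports
        sqrt(sd_theta^2 + sd_r^2) with ddof=0, which coincides with RMS —
        it exists so per-axis spreads can be inspected on the geometry.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("compute_geometry needs at least one point")
    labels = list(labels)
    if len(labels) != len(pts):
        raise ValueError("points and labels differ in length")
    bad = set(labels) - set(GENOTYPE_CLASSES)
    if bad:
        raise ValueError(f"labels must be AA/AB/BB, got {sorted(bad)}")

    geom = ClusterGeometry()
    lab = np.asarray(labels)
    for g in GENOTYPE_CLASSES:
        mask = lab == g
        if not mask.any():
            continue
        cluster = pts[mask]
        centroid = cluster.mean(axis=0)
        diffs = cluster - centroid
        if width_metric == "rms":
            width = float(np.sqrt((diffs ** 2).sum(axis=1).mean()))
        elif width_metric == "per_axis_sd":
            width = float(np.sqrt((diffs.std(axis=0, ddof=0) ** 2).sum()))
        else:
            raise ValueError(f"unknown width metric {width_metric!r}")
        geom.n[g] = int(mask.sum())
        geom.centroids[g] = (float(centroid[0]), float(centroid[1]))
        geom.widths[g] = width
    present = geom.present_classes
    for i, g1 in enumerate(present):
        for g2 in present[i + 1 :]:
            geom.theta_separations[(g1, g2)] = abs(
                geom.centroids[g1][0] - geom.centroids[g2][0]
            )
    geom.min_centroid_r = min(geom.centroids[g][1] for g in present)
    return geom


def flag_snp(
    geometry: ClusterGeometry,
    thresholds: Optional[QcThresholds] = None,
    variant: Optional[VariantKey] = None,
) -> FlagRow:
    """Flag a SNP for non-clustering behavior.

    Flags: ``too_wide`` (any present class width > w_max),
    ``centroids_too_close`` (any pairwise Theta separation < d_min),
    ``low_r_centroid`` (lowest centroid R < r_min), and
    ``insufficient_data`` (every present class has fewer than n_min
    points).  ``flagged`` — the exclusion recommendation — is True iff any
    geometric flag is set; insufficient_data alone never excludes.
    """
    th = thresholds or QcThresholds()
    flags = set()
    if any(w > th.w_max for w in geometry.widths.values()):
        flags.add("too_wide")
    if any(d < th.d_min for d in geometry.theta_separations.values()):
        flags.add("centroids_too_close")
    if geometry.min_centroid_r is not None and geometry.min_centroid_r < th.r_min:
        flags.add("low_r_centroid")
    if geometry.n and all(n < th.n_min for n in geometry.n.values()):
        flags.add("insufficient_data")
    flagged = bool(flags - {"insufficient_data"})
    return FlagRow(variant=variant, flags=flags, flagged=flagged, geometry=geometry)


def flag_report_to_tsv(rows: Sequence[FlagRow], path) -> None:
    """Write per-SNP geometry and flags as TSV."""
    cols = ["chromosome", "position", "ref", "alt"]
    for g in GENOTYPE_CLASSES:
        cols += [f"{g}_n", f"{g}_theta", f"{g}_r", f"{g}_width"]
    cols += ["min_separation", "min_centroid_r", "flags", "flagged"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            geom = row.geometry
            vals = (
                [row.variant.chromosome, row.variant.position,
                 row.variant.ref_allele, row.variant.alt_allele]
                if row.variant is not None else ["NA"] * 4
            )
            for g in GENOTYPE_CLASSES:
                if geom is not None and g in geom.centroids:
                    vals += [geom.n[g], f"{geom.centroids[g][0]:.6g}",
                             f"{geom.centroids[g][1]:.6g}", f"{geom.widths[g]:.6g}"]
                else:
                    vals += ["0", "NA", "NA", "NA"]
            seps = list(geom.theta_separations.values()) if geom is not None else []
            vals += [f"{min(seps):.6g}" if seps else "NA",
                     f"{geom.min_centroid_r:.6g}" if geom is not None else "NA",
                     ",".join(sorted(row.flags)) or "none", str(row.flagged)]
            fh.write("\t".join(str(v) for v in vals) + "\n")
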