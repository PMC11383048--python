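"""Cluster plots: per-SNP (Theta, R) scatter colored by genotype.

The fixed palette keeps figures comparable across SNPs and genotype
sources: AA blue, AB green, BB red, NC grey.  An optional semi-transparent
background layer of a second genotype source (typically the valid Gencall
calls) sits under each panel, and up to three genotype layers render as
side-by-side panels sharing axes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .snp_metrics_io import SnpMetricsRecord, VariantKey

#: Fixed genotype palette (documented for cross-figure comparability).
PALETTE = {"AA": "#1f77b4", "AB": "#2ca02c", "BB": "#d62728", "NC": "#7f7f7f"}


def plot_snp_clusters(
    variant: VariantKey,
    records: Sequence[SnpMetricsRecord],
    genotype_layers: dict,
    out_path,
    background_layer: Optional[str] = None,
    dpi: int = 120,
) -> Path:
    """Render up to three genotype layers for one SNP as scatter panels.

    Parameters
    ----------
    variant : VariantKey
        The SNP to plot; records for other variants are an error.
    records : SnpMetricsRecords
        Observations carrying the (Theta, R) coordinates.
    genotype_layers : dict
        ``{source_name: [genotype per record]}``, 1-3 entries; each list is
        parallel to ``records`` (values in AA/AB/BB/NC, None to omit a point).
    background_layer : str, optional
        Name of a layer to draw semi-transparently behind every panel.
    """
    matching = [r for r in records if r.variant == variant]
    if not matching:
        available = sorted({str(r.variant) for r in records})
        raise ValueError(
            f"no records for {variant}; available variants: {', '.join(available[:20])}"
        )
    if not (1 <= len(genotype_layers) <= 3):
        raise ValueError("genotype_layers must contain 1-3 sources")
    for name, layer in genotype_layers.items():
        if len(layer) != len(records):
            raise ValueError(f"layer {name!r} length differs from records")

    keep = [i for i, r in enumerate(records) if r.variant == variant
            and r.theta is not None and r.r is not None]
    thetas = [records[i].theta for i in keep]
    rs = [records[i].r for i in keep]

    panels = [k for k in genotype_layers if k != background_layer] or list(genotype_layers)
    fig, axes = plt.subplots(
        1, len(panels), figsize=(4.2 * len(panels), 3.6),
        sharex=True, sharey=True, squeeze=False,
    )
    for ax, name in zip(axes[0], panels):
        if background_layer is not None and background_layer in genotype_layers:
            bg = genotype_layers[background_layer]
            for g, color in PALETTE.items():
                xs = [thetas[k] for k, i in enumerate(keep) if bg[i] == g]
                ys = [rs[k] for k, i in enumerate(keep) if bg[i] == g]
                if xs:
                    ax.scatter(xs, ys, c=color, s=12, alpha=0.15, linewidths=0)
        layer = genotype_layers[name]
        for g, color in PALETTE.items():
            xs = [thetas[k] for k, i in enumerate(keep) if layer[i] == g]
            ys = [rs[k] for k, i in enumerate(keep) if layer[i] == g]
            if xs:
                ax.scatter(xs, ys, c=color, s=14, alpha=0.85, linewidths=0, label=g)
        ax.set_title(name)
        ax.set_xlabel("Theta")
        ax.set_xlim(-0.02, 1.02)
    axes[0][0].set_ylabel("R")
    axes[0][-1].legend(loc="upper right", fontsize=8, title="genotype")
    fig.suptitle(str(variant))
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=dpi, metadata=_deterministic_metadata(out_path))
    plt.close(fig)
    return out_path


def _deterministic_metadata(path: Path) -> Optional[dict]:
    # Strip writer/date metadata so identical inputs give identical bytes.
    suffix = path.suffix.lower()
    if suffix == ".png":
        return {"Software": None}
    if suffix == ".svg":
        return {"Date": None, "Creator": None}
    return None
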