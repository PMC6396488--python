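"""Optional diagnostic plots (headless; written as image files behind a flag)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dyad import DyadRecord
from .triad import GapResult


def plot_gd_scatter(gds: np.ndarray, gap: GapResult, path: str | Path, *, zoom: bool = True) -> None:
    """Ordered scatter of all triad GD values with the gap threshold line.

    With ``zoom`` a second panel restricts the y-axis to the MaxIdent
    region, where the gap separating true triads from spurious associations
    is visible.
    """
    g = np.sort(np.asarray(gds)[np.isfinite(gds)])
    n_panels = 2 if zoom and gap.determinable else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4), squeeze=False)
    for col, ax in enumerate(axes[0]):
        ax.scatter(np.arange(g.size), g, s=3, color="#3465a4", rasterized=True)
        if gap.determinable:
            ax.axhline(gap.threshold, color="crimson", lw=1,
                       label=f"threshold = {gap.threshold:.4g}")
            ax.legend(loc="upper left", fontsize=8)
        ax.set_xlabel("triad rank")
        ax.set_ylabel("Gower dissimilarity")
        if col == 1:
            ax.set_ylim(-0.005, gap.search_ceiling * 1.05)
            ax.set_xlim(-1, max(gap.n_in_region * 1.2, 5))
            ax.set_title(f"below MaxIdent = {gap.search_ceiling:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dyad_scores(records: list[DyadRecord], offspring_id: str, path: str | Path) -> None:
    """GDM and GDCV distributions for one offspring, reported pairs marked."""
    recs = [r for r in records if r.offspring_id == offspring_id]
    if not recs:
        raise ValueError(f"no dyad records for offspring {offspring_id!r}")
    gdm = np.array([r.gdm for r in recs])
    gdcv = np.array([r.gdcv for r in recs])
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for ax, vals, name in ((ax1, gdm, "GDM"), (ax2, gdcv, "GDCV")):
        finite = vals[np.isfinite(vals)]
        ax.hist(finite, bins=min(30, max(5, finite.size // 3)), color="#888", alpha=0.7)
        for r in recs:
            if r.stage1_flag and r.stage2_flag:
                v = r.gdm if name == "GDM" else r.gdcv
                ax.axvline(v, color="crimson", lw=1.2)
                ax.annotate(r.parent_id, (v, ax.get_ylim()[1] * 0.9),
                            rotation=90, fontsize=7, color="crimson")
        ax.set_xlabel(name)
        ax.set_ylabel("candidate parents")
    fig.suptitle(f"dyad statistics for offspring {offspring_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
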