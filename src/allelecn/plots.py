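"""Minimal diagnostic plot: log-ratio profile with fitted copy levels and
variant allelic fractions with their expected values."""

from __future__ import annotations

from typing import Optional


def plot_sample(result, path: Optional[str] = None):
    """Two-panel diagnostic figure for a pipeline RunResult.

    Top: segment mean log-ratios with the expected level for each assigned
    copy number at the fitted purity/ploidy. Bottom (if variants were fit):
    observed allelic fractions colored by ML somatic status, with the
    expected fraction of each variant's ML state.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from .cnfit import expected_log_ratio
    from .segmentation import SUBCLONAL

    best = result.best
    has_snv = result.variant_table is not None
    fig, axes = plt.subplots(
        2 if has_snv else 1, 1, figsize=(10, 6 if has_snv else 3.5), sharex=False
    )
    ax0 = axes[0] if has_snv else axes

    x0 = 0
    for si, seg in enumerate(result.segments):
        x1 = x0 + seg.num_targets
        ax0.hlines(seg.r + best.shift, x0, x1, color="0.3", lw=2)
        c = best.C[si]
        if c != SUBCLONAL and c is not None:
            mu = float(expected_log_ratio(best.purity, int(c), best.ploidy))
            ax0.hlines(mu, x0, x1, color="tab:red", lw=1, linestyle="--")
        x0 = x1
    ax0.axhline(0, color="0.8", lw=0.5)
    ax0.set_ylabel("log2 ratio")
    ax0.set_title(
        f"purity {best.purity:.2f}, ploidy {best.ploidy:.2f}"
        + (f", GoF {best.gof:.0f}%" if best.gof is not None else "")
    )

    if has_snv:
        tbl = result.variant_table
        ax1 = axes[1]
        som = tbl["ML.SOMATIC"].to_numpy()
        pos = np.arange(len(tbl))
        ax1.scatter(pos[~som], tbl["f"][~som], s=6, color="tab:blue", label="germline")
        ax1.scatter(pos[som], tbl["f"][som], s=6, color="tab:red", label="somatic")
        ax1.scatter(pos, tbl["expected_f"], s=3, color="0.5", marker="_", label="expected")
        ax1.set_ylim(0, 1)
        ax1.set_ylabel("allelic fraction")
        ax1.set_xlabel("variant index (genome order)")
        ax1.legend(loc="upper right", fontsize=8, markerscale=2)

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
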