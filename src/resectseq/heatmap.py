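"""Locally normalized, decile-classified hotspot heatmaps.

Each hotspot row shows strand-specific signal in 40-bp bins across a 4001-bp
window centered on the hotspot.  Rows are divided by the hotspot's own
combined-strand total inside the window, so every hotspot sums to 1 and color
reflects the local spatial pattern regardless of hotspot strength.  The
combined-strand total is pooled across strands so that strand asymmetry (the
double-cut signature) survives normalization.  Normalized values are then
classified into deciles of the pooled nonzero values across the whole heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_tracks import HotspotSet
from .profiles import AnalysisConfig, HotspotMatrix


@dataclass
class BinnedHeatmap:
    """Strand-specific binned heatmap, strongest hotspot first.

    ``top``/``bottom`` are ``(n_hotspots, n_bins)`` normalized values;
    ``classes_top``/``classes_bottom`` hold decile classes 1-10 after
    :func:`decile_classify`.  Hotspots with zero signal in the window are
    flagged in ``zero_total`` and left as all-zero rows.
    """

    hotspot_index: np.ndarray
    strengths: np.ndarray
    bin_edges: np.ndarray
    top: np.ndarray
    bottom: np.ndarray
    zero_total: np.ndarray
    classes_top: np.ndarray | None = None
    classes_bottom: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.top.shape[1]


def build_heatmap(matrix: HotspotMatrix, hotspots: HotspotSet, cfg: AnalysisConfig) -> BinnedHeatmap:
    """Bin strand-specific windows (40 bp) and normalize each hotspot to total 1.

    Strands are kept separate for display (the matrix must not be co-oriented).
    The 4001-bp window holds 100 full 40-bp bins plus one leftover position,
    which is absorbed into the last bin.
    """
    if matrix.co_oriented:
        raise ValidationError("heatmaps display strands separately; pass a non-co-oriented matrix")
    half = (cfg.heatmap_window - 1) // 2
    if half > matrix.half_width:
        raise ValidationError("heatmap window exceeds the stacked window")
    offsets = matrix.offsets
    sel = (offsets >= -half) & (offsets <= half)
    n_bins = cfg.heatmap_window // cfg.heatmap_bin
    binidx = np.minimum((offsets[sel] + half) // cfg.heatmap_bin, n_bins - 1)
    edges = np.concatenate([np.arange(-half, -half + n_bins * cfg.heatmap_bin,
                                      cfg.heatmap_bin), [half + 1]])

    def binrows(mat: np.ndarray) -> np.ndarray:
        out = np.zeros((mat.shape[0], n_bins))
        np.add.at(out.T, binidx, mat[:, sel].T)
        return out

    top = binrows(matrix.top)
    bottom = binrows(matrix.bottom)
    totals = top.sum(axis=1) + bottom.sum(axis=1)
    zero = totals <= 0
    denom = np.where(zero, 1.0, totals)
    top = top / denom[:, None]
    bottom = bottom / denom[:, None]

    strengths = hotspots.strengths[matrix.hotspot_index]
    order = np.argsort(-strengths, kind="stable")  # strongest at the top
    return BinnedHeatmap(
        hotspot_index=matrix.hotspot_index[order],
        strengths=strengths[order],
        bin_edges=edges,
        top=top[order],
        bottom=bottom[order],
        zero_total=zero[order],
    )


def decile_classify(heatmap: BinnedHeatmap) -> BinnedHeatmap:
    """Assign decile classes 1-10 over the pooled nonzero normalized values.

    A value tied with a decile boundary takes the higher class (so if every
    nonzero value is equal, all nonzero bins are class 10); zero bins are
    class 1.  Boundaries are global across the whole heatmap.
    """
    pooled = np.concatenate([heatmap.top.ravel(), heatmap.bottom.ravel()])
    nonzero = pooled[pooled > 0]
    if nonzero.size == 0:
        cls_top = np.ones_like(heatmap.top, dtype=np.int64)
        cls_bottom = np.ones_like(heatmap.bottom, dtype=np.int64)
    else:
        boundaries = np.quantile(nonzero, np.arange(1, 10) / 10.0)

        def classify(mat: np.ndarray) -> np.ndarray:
            cls = np.searchsorted(boundaries, mat, side="right") + 1
            cls[mat <= 0] = 1
            return cls.astype(np.int64)

        cls_top, cls_bottom = classify(heatmap.top), classify(heatmap.bottom)
    heatmap.classes_top = cls_top
    heatmap.classes_bottom = cls_bottom
    return heatmap


def export_heatmap_tsv(heatmap: BinnedHeatmap, path) -> None:
    starts = heatmap.bin_edges[:-1]
    with open(path, "w") as fh:
        fh.write("hotspot\tstrand\t" + "\t".join(str(int(s)) for s in starts) + "\n")
        for row in range(heatmap.top.shape[0]):
            hid = int(heatmap.hotspot_index[row])
            for strand, mat in (("top", heatmap.top), ("bottom", heatmap.bottom)):
                fh.write(f"{hid}\t{strand}\t" + "\t".join(f"{v:.6g}" for v in mat[row]) + "\n")


def render_heatmap_png(heatmap: BinnedHeatmap, path) -> None:
    """Optional PNG rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if heatmap.classes_top is None:
        decile_classify(heatmap)
    fig, axes = plt.subplots(1, 2, figsize=(8, 6), sharey=True)
    for ax, cls, title in ((axes[0], heatmap.classes_top, "top strand"),
                           (axes[1], heatmap.classes_bottom, "bottom strand")):
        ax.imshow(cls, aspect="auto", cmap="viridis", interpolation="nearest")
        ax.set_title(title)
        ax.set_xlabel("40-bp bin")
    axes[0].set_ylabel("hotspot (strongest first)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
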