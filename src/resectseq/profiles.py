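"""Hotspot-centered signal windows and co-oriented genome-average profiles.

The analysis views each DSB hotspot through a fixed window of ``2W + 1``
positions around its center (offsets ``-W .. +W``).  Bottom-strand signal,
which marks leftward-moving resection, is co-oriented by mirroring its offsets
about the center so that leftward and rightward tracts superimpose; averaging
the co-oriented signal across hotspots yields one genome-average profile per
genotype.  Smoothing uses a Hann window (151 bp for plotted/modal profiles,
51 bp near hotspot centers), background is the signal level 2.5 kb from the
center, and two normalizations are provided: by the resection-peak height and
by the area under the curve from -1.0 to +2.5 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateProfileError, ValidationError
from .io_tracks import HotspotSet, StrandedTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """All window and bin constants used by the analysis, in bp.

    Defaults follow the standard endpoint-map analysis: 3-kb half-window,
    151-bp Hann smoothing for plotted profiles and 51-bp near centers,
    background estimated 2.5 kb from the center, resection statistics over
    100-2500 bp in 100-bp bins, central (recombination-intermediate) window
    -300..+100 bp, 40-bp heatmap bins over a 4001-bp window, and area
    normalization over -1000..+2500 bp.
    """

    half_width: int = 3000
    smooth_plot: int = 151
    smooth_central: int = 51
    background_offset: int = 2500
    background_half_width: int = 75
    resection_window: tuple[int, int] = (100, 2500)
    central_window: tuple[int, int] = (-300, 100)
    length_bin: int = 100
    heatmap_bin: int = 40
    heatmap_window: int = 4001
    area_window: tuple[int, int] = (-1000, 2500)

    def __post_init__(self):
        W = self.half_width
        for lo, hi in (self.resection_window, self.central_window, self.area_window):
            if not (-W <= lo < hi <= W):
                raise ValidationError(f"window ({lo},{hi}) outside +/-{W}")
        if not (0 < self.background_offset - self.background_half_width
                and self.background_offset + self.background_half_width <= W):
            raise ValidationError("background window outside profile")
        if self.smooth_plot % 2 == 0 or self.smooth_central % 2 == 0:
            raise ValidationError("Hann windows must be odd")
        span = self.resection_window[1] - self.resection_window[0]
        if span % self.length_bin:
            raise ValidationError("length_bin must divide the resection window")
        if self.heatmap_window % 2 == 0 or self.heatmap_window > 2 * W + 1:
            raise ValidationError("heatmap window must be odd and fit inside +/-W")


@dataclass
class HotspotMatrix:
    """Per-hotspot strand-specific signal windows (rows follow HotspotSet order).

    ``top`` and ``bottom`` are ``(n_hotspots, 2W+1)`` arrays over offsets
    ``-W .. +W``; ``hotspot_index`` maps rows back to the originating
    :class:`~resectseq.io_tracks.HotspotSet` records (hotspots whose window
    would leave the chromosome are dropped, with a logged count).
    """

    top: np.ndarray
    bottom: np.ndarray
    half_width: int
    units: str
    hotspot_index: np.ndarray
    co_oriented: bool = False
    n_dropped: int = 0

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)

    @property
    def n_hotspots(self) -> int:
        return self.top.shape[0]


@dataclass
class AverageProfile:
    """Genome-average signal versus distance from hotspot center.

    Tracks its own processing state so downstream statistics can check their
    preconditions: co-orientation, smoothing window, background subtraction
    and normalization mode (``none`` | ``peak`` | ``area``).
    """

    offsets: np.ndarray
    values: np.ndarray
    units: str
    co_oriented: bool
    smoothing_window: int | None = None
    background_subtracted: bool = False
    normalization: str = "none"

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.offsets.shape != self.values.shape:
            raise ValidationError("offsets and values must be parallel")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile values must be finite")

    def window_sum(self, lo: int, hi: int) -> float:
        """Sum of per-bp values over offsets lo..hi inclusive."""
        sel = (self.offsets >= lo) & (self.offsets <= hi)
        return float(self.values[sel].sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# units={self.units} co_oriented={self.co_oriented} "
                     f"smoothing_window={self.smoothing_window} "
                     f"background_subtracted={self.background_subtracted} "
                     f"normalization={self.normalization}\n")
            fh.write("offset\tvalue\n")
            for o, v in zip(self.offsets.tolist(), self.values.tolist()):
                fh.write(f"{o}\t{v:.10g}\n")


def stack_windows(track: StrandedTrack, hotspots: HotspotSet, half_width: int = 3000) -> HotspotMatrix:
    """Collect per-strand track counts into windows around hotspot centers.

    Counts at genomic position ``p`` land at offset ``p - center``; positions
    outside ``[center - W, center + W]`` are excluded.  Hotspots whose window
    exceeds the chromosome bounds are dropped (count logged).
    """
    if len(hotspots) == 0:
        raise ValidationError("empty hotspot set")
    W = half_width
    L = 2 * W + 1
    keep = []
    for i, (chrom, center) in enumerate(zip(hotspots.chroms, hotspots.centers)):
        if center - W >= 0 and center + W < track.genome.lengths[chrom]:
            keep.append(i)
    n_dropped = len(hotspots) - len(keep)
    if n_dropped:
        logger.info("stack_windows: dropped %d hotspot(s) whose window exceeds chromosome bounds",
                    n_dropped)
    keep_arr = np.asarray(keep, dtype=np.int64)
    mats = {}
    for strand in ("top", "bottom"):
        mat = np.zeros((len(keep_arr), L), dtype=np.float64)
        for row, i in enumerate(keep_arr):
            chrom = hotspots.chroms[i]
            center = int(hotspots.centers[i])
            pos, val = track.arrays(chrom, strand)
            i0 = np.searchsorted(pos, center - W, side="left")
            i1 = np.searchsorted(pos, center + W, side="right")
            mat[row, pos[i0:i1] - (center - W)] = val[i0:i1]
        mats[strand] = mat
    return HotspotMatrix(top=mats["top"], bottom=mats["bottom"], half_width=W,
                         units=track.units, hotspot_index=keep_arr,
                         co_oriented=False, n_dropped=n_dropped)


def coorient(matrix: HotspotMatrix) -> HotspotMatrix:
    """Mirror bottom-strand offsets about the hotspot center (x -> -x)."""
    if matrix.co_oriented:
        raise ValidationError("matrix is already co-oriented")
    return HotspotMatrix(top=matrix.top.copy(), bottom=matrix.bottom[:, ::-1].copy(),
                         half_width=matrix.half_width, units=matrix.units,
                         hotspot_index=matrix.hotspot_index.copy(),
                         co_oriented=True, n_dropped=matrix.n_dropped)


def genome_average(matrix: HotspotMatrix, combine_strands: bool = True,
                   mask: np.ndarray | None = None):
    """Unweighted mean over hotspot rows.

    With ``combine_strands`` (requires a co-oriented matrix) the mean runs over
    all ``2N`` strand-rows and one profile is returned; otherwise a
    ``(top, bottom)`` profile pair is returned.  ``mask`` restricts the
    average to a hotspot subset (e.g. autosomes only).
    """
    if matrix.n_hotspots == 0:
        raise ValidationError("matrix has zero hotspots")
    sel = np.ones(matrix.n_hotspots, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if sel.sum() == 0:
        raise ValidationError("hotspot mask selects nothing")
    offsets = matrix.offsets
    if combine_strands:
        if not matrix.co_oriented:
            raise ValidationError("combine_strands requires a co-oriented matrix")
        values = (matrix.top[sel].sum(axis=0) + matrix.bottom[sel].sum(axis=0)) / (2 * sel.sum())
        return AverageProfile(offsets, values, matrix.units, co_oriented=True)
    top = AverageProfile(offsets, matrix.top[sel].mean(axis=0), matrix.units,
                         co_oriented=matrix.co_oriented)
    bottom = AverageProfile(offsets, matrix.bottom[sel].mean(axis=0), matrix.units,
                            co_oriented=matrix.co_oriented)
    return top, bottom


def hann_kernel(window: int) -> np.ndarray:
    """Hann taper of odd length ``window``, normalized to sum 1."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("Hann window must be odd and >= 1")
    if window == 1:
        return np.ones(1)
    k = np.hanning(window)  # 0.5 * (1 - cos(2*pi*n/(window-1))), zero endpoints
    return k / k.sum()


def hann_smooth_array(values: np.ndarray, window: int) -> np.ndarray:
    """Hann-convolve with edge truncation + renormalization (constants preserved)."""
    kernel = hann_kernel(window)
    if window == 1:
        return values.astype(np.float64, copy=True)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values, dtype=np.float64), kernel, mode="same")
    return num / den


def hann_smooth(profile: AverageProfile, window: int) -> AverageProfile:
    """Smooth a profile with a normalized Hann kernel of odd width ``window``."""
    out = replace(profile, values=hann_smooth_array(profile.values, window))
    out.smoothing_window = window
    return out


def subtract_background(profile: AverageProfile, cfg: AnalysisConfig) -> AverageProfile:
    """Remove the estimated background: the signal level 2.5 kb from the center.

    The estimate is the mean over a ``2 * background_half_width + 1`` window
    centered at ``+background_offset`` (robust to sparse counts while matching
    the single-point value in expectation); negative values are set to zero.
    """
    if not profile.co_oriented:
        raise ValidationError("background subtraction is defined on co-oriented profiles")
    lo = cfg.background_offset - cfg.background_half_width
    hi = cfg.background_offset + cfg.background_half_width
    sel = (profile.offsets >= lo) & (profile.offsets <= hi)
    if sel.sum() != hi - lo + 1:
        raise ValidationError("background window falls outside the profile")
    b = float(profile.values[sel].mean())
    out = replace(profile, values=np.maximum(profile.values - b, 0.0))
    out.background_subtracted = True
    return out


def normalize_to_peak(profile: AverageProfile, cfg: AnalysisConfig) -> AverageProfile:
    """Scale so the maximum over the resection window (100-2500 bp) is exactly 1."""
    if not profile.background_subtracted:
        raise ValidationError("peak normalization requires background subtraction")
    lo, hi = cfg.resection_window
    sel = (profile.offsets >= lo) & (profile.offsets <= hi)
    m = float(profile.values[sel].max())
    if m <= 0:
        raise DegenerateProfileError("no signal in the resection window")
    out = replace(profile, values=profile.values / m)
    out.normalization = "peak"
    return out


def normalize_area(profile: AverageProfile, cfg: AnalysisConfig) -> AverageProfile:
    """Scale so the area under the curve over -1.0..+2.5 kb is 1 (coverage profiles)."""
    if not profile.background_subtracted:
        raise ValidationError("area normalization requires background subtraction")
    lo, hi = cfg.area_window
    area = profile.window_sum(lo, hi)
    if area <= 0:
        raise DegenerateProfileError("zero area in the normalization window")
    out = replace(profile, values=profile.values / area)
    out.normalization = "area"
    return out


def export_matrix_tsv(matrix: HotspotMatrix, path) -> None:
    """Wide TSV export of a hotspot matrix (one row per hotspot per strand)."""
    offsets = matrix.offsets
    with open(path, "w") as fh:
        fh.write("hotspot\tstrand\t" + "\t".join(str(o) for o in offsets.tolist()) + "\n")
        for row in range(matrix.n_hotspots):
            hid = int(matrix.hotspot_index[row])
            for strand, mat in (("top", matrix.top), ("bottom", matrix.bottom)):
                vals = "\t".join(f"{v:.6g}" for v in mat[row].tolist())
                fh.write(f"{hid}\t{strand}\t{vals}\n")
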