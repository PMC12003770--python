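"""Headline resection statistics computed from genome-average profiles.

* mean resection length -- 100-bp signal fractions over 100-2500 bp from the
  hotspot center, each bin represented by its midpoint;
* modal resection length -- argmax of the 151-bp-Hann-smoothed profile over
  the same window;
* central:resection ratio -- area under the curve for the central
  (recombination-intermediate) peak, -300..+100 bp, divided by the AUC of the
  resection peak, +100..+2500 bp;
* replicate CV -- percent coefficient of variation across replicate estimates.

Mean and ratio are computed on the *unsmoothed* background-subtracted average;
the mode uses the smoothed profile, since it is defined as the peak position
of the plotted genome-average curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateProfileError, ValidationError
from .io_tracks import HotspotSet, StrandedTrack, rpm_normalize
from .profiles import (AnalysisConfig, AverageProfile, coorient, genome_average,
                       hann_smooth, stack_windows, subtract_background)


@dataclass
class ResectionSummary:
    """One genotype/replicate row of resection statistics."""

    genotype: str
    replicate: str
    n_hotspots: int
    mean_length: float
    modal_length: int
    central_ratio: float


def _require(profile: AverageProfile, *, smoothed: int | None, subtracted: bool = True) -> None:
    if not profile.co_oriented:
        raise ValidationError("statistic requires a co-oriented profile")
    if subtracted and not profile.background_subtracted:
        raise ValidationError("statistic requires a background-subtracted profile")
    if smoothed is None and profile.smoothing_window is not None:
        raise ValidationError("statistic is defined on the unsmoothed profile")
    if smoothed is not None and profile.smoothing_window != smoothed:
        raise ValidationError(f"statistic requires smoothing_window={smoothed}, "
                              f"got {profile.smoothing_window}")


def mean_resection_length(profile: AverageProfile, cfg: AnalysisConfig) -> float:
    """Fraction-weighted mean of 100-bp bin midpoints over 100-2500 bp.

    Signal below 100 bp and beyond 2.5 kb is zeroed; each 100-bp bin of the
    remaining signal contributes its midpoint (150, 250, ..., 2450 nt)
    weighted by its fraction of the windowed total.
    """
    _require(profile, smoothed=None)
    lo, hi = cfg.resection_window
    h = cfg.length_bin
    sel = (profile.offsets >= lo) & (profile.offsets < hi)
    off = profile.offsets[sel]
    val = profile.values[sel]
    total = val.sum()
    if total <= 0:
        raise DegenerateProfileError("no signal between 100 bp and 2.5 kb")
    bins = (off - lo) // h
    mids = lo + h * bins + h / 2
    return float((val * mids).sum() / total)


def modal_resection_length(profile: AverageProfile, cfg: AnalysisConfig) -> int:
    """Peak position of the smoothed genome-average profile over 100-2500 bp.

    Ties break toward the smallest offset.
    """
    _require(profile, smoothed=cfg.smooth_plot)
    lo, hi = cfg.resection_window
    sel = (profile.offsets >= lo) & (profile.offsets <= hi)
    vals = profile.values[sel]
    if vals.max() <= 0:
        raise DegenerateProfileError("all-zero resection window")
    return int(profile.offsets[sel][np.argmax(vals)])


def central_resection_ratio(profile: AverageProfile, cfg: AnalysisConfig) -> float:
    """AUC(central peak, -300..+100) / AUC(resection peak, +100..+2500).

    The shared boundary offset +100 is assigned to the resection window only,
    so no position is double-counted.
    """
    _require(profile, smoothed=None)
    clo, chi = cfg.central_window
    rlo, rhi = cfg.resection_window
    central = profile.window_sum(clo, min(chi, rlo) - 1)
    resection = profile.window_sum(rlo, rhi)
    if resection <= 0:
        raise DegenerateProfileError("zero resection AUC")
    return float(central / resection)


def replicate_cv(values: Sequence[float]) -> float:
    """Percent coefficient of variation (sample SD / mean * 100)."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size < 2:
        raise ValidationError("replicate CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("replicate CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def analysis_profiles(
    track: StrandedTrack, hotspots: HotspotSet, cfg: AnalysisConfig,
    mask: np.ndarray | None = None,
) -> tuple[AverageProfile, AverageProfile]:
    """Run RPM -> stack -> coorient -> average -> background subtraction.

    Returns ``(raw, smoothed)``: the unsmoothed background-subtracted average
    (input to the mean and ratio) and its 151-bp-Hann-smoothed counterpart
    (input to the mode).
    """
    if track.units == "raw":
        track = rpm_normalize(track)
    matrix = coorient(stack_windows(track, hotspots, cfg.half_width))
    avg = genome_average(matrix, combine_strands=True, mask=mask)
    raw = subtract_background(avg, cfg)
    smoothed = hann_smooth(raw, cfg.smooth_plot)
    return raw, smoothed


def summarize(
    track: StrandedTrack, hotspots: HotspotSet, cfg: AnalysisConfig,
    genotype: str = "", replicate: str = "", mask: np.ndarray | None = None,
) -> ResectionSummary:
    """Full per-library summary: mean, modal length and central ratio."""
    raw, smoothed = analysis_profiles(track, hotspots, cfg, mask=mask)
    return ResectionSummary(
        genotype=genotype,
        replicate=replicate,
        n_hotspots=len(hotspots),
        mean_length=mean_resection_length(raw, cfg),
        modal_length=modal_resection_length(smoothed, cfg),
        central_ratio=central_resection_ratio(raw, cfg),
    )


def write_summary_table(rows: Sequence[ResectionSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("genotype\treplicate\tn_hotspots\tmean_length\tmodal_length\tcentral_ratio\n")
        for r in rows:
            fh.write(f"{r.genotype}\t{r.replicate}\t{r.n_hotspots}\t"
                     f"{r.mean_length:.2f}\t{r.modal_length}\t{r.central_ratio:.4f}\n")
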