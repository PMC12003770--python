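"""Mechanistic simulator of meiotic DSB end-sequencing data with ground truth.

The generative model follows the biology of SPO11 break formation and
processing.  Per molecule: a hotspot is drawn proportional to strength; one cut
position is drawn from a trimodal within-hotspot model (a strong central
cluster plus weaker subsidiary clusters to either side); with probability
``p_double_cut`` the molecule receives a second cut, spaced by roughly a
33-nt base plus geometric multiples of ~10 nt (the spacing signature of
adjacent SPO11 dimers) -- only the outermost ends are observable.  The
molecule's fate is then:

* recombination intermediate (probability ``ri_fraction``): one read near the
  hotspot center, displaced by a truncated normal confined to the central
  window (top strand at center + d, bottom strand mirrored);
* unresected (probability ``p_unresected`` of the remainder): a top-strand
  endpoint at the rightmost cut and a bottom-strand endpoint at the leftmost
  cut;
* resected (the rest): endpoints pushed outward by independent left/right
  tract lengths drawn from a truncated gamma distribution calibrated to a
  target mean and mode.

Uniform background reads are added per strand, and the full ground truth
(fates, cuts, tracts, read-mass ratios) is recorded so every pipeline stage
can be validated by parameter recovery.

Randomness contract: one seed per simulate call; hotspot layout, molecule
draws and background come from independent child streams of one
``SeedSequence``, so adding background never perturbs the molecule draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import optimize, special, stats

from .doublecut import OligoLengthSample
from .errors import CalibrationError, ValidationError
from .io_tracks import AlignmentRecordLite, GenomeSpec, HotspotSet, StrandedTrack

FATE_RI, FATE_UNRESECTED, FATE_RESECTED = 0, 1, 2
FATE_NAMES = {FATE_RI: "RI", FATE_UNRESECTED: "unresected", FATE_RESECTED: "resected"}


@dataclass(frozen=True)
class DoubleCutModel:
    """Spacing between adjacent cuts: base + step * Geometric + Normal jitter."""

    base: float = 33.0
    step: float = 10.0
    geom_p: float = 0.4     # P(success) for the geometric step count (support 0,1,...)
    jitter_sd: float = 1.0

    def __post_init__(self):
        if not (0 < self.geom_p <= 1):
            raise ValidationError("geom_p must be in (0, 1]")
        if self.base + self.jitter_sd < 1:
            raise ValidationError("spacing model must keep spacings >= 1 nt")


@dataclass(frozen=True)
class TractModel:
    """Truncated-gamma resection-tract model targeting a mean and mode (nt)."""

    target_mean: float
    target_mode: float
    lo: float = 200.0
    hi: float = 2450.0

    def __post_init__(self):
        if not (self.lo < self.target_mode < self.target_mean < self.hi):
            raise ValidationError("need lo < mode < mean < hi for a gamma tract model")
        if self.lo < 100:
            raise ValidationError("tract lower bound must be >= 100 nt")


@dataclass(frozen=True)
class RIDisplacementModel:
    """Recombination-intermediate read displacement, co-oriented bp (truncated normal)."""

    mean: float = -100.0
    sd: float = 80.0
    lo: float = -300.0
    hi: float = 100.0


@dataclass(frozen=True)
class OligoMixture:
    """SPO11-oligo class weights: canonical short/long ranges plus double-cut ladder."""

    short: float = 0.60
    long: float = 0.40
    double_cut: float = 0.0
    short_range: tuple[int, int] = (15, 27)
    long_range: tuple[int, int] = (31, 35)

    def __post_init__(self):
        if min(self.short, self.long, self.double_cut) < 0:
            raise ValidationError("oligo class weights must be >= 0")
        if self.short + self.long + self.double_cut <= 0:
            raise ValidationError("all oligo class weights are zero")


@dataclass(frozen=True)
class GenotypePreset:
    """Simulator parameters for one genotype."""

    name: str
    description: str
    p_unresected: float
    p_double_cut: float
    ri_fraction: float
    tract: TractModel | None
    double_cut: DoubleCutModel = DoubleCutModel()
    ri: RIDisplacementModel = RIDisplacementModel()
    background_per_mb: float = 30.0   # uniform reads per Mb per strand
    oligo: OligoMixture = OligoMixture()

    def __post_init__(self):
        for p, label in ((self.p_unresected, "p_unresected"),
                         (self.p_double_cut, "p_double_cut"),
                         (self.ri_fraction, "ri_fraction")):
            if not (0 <= p <= 1):
                raise ValidationError(f"{label} must be in [0, 1], got {p}")
        if self.tract is None and self.ri_fraction + self.p_unresected < 1:
            raise ValidationError("a preset producing resected molecules needs a tract model")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic genome, hotspot layout and within-hotspot cut-position model."""

    chrom_name: str = "chrSim"
    chrom_length: int = 30_000_000
    n_hotspots: int = 1000
    min_spacing: int = 10_000
    strength_scale: float = 1.0       # exponential hotspot-strength distribution
    cut_sd: float = 60.0              # sd of each cut-position cluster, bp
    subsidiary_offset: float = 200.0  # subsidiary clusters at +/- this offset
    subsidiary_weight: float = 0.1    # weight of each subsidiary cluster
    n_molecules: int = 500_000
    include_sex_chromosome: bool = False
    sex_chrom_name: str = "chrXSim"
    sex_chrom_length: int = 5_000_000
    n_sex_hotspots: int = 25
    edge_margin: int = 5_000          # keep hotspot windows clear of chromosome ends

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        if self.n_hotspots < 1:
            raise ValidationError("n_hotspots must be >= 1")
        if 2 * self.subsidiary_weight >= 1:
            raise ValidationError("subsidiary weights must sum to < 1")
        usable = self.chrom_length - 2 * (self.edge_margin + 3000)
        if usable // self.n_hotspots < self.min_spacing:
            raise ValidationError("chromosome too short for the requested hotspot spacing")

    def genome(self) -> GenomeSpec:
        lengths = {self.chrom_name: self.chrom_length}
        sex: frozenset[str] = frozenset()
        if self.include_sex_chromosome:
            lengths[self.sex_chrom_name] = self.sex_chrom_length
            sex = frozenset({self.sex_chrom_name})
        return GenomeSpec(lengths, sex)


@dataclass
class SimTruth:
    """Ground truth recorded per molecule, plus the summaries the pipeline estimates."""

    hotspot_id: np.ndarray       # int, row into the HotspotSet
    fate: np.ndarray             # int8: 0 RI, 1 unresected, 2 resected
    n_cuts: np.ndarray           # 1 or 2
    outer_spacing: np.ndarray    # bp between outermost cuts (0 for single cuts)
    tract_left: np.ndarray       # nt, NaN unless resected
    tract_right: np.ndarray
    n_background_reads: int
    n_dropped_reads: int
    total_reads: int

    @property
    def true_mean_tract(self) -> float:
        res = self.fate == FATE_RESECTED
        return float(np.concatenate([self.tract_left[res], self.tract_right[res]]).mean())

    @property
    def true_central_ratio(self) -> float:
        """Configured central:resection read-mass ratio (1 RI read vs 2 resected reads)."""
        n_ri = int((self.fate == FATE_RI).sum())
        n_res = int((self.fate == FATE_RESECTED).sum())
        return n_ri / (2.0 * n_res) if n_res else float("inf")

    @property
    def true_mean_outer_spacing(self) -> float:
        dc = self.n_cuts >= 2
        return float(self.outer_spacing[dc].mean()) if dc.any() else 0.0

    def counts(self) -> dict:
        return {
            "n_molecules": int(len(self.fate)),
            "n_ri": int((self.fate == FATE_RI).sum()),
            "n_unresected": int((self.fate == FATE_UNRESECTED).sum()),
            "n_resected": int((self.fate == FATE_RESECTED).sum()),
            "n_double_cut": int((self.n_cuts >= 2).sum()),
            "n_background_reads": self.n_background_reads,
            "n_dropped_reads": self.n_dropped_reads,
            "total_reads": self.total_reads,
        }

    def summary(self) -> dict:
        out = self.counts()
        res = self.fate == FATE_RESECTED
        out["true_mean_tract"] = self.true_mean_tract if res.any() else None
        out["true_central_ratio"] = (self.true_central_ratio
                                     if np.isfinite(self.true_central_ratio) else None)
        out["true_mean_outer_spacing"] = self.true_mean_outer_spacing
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# tract-distribution calibration


def _trunc_gamma_mean(k: float, theta: float, lo: float, hi: float) -> float:
    # E[X | lo < X < hi] for gamma(k, theta), via the k+1 CDF identity
    a = special.gammainc(k, lo / theta)
    b = special.gammainc(k, hi / theta)
    a1 = special.gammainc(k + 1, lo / theta)
    b1 = special.gammainc(k + 1, hi / theta)
    if b - a <= 0:
        return float("nan")
    return k * theta * (b1 - a1) / (b - a)


def calibrate_tract_distribution(
    target_mean: float, target_mode: float, bounds: tuple[float, float] = (200.0, 2450.0)
) -> tuple[float, float]:
    """Gamma (shape k, scale theta) whose truncation to ``bounds`` hits the targets.

    Initialization uses the untruncated identities ``mean - mode = theta`` and
    ``mean = k * theta``; the scale is then adjusted numerically, holding the
    interior mode ``(k - 1) * theta`` exact, until the truncated mean matches
    within 1 nt.  Deterministic for given inputs.
    """
    lo, hi = bounds
    if not (lo < target_mode < target_mean < hi):
        raise CalibrationError(
            f"infeasible targets: need {lo} < mode ({target_mode}) < mean ({target_mean}) < {hi}")
    theta0 = target_mean - target_mode

    def gap(theta: float) -> float:
        k = target_mode / theta + 1.0
        return _trunc_gamma_mean(k, theta, lo, hi) - target_mean

    t_lo, t_hi = theta0, theta0
    for _ in range(60):
        if gap(t_lo) < 0:
            break
        t_lo *= 0.7
    for _ in range(60):
        if gap(t_hi) > 0:
            break
        t_hi *= 1.3
    if not (gap(t_lo) < 0 < gap(t_hi)):
        raise CalibrationError("tract calibration did not bracket a solution")
    theta = optimize.brentq(gap, t_lo, t_hi, xtol=1e-6)
    k = target_mode / theta + 1.0
    if abs(_trunc_gamma_mean(k, theta, lo, hi) - target_mean) > 1.0:
        raise CalibrationError("tract calibration did not converge to within 1 nt")
    return k, theta


def _sample_trunc_gamma(rng: np.random.Generator, k: float, theta: float,
                        lo: float, hi: float, size: int) -> np.ndarray:
    d = stats.gamma(k, scale=theta)
    a, b = d.cdf(lo), d.cdf(hi)
    u = rng.uniform(a, b, size=size)
    return d.ppf(u)


def _sample_trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                         lo: float, hi: float, size: int) -> np.ndarray:
    a, b = stats.norm.cdf([lo, hi], loc=mean, scale=sd)
    u = rng.uniform(a, b, size=size)
    return stats.norm.ppf(u, loc=mean, scale=sd)


# ---------------------------------------------------------------------------
# preset table


def _preset_from_dict(name: str, raw: dict) -> GenotypePreset:
    tract = None
    if raw.get("tract"):
        t = raw["tract"]
        tract = TractModel(target_mean=float(t["target_mean"]),
                           target_mode=float(t["target_mode"]),
                           lo=float(t.get("lo", 200.0)), hi=float(t.get("hi", 2450.0)))
    dc = DoubleCutModel(**raw.get("double_cut", {}))
    ri_model = RIDisplacementModel(**raw.get("ri_displacement", {}))
    oligo = OligoMixture(**{k: v for k, v in raw.get("oligo_weights", {}).items()})
    p_unres = float(raw.get("p_unresected", 0.0))
    if "ri_fraction" in raw:
        ri_fraction = float(raw["ri_fraction"])
    elif "central_to_resection_ratio" in raw:
        # invert the read-mass bookkeeping: one RI read versus two resected
        # endpoints per molecule, so rho = r / (2 (1 - r)(1 - p_unresected))
        rho = float(raw["central_to_resection_ratio"])
        ri_fraction = 2 * rho * (1 - p_unres) / (1 + 2 * rho * (1 - p_unres))
    else:
        ri_fraction = 0.0
    return GenotypePreset(
        name=name,
        description=str(raw.get("description", "")),
        p_unresected=p_unres,
        p_double_cut=float(raw.get("p_double_cut", 0.0)),
        ri_fraction=ri_fraction,
        tract=tract,
        double_cut=dc,
        ri=ri_model,
        background_per_mb=float(raw.get("background_per_mb", 30.0)),
        oligo=oligo,
    )


def load_presets() -> dict[str, GenotypePreset]:
    """Load the packaged genotype preset table."""
    text = resources.files("resectseq").joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: _preset_from_dict(name, entry) for name, entry in raw.items()}


def get_preset(name: str) -> GenotypePreset:
    presets = load_presets()
    if name not in presets:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}")
    return presets[name]


# ---------------------------------------------------------------------------
# dataset simulation


def _hotspot_layout(cfg: SimConfig, rng: np.random.Generator) -> HotspotSet:
    chroms, centers, sex = [], [], []
    plan = [(cfg.chrom_name, cfg.chrom_length, cfg.n_hotspots, False)]
    if cfg.include_sex_chromosome:
        plan.append((cfg.sex_chrom_name, cfg.sex_chrom_length, cfg.n_sex_hotspots, True))
    for chrom, length, n, is_sex in plan:
        margin = cfg.edge_margin + 3000  # keep +/-3 kb windows on-chromosome
        usable = length - 2 * margin
        step = usable // n
        jitter = max(0, (step - cfg.min_spacing) // 2)
        base = margin + step * np.arange(n) + step // 2
        off = rng.integers(-jitter, jitter + 1, size=n) if jitter else np.zeros(n, dtype=np.int64)
        chroms.extend([chrom] * n)
        centers.extend((base + off).tolist())
        sex.extend([is_sex] * n)
    strengths = rng.exponential(cfg.strength_scale, size=len(centers))
    strengths = np.maximum(strengths, 1e-6)
    return HotspotSet(np.asarray(chroms, dtype=object), np.asarray(centers, dtype=np.int64),
                      strengths, np.asarray(sex, dtype=bool), provenance="simulated")


def simulate_dataset(
    cfg: SimConfig, preset: GenotypePreset, seed: int
) -> tuple[StrandedTrack, HotspotSet, SimTruth]:
    """Simulate one end-sequencing library; returns (track, hotspots, truth).

    Fixed seed gives bit-identical output.  ``total_mapped_reads`` equals the
    number of emitted reads (signal plus background, after bounds filtering).
    """
    ss = np.random.SeedSequence(seed)
    r_hot, r_mol, r_bg = (np.random.default_rng(s) for s in ss.spawn(3))
    genome = cfg.genome()
    hotspots = _hotspot_layout(cfg, r_hot)
    n = cfg.n_molecules
    N = len(hotspots)

    probs = hotspots.strengths / hotspots.strengths.sum()
    hid = r_mol.choice(N, size=n, p=probs)
    centers = hotspots.centers[hid]

    # within-hotspot cut position: central cluster + two subsidiary clusters
    w = cfg.subsidiary_weight
    comp = r_mol.choice(3, size=n, p=[1 - 2 * w, w, w])
    mu = np.select([comp == 1, comp == 2], [-cfg.subsidiary_offset, cfg.subsidiary_offset], 0.0)
    cut = centers + np.rint(r_mol.normal(mu, cfg.cut_sd)).astype(np.int64)

    # double cuts: a second cut at the modeled spacing; outermost ends observable
    dc = r_mol.random(n) < preset.p_double_cut
    g = r_mol.geometric(preset.double_cut.geom_p, size=n) - 1
    eps = r_mol.normal(0.0, preset.double_cut.jitter_sd, size=n)
    spacing = np.maximum(
        np.rint(preset.double_cut.base + preset.double_cut.step * g + eps), 1
    ).astype(np.int64)
    spacing[~dc] = 0
    left = cut - spacing // 2
    right = left + spacing

    # fates
    u1 = r_mol.random(n)
    u2 = r_mol.random(n)
    fate = np.full(n, FATE_RESECTED, dtype=np.int8)
    fate[u1 < preset.ri_fraction] = FATE_RI
    fate[(u1 >= preset.ri_fraction) & (u2 < preset.p_unresected)] = FATE_UNRESECTED

    tract_left = np.full(n, np.nan)
    tract_right = np.full(n, np.nan)
    res = fate == FATE_RESECTED
    if res.any():
        if preset.tract is None:
            raise ValidationError("preset lacking a tract model produced resected molecules")
        k, theta = calibrate_tract_distribution(
            preset.tract.target_mean, preset.tract.target_mode,
            (preset.tract.lo, preset.tract.hi))
        n_res = int(res.sum())
        tract_left[res] = _sample_trunc_gamma(r_mol, k, theta, preset.tract.lo,
                                              preset.tract.hi, n_res)
        tract_right[res] = _sample_trunc_gamma(r_mol, k, theta, preset.tract.lo,
                                               preset.tract.hi, n_res)

    # emit reads
    ri = fate == FATE_RI
    unres = fate == FATE_UNRESECTED
    n_ri = int(ri.sum())
    d = np.rint(_sample_trunc_normal(r_mol, preset.ri.mean, preset.ri.sd,
                                     preset.ri.lo, preset.ri.hi, n_ri)).astype(np.int64)
    ri_top = r_mol.random(n_ri) < 0.5

    top_pos = np.concatenate([
        centers[ri][ri_top] + d[ri_top],
        right[unres],
        right[res] + np.rint(tract_right[res]).astype(np.int64),
    ])
    top_chrom = np.concatenate([
        hotspots.chroms[hid[ri]][ri_top], hotspots.chroms[hid[unres]],
        hotspots.chroms[hid[res]],
    ])
    bottom_pos = np.concatenate([
        centers[ri][~ri_top] - d[~ri_top],
        left[unres],
        left[res] - np.rint(tract_left[res]).astype(np.int64),
    ])
    bottom_chrom = np.concatenate([
        hotspots.chroms[hid[ri]][~ri_top], hotspots.chroms[hid[unres]],
        hotspots.chroms[hid[res]],
    ])

    positions: dict[tuple[str, str], list[np.ndarray]] = {}
    n_dropped = 0
    for strand, pos_arr, chrom_arr in (("top", top_pos, top_chrom),
                                       ("bottom", bottom_pos, bottom_chrom)):
        for chrom in genome.chromosomes:
            m = chrom_arr == chrom
            p = pos_arr[m]
            ok = (p >= 0) & (p < genome.lengths[chrom])
            n_dropped += int((~ok).sum())
            positions.setdefault((chrom, strand), []).append(p[ok])

    # uniform background, from its own stream
    n_background = 0
    for chrom in genome.chromosomes:
        length = genome.lengths[chrom]
        lam = preset.background_per_mb * length / 1e6
        for strand in ("top", "bottom"):
            nb = int(r_bg.poisson(lam))
            n_background += nb
            positions.setdefault((chrom, strand), []).append(
                r_bg.integers(0, length, size=nb))

    merged = {key: np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
              for key, chunks in positions.items()}
    track = StrandedTrack.from_positions(genome, merged)

    truth = SimTruth(
        hotspot_id=hid, fate=fate, n_cuts=np.where(dc, 2, 1).astype(np.int8),
        outer_spacing=spacing, tract_left=tract_left, tract_right=tract_right,
        n_background_reads=n_background, n_dropped_reads=n_dropped,
        total_reads=int(track.total_mapped_reads),
    )
    return track, hotspots, truth


def simulate_spo11_oligos(
    preset: GenotypePreset, n: int, seed: int,
    classes: tuple[str, ...] | None = None,
) -> OligoLengthSample:
    """Draw SPO11-oligo lengths from the preset's class mixture.

    ``classes`` restricts the mixture to a subset (weights renormalized), e.g.
    ``("double-cut",)`` for the pure double-cut ladder.  Canonical classes are
    uniform over their ranges; double-cut lengths follow
    ``round(base + step * Geometric + Normal jitter)`` floored at the base.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mix = preset.oligo
    table = {
        "canonical-short": mix.short,
        "canonical-long": mix.long,
        "double-cut": mix.double_cut,
    }
    if classes is not None:
        unknown = set(classes) - set(table)
        if unknown:
            raise ValidationError(f"unknown oligo classes: {sorted(unknown)}")
        table = {k: v for k, v in table.items() if k in classes}
    names = list(table)
    weights = np.asarray([table[k] for k in names], dtype=np.float64)
    if weights.sum() <= 0:
        raise ValidationError("selected oligo class weights are all zero")
    weights = weights / weights.sum()
    draw = rng.choice(len(names), size=n, p=weights)
    lengths = np.empty(n, dtype=np.int64)
    labels = np.empty(n, dtype=object)
    for i, name in enumerate(names):
        m = draw == i
        cnt = int(m.sum())
        if not cnt:
            continue
        labels[m] = name
        if name == "canonical-short":
            lo, hi = mix.short_range
            lengths[m] = rng.integers(lo, hi + 1, size=cnt)
        elif name == "canonical-long":
            lo, hi = mix.long_range
            lengths[m] = rng.integers(lo, hi + 1, size=cnt)
        else:
            dcm = preset.double_cut
            g = rng.geometric(dcm.geom_p, size=cnt) - 1
            eps = rng.normal(0.0, dcm.jitter_sd, size=cnt)
            raw = np.rint(dcm.base + dcm.step * g + eps)
            lengths[m] = np.maximum(raw, np.floor(dcm.base)).astype(np.int64)
    return OligoLengthSample(lengths, labels)


def alignments_from_track(
    track: StrandedTrack, seed: int = 0, span: int = 50,
    distal_per_read: bool = False,
) -> list[AlignmentRecordLite]:
    """Write alignment records whose endpoint extraction reproduces the track.

    Uses the package's endpoint convention: top endpoints become forward
    adapter-proximal mates with ``pos = endpoint``; bottom endpoints become
    reverse adapter-proximal mates with ``pos = endpoint - span + 1``.  With
    ``distal_per_read`` a non-contributing distal mate accompanies each read.
    """
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecordLite] = []
    for (chrom, strand), (pos, val) in sorted(track.data.items()):
        length = track.genome.lengths[chrom]
        for p, v in zip(pos.tolist(), val.tolist()):
            for _ in range(int(round(v))):
                if strand == "top":
                    s = min(span, length - p)
                    rec = AlignmentRecordLite(chrom, p, s, "forward", "adapter_proximal")
                else:
                    start = max(0, p - span + 1)
                    rec = AlignmentRecordLite(chrom, start, p - start + 1,
                                              "reverse", "adapter_proximal")
                records.append(rec)
                if distal_per_read:
                    q = int(rng.integers(0, length - span))
                    records.append(AlignmentRecordLite(
                        chrom, q, span,
                        "reverse" if strand == "top" else "forward", "distal"))
    return records
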