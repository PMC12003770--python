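"""Strand-specific DSB endpoint tracks and the file formats around them.

End-sequencing assays of meiotic double-strand break (DSB) processing (S1-seq,
Exo7/T-seq, END-seq) report, for each genomic position, how many sequenced
ends terminate there -- top-strand counts mark rightward-moving resection
endpoints, bottom-strand counts mark leftward ones.  This module holds the
sparse per-strand count container (:class:`StrandedTrack`), the hotspot table
(:class:`HotspotSet`), bedGraph/BED readers and writers, library-size (RPM)
normalization, and the endpoint-assignment rule that converts aligned read
pairs into per-base endpoint counts.

Coordinate conventions: 0-based, half-open in files and internally.  A hotspot
"center" is a single 0-based position, ``floor((start + end) / 2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import BoundsError, ParseError, ValidationError

logger = logging.getLogger(__name__)

Strand = Literal["top", "bottom"]
STRANDS: tuple[Strand, Strand] = ("top", "bottom")

#: file-name suffixes used for the per-strand bedGraph pair
TOP_SUFFIX = ".top.bedgraph"
BOTTOM_SUFFIX = ".bottom.bedgraph"


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths, with sex chromosomes labelled.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp (must be positive).
    sex_chromosomes
        Subset of chromosome names carrying the non-homologous (X/Y) flag.
    """

    lengths: Mapping[str, int]
    sex_chromosomes: frozenset[str] = frozenset()

    def __post_init__(self):
        if len(self.lengths) == 0:
            raise ValidationError("genome must contain at least one chromosome")
        for name, n in self.lengths.items():
            if int(n) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {n}")
        unknown = set(self.sex_chromosomes) - set(self.lengths)
        if unknown:
            raise ValidationError(f"sex chromosomes not in genome: {sorted(unknown)}")
        object.__setattr__(self, "lengths", dict(self.lengths))
        object.__setattr__(self, "sex_chromosomes", frozenset(self.sex_chromosomes))

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


def _empty_pair() -> tuple[np.ndarray, np.ndarray]:
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)


@dataclass
class StrandedTrack:
    """Sparse per-chromosome, per-strand endpoint counts.

    ``data[(chrom, strand)]`` is a pair of parallel arrays ``(positions,
    values)`` with positions sorted, unique and 0-based.  ``units`` is either
    ``"raw"`` (integer-like counts) or ``"RPM"`` (reads per million mapped
    reads); both strands of one library always share the same
    ``total_mapped_reads``.
    """

    genome: GenomeSpec
    data: dict[tuple[str, Strand], tuple[np.ndarray, np.ndarray]]
    total_mapped_reads: float
    units: str = "raw"

    def __post_init__(self):
        if self.units not in ("raw", "RPM"):
            raise ValidationError(f"unknown units {self.units!r}")
        clean: dict[tuple[str, Strand], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), (pos, val) in self.data.items():
            if chrom not in self.genome:
                raise BoundsError(f"track chromosome {chrom!r} not in genome")
            pos = np.asarray(pos, dtype=np.int64)
            val = np.asarray(val, dtype=np.float64)
            if pos.shape != val.shape:
                raise ValidationError("positions and values must be parallel arrays")
            if pos.size and (pos.min() < 0 or pos.max() >= self.genome.lengths[chrom]):
                raise BoundsError(f"position out of bounds on {chrom}")
            if np.any(val < 0):
                raise ValidationError("negative counts are not allowed")
            if pos.size and np.any(np.diff(pos) <= 0):
                order = np.argsort(pos, kind="stable")
                pos, val = pos[order], val[order]
                if np.any(np.diff(pos) == 0):
                    raise ValidationError(f"duplicate positions on {chrom}/{strand}")
            clean[(chrom, strand)] = (pos, val)
        self.data = clean
        if self.units == "raw" and self.total_mapped_reads + 1e-9 < self.sum_counts():
            raise ValidationError("total_mapped_reads below the track's own read count")

    def arrays(self, chrom: str, strand: Strand) -> tuple[np.ndarray, np.ndarray]:
        return self.data.get((chrom, strand), _empty_pair())

    def sum_counts(self) -> float:
        return float(sum(v.sum() for _, v in self.data.values()))

    def window_counts(self, chrom: str, start: int, stop: int, strand: Strand) -> np.ndarray:
        """Dense count vector for [start, stop) on one strand."""
        pos, val = self.arrays(chrom, strand)
        out = np.zeros(stop - start, dtype=np.float64)
        i0 = np.searchsorted(pos, start, side="left")
        i1 = np.searchsorted(pos, stop, side="left")
        out[pos[i0:i1] - start] = val[i0:i1]
        return out

    @classmethod
    def from_positions(
        cls,
        genome: GenomeSpec,
        positions: Mapping[tuple[str, Strand], np.ndarray],
        total_mapped_reads: float | None = None,
    ) -> "StrandedTrack":
        """Aggregate raw (possibly repeated) endpoint positions into a track."""
        data = {}
        n = 0
        for key, p in positions.items():
            p = np.asarray(p, dtype=np.int64)
            n += p.size
            if p.size:
                pos, cnt = np.unique(p, return_counts=True)
                data[key] = (pos, cnt.astype(np.float64))
        return cls(genome, data, float(total_mapped_reads if total_mapped_reads is not None else n))


@dataclass(frozen=True)
class HotspotSet:
    """DSB hotspots: chromosome, single-bp center, strength, sex-chromosome flag.

    Records are sorted by (chromosome, center).
    """

    chroms: np.ndarray
    centers: np.ndarray
    strengths: np.ndarray
    is_sex_chromosome: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        c = np.asarray(self.chroms, dtype=object)
        pos = np.asarray(self.centers, dtype=np.int64)
        s = np.asarray(self.strengths, dtype=np.float64)
        sex = np.asarray(self.is_sex_chromosome, dtype=bool)
        if not (len(c) == len(pos) == len(s) == len(sex)):
            raise ValidationError("hotspot field arrays must have equal length")
        if np.any(~np.isfinite(s)) or np.any(s < 0):
            raise ValidationError("hotspot strengths must be finite and >= 0")
        order = np.lexsort((pos, c.astype(str)))
        object.__setattr__(self, "chroms", c[order])
        object.__setattr__(self, "centers", pos[order])
        object.__setattr__(self, "strengths", s[order])
        object.__setattr__(self, "is_sex_chromosome", sex[order])

    def __len__(self) -> int:
        return len(self.centers)

    def subset(self, mask: np.ndarray) -> "HotspotSet":
        mask = np.asarray(mask, dtype=bool)
        return HotspotSet(
            self.chroms[mask], self.centers[mask], self.strengths[mask],
            self.is_sex_chromosome[mask], provenance=self.provenance,
        )


@dataclass(frozen=True)
class AlignmentRecordLite:
    """Minimal projection of one aligned mate of a read pair."""

    chrom: str
    pos: int          # leftmost aligned position, 0-based
    span: int         # aligned reference span in bp, >= 1
    orientation: Literal["forward", "reverse"]
    mate_role: Literal["adapter_proximal", "distal"]

    def __post_init__(self):
        if self.span < 1:
            raise ValidationError("alignment span must be >= 1")
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if self.mate_role not in ("adapter_proximal", "distal"):
            raise ValidationError(f"bad mate role {self.mate_role!r}")


# ---------------------------------------------------------------------------
# bedGraph endpoint tracks


def _read_bedgraph(path, genome: GenomeSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    chrom_pos: dict[str, list] = {}
    chrom_val: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError("expected 4 columns (chrom start end value)",
                                 path=str(path), line=lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"malformed numeric field: {exc}",
                                 path=str(path), line=lineno) from None
            if chrom not in genome:
                raise BoundsError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > genome.lengths[chrom] or end <= start:
                raise BoundsError(f"{path}:{lineno}: interval [{start},{end}) out of bounds")
            if not np.isfinite(value) or value < 0:
                raise ParseError(f"value must be finite and >= 0, got {value}",
                                 path=str(path), line=lineno)
            # bedGraph values are per-position counts; wider intervals expand.
            ps = chrom_pos.setdefault(chrom, [])
            vs = chrom_val.setdefault(chrom, [])
            if end - start == 1:
                ps.append(start)
                vs.append(value)
            else:
                ps.extend(range(start, end))
                vs.extend([value] * (end - start))
    out = {}
    for chrom in chrom_pos:
        pos = np.asarray(chrom_pos[chrom], dtype=np.int64)
        val = np.asarray(chrom_val[chrom], dtype=np.float64)
        order = np.argsort(pos, kind="stable")
        pos, val = pos[order], val[order]
        if np.any(np.diff(pos) == 0):
            raise ParseError(f"overlapping intervals on {chrom}", path=str(path))
        out[chrom] = (pos, val)
    return out


def read_endpoint_tracks(
    top_path, bottom_path, genome: GenomeSpec,
    total_mapped_reads: float | None = None,
) -> StrandedTrack:
    """Read one library's per-strand endpoint bedGraph pair.

    Each interval ``[a, b)`` with value ``v`` contributes a count of ``v`` at
    every covered position (the package's own writer emits width-1 intervals).
    When ``total_mapped_reads`` is not given, the track's own summed count is
    used, which is exact for the simulator's output.
    """
    data: dict[tuple[str, Strand], tuple[np.ndarray, np.ndarray]] = {}
    for path, strand in ((top_path, "top"), (bottom_path, "bottom")):
        for chrom, pair in _read_bedgraph(path, genome).items():
            data[(chrom, strand)] = pair
    total = total_mapped_reads
    if total is None:
        total = float(sum(v.sum() for _, v in data.values()))
    return StrandedTrack(genome, data, total, units="raw")


def write_endpoint_tracks(track: StrandedTrack, top_path, bottom_path) -> None:
    """Write width-1, sorted bedGraph intervals, one file per strand.

    Lossless for integer counts; zero-count positions are omitted.
    """
    for path, strand in ((top_path, "top"), (bottom_path, "bottom")):
        with open(path, "w") as fh:
            fh.write(f"track type=bedGraph name=resectseq_{strand}\n")
            for chrom in track.genome.chromosomes:
                pos, val = track.arrays(chrom, strand)
                for p, v in zip(pos.tolist(), val.tolist()):
                    v_out = int(v) if float(v).is_integer() else repr(v)
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{v_out}\n")


# ---------------------------------------------------------------------------
# hotspots


def read_hotspots(path, genome: GenomeSpec, provenance: str = "") -> HotspotSet:
    """Read a BED-like hotspot table (chrom, start, end, strength).

    The center is ``floor((start + end) / 2)``; the sex-chromosome flag comes
    from the genome's labels.  Lines starting with ``#`` are comments.
    """
    chroms, centers, strengths = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError("expected >= 4 columns (chrom start end strength)",
                                 path=str(path), line=lineno)
            chrom = parts[0]
            try:
                start, end, strength = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"malformed field: {exc}", path=str(path), line=lineno) from None
            if chrom not in genome:
                raise BoundsError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            center = (start + end) // 2
            if not (0 <= center < genome.lengths[chrom]):
                raise BoundsError(f"{path}:{lineno}: center {center} out of bounds")
            if strength < 0:
                raise ValidationError(f"{path}:{lineno}: negative strength {strength}")
            chroms.append(chrom)
            centers.append(center)
            strengths.append(strength)
    chroms_arr = np.asarray(chroms, dtype=object)
    is_sex = np.asarray([c in genome.sex_chromosomes for c in chroms], dtype=bool)
    return HotspotSet(chroms_arr, np.asarray(centers, dtype=np.int64),
                      np.asarray(strengths), is_sex, provenance=provenance)


def write_hotspots(hotspots: HotspotSet, path, half_width: int = 150) -> None:
    """Write hotspots as BED intervals of ``2 * half_width`` centered on each center."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tstrength\n")
        for chrom, center, s in zip(hotspots.chroms, hotspots.centers, hotspots.strengths):
            fh.write(f"{chrom}\t{center - half_width}\t{center + half_width}\t{s:.6g}\n")


# ---------------------------------------------------------------------------
# normalization and endpoint extraction


def rpm_normalize(track: StrandedTrack) -> StrandedTrack:
    """Convert raw counts to reads per million mapped reads (RPM).

    Both strands are scaled by the same library-wide total.
    """
    if track.units != "raw":
        raise ValidationError("track is already RPM-normalized")
    if track.total_mapped_reads <= 0:
        raise ValidationError("total_mapped_reads must be > 0 for RPM normalization")
    scale = 1e6 / track.total_mapped_reads
    data = {key: (pos.copy(), val * scale) for key, (pos, val) in track.data.items()}
    return StrandedTrack(track.genome, data, track.total_mapped_reads, units="RPM")


def endpoints_from_alignments(
    records: Iterable[AlignmentRecordLite], genome: GenomeSpec
) -> StrandedTrack:
    """Assign each adapter-proximal mate to the base next to the adapter.

    Forward-orientation mates mark a top-strand endpoint at their leftmost
    aligned position; reverse-orientation mates mark a bottom-strand endpoint
    at their rightmost aligned position.  Distal mates never contribute.
    """
    raw: dict[tuple[str, Strand], list[int]] = {}
    n = 0
    for rec in records:
        if rec.mate_role != "adapter_proximal":
            continue
        if rec.chrom not in genome:
            raise BoundsError(f"alignment chromosome {rec.chrom!r} not in genome")
        if rec.pos < 0 or rec.pos + rec.span > genome.lengths[rec.chrom]:
            raise BoundsError(f"alignment [{rec.pos},{rec.pos + rec.span}) out of bounds on {rec.chrom}")
        if rec.orientation == "forward":
            key, endpoint = (rec.chrom, "top"), rec.pos
        else:
            key, endpoint = (rec.chrom, "bottom"), rec.pos + rec.span - 1
        raw.setdefault(key, []).append(endpoint)
        n += 1
    positions = {k: np.asarray(v, dtype=np.int64) for k, v in raw.items()}
    return StrandedTrack.from_positions(genome, positions, total_mapped_reads=n)


def read_sam_records(path) -> list[AlignmentRecordLite]:
    """Thin SAM adapter: FLAG gives strand and mate role, CIGAR gives the span.

    Read 1 of each pair is taken as the adapter-proximal mate (the package's
    fixed convention; the simulator's SAM writer uses the same one).
    Unmapped records are skipped.
    """
    import pysam

    out: list[AlignmentRecordLite] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            span = aln.reference_length or 0
            if span < 1:
                continue
            role = "adapter_proximal" if (not aln.is_paired or aln.is_read1) else "distal"
            out.append(AlignmentRecordLite(
                chrom=aln.reference_name,
                pos=aln.reference_start,
                span=span,
                orientation="reverse" if aln.is_reverse else "forward",
                mate_role=role,
            ))
    return out


def average_tracks(tracks: Sequence[StrandedTrack]) -> StrandedTrack:
    """Average RPM maps across biological replicates, position by position."""
    if len(tracks) == 0:
        raise ValidationError("need at least one track")
    if any(t.units != "RPM" for t in tracks):
        raise ValidationError("replicate averaging is defined on RPM tracks")
    genome = tracks[0].genome
    if any(t.genome.lengths != genome.lengths for t in tracks):
        raise ValidationError("replicate tracks must share one genome")
    keys = sorted({k for t in tracks for k in t.data}, key=lambda k: (k[0], k[1]))
    data = {}
    for key in keys:
        pairs = [t.data[key] for t in tracks if key in t.data]
        allpos = np.unique(np.concatenate([p for p, _ in pairs]))
        acc = np.zeros(allpos.size)
        for pos, val in pairs:
            acc[np.searchsorted(allpos, pos)] += val
        data[key] = (allpos, acc / len(tracks))
    total = float(np.mean([t.total_mapped_reads for t in tracks]))
    return StrandedTrack(genome, data, total, units="RPM")
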