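"""Fragment ingestion, repeat masking and binned genome tracks.

Paired-end MNase fragments are reduced to genomic intervals, counted into
fixed-width bins (10 bp by default), depth-normalized so that the genome-wide
mean equals the bin size, and combined by subtraction or windowed log2 ratio.
Bins overlapping excluded (simple-repeat) regions carry NaN and are ignored by
every downstream statistic.

Coordinates are 0-based half-open throughout (BED convention); 1-based input
dialects are converted at the reader boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBuild",
    "FragmentSet",
    "BinnedTrack",
    "read_fragments",
    "bin_fragments",
    "normalize_track",
    "subtract_track",
    "log2_ratio_track",
    "mask_regions",
    "write_bedgraph",
    "read_bedgraph",
    "merge_intervals",
]

# Default fragment-length bounds: the paired-end library protocol retains all
# fragments >25 bp; size-class analyses use 21-500 bp (see fragsize module).
DEFAULT_MIN_LENGTH = 25
DEFAULT_MAX_LENGTH = 1000
DEFAULT_BIN_SIZE = 10


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome sizes plus excluded (repeat) intervals.

    ``chroms`` is an ordered name -> length map; ``excluded`` maps chromosome
    name to a sorted, merged list of half-open intervals that are removed from
    every analysis.
    """

    chroms: dict[str, int]
    excluded: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValueError("GenomeBuild needs at least one chromosome")
        for name, length in self.chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        clean: dict[str, list[tuple[int, int]]] = {}
        for name, ivs in self.excluded.items():
            if name not in self.chroms:
                raise ValueError(f"excluded interval on unknown chromosome {name!r}")
            merged = merge_intervals(ivs)
            for s, e in merged:
                if not (0 <= s < e <= self.chroms[name]):
                    raise ValueError(
                        f"excluded interval {name}:{s}-{e} outside chromosome bounds"
                    )
            clean[name] = merged
        object.__setattr__(self, "excluded", clean)

    @property
    def total_length(self) -> int:
        return sum(self.chroms.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chroms[chrom] / bin_size)

    @classmethod
    def from_files(
        cls, chrom_sizes: str | Path, exclude_bed: str | Path | None = None
    ) -> "GenomeBuild":
        """Build from a two-column chrom.sizes file and optional BED3 of repeats."""
        chroms: dict[str, int] = {}
        for i, line in enumerate(Path(chrom_sizes).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{chrom_sizes}: malformed line {i}: {line!r}")
            chroms[parts[0]] = int(parts[1])
        excluded: dict[str, list[tuple[int, int]]] = {}
        if exclude_bed is not None:
            for i, line in enumerate(Path(exclude_bed).read_text().splitlines(), 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 3:
                    raise ValueError(f"{exclude_bed}: malformed line {i}: {line!r}")
                excluded.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
        return cls(chroms=chroms, excluded=excluded)


@dataclass
class FragmentSet:
    """A labeled collection of fragment intervals.

    Fragments live in a DataFrame with columns ``chrom``, ``start``, ``end``
    (0-based half-open).  ``skipped`` tallies input records dropped at read
    time, keyed by reason.
    """

    df: pd.DataFrame
    track: str = "unknown"
    replicate: str = "1"
    mnase_minutes: float | None = None
    condition: str = "wildtype"
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"fragment table must have columns {sorted(required)}")
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("fragments must satisfy start < end")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            self.df[mask].reset_index(drop=True),
            track=self.track,
            replicate=self.replicate,
            mnase_minutes=self.mnase_minutes,
            condition=self.condition,
        )

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str] | np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        **labels,
    ) -> "FragmentSet":
        df = pd.DataFrame(
            {
                "chrom": pd.Categorical(chrom),
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
            }
        )
        return cls(df, **labels)


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome signal vectors; NaN marks masked bins."""

    bin_size: int
    values: dict[str, np.ndarray]
    kind: str  # raw | normalized | difference | log2ratio
    counting_mode: str | None = None  # midpoint | coverage

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = {c: np.asarray(v, dtype=np.float64) for c, v in self.values.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.bin_size == other.bin_size and all(
            c in other.values and len(self.values[c]) == len(other.values[c])
            for c in self.values
        ) and set(self.values) == set(other.values)

    def copy(self, kind: str | None = None) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            values={c: v.copy() for c, v in self.values.items()},
            kind=kind or self.kind,
            counting_mode=self.counting_mode,
        )

    def bin_widths(self, genome: GenomeBuild) -> dict[str, np.ndarray]:
        """Width in bp of every bin (the last bin of a chromosome may be short)."""
        out = {}
        for chrom, vec in self.values.items():
            w = np.full(len(vec), self.bin_size, dtype=np.float64)
            tail = genome.chroms[chrom] - (len(vec) - 1) * self.bin_size
            w[-1] = tail
            out[chrom] = w
        return out

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.values]) if self.values else np.array([])

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][pos // self.bin_size])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _check_chrom(name: str, genome: GenomeBuild, lineno: int, path) -> None:
    if name not in genome.chroms:
        raise ValueError(f"{path}: line {lineno}: unknown chromosome {name!r}")


def read_fragments(
    path: str | Path,
    format: str,
    genome: GenomeBuild,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
    **labels,
) -> FragmentSet:
    """Read fragments from BED6, BEDPE or paired-end alignments (SAM/BAM).

    BEDPE mate pairs are collapsed to the outermost span (min start, max end);
    pairs on different chromosomes are rejected with a counted skip.  Fragments
    outside ``[min_length, max_length]`` or off-chromosome are dropped and
    counted in the returned set's ``skipped`` tally.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    skipped: dict[str, int] = {}
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []

    def _tally(reason: str) -> None:
        skipped[reason] = skipped.get(reason, 0) + 1

    if format in ("bed", "bedpe"):
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t") if "\t" in line else line.split()
            if format == "bed":
                if len(parts) < 3:
                    raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
                chrom, start, end = parts[0], parts[1], parts[2]
            else:
                if len(parts) < 6:
                    raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
                c1, s1, e1, c2, s2, e2 = parts[:6]
                if c1 != c2:
                    _tally("discordant_chromosomes")
                    continue
                _check_chrom(c1, genome, lineno, path)
                chrom = c1
                start = min(int(s1), int(s2))
                end = max(int(e1), int(e2))
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            _check_chrom(chrom, genome, lineno, path)
            length = end - start
            if length < min_length or length > max_length:
                _tally("length_out_of_range")
                continue
            if start < 0 or end > genome.chroms[chrom]:
                _tally("off_chromosome")
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    elif format == "paired_alignments":
        import pysam

        with pysam.AlignmentFile(str(path)) as af:
            for aln in af:
                if (
                    aln.is_unmapped
                    or not aln.is_proper_pair
                    or aln.is_secondary
                    or aln.is_supplementary
                ):
                    continue
                if aln.template_length <= 0:  # count each pair once, from leftmost mate
                    continue
                chrom = aln.reference_name
                if chrom not in genome.chroms:
                    raise ValueError(f"{path}: unknown chromosome {chrom!r}")
                start = aln.reference_start
                end = start + aln.template_length
                length = end - start
                if length < min_length or length > max_length:
                    _tally("length_out_of_range")
                    continue
                if start < 0 or end > genome.chroms[chrom]:
                    _tally("off_chromosome")
                    continue
                chroms.append(chrom)
                starts.append(start)
                ends.append(end)
    else:
        raise ValueError(f"unknown format {format!r}")

    frags = FragmentSet.from_arrays(chroms, np.array(starts, dtype=np.int64),
                                    np.array(ends, dtype=np.int64), **labels)
    frags.skipped = skipped
    return frags


# ---------------------------------------------------------------------------
# Binning and track algebra
# ---------------------------------------------------------------------------

def bin_fragments(
    frags: FragmentSet,
    genome: GenomeBuild,
    bin_size: int = DEFAULT_BIN_SIZE,
    counting_mode: str = "midpoint",
) -> BinnedTrack:
    """Count fragments into fixed-width bins.

    In midpoint mode each fragment adds 1 to the bin containing
    floor((start + end) / 2), so total counts are conserved.  In coverage mode
    each fragment adds 1 to every bin it overlaps.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if counting_mode not in ("midpoint", "coverage"):
        raise ValueError(f"unknown counting_mode {counting_mode!r}")

    values: dict[str, np.ndarray] = {
        c: np.zeros(math.ceil(l / bin_size), dtype=np.float64)
        for c, l in genome.chroms.items()
    }
    if len(frags):
        df = frags.df
        for chrom, sub in df.groupby("chrom", observed=True):
            nbins = len(values[str(chrom)])
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            if counting_mode == "midpoint":
                mids = (start + end) // 2
                counts = np.bincount(mids // bin_size, minlength=nbins)
                values[str(chrom)] += counts[:nbins]
            else:
                first = start // bin_size
                last = (end - 1) // bin_size  # inclusive
                delta = np.zeros(nbins + 1, dtype=np.float64)
                np.add.at(delta, first, 1.0)
                np.add.at(delta, np.minimum(last + 1, nbins), -1.0)
                values[str(chrom)] += np.cumsum(delta[:-1])
    return BinnedTrack(bin_size=bin_size, values=values, kind="raw",
                       counting_mode=counting_mode)


def _unmasked_genome_bases(track: BinnedTrack, genome: GenomeBuild) -> float:
    total = 0.0
    widths = track.bin_widths(genome)
    for chrom, vec in track.values.items():
        ok = ~np.isnan(vec)
        total += widths[chrom][ok].sum()
    return total


def normalize_track(raw: BinnedTrack, genome: GenomeBuild) -> BinnedTrack:
    """Depth-normalize: value_i = raw_i / total * unmasked genome length.

    With full-width bins the genome-wide mean of the result equals the bin
    size, and the sum over unmasked bins equals the unmasked genome length.
    """
    if raw.kind != "raw":
        raise ValueError("normalize_track expects a raw track")
    total = float(np.nansum(raw.flat()))
    if total <= 0:
        raise ValueError("empty track cannot be normalized")
    genome_bases = _unmasked_genome_bases(raw, genome)
    out = raw.copy(kind="normalized")
    scale = genome_bases / total
    for chrom in out.values:
        out.values[chrom] *= scale
    return out


def subtract_track(a: BinnedTrack, b: BinnedTrack) -> BinnedTrack:
    """ChIP minus input on matching grids; masks propagate from either side."""
    if not a.same_grid(b):
        raise ValueError("subtract_track requires matching bin grids")
    if a.kind != "normalized" or b.kind != "normalized":
        raise ValueError("subtract_track expects normalized tracks")
    out = a.copy(kind="difference")
    for chrom in out.values:
        out.values[chrom] = a.values[chrom] - b.values[chrom]
    return out


def log2_ratio_track(
    a: BinnedTrack,
    b: BinnedTrack,
    window: int = 10_000,
    pseudocount: float = 1.0,
) -> BinnedTrack:
    """Windowed log2(a/b) with a pseudocount, re-binned at window resolution."""
    if not a.same_grid(b):
        raise ValueError("log2_ratio_track requires matching bin grids")
    if window < a.bin_size:
        raise ValueError("window must be >= bin_size")
    if window % a.bin_size:
        raise ValueError("window must be a multiple of bin_size")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    per = window // a.bin_size
    out_values: dict[str, np.ndarray] = {}
    for chrom in a.values:
        va, vb = a.values[chrom], b.values[chrom]
        nwin = math.ceil(len(va) / per)
        pad = nwin * per - len(va)
        if pad:
            va = np.concatenate([va, np.full(pad, np.nan)])
            vb = np.concatenate([vb, np.full(pad, np.nan)])
        with np.errstate(invalid="ignore"):
            ma = np.nanmean(va.reshape(nwin, per), axis=1)
            mb = np.nanmean(vb.reshape(nwin, per), axis=1)
        out_values[chrom] = np.log2((ma + pseudocount) / (mb + pseudocount))
    return BinnedTrack(bin_size=window, values=out_values, kind="log2ratio",
                       counting_mode=a.counting_mode)


def mask_regions(track: BinnedTrack, genome: GenomeBuild) -> BinnedTrack:
    """NaN-out every bin overlapping an excluded interval.

    A normalized track is rescaled afterwards so the sum over surviving bins
    again equals the unmasked genome length; raw/difference/log2ratio values
    are left untouched apart from the mask.
    """
    out = track.copy()
    b = track.bin_size
    for chrom, ivs in genome.excluded.items():
        if chrom not in out.values:
            continue
        vec = out.values[chrom]
        for s, e in ivs:
            first = s // b
            last = (e - 1) // b
            vec[first : last + 1] = np.nan
    if track.kind == "normalized":
        total = float(np.nansum(out.flat()))
        if total > 0:
            target = _unmasked_genome_bases(out, genome)
            scale = target / total
            for chrom in out.values:
                out.values[chrom] *= scale
    return out


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def write_bedgraph(track: BinnedTrack, genome: GenomeBuild, path: str | Path) -> None:
    """Write a 4-column bedGraph; masked bins are omitted."""
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            length = genome.chroms[chrom]
            b = track.bin_size
            for i, v in enumerate(vec):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{i * b}\t{min((i + 1) * b, length)}\t{v:.6g}\n")


def read_bedgraph(
    path: str | Path, genome: GenomeBuild, bin_size: int, kind: str = "normalized"
) -> BinnedTrack:
    """Read a bin-aligned bedGraph back into a BinnedTrack (gaps become NaN)."""
    values = {
        c: np.full(math.ceil(l / bin_size), np.nan)
        for c, l in genome.chroms.items()
    }
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
        chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if chrom not in genome.chroms:
            raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
        if start % bin_size:
            raise ValueError(f"{path}: line {lineno}: interval not aligned to {bin_size}-bp grid")
        values[chrom][start // bin_size : math.ceil(end / bin_size)] = value
    return BinnedTrack(bin_size=bin_size, values=values, kind=kind)
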