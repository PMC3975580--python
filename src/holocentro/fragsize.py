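"""Fragment-geometry analytics.

MNase protection footprints are read out of paired-end fragment lengths:
size-class partitioning separates nucleosomal (141-500 bp) from
sub-nucleosomal (21-140 bp) particles, center-crossing length distributions
estimate the protected footprint of a particle at an anchored position, the
half-height width of an averaged occupancy peak sizes heavily digested
particles, and flanking-nucleosome dyads are located as the signal maxima on
either side of a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks import FragmentSet

__all__ = [
    "SizeClassSpec",
    "SizeDistribution",
    "partition_by_size",
    "crossing_size_distribution",
    "half_height_width",
    "locate_flanking_nucleosomes",
]

MAX_LENGTH = 1000  # histograms are defined over [1, 1000] bp


@dataclass(frozen=True)
class SizeClassSpec:
    """Named inclusive fragment-length ranges, e.g. small=21-140, nucleosomal=141-500."""

    classes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"small": (21, 140), "nucleosomal": (141, 500)}
    )

    def __post_init__(self) -> None:
        ranges = sorted(self.classes.values())
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"size class with lower bound {lo} > upper bound {hi}")
        for (_, hi1), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi1:
                raise ValueError("size classes must not overlap")


@dataclass
class SizeDistribution:
    """1-bp-resolution fragment-length histogram."""

    counts: np.ndarray  # index = length in bp, length MAX_LENGTH + 1; index 0 unused
    anchor_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != MAX_LENGTH + 1:
            raise ValueError(f"counts must cover lengths 0..{MAX_LENGTH}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def mode(self) -> int:
        """Most frequent length; ties break toward the smaller length."""
        if self.n_total == 0:
            raise ValueError("empty distribution has no mode")
        return int(np.argmax(self.counts))  # argmax is leftmost on ties

    def smoothed(self, width: int = 5) -> np.ndarray:
        """Centered running mean for plotting only; statistics use raw counts."""
        kernel = np.ones(width) / width
        return np.convolve(self.counts.astype(float), kernel, mode="same")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\n")
            for length in range(1, MAX_LENGTH + 1):
                if self.counts[length]:
                    fh.write(f"{length}\t{self.counts[length]}\n")


def partition_by_size(
    frags: FragmentSet, spec: SizeClassSpec | None = None
) -> tuple[dict[str, FragmentSet], int]:
    """Assign each fragment to at most one size class by length.

    Returns (class name -> FragmentSet, number of out-of-range fragments
    dropped); class membership partitions the input.
    """
    spec = spec or SizeClassSpec()
    lengths = frags.lengths
    out: dict[str, FragmentSet] = {}
    assigned = np.zeros(len(frags), dtype=bool)
    for name, (lo, hi) in spec.classes.items():
        mask = (lengths >= lo) & (lengths <= hi)
        out[name] = frags.subset(mask)
        assigned |= mask
    return out, int((~assigned).sum())


def crossing_size_distribution(
    frags: FragmentSet,
    anchors: list[tuple[str, int]],
    anchor_label: str = "",
) -> SizeDistribution:
    """Length histogram of fragments that cross anchor positions.

    A fragment crosses an anchor at ``pos`` iff start <= pos < end, and is
    counted once per anchor it covers.
    """
    if not anchors:
        raise ValueError("crossing_size_distribution needs at least one anchor")
    counts = np.zeros(MAX_LENGTH + 1, dtype=np.int64)
    anchor_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in anchors:
        anchor_by_chrom.setdefault(chrom, [])
    for chrom, pos in anchors:
        anchor_by_chrom[chrom].append(pos)
    anchor_by_chrom = {c: np.sort(np.asarray(v)) for c, v in anchor_by_chrom.items()}

    for chrom, sub in frags.df.groupby("chrom", observed=True):
        positions = anchor_by_chrom.get(str(chrom))
        if positions is None or not len(sub):
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        # anchors a with start <= a < end  <=>  a in [start, end)
        n_cross = np.searchsorted(positions, end, side="left") - np.searchsorted(
            positions, start, side="left"
        )
        lengths = np.clip(end - start, 0, MAX_LENGTH)
        np.add.at(counts, lengths, n_cross)
    counts[0] = 0
    return SizeDistribution(counts=counts, anchor_label=anchor_label)


def half_height_width(
    positions: np.ndarray,
    values: np.ndarray,
    baseline_fraction: float = 0.1,
) -> float:
    """Width of an averaged signal peak at half its baseline-corrected height.

    The baseline is the median of the outermost ``baseline_fraction`` of
    positions on each side; the half level is baseline + (max - baseline) / 2;
    the width is the distance between the two level crossings found by linear
    interpolation, moving outward from the maximum.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(positions) != len(values) or len(positions) < 5:
        raise ValueError("profile needs matched positions/values with >= 5 points")
    n_edge = max(1, int(round(baseline_fraction * len(values))))
    baseline = float(np.median(np.concatenate([values[:n_edge], values[-n_edge:]])))
    imax = int(np.argmax(values))
    peak = values[imax]
    if peak <= baseline:
        raise ValueError("profile has no peak above baseline")
    half = baseline + (peak - baseline) / 2.0

    def _cross(direction: int) -> float:
        i = imax
        while 0 <= i + direction < len(values):
            j = i + direction
            if values[j] < half <= values[i]:
                # linear interpolation between samples i and j
                frac = (values[i] - half) / (values[i] - values[j])
                return positions[i] + frac * (positions[j] - positions[i])
            i = j
        raise ValueError("unbounded peak")

    return float(abs(_cross(+1) - _cross(-1)))


def locate_flanking_nucleosomes(
    positions: np.ndarray,
    values: np.ndarray,
    exclusion_radius: int = 75,
) -> tuple[float, float]:
    """Positions of the maxima left of -radius and right of +radius.

    ``positions`` are bp offsets from the site center.  Ties break toward the
    center.  Raises on a flat profile.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    left = positions < -exclusion_radius
    right = positions > exclusion_radius
    if not left.any() or not right.any():
        raise ValueError("profile window must extend beyond the exclusion radius")
    if np.nanmax(values) == np.nanmin(values):
        raise ValueError("no flanking maxima")

    def _best(mask: np.ndarray) -> float:
        pos, val = positions[mask], values[mask]
        best = np.nanmax(val)
        cands = pos[val == best]
        return float(cands[np.argmin(np.abs(cands))])  # tie -> nearest center

    return _best(left), _best(right)
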