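"""Threshold peak calling on input-subtracted tracks.

Centromeric sites appear as sharp bins of high normalized signal, so peaks are
called by simple thresholding: maximal runs of contiguous bins at or above a
threshold (mean + k·SD of the genome-wide signal, or a fixed normalized count)
are peaks, replicate runs that overlap are unioned with support counting, and
the summit is the center of the bin with the maximum replicate-mean signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks import BinnedTrack, GenomeBuild, merge_intervals

__all__ = [
    "Peak",
    "PeakSet",
    "threshold_from_stats",
    "call_peaks",
    "peak_windows",
    "DEFAULT_THRESHOLDS",
]

# Track-specific default thresholds in normalized-count units.
DEFAULT_THRESHOLDS = {"cenH3-ChIP": 30.0, "CENP-C-ChIP": 20.0, "insoluble": 100.0}


@dataclass(frozen=True)
class Peak:
    chrom: str
    run_start: int  # bp, half-open run of above-threshold bins
    run_end: int
    summit: int  # bp, center of the maximum bin
    max_value: float
    support: int  # number of replicates with an above-threshold run here

    def __post_init__(self) -> None:
        if not (self.run_start <= self.summit < self.run_end):
            raise ValueError("summit must lie inside the run interval")
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class PeakSet:
    peaks: list[Peak]
    threshold: float
    track_label: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.summit))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def summits_by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p.summit)
        return {c: np.array(v, dtype=np.int64) for c, v in out.items()}

    def to_bed(self, path) -> None:
        """BED6: chrom, run_start, run_end, id, max_value, '.'"""
        with open(path, "w") as fh:
            for i, p in enumerate(self.peaks, 1):
                fh.write(
                    f"{p.chrom}\t{p.run_start}\t{p.run_end}\tpeak_{i}\t{p.max_value:.6g}\t.\n"
                )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\trun_start\trun_end\tsummit\tmax_value\tsupport\n")
            for p in self.peaks:
                fh.write(
                    f"{p.chrom}\t{p.run_start}\t{p.run_end}\t{p.summit}"
                    f"\t{p.max_value:.6g}\t{p.support}\n"
                )


def threshold_from_stats(track: BinnedTrack, k: float = 7.0) -> float:
    """mean + k·SD (population SD) of the genome-wide signal over unmasked bins."""
    flat = track.flat()
    flat = flat[~np.isnan(flat)]
    if len(flat) < 2:
        raise ValueError("need at least 2 unmasked bins to estimate a threshold")
    return float(np.mean(flat) + k * np.std(flat))


def _runs_at_or_above(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (bin index, half-open) of contiguous unmasked bins >= threshold."""
    ok = ~np.isnan(values) & (values >= threshold)
    if not ok.any():
        return []
    padded = np.concatenate([[False], ok, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def call_peaks(
    diff_tracks: list[BinnedTrack],
    threshold: float,
    min_support: int = 1,
) -> PeakSet:
    """Call peaks from one or more replicate difference tracks.

    Per replicate, maximal runs of bins >= threshold are found; overlapping
    runs from different replicates are unioned into one candidate, emitted iff
    at least ``min_support`` replicates contributed a run.  The summit is the
    center of the bin with the maximum replicate-mean signal inside the union
    (ties resolved leftmost), and ``max_value`` is that maximum.
    """
    if not diff_tracks:
        raise ValueError("call_peaks needs at least one track")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not (1 <= min_support <= len(diff_tracks)):
        raise ValueError("min_support out of range")
    first = diff_tracks[0]
    for t in diff_tracks[1:]:
        if not first.same_grid(t):
            raise ValueError("all replicate tracks must share the bin grid")
    b = first.bin_size

    peaks: list[Peak] = []
    for chrom in first.values:
        rep_runs = [
            _runs_at_or_above(t.values[chrom], threshold) for t in diff_tracks
        ]
        all_runs = [r for runs in rep_runs for r in runs]
        if not all_runs:
            continue
        candidates = merge_intervals(all_runs)
        # replicate-mean signal, NaN-tolerant
        stack = np.stack([t.values[chrom] for t in diff_tracks])
        with np.errstate(invalid="ignore"):
            mean_sig = np.nanmean(stack, axis=0)
        for s_bin, e_bin in candidates:
            support = sum(
                1
                for runs in rep_runs
                if any(rs < e_bin and re > s_bin for rs, re in runs)
            )
            if support < min_support:
                continue
            window = mean_sig[s_bin:e_bin]
            window = np.where(np.isnan(window), -np.inf, window)
            imax = int(np.argmax(window))  # argmax is leftmost on ties
            summit = (s_bin + imax) * b + b // 2
            peaks.append(
                Peak(
                    chrom=chrom,
                    run_start=s_bin * b,
                    run_end=e_bin * b,
                    summit=summit,
                    max_value=float(mean_sig[s_bin + imax]),
                    support=support,
                )
            )
    return PeakSet(peaks=peaks, threshold=threshold)


def peak_windows(
    peaks: PeakSet,
    width: int = 200,
    genome: GenomeBuild | None = None,
) -> tuple[list[tuple[str, int, int]], int]:
    """Fixed-width windows centered on summits, clipped to chromosome bounds.

    Returns the per-peak windows and the total bp covered by their union.
    """
    if width % 2 or width < 1:
        raise ValueError("width must be a positive even number")
    half = width // 2
    windows: list[tuple[str, int, int]] = []
    for p in peaks:
        start = max(0, p.summit - half)
        end = p.summit + half
        if genome is not None:
            end = min(end, genome.chroms[p.chrom])
        windows.append((p.chrom, start, end))
    union = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in windows:
        by_chrom.setdefault(chrom, []).append((s, e))
    for ivs in by_chrom.values():
        union += sum(e - s for s, e in merge_intervals(ivs))
    return windows, union
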