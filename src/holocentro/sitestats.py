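"""Site-centered aggregation and interval statistics.

Covers heatmap/average-profile matrices around anchor sets, per-group
occupancy summaries, interval-overlap counting with hypergeometric and
permutation tests, coverage-normalized peak densities and fold enrichments,
windowed track correlations, inter-peak distances and feature density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, linregress

from .peaks import PeakSet
from .tracks import BinnedTrack, GenomeBuild, merge_intervals

__all__ = [
    "ProfileMatrix",
    "OverlapResult",
    "site_matrix",
    "average_profile",
    "group_occupancy_summary",
    "overlap_count",
    "fold_enrichment",
    "hypergeometric_overlap",
    "permutation_overlap_test",
    "windowed_correlation",
    "interpeak_distances",
    "feature_density",
]

Interval = tuple[str, int, int]
Anchor = tuple[str, int]


# ---------------------------------------------------------------------------
# Profile matrices
# ---------------------------------------------------------------------------

@dataclass
class ProfileMatrix:
    """Anchor-by-position signal matrix for heatmaps and average profiles."""

    anchors: list[Anchor]  # in row order (after sorting)
    offsets: np.ndarray  # bp offset of each column's bin center from the anchor
    values: np.ndarray  # shape (n_anchors, n_cols); NaN = missing
    sort_key: str = "signal"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.anchors), len(self.offsets)):
            raise ValueError("matrix shape must match anchors x offsets")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\t" + "\t".join(f"{o:g}" for o in self.offsets) + "\n")
            for (chrom, pos), row in zip(self.anchors, self.values):
                fh.write(f"{chrom}\t{pos}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def site_matrix(
    track: BinnedTrack,
    anchors: list[Anchor],
    window: int = 2000,
    sort_by: str | np.ndarray = "signal",
) -> ProfileMatrix:
    """Signal in [anchor - window/2, anchor + window/2) per anchor.

    Rows near chromosome ends are NaN-padded.  ``sort_by="signal"`` orders rows
    by descending row sum; an explicit array of per-anchor keys sorts by that
    key descending; ``"none"`` keeps input order.
    """
    if not anchors:
        raise ValueError("site_matrix needs at least one anchor")
    b = track.bin_size
    if window % (2 * b):
        raise ValueError("window must be an even multiple of bin_size")
    half_bins = window // 2 // b
    ncols = 2 * half_bins
    values = np.full((len(anchors), ncols), np.nan)
    for i, (chrom, pos) in enumerate(anchors):
        vec = track.values[chrom]
        center_bin = pos // b
        lo, hi = center_bin - half_bins, center_bin + half_bins
        src_lo, src_hi = max(lo, 0), min(hi, len(vec))
        if src_lo < src_hi:
            values[i, src_lo - lo : src_hi - lo] = vec[src_lo:src_hi]
    offsets = (np.arange(ncols) - half_bins) * b + b / 2.0

    if isinstance(sort_by, str) and sort_by == "signal":
        key = np.nansum(np.where(np.isnan(values), 0.0, values), axis=1)
        sort_label = "signal"
    elif isinstance(sort_by, str) and sort_by == "none":
        key = None
        sort_label = "none"
    else:
        key = np.asarray(sort_by, dtype=float)
        if len(key) != len(anchors):
            raise ValueError("sort key length must match anchor count")
        sort_label = "external"
    if key is not None:
        order = np.argsort(-key, kind="stable")
        values = values[order]
        anchors = [anchors[i] for i in order]
    return ProfileMatrix(anchors=anchors, offsets=offsets, values=values,
                         sort_key=sort_label)


def average_profile(m: ProfileMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column means over non-missing cells, plus contributing row counts."""
    if m.values.size == 0:
        raise ValueError("empty matrix")
    counts = (~np.isnan(m.values)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(m.values, axis=0)
    means[counts == 0] = np.nan
    return means, counts


# ---------------------------------------------------------------------------
# Group occupancy
# ---------------------------------------------------------------------------

def group_occupancy_summary(
    track: BinnedTrack,
    groups: dict[str, list[Interval]],
) -> dict[str, dict]:
    """Per-element mean signal, then a five-number summary per group.

    Elements with all bins masked are skipped; an empty group is reported with
    n=0 and no summary.
    """
    if not groups:
        raise ValueError("no groups provided")
    b = track.bin_size
    out: dict[str, dict] = {}
    for name, intervals in groups.items():
        means: list[float] = []
        for chrom, s, e in intervals:
            vec = track.values[chrom]
            window = vec[s // b : -(-e // b)]
            if len(window) and not np.isnan(window).all():
                means.append(float(np.nanmean(window)))
        if not means:
            out[name] = {"n": 0}
            continue
        arr = np.array(means)
        out[name] = {
            "n": len(arr),
            "min": float(arr.min()),
            "q1": float(np.percentile(arr, 25)),
            "median": float(np.median(arr)),
            "q3": float(np.percentile(arr, 75)),
            "max": float(arr.max()),
            "element_means": arr,
        }
    return out


# ---------------------------------------------------------------------------
# Overlap counting and enrichment
# ---------------------------------------------------------------------------

def _intervals_by_chrom(intervals: list[Interval]) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by.setdefault(chrom, []).append((s, e))
    return {c: np.array(merge_intervals(v)) for c, v in by.items()}


def _summits_in_intervals(
    positions: np.ndarray, merged: np.ndarray
) -> np.ndarray:
    """Boolean mask: position falls inside a merged half-open interval."""
    if merged.size == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(merged[:, 0], positions, side="right") - 1
    ok = idx >= 0
    ok[ok] &= positions[ok] < merged[idx[ok], 1]
    return ok


def overlap_count(
    set_a: list[Anchor] | list[Interval],
    set_b: list[Interval],
    rule: str = "summit-in-interval",
) -> int:
    """Number of A elements coinciding with B (each counted at most once).

    ``summit-in-interval``: A is a list of (chrom, pos) summits, counted when
    the summit falls inside a B interval.  ``any-overlap``: A is a list of
    intervals, counted when it overlaps any B interval.
    """
    b_by = _intervals_by_chrom(set_b)
    n = 0
    if rule == "summit-in-interval":
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in set_a:  # type: ignore[misc]
            by_chrom.setdefault(chrom, []).append(pos)
        for chrom, positions in by_chrom.items():
            merged = b_by.get(chrom, np.empty((0, 2), dtype=int))
            n += int(_summits_in_intervals(np.asarray(positions), merged).sum())
    elif rule == "any-overlap":
        for chrom, s, e in set_a:  # type: ignore[misc]
            merged = b_by.get(chrom)
            if merged is None or merged.size == 0:
                continue
            i = np.searchsorted(merged[:, 1], s, side="right")
            if i < len(merged) and merged[i, 0] < e:
                n += 1
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return n


def fold_enrichment(
    counts: dict[str, int],
    coverages: dict[str, float],
    per: float = 1e7,
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Coverage-normalized densities and all pairwise fold ratios.

    density_g = n_g / coverage_g * per (default per 10 Mb);
    fold[(a, b)] = density_a / density_b.
    """
    for g, cov in coverages.items():
        if cov <= 0:
            raise ValueError(f"group {g!r} has zero coverage")
    densities = {g: counts[g] / coverages[g] * per for g in counts}
    ratios: dict[tuple[str, str], float] = {}
    for a in counts:
        for b in counts:
            if a == b:
                continue
            if densities[b] == 0:
                if counts[a] == 0:
                    ratios[(a, b)] = 0.0
                else:
                    raise ValueError(f"zero density in denominator group {b!r}")
            else:
                ratios[(a, b)] = densities[a] / densities[b]
    return densities, ratios


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    p_hypergeometric: float | None = None
    p_permutation: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_overlap <= min(self.n_a, self.n_b)):
            raise ValueError("overlap count out of range")


def hypergeometric_overlap(n_universe: int, k_pop: int, n_draw: int, k_observed: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    ``n_universe`` is the total number of sites in the universe, ``k_pop`` the
    number marked (e.g. centromeric), ``n_draw`` the number drawn (e.g. HOT
    sites), ``k_observed`` the observed overlap.  Survives tails down to
    ~1e-300.
    """
    if not (0 <= k_observed <= min(k_pop, n_draw) <= n_universe):
        raise ValueError("inconsistent counts for hypergeometric test")
    if k_observed == 0:
        return 1.0
    ks = np.arange(k_observed, min(k_pop, n_draw) + 1)
    logp = hypergeom.logpmf(ks, n_universe, k_pop, n_draw)
    return float(np.exp(logsumexp(logp)))


def _callable_gaps(genome: GenomeBuild, chrom: str) -> np.ndarray:
    """Unmasked (callable) intervals of a chromosome as an (n, 2) array."""
    length = genome.chroms[chrom]
    gaps = []
    prev = 0
    for s, e in genome.excluded.get(chrom, []):
        if s > prev:
            gaps.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        gaps.append((prev, length))
    return np.array(gaps, dtype=np.int64).reshape(-1, 2)


def permutation_overlap_test(
    set_a: list[Anchor],
    set_b: list[Interval],
    genome: GenomeBuild,
    n_perm: int = 1000,
    seed: int = 0,
    side: str = "depleted",
) -> tuple[float, int]:
    """Empirical p-value for overlap of A summits with B intervals.

    Summits are re-placed uniformly on the callable (unmasked) genome per
    permutation, preserving per-chromosome counts;
    p = (1 + #{permutations at least as extreme}) / (n_perm + 1), where
    "extreme" means overlap <= observed (``depleted``) or >= observed
    (``enriched``).  Returns (p, observed overlap).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if side not in ("depleted", "enriched"):
        raise ValueError(f"unknown side {side!r}")
    observed = overlap_count(set_a, set_b, rule="summit-in-interval")
    b_by = _intervals_by_chrom(set_b)

    counts_by_chrom: dict[str, int] = {}
    for chrom, _ in set_a:
        counts_by_chrom[chrom] = counts_by_chrom.get(chrom, 0) + 1

    rng = np.random.default_rng(seed)
    perm_overlaps = np.zeros(n_perm, dtype=np.int64)
    for chrom, n_summits in counts_by_chrom.items():
        gaps = _callable_gaps(genome, chrom)
        widths = gaps[:, 1] - gaps[:, 0]
        callable_len = int(widths.sum())
        if callable_len <= 0:
            raise ValueError(f"no callable sequence on chromosome {chrom!r}")
        cum = np.concatenate([[0], np.cumsum(widths)])
        merged = b_by.get(chrom, np.empty((0, 2), dtype=int))
        draws = rng.integers(0, callable_len, size=(n_perm, n_summits))
        gap_idx = np.searchsorted(cum, draws, side="right") - 1
        positions = gaps[gap_idx, 0] + (draws - cum[gap_idx])
        hits = _summits_in_intervals(positions.ravel(), merged).reshape(n_perm, n_summits)
        perm_overlaps += hits.sum(axis=1)

    if side == "depleted":
        extreme = int((perm_overlaps <= observed).sum())
    else:
        extreme = int((perm_overlaps >= observed).sum())
    return (1 + extreme) / (n_perm + 1), observed


# ---------------------------------------------------------------------------
# Correlation, distances, density
# ---------------------------------------------------------------------------

def windowed_correlation(
    a: BinnedTrack, b: BinnedTrack, window: int = 10_000
) -> tuple[float, float, float]:
    """Pearson r and least-squares slope/intercept over per-window means.

    Windows with a missing value on either side are dropped pairwise.
    """
    if not a.same_grid(b):
        raise ValueError("windowed_correlation requires matching grids")
    if window % a.bin_size:
        raise ValueError("window must be a multiple of bin_size")
    per = window // a.bin_size
    xs, ys = [], []
    for chrom in a.values:
        va, vb = a.values[chrom], b.values[chrom]
        nwin = len(va) // per  # drop ragged tail window
        if nwin == 0:
            continue
        with np.errstate(invalid="ignore"):
            ma = np.nanmean(va[: nwin * per].reshape(nwin, per), axis=1)
            mb = np.nanmean(vb[: nwin * per].reshape(nwin, per), axis=1)
        ok = ~np.isnan(ma) & ~np.isnan(mb)
        xs.append(ma[ok])
        ys.append(mb[ok])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if len(x) < 3:
        raise ValueError("need at least 3 windows with both sides unmasked")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance on one side")
    fit = linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def interpeak_distances(
    peaks: PeakSet | dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Distances between consecutive summits within each chromosome.

    Accepts a PeakSet or a chrom -> sorted summit-position mapping.  Returns
    (per-chromosome distance arrays, pooled summary with min/median/max).
    Distances never span chromosomes.
    """
    if isinstance(peaks, PeakSet):
        summits = peaks.summits_by_chrom()
    else:
        summits = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in peaks.items()}
    dists = {c: np.diff(v) for c, v in summits.items() if len(v) >= 2}
    pooled = np.concatenate(list(dists.values())) if dists else np.array([])
    if len(pooled) == 0:
        raise ValueError("need at least 2 peaks on one chromosome")
    summary = {
        "min": float(pooled.min()),
        "median": float(np.median(pooled)),
        "max": float(pooled.max()),
        "n": int(len(pooled)),
    }
    return dists, summary


def feature_density(
    anchors: list[Anchor],
    features: list[Interval],
    window: int = 2000,
    n_bins: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of anchors whose window bin overlaps a feature, per position bin.

    Returns (bin-center offsets from the anchor, per-bin fractions).
    """
    if window % 2:
        raise ValueError("window must be even")
    if not anchors:
        raise ValueError("feature_density needs at least one anchor")
    half = window / 2.0
    edges = np.linspace(-half, half, n_bins + 1)
    by_chrom = _intervals_by_chrom(features)
    hits = np.zeros(n_bins, dtype=np.int64)
    for chrom, pos in anchors:
        merged = by_chrom.get(chrom, np.empty((0, 2), dtype=int))
        for j in range(n_bins):
            s = pos + edges[j]
            e = pos + edges[j + 1]
            if merged.size:
                i = np.searchsorted(merged[:, 1], s, side="right")
                if i < len(merged) and merged[i, 0] < e:
                    hits[j] += 1
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, hits / len(anchors)
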