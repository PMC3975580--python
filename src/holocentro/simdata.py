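"""Synthetic paired-end MNase fragment scenarios with planted ground truth.

The generator emulates the chromatin architecture the pipeline is built to
analyze: dispersed point-centromere sites where a sub-nucleosomal particle
(60-100 bp protection) sits between two positioned canonical nucleosomes at
+-150 bp; broad ~10-kb domains of mild enrichment protecting 135-155 bp;
an MNase time course in which centromeric particles decay faster than
nucleosomes; a depletion condition with reduced site-derived ChIP signal; and
a HOT-site interval set partially coincident with the planted sites.

The digestion model is phenomenological: fragment abundance per particle
class decays exponentially with digestion time (survival exp(-lambda*t)),
and fragment length is protection size plus a residual linker that is trimmed
as exp(-lambda*t), plus Gaussian jitter, truncated to [21, 500] bp.  With the
default rates a canonical nucleosome yields ~167-bp fragments at 2 min
(147-bp core + partially trimmed 40-bp linker), matching light digestion.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .tracks import FragmentSet, GenomeBuild

__all__ = ["ScenarioConfig", "TruthSet", "simulate_scenario", "write_scenario",
           "read_scenario", "DEFAULT_TRACK_PLAN"]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]

TrackKey = tuple[str, float, str, str]  # (track, minutes, replicate, condition)

# Which (track, minutes, replicate, condition) fragment sets a default
# scenario produces: an input/ChIP time course with duplicate 2-min
# replicates, the depletion condition at the reference 2-min digestion, and
# light/heavy insoluble chromatin.
DEFAULT_TRACK_PLAN: tuple[TrackKey, ...] = (
    ("input", 1.0, "1", "wildtype"),
    ("input", 2.0, "1", "wildtype"),
    ("input", 2.0, "2", "wildtype"),
    ("input", 5.0, "1", "wildtype"),
    ("input", 10.0, "1", "wildtype"),
    ("cenH3-ChIP", 1.0, "1", "wildtype"),
    ("cenH3-ChIP", 2.0, "1", "wildtype"),
    ("cenH3-ChIP", 2.0, "2", "wildtype"),
    ("cenH3-ChIP", 5.0, "1", "wildtype"),
    ("cenH3-ChIP", 10.0, "1", "wildtype"),
    ("input", 2.0, "1", "knl2-depleted"),
    ("cenH3-ChIP", 2.0, "1", "knl2-depleted"),
    ("insoluble", 2.0, "1", "wildtype"),
    ("insoluble", 10.0, "1", "wildtype"),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a synthetic scenario; defaults are the reference setup."""

    seed: int = 7
    n_chroms: int = 1
    chrom_length: int = 5_000_000
    n_sites: int = 50
    # centromeric particle geometry
    site_protection_range: tuple[int, int] = (60, 100)  # bp, uniform
    site_center_jitter_sd: float = 5.0  # bp, fragment placement around the site
    site_linker_bp: float = 40.0  # residual linker at t=0, trimmed at lambda_cen
    # flanking nucleosomes
    flanking_offset: int = 150  # bp from the site center
    flanking_jitter_sd: float = 10.0  # positional jitter of the planted dyads
    # canonical nucleosome digestion
    nucleosome_core_bp: float = 147.0
    linker_bp: float = 40.0
    lambda_nuc: float = 0.35  # per minute; trimming and nucleosomal survival
    lambda_cen_factor: float = 2.0  # lambda_cen = factor * lambda_nuc
    lambda_insoluble_factor: float = 0.3  # lambda_ins = factor * lambda_cen
    length_jitter_sd: float = 8.0
    fragment_center_sd: float = 4.0  # placement noise around a planted dyad
    # domains of mild enrichment
    n_domains: int = 100
    domain_width_bp: int = 10_000
    domain_fragment_range: tuple[int, int] = (135, 155)
    # enrichment and depletion factors
    chip_enrichment: float = 30.0
    domain_chip_enrichment: float = 2.0
    knl2_factor: float = 0.15
    # HOT sites
    hot_fraction: float = 0.5
    hot_extra: int = 25
    hot_width: int = 200
    # sequencing depth (expected counts at t=0; abundance decays with digestion)
    background_frags_per_kb: float = 150.0
    site_frags_per_site: float = 20.0  # input level; ChIP multiplies by enrichment
    flank_frags_per_dyad: float = 30.0
    # fragment-length truncation
    min_length: int = 21
    max_length: int = 500
    # placement constraints
    min_site_spacing: int = 2000
    site_edge_margin: int = 1000
    track_plan: tuple[TrackKey, ...] = DEFAULT_TRACK_PLAN

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length <= 0 or self.n_sites < 0:
            raise ValueError("invalid genome/site configuration")
        if not (0.0 <= self.hot_fraction <= 1.0):
            raise ValueError("hot_fraction must be in [0, 1]")
        for name in ("chip_enrichment", "domain_chip_enrichment", "knl2_factor",
                     "background_frags_per_kb", "site_frags_per_site",
                     "flank_frags_per_dyad", "lambda_nuc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def lambda_cen(self) -> float:
        return self.lambda_cen_factor * self.lambda_nuc

    @property
    def lambda_insoluble(self) -> float:
        return self.lambda_insoluble_factor * self.lambda_cen


@dataclass
class TruthSet:
    """Planted ground truth serialized alongside the fragments."""

    sites: list[tuple[str, int]]
    protection: list[int]  # bp per site, parallel to sites
    flanking_dyads: list[tuple[str, int]]  # two per site
    domains: list[tuple[str, int, int]]
    hot_sites: list[tuple[str, int, int]]
    condition_factors: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sites": [[c, int(p)] for c, p in self.sites],
                    "protection": [int(p) for p in self.protection],
                    "flanking_dyads": [[c, int(p)] for c, p in self.flanking_dyads],
                    "domains": [[c, int(s), int(e)] for c, s, e in self.domains],
                    "hot_sites": [[c, int(s), int(e)] for c, s, e in self.hot_sites],
                    "condition_factors": self.condition_factors,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            sites=[(c, p) for c, p in d["sites"]],
            protection=list(d["protection"]),
            flanking_dyads=[(c, p) for c, p in d["flanking_dyads"]],
            domains=[(c, s, e) for c, s, e in d["domains"]],
            hot_sites=[(c, s, e) for c, s, e in d["hot_sites"]],
            condition_factors=d["condition_factors"],
        )


def _chrom_names(n: int) -> list[str]:
    return [f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}" for i in range(n)]


def _place_spaced(
    rng: np.random.Generator, n: int, lo: int, hi: int, spacing: int
) -> np.ndarray:
    """n sorted positions in [lo, hi) with pairwise distance >= spacing."""
    if n == 0:
        return np.array([], dtype=np.int64)
    avail = (hi - lo) - (n - 1) * spacing
    if avail <= 0:
        raise ValueError("infeasible placement: too many sites for the genome")
    raw = np.sort(rng.uniform(0, avail, size=n))
    return (lo + raw + np.arange(n) * spacing).astype(np.int64)


def _plant_truth(config: ScenarioConfig, rng: np.random.Generator,
                 genome: GenomeBuild) -> TruthSet:
    chroms = list(genome.chroms)
    total = genome.total_length
    # distribute sites/domains across chromosomes proportional to length
    site_counts = {c: int(round(config.n_sites * genome.chroms[c] / total)) for c in chroms}
    drift = config.n_sites - sum(site_counts.values())
    site_counts[chroms[0]] += drift

    sites: list[tuple[str, int]] = []
    dyads: list[tuple[str, int]] = []
    for chrom in chroms:
        positions = _place_spaced(
            rng,
            site_counts[chrom],
            config.site_edge_margin,
            genome.chroms[chrom] - config.site_edge_margin,
            config.min_site_spacing,
        )
        for pos in positions:
            sites.append((chrom, int(pos)))
            for sign in (-1, +1):
                dyad = pos + sign * config.flanking_offset + rng.normal(
                    0, config.flanking_jitter_sd
                )
                dyads.append((chrom, int(round(dyad))))
    lo, hi = config.site_protection_range
    protection = rng.integers(lo, hi + 1, size=len(sites)).tolist()

    # domains, placed independently of sites
    domain_counts = {c: int(round(config.n_domains * genome.chroms[c] / total)) for c in chroms}
    domain_counts[chroms[0]] += config.n_domains - sum(domain_counts.values())
    domains: list[tuple[str, int, int]] = []
    for chrom in chroms:
        for _ in range(domain_counts[chrom]):
            width = int(config.domain_width_bp * rng.uniform(0.8, 1.2))
            start = int(rng.integers(0, max(1, genome.chroms[chrom] - width)))
            domains.append((chrom, start, start + width))
    domains.sort()

    # HOT sites: a fraction of the planted sites plus extra decoys
    n_hot = int(np.floor(config.hot_fraction * len(sites)))
    hot: list[tuple[str, int, int]] = []
    if n_hot:
        chosen = rng.choice(len(sites), size=n_hot, replace=False)
        for i in sorted(chosen):
            chrom, pos = sites[i]
            hot.append((chrom, pos - config.hot_width // 2, pos + config.hot_width // 2))
    for _ in range(config.hot_extra):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(config.site_edge_margin,
                                 genome.chroms[chrom] - config.hot_width))
        hot.append((chrom, start, start + config.hot_width))
    hot.sort()

    return TruthSet(
        sites=sites,
        protection=protection,
        flanking_dyads=dyads,
        domains=domains,
        hot_sites=hot,
        condition_factors={
            "chip_enrichment": config.chip_enrichment,
            "domain_chip_enrichment": config.domain_chip_enrichment,
            "knl2_factor": config.knl2_factor,
        },
    )


def _draw_fragments(
    rng: np.random.Generator,
    config: ScenarioConfig,
    centers: np.ndarray,
    lengths: np.ndarray,
    chrom_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Turn particle centers + protected lengths into clipped (start, end) arrays."""
    lengths = np.clip(np.round(lengths), config.min_length, config.max_length)
    start = np.round(centers - lengths / 2.0).astype(np.int64)
    end = (start + lengths).astype(np.int64)
    start = np.clip(start, 0, chrom_length - 1)
    end = np.clip(end, 1, chrom_length)
    ok = start < end
    return start[ok], end[ok]


def _simulate_one(
    rng: np.random.Generator,
    config: ScenarioConfig,
    genome: GenomeBuild,
    truth: TruthSet,
    track: str,
    minutes: float,
    condition: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fragment arrays (chrom codes, start, end) for one track/time/condition."""
    s_nuc = np.exp(-config.lambda_nuc * minutes)
    s_cen = np.exp(-config.lambda_cen * minutes)
    s_ins = np.exp(-config.lambda_insoluble * minutes)
    nuc_len = config.nucleosome_core_bp + config.linker_bp * s_nuc
    site_extra = config.site_linker_bp * s_cen

    chrom_codes: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    chroms = list(genome.chroms)

    def _emit(chrom: str, s: np.ndarray, e: np.ndarray) -> None:
        chrom_codes.append(np.full(len(s), chroms.index(chrom), dtype=np.int16))
        starts.append(s)
        ends.append(e)

    # 1) genome-wide background nucleosomal fragments
    for chrom in chroms:
        length = genome.chroms[chrom]
        n = rng.poisson(config.background_frags_per_kb * length / 1000.0 * s_nuc)
        centers = rng.uniform(0, length, size=n)
        lens = nuc_len + rng.normal(0, config.length_jitter_sd, size=n)
        _emit(chrom, *_draw_fragments(rng, config, centers, lens, length))

    # 2) positioned flanking nucleosomes (input and insoluble chromatin only;
    #    the cenH3 antibody does not pull down the neighbors)
    if track in ("input", "insoluble"):
        for chrom, dyad in truth.flanking_dyads:
            length = genome.chroms[chrom]
            n = rng.poisson(config.flank_frags_per_dyad * s_nuc)
            centers = dyad + rng.normal(0, config.fragment_center_sd, size=n)
            lens = nuc_len + rng.normal(0, config.length_jitter_sd, size=n)
            _emit(chrom, *_draw_fragments(rng, config, centers, lens, length))

    # 3) centromeric site particles
    if track == "input":
        site_factor, survival = 1.0, s_cen
    elif track == "cenH3-ChIP":
        site_factor, survival = config.chip_enrichment, s_cen
        if condition == "knl2-depleted":
            site_factor *= config.knl2_factor
    elif track == "insoluble":
        site_factor, survival = config.chip_enrichment, s_ins
        if condition == "knl2-depleted":
            site_factor *= config.knl2_factor
    else:
        raise ValueError(f"unknown track {track!r}")
    for (chrom, pos), prot in zip(truth.sites, truth.protection):
        length = genome.chroms[chrom]
        n = rng.poisson(config.site_frags_per_site * site_factor * survival)
        centers = pos + rng.normal(0, config.site_center_jitter_sd, size=n)
        lens = prot + site_extra + rng.normal(0, config.length_jitter_sd, size=n)
        _emit(chrom, *_draw_fragments(rng, config, centers, lens, length))

    # 4) mild domain enrichment in ChIP (lost in the depletion condition)
    if track == "cenH3-ChIP" and condition != "knl2-depleted":
        extra = config.domain_chip_enrichment - 1.0
        lo, hi = config.domain_fragment_range
        for chrom, d_start, d_end in truth.domains:
            length = genome.chroms[chrom]
            n = rng.poisson(extra * config.background_frags_per_kb
                            * (d_end - d_start) / 1000.0 * s_nuc)
            centers = rng.uniform(d_start, d_end, size=n)
            lens = rng.uniform(lo, hi + 1, size=n)
            _emit(chrom, *_draw_fragments(rng, config, centers, lens, length))

    code = np.concatenate(chrom_codes) if chrom_codes else np.array([], dtype=np.int16)
    s = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    e = np.concatenate(ends) if ends else np.array([], dtype=np.int64)
    order = np.lexsort((s, code))
    return code[order], s[order], e[order]


def simulate_scenario(
    config: ScenarioConfig,
) -> tuple[dict[TrackKey, FragmentSet], TruthSet, GenomeBuild]:
    """Generate all fragment sets of a scenario plus planted truth and genome.

    Fully deterministic for a given config (including seed).
    """
    genome = GenomeBuild(
        chroms={name: config.chrom_length for name in _chrom_names(config.n_chroms)}
    )
    truth_rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    truth = _plant_truth(config, truth_rng, genome)

    chroms = np.array(list(genome.chroms))
    datasets: dict[TrackKey, FragmentSet] = {}
    for i, (track, minutes, replicate, condition) in enumerate(config.track_plan):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i + 1,))
        )
        code, s, e = _simulate_one(rng, config, genome, truth, track, minutes, condition)
        datasets[(track, minutes, replicate, condition)] = FragmentSet.from_arrays(
            chroms[code],
            s,
            e,
            track=track,
            replicate=replicate,
            mnase_minutes=minutes,
            condition=condition,
        )
    return datasets, truth, genome


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _fragset_filename(key: TrackKey) -> str:
    track, minutes, replicate, condition = key
    return f"{track}_t{minutes:g}min_rep{replicate}_{condition}.bedpe"


def parse_fragset_filename(name: str) -> TrackKey:
    stem = Path(name).name.removesuffix(".bedpe")
    track, t_part, rep_part, condition = stem.rsplit("_", 3)
    return (
        track,
        float(t_part.removeprefix("t").removesuffix("min")),
        rep_part.removeprefix("rep"),
        condition,
    )


def write_scenario(
    datasets: dict[TrackKey, FragmentSet],
    truth: TruthSet,
    genome: GenomeBuild,
    out_dir: str | Path,
    read_length: int = 25,
) -> list[Path]:
    """Write one BEDPE per fragment set, chrom.sizes, truth BED/JSON.

    BEDPE mates are the two fragment ends (``read_length`` bp each, shorter
    for short fragments); the reader's outermost-span convention recovers the
    fragment multiset exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for key, frags in datasets.items():
        path = out / _fragset_filename(key)
        with open(path, "w") as fh:
            for i, (chrom, s, e) in enumerate(
                zip(frags.df["chrom"], frags.df["start"], frags.df["end"]), 1
            ):
                r = min(read_length, e - s)
                fh.write(
                    f"{chrom}\t{s}\t{s + r}\t{chrom}\t{e - r}\t{e}"
                    f"\tfrag_{i}\t0\t+\t-\n"
                )
        written.append(path)
    sizes = out / "chrom.sizes"
    with open(sizes, "w") as fh:
        for name, length in genome.chroms.items():
            fh.write(f"{name}\t{length}\n")
    written.append(sizes)
    truth_json = out / "truth.json"
    truth.to_json(truth_json)
    written.append(truth_json)
    sites_bed = out / "truth_sites.bed"
    with open(sites_bed, "w") as fh:
        for (chrom, pos), prot in zip(truth.sites, truth.protection):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tsite\t{prot}\t.\n")
    written.append(sites_bed)
    return written


def read_scenario(
    in_dir: str | Path, genome: GenomeBuild, min_length: int = 21, max_length: int = 500
) -> dict[TrackKey, FragmentSet]:
    """Read every scenario BEDPE in a directory back into fragment sets."""
    from .tracks import read_fragments

    out: dict[TrackKey, FragmentSet] = {}
    for path in sorted(Path(in_dir).glob("*.bedpe")):
        key = parse_fragset_filename(path.name)
        track, minutes, replicate, condition = key
        fs = read_fragments(path, "bedpe", genome, min_length=min_length,
                            max_length=max_length, track=track, replicate=replicate,
                            mnase_minutes=minutes, condition=condition)
        out[key] = fs
    return out


def scenario_digest(datasets: dict[TrackKey, FragmentSet]) -> str:
    """SHA-256 over all fragment coordinates, for determinism checks."""
    h = hashlib.sha256()
    for key in sorted(datasets):
        h.update(repr(key).encode())
        df = datasets[key].df
        h.update(np.ascontiguousarray(df["start"].to_numpy()).tobytes())
        h.update(np.ascontiguousarray(df["end"].to_numpy()).tobytes())
    return h.hexdigest()


def default_config_dict() -> dict:
    """All defaults as a plain dict (for --dump-defaults)."""
    d = asdict(ScenarioConfig())
    d["track_plan"] = [list(k) for k in d["track_plan"]]
    return d
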