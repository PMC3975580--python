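import numpy as np
import pytest

import holocentro as hc


@pytest.fixture(scope="session")
def default_scenario():
    """The reference synthetic scenario: 1 chromosome x 5 Mb, 50 planted sites."""
    cfg = hc.ScenarioConfig()
    datasets, truth, genome = hc.simulate_scenario(cfg)
    return cfg, datasets, truth, genome


@pytest.fixture(scope="session")
def reference_diff_tracks(default_scenario):
    """Normalized ChIP-minus-input difference tracks for the two 2-min replicates."""
    _, ds, _, genome = default_scenario

    def norm(key):
        return hc.normalize_track(hc.bin_fragments(ds[key], genome, 10), genome)

    d1 = hc.subtract_track(
        norm(("cenH3-ChIP", 2.0, "1", "wildtype")), norm(("input", 2.0, "1", "wildtype"))
    )
    d2 = hc.subtract_track(
        norm(("cenH3-ChIP", 2.0, "2", "wildtype")), norm(("input", 2.0, "2", "wildtype"))
    )
    return d1, d2


@pytest.fixture(scope="session")
def reference_peaks(default_scenario, reference_diff_tracks):
    d1, d2 = reference_diff_tracks
    threshold = hc.threshold_from_stats(d1, 7.0)
    return hc.call_peaks([d1, d2], threshold=threshold, min_support=1)


@pytest.fixture
def toy_genome():
    return hc.GenomeBuild(chroms={"chrI": 1000})


def make_track(values, bin_size=10, kind="difference", chrom="chrI"):
    return hc.BinnedTrack(
        bin_size=bin_size, values={chrom: np.asarray(values, dtype=float)}, kind=kind
    )


def match_sites(peakset, truth_sites, tol=100):
    """(n true positives, n false positives, n missed) for summit-vs-truth matching."""
    by_chrom = {}
    for chrom, pos in truth_sites:
        by_chrom.setdefault(chrom, []).append(pos)
    by_chrom = {c: np.sort(v) for c, v in by_chrom.items()}
    tp = 0
    hit = {c: np.zeros(len(v), dtype=bool) for c, v in by_chrom.items()}
    for p in peakset:
        sites = by_chrom.get(p.chrom, np.array([]))
        if len(sites):
            i = np.argmin(np.abs(sites - p.summit))
            if abs(sites[i] - p.summit) <= tol:
                tp += 1
                hit[p.chrom][i] = True
                continue
    fp = len(peakset) - tp
    missed = sum(int((~h).sum()) for h in hit.values())
    return tp, fp, missed
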