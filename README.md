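# holocentro

Tools for mapping **dispersed point centromeres** on holocentric chromosomes
from MNase-digested chromatin profiling (paired-end MNase ChIP-seq).

On holocentric chromosomes such as those of *C. elegans*, kinetochores attach
along the whole chromosome, yet microtubules must bind discrete sites.  With
native ChIP of the centromeric histone variant cenH3 (CENP-A) after light
MNase digestion, those sites appear as sharp loci of high normalized fragment
count: a single sub-nucleosomal particle protecting ~60–100 bp of DNA, set
between two well-positioned canonical nucleosomes and unusually sensitive to
further nuclease digestion.  `holocentro` implements the complete analysis
path from fragment intervals to site catalogues and particle geometry:

- **tracks** — fragment ingestion (BEDPE / BED / SAM), exclusion of repeat
  regions, fixed-width binning (10 bp default, midpoint or coverage
  counting), depth normalization (counts scaled so the genome-wide mean per
  bin equals the bin size), input subtraction and windowed log2 ratios.
- **peaks** — threshold peak calling on input-subtracted tracks.  The
  threshold is `mean + k·SD` of the genome-wide signal (k = 7 default, i.e.
  ~30 normalized counts for cenH3 ChIP); maximal above-threshold bin runs
  from replicate tracks are unioned with support counting, summits are bin
  centers of the replicate-mean maximum.
- **fragsize** — size-class partitioning (small 21–140 bp vs nucleosomal
  141–500 bp), center-crossing fragment-length distributions that read out a
  particle's protected footprint, half-height-width particle sizing, and
  flanking-nucleosome localization.
- **kinetics** — MNase-sensitivity series: feature occupancy per digestion
  time point divided by occupancy at the first time point.
- **sitestats** — site-centered heatmap/average-profile matrices, per-group
  occupancy summaries, interval-overlap counting, coverage-normalized
  densities and fold enrichments, exact (log-space) hypergeometric tail
  tests, permutation overlap tests on the callable genome, windowed Pearson
  correlation, inter-peak distances and feature density.
- **simdata** — a synthetic paired-end fragment generator with planted
  ground truth (sites, protections, flanking dyads, domains, HOT intervals,
  digestion-decay rates) that exercises every stage of the pipeline.

## Worked example

Simulate the reference scenario (one 5-Mb chromosome, 50 planted centromeric
sites), bin and normalize, subtract input, and call peaks:

```bash
holocentro simulate --out demo --seed 3
holocentro bin --frags demo/cenH3-ChIP_t2min_rep1_wildtype.bedpe \
    --genome demo/chrom.sizes --min-length 21 --max-length 500 --out chip.bedGraph
holocentro bin --frags demo/input_t2min_rep1_wildtype.bedpe \
    --genome demo/chrom.sizes --min-length 21 --max-length 500 --out input.bedGraph
python - <<'PY'
import holocentro as hc
g = hc.GenomeBuild.from_files("demo/chrom.sizes")
d = hc.subtract_track(hc.read_bedgraph("chip.bedGraph", g, 10),
                      hc.read_bedgraph("input.bedGraph", g, 10))
hc.write_bedgraph(d, g, "diff.bedGraph")
print("threshold", round(hc.threshold_from_stats(d, 7.0), 1))
PY
holocentro callpeaks --diff diff.bedGraph --genome demo/chrom.sizes \
    --threshold 136 --out peaks.bed
holocentro sizes --frags demo/cenH3-ChIP_t2min_rep1_wildtype.bedpe \
    --genome demo/chrom.sizes --anchors demo/truth_sites.bed --out dist.tsv
```

prints

```
threshold 136.1
50 peaks; 200-bp window union coverage 10000 bp
mode 79 bp over 8049 crossings; small: 27447, nucleosomal: 429444; dropped 0
```

All 50 planted sites are recovered (none missed, no false calls: precision
and recall 1.0 against the planted truth), the 50 non-overlapping 200-bp
summit windows cover exactly 50 × 200 = 10,000 bp, and the mode of the
lengths of ChIP fragments crossing the site centers — 79 bp — recovers the
planted 60–100 bp protected footprint of the centromeric particle, far below
the ~167 bp protected by flanking nucleosomes at this light (2-min)
digestion.

As a library, `fold_enrichment` reproduces the coverage-normalized
density arithmetic for peak/domain comparisons:

```python
>>> import holocentro as hc
>>> dens, ratios = hc.fold_enrichment({"peaks": 460, "domains": 174},
...                                   {"peaks": 141_400, "domains": 42_722_880})
>>> round(ratios[("peaks", "domains")])   # density per 10 Mb at peaks vs domains
799
```

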