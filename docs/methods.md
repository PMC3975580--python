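# Methods

## Signal model and coordinate conventions

All coordinates are 0-based half-open (BED convention); 1-based input
dialects are converted at the reader boundary.  Paired-end mates are
collapsed to the outermost span (min start, max end); pairs mapping to
different chromosomes are dropped with a counted skip.  Fragments outside a
configurable length window (general tracks 25–1000 bp, size analyses
21–500 bp) are dropped and tallied.

Fragments are counted into fixed-width bins (default 10 bp).  Two counting
modes exist because "count per interval" is ambiguous:

- **midpoint** (default): each fragment adds 1 to the bin containing
  `floor((start + end) / 2)`.  Counts are conserved exactly, which keeps the
  `mean + k·SD` peak threshold well defined; this is the mode used for peak
  calling and occupancy statistics.
- **coverage**: each fragment adds 1 to every bin it overlaps; used for
  occupancy-shape profiles (e.g. particle sizing, below).

Normalization divides each bin by the total count and multiplies by the
number of unmasked genome bases, so the genome-wide mean equals the bin size
(10 normalized counts per 10-bp bin) and the sum over unmasked bins equals
the unmasked genome length.  Bins overlapping excluded (simple-repeat)
intervals carry NaN, are ignored by every downstream mean/SD/threshold, and
are never imputed.  Masking a normalized track rescales the surviving bins
so the sum invariant is restored.  Input chromatin is treated as a separate
blank experiment subtracted bin-wise from ChIP; log2 ratios (pseudocount 1
normalized count, 10-kb windows) are provided only for comparisons with
ratio-based datasets.

## Peak calling

Centromeric sites are sharp, so calling is by thresholding, not model
fitting.  The threshold is `mean + k·SD` (population SD over unmasked bins;
k = 7 by default, corresponding to ~30 normalized counts for cenH3 ChIP;
fixed defaults of 20 / 100 normalized counts are kept for CENP-C and
insoluble-chromatin tracks).  Per replicate, maximal runs of contiguous
unmasked bins at or above threshold are found; runs from different
replicates whose intervals overlap are unioned into one candidate, emitted
when at least `min_support` replicates contributed (default 1, the
"at least one of two biological replicates" rule).  The summit is the center
of the bin with the maximum replicate-mean signal inside the union, ties
resolved leftmost for determinism; distinct runs separated by even a single
below-threshold bin are never merged, because genuine sites can sit a few
hundred bp apart.

Raising the threshold nests runs (every higher-threshold run lies inside a
lower-threshold run and total covered bases shrink) but can *split* a run in
two, so the peak count itself is not monotone in the threshold; the nesting
form is what the property tests assert.

## Fragment geometry

Size classes default to small = 21–140 bp (sub-nucleosomal particles) and
nucleosomal = 141–500 bp, inclusive.  A fragment "crosses" an anchor
position `p` iff `start <= p < end`, and is counted once per anchor covered;
the mode of the crossing-length histogram (1-bp resolution, ties toward the
smaller length for a conservative footprint) estimates a particle's
protected size.  Optional 5-bp running-mean smoothing is for plotting only.

Half-height particle sizing takes an averaged occupancy profile, subtracts a
baseline (median of the outer 10% of positions on each side), and measures
the distance between the two half-level crossings found by linear
interpolation moving outward from the maximum.  Coverage counting widens an
apparent footprint by roughly one bin width, so this profile is built at
1-bp bins.  Flanking nucleosomes are located as the maxima of the
nucleosomal-size fragment *midpoint* (dyad) density beyond an exclusion
radius of ±75 bp (just over half a nucleosome) from the site center — dyad
density peaks at the positioned dyads, whereas coverage plateaus.

## Digestion kinetics

Occupancy is the mean unmasked signal in a fixed window around each anchor,
averaged over anchors: 200 bp for the focal centromeric particle, 150 bp for
flanking-nucleosome midpoints (the windows are a package choice; they are
configurable).  The sensitivity series divides each time point's occupancy
by that of the first time point, so it is invariant under any common
rescaling of the tracks.  Time points are labels; nothing is interpolated.

## Overlap and interval statistics

"Coincidence" is summit-within-interval for summit sets against interval
sets and any-overlap for interval/interval comparisons.  Densities are
`count / group coverage × 10 Mb` and fold enrichment is their ratio (nearest
integer for reporting).  The hypergeometric upper tail is summed in log
space (logpmf + logsumexp) and is exact against enumeration for all
universes up to N = 12; the universe size is a required explicit parameter
because it is not derivable from interval sets alone.  The permutation test
re-places summits uniformly on the callable (unmasked) genome, preserving
per-chromosome counts, with `p = (1 + #extreme) / (n_perm + 1)`; because the
overlap statistic is an integer, the p-value is valid but mildly
conservative at any fixed level (by at most the tie mass of the null
overlap distribution), which the calibration test accounts for.  Windowed
correlation is Pearson with a least-squares line on per-window means,
pairwise-complete.  Inter-peak distances are between consecutive summits
within a chromosome, never across.

## Synthetic scenarios

The generator plants, on a configurable genome (default one 5-Mb
chromosome):

- `n_sites = 50` point-centromere sites, ≥ 2 kb apart and ≥ 1 kb from
  chromosome ends, each with a protected footprint drawn uniformly from
  60–100 bp and two flanking nucleosome dyads at ±150 bp (positional jitter
  SD 10 bp);
- ~100 domains of ~10 kb (placed independently of the sites) with mild
  (2×) ChIP enrichment producing 135–155 bp fragments;
- HOT intervals over half of the sites plus 25 decoys elsewhere.

Digestion is phenomenological, not enzyme kinetics.  Fragment length is
protection + residual linker + Gaussian jitter (SD 8 bp), truncated to
[21, 500] bp; the linker (40 bp at t = 0) is trimmed as `exp(-λ·t)`.
Fragment abundance per particle class survives as `exp(-λ·t)`:
λ_nuc = 0.35/min for canonical nucleosomes (which also sets trimming, so a
nucleosome protects ~167 bp at the 2-min reference digestion),
λ_cen = 2·λ_nuc = 0.7/min for centromeric particles (centromeric chromatin
is digested away twice as fast), and λ_ins = 0.3·λ_cen for the insoluble
fraction, emulating protection of the site particle by bound kinetochore
complexes so that insoluble signal persists at 10 min.  ChIP oversamples
site-derived fragments 30-fold; the depletion condition multiplies
site-derived ChIP sampling by 0.15 and removes the domain enrichment, while
input chromatin is unchanged.  Depths (150 background fragments/kb at t = 0,
20 site fragments/site input-level, 30 per flanking dyad) are sized so the
full default scenario simulates and analyzes in well under two minutes on
one CPU while leaving comfortable signal-to-noise for the mean + 7·SD
threshold.

A single integer seed drives everything (truth placement and each fragment
set get independent child generators), so identical configurations are
byte-identical.  What the generator does **not** model: sequence (no FASTA,
mapping bias, GC or MNase sequence preference), inter-cell heterogeneity
beyond Poisson sampling, chromatin higher-order structure, and partial or
heterotypic site occupancy.  Tests passing on these scenarios therefore
demonstrate the correctness of the analysis pipeline under the planted
model, not the biological completeness of that model.

## Numerical and design notes

- Population (ddof = 0) SD for thresholds.
- Summit ties → leftmost bin; crossing-mode ties → smaller length;
  flanking-maximum ties → position nearest the center.
- `log2_ratio` guards 0/0 with its pseudocount and returns 0 for
  signal-free windows.
- Fold-ratio of two groups with zero counts is defined as 0; a nonzero
  numerator over a zero-density denominator is an error.
- Interval containers are sorted numpy arrays queried with `searchsorted`;
  excluded intervals are merged at construction.
- Reported scenario quantities with high sampling variance (e.g. the
  centromeric occupancy ratio at 10 min, where only tens of site fragments
  survive) fluctuate noticeably between seeds; ordering properties are
  stable.

## Known limitations

- The peak caller is a pure threshold method by design: no FDR control, no
  local background model, no peak-shape classification.
- The hypergeometric test requires the caller to choose the universe; a
  defensible choice is callable-genome length divided by a nominal site
  footprint.
- SAM/BAM ingestion uses proper pairs with positive template length only;
  duplicate marking and multi-mapper handling are assumed to have happened
  upstream.
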