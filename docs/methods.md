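# Methods

## Enrichment model and peak calling

The caller treats each 50-bp window's IP count as Poisson. The rate for a
window is `max(matched input count, genome-wide mean input per window)`:
a local background (the matched input window) with a global floor that
prevents zero-rate artifacts where the sparse input happens to contain no
reads. The background mean is computed per genome, not per chromosome — the
toy genomes used here have one or two chromosomes, so a per-chromosome mean
would be noisier without changing behaviour. Depths are equalized by random
subsampling without replacement (seeded) before tiling, so IP and input
counts are directly comparable.

A window passing `p < alpha` (default 1e-3) is a candidate. The
significance rule requires neighbouring windows to pass the same cutoff;
two readings are possible and both are implemented behind `neighbor_rule`:

* `both` (default): both immediate flanking windows must be candidates, so
  significant windows sit inside runs of >= 3 candidates;
* `any_adjacent`: at least one flanking window suffices.

Chromosome-edge windows lack a neighbour and can never be significant.
Peaks are maximal runs of >= 3 consecutive candidate windows containing at
least one significant window; the run's span, window count, minimum p and
mean IP/input counts are recorded. Reads are assigned to windows by their
midpoint with no fragment extension — no fragment-size information is
modelled, and `read_length` is a free simulator parameter.

There is no FDR correction across windows: the procedure is a fixed Poisson
cutoff by design, and the calibration study (analysis/06) verifies that the
realised candidate rate on enrichment-free data stays below the nominal
cutoff (the `max(input, mean)` floor makes the test conservative).

## Profiles

All profile operations work in transcription orientation: minus-strand genes
are mirrored so position +x means x bp downstream of the TSS. Positions off
the chromosome end contribute 0 but stay in the averaging denominator, so
profiles near contig edges are attenuated rather than silently truncated.
Bins must be multiples of the window size; each bin averages the window
values it covers, so a constant track gives a flat profile at the constant —
a property the tests rely on.

Metagene bodies are sampled at window resolution and linearly interpolated
onto a fixed 3-kb axis (60 bins at 50 bp); flanks are copied unscaled.
Linear interpolation is the simplest rule consistent with flatness
preservation; genes shorter than one window cannot be sampled and are
skipped with a reported count. Heat-map matrices sort rows by descending
mean signal; a reference row order can be reused across conditions so
panels align gene-for-gene.

Difference tracks are reads-per-million normalized before subtraction. In
the pipeline the depths are already equalized, making this nearly a no-op,
but it keeps the operation meaningful on standalone unequal-depth tracks.

## Resampling null

The statistic is the mean differential signal within ±1 kb of the TSS,
averaged over the gene set. Null sets are drawn without replacement from a
universe that excludes the target genes, independently across trials; the
per-gene profile rows are computed once, so trials are row-subset means.
The empirical p-value uses the add-one form `(1 + #{null >= obs})/(n + 1)`,
which cannot be 0 and is uniform on its support under the null (verified by
a KS test over replicate experiments). The reported envelope is the
pointwise min/max of the trial profiles. An exhaustive mode enumerates all
subsets of small universes, which the tests compare against independent
brute-force enumeration. Null sets are matched on size only — not on
expression, length or GC content.

## Expression

RPKM uses the per-sample total count as the mapped-read denominator. The
spike-in rescaling reference is the cross-sample mean of spike-in RPKM sums;
any fixed reference would equalize the sums, and the mean keeps adjusted
values on the scale of raw RPKM. Differential labels are deliberately
fold-change-based (default cutoff 2 on adjusted RPKM, detection floor 0.1
RPKM, pseudo-RPKM floor 0.01 in ratios to avoid division by zero):
model-based significance testing of counts is out of scope here, and the
labels are documented as fold-change classifications, not p-value calls.
Category enrichment excludes categories overlapping the selection in fewer
than 10 genes *before* Bonferroni correction, so the correction denominator
is the number of hypotheses actually tested.

## Synthetic data: what it emulates and what it does not

ChIP reads are drawn from a piecewise-constant intensity — uniform
background multiplied by per-gene body and promoter factors — with exact
multinomial allocation of the requested read total, uniform strand
assignment and fixed read length. Noise is Poisson everywhere (matching the
caller's model); there is no overdispersion, GC or mappability bias,
fragment-size distribution, or diploidy. Passing tests therefore show the
procedures are correct under their own noise model, not that they are robust
to every artefact of real libraries.

Study conditions are fixed in the generators: the demo ChIP experiment uses
one 5-Mb chromosome, 200 non-overlapping genes, an 8x gene-body mark in
condition 1 reduced by 40% at every gene in condition 2, a 4x promoter gain
at 50 target genes, and 5e5 reads per sample. Gene lengths are uniform on
2–10 kb, chosen so that marked gene bodies cover a minority (~24%) of the
toy genome: in a real genome the marked fraction is small, and because the
simulator normalizes total read count, covering half the toy genome with
enriched bodies would depress per-window IP enrichment below any caller's
Poisson threshold — a property of toy-genome compression, not of the method.
Expression simulations use 200–300 genes at base mean 200, fold changes
log2 = {−2, 0, +2}, ten spike-ins and a 2x library-scale distortion.
Polysome traces place one monosome Gaussian and a three-peak polysome train
well inside their integration regions, so trapezoidal region AUCs match the
requested areas to well under 1%.

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere internally; GTF-lite input
  (1-based closed) is converted on read. Duplicate reads are keyed on
  (chrom, start, strand) — with fixed-length single-end reads the end is
  redundant.
* Poisson tails come from `scipy.stats.poisson.sf` and are cross-checked in
  the tests against explicit summation to 1e-12 relative error; the
  hypergeometric tail is similarly cross-checked against
  binomial-coefficient enumeration.
* bedGraph output run-length-encodes equal-valued windows; reading requires
  intervals aligned to the window grid.
* All generators and subsampling steps take explicit integer seeds and are
  bit-reproducible; the pipeline manifest records parameters, seeds and
  input checksums.

## Problem sizes

The bundled analyses and the acceptance script run at the demo scale above
(1e5 windows, 2e6 total reads across samples), which completes in a few
seconds per experiment on one CPU; the calibration and detection studies
repeat their simulations over 10–20 seeds. These sizes were chosen as the
smallest at which the genome-wide claims are statistically comfortable.

## Known limitations

* The caller's background model is a design choice; the original
  window-caller lineage it follows does not pin down the exact rate
  estimator, and alternatives (strict local input, per-chromosome means)
  would differ on sparse data.
* Fold-change DE labels are not a substitute for count-model inference when
  replicates are available.
* Real-data mode is limited to the supported text formats (BED6, tagAlign,
  BED12, GTF-lite, bedGraph, TSV); BAM/bigWig are out of scope.
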