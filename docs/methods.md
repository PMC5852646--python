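# Methods

This note documents the statistical model behind `mprna`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions used throughout.

## Assay model

An MPRNA pool tiles each transcript of interest with fixed-length windows
(default 110 nt) at a fixed step (default 10 nt), so that an interior base
is covered by window/step = 11 oligos. Each oligo carries a unique 10-nt
barcode; sequencing reads begin at the barcode and extend into the adjacent
oligo sequence in read orientation (the reverse complement of the sense
strand). Nuclear and total (whole-cell) fractions are sequenced as matched
replicates — six of each by default — and each oligo's nuclear enrichment
is read off the barcode counts.

## Read mapping

A read maps to an oligo iff (i) its first `barcode_len` nucleotides exactly
match that oligo's read-orientation barcode and (ii) the continuation has
at most `max_mismatches` (default 2) substitutions against the expected
sequence within the first `check_len` nucleotides. `check_len` defaults to
90, which saturates a 100-nt read; 65 is a common alternative for shorter
verification windows and is exposed as a parameter. `N` counts as a
mismatch; quality strings are ignored.

Because barcodes are designed with pairwise Hamming distance ≥ 3, a single
substitution inside the barcode can never convert one pool barcode into
another: misassignment is essentially impossible, and errors only cost
yield. At a per-base error rate ε the expected mappable fraction is
`(1−ε)^10 · P(Bin(90, ε) ≤ 2)` — about 94 % at ε = 0.5 % — and the QC
question is therefore about recovery, not accuracy. A sample passes
library QC when ≥ 70 % of manifest oligos have at least one count
(boundary inclusive).

## Normalization and the nucleotide model

Counts are scaled to counts per million (CPM) per sample — a library-size
correction with the scale pinned to 10^6 so thresholds are portable across
sequencing depths. Undetected oligos keep
their zeros and participate in medians — dropping or imputing them would
bias positions where synthesis or cloning lost oligos.

The modeled signal at grid position *p* (multiples of the step) is the
median CPM of all oligos whose window contains *p*. The median is the
right summarizer here: individual oligos carry both biological effects and
synthesis/amplification artifacts, and 11-fold coverage gives the median a
50 % breakdown point against jackpotted oligos. One value is emitted per
step interval, indexed by its left endpoint, because every base within a
step shares the same covering-oligo set.

## Differential regions

For replicate pair *i*, `d(p) = median_i( N_i(p) − T_i(p) )` on the modeled
tracks (identity scale by default; `log2(x+1)` is available for strongly
depth-skewed data). Candidate regions are maximal runs of grid positions
with `d(p)` above a threshold, allowing up to `max_gap` (default 0)
sub-threshold positions inside a run and discarding runs shorter than
`min_positions` (default 2).

**Threshold.** The default (`threshold="noise"`) is the 90th percentile of
the magnitudes of the *negative* part of the pooled d distribution. Under
a pure null d is symmetric about zero, so this equals the 90th percentile
of the positive part; when a sizable share of positions is genuinely
enriched, however, the positive-part quantile climbs into the signal and
fragments true regions, while the negative side remains signal-free for a
one-sided (nuclear-enrichment) assay. The positive-part variant is kept as
`threshold="auto"`, and any absolute value can be supplied.

**Region statistic.** `stat = area × consistency`, where area is the sum
of d over the region's grid positions and consistency is the mean fraction
of replicate pairs with a positive nuclear−total difference — the area
captures the magnitude of the difference, the consistency its trend across
replicates. A pure `area` mode is provided. The statistic is computed on
the detection-level run; boundary refinement (below) does not feed back
into it.

**Permutation null.** Null candidates are generated by relabeling samples
and re-running the identical detection (same threshold, not re-estimated):
`pair-flip` swaps nuclear/total within chosen replicate pairs (63
non-identity relabelings for 6 pairs, enumerated exhaustively by default);
`balanced-shuffle` splits all samples at random into two equal groups
(default 200 draws). All null region statistics are pooled, and each
observed region gets the add-one empirical p-value
`(1 + #{null ≥ obs}) / (1 + #null)`, converted to q-values by
Benjamini–Hochberg; regions with q < 0.1 are reported. A property of this
construction worth knowing: relabelings that flip few pairs retain most of
a strong, replicate-consistent signal, so the null tail is conservative
exactly when a dataset contains large effects — weak regions co-occurring
with much stronger ones are called conservatively.

**Boundary refinement.** Tiling dilutes a region's effect at its edges: an
oligo overlapping the region by a fraction w of its window sees the effect
attenuated to `1 + (fold−1)·w`, producing a linear ramp roughly one window
long around each true edge. Any single global threshold therefore biases
detected edges by tens of nucleotides. Since the per-oligo enrichment is
linear in w, the edge can be recovered by fitting the overlap model
directly: each oligo's relative enrichment (median over pairs of
`(N−T)/mean-T`, oligos under 5 CPM excluded) is modeled as `c0 + h·w(S,E)`,
where `c0` is the pool-wide compositional offset (CPM renormalization
pushes background oligos slightly negative whenever part of the pool is
enriched), `h` the plateau estimated from oligos fully inside the detected
region, and `w(S,E)` the fractional overlap with candidate edges. Each
edge is chosen by weighted least squares over a ±100-nt grid at the design
step, with inverse-variance weights `1/(1+m²)` reflecting that
negative-binomial noise grows with the fold-change m. On simulated 3-fold,
300-nt regions this recovers edges with ≈ 10-nt standard deviation; the
statistic and p-value of a region are unaffected.

## Downstream sequence statistics

- **k-mer ridge regression**: all 4^k overlapping k-mer counts (default
  k = 4, configurable 1–8) are standardized and fit by ridge regression
  against region labels or continuous enrichment; the penalty is chosen by
  5-fold cross-validated MSE over a grid (10^−2…10^4 by default) with
  seeded fold assignment. Both binary and continuous responses are
  accepted, since either is a reasonable operationalization of "enriched".
- **Mann–Whitney**: exact enumeration when n·m ≤ 400 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction.
- **Shuffle controls**: each query region gets a length-matched control
  placed uniformly over all feasible starts within the same transcript's
  exons, never identical to the source; infeasible regions are flagged,
  not dropped.
- **PWM scanning**: a log-odds occurrence scanner over MEME minimal-format
  matrices (pseudocount 10^−4 on zeros), strand-less, reporting positions
  at or above a score threshold. It deliberately does not compute
  occurrence p-values or E-values; calibrated motif scanning remains the
  domain of dedicated motif suites.

## Simulator

`SimConfig` defaults describe a full-scale experiment: 38 transcripts of
1200–4000 nt (≈ 10^4 oligos), one planted 300-nt region per transcript at
3-fold nuclear enrichment, 6+6 replicates at 10^6 reads each, 100-nt reads
at 0.5 % per-base substitution error. Per-oligo baselines are log-normal
with σ = 0.5 on the natural log (≈ 4-fold 10–90 % spread, a typical
post-amplification abundance distribution for array-synthesized pools);
counts are gamma-Poisson with dispersion 0.2 (MPRA-scale overdispersion);
5 % of oligos are dropped entirely to emulate synthesis/cloning losses.
Planted region starts are snapped to the tiling grid so truth and calls
share a coordinate lattice. Partial overlaps attenuate the effect linearly
in the overlap fraction — the simulator's key linearity assumption, which
the boundary-refinement model mirrors.

What the simulator does **not** emulate: PCR jackpotting dynamics and
amplification-efficiency differences between oligos, sequence-dependent
synthesis bias, splice-junction effects on tiling, positional correlation
of baseline abundances along a transcript, and cytosolic-direction
enrichment. Tests passing on simulated data therefore demonstrate the
pipeline's statistical behaviour under a clean generative model, not
robustness to every artifact of real pools.

Problem sizes in the test suite are scaled to keep the full run fast:
recovery experiments use 5 transcripts × 2 kb (≈ 950 oligos) at depth
10^6, the mapper check uses 10^5 reads, and the global-null calibration
uses 40 seeded replicate experiments.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based, half-open everywhere (memory, TSV, BED).
- Even-cardinality medians are the mean of the two middle values.
- Sample standard deviations use the n−1 denominator.
- All stochastic steps (barcode sampling, simulation, fold assignment,
  permutation subsampling) take explicit seeds; identical inputs and seeds
  give byte-identical outputs.
- `U` in input sequences is converted to `T` with a warning; other
  ambiguity codes are rejected at design time. Reads may contain `N`,
  which counts as a mismatch.
- All-zero samples, empty manifests, unbalanced replicate structures,
  constant regression responses and empty null distributions raise
  explicit errors rather than propagating NaNs.

## Known limitations

- The pair-flip null is conservative for weak regions that share a dataset
  with much stronger ones (see above); `balanced-shuffle` dilutes but does
  not remove this.
- The boundary-refinement model assumes a single rectangular effect per
  candidate; closely spaced or nested regions are refined as one edge pair.
- Only nuclear-direction (positive d) regions are called; cytosolic
  enrichment would require a mirrored run.
- The PWM scanner and the shuffle controls operate in transcript
  coordinates; genome-coordinate lift-over is out of scope.
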