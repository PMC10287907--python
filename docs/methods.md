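# Methods

## The model

SuRE-style massively parallel reporter assays measure the autonomous
promoter activity of hundreds of millions of random genomic fragments:
each fragment is cloned upstream of a promoter-less barcoded reporter, and
its activity is read out as the barcode count in cDNA, with an iPCR count
measuring its abundance in the input plasmid pool. Because fragments
overlap densely, the per-base contribution of the genome to reporter
expression can be deconvolved from the fragment-level counts.

`suredec` models the pooled reporter count of element *i* as

    y_i ~ Poisson(exp(mu_i))
    mu_i = sum_j x_ij b_j  +  L_i th_L
           + sum_k z_ik (th_k0 + log(n_i) th_k1 + log(n_i)^2 th_k2)

* **Spatial term.** The covered genome of each strand is partitioned into
  variable-width *bins*: maximal runs of consecutive positions overlapped
  by an identical set of same-strand elements. Breakpoints are exactly the
  distinct fragment endpoints, so no element ever partially overlaps a
  bin. `x_ij = sqrt(l_j)` when element *i* contains bin *j* (else 0); with
  a common prior variance on coefficients, the square-root coding makes
  the implied per-base prior independent of how positions happen to be
  grouped into bins. No covariate standardization is applied.
* **Non-spatial terms.** `th_L` absorbs the dependence of expression on
  insert length `L_i` (transfection efficiency); per-library intercepts
  `th_k0` absorb sequencing-depth differences; `log n_i` and its square
  absorb the weakly non-linear, library-specific relation between input
  abundance and reporter count. These columns are unpenalized.

Bin coefficients are elastic-net penalized, minimizing

    F = -(1/N) sum_i [y_i mu_i - exp(mu_i)]
        + lam * sum_j [alpha |b_j| + (1-alpha)/2 b_j^2]

(the `log y!` term is constant and dropped everywhere, consistently). The
L1 part drives coefficients of inactive sequence to exactly zero; the L2
part stabilizes the strong collinearity of neighbouring bins. Fits are
performed separately per strand, so coefficients are orientation-specific.

## Solver

The objective is minimized by iteratively-reweighted least squares with a
cyclic coordinate-descent inner loop (soft-thresholding updates over the
sparse design, active-set sweeps between full sweeps), warm-started along
a decreasing penalty path — the standard pathwise strategy for elastic-net
GLMs. Numerical choices:

* outer convergence: relative objective change below `tol` (default 1e-7),
  error after `max_iter` (100) IRLS iterations;
* inner convergence: maximum weighted-scale coefficient change
  `|db_j| * sqrt((1/N) sum_i w_i x_ij^2)` below `inner_tol` (default
  3e-6, i.e. ~1e-11 on the squared/energy scale — tighter than the
  customary 1e-7 coordinate-descent threshold, cheap because of warm
  starts);
* the linear predictor is clamped at ±30 when forming IRLS weights, and
  weights floored at 1e-9, so extreme intermediate iterates cannot
  overflow;
* when fitting from scratch at `lam > 0`, the unpenalized columns are
  initialized at their null-model optimum so the KKT threshold at zero is
  evaluated with the correct weights — a fit at `lam >= lam_max` then
  returns exact zeros for every penalized coefficient;
* `lam_max = max_j |x_j' (y - mu_null)| / (N alpha)` (inflated by a 1e-10
  relative guard against summation-order rounding);
* perfectly collinear bins are tolerated: for `alpha < 1` the ridge term
  makes the objective strictly convex in the spatial coefficients.

In tests the solver is checked, on small instances, against an
independent generic convex minimizer (L-BFGS-B on the smooth
split-variable reformulation of the same objective).

## Penalty tuning

For each `alpha` in a grid (default `{1e-3, 3e-3, 1e-2, 3e-2, 1e-1}`),
models are fit along a `lam` path of `n_lambda` values log-evenly spaced
from `lam_max` down to `lam_max * lambda_min_ratio`, and scored by the
Poisson log-likelihood of held-out elements. The hold-out is 10% of
elements, uniform at random (seeded) within each block: bins are built
from training elements only, and a held-out element is scored by summing
the per-bp coefficients of the training fit over its span (positions
outside training coverage contribute 0) plus its non-spatial terms. A
block-level hold-out is not meaningful here because blocks have disjoint
spatial columns, so cross-block spatial evaluation would be vacuous. If
the best `lam` for some `alpha` is the smallest tested, the path is
extended downward with the same log-spacing (up to 3 extensions) so the
selected optimum is interior whenever the data allow.

Held-out likelihood rewards accurate *fragment-level* prediction; since a
fragment sums 150–500 per-bp coefficients, small-scale noise in the track
partly cancels in that sum, and the selected penalty can admit more
per-bp roughness than a track-level criterion would. This is inherent to
the tuning target, not a solver artifact.

## Two-step genome-scale fits

Elements are partitioned into blocks: maximal segments of continuous
joint (both-strand) coverage, greedily merged left-to-right up to
`max_block_bp` (default 8 Mb); a contiguous segment is never split, so no
element spans two blocks. Fitting then proceeds in two steps at the tuned
`(alpha, lam)`:

1. the full model is fit independently per (block, strand) unit and the
   unpenalized coefficients are averaged arithmetically across units (a
   library absent from a unit contributes nothing to its average). The
   step-1 fits include the penalized spatial columns so the non-spatial
   estimates are not inflated by absorbing spatial signal;
2. the averaged non-spatial coefficients are frozen into per-element
   offsets and only the spatial coefficients are re-fit per unit.

Units are independent, so results are identical regardless of execution
order (process-level parallelism is safe but not built in).

The fitted bin coefficients are spread onto single base pairs as
`b_j / sqrt(l_j)`; summed over the bin this recovers the bin's exact
contribution `sqrt(l_j) b_j` to any containing element, so predictions
are invariant to bin refinement.

## Prediction

The predicted expression of an arbitrary fragment is
`exp(sum of per-bp coefficients over its span + th_L * L)`. Library- and
input-specific terms are excluded on purpose: predictions are on a
depth- and input-normalized scale, proportional to (not equal to)
expected raw counts. Positions without a coefficient contribute 0 ("no
evidence") and their count is reported so users can distrust predictions
that span coverage gaps. 2D promoter maps enumerate every (start, end)
pair up to `max_len` (default 600 bp, the upper end of assayed fragment
sizes) around a focus position via prefix sums; `min_len` defaults to
1 bp and ties in the optimal fragment are broken toward the shorter, then
leftmost, interval.

For validation against an independently measured library, elements are
grouped by 50 bp start and end bins, and the mean log prediction is
compared with the log mean observation per group (Pearson in log space);
grouping suppresses the high count noise of individual elements.

## Motif cross-correlation

Motif count matrices are converted to pseudo position-specific affinity
matrices by dividing each column by its most abundant nucleotide, so
entries lie in [0, 1] with column maxima 1. Window affinity is the
product of matching entries; forward and reverse-complement affinities
are summed and assigned to the window's central position
(`start + floor(m/2)`, the right-of-center base for even widths); windows
containing N score 0. An alternative reading — summing all windows
overlapping each position — was considered and rejected in favour of
central assignment. Cross-correlation between matched per-region profiles
(e.g. 1 kb promoter windows) is the per-region Pearson correlation at
each lag, averaged across regions (per-region normalization prevents
high-amplitude promoters from dominating; degenerate regions are skipped
at that lag), then smoothed with a centered 25 bp running mean.
Auto-correlation is the same computation against the profile itself with
the lag-0 entry removed.

## Synthetic data

The generator draws libraries exactly from the model above: uniform
fragment starts (random shearing has no positional preference under the
null), lengths uniform in 150–500 bp, multinomial library assignment,
shifted-geometric input counts (minimum 1, p = 0.5, mimicking low
per-element input depth), and `y_i ~ Poisson(exp(mu_i))` with `mu_i`
assembled from a planted per-bp track plus the non-spatial terms.
Defaults describe a desk-scale version of a deep SuRE screen:

* 20 kb genome, 20,000 fragments (~240x coverage, the regime of the
  genome-wide libraries this model targets, at toy scale);
* 6 planted coefficient "spikes" per strand, widths 25–60 bp, values of
  alternating sign in ±[0.02, 0.06] per bp — a 40 bp spike at 0.05/bp
  multiplies expression of containing fragments by e^2 ≈ 7;
* `th_L = -0.002` per bp (longer inserts transfect slightly worse);
* two libraries with intercepts 1.3 and 0.9 (a 0.4 log-depth ratio) and
  weak input-count non-linearity (`th_k1 = 0.1`, `th_k2 = -0.02`),
  giving mean counts of ~2 — sparse-count regime like real data.

What the generator does *not* emulate: sequence composition (the model is
geometry-only by design), overdispersion and transfection dropout beyond
Poisson noise, mapping artifacts, and duplicate fragments across
libraries. Parameter-recovery results on synthetic data therefore
demonstrate the correctness of the deconvolution machinery under the
model's own assumptions, not robustness to the extra noise sources of
real screens.

## Problem sizes used in tests and the acceptance script

End-to-end recovery runs use the 20 kb / 20,000-fragment default above
with a 3-point alpha grid {1e-3, 1e-2, 1e-1} bracketing the sparse-alpha
regime appropriate for this data type, a 40-point lam path down to
`3e-3 * lam_max`, and a 10% element hold-out; these sizes keep a full
tune + two-step fit to a few minutes on one CPU while preserving the
coverage regime. Oracle-equivalence checks run on hundreds of small
random instances; correlation-behaviour checks use 200 independent 1 kb
regions.

## Known limitations

* Poisson likelihood only; real SuRE counts are overdispersed, which the
  original analysis also notes but does not model.
* The hold-out construction (elements within blocks) is one of several
  readings of tuning on "10% of blocks"; it is the only one under which
  held-out spatial likelihood is well-defined, but selected penalties may
  differ from a block-level criterion.
* Coefficients far (> fragment length) from any active promoter reflect
  plasmid-context initiation and should be interpreted cautiously; the
  package deliberately does not post-process them.
* Fits are in-process and single-machine; block independence is the
  parallelism contract, but no scheduler is included.
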