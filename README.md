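# suredec

Deconvolution of SuRE/MPRA fragment counts into per-base-pair promoter
activity tracks, with downstream fragment-expression prediction, 2D
promoter maps, and motif/ChIP cross-correlation analysis.

## The problem

SuRE (Survey of Regulatory Elements) and related massively parallel
reporter assays clone millions of random genomic fragments upstream of a
promoter-less barcoded reporter: a fragment produces transcript only if
it carries autonomous promoter activity, measured as its barcode count in
cDNA. Individual fragments are long (150–500 bp) and noisy, so the raw
data only coarsely localize the sequences that drive expression. This
package deconvolves overlapping fragment counts into a per-base-pair
coefficient track: the additive contribution of each genomic base, on the
natural-log scale, to the expression of any reporter fragment containing
it.

## The model

For element *i* with pooled reporter count *y<sub>i</sub>*, input (iPCR)
count *n<sub>i</sub>*, length *L<sub>i</sub>* and library *k*:

```
y_i ~ Poisson(exp(mu_i))
mu_i = sum_j x_ij * beta_j  +  L_i * theta_L
       + sum_k z_ik * (theta_k0 + log(n_i) * theta_k1 + log(n_i)^2 * theta_k2)
```

The covered genome of each strand is partitioned into variable-width
*bins* — maximal runs of positions overlapped by an identical set of
elements — and `x_ij = sqrt(l_j)` when element *i* contains bin *j*. Bin
coefficients `beta_j` are elastic-net penalized (`lambda_1 = alpha*lambda`
L1, `lambda_2 = (1-alpha)*lambda` L2) and fit by IRLS + coordinate
descent along a warm-started lambda path; `(alpha, lambda)` are tuned by
the Poisson log-likelihood of held-out elements. Genome-scale fits run in
two steps: unpenalized (non-spatial) coefficients are averaged across
independent genomic blocks, frozen into per-element offsets, and the
spatial coefficients re-fit per block. The fitted track carries
`beta_j / sqrt(l_j)` at every base of bin *j*; the predicted expression
of any hypothetical fragment is `exp(sum of its per-bp coefficients +
theta_L * L)`.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

`examples/simulate_and_fit.py` simulates a 4 kb genome with three planted
regulatory elements (two activating, one repressive; ±0.05 per bp), draws
3,000 fragments from the count model, tunes the penalties and runs the
two-step fit:

```
$ python examples/simulate_and_fit.py
simulated 3000 fragments, mean reporter count 3.68
plus strand: 2133 bins, median width 1 bp
tuned penalties: alpha*=0.1, lambda*=0.2003 (held-out log-likelihood selection)
per-bp Pearson(truth, fitted) = 0.759 over 7985 covered positions
length coefficient: true -0.002, fitted -0.00215 (abs error 0.00015)
all planted element signs recovered: True
```

The correlation of 0.76 between the fitted and planted per-bp tracks,
with every element's sign recovered and the length coefficient accurate
to 1.5e-4, shows the deconvolution localizing regulatory sequence from
fragments 2–6 times wider than the elements themselves. The other
examples predict fragment expression and optimal promoter fragments from
a track (`predict_and_map.py`) and cross-correlate a track against a
motif affinity landscape (`motif_crosscorrelation.py`).

A thin CLI wraps the same API:

```bash
suredec simulate --seed 1 --out-prefix lib
suredec tune --fragments lib.fragments.tsv --out tune.json
suredec fit --fragments lib.fragments.tsv --alpha 0.01 --lam 0.1 --out-prefix coef
suredec predict --track coef --bed queries.bed --out predictions.tsv
suredec map --track coef --center chrS:10000 --out map.tsv
```

Fragment tables are TSV (`chrom start end strand library ipcr` plus cDNA
replicate columns, 0-based half-open coordinates); tracks are bedGraph
per strand with a JSON sidecar carrying `theta_L`.

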