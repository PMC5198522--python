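# Methods

## Observation model and design

Read counts for gene *i* in library *j* are modelled as negative
binomial with mean `mu_ij` and dispersion `kappa` (`Var = mu + kappa
mu^2`; `kappa = 0` is the Poisson limit, used numerically below
`kappa < 1e-8`). The mean is linked through the log:

```
log mu_ij = log s_j + x_j' beta_i
```

with `s_j` the library size factor (an offset) and `x_j` the design
row. The alternative design has four columns — intercept, protocol
(RF = 1), condition (treatment = 1), and their interaction — and is
saturated over the four (protocol, condition) groups; the null design
drops the interaction. The interaction coefficient is the natural-log
TE fold change between conditions, so the null hypothesis of no
translational effect is a one-degree-of-freedom constraint and the
likelihood-ratio statistic is referred to chi-square(1). Samples are
assumed unpaired; paired designs are not supported.

## Normalization

Size factors are median-of-ratios estimates computed independently
within each protocol, because RF and RNA-Seq libraries are not
comparable in depth or spread. The reference is the per-gene geometric
mean over the protocol's libraries using genes with strictly positive
counts in all of them; when no such gene exists (tiny or sparse data)
the reference relaxes to genes covered in at least half of the
libraries, with the geometric mean taken over positive entries only,
and a warning is emitted. Factors are rescaled to geometric mean 1
within each protocol; the absolute scale is absorbed by the protocol
coefficients. Raw counts are never divided by factors inside the
likelihood — factors enter as log offsets — but normalized counts
(count / factor) are used for reported TE values and as the abscissa
of the dispersion trend.

Note one consequence of median-of-ratios normalization worth knowing
when interpreting simulations: if a large fraction of genes changes TE
in the *same* direction, part of that shared shift is absorbed into
the treatment RF size factors and the fitted interaction is biased
toward zero by the corresponding amount. With effects of mixed sign
(the generator's default) the contamination cancels.

## Fitting

For fixed dispersions, coefficients are fitted by Newton–Raphson on
the log link using the Fisher information, with step halving so the
log-likelihood never decreases, convergence at `|delta loglik| <
1e-8`, at most 100 iterations, and a Nelder–Mead polish if Newton
stalls. Initialization is least squares of `log(normalized count +
0.5)` on the design. Fitted means are floored at `1e-8`, which bounds
the coefficients of structurally all-zero groups while keeping the
likelihood finite; such genes are flagged.

Gene-wise dispersions are estimated, for fixed coefficients, by
bounded 1-D likelihood maximization on the log scale over
`[1e-6, 10]` — a range covering realistic biological over-dispersion —
shared across all samples (joint mode) or per protocol (separate
mode, the default; the mean model is never split). Estimates within 1%
of a bound are snapped to it and flagged as boundary values.
Coefficients and dispersions alternate until the joint log-likelihood
changes by less than the tolerance; both partial steps maximize the
same objective, so the loop is monotone. The pipeline runs the loop at
tolerance `1e-11` (up to 200 rounds): a looser loop stops at points
that depend on how the condition labels are encoded, and the tight
tolerance is what makes p-values invariant (to ~1e-6) under swapping
control and treatment labels.

**Plug-in bias correction.** Maximizing the likelihood in `kappa` at
fitted means ignores the mean parameters the fit consumed — the same
effect that biases a residual variance computed with denominator *n*.
With three replicates per group each protocol contributes 6
observations and 2 fitted group means, deflating dispersions by about
a third and visibly inflating the test's type-I error. After the
alternating loop each group's estimate is therefore corrected by
rescaling the implied variance `mu + kappa mu^2` by `n / (n - p)`
(`p` = rank of the design rows of that group's samples) and solving
back for `kappa`. Lower-boundary estimates are left untouched, since
there the estimate is not an interior MLE and the variance-scaling
argument does not apply. The correction is a moment-style first-order
adjustment, deliberately simpler than adjusted-profile-likelihood
schemes.

## Dispersion trend and shrinkage

Raw per-gene dispersions are regressed on `(1, 1/mean)` — the trend
`f(mu) = lambda0 + lambda1 / mu` — using only genes whose raw estimate
is off the search boundary, with two re-fits after discarding genes
whose ratio to the fitted trend is above 10 or below 0.1; negative
coefficients are clipped to zero with a warning. The abscissa is the
mean size-factor-normalized count over the samples the dispersion was
estimated from. At least 10 usable genes are required; inside the
pipeline a failure falls back to a flat trend at the median raw
dispersion (with a warning) so that small runs complete, rather than
aborting.

Each gene's dispersion is then shrunk toward the trend by maximizing
its NB log-likelihood plus a normal penalty on log-kappa centred at
`log f(mu)` — a MAP estimate under a log-normal empirical-Bayes
prior. The prior width is `1.4826 x MAD` of the `log(raw/trend)`
residuals over non-boundary genes, floored at 0.25 so essentially
noise-free simulations are not over-shrunk; the estimator is isolated
in `estimate_prior_sd` so it can be swapped. The shrunken value is
clamped between raw and trend on the log scale (the MAP lies there
whenever the likelihood is unimodal; the clamp is a numerical
safeguard). In separate mode the whole trend + shrinkage procedure
runs twice, once per protocol, with no sharing.

## Testing

Both hypotheses are re-fitted with the shrunken dispersions frozen
(estimated once under the alternative fit), which makes the LRT
statistic structurally non-negative; if numerical noise still leaves
the alternative below the null, the alternative is re-fitted from the
null solution. P-values come from the chi-square(1) upper tail,
Benjamini–Hochberg correction runs over the testable genes only, and
reported TE values are ratios of mean normalized RF to mean normalized
RNA counts per condition (missing whenever a denominator is zero).
Genes with zero counts everywhere, or in an entire protocol, are
untestable and get missing p-values without entering the BH
denominator. Output row order is input gene order and the whole
pipeline is deterministic given its inputs.

## Synthetic data

The generator draws per-gene baseline expression log-normally
(default `lognormal(log 100, 1.5^2)`, spanning realistic depths), sets
RNA-Seq means to the baseline in both conditions (transcription
unchanged unless the `rna_effect_size` knob is used), multiplies RF
means by `exp(beta_Delta)` in the treatment for a configurable
fraction of genes, and draws counts NB with protocol-specific
dispersions, optionally mean-dependent via a `(lambda0, lambda1)`
pair. Defaults describe the benchmark regime the method targets:
2000 genes, 3 replicates per group, `kappa_RNA = 0.01`,
`kappa_RF = 0.5` (a 50-fold dispersion gap), 10% of genes affected at
a 4-fold TE change with random sign, unit library-size multipliers.
All randomness flows from one seeded generator.

What the generator does **not** emulate: gene-length and
positional/codon-level structure of footprints, correlated
transcriptional and translational changes, batch effects, multimodal
library compositions, or isoform mixtures. Passing tests therefore
demonstrate correctness and calibration *under the model's own
assumptions*, not robustness to every artifact of real ribosome
profiling data.

The Z-score baseline standardizes each gene's between-condition TE
log-ratio by the mean and standard deviation of that ratio among genes
of similar mRNA expression (20 equal-occupancy bins; `n_bins=1` gives
the classical unbinned statistic). On null data the unbinned statistic
is visibly inflated for low-count genes — the bias that motivates the
likelihood-based test — while the LRT p-values show no expression
trend.

## Problem sizes and evaluation choices

The statistical acceptance checks use 2000-gene experiments for
calibration and effect recovery, and ten matched 500-gene experiments
per dispersion regime for the separate-vs-joint ROC comparison; the
acceptance script uses 800–2000 genes per scenario. These sizes give
binomial/AUC noise well inside the asserted bands while keeping runs
desk-sized. Effect recovery is summarized by the sign-corrected mean
interaction coefficient because simulated effects have mixed signs.
Expression-trend checks use per-gene rank correlation between
expression decile and p-value over all testable genes, which has
proper power to detect a monotone trend.

## Known limitations

* Unpaired designs only; two conditions only.
* The plug-in bias correction is first-order; a small residual
  anti-conservativeness remains at 3 replicates (measured type-I
  error ~0.07 at nominal 0.05 on the benchmark null).
* Dispersion outliers are always shrunk; there is no refuse-to-shrink
  rule for extreme genes.
* Median-of-ratios factors assume most genes unchanged; strongly
  asymmetric global TE shifts bias the interaction toward zero (see
  Normalization).
* No independent filtering of low-count genes beyond degenerate
  all-zero cases; power at very low counts is limited.
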