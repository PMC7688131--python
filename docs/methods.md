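# Methods

This note records the statistical models implemented in `ras6m`, the
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Dose–response model and the six-model selection

Percent growth is modelled as the four-parameter logistic

Y(X) = d + (a − d) / (1 + (X/c)^b),

X the arithmetic dose in µM, a the untreated (zero-dose) growth in percent,
d the infinite-dose growth, c the dose at which growth is midway between a
and d, b the dimensionless Hill slope. Six constrained variants are fitted:
3P, 3P-Top100, 3P-Bottom0, 4P, 4P-Top100, 4P-Bottom0, where Top100 pins
a = 100, Bottom0 pins d = 0, and the 3P family drops the Hill slope. "No
Hill slope" is implemented as b fixed to 1 — the only reading under which c
retains its midpoint interpretation.

Fitting is bounded nonlinear least squares (trust-region reflective) on the
free parameters, with c optimized on the log10 scale. Bounds: a, d ∈
[−100, 300] unless fixed; c ∈ (0, 10³ · max dose]; b ∈ [0.05, 20]. The
optimizer starts from (a₀ = max Y, d₀ = min Y, log c₀ = mean log dose,
b₀ = 1) plus four jittered restarts drawn from a fixed seed, so fits are a
deterministic function of the data. Replicate wells enter as individual
points by default (an averaging option exists). Convergence tolerances are
1e-12 so that noise-free inputs are recovered to machine precision.

The selected model minimizes the residual standard error
rse = √(RSS/(n − p)), p the variant's free-parameter count. Ties break
toward fewer free parameters, then the canonical variant order. Note that
a constrained variant can legitimately beat the free 4P fit on rse through
the smaller p in the denominator; on identical data the free 4P fit always
has the smallest RSS, and the test suite asserts exactly that distinction.
Flat winners (|a − d| ≈ 0) carry no dose information; the default policy is
to raise, with `on_flat="flag"` to accept them marked non-informative.

### Derived metrics

ICxx is the dose at which predicted growth equals xx percent — the literal
growth convention, so on a killing curve IC90 (growth 90%) is a *low* dose.
The conventional inhibition reading (IC90 ⇒ growth 10%) is available via
`convention="inhibition"`. Closed form: X = c·((a − t)/(t − d))^(1/b),
reported as "not reached" (None) when t lies outside the open interval
between the asymptotes. EC50 is the midpoint-response dose, i.e. c; the
definition "X where Ŷ = a + d" that sometimes appears in print is
unattainable on the curve and is read as the midpoint (a + d)/2. Amax is
exactly a − d. The Activity Area is the plain sum of predicted growth over
the inclusive arithmetic grid from the lowest to the highest tested dose in
0.01 µM steps — a discrete AUC surrogate deliberately *not* scaled by the
step, matching the screening convention it reproduces. IC50s are kept in µM
throughout; downstream regression consumes them untransformed (a natural-log
transform can be applied by the caller if a log-scale convention is wanted).

## Expression filtering, collapse, correlation

The probe filter computes per-probe sample variance (n − 1 denominator by
default; a population option exists), mean, and min–max difference over an
explicit sample subset (defaulting to the full matrix — callers working
with a sub-cohort should pass it). Pass rule: variance ≥ 0.8 AND mean ≥ 5.5
AND range > 3, all in log2 units; the two ≥ are inclusive, the range is
strict. Probeset→gene collapse keeps the probe with the highest mean
expression across samples (ties broken by lexicographic probe id; a
highest-single-sample option exists). Correlation against IC50 is Pearson r
with the two-sided p from the t distribution at n − 2 df; a zero-variance
probe yields NaN with an `undefined` flag rather than aborting the whole
screen, while a zero-variance response raises. No multiple-testing
correction is applied to the correlation screen by default, matching the
workflow this package reproduces.

## Best-subsets regression and cohort splitting

All 2^m − 1 non-empty predictor subsets (guard: m ≤ 20) are fitted by OLS
with intercept; the winner maximizes adjusted R² = 1 − (1 − R²)(n − 1)/
(n − k − 1), ties toward fewer predictors then lexicographic names.
Rank-deficient subsets are skipped with a warning. Sy.x = √(Σ(obs−pred)²/
(n − 2)) is the held-out goodness-of-fit measure, reported with the squared
Pearson correlation of observed vs predicted.

Repeated cross-validation draws `n_repeats` random discovery/test splits
(default 12/5 of a 17-sample cohort) without replacement from a single
seeded generator; per repeat the model is refitted on discovery and its
formula applied to the held-out samples. Both the discovery-fit adjusted R²
(the figure of merit) and the held-out r²/Sy.x are reported, since the two
answer different questions. The manual "range-spanning" split is
implemented deterministically: samples are ranked by response and evenly
spaced ranks, extremes included, form the test group — a reproducible
stand-in for an otherwise unstated manual choice.

## Survival: log-rank, LRMC, KM, Cox, combined classifier

The log-rank test is Mantel–Haenszel with the hypergeometric variance; the
hazard ratio is the O/E estimator (O_b/E_b)/(O_a/E_a). The LRMC scan tries
every distinct expression value as a cutoff, Low = strictly below, High =
at or above (ties deliberately land in High); a cutoff is admissible when
both groups have at least `min_group_size` patients (default 3 — log-rank
degenerates at size 1; set 1 for the literal all-cutoffs reading). The
selected cutoff minimizes p, ties resolved toward the cutoff nearest the
median expression. Because the minimum is taken over ~n dependent tests,
the selected p is anti-conservative: in null simulations (163 patients, no
effect) the scan's minimal p is below 0.05 in roughly half the runs. The
scan result therefore always carries a "selected by minimum p over K
cutoffs" annotation and applies no correction by default.

Kaplan–Meier is the product-limit estimator; the median is the smallest
event time with S(t) ≤ 0.5. The univariate Cox fit for the binary High/Low
indicator maximizes the Breslow partial likelihood by Newton iteration
(single coefficient; |β| capped at 15 with a `converged=False` flag for
monotone likelihoods); HR = exp(β) with Wald CI and p. The O/E log-rank HR
and the Cox HR are reported side by side: they agree closely for moderate
effects (within a few percent at HR ≈ 2) but the O/E estimator is biased
toward the null as the true HR grows (≈ 15–20% low at HR 3) — a known
property of O/E, not a numerical defect, and the reason the package's
HR-agreement diagnostic is run at HR 2.

The combined classifier calls a patient "Good" when every favorable-high
gene is at or above its cutoff and every favorable-low gene is strictly
below (defaults: IGF2R High ∧ CTSA High ∧ ATP6AP2 Low); everything else is
"Bad".

## ddCT

dCt = Ct_target − Ct_reference (reference GAPDH by default), ddCt relative
to a calibrator sample or to the cohort-mean dCt (default), RQ = 2^(−ddCt)
with amplification efficiency fixed at 2. Technical replicates are averaged
on the Ct scale before dCt. With the mean calibrator, RQs multiply to 1 by
construction. To feed measured expression into regression formulas trained
on log2 microarray intensities, log2 RQ (= −ddCt) is reported alongside RQ;
this bridge is a package convention — absolute microarray and qPCR scales
are not commensurable, so predictions from qPCR input should be read as
relative rankings, not absolute IC50s.

## Synthetic generators: what they emulate, what they do not

Generator defaults encode the study-scale conditions: 17 cell lines at six
doses (20, 10, 2, 1, 0.2, 0.1 µM) × 3 replicates with 5%-growth Gaussian
noise; curve parameters a = 100, d ~ U[0, 30], c log-uniform over the dose
range, b ~ U[0.5, 3]; 9 candidate genes of which 3 drive IC50 linearly
(coefficients 2, −1.5, 1, intercept 1, expression N(7, 1), response noise
0.25 µM); 163 patients, biomarker N(8, 1.5), hazard ratio 3 at or above the
40th-percentile cutoff, exponential baseline hazard 1/400 per day (low-risk
median ≈ 277 days, plausible for an adult AML cohort), 20% censoring
(censored patients observed at a uniform fraction of their event time,
floored at half a day). Every generator consumes a single seeded RNG and
writes byte-identical files on rerun; ground truth goes to sidecar TSVs.

These generators reproduce the *statistical shapes* the methods assume —
they do not emulate microarray batch effects, probe cross-hybridization,
heteroscedastic plate noise, correlated gene expression, or non-proportional
hazards. Passing the recovery tests therefore demonstrates that the
machinery is correct and well-calibrated under its own assumptions, not
that real cohorts satisfy those assumptions.

## Problem sizes in the shipped checks

The reproduction script and acceptance tests use 100 simulated
dose–response curves, 50 regression oracle instances and 100
support-recovery cohorts (12 × 9), five 200-patient HR-agreement cohorts,
and 50 + 50 LRMC recovery/null cohorts (200 and 163 patients) — sizes
chosen to make the Monte-Carlo rates stable at single-percent resolution
while a full run stays in the low minutes on one CPU.

## Known limitations

- The 6M selection compares nested and non-nested constrained fits by rse
  only; no information criterion or F-test is used, by design fidelity.
- Best subsets is exhaustive and intended for ≤ ~20 candidates.
- The Cox module handles exactly one binary covariate; multivariate and
  time-dependent models are out of scope.
- LRMC reports uncorrected minimal-p cutoffs; treat selected p-values as
  descriptive, not confirmatory.
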