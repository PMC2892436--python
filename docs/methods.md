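# Methods

## The problem

Sigmoidal curves are ubiquitous in pharmacological and biochemical
assays — dose-response relationships, enzyme progress curves, and in
particular qPCR amplification curves, where fluorescence rises
sigmoidally with cycle number on a linear, equidistant abscissa.
Practitioners routinely justify a chosen nonlinear model with its
coefficient of determination. For nonlinear fits, however, the total sum
of squares does not decompose into regression and residual parts, R²
lacks its variance-explained interpretation, and — the quantitative
point this package demonstrates — R² and even adjusted R² are compressed
into a narrow band near 1 where decisive evidence ratios between models
show up only in the third to fifth decimal place. Likelihood-based
criteria (AICc, BIC) and Akaike weights expose the same evidence on an
interpretable scale.

`sigmofit` packages the machinery needed to show this by simulation:
the model families, a least-squares engine with self-starting values,
the goodness-of-fit measures, and a Monte Carlo pipeline that tabulates
how often each measure selects the generating model.

## Model families

Nine sigmoid families with parameters drawn from
{slope *b*, lower asymptote *c*, upper asymptote *d*, midpoint *e*,
asymmetry *f*}:

| id    | p | form |
|-------|---|------|
| L5    | 5 | c + (d−c) / (1 + exp(b(ln x − ln e)))^f |
| L4    | 4 | L5 with f = 1 |
| L3    | 3 | L4 with c = 0 |
| B5    | 5 | c + (d−c) / (1 + exp(b(x − e)))^f |
| B4    | 4 | B5 with f = 1 |
| B3    | 3 | B4 with c = 0 |
| W4    | 4 | c + (d−c) exp(−exp(b(ln x − ln e))) |
| W3    | 3 | W4 with c = 0 |
| baro5 | 5 | c + (d−c) / (1 + g e^{b₁u} + (1−g) e^{b₂u}), u = ln x − ln e |

For baro5 the weight g = 1/(1 + exp(h·u)) with the harmonic-mean slope
h = 2b₁b₂/(b₁+b₂) moves smoothly between the two slope regimes
(Ricketts & Head's two-slope logistic). We implement it on the log
abscissa, so that b₁ = b₂ collapses it exactly to L4; on this study's
data the log-x form fits the log-logistic truth essentially perfectly,
which is the behaviour the reference results for baro5 display, whereas
a linear-x variant cannot (we verified this with a 300-start global
search: its best residual variance on the noiseless truth stays ~2·10⁻⁴).

Nesting identities (L3 ⊂ L4 ⊂ L5, B3 ⊂ B4 ⊂ B5, W3 ⊂ W4,
L4 ⊂ baro5) hold to machine precision and are tested pointwise.

## Self-start and fitting

Starting values come from linearising each sigmoid: with the response
scaled into (0, 1) by asymptote guesses taken just outside the data
range (c₀ slightly below min y — or 0 for the c = 0 families — and d₀
slightly above max y), the logistic kernels satisfy
logit(z) = −b(u − ln e) and the Weibull kernel
ln(−ln z) = b(u − ln e), each linear in u (= ln x or x). An ordinary
line fit through the interior points (z clipped away from 0 and 1)
yields b₀ and e₀; the asymmetry starts at f₀ = 1, and baro5 starts with
its two slopes split ±5% around the logistic start so the transition
weight has a usable gradient. This is the same idea behind R's
`SSfpl`-style self-starters and proved more robust than
finite-difference slope heuristics; across the full 6 × 2000 × 9 design
every fit converges from it.

Optimisation is `scipy.optimize.least_squares` (Levenberg–Marquardt via
MINPACK when unbounded, trust-region-reflective when box bounds are
requested), tolerances 10⁻⁸ on cost, parameters and gradient, at most
1000 function evaluations. On failure up to three restarts perturb the
self-start by multiplicative Gaussian factors (s.d. 10%) drawn from a
generator seeded per fit, so retries are reproducible. A fit that still
fails is returned flagged (`converged=False`), excluded from that
iteration's selection cohort and Akaike-weight normalisation, and
tallied in the failure table — never silently dropped or raised.

## Goodness-of-fit measures

Per fit (n points, p curve parameters, residual sum of squares RSS):

* R² = 1 − RSS/TSS (the most general definition; no variance
  decomposition is implied for nonlinear fits),
* R²_adj = 1 − (1 − R²)(n − 1)/(n − p),
* profile Gaussian log-likelihood ln L = −(n/2)(ln 2π + ln(RSS/n) + 1),
* AIC = 2k − 2 ln L, AICc = AIC + 2k(k+1)/(n − k − 1),
  BIC = k ln n − 2 ln L,
* Akaike weights wᵢ = exp(−Δᵢ/2)/Σ exp(−Δₖ/2), Δᵢ from AICc within the
  cohort of converged models of one iteration,
* residual variance RSS/(n − p),
* reduced chi-square χ²/(n − p) with χ² = Σ rᵢ²/σ², σ the *a priori*
  known noise s.d. of the simulation (not an estimate).

The effective parameter count is k = p + 1 by default, counting the
estimated error variance alongside the curve parameters as
likelihood-based `AIC` machinery does for Gaussian regression; this is
configurable to k = p (`k_convention="p"`). Differences between
equal-p models are invariant to the choice, and BIC differences are
invariant for any p because the k ln n term shifts all models by the
same ln n per extra parameter. The reference study's printed absolute
AICc/BIC columns are internally consistent with neither convention
(their BIC − AICc gaps are slightly negative, which no k reproduces at
n = 26), so absolute criterion values are reproduced only approximately
(within ~0.2 under k = p + 1); all conclusions rest on deltas, weights
and selection frequencies, which are robust.

An exactly perfect fit (RSS = 0) makes the profile likelihood
unbounded; this is signalled as `PerfectFitError` rather than returning
infinities.

## The synthetic data

The generator reproduces the reference study design: the truth is the
L3 curve with b = −9.90, d = 11.07, e = 24.75 on x = 10, 11, …, 35
(n = 26, "cycles"); replicates add i.i.d. homoscedastic Gaussian noise
with s.d. ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.4} — roughly 0.1% to 4% of
the ~11.07 response range — with 2000 replicates per level. These
defaults are the study conditions, not tuning knobs.

Every (s.d., iteration) cell owns an independent `SeedSequence`-derived
RNG sub-stream keyed by the master seed and a fixed-point decimal
encoding of the s.d., so a run of a single noise level, or with fewer
replicates, reproduces exactly the same first datasets, and results are
independent of scheduling.

What the generator deliberately does not emulate: heteroscedastic or
autocorrelated noise (real qPCR fluorescence noise grows with signal),
baseline drift, and plateau artefacts. Passing tests therefore
demonstrate the inadequacy of R²-type measures under clean homoscedastic
Gaussian conditions — the conclusion transfers a fortiori to messier
real data, but the specific frequencies do not.

## Selection analysis

Two summaries per noise level:

1. **Averaged measures** — per model, the mean of R²_adj, AICc, BIC,
   residual variance, reduced chi-square, and of the per-iteration
   Akaike weights (weights are normalised within each iteration before
   averaging, so each model column averages to a cohort share and the
   shares sum to 1).
2. **Best-model selection** — per iteration, the winner under each of:
   highest R²_adj, lowest AICc, lowest BIC, lowest residual variance,
   reduced chi-square closest to 1; then counts per model and the
   percentage of iterations recovering L3.

Ties (probability zero for continuous measures, but constructible)
break deterministically: fewer parameters first, then registry order
(L5, L4, L3, B5, B4, B3, W4, W3, baro5). Note that ranking by R²_adj
and by residual variance is mathematically the same ordering (R²_adj is
a decreasing affine transform of residual variance at fixed n and TSS),
so their selection tables coincide here by construction.

## Problem sizes and runtime

The full design (6 × 2000 × 9 = 108 000 fits) runs in about five
minutes on one CPU; the acceptance script runs the five noise levels
its reported quantities live at (0.01, 0.02, 0.1, 0.2, 0.4) at the full
2000 replicates. A 200-replicate single-level run — the scale used in
the quick pipeline test — takes a few seconds and already reproduces
the headline ordering (information criteria ≈ 80% true-model recovery
vs ≈ 43% for adjusted R² at s.d. = 0.02).

## Known limitations

* Homoscedastic Gaussian noise only; no robust losses, no weighting.
* No standard errors or confidence intervals on fitted parameters.
* The optimiser is local; self-starts are good enough on monotone
  sigmoid data, but pathological curves may need user-supplied bounds.
* Absolute AICc/BIC values depend on the k convention (above); compare
  deltas and weights across models, not absolute values across
  software.
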