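# Methods

This note documents the models implemented in `mesoweb`, the conventions
chosen where several reasonable ones exist, and the limits of what the test
suite demonstrates.

## Data model and composites

The unit of observation is a *fragment*: one tank × year run of consecutive
censuses (10, or 9 for a shortened monitoring year) for one taxon.  The full
design holds 24 fragments per taxon (8 tanks × 3 years), i.e. 240 composite
points (232 with one 9-census year).  Densities are ln(x+1)-transformed —
the +1 keeps zeros finite — except for coverage-type variables (default
exemption: macrophytes, which are proportions), then z-scored *globally*
over the concatenated fragments.  Standardization is never per-fragment:
a point's coordinate must encode where the community state sits relative to
the whole experiment, and per-fragment means are generally non-zero.
Fragments carry both raw and standardized values; per-capita growth
ln((N_{t+1}+1)/(N_t+1)) always comes from raw densities and never spans a
fragment boundary.  Census indices are 1-based in I/O, offsets half-open
internally.  No interpolation or gap-filling: a fragment with an internal
gap is a validation error; a shorter fragment is simply shorter.

## Simplex projection and embedding choice

Delay vectors (x_t, …, x_{t−E+1}) are valid only when all lags and the
prediction target lie in the same fragment.  Forecasts use the k = E+1
nearest neighbours (Euclidean metric) with weights exp(−d_i/d₁), d₁ the
nearest distance.  Conventions:

- Under LOOCV the predictee row is excluded from its own neighbour set;
  exact duplicates of it remain, and if any neighbour sits at distance zero
  the zero-distance neighbours take over with unit weights (avoids 0/0).
- Equidistant neighbours break ties by (fragment, position) order.
- No Theiler-style temporal exclusion beyond the predictee itself: fragments
  are 10 points long, so a window would delete most of the library.  The
  exclusion rule is a config field should that judgement change.
- E is scanned over 2..6; ρ, MAE and RMSE are all reported and the argmin-
  RMSE E is chosen ("most obvious peak" judgements are not reproducible; the
  full table is always emitted and the criterion is overridable).  A flag
  records when the three criteria disagree.

## Convergent cross mapping

Direction convention: to test donor → recipient, the *recipient's* manifold
cross-maps the donor (the affected variable contains information about its
causes).  Library lengths run from E+1 to all valid rows (24·(10−(E−1)) for
complete 10-point fragments); libraries are drawn uniformly without
replacement, 1000 draws, and skill is the Pearson ρ between cross-mapped
and observed donor values (mean over draws; the full-library value is
deterministic).  The acceptance cascade, in order, short-circuiting:

1. Δρ = ρ(L_max) − ρ(L_min) > 0.1.
2. One-sided surrogate test at L_max, p = (1+#{null ≥ obs})/(1+n) with 1000
   seasonal surrogates; p < 0.05 passes, 0.05 < p < 0.1 is carried as
   "marginal".  Surrogates replace the putative cause; the recipient
   manifold stays intact.  E is held fixed under the null.
3. Lagged CCM over lags −2..+2 (100 draws each): the argmax lag must be ≤ 0;
   a positive optimal lag (the recipient "predicting" the donor's future
   better than its present) vetoes the pair.  Ties prefer smaller |lag|,
   then the more negative lag.  Lags whose targets leave the fragment for
   every row are reported as NA and excluded.

Seasonal surrogates treat the 24 fragments as one series with a 10-census
cycle.  The mean at each census position is preserved *exactly* and
anomalies are permuted within their census position (position means are
computed over available observations, so 9-point fragments pose no
problem).  Within-position permutation is the variant that makes the
preservation property exact rather than approximate, while still destroying
the cross-fragment alignment that carries any causal signal.

## Regularized S-map

For each recipient with accepted donors, the mixed embedding has dimension
max(E, 1+n_donors): donor contemporaneous standardized densities replace
the deepest recipient lags, but at least one recipient column (lag 0) is
always kept.  The response is the recipient's per-capita growth.  At each
target point t the fit solves

    min Σ_i w_i (y_i − b0 − b·x_i)² + λ‖b‖²,   w_i = exp(−θ d_i / d̄_t),

with d̄_t the mean distance from t to the other rows, an unpenalized
intercept, and no internal rescaling (predictors are already standardized;
λ is applied to the weighted problem as written, not scaled by n).  Both
the tuning RMSE and the reported coefficients exclude the target row from
its own fit (a toggle restores in-sample fits; with θ=0, λ=0 and the toggle
off the fit reduces exactly to global OLS).  (θ, λ) are tuned over the
grids {0, 0.1, 0.5, 1, 1.5, 2, 2.5, 3, 4, 6, 8} × {0, 0.0001, 0.001, 0.01,
0.1, 0.5, 1, 2}; ties prefer smaller λ, then smaller θ.  One model per
recipient: with several donors, every donor's coefficient series comes from
that single fit.

## Interaction properties and consistency

IDD is the OLS slope of a link's coefficients on the recipient's
standardized density at the same census, pooling all treatments and years;
its sign is the direction (statistical significance is deliberately not
consulted; exactly zero slopes are kept with a "degenerate" flag and called
negative by convention).  A separate three-way classifier
(`classify_idd`) additionally labels links whose |slope| sits inside the
95% permutation null band as density-independent.  Mean strength and
temporal variability use control coefficients only: per year × replicate
cell, the mean and SD over censuses; then the absolute values are averaged
over cells (cells with <2 points drop from the SD average with a warning).
The replicate-consistency check is a plain two-way fixed-effects ANOVA of
coefficients on treatment × census date — no random effects, no
autocorrelation — flagging unreplicated interactions.

## Sensitivity and mixed models

LRR = ln((T+0.1)/(C+0.1)) on raw mean densities (means over both replicate
tanks and all censuses of a year); sensitivity is |LRR|.  The headline
regression models ln(1+|LRR|) per link × year on mean strength, temporal
variability, ln(IDD magnitude), IDD direction, their interaction and
recipient function (producer/prey/predator; the mapping is a config table,
default: producers = {phytoplankton, macrophytes}, predators = the three
predator groups, prey = the rest), with random intercepts for link identity
and year.  Categorical terms are sum-coded so Type III (marginal) drops are
meaningful with the interaction present; each term's χ² is 2·Δloglik from
full-vs-reduced ML fits.  Links with exactly zero IDD magnitude would make
ln undefined and are excluded with a warning (impossible with continuous
data).

Mixed models are fitted by a small direct-ML engine (`lmm.py`): fixed
effects are profiled out by GLS and the variance parameters (log-variances;
atanh ρ for AR-1) are optimized with L-BFGS-B from several starts.  This
one code path covers crossed random intercepts *and* AR-1 residual
correlation within tank-year blocks, which the per-taxon treatment-effect
model requires (standardized density ~ treatment + census, random tank and
year intercepts, AR-1 residuals; Dunnett-style two-sided contrasts vs
control are adjusted by Monte-Carlo on the joint normal of the contrasts —
method recorded as "mvn-monte-carlo").  The fitter is cross-checked against
statsmodels MixedLM on the models MixedLM can express.  If the AR-1 fit
fails to converge the model falls back to independent residuals and the
result records the downgrade.

## Synthetic community

The generator mirrors the design exactly (2 tanks × 4 treatments × 3 years
× 10 censuses × 10 functional groups) with log-scale Ricker dynamics:

    L_i(t+1) = max(L_i(t) + r_i(season) + s·Ñ_i + Σ_d J_id·clip(Ñ_d) + press_i + ε, 0)

where L = ln(N+1), Ñ = (L − μ)/σ with fixed reference scale (μ = 3,
σ = 0.5), and J_dr(t) = a_dr + b_dr·clip(Ñ_r) + ε_int.  Defaults: 8 links
spanning negative (b<0), positive (b>0) and density-independent (b=0)
classes with |a| ≈ 0.35–0.45 and |b| ≈ 0.25–0.3; self-regulation s = −0.4;
sinusoidal seasonal forcing (amplitude 0.3, 10-census period, taxon-specific
phases); interaction and process noise SD 0.05; presses as per-census
log-survival (insecticide: predators 0.45, detritivores 0.8; herbicide:
macrophytes 0.5, phytoplankton 0.85; the combined treatment multiplies
them).  Interactions act on standardized densities, so the generator's J
lives on the same scale as estimated S-map coefficients (up to the
empirical/reference standardization ratio, which preserves signs and
correlations).  Interaction responses saturate outside ±2.5 standardized
units while self-limitation acts on the unclipped state — the saturating
form is what keeps press-perturbed trajectories bounded (verified stable
over 100 seeds) and is also the ecologically defensible choice (functional
responses saturate; self-crowding does not).

What the generator does *not* emulate: observation/sampling error distinct
from process noise, species turnover within functional groups, chemical
fate of the pesticides, spatial structure, and zero-inflated counts (zeros
arise only through the extinction floor).  Passing tests therefore show
that the pipeline recovers known dynamics of this class — short, seasonally
forced, press-disturbed, moderately noisy — not that field estimates are
unbiased where those ignored features dominate.

There is also a parametric companion (`simulate_sensitivity_experiment`)
that generates link properties and sensitivities directly from the headline
mixed model with density-independent temporal variability as the dominant
destabilizer; it is the ground truth for parameter-recovery tests of the
regression machinery, deliberately decoupled from the mechanistic
simulator.

## Problem sizes and numerics

Tests and the acceptance script run at the study's own scale (240-point
composites, 90 ordered pairs, 1000 cross-map draws and surrogates), which
is fast because the recipient-side neighbour geometry is computed once per
(recipient, E) and reused across donors, lags, draws and surrogates (the
surrogate null reduces to one sparse weight matrix applied to all 1000
surrogate target vectors at once).  Brute-force oracles (explicit sorts and
normal equations) back the simplex and S-map implementations at 1e-12 and
1e-8.  Known limitations: the χ² of boundary-variance mixed models is
approximate (variances pinned near zero are flagged); lagged CCM at the
full library is deterministic, so its "100 draws" collapse to one
evaluation; and cross mapping in a densely connected web accepts net
(indirect) influences by design, so accepted-link counts exceed the direct
adjacency.
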