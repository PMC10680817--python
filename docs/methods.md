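# Methods

## Model and assumptions

The package treats a parcellated resting-state scan as a sequence of spin
configurations: region i at time t carries σᵢ(t) = +1 if its signal rose
from t to t+1 and −1 if it fell. Binarization discards amplitude and keeps
only co-fluctuation structure; an exact tie (zero slope) maps
deterministically to +1, which is measure-zero for real-valued scans and
keeps integer-valued synthetic inputs unambiguous.

The synchrony s(t) = (1/N) Σᵢ σᵢ(t) is modeled by a mean-field
maximum-entropy Ising distribution over `n_eff` exchangeable units,

    P(n) = (1/Z) · C(n_eff, (n_eff+n)/2) · exp(λ n²/n_eff²),

with n = n_eff·s on the parity grid. The key assumptions are (i)
exchangeability — all units are statistically identical, which atlas
regions are not; this is exactly why the effective count `n_eff`
(typically a few tens) replaces the atlas size N in the model while the
data's synchrony is still computed over all N regions — and (ii) temporal
independence of the samples entering the moments, which only matters for
error bars, not for the point estimates.

Moments, not histograms, are the fitting currency: the model's grid
(spacing 2/n_eff) is coarser than the data's (2/N), so the only scale-free
way to compare them is through ⟨s²⟩ and ⟨s⁴⟩. The coupling λ is fitted per
subject by matching the model's ⟨s²⟩ to the observed one; `n_eff` is chosen
per data set by scanning candidates (multiples of 5) and minimizing the
root-mean-square error of ⟨s⁴⟩ across subjects — the next moment the
one-parameter fit does not constrain (odd moments vanish by the symmetric
prior). Two readings of the scan objective are implemented (cohort-level
RMSE, the default, and a per-subject absolute-error sum); their argmin
agrees in every planted-recovery setting we test because they are monotone
reweightings of the same per-candidate error profile.

## Critical point, threshold calibration and Pseg

Writing ln C(n_eff, (n_eff+n)/2) ≈ const − n²/(2·n_eff) − n⁴/(12·n_eff³),
the quadratic term cancels against λn²/n_eff² at λ_c = n_eff/2. Around this
point the synchrony density takes the Landau form

    f(s) ∝ exp(Λ s² − n_eff·s⁴/12),   Λ = λ − n_eff/2,   s ∈ [−1, 1],

unimodal (disordered, segregated) for Λ < 0 and bimodal (ordered,
integrated) for Λ > 0. The threshold s\* is defined by Pseg(Λ=0) = 1/2
under this density, solved by bracketed root finding on the numerically
integrated cumulative mass. Model Pseg at arbitrary λ uses the same Landau
density and normalization domain, so the half-point at criticality holds by
construction (to the 1e−13 root tolerance). This continuum ("extrapolated")
convention, rather than step-wise summation of the discrete pmf, is what
makes s\* well defined between grid points; it yields s\*(40) = 0.3371,
s\*(30) = 0.3601, s\*(64) = 0.3007, and implies the scaling
s\* ≈ 0.8505·n_eff^(−1/4). A discrete variant of model Pseg
(`pseg_model(..., method="discrete")`) evaluates the strict truncated sum
Σ_{|n| < n_eff·s\*} P(n) for cross-checks against direct binomial
summation. Empirical Pseg on data is always the strict count
(fraction of time points with |s| < s\*; boundary points count as
integrated). Reported s\* values are rounded to two decimals; full
precision is used internally.

Finite-size corrections to λ_c beyond the quadratic-cancellation value are
not modeled; all thresholds quoted above tolerate ±0.01 in this regard.

## Coupling fit

`fit_lambda` solves model ⟨s²⟩(λ) = m2_obs by bisection (residual tolerance
1e−10 on m2, ≤200 iterations; the bracket grows geometrically until it
straddles the root). The model's second moment is strictly increasing in λ,
so the root is unique: 1/n_eff at λ=0 (fair binomial) rising to 1 as
λ → ∞. Observed m2 below 1/n_eff would require λ < 0 — sub-binomial
synchrony variance, non-physical under the ferromagnetic model — and flags
the subject for exclusion while retaining the negative root as a
diagnostic.

## Graph-Ising simulation

On an explicit connectome, each edge contributes J_edge·σᵢσⱼ to the
log-weight with J_edge = 2λ₀/n_nodes². Because n² = (Σσᵢ)² counts every
unordered pair twice, this convention makes the complete-graph stationary
distribution exactly the mean-field pmf at coupling λ₀, and a graph of edge
density p_edge has graph-averaged effective coupling λ = λ₀·p_edge. Both
facts are enforced by tests (complete-graph sampling vs. the exact pmf;
full enumeration of tiny graphs vs. the sampled Boltzmann marginal).

Dynamics are single-spin-flip Metropolis: per recorded step, 640 attempts
at uniformly chosen nodes (10 × 64 single flips), acceptance
min(1, exp(ΔlogW)), synchrony recorded after the step's attempts; spins
start uniformly at random. The exact flip schedule only affects mixing, not
the stationary law. No burn-in is discarded by default; a `burn_in` knob
exists and ≥100 steps are recommended when measuring stationary moments.
The default run length is 2500 recorded steps. The inner loop is
numba-compiled; one default run takes well under a second, which is what
makes the full removal protocol and multi-seed averages cheap.

The edge-removal experiment records (average degree, Pseg at the threshold
calibrated for n_nodes), removes 5 undirected edges uniformly at random
(removing an undirected edge removes both directions at once), and repeats
for 83 rounds, then reports the Spearman correlation between average degree
and Pseg over all 84 records. Under the defaults (64 nodes, starting
density 0.40, λ₀ = 86 so the starting effective coupling is 34.4, just
above λ_c = 32) the effective coupling decays with density and the system
crosses into the disordered phase: Pseg rises monotonically toward 1 and
the correlation is strongly negative (< −0.9 across seeds).

**Known limitation — surrogate structure.** Real anatomical connectomes
are modular and degree-heterogeneous; their adjacency spectral radius
exceeds the mean degree, which raises the effective coupling above
λ₀·p_edge. The package substitutes Erdős–Rényi surrogates (near-homogeneous
by construction), so the simulated starting Pseg at λ = 34.4 is ≈ 0.35 —
in close agreement with the exact mean-field pmf at that coupling — whereas
anatomically informed structures at the same density sit deeper in the
ordered phase (Pseg ≈ 0.2 corresponds to an effective coupling of ≈ 37,
i.e. a ~7% heterogeneity enhancement). Absolute starting Pseg values from
ER surrogates therefore undershoot the ordered character of real
structures; the degradation trend (Pseg rising as edges are lost) is
unaffected.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
assumes. Per subject, magnetizations are drawn from the exact pmf at a
planted (n_eff, λ) by inverse-CDF and realized as spin columns using
exchangeability ((n_eff+n)/2 uniformly chosen units set to +1; columns
independent across time). Each meta-unit is copied to
⌊n_regions/n_eff⌋ region channels (remainder channels attached to the
first meta-units), each copied spin flipping sign independently with
probability ε ∈ [0, 0.5]; ε = 0.5 destroys all structure (independent fair
coins). The continuous trace is the cumulative sum of spin-signed
increments drawn uniformly from [0.5, 1.5] — positive, unit mean, bounded
away from zero — so traces are strictly monotone between flips and
binarization recovers the planted spins exactly.

Cohort defaults: 300-region atlas, n_eff = 40, 500-point scans, ages
uniform on [20, 80], coupling declining linearly from 30 (near-critical,
Λ = 10) at age 20 to 8 (deeply disordered) at age 80, ε = 0, sex balanced
and handedness 90% right with zero true effect. These place young subjects
near the ordered phase and old subjects near the random-activation limit,
producing a strong, recoverable Pseg–age trend; a constant schedule gives a
null cohort for calibration.

What the generator does **not** emulate: hemodynamics, autocorrelated or
1/f noise, motion artifacts, spatial covariance beyond the block structure,
or subject-level n_eff variability. Passing recovery tests therefore show
that the pipeline is correct and well-calibrated under its own model
assumptions — not that the model is adequate for any particular real data
set.

## Cohort statistics and QC

QC keeps subjects whose scan length equals the cohort mode (ties broken
toward the longer scan) and, optionally, below an age cap (default 90
years); every exclusion is logged with its reason, and the negative-coupling
rule above removes non-physical fits. The aging analysis reports the
Spearman correlation between age and Pseg over included subjects (Pint
gives the exact negative); 5-year, left-closed age bins anchored at the
floor of the youngest age, summarized by the median with standard error
1.2533·SD/√n (normal approximation — the bootstrap is a drop-in
replacement); and an additive OLS of Pseg on age, sex and handedness
(categorical covariates enter as dummies; no interactions, no
standardization, p-values reported without multiplicity correction).
Per-subject Pseg variability is the standard deviation of Pseg over
non-overlapping 60-point synchrony windows (window length configurable;
omitted when fewer than two windows fit).

## Problem sizes and numerical conventions

Test and reproduction runs use desk-scale sizes chosen to make Monte-Carlo
error comfortably smaller than the asserted tolerances: 5000-sample series
for single-coupling recovery (recovery asserted within 3 Monte-Carlo
standard errors), 100 noiseless subjects × 2000 samples for the n_eff scan
(candidates 20–60 in steps of 5), 200-subject cohorts for trend recovery,
five seeds for the simulation anchor and three for the removal protocol.
Degenerate inputs are handled explicitly: empty synchrony series,
out-of-range thresholds and sub-2-region matrices raise; empty graphs
simulate free spins; exhausted graphs truncate the removal trajectory with
a warning. All stochastic components take explicit seeds and are
bit-reproducible given them.
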