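# Methods

## Model structure and assumptions

The model is a deliberately compact, nine-state description of systemic
endotoxemia. It keeps the interactions that the four measured plasma
analytes can actually constrain: LPS activates macrophages and neutrophils
(saturating in dose); tissue damage and IL-6 feed back on macrophage
activation; IL-10 applies a shared Hill-type brake on leukocyte activation;
leukocytes induce iNOS, read out as the slow NO₂⁻/NO₃⁻ pool; macrophages
produce TNF-α (inhibited by IL-6 and IL-10), IL-6 (amplified by TNF and NO)
and IL-10 (amplified by TNF); neutrophils generate damage, which repairs at
a first-order rate. Logistic (1 − X/Xmax) terms cap the cell pools. Blood
pressure and organ-level physiology are intentionally out of scope: the
lumped damage variable is the only systemic-health readout, and its failure
to return to baseline within the 24 h observation window is the mortality
surrogate.

Units are concrete: minutes for time, pg/ml for cytokines, µM for
NO₂⁻/NO₃⁻; model concentrations are identified with measured plasma
concentrations (no hidden observation scaling). The 3 mg/kg intraperitoneal
LPS bolus maps to one dose unit added to `P` at the protocol start; only
relative dose matters anywhere downstream.

## Baseline parameterization

The shipped young baseline (`src/inflammode/data/young_params.json`) is an
engineering choice, not a fit to animal data. Decay constants were seeded
from half-life reasoning — TNF fastest (t½ ≈ 50 min as configured), IL-6
and IL-10 intermediate, the NO₂⁻/NO₃⁻ pool slowest (t½ ≈ 11.5 h) — and the
remaining rates chosen so that (i) the unperturbed state is a stable fixed
point, (ii) a unit LPS dose produces the canonical cascade (TNF peak within
60–120 min, IL-6 within 120–360 min, NO after 360 min), (iii) damage
resolves within 24 h, and (iv) peak TNF is non-decreasing in dose. The two
baseline Hill coefficients that the reference middle-aged overlay folds
*down* (h10cp = 8, hn10 = 5) are set at least as large as those folds so
that folded parameter sets never violate the Hill ≥ 1 constraint.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) at rtol 1e-6 / atol 1e-9,
with the right-hand side JIT-compiled when numba is importable (the
compiled function is formula-identical to the pure-Python one, which
remains the fallback). Hill terms are evaluated as logistics in
h·log(x/X), so extreme searched Hill exponents cannot overflow; state
inputs to Hill terms are clamped at zero, and reported trajectories are
clipped at zero with the pre-clip minimum recorded in the solver report.
The resting state exploits the structure of the P = 0 equilibrium (P, NA
and D vanish identically; iNOS and NO follow MA in closed form): a damped
fixed-point iteration on the reduced four-variable system seeds a hybrid
Newton polish, with a relax-and-retry fallback; the accepted state has RHS
residual below 1e-9 in every component.

Outcome classification compares final damage against
`baseline_D·(1 + tol) + 1e-3`. The small absolute floor exists because the
model's resting damage is exactly zero, so a purely relative band would be
empty; 1e-3 is ≈ 0.5 % of the damage dynamic range at baseline parameters.

## Synthetic data

The generator emulates the study design the analyses expect: two age
groups, saline or LPS at t = 0, samples at 0, 60, 90, 240, 720 and 1440
minutes, n = 4 animals per time point, analytes IL-6, TNF-α, IL-10 and
NO₂⁻/NO₃⁻. Replicates are model truth multiplied by i.i.d. lognormal noise
with median 1; the shape parameter comes from the configured coefficient of
variation (default CV 0.3 for general use; the validation experiments use
CV 0.2). Plasma cytokine replicates are right-skewed and positive, which
motivates the multiplicative family; the real study's split between
between-animal and assay variance is unreported, so a single noise
component is assumed. Values below the 1 pg/ml detection floor are stored
as zeros, mimicking assay limits (this also means a "noiseless" self-fit is
only exact with the floor disabled, which the tests do explicitly).

The default middle-aged ground truth is the reference seven-parameter
overlay (h10cp 8-fold lower, hn10 5-fold lower, kmd 3-fold lower, kmpe
9-fold higher, kn 16-fold higher, knpe 5-fold higher, xcp6 11-fold higher).
Under the shipped baseline this reproduces the qualitative age pattern in
the synthetic data: higher IL-6, IL-10 and TNF-α at 60–90 min in the
middle-aged group, and lower NO₂⁻/NO₃⁻ at 12–24 h (the 16-fold faster
neutrophil death shrinks the iNOS source). Passing tests on these data show
the pipeline recovers structure *it generated itself* under this noise
model; they do not show that real plasma data are lognormal, that real
noise is time-independent, or that the reconstructed equations are the true
physiology.

## Sparse re-calibration

The fit error is the mean over observed analytes of the mean squared
difference between log₁₀(model + 1) and log₁₀(group mean + 1) at the
observed times; the +1 offset (one concentration unit) keeps floored zeros
finite, and the per-analyte averaging weights each mediator equally
regardless of scale.

The original optimization used a proprietary stochastic gradient descent;
this package replaces it with a seeded, dependency-light scheme in
log₁₀-fold space over a 40-parameter candidate set (every parameter
appearing in the TNF, IL-6, IL-10, NO, macrophage, neutrophil and iNOS
equations — endotoxin kinetics and the damage equation are excluded so the
optimizer cannot exploit unobserved dynamics). Within a fixed subset,
coordinate descent tries multiplicative up/down moves with a geometrically
shrinking step (×2 down to ×1.01), re-coarsening after convergence while
that still helps; bounds are ±2.5 decades per fold, tightened for Hill
coefficients so they never drop below 1. Candidate evaluations that fail
(no stable resting state, solver breakdown) score infinity and are simply
rejected.

The outer search escalates the change budget N = 1…8. Each level runs a
mixture of draws: *greedy forward steps* — every single-parameter extension
of the current incumbent(s) is scored by a cheap one-dimensional descent,
and the best few are fully optimized warm-started from the incumbent's
folds (this also guarantees the best error is non-increasing in N) —
plus fully random N-subsets, plus *swap moves* that replace the incumbent's
weakest parameter with a fresh high-scoring candidate when the level is
still above threshold. Escalation stops at the first level with an accepted
fit; that level is then *harvested* (further extensions and swaps) so the
ensemble reflects the spread of near-equivalent fits rather than the first
one past the bar. Members closer than 0.3 in log₁₀-fold Euclidean distance
are merged (best error kept; ties broken by fewer changes, then
lexicographic order). Everything derives from the single config seed, so a
rerun is bit-identical.

For synthetic data the acceptance threshold is pinned to an oracle: 1.2 ×
the objective of the generating parameters on the same noisy dataset. This
replaces the original judgement-based "sufficient fit quality" call with a
reproducible bound; for real data the threshold is user-supplied. A search
that reaches N = 8 without an accepted fit returns an empty ensemble with a
structured "insufficient fit quality" report — an expected outcome on
unlucky noise realizations, not an error.

## Validation experiments

Two canned experiments (`inflammode.experiments`) exercise the full stack:

* **Ensemble re-calibration** — data from the reference seven-parameter
  overlay with 20 % noise; the claim checked is structural: an accepted fit
  with ≤ 8 changed parameters exists and the ensemble holds ≥ 5 distinct
  members. Because a single noise realization can be unlucky for a
  stochastic search (the underlying procedure was always run many times),
  the experiment draws up to three replicate datasets from the master seed
  and reports the best-populated accepted ensemble; an all-replicate
  failure is reported honestly as zero members.
* **Direction recovery** — ten seeded searches against a ground truth of
  three strongly identifiable parameters (kmpe ×9, kn ×16, xcp6 ×11, each
  with a direct, visible effect on the observed curves). The check: the
  best member's changed set, intersected with the strong truth parameters,
  has the correct direction for every such parameter. Recovery is assessed
  on identifiable parameters by design — a parameter like kmd, whose Hill
  term is barely engaged at baseline damage levels, produces almost no
  signal at these doses, and no method could recover its direction from
  these data.

Problem sizes throughout (6 time points, 4 replicates, ≤ 8-parameter
budgets, 10 recovery searches, 3 dataset replicates) are the package's
choices for a desk-scale validation of the methodology.

## Statistics layer

All tests are two-sided and computable from (mean, SEM, n) summaries alone,
matching how such group data are reported; summary-level and raw-replicate
computations agree to 1e-10 by construction (SEM = sd/√n is invertible).
Welch is the default two-sample method, with the pooled ("Student's") form
retained as an option. When exactly one group has zero SEM — e.g. every
value at the detection floor — a two-sample statistic is undefined, and the
test degrades to a one-sample comparison of the other group against that
constant (df = n − 1), flagged `one-sample-degenerate`. The two-way ANOVA
operates on cell summaries via weighted model comparisons on cell means
(Type II) plus the within-cell sum of squares Σ(n−1)·sd²; on balanced grids
this equals the classical raw-data ANOVA exactly, which the tests verify
against an independent raw-data implementation. Holm–Šidák is the step-down
adjustment 1 − (1 − p)^(m−rank), enforced monotone. The fold-change
contrast divides each LPS animal's value by its age group's saline mean at
the same time point and compares the per-age fold distributions with the
two-sample machinery; a zero (floored) saline mean makes the fold undefined
and is reported as missing with a reason code, not silently dropped.

Tukey's post-hoc procedure is not implemented; the step-down Šidák
adjustment is the one applied throughout.

## Known limitations

* The nine-equation closure is one defensible reconstruction of a larger
  model family; parameters of mechanisms it omits (pressure, organ-specific
  damage) have no counterpart here.
* Sparse re-calibration is a stochastic local search: acceptance and
  ensemble size vary across noise realizations and seeds, global optimality
  is never guaranteed, and weakly identifiable parameters can absorb
  compensating changes with arbitrary direction.
* The k10 constant is implemented as a pure IL-10 decay rate; its
  documented role ("modulating production/decay") admits other readings.
* The IL-6/TNF Hill coefficient h6cp follows the TNF→IL-6 interpretation;
  its published definition string is ambiguous (it duplicates the TNF→IL-10
  wording), which is flagged here rather than resolved.
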