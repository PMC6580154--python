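# Methods

## Model family

The package evaluates and fits the nested SABRE family of receptor
models.  All variants express the fractional response E/Emax as a
function of free ligand concentration [L]:

| variant | parameters | form |
|---|---|---|
| `clark` | K_d | [L]/([L]+K_d) |
| `emax` | K_d, ε | ε[L]/([L]+K_d) |
| `sabre3` | K_d, ε, γ | εγ[L]/((εγ−ε+1)[L]+K_d) |
| `sabre4` | K_d, ε, γ, ε_R0 | (εγ[L]+ε_R0γK_d)/((εγ−ε+1)[L]+(ε_R0γ−ε_R0+1)K_d) |
| `constitutive_no_amp` | K_d, ε, ε_R0 | ε_R0K_d/(K_d+[L]) + ε[L]/([L]+K_d) |
| `operational` | K_d, τ | τ[L]/((τ+1)[L]+K_d) |

Assumptions: equilibrium binding with a single ensemble-average K_d
(no separate affinity for the active conformation); induced-fit
activation so that ε is the fraction of bound receptors that are
active; amplification by a single hyperbolic transduction function
acting on the odds transform Λ = f_act/(1−f_act) of the active-receptor
fraction, which collapses any cascade of saturable steps into one gain
parameter γ.  All response evaluations use the rational closed forms,
not the Λ pathway, for numerical robustness (Λ diverges at f_act = 1,
while the rational form returns exactly 1 there); the Λ route is kept
only as an independent oracle in the test suite.

Parameter scopes follow the physics: K_d and ε belong to the ligand,
γ and ε_R0 to the pathway/receptor system (amplification is
tissue-dependent), and the surviving-receptor fraction q to the
experimental condition.  γ is constrained to γ ≥ 1: a gain below unity
would be signal attenuation, which the transduction cascades the model
describes do not produce; allowing it would also let γ absorb partial
agonism that belongs in ε.  Hill-slope extensions, kinetic binding and
the α-parameterised conformational-selection model are out of scope.

q enters as an apparent efficacy ε′ = qε, which is exact for the
three-parameter model (and trivially for `emax`); it is deliberately
not extended to the constitutive-activity variants, where no such
closed form holds, and requesting it raises an error.

## Identifiability — what response data can and cannot determine

A `sabre3` curve is observationally a two-parameter scaled hyperbola
(asymptote εγ/(εγ+1−ε) and EC50 K_d/(εγ+1−ε)).  Consequently
(K_d, ε, γ) can never be determined jointly from response data alone —
any γ can reproduce the curves exactly with compensating (K_d, ε).
The intended workflow, which the fitting surface encourages, is to fix
K_d per ligand to independently measured binding values; the shared
pathway gain and per-ligand efficacies are then identified.  Three
consequences are built in:

* an irreversible-inactivation series (several q conditions sharing
  one K_d, ε, γ) *is* fully identifiable including K_d, and is fitted
  with K_d free by default;
* under very strong amplification the sum of squares is nearly flat
  when all efficacies are scaled down and the gain scaled up (only the
  εγ products are determined); a post-fit guard probes exactly that ray
  and attaches a warning when the profile is flat within 1e-3 of the
  total sum of squares;
* the relative-response ("bias plot") curve depends only on the
  per-ligand efficacy ratio ε₂/ε₁ and the two gains — the absolute
  efficacy scale cancels algebraically — so `fit_relative_response`
  always reports the ratios (with delta-method standard errors) in
  `extras["epsilon_ratio"]` and carries a standing warning about the
  raw efficacies.  K_d-anchored per-pathway fitting is the primary
  bias route; direct bias-plot fitting is the fallback.

Within one inactivation condition only the product qε is identifiable;
the reference condition is pinned at q = 1, anchoring the efficacy
scale.  The reference must be the least-inactivated condition — since
ε ≤ 1 and q ≤ 1, anchoring on a strongly inactivated condition would
require infeasible parameters.

## Fitting machinery

Global bounded least squares (`scipy.optimize.least_squares`, TRF) over
a parameter vector assembled from the sharing scheme.  Internal
coordinates are log10(K_d) and log10(γ−1+δ) with δ = 1e-6 (so γ = 1 is
exactly reachable and steps are scale-free across orders of magnitude);
the fraction parameters ε, ε_R0 and q are box-bounded on their natural
scale so that boundary values such as a full agonist's ε = 1 are
exactly representable — a logit coordinate can only approach them
asymptotically, which would break exact-recovery behaviour on clean
data.  τ uses log10(τ+δ).

Multi-start: a deterministic Latin hypercube (`scipy.stats.qmc`,
seeded, default seed 0) of 16 starts over a start box (K_d starts span
the observed concentration range ±2 decades), plus a centre start; best
sum of squares wins, ties broken by fewer function evaluations.
Convergence tolerances are ftol 1e-13 / xtol 1e-14 / gtol 1e-12 with at
most 500 iterations per start; the tight tolerances are needed for the
noiseless-recovery contract (SS ≤ 1e-12, parameters to ≤ 1e-4
relative).

Uncertainty: asymptotic standard errors s²(JᵀJ)⁻¹ at the optimum,
computed from the SVD of the Jacobian itself rather than of JᵀJ —
squaring the condition number can silently truncate a weakly identified
direction and produce overconfident errors, which matters precisely in
the high-gain regime above.  Errors are propagated to natural scale by
the delta method.  Bias flags use the ratio ± 2·SE rule with a 1e-6
relative tie guard so solver-precision deviations on noiseless data do
not read as bias.

Least squares is unweighted by default (matching the additive
homoscedastic noise model below); per-record weights are accepted.
Responses are assumed already normalised to the system maximum; an
optional `normalize_to_reference` step divides by the fitted top of a
designated reference full agonist.

Model selection: the nested ladder clark → emax → sabre3 → sabre4 is
fitted and the recommendation is the simplest model that no richer
model significantly improves upon by the extra-sum-of-squares F test
(α = 0.05), with AICc reported alongside.  A fit with fewer than 5
observations per adjustable parameter carries a warning (5–10
well-distributed points per parameter is the working guidance); fewer
observations than parameters is an error.

## Furchgott analysis

Two routes, which agree on clean data to ≤ 1e-3 relative:

* **classical**: equiactive concentration pairs are extracted from the
  pre- and post-inactivation curves by monotone piecewise-linear
  interpolation in (log concentration, response) space — the
  least-assumption choice; response levels default to deciles of the
  overlapping response range.  Ordinary least squares of 1/[L] on
  1/[L]′ gives q = 1/slope and K_d = (1−q)/(q·intercept).  The
  reciprocal transform distorts the error structure, and under strong
  gain the intercept extrapolates far outside the data, so this route
  is noise- and interpolation-sensitive (the model-based route is
  preferred for noisy data);
* **model-based**: a global fit of the q-scaled three-parameter model
  across all conditions with one K_d, one γ and free per-condition q.

## Synthetic data

`datasim` emulates multi-ligand / multi-pathway / multi-condition
functional assays: closed-form model responses on per-ligand 10-point
log-spaced grids spanning K_d·10^±3 (so every curve is sampled around
its own transition), plus additive homoscedastic Gaussian noise on the
fractional response.  This matches the unweighted least-squares
objective; it does not emulate assay-specific features of real data —
heteroscedastic or multiplicative noise, baseline drift, plate effects,
solubility-truncated top concentrations — so passing recovery tests
demonstrate correctness of the estimation machinery under the stated
noise model, not robustness to real-world artefacts.  Out-of-range
noisy responses are retained (not clipped), flagged by the table, so
the fitter sees realistic excursions.

Fixture registry (generating parameters are arbitrary test choices,
not claims about published datasets): `reserve_series` (five ligands,
one pathway, γ = 12, σ = 0.02), `dual_gain` (five ligands on two
pathways with γ = 2 vs 2000 — contrasting vantage points along one
cascade), `inactivation_series` (γ = 40, q ∈ {1, 0.3, 0.05}),
`dual_inactivation` (two ligands of 20-fold affinity and efficacy
contrast, shared q), `balanced_bias` (equal efficacies, γ = 10 vs
1000), `constitutive` (ε_R0 = 0.45, γ = 1, full/partial/neutral/inverse
agonists).

## Simulation-study sizes

The recovery and calibration suites use 8–10 point curves, 5 ligands,
σ = 0.02 and 200 replications (20 for the bias power check), with 4–6
optimiser starts per noisy replicate — noisy objectives have no narrow
global basin, so the full 16-start hypercube is reserved for the
deterministic fits.  These sizes give Monte-Carlo standard errors
comfortably below the acceptance margins they are checked against.

## Numerical conventions and degenerate inputs

Concentration 0 is legal everywhere (it carries the basal response);
infinite concentration is not — asymptotes are exposed through
`max_response`.  `amplify` returns exactly 1 at full activation.
`kobs` raises a `FlatResponseError` for a neutral antagonist
(ε = ε_R0), where no EC50 exists.  `occupancy_from_response` rejects
responses at or above the ligand's attainable maximum, and
`occupancy_at_half_response` requires ε(γ+1) > 1 — weaker ligands never
reach half-maximal response.  Equiactive extraction requires ≥ 3 usable
pairs and skips levels outside the overlap with a warning;
non-monotone curves are flagged and their running maximum is used.

## Known limitations

* No Hill coefficient: abrupt or shallow curves beyond the hyperbolic
  family cannot be captured.
* Asymptotic standard errors; no profile likelihood or bootstrap.  The
  ±2·SE bias rule inherits the usual near-boundary caveats of Wald
  intervals.
* The classical Furchgott regression is exact only on exact equiactive
  pairs; interpolation error propagates disproportionately into K_d
  under strong amplification.
* Constitutive-activity variants do not support receptor-inactivation
  conditions (no closed form), and occupancy–response linking is only
  provided for ε_R0 = 0.
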