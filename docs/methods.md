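# Methods

## Model structure

The model couples an oral-challenge glucose/insulin backbone of the E-DES
family with single-pool triglyceride (TG) and NEFA kinetics.  It has exactly
13 states and 25 named parameters; state order and units are documented in
`mixedmeal.model`.

**Glucose.** A meal bolus of `f_G · G_meal` (converted at 180.16 g/mol) is
emptied from an *analytic* stomach at rate `k1` into a gut-lumen mass state,
which transfers to plasma at `k2`.  The stomach is kept out of the state
vector (its content is `D·exp(−k1 t)` in closed form), so gastric emptying
and intestinal transfer are separate processes without a 14th state.
Plasma glucose is produced endogenously at

    EGP = max(0, EGP_b − k3·(G − G_b) − k4·(I_int − I_b))

and removed by (i) insulin-independent Michaelis–Menten uptake scaled so it
balances EGP_b at the fasting state, (ii) insulin-dependent uptake
`k5 · (I_int − I_b)/I_b · G/(K_M + G)`, and (iii) renal excretion
`k10·(G − G_thresh)` above the threshold.  The insulin drive in (ii) is
normalized by fasting insulin so that the published magnitudes of `k5`
(≈0.04–0.14) yield physiologic disposal rates with insulin tracked in mU/L;
`k5` therefore carries units mmol·L⁻¹·min⁻¹.  EGP is clipped at zero
(no net hepatic glucose uptake), which also guarantees glucose cannot be
driven negative.

**Insulin.** Secretion is a proportional–integral–derivative response to
the glucose excursion, `k6·ΔG + k7·E + k8·dG/dt`, clipped at zero (the
pancreas cannot secrete negatively); clearance is first-order (`k9`)
anchored at fasting insulin, so the fasting state is an equilibrium and
insulin never falls below basal.  The integral state is leaky
(`dE/dt = ΔG − E/tau_i`) with an anti-windup floor at zero; a pure
integrator would prevent the system from ever returning to the fasting
steady state.  A four-stage linear delay chain at rate `k14` propagates
plasma insulin to the remote signals; stage 1 doubles as the interstitial
insulin driving glucose uptake and stage 4 (`I_d4`) acts on the lipid
fluxes, which keeps the total dimension at 13.

**Triglyceride.** Meal TG (860 g/mol) is a bolus into the first of three
gut/lymph transit compartments (rate `k13`, Erlang-3 delay), appearing in
plasma as chylomicron TG.  Chylomicron and VLDL TG are pooled.  The liver
secretes `TG_liver = max(0, k16 − k15·(I_d4 − I_b))`; the clip avoids
negative secretion at high insulin.  LPL lipolysis is

    TG_LPL = (k11 · [I_d4]_pmol + c_lpl) · TG_pl

proportional to plasma TG and increasing in delayed insulin.  Two unit/
closure conventions matter here.  First, `k11` is interpreted per pmol/L of
insulin (1 mU/L = 6.945 pmol/L) so that its published magnitude (~1e-4)
produces realistic postprandial TG clearance while the model tracks insulin
in mU/L.  Second, `c_lpl = k16/TG_b − k11·[I_b]_pmol` is a derived basal
LPL activity: a purely insulin-proportional form cannot balance hepatic
secretion at the measured fasting TG for the published parameter
magnitudes, so the basal closure supplies the insulin-independent share of
LPL activity.

**NEFA.** Adipose lipolysis releases NEFA at

    NEFA_ATL = max(0, R + K_ATL / (1 + c_ins·max(0, I_d4 − I_b)))

where `K_ATL` is the insulin-suppressible release and
`R = k12·NEFA_b − 3·f_spill·k16 − K_ATL` is a derived offset making the
fasting state balance exactly (R = 0 at the default parameter set and
subject).  Three NEFA are liberated per TG molecule hydrolyzed by LPL and a
fraction `f_spill` spills into plasma; uptake is first-order (`k12`).
Putting `K_ATL` *inside* the suppressible term rather than as a pure
closure scale is deliberate: a multiplicative closure would cancel it from
the dynamics entirely and make it unestimable.

**Basal closure.** `basal_closure(params, subject)` returns the derived
constants (EGP_b = 0.065 mmol/L/min, a documented physiologic basal glucose
turnover of ~2 mg/kg/min at a 0.17 L/kg distribution volume; the basal
insulin-independent uptake; `c_lpl`; the adipose offset) such that the
right-hand side vanishes identically at the measured fasting concentrations.
It raises when no non-negative balance exists — e.g. spillover alone
exceeding basal NEFA turnover, or the insulin-driven LPL flux exceeding
`k16`.  Because closure is re-derived for every candidate parameter vector
during estimation, zero-meal simulations are constant by construction and
fasting data points carry no misfit.

## Parameters

Five parameters default to published population-average estimates from a
10-sample meal-challenge cohort: `k5` = 0.102, `k6` = 2.852,
`k11` = 8.3e-5, `K_ATL` = 0.126, `k16` = 0.015 mmol/L/min.  The
glucose/insulin backbone constants (`k1`–`k4`, `K_M`, `k7`–`k10`,
`G_thresh`, `tau_i`) are E-DES-derived magnitudes calibrated once so the
default simulation reproduces textbook postprandial physiology (glucose
peak < renal threshold within 30 min, insulin peak ~9× basal, TG peak
~3.5 h, NEFA dip to ~55% of fasting).  `k13` = 0.02/min makes lymphatic TG
delivery >99.9% complete by 10 h and returns plasma TG to fasting by 12 h,
consistent with the physiological constraints the regularizer encodes.
`k14` = 0.15/min gives a remote-insulin delay of ~7 min per stage.  Default
bounds span roughly a factor 10 around each default (fractions bounded by
1).  Registry invariants: 25 entries, 9 free by default.

The default **free set** is `{k1, k5, k6, k7, k11, k13, k14, k16, K_ATL}`:
the five tabulated above plus the rates that control meal timing.  It was
selected by the package's own model-reduction workflow — ±50% local
sensitivity ranking followed by profile-likelihood confirmation on a
noiseless 6-sample fixture.  Two findings from that workflow are worth
recording.  `k12` (NEFA uptake) is excluded because freeing it opens a
NEFA-shape compensation channel that makes `k11` and `K_ATL` practically
non-identifiable.  And under the 6-sample design, eight of the nine free
parameters are two-sided identifiable but the lower side of `k7` is flat:
with so few insulin samples the proportional and integral secretion gains
cannot be separated, and every alternative ninth parameter we tested (k2,
k3, k9, k12, k15, c_ins, f_spill, tau_i, K_M, v_G, v_TG) either stayed
one-sided or de-identified a partner.  Denser designs (the 10-sample
protocol) do not have this limitation.

## Estimation

The cost is the max-normalized sum of squares over all observed
metabolites; observations are interpolated from a dense simulation (4-min
lattice merged with the observation times).  Missing samples are simply
absent per metabolite, which accommodates designs whose TG/NEFA grids are
sparser than glucose/insulin.

Regularization appends four residuals to the least-squares vector:

    (AUC_G(240) − G_meal)/G_meal,  (AUC_TG(600) − TG_meal)/TG_meal,
    (TG_pl(720) − TG_b)/TG_b,      (NEFA_pl(0) − NEFA_b)/NEFA_b

each multiplied by a configurable weight (default 1).  They are implemented
as *normalized, signed residuals that the solver squares* rather than the
raw signed differences of the printed composite cost: raw signed penalties
would reward undershoot, and a least-squares solver squares residual
entries anyway.  Normalizing by the target quantity puts penalties and data
residuals on a common scale.  AUCs are mass integrals of the appearance
fluxes (grams).  With equilibrium-anchored initial conditions the NEFA(0)
penalty is identically zero; it is retained for interface fidelity and
becomes active only if initialization conventions change.

Optimization: trust-region-reflective bounded least squares in log10
parameter space, 25 Latin-hypercube starts (stratified in log-space,
reproducible under a seed), finite-difference step 1e-3 (chosen above the
ODE tolerance so gradients are not noise), up to 400 function evaluations
per start, ftol = xtol = 1e-12.  Candidates whose basal closure is
infeasible return a large sentinel residual graded by the constraint
violation, which slopes the landscape back toward the feasible region
instead of stranding the solver on a flat plateau.  A start is "converged"
when the solver reports success with a sub-sentinel cost; the best
converged start is reported along with the full per-start ledger.

## Identifiability

Local sensitivity simulates every parameter at 0.5× and 1.5× (clipped to
its bounds, with the applied factor recorded) and reports the per-metabolite
normalized L2 trajectory deviation, summarized as the mean over the four
plasma metabolites and the max over directions.

Profile likelihood fixes one parameter on an 11-point log grid spanning
[0.2×, 5×] of its fitted value (clipped to bounds), re-optimizes the
remaining free parameters warm-started from the nearest profiled point, and
classifies: *identifiable* if the cost rises above threshold on both sides;
*structurally non-identifiable* if the profile is flat to within 5% of the
threshold; *practically non-identifiable* otherwise.  The default threshold
is χ²₀.₉₅,₁ = 3.84 **scaled by the nominal noise variance on the
max-normalized residual scale** (σ_rel = 0.05, i.e. threshold 0.0096): the
χ² rise applies to noise-standardized residuals, and applying 3.84 directly
to the max-normalized cost would declare even strongly constrained
parameters non-identifiable.  Both σ_rel and the threshold are conventions,
exposed as arguments.

## Synthetic data

Two sampling designs are built in: a 6-sample 0–480 min design with a
75/60/20 g (glucose/lipid/protein) meal, and a 0–300 min design with 10
glucose/insulin samples and 7 TG/NEFA samples and a 67/36/12 g meal.
Phenotype presets carry published subgroup estimates of the five tabulated
parameters (insulin-sensitive/-resistant and lower/higher-liver-fat
subgroups plus population averages).  Subject fasting values per phenotype
— (5.0, 8.0, 1.3, 0.45) for sensitive-like, (5.3, 10.0, 1.5, 0.5)
intermediate, (5.6, 14.0, 1.8, 0.55) for resistant-like, BW 85 kg — are
*fabricated defaults* chosen to be typical of overweight cohorts, not
published values.  Measurement noise is multiplicative Gaussian with
per-metabolite CVs (glucose 3%, insulin 8%, TG 5%, NEFA 8%) resembling
clinical assay precision; cohorts add log-normal between-subject parameter
spread (default CV 15%) on the free parameters, redrawing the rare
combination whose basal closure is infeasible.

What the generator does *not* emulate: assay-specific error structure,
dropouts, within-day circadian drift, second meals, and chylomicron/VLDL
subfraction differences.  Passing recovery tests on these fixtures
therefore demonstrates correctness of the inverse machinery under the
model's own assumptions, not robustness to real-data model misfit.

## Numerical choices

LSODA (via `scipy.integrate.odeint`) at rtol 1e-6 / atol 1e-8; the
right-hand side is a scalar-math routine JIT-compiled with numba when
available (pure-Python fallback).  State values are evaluated on the
non-negative cone inside the RHS and solver output is clipped at zero
(solver noise only; the dynamics keep the cone invariant).  Appearance-flux
AUCs use trapezoidal quadrature on the reporting grid; halving the solver
tolerances moves plasma trajectories by <0.1%.  Gram↔mmol conversions use
180.16 g/mol (glucose) and 860 g/mol (generic TG).

## Known limitations

* Protein and incretin effects are out of scope; the protein mass is
  carried for provenance only.
* Chylomicron and VLDL TG are pooled; subfraction kinetics cannot be
  resolved.
* The fasting state is an exact model equilibrium by construction, so
  "failure to return to steady state" manifests as slow transients rather
  than a shifted equilibrium; the TG-at-720-min penalty accordingly
  constrains return *speed*.
* Single meal, single subject per fit; no hierarchical pooling across a
  cohort beyond fitting the cohort-mean curve.
* `k7`'s lower side is not identifiable from 6-sample designs (see above);
  fits to such designs should fix it or report its profile.
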