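# Methods

## Model

The package simulates a population-level model of an antigen-specific
T-cell compartment: resting effector (E_r) and regulatory (R_r) pools feed
activated pools (E, R) that cross-regulate as a prey–predator negative
feedback. Treg act on Teff twice — they suppress proliferation
(multiplying α_E by the decreasing Hill term H⁻(R; k_R, h)) and raise
clearance (multiplying γ_E by 1 + H⁺(R; k_R, h), so the Teff residence
time is maximal, 1/γ_E = 5 days, when no activated Treg are present).
Teff act on Treg once, driving their expansion through α_R·H⁺(E; k_E, h).
Treg clearance γ_R is constant. Both activated pools return to rest at
the memory rate η; resting pools activate at δ and die/anergize at β.
Populations are continuous cell counts and time is in days.

Two damage compartments are driven one-way by activated Teff through the
second-order term E′ = (E/a)²: reversible damage l gains d₁·E′ and drains
through recovery (r) and irreversible conversion (d₂); irreversible damage
L integrates d₂·l and never decreases. Damage has no feedback on the
T-cell dynamics; l is the model's counterpart of acute MRI activity (CEL
counts), L of accumulated deficit.

Two equation details are deliberate modelling conventions, recorded in the
constant `EQUATION_FORM` in `tregloop.model`: the Treg-dependent Teff
clearance uses the form γ_E·(1 + H⁺), i.e. Treg at most double the
baseline clearance, and the damage parameters follow their labels
(d₂ = irreversible conversion, r = recovery), so dl/dt = d₁E′ − (r+d₂)l,
dL/dt = d₂l.

### Parameters (defaults)

| parameter | meaning | default | units |
|---|---|---|---|
| δ | activation (antigen presentation) rate | 1 | 1/day |
| β | resting anergy/death rate | 0.01 | 1/day |
| η | return-to-resting (memory) rate | 0.01 | 1/day |
| α_E | max Teff proliferation rate | 2 (presets) | 1/day |
| α_R | max Treg proliferation/activation rate | 1 healthy / 0.25 autoimmune | 1/day |
| γ_E, γ_R | clearance rates | 0.2 | 1/day |
| k_E, k_R | half-maximal population sizes | 1000, 200 | cells |
| h | Hill coefficient | 5 | — |
| d₁, d₂ | reversible / irreversible damage rates | 1, 0.02 | 1/day |
| a | damage threshold population scale | 22 800 | cells |
| r | recovery rate | 0.1 | 1/day |

Initial state: E_r = R_r = 0, E = 1000, R = 200 cells, l = L = 0.
Runs default to 1825 days (5 years) at dt = 0.05 days. The 22 800-cell
scale `a` doubles as the default relapse-detection threshold, being the
only population scale the damage model defines.

## Stochastic forcing

Thymic escape of self-reactive cells is modelled as spike trains: each
pool receives a fixed count of round(100 · duration/365) impulses at
i.i.d. uniform times on [0, duration) — a fixed-frequency scheme, so
changing the seed moves the impulse times but never the count (a Poisson
count is available behind a flag for robustness studies). The Teff and
Treg trains are independent streams spawned from one master seed. An
impulse adds its amplitude to the resting pool as a state jump at the
first grid point at or after its time.

**Impulse amplitudes.** The amplitudes are free constants of the model;
the package fixes them at 300 resting Teff and 60 resting Treg cells per
impulse (expected influx Λ_E ≈ 82.2, Λ_R ≈ 16.4 cells/day). The 5:1 ratio
mirrors the half-max constants and initial activated pools; the scale is
the largest (at that ratio) for which the model retains its qualitative
structure, established by a one-time scan: the healthy preset stays
homeostatic (bounded Treg over 10-year runs across seeds), the reduced
model keeps a finite, stable-spiral equilibrium across the whole
α_R ∈ [0.25, 2] range with E* monotone decreasing in α_R, and the
autoimmune preset relapses in essentially every seed. At roughly three
times this forcing the healthy Treg pool grows without bound (the mean
Treg gain α_R·H⁺(E) exceeds clearance at the Teff levels the stronger Teff
influx sustains) and the spiral degenerates: those regimes are artifacts
of over-forcing, not of the loop. Amplitudes remain configurable, and the
test suite checks the conclusions that should survive amplitude changes
rather than fixing the scale as a claim.

## Integration

Explicit Euler on the model's native grid (dt = 0.05 days) is the
reference scheme, because impulses are state jumps and fixed-step
integration keeps runs bit-reproducible from their configuration. After
each step any component driven below zero is clipped to exactly zero and
the event counted in the trajectory log (impulse forcing plus explicit
stepping can transiently undershoot). Hill terms saturate to 1 before the
(x/k)ʰ power can overflow; a non-finite state aborts with an error naming
the step and state. Measured accuracy: halving dt changes
log₁₀-populations by at most ~2% over 100-day autoimmune runs (asserted
in the suite with grid-aligned impulse times, which isolate truncation
error from impulse-placement differences) and by 5–90% over multi-year
horizons — the dynamics amplify phase differences at relapse onsets, so
long-horizon agreement is statistical (peak distributions, episode
counts), not pointwise. Runs sized to verify properties therefore use
100–2000-day horizons as appropriate to the property, a package choice.

## Reduced model and phase-plane analysis

Replacing each train by its expected influx (Λ = rate × amplitude/365)
reduces the system to (E, R). Equilibria are found by a hybrid
Newton–Powell root search from the standard initial state, with a
2000-day relaxation fallback when the search stalls; the residual
tolerance is 10⁻⁸ cells/day and the result is independent of the initial
guess (tested over random guesses). The Jacobian is computed by central
finite differences with relative step 10⁻⁶; eigenvalues classify the
point (stable spiral/node, saddle, unstable). When no finite equilibrium
exists (strong forcing plus large α_R lets the Treg pool grow without
bound) the solver raises rather than returning a pseudo-root.

Phase-plane sectors are the four growth-sign quadrants: I = both
populations growing (dE/dt > 0, dR/dt > 0), II = Teff shrinking / Treg
growing, III = both shrinking, IV = Teff growing / Treg shrinking.
Boundary states (either rate ≈ 0, e.g. the equilibrium) are deliberately
unassigned. This sign convention is fixed here once; perturbation timing
rules ("first entry into sector IV after day 100") refer to it.

## Experiments

**Sensitivity sweep.** Full-factorial α_E ∈ [1, 2] × α_R ∈ [0.25, 1] at
step 0.05 (21 × 16 cells), retaining the per-run maximum activated-Teff
count over many noise realizations per cell; per-cell seeds derive from
(master seed, i, j, replicate) via seed-sequence spawn keys, so cells are
independent and order-insensitive. The full 21×16×200 sweep is provided;
routine verification uses a 4×4×20 sub-grid, which preserves the
distribution-level trend (higher peak medians at low α_R) at desk-scale
cost. Per-seed peaks are deliberately not assumed monotone in α_E — a
slower Teff response can interact with impulse timing to produce a larger
relapse — so the suite asserts medians only. Convergence of a running
statistic over seeds is declared when its trailing-50 window spread,
normalized by the current value (peaks span orders of magnitude, so the
criterion is relative; the raw threshold 10⁻⁵ is kept on that normalized
scale), falls below 10⁻⁵.

**Perturbation (therapy) experiments.** A cell bolus is injected into a
chosen pool at an explicit day or at first entry into a named sector;
both arms replay identical pulse trains (common random numbers), so any
difference is attributable to the bolus. The default magnitude raises R
by the maximum activated-Treg count observed on the unperturbed
trajectory — a bolus near the largest attainable Treg level. The healthy
regime is essentially insensitive (post-bolus Teff maxima stay in the
10³–10⁴ range) while the autoimmune regime can rebound 3–5 orders of
magnitude higher: suppressing Teff lets the Treg pool decay with little
Teff-driven support, and the subsequent Teff escape through the weakened
loop overshoots far beyond the unperturbed peaks. Under the fallback
equation form and any forcing consistent with the anchors above this
rebound ceiling is ~10⁸ cells; a rebound of >10⁹ would
require a still-weaker Treg resupply than those anchors admit.

## Clinical comparison pipeline

Monthly CEL counts per patient (48 months in the reference design) are
compared with simulated reversible damage: the simulation is sampled
instantaneously at each month boundary (month = 365/12 days, so 120
months = 3650 days; a 30-day month and within-month means are available
behind flags), both series are first-differenced ("evolution" series:
zero = stable, positive = exacerbation), and the patient series is slid
along each simulated series, keeping the best Pearson correlation over
all n − m + 1 alignments (73 for 47-point windows in 119-point series;
ties broken at the smallest offset; zero-variance simulated windows are
skipped and counted, a zero-variance patient series is an error).
Repeating over a bank of autoimmune simulations — shared across patients
— yields one best-r distribution per patient, summarized by median, modal
0.1-wide histogram bin, and maximum. The maximum-over-alignments
selection biases the null upward; the suite quantifies this with a
white-noise null, which concentrates well below the correlations that
matched dynamics produce.

## Synthetic cohorts

Each synthetic patient is one autoimmune-regime run (own seed, optionally
own α_R as a severity knob): monthly reversible damage sets the expected
lesion count and the observed count is Poisson(scale · l) — negative
binomial behind a flag for extra dispersion. A month is flagged as a
relapse when activated Teff crossed the 22 800-cell threshold within it.
The default scale (0.3 lesions per damage unit) was calibrated once so
the long-run mean monthly count is ≈ 2 lesions, a typical order for
active RRMS; because the damage series is heavy-tailed (quiet months near
zero, relapse months orders of magnitude higher), realized small-cohort
means scatter widely around that figure, and individual series can be
all-zero (lesion-free patients are skipped by correlation analyses, whose
statistic is undefined for constant series). The generator reproduces the
statistical structure the pipeline assumes — non-negative integer counts,
bursty clustering (variance/mean > 1), patient heterogeneity from
independent noise — but not scanner/reader noise, EDSS dynamics, or any
claimed quantitative lesion calibration; pipeline results on synthetic
cohorts validate the machinery (including closed-loop recovery of a
planted generating trajectory), not clinical effect sizes.

## Known limitations

- One well-mixed compartment: no CNS/periphery structure, innate
  immunity, or TCR repertoire diversity.
- Parameter values are adopted as given; no fitting to patient data is
  provided or attempted.
- Explicit Euler at dt = 0.05 is first-order: long-horizon trajectories
  are reproducible but pointwise-sensitive to step size; conclusions are
  drawn at the distribution level.
- The perturbation-rebound magnitude depends steeply on the Treg influx
  (see above); absolute burst heights should be read as orders of
  magnitude, not calibrated counts.
- The damage→lesion mapping is a convention; correlation analyses are
  invariant to its positive rescaling but its absolute scale is not
  identified.
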