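# Methods

`hcmcell` simulates the twitch of a human ventricular cardiomyocyte as a
seven-state ODE system paced at 1 Hz, and builds on top of it the analysis
layers used for cellular in-silico trials in hypertrophic cardiomyopathy
(HCM): genotype remodelling, populations of models, sensitivity analysis,
drug trials and nonparametric statistics.  This note describes the model,
its assumptions, the calibration of its default constants, the numerical
choices, and what the synthetic test fixtures do and do not establish.

## 1. Cell model

### 1.1 Myofilament subsystem

Four fractional states describe the contractile machinery:

- `CaTRPN` — calcium occupancy of troponin C,
- `B` — tropomyosin in the blocked position,
- `W` — weakly bound (pre-powerstroke) crossbridges,
- `S` — strongly bound, force-generating crossbridges,

with the unblocked crossbridge-free fraction `U = 1 − B − W − S` implicit,
so occupancy conservation holds exactly by construction.

```
dCaTRPN/dt = k_on (Cai/Ca50_eff)^n_trpn (1 − CaTRPN) − k_off CaTRPN
dB/dt      = k_ub min(CaTRPN^(−n_tm/2), cap) U − k_bu CaTRPN^(n_tm/2) B
dW/dt      = k_uw a(R) U − (k_wu + k_ws) W
dS/dt      = k_ws W − k_su S
T_a        = T_ref · S                    (isometric, extension ratio λ = 1)
```

`Ca50` is the free-calcium concentration at half-maximal thin-filament
activation (µM); a smaller value means a more calcium-sensitive filament.
The tropomyosin blocked/unblocked equilibrium constant K_B is manipulated
through its reverse rate `k_ub`, so a K_B × 0.8 remodelling is `k_ub × 0.8`.

**Myosin availability.** Myosin heads in the super-relaxed state (SRX)
cannot attach to actin; the disordered-relaxed (DRX) heads can.  With
control DRX:SRX odds `rho0` and the relative odds
`R = (DRX:SRX)/(DRX:SRX)_control`, the DRX head fraction is
`f(R) = R·rho0/(1 + R·rho0)` and the crossbridge attachment rate is scaled
by `a(R) = f(R)/f(1)`, so the control model is unchanged at `R = 1`.
A config switch (`r_scales_tref`) lets `a(R)` scale `T_ref` instead of
`k_uw`; the attachment-rate route is the default because it keeps
duty-cycle dynamics responsive to availability.

**Myosin → thin-filament feedback.** DRX myosin can itself activate the thin
filament.  The default (`fb_mode="static"`) form scales the effective
calcium sensitivity with availability:

```
Ca50_eff = Ca50 · clip(1 − γ_fb (R − 1), 0.5, 1.5)
```

so excess DRX (R > 1) sensitises the filament and an SRX stabiliser drug
(R < 1) desensitises it.  A dynamic variant driven by instantaneous
crossbridge occupancy `(W+S)` is available behind `fb_mode="dynamic"` for
exploration.  The gain `γ_fb = 0.63` is a calibration product chosen so
that the `MYH7` scenario with feedback prolongs tension RT90 clearly while
availability alone does not (see §4).  The feedback is attached per
scenario: it is enabled by the `MYH7_R403Q` remodelling and off elsewhere,
which is what makes the myosin inhibitor's relaxation benefit
genotype-specific.

### 1.2 Calcium subsystem

A deliberately reduced calcium-handling description replaces a full
membrane/electrophysiology model (membrane potential, sodium and potassium
dynamics are out of scope):

```
J_rel   = k_rel · g · Ca_sr            dg/dt = −g/τ_rel,  g += g_amp at each stimulus
J_serca = serca_scale · V_serca · Cai^h/(Cai^h + K_serca^h)
J_ncx   = ncx_scale (1 + α_nal·inal_block) k_ncx (Cai − Ca_dia)
J_in    = lcc_scale · A_in · [t < d_in]
dCai/dt = β(Cai) (J_in + J_rel − J_serca − J_ncx − J_trpn)
dCa_sr/dt = vr (J_serca − J_rel)
```

with rapid calmodulin-class buffering folded into
`β(Cai) = 1/(1 + B_cmdn K_cmdn/(K_cmdn + Cai)²)` and the troponin flux
`J_trpn = TRPN_tot · dCaTRPN/dt` coupling bidirectionally to the
myofilament: troponin-kinetics remodelling therefore reshapes the calcium
transient, as it must for the troponin-I phenotype.  In the closed
configuration (`A_in = 0`, `k_ncx = 0`) total calcium
(free + fast-buffered + troponin-bound + SR/vr) is conserved exactly by
construction and to < 1e−6 relative per beat numerically.

The intervention knobs map pharmacology onto fluxes: L-type block scales the
trigger influx, SERCA upregulation scales the uptake, and late-sodium block
is represented phenomenologically as enhanced extrusion (reduced sodium
load → stronger forward exchange; gain `α_nal = 0.3`).  The latter is a
directional stand-in: its acceptance surface is "mild relaxation effect,
partial anti-hypercontractile effect", not quantitative INaL physiology.

### 1.3 Pacing and integration

Pacing is a timing event with a 1000 ms cycle (1 Hz): at each cycle start
the release gate jumps by `g_amp` and integration restarts (clean handling
of the upstroke discontinuity); the influx pulse boundary `d_in` also splits
the integration window.  Two backends exist:

- scalar LSODA (stiff-capable adaptive, `scipy.integrate.odeint`) for
  single cells, and
- a vectorised adaptive Runge–Kutta batch path that integrates an entire
  population as one flattened `7N`-state system, which is what makes
  population trials tractable on one CPU.

The two paths agree to < 0.2% on all biomarkers and are cross-checked in
the test suite.  Steady state is declared when the state at successive
cycle starts changes by less than `tol` (default 1e−6 relative, with
per-state magnitude floors so that states at the integrator noise floor —
e.g. the fully decayed release gate, ~2e−7 at end-diastole — cannot stall
the criterion).  Population work uses `tol = 1e−4`, which changes
biomarkers by < 0.1% relative to 1e−6 while roughly halving pacing cost.
Simulations start from a state near the control limit cycle rather than a
quiescent state with an unloaded SR, and scenario re-runs warm-start from
each model's own calibrated state; this shortens the pacing transient by
hundreds of beats without changing any limit cycle.

## 2. Default constants

Default constants are calibration values, not measurements.  They were
tuned so that the control steady twitch at 1 Hz has diastolic Cai
≈ 0.085 µM, calcium-transient amplitude ≈ 0.75 µM, tension amplitude
≈ 21 kPa, tension time-to-peak ≈ 146 ms and tension RT90 ≈ 356 ms —
ranges typical of human ventricular cell models — while reproducing the
qualitative genotype and pharmacology surfaces in §4.  Two calibration
choices deserve explanation:

- **Troponin kinetics.** `k_on = 0.032 /ms`, `k_off = 0.0224 /ms`,
  `Ca50 = 0.96 µM`, `n_trpn = 2`.  The steady-state occupancy curve
  `c(Cai) = Cai²/(Cai² + Ca50²·k_off/k_on)` is identical to the more
  conventional symmetric parameterisation (`Ca50 = 0.80 µM`,
  `k_on = k_off`), but the asymmetric split places the buffer in the
  kinetic regime on the upstroke timescale.  There, the dissociation rate
  — not the equilibrium sensitivity — controls the timing of the free
  calcium peak: lowering `k_off` makes troponin hold calcium, saturating
  the buffer earlier in the rise (earlier, lower calcium peak) and
  releasing it more slowly during decay (prolonged transient).  This is
  the mechanism behind the troponin-I phenotype of accelerated calcium
  rise with slowed decay, and it is why the calcium time-to-peak is more
  sensitive to `k_off` (±50%) than to `Ca50` (±30%) at baseline.  In a
  near-equilibrium buffer a `k_off` scaling is exactly equivalent to a
  `Ca50` scaling of `f^(1/n)` and could never dominate; the kinetic regime
  is therefore a structural requirement, not a tuning accident.
- **SERCA shape.** `V_serca = 1.22 µM/ms`, `K_serca = 0.77 µM`, `h = 2.8`,
  with weak linear extrusion (`k_ncx = 0.013 /ms`, reversal at 0.053 µM).
  SERCA dominates calcium removal over most of the decay, which is what
  gives SERCA upregulation its leverage on relaxation.

## 3. Analysis layers

### 3.1 Genotype library

| name | remodelling | rationale |
|---|---|---|
| `MYH7_R403Q` | `R = 1.3`, feedback on | SRX destabilisation measured in mutant hiPSC-CMs; knock-on thin-filament activation |
| `TNNT2_R92Q` | `Ca50 × 0.7`, `k_ub × 0.8` | calcium sensitisation plus altered tropomyosin positioning (K_B × 0.8) |
| `TNNI3_R21C` | `Ca50 × 0.7`, `k_off × 0.5` | increased calcium binding and slowed dissociation from troponin |

Remodellings are `ScalingSpec` objects: named multiplicative factors plus
optional overrides (`R`, `fb_mode`, `inal_block`).  Overrides apply first,
factors second, so a drug's multiplicative `R` factor composes on top of a
variant's `R` override; spec composition is elementwise factor
multiplication.

### 3.2 Populations of models

An initial population (default 2000 models at full scale; tests and the
acceptance script use 80–100 for runtime) is sampled by Latin Hypercube
over [50–200]% of baseline on eight calcium/myofilament axes: `g_amp`,
`V_serca`, `K_serca`, `k_ncx`, `Ca50`, `k_uw`, `k_ws`, `TRPN_tot`.  The
membrane-conductance axes of a full electrophysiology population cannot be
represented in the reduced model and are deliberately omitted.  Each model
is paced to steady state and accepted iff every calibrated biomarker
(tension amplitude, RT50, RT90; calcium amplitude, TD50, TD95) lies inside
its calibration range.  Shipped ranges are a synthetic fixture — the
[2.5, 97.5] percentiles of the sampled control population itself —
standing in for experimentally derived physiological ranges; users can
supply their own ranges file.  With the shipped fixture roughly 80% of
sampled models are accepted and the accepted population is deliberately
heterogeneous (tension-amplitude IQR spans about ±2× around the median).

### 3.3 Sensitivity analysis

The absolute sensitivity of biomarker B to parameter p is the normalised
central difference `|S| = |(B(p(1+d)) − B(p(1−d)))/B(p)|/(2d)`, unit-free
and comparable across biomarkers; `d = 0.3` for `Ca50` and `k_ub` (K_B) and
`d = 0.5` for `k_off`.  The default analysis evaluates the baseline model.
A population-median mode exists, but under ±2× parameter sampling many
population members sit near a transient-morphology switch (the calcium
transient can trade its early release-driven peak against a later
buffer-rebound shoulder), which makes per-model time-to-peak sensitivities
discontinuous; the baseline-model analysis is the numerically well-posed
summary and is the shipped default.

### 3.4 Drug trials

Mavacamten is modelled purely as an SRX stabiliser: a saturating
dose–response maps free concentration to an `R` reduction,
`R(c) = R_base(1 − E_max c^h/(c^h + IC50^h))`.  The shipped constants
(`E_max = 1.0`, `IC50 = 1.084 µM`, `h = 1.5`) are calibration products of
`calibrate_dose_response` against the default `MYH7` model, anchored so the
0.5 µM reference dose restores control tension amplitude and a 3 µM dose
suppresses amplitude to 30%; they carry no claim about the real compound's
binding constants.  Clinical ng/ml concentrations convert to µM via
molar mass and free fraction, both of which must be supplied from a
compound database.  The designed thin-filament desensitiser maps level d to
`Ca50 × (1 + d)` (a 50% desensitisation approximately inverts the variants'
`Ca50 × 0.7`); a reciprocal `1/(1 − d)` mapping is selectable.

### 3.5 Statistics

Scenario populations are compared with the Mann–Whitney U test (exact null
distribution when the pooled sample is ≤ 12 without ties, tie-corrected
normal approximation otherwise) and with Kruskal–Wallis plus Dunn's
post-hoc pairwise z-tests on pooled ranks with tie correction.  The Dunn
family adjustment is Bonferroni by default (selectable); significance is
read at P < 0.05.  Parametric tests are not part of the simulation
pipeline.  Dunn's test is implemented directly from its rank formulas on
scipy primitives.

### 3.6 Parameter recovery

`TwitchParameterFit` recovers multiplicative remodelling factors from an
observed steady-twitch trace by bounded nonlinear least squares in log
space, fitting both channels normalised by their amplitude ranges.
Candidate parameter sets are paced for a fixed number of beats
(warm-started from the baseline steady state) rather than to a stopping
tolerance, because a tolerance-terminated pacing loop makes the residual a
step function of the parameters (the beat count changes discretely) and
stalls trust-region optimisers.  Standard errors come from the Gauss–Newton
covariance at the optimum via the delta method.

## 4. What the defaults reproduce

On the calibrated population (accepted n ≈ 80), with medians against the
control population's interquartile range (IQR):

- all three genotypes raise median tension amplitude and median tension
  RT90 (hypercontractility with slowed relaxation);
- `R = 1.3` *without* feedback leaves RT90 within ~1% of control —
  availability alone explains hypercontractility but not slowed
  relaxation; with feedback RT90 is prolonged ~20%;
- `TNNI3_R21C` shortens median calcium time-to-peak (~−30%) while
  prolonging calcium RT90; `TNNT2_R92Q` prolongs calcium RT90;
- Mavacamten monotonically suppresses tension amplitude in every genotype;
  a dose ≤ 1 µM jointly returns the `MYH7` amplitude and RT90 medians into
  the control IQR, while no amplitude-safe dose (amplitude ≥ 50% of
  control) does so for `TNNT2`;
- the designed desensitiser at level 0.5 returns both `TNNT2` medians into
  the control IQR;
- SERCA-up 0.5 combined with 0.5 µM Mavacamten returns the `TNNT2` RT90
  median into the control IQR without pushing amplitude above it.

On the single baseline model the combination arm is only a partial rescue:
SERCA upregulation multiplies its share of calcium removal by at most 1.5,
which cancels roughly two thirds of the Ca50-driven RT90 excess.  The
population-level pass reflects both that partial correction and the
population's heterogeneity.  This is a structural bound of the reduced
calcium subsystem and is reported as such.

## 5. Synthetic fixtures, and what passing tests show

All fixtures are generated in code: two-exponential twitches whose
amplitude and peak time have closed forms (exact oracles for the biomarker
extractor), percentile-based calibration ranges derived from simulated
control populations, and Gaussian cohorts with known effect sizes for the
statistics layer.  They emulate the *shape* of twitch and transient data
and the *structure* of population variability — they do not carry
experimental noise spectra, drift, cell-to-cell correlation structure or
measurement artefacts.  Passing tests therefore establish internal
correctness (conservation laws, closed forms, rank structure, recovery,
calibrated error rates) and qualitative agreement with the published
cellular phenotypes; they do not validate the model against new
experimental recordings.

## 6. Numerical choices and degenerate inputs

- Integration tolerances default to `rtol = 1e−6` with state-scaled
  absolute tolerances; tightening both tenfold changes biomarkers by
  < 0.5%.
- Biomarker threshold crossings are linearly interpolated; the peak is
  refined by parabolic interpolation around the maximal sample; for noisy
  plateaus the first sample within 1e−3·amplitude of the peak anchors the
  relaxation search.
- Flat channels (amplitude below 1e−9) report amplitude 0 and NaN time
  metrics; truncated decays (no crossing inside the analysed window, e.g.
  tension nearly suppressed at high inhibitor dose) report NaN with a
  warning rather than a fabricated value, and such models are retained and
  flagged in population tables.
- All randomness (LHS sampling, synthetic noise, cohorts) flows from
  explicit integer seeds; identical seeds give byte-identical tables.

## 7. Known limitations

- No membrane potential: action-potential biomarkers, AP-based population
  calibration and conductance variability axes are out of scope.
- No length or velocity dependence: λ is fixed at 1, crossbridge
  distortion and passive viscoelasticity are omitted, tension is `T_ref·S`.
- The feedback form and the dose–response constants are calibration
  products constrained by directionality, not mechanistic measurements.
- Single-rate pacing only (1 Hz); no restitution or arrhythmia protocols.
- Organ-level endpoints (ejection fraction, PV loops, ECG) require a
  ventricular electromechanics solver and are outside this package.
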