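# Methods

## Scope and modelling philosophy

`mitotoxsim` studies how doxorubicin (DOX) damages cardiac mitochondria
through three pathways — inhibition of the electron transport chain (ETC),
redox cycling at Complex I, and damage to mitochondrial DNA — and how those
pathways separately and jointly produce acute collapse, transient
dysfunction, and chronic, self-sustaining decline.

The bioenergetic core is deliberately a *reduced surrogate*, not a
transcription of a full biophysical mitochondrial model (TCA cycle, explicit
Q-cycle states, ion transporters, matrix pH). All of the package's
conclusions are expressed as normalized, emergent behaviours — collapse
thresholds, ROS dose–response, the mtDNA phase curve — so the surrogate is
calibrated to reproduce those behaviours rather than absolute
concentrations. The core sits behind a narrow interface
(`derivatives`, `solve_steady_state`, `scale_densities`), so a richer model
can be substituted without touching the pathway, mtDNA or experiment layers.

## The bioenergetic core

Six states: membrane potential ΔΨ (mV), reduced NADH fraction, matrix ATP
(mM), and normalized superoxide, peroxide and hydroxyl levels.

Fluxes (time unit: hours):

- electron flux `v_etc = k_etc · G · NADH · g(ΔΨ)`, where
  `G = 3/(1/c₁ + 1/c₃ + 1/c₄)` is the harmonic mean of per-complex
  conductances `c_i = ρ_i a_i` (density × drug activity) and
  `g(ΔΨ) = 1/(1+exp((ΔΨ−ΔΨ_cap)/σ_g))` is thermodynamic back-pressure;
- charge balance `C_m dΔΨ/dt = k_pump v_etc − c_synH v_syn − v_leak` with a
  sigmoidal ATP synthase gate in ΔΨ and an **ohmic** proton leak
  `v_leak = k_leak ΔΨ (1 + λ max(H₂O₂ₙ−1,0)²)`. The quadratic ROS term is
  oxidative uncoupling: mild ROS elevations barely load the membrane, large
  ones dissipate it. The ohmic (rather than exponential) leak is what lets
  the collapsed branch sit near 0 mV, so that "collapse" (ΔΨ < 20% of
  baseline) is a real state rather than an asymptote;
- ATP: `dATP/dt = v_syn − k_cons·ATP`, with ADP = A_tot − ATP conserved by
  construction;
- NADH: regenerated by a lumped substrate-supply term gated sigmoidally by
  ATP (`φ(ATP)` with a small ATP-independent basal fraction), oxidized by
  the chain and by redox cycling. The ATP gate closes the positive feedback
  loop (ΔΨ↓ → ATP↓ → substrate supply↓ → flux↓ → ΔΨ↓) that creates the fold
  bifurcation behind discontinuous collapse.

Superoxide production has two sites plus the drug source, expressed in
units normalized so the three sum to 1 at baseline
(`eps_c1 : eps_c3` sets the baseline share, default 50:50 — the relative
weight is a calibration degree of freedom, not an observable):

- **Complex I**: ∝ density × NADH. An inhibited, backed-up chain (high
  NADH) leaks more; a depleted chain (low density) leaks less.
- **Complex III**: ∝ `v_etc · (a₃^{-p_a} − slack) · D(ρ₃)`, a semiquinone
  occupancy proxy. Drug inhibition of Complex III raises occupancy through
  `a₃^{-p_a}`; density loss raises it through
  `D(ρ) = 1 + b (ρ^{-1} − 1)^q`, a saturating-onset amplification (spare
  Q-cycle capacity near baseline, steep growth once depleted). Separating
  the two responses is essential: the drug response is calibrated against
  the acute ROS crossover, the density response against the mtDNA
  bifurcation, and a single shared form cannot satisfy both.
- **redox cycling**: `η · [DOX] · NADH/NADH₀` — electrons diverted from
  Complex I directly to oxygen.

Peroxide relaxes toward superoxide (dismutation vs clearance), hydroxyl
toward `Fe_n × H₂O₂ₙ` (iron-catalysed Fenton/Haber-Weiss production vs
clearance), each first order.

**Inverse-designed baseline.** Rate constants are constructed so the
drug-free steady state sits exactly at the chosen operating point
(ΔΨ = 150 mV, NADH = 0.4, ATP = 6.5 mM of A_tot = 10 mM, 20% baseline
proton-leak share); `default_core_params()` performs this construction, so
the baseline fixed point is exact to rounding and all normalizations are
well defined. Absolute baseline values are configuration choices — only
normalized behaviour is meaningful.

## Acute drug pathways

- **Pharmacokinetics**: per dose, a two-exponential (first-order absorption,
  half-time 5 min; first-order elimination, half-time 24 h) curve, peak
  normalized so a "30 μM dose" reaches 30 μM at its maximum; doses
  superpose. Peak normalization (rather than area) makes the constant
  concentration of a steady-state sweep and the transient peak of a dynamic
  run commensurate. Body doses convert at 30 μM per mg/kg.
- **ETC inhibition**: per-complex Hill activity scaling, IC50s
  784/941/471/1020 μM (I/II/III/IV), Hill 2.25. These are calibration
  degrees of freedom anchored to the printed collapse thresholds;
  Complex III is given the lowest IC50 (it hosts the semiquinone site).
  Complex II is accepted in configuration but the surrogate's lumped chain
  has no Complex II branch, so its scale has no effect.
- **Redox cycling**: gain η = 0.007276 per μM, calibrated so a constant
  10 μM exposure yields a 7.0% steady superoxide increase.
- **Iron**: quasi-steady `Fe = Fe₀(1 + k_Fe [DOX])` (k_Fe = 0.01/μM);
  dynamic runs relax iron toward that value with a 336-h clearance
  half-time (DOX-mobilized iron clears slowly). Chelation windows clamp
  iron at baseline. With every toxicity pathway switched off the drug has
  no effects at all, iron included, so such runs reproduce the no-drug
  trajectory bit for bit.

## mtDNA damage and repair

`dm/dt = α(1−m)/((1−m)+κ) − β[•OH]ₙ m − γ[DOX] m`, with α = 0.0045/week,
κ = 0.05, γ = 0.00165/(μM·week), baseline content m₀ = 0.75. β is *derived*
from the baseline balance (β = α(1−m₀)/(((1−m₀)+κ)m₀) = 0.005/week), which
makes m₀ an exact fixed point and removes one fitting dimension. The
normalized hydroxyl level entering the damage term is capped (default 10³)
to keep the system integrable through collapse; collapsed bioenergetic
states contribute the cap (their instantaneous ROS is not meaningful).
Content is clamped to [0, 1]; reaching the collapse content marks
bioenergetic failure.

Rates are per week — the natural clock of weekly dosing protocols — and are
converted to per hour inside the integrators.

**Phase plane and bifurcation.** Holding content fixed, the core is relaxed
to steady state and dm/dt evaluated with the resulting hydroxyl level. The
curve is zero at 0.75, positive in a narrow recovery band, and crosses zero
at the bifurcation content m* (bisection to 1e-4; shipped defaults place it
at 0.730). Below the core's collapse content (0.615 at default parameters)
no functioning steady state exists. The drug term is absent from this
analysis, so m* depends only on κ and the core's ROS-vs-content response —
a fact the calibration exploits.

**Attribution.** Over an acute window (dose time until [DOX] < 1% of its
peak, ≈ 160 h), the direct (`γ[DOX]m`) and *excess* oxidative
(`β max([•OH]ₙ−1, 0) m`) damage terms are integrated by trapezoid on the
trajectory grid. Baseline oxidative damage is excluded from the denominator
because it is balanced by repair and causes no net content reduction.

## Integration strategy

Bioenergetics equilibrate in minutes; content moves over weeks. Chronic
protocols therefore run a **hybrid multiscale integrator**: full stiff
(BDF) integration of the eight-quantity system inside each dose's acute
window, and a two-ODE slow system (content, iron) between windows with the
core held at its quasi-steady state, interpolated (monotone cubic) from a
cached content → steady-state map. The brute-force mode (full system
throughout) is retained as the oracle; the two agree to well under 0.5% in
content on multi-dose instances (verified in the test suite). A still
faster quasi-steady-only forward model backs the calibration loops and the
robustness sweep, where thousands of protocol evaluations are needed.

Steady states are found by relaxation from baseline with BDF until the
normalized derivative infinity-norm falls below 1e-8, with a
relative-change fallback; the horizon is generous (24 h of model time,
early-terminated) because near-threshold collapse transients slow down
critically. The tie between "collapsed" and "non-converged" is broken by
the ΔΨ level: collapse is declared iff ΔΨ < 20% of baseline. Collapse
thresholds are bisected to 1 μM.

Outcome labels for chronic runs: *collapsed* if the collapse event fires;
*recovered* if final content is above the bifurcation and drifting toward
baseline (or already within 0.005 of it); *progressing* otherwise. Recovery
through the narrow stable band is slow, so a recovered run is classified by
its direction of travel, not by having completed the return.

## Calibration and synthetic data

The model is calibrated in the staged order its structure dictates:

1. **η** (redox cycling) from the 7%-at-10-μM superoxide anchor (secant on
   the steady state — essentially exact).
2. **IC50 scale and ROS-leak gain** from the per-pathway collapse
   thresholds and the ROS crossover (nested bisections; these are frozen
   into the shipped defaults).
3. **κ** by root-finding the bifurcation anchor (0.73): the unstable-root
   condition divides out α and contains no γ, so the anchor determines κ
   alone. Treating it as a soft penalty instead leaves a flat (α, κ)
   direction in the fit.
4. **(α, γ)** by bounded trust-region least squares (log-space) against
   mtDNA-content observations.

**Synthetic observations.** No real measurements ship with the package.
`generate_observations` runs the model under the chronic fitting protocols
(seven weekly 30 μM doses measured during/after treatment; seven weekly
24 μM doses measured 37 weeks after treatment, with and without chelation)
and records group means of `n_replicates` Gaussian-noised measurements
(per-measurement SD default 0.03, the scale of typical published error
bars; reported SE = SD/√n). This emulates the *structure* of in-vivo
error-bar data — group means at sparse time points — but none of its
biology: no inter-animal variability in parameters, no assay bias, no
dropout. Passing calibration tests therefore demonstrates the pipeline's
statistical correctness on data of this structure, not fidelity to any real
experiment.

**Parameter recovery.** The recovery experiment uses six group means
(weekly-30 protocol at weeks 2/4/6/8 — early points carry γ — and weekly-24
at weeks 38/44, whose post-treatment decline carries α) with 12 replicates
per point at noise 0.02. Under these conditions all four fitted parameters
return within 20% of the generator's truth, and the bias vanishes as the
noise is reduced. With single measurements instead of group means, α is not
identifiable to that precision: its information sits almost entirely in a
direction collinear with γ.

**Robustness sweep.** A log-space Latin hypercube over
(α, κ, γ, η, k_Fe) — 500 samples by default, a desk-scale stand-in for an
exhaustive scan — runs the fitting protocols with the fast forward model,
accepts samples whose predictions stay within ±2 SE of every observation
(the documented acceptance definition), and records each sample's
single-dose direct-damage fraction. The test suite asserts the sweep's
mechanics (determinism, degenerate bounds, the γ = 0 negative control);
the accepted-region attribution summary is reported by the
`param-sweep` CLI/example.

## Known limitations

- Post-collapse ROS falls in the surrogate (electron flux and NADH are
  depleted), whereas the full-model picture is a sharp ROS spike at
  collapse; pre-collapse ROS growth is reproduced, the collapsed state's
  ROS level is not meaningful here.
- The core's no-drug collapse content (0.615) is likely higher than a full
  model's; function below content ~0.6 is outside this surrogate's
  competence.
- Extended chelation (2–3× treatment duration) adds only marginal
  protection beyond chelation during treatment: clamping iron while dosing
  already prevents accumulation, and the drug is eliminated within days of
  the last dose. A model in which iron, or ongoing oxidative injury,
  persisted longer after treatment would show a larger benefit of extended
  windows.
- Matrix pH is not a state; its effect on Complex IV (and hence the
  reported oxygen-consumption increase under acute drug) is absorbed into
  the ΔΨ dependence of the electron flux. Oxygen consumption rises only
  modestly in the redox-cycling arm here.
- No calcium handling, permeability transition, apoptosis, transcription /
  translation delay between content and protein density, or mtDNA
  copy-number stochasticity.
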