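# mitotoxsim

Simulator of doxorubicin (DOX) mitochondrial cardiotoxicity: a reduced
mitochondrial bioenergetics model coupled to the drug's three toxicity
pathways — electron-transport-chain (ETC) inhibition, redox cycling, and
mtDNA damage — with the experiment pipelines needed to study acute
dose–response, transient recovery, chronic weekly dosing, and iron-chelator
co-treatment.

It is written for systems-biology and quantitative-pharmacology work: the
public surface is an importable Python API (`examples/` walks through each
capability) plus a thin `mitotoxsim` command line for running the standard
experiments from a shell.

## The model

**Bioenergetic core.** A six-state ODE surrogate of state-3 respiration:
membrane potential ΔΨ (mV), reduced NADH fraction, matrix ATP (mM, with
ADP = A_tot − ATP), and the ROS chain O₂·⁻ → H₂O₂ → •OH, each ROS species
normalized to the drug-free baseline (= 1). Electron flux through a lumped
Complex I/III/IV chain pumps charge; ATP synthesis and an ohmic proton leak
dissipate it; hydrogen peroxide above baseline uncouples the membrane
(quadratic leak gain), and hydroxyl radicals form from peroxide by
iron-catalysed Fenton chemistry. Densities of the mtDNA-encoded complexes
(I, III, IV, ATP synthase) scale linearly with mtDNA content (baseline
content 0.75 ⇒ scale 1).

**Acute drug pathways.** Mitochondrial DOX concentration follows
one-compartment pharmacokinetics (absorption half-time 5 min, elimination
half-time 24 h, peak normalized to the nominal dose in μM; 1 mg/kg body dose
≡ 30 μM). Each ETC complex is inhibited by a Hill curve
`a_c = 1/(1 + ([DOX]/IC50_c)^h_c)`; redox cycling adds a superoxide source at
Complex I proportional to `[DOX]` and gated by NADH; free iron rises with the
drug (`Fe = Fe₀(1 + k_Fe·[DOX])` at quasi-steady state) unless clamped at
baseline by a chelation window.

**mtDNA damage and repair.** Content `m` obeys a mass-action balance

```
dm/dt = α (1−m)/((1−m)+κ)  −  β [•OH]ₙ m  −  γ [DOX] m
```

with saturating enzymatic repair (maximum rate α, half-saturation κ),
oxidative damage by the normalized hydroxyl level, and direct drug damage.
β is derived from the baseline balance (repair = damage at m = 0.75 with
[•OH]ₙ = 1), so the baseline is a fixed point by construction. The coupled
system is bistable: below a bifurcation content m* ≈ 0.73, rising Complex III
superoxide outpaces repair and decline is self-sustaining (the
ROS → mtDNA damage → protein loss → ROS vicious cycle).

Shipped defaults are calibrated so the emergent behaviour reproduces the
anchor values the model is built around: collapse of function at 270 μM
(ETC inhibition alone), 480 μM (redox cycling alone) and ~210 μM (combined);
ETC-driven ROS overtaking redox-cycling ROS at 160 μM; a 7% superoxide rise
at a constant 10 μM; and the bifurcation at content 0.73.

## Worked example

```python
from mitotoxsim import DoxToxicityModel, chronic_protocol

model = DoxToxicityModel()          # shipped calibrated parameters
for n in (1, 4, 7, 10):
    res = chronic_protocol(model, n_doses=n, dose_um=30.0)
    print(n, res.outcome, round(res.raw["m"][-1], 4))
```

prints

```
1 recovered 0.7436
4 progressing 0.7058
7 collapsed 0.615
10 collapsed 0.615
```

One weekly 30 μM dose leaves mtDNA content (0.7436) above the bifurcation
(0.73) and the mitochondria recover; four doses push it below, triggering a
slow self-sustaining decline; with seven or ten the decline reaches
bioenergetic collapse (membrane potential < 20% of baseline — content is
reported at the collapse event, here the collapse content 0.615) within the
40-week horizon, at weeks 34 and 21 respectively. `examples/` contains six
narrative scripts covering the acute dose sweep, single-dose transients, the
phase plane, chronic dosing, chelation, and calibration/robustness; the same
pipelines are exposed as CLI subcommands
(`mitotoxsim sweep|dynamic|chronic|chelation|phase|calibrate|recover|param-sweep`).

## Layout

- `src/mitotoxsim/core.py` — reduced bioenergetics ODE core
- `src/mitotoxsim/pathways.py` — pharmacokinetics, ETC inhibition, redox cycling, iron/chelation
- `src/mitotoxsim/mtdna.py` — mtDNA damage/repair, phase plane, attribution
- `src/mitotoxsim/simulate.py` — full-system and hybrid multiscale integrators
- `src/mitotoxsim/experiments.py` — sweep / dynamic / chronic / chelation pipelines
- `src/mitotoxsim/calibration.py` — synthetic observations, anchor calibration, robustness sweep
- `src/mitotoxsim/config.py`, `cli.py` — validated YAML/JSON configuration, CSV/JSON output, CLI
- `docs/methods.md` — model description, assumptions, numerical choices, limitations
- `docs/UNITS.md` — unit conventions used in all files the package reads/writes
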