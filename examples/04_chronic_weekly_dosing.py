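"""Chronic weekly dosing ladder: cumulative, irreversible toxicity.

Weekly 30 uM doses (the model equivalent of 1 mg/kg in rats) are simulated
with the hybrid multiscale integrator over a 40-week horizon.  Outcomes
change qualitatively with dose count: one dose recovers, four trigger a slow
self-sustaining decline, ten collapse bioenergetics within the horizon.
"""

from mitotoxsim import DoxToxicityModel, chronic_protocol, mg_per_kg_to_um

model = DoxToxicityModel()
print("weekly dose of 1 mg/kg ->", mg_per_kg_to_um(1.0), "uM in the model\n")
print(f"{'doses':>6} {'outcome':>12} {'final content':>14} {'collapse wk':>12}")
for n in (1, 4, 7, 10):
    res = chronic_protocol(model, n, 30.0)
    wk = "" if res.collapse_time_h is None else f"{res.collapse_time_h / 168:.1f}"
    print(f"{n:>6} {res.outcome:>12} {res.raw['m'][-1]:14.4f} {wk:>12}")

print(f"\nbifurcation content: {model.bifurcation_content:.4f} "
      f"(baseline 0.75)")
print("""
Each dose knocks ~0.01 off the mtDNA content during its acute window.  One
dose leaves content inside the recovery band; four push it past the
bifurcation into slow progression; with ten the decline accelerates to
bioenergetic collapse (membrane potential below 20% of baseline) well inside
the simulated horizon.""")
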