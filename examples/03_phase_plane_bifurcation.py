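"""mtDNA phase plane: the bifurcation behind chronic toxicity.

Holding mtDNA content fixed at each grid value, the bioenergetics relax to
steady state; the resulting hydroxyl level sets the content's drift dm/dt.
The drift is zero at baseline (0.75), positive in a narrow recovery band
below it, and turns negative below the bifurcation content — the point of no
return where the ROS -> mtDNA damage -> protein loss -> ROS vicious cycle
becomes self-sustaining.
"""

from mitotoxsim import DoxToxicityModel, find_bifurcation, phase_curve

model = DoxToxicityModel()
print(f"{'content':>8} {'dm/dt per week':>15} {'superoxide':>11}")
for p in phase_curve([0.78, 0.75, 0.74, 0.73, 0.71, 0.68, 0.65],
                     model.core, model.mtdna):
    print(f"{p.m:8.3f} {p.dmdt_per_week:+15.2e} {p.indices['superoxide']:11.3f}")

m_star = find_bifurcation(model.core, model.mtdna)
print(f"\nbifurcation content (bisection to 1e-4): {m_star:.4f}")
print("""
A content reduction of only ~3% from baseline (0.75 -> 0.73) is enough to
flip the sign of dm/dt: above 0.73 repair wins and content creeps back,
below it rising Complex III superoxide outpaces repair and decline is
perpetual.""")
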