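"""Iron chelation co-treatment: partial cardioprotection.

Seven weekly 24 uM doses (0.8 mg/kg equivalent) with the free-iron level
clamped at baseline during a chelation window, measured 37 weeks after the
end of treatment.  Chelation removes the iron-catalysed (Fenton) share of
hydroxyl production — but not the peroxide rise itself, so protection is
partial.
"""

from mitotoxsim import DoxToxicityModel
from mitotoxsim.experiments import chelation_experiment

model = DoxToxicityModel()
print(f"{'chelation':>10} {'outcome':>12} {'content at +37 wk':>18}")
finals = {}
for mode in ("none", "during", "2x", "3x"):
    res = chelation_experiment(model, n_doses=7, dose_um=24.0,
                               chelation_mode=mode, follow_up_weeks=37.0)
    finals[mode] = res.raw["m"][-1]
    print(f"{mode:>10} {res.outcome:>12} {finals[mode]:18.4f}")

gain = finals["during"] - finals["none"]
print(f"\nchelation during treatment preserves {gain:+.4f} content vs none")
print("""
The untreated arm loses the most mtDNA.  Clamping iron during the dosing
period blunts oxidative damage at each dose; extending the window (2x/3x the
treatment duration) adds little more here because the drug — and with it the
iron rise — is essentially gone within days of the last dose.""")
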