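# Unit conventions

All files this package reads and writes, and all public APIs, use:

| quantity | unit |
|---|---|
| time | hours (`time_h`); dosing spacings given in hours (1 week = 168 h) |
| drug concentration | μM (mitochondrial); body doses convertible via `mg_per_kg_to_um` (1 mg/kg ≡ 30 μM) |
| membrane potential ΔΨ | mV |
| ATP | mM (ADP = `a_tot` − ATP) |
| NADH | reduced fraction, 0–1, unitless |
| ROS species (O₂·⁻, H₂O₂, •OH) | normalized to the drug-free baseline = 1 |
| mtDNA content | unitless, in [0, 1]; baseline 0.75 |
| free iron | normalized to baseline `fe0` = 1 |
| mtDNA rate coefficients α, β, γ | per week (γ per μM per week); converted to per hour internally |
| oxygen consumption | normalized to baseline = 1 in reports (electron-flux units internally) |

CSV time series columns: `time_h`, raw state/flux columns, then
baseline-normalized copies prefixed `norm_`.
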