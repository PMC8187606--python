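"""Thermal melt: fit a van't Hoff two-state model to simulated CD melts
and recover the melting temperature.

Truth: Tm = 43.3 degC (316.45 K) with a 70 kcal/mol van't Hoff enthalpy,
scanned 20-90 degC in 1-degree steps, triplicate, 2% amplitude noise.
"""

from lemfold import (
    SyntheticConfig,
    ThermalParams,
    aggregate_replicates,
    fit_thermal,
    simulate_curves,
)

truth = ThermalParams(Tm=316.45, dH_vH=70.0, a1=1.0, b1=-0.001, c1=0.05, p1=0.0005)
cfg = SyntheticConfig(model="thermal", truth=truth, noise_sd=0.02, n_replicates=3, seed=42)

results = [fit_thermal(curve) for curve in simulate_curves(cfg)]
summary = aggregate_replicates(results)

print("truth:      Tm = 43.3 degC, dH_vH = 70 kcal/mol")
print(
    "recovered:  Tm = {:.1f} ± {:.1f} degC, dH_vH = {:.1f} ± {:.1f} kcal/mol".format(
        summary.mean["Tm_C"], summary.sem["Tm_C"],
        summary.mean["dH_vH"], summary.sem["dH_vH"],
    )
)
print()
print("Tm is the temperature with equal folded/unfolded populations; dH_vH")
print("(the van't Hoff enthalpy) sets how sharp the melt is. Heat-capacity")
print("change is neglected - it is not identifiable from a single melt.")
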