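"""Fit enzyme kinetics and compute fermentation yield arithmetic.

Generates noise-free Michaelis-Menten data with the published EbF7GAT
parameters for both substrates, refits them, and reproduces the study's
yield bookkeeping (fold improvement, titer sum, secretion split).
"""

import numpy as np

from clademiner.kinetics import fit_michaelis_menten, round_half_up, yield_metrics
from clademiner.simulate import simulate_kinetics

for name, km, kcat, lo, hi in [
    ("apigenin", 9.24, 0.57, 0.1, 20.0),
    ("scutellarein", 70.15, 0.24, 5.0, 300.0),
]:
    data = simulate_kinetics(
        km=km, kcat=kcat, enzyme_conc=0.01,
        concs=np.geomspace(lo, hi, 12), noise_sd=0.0,
    )
    fit = fit_michaelis_menten(data)
    print(
        f"{name:>12}: Km = {fit.km:.2f} uM (true {km}), "
        f"kcat = {fit.kcat:.2f} 1/s (true {kcat}), R^2 = {fit.r2:.6f}"
    )

summary = yield_metrics(
    {"scutellarin": 108.0, "apigenin-7-O-glucuronide": 185.0},
    specific_yield=15.5,
    baseline_specific_yield=9.2,
    extracellular_fraction=73.4,
)
print(f"fold improvement over starting strain: {summary.fold_change}")
print(
    f"total titer: {summary.total_titer:.0f} mg/L "
    f"(~{round_half_up(summary.total_titer, -2):.0f} at nearest hundred)"
)
print(
    f"secretion split: {summary.fraction_extracellular}% extracellular, "
    f"{summary.fraction_intracellular:.1f}% intracellular"
)
# Noise-free refits recover the generating parameters to < 0.1%, so any
# deviation on real data reflects the data, not the optimizer.
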