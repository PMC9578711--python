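"""Extracellular-flux summary rates from a synthetic ECAR/OCR run.

Builds a noiseless five-phase series (basal, then oligomycin, FCCP,
Rot+AA and 2-DG injections) and prints the summary rates. With these
phase means: basal glycolysis = 20 - 5 = 15, max glycolysis = 35,
basal respiration = 50 - 10 = 40, max respiration = 90.
"""

import numpy as np

import macroflim as mf
from macroflim.synthetic_data import generate_flux_timeseries

phase_means = np.array([  # (ECAR, OCR) per phase
    [20.0, 50.0],   # basal
    [35.0, 20.0],   # after oligomycin
    [30.0, 90.0],   # after FCCP
    [28.0, 10.0],   # after Rot+AA
    [5.0, 10.0],    # after 2-DG
])
(series,) = generate_flux_timeseries(phase_means, (20, 40, 60, 80),
                                     noise_sd=0.0, seed=0)
rates = mf.compute_flux_rates(series)
print(f"basal glycolysis:  {rates.basal_glycolysis:.1f}")
print(f"max glycolysis:    {rates.max_glycolysis:.1f}")
print(f"basal respiration: {rates.basal_respiration:.1f}")
print(f"max respiration:   {rates.max_respiration:.1f}")
print(f"basal-phase ECAR AUC: {rates.ecar_auc['basal']:.1f} (units x min)")
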