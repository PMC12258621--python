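"""Non-specific binding from baseline twist shifts: the Langmuir fit.

Prolonged, concentration-dependent shifts of the closed-state twist
baseline report non-specific RNP binding.  This example simulates mean
shifts for 5 tethers per concentration (0.3-bp measurement noise) from
a Langmuir isotherm and fits back the effective dissociation constant
and saturating amplitude.
"""

import numpy as np

import rloopkinetics as rk

df = rk.simulate.simulate_bulk_dataset(
    "binding",
    {"delta_theta_sat": 3.7, "kd": 14.0,
     "concentrations": [2, 5, 10, 25, 50, 100], "n_tethers": 5},
    noise=0.3,
    seed=30,
)
g = df.groupby("conc_nM")["delta_theta0_bp"]
print(g.mean().rename("mean_shift_bp").to_string(float_format="%.2f"))

points = [(c, m, 0.3 / np.sqrt(5)) for c, m in g.mean().items()]
params, ses = rk.langmuir_fit(points)
print(
    f"\nLangmuir fit: KD = {params['kd']:.1f} +- {ses['kd']:.1f} nM "
    f"(generative 14), saturation = {params['delta_theta_sat']:.2f} "
    f"+- {ses['delta_theta_sat']:.2f} bp (generative 3.7)"
)
print(
    "A ~nM effective KD with only partial unwinding at saturation is "
    "the signature of tight but unproductive non-specific binding."
)
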