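"""Concentration dependence of R-loop initiation: the two-step capture fit.

Simulates twist traces across seven RNP concentrations with a
saturating (hyperbolic) C->I rate law, estimates k_CI per trace from
counted transitions, and fits both capture models.  The hyperbolic
parameters are the unwinding rate out of the initial bound complex
(kopen) and its dissociation constant (Kd_init).
"""

import numpy as np

import rloopkinetics as rk
from rloopkinetics.pipeline import concentration_series_rates

cfg = rk.simulate.dspry_config(duration=1200.0, seed=20)  # 20 min per point
traces = rk.simulate.simulate_concentration_series(
    cfg, [1, 2, 5, 10, 20, 50, 100], np.random.default_rng(20)
)

baseline_cfg = rk.simulate.dspry_config(
    rate_kCI_law=rk.FixedLaw(0.0), duration=120.0, seed=21
)
_, baseline = rk.simulate.simulate_experiment(baseline_cfg)
ou = rk.calibrate_ou(baseline)

table = concentration_series_rates(traces, ou)
print(table.to_string(index=False, float_format="%.4f"))

fit = rk.fit_capture_model(
    table[["conc_nM", "k_ci_per_s", "se_per_s"]],
    model="hyperbolic",
    occupancy=table["occupancy_s"],
)
model = rk.two_step_interpret(fit, assumed_kon_init=0.1)
print(
    f"\nhyperbolic fit: kopen = {fit.params['kopen']:.3f}/s "
    f"(generative 0.06), Kd_init = {fit.params['kd_init']:.1f} nM "
    f"(generative 10)"
)
print(
    f"two-step reading: koff_init = {model.koff_init:.2f}/s at assumed "
    f"kon_init = {model.kon_init}/nM/s; low-concentration slope "
    f"kon_eff = {model.kon_eff:.4f}/nM/s"
)
print(
    "A plateau in k_CI vs [RNP] means capture is limited by unwinding "
    "out of a saturably-bound initial complex, not by arrival."
)
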