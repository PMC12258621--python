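"""Rate estimation and concentration-dependence fits: occupancy
counting, linear vs hyperbolic capture models, Langmuir isotherms and
the two-step interpretation."""

import numpy as np
import pytest

import rloopkinetics as rk
from rloopkinetics.kinetics import (
    estimate_rates,
    fit_capture_model,
    langmuir_fit,
    two_step_interpret,
)
from rloopkinetics.states import State, StateSequence

from conftest import states_from_path


def sequence_from_labels(labels, dwells):
    t = 0.0
    seq = StateSequence()
    levels = {"C": 0.0, "I": 10.0, "O": 20.0, "overwound": -2.0}
    for lab, d in zip(labels, dwells):
        seq.append(State(lab, levels[lab], float(d), t, t + d))
        t += d
    return seq


class TestEstimateRates:
    def test_rate_and_poisson_se_definition(self):
        # 30 C->I transitions over 1000 s of C occupancy after the first
        # transition -> k = 0.03 /s, SE = sqrt(30)/1000
        labels, dwells = ["I"], [1.0]  # first state is excluded from counting
        for _ in range(30):
            labels += ["C", "I"]
            dwells += [1000.0 / 30.0, 1.0]
        seq = sequence_from_labels(labels, dwells)
        rs = estimate_rates(seq)
        assert rs.counts[("C", "I")] == 30
        assert rs.occupancy["C"] == pytest.approx(1000.0)
        assert rs.rate("C", "I") == pytest.approx(0.03)
        assert rs.se("C", "I") == pytest.approx(np.sqrt(30) / 1000.0)

    def test_sequence_without_open_visits(self):
        seq = sequence_from_labels(["C", "I", "C", "I", "C"], [5, 1, 5, 1, 5])
        rs = estimate_rates(seq)
        assert ("I", "O") not in rs.counts
        assert "O" not in rs.occupancy
        assert rs.rate("C", "I") > 0
        with pytest.raises(ValueError, match="occupancy"):
            rs.rate("O", "I")

    def test_unobserved_transition_reports_one_sided_se(self):
        seq = sequence_from_labels(["C", "I", "C", "I", "C"], [5, 1, 5, 1, 5])
        rs = estimate_rates(seq)
        assert rs.rate("C", "I") > 0
        assert rs.rate("I", "C") > 0
        # no I->O events: rate 0 with one-sided SE 1/T_I
        assert rs.rate("I", "O") == 0.0
        assert rs.se("I", "O") == pytest.approx(1.0 / rs.occupancy["I"])

    def test_matches_brute_force_counter_on_random_sequences(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            labels = ["C"]
            for _ in range(n - 1):
                labels.append(
                    rng.choice([s for s in "CIO" if s != labels[-1]])
                )
            dwells = rng.uniform(0.1, 5.0, n)
            seq = sequence_from_labels(labels, dwells)
            rs = estimate_rates(seq)
            # independent naive counter, skipping the pre-transition state
            for i in "CIO":
                for j in "CIO":
                    if i == j:
                        continue
                    n_ij = sum(
                        1
                        for a, b in zip(labels[1:], labels[2:])
                        if a == i and b == j
                    )
                    t_i = sum(d for l, d in zip(labels[1:], dwells[1:]) if l == i)
                    if t_i > 0:
                        assert rs.rate(i, j) == pytest.approx(n_ij / t_i)

    def test_too_few_transitions_rejected(self):
        with pytest.raises(ValueError, match="transitions"):
            estimate_rates(sequence_from_labels(["C", "I"], [1.0, 1.0]))

    def test_overwound_states_excluded_from_kinetics(self):
        seq = sequence_from_labels(
            ["C", "overwound", "C", "I", "C", "I", "C"], [5, 2, 5, 1, 5, 1, 5]
        )
        rs = estimate_rates(seq)
        assert all("overwound" not in pair for pair in rs.counts)

    def test_rates_scale_inversely_with_time_units(self):
        labels = ["C", "I", "C", "I", "C", "I", "C"]
        dwells = [4.0, 1.0, 5.0, 1.5, 6.0, 0.5, 3.0]
        r1 = estimate_rates(sequence_from_labels(labels, dwells))
        r2 = estimate_rates(sequence_from_labels(labels, [d * 60 for d in dwells]))
        assert r2.rate("C", "I") == pytest.approx(r1.rate("C", "I") / 60)

    def test_simulated_path_rates_within_three_se(self, ou_baseline):
        cfg = rk.simulate.dspry_config(
            rate_kCI_law=rk.FixedLaw(0.05),
            rate_kIC=0.3,
            rate_kIO=0.2,
            rate_kOI=0.15,
            duration=3600.0,
            seed=903,
        )
        path = rk.simulate_state_path(cfg)
        rs = estimate_rates(states_from_path(path))
        truth = {
            ("C", "I"): 0.05, ("I", "C"): 0.3, ("I", "O"): 0.2, ("O", "I"): 0.15,
        }
        for (i, j), k_true in truth.items():
            assert abs(rs.rate(i, j) - k_true) < 3 * rs.se(i, j)


class TestCaptureModelFit:
    CONC = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0])

    def test_noiseless_linear_recovered_exactly(self):
        pts = [(c, 0.15 * c, 0.01) for c in self.CONC]
        fit = fit_capture_model(pts, model="auto")
        assert fit.model == "linear"
        assert fit.params["kon_eff"] == pytest.approx(0.15)

    def test_noiseless_hyperbolic_recovered_exactly(self):
        pts = [(c, 0.06 * c / (10 + c), 0.001) for c in self.CONC]
        fit = fit_capture_model(pts, model="auto")
        assert fit.model == "hyperbolic"
        assert fit.params["kopen"] == pytest.approx(0.06, rel=1e-6)
        assert fit.params["kd_init"] == pytest.approx(10.0, rel=1e-6)
        assert fit.low_conc_slope == pytest.approx(0.006, rel=1e-6)

    def test_noisy_recovery_within_two_se_and_matches_grid_oracle(self):
        rng = np.random.default_rng(11)
        k_true = 0.06 * self.CONC / (10 + self.CONC)
        se = 0.05 * k_true
        k_obs = k_true + se * rng.standard_normal(self.CONC.size)
        pts = list(zip(self.CONC, k_obs, se))
        fit = fit_capture_model(pts, model="hyperbolic")
        assert abs(fit.params["kopen"] - 0.06) < 2 * fit.ses["kopen"]
        assert abs(fit.params["kd_init"] - 10.0) < 2 * fit.ses["kd_init"]
        # dense grid-search oracle over (kopen, Kd)
        grid_ko = np.linspace(0.03, 0.12, 181)
        grid_kd = np.linspace(3, 30, 271)
        ko_g, kd_g = np.meshgrid(grid_ko, grid_kd, indexing="ij")
        pred = ko_g[..., None] * self.CONC / (kd_g[..., None] + self.CONC)
        chi2 = np.sum(((k_obs - pred) / se) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(chi2), chi2.shape)
        assert fit.params["kopen"] == pytest.approx(grid_ko[i], abs=0.001)
        assert fit.params["kd_init"] == pytest.approx(grid_kd[j], abs=0.2)
        assert fit.chi2 <= chi2[i, j] + 1e-9

    def test_unsaturated_hyperbolic_flags_lower_bound(self):
        conc = np.array([1.0, 2.0, 5.0, 10.0])
        pts = [(c, 0.001 * c, 1e-5) for c in conc]  # linear within range
        fit = fit_capture_model(pts, model="hyperbolic")
        assert any("saturation" in f for f in fit.flags)

    def test_linear_limit_consistency(self):
        # hyperbolic fit of linear-law data at conc << Kd returns the slope
        conc = np.array([0.1, 0.2, 0.5, 1.0])
        pts = [(c, 0.02 * c, 2e-5 * max(c, 0.1)) for c in conc]
        fit = fit_capture_model(pts, model="hyperbolic")
        assert fit.low_conc_slope == pytest.approx(0.02, rel=0.02)

    def test_auto_prefers_linear_on_linear_data(self):
        rng = np.random.default_rng(12)
        pts = [
            (c, 0.15 * c * (1 + 0.03 * rng.standard_normal()), 0.15 * c * 0.03)
            for c in self.CONC
        ]
        assert fit_capture_model(pts, model="auto").model == "linear"

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_capture_model([(1, 0.1, 0.01), (1, 0.2, 0.01)])


class TestTwoStepInterpretation:
    def test_printed_parameter_composition(self):
        fit = fit_capture_model(
            [(c, 0.06 * c / (10 + c), 0.001) for c in (1, 2, 5, 10, 20, 50, 100)],
            model="hyperbolic",
        )
        model = two_step_interpret(fit, assumed_kon_init=0.1)
        assert model.koff_init == pytest.approx(1.0, rel=1e-6)
        assert model.kon_eff == pytest.approx(0.006, rel=1e-6)

    def test_linear_fit_rejected(self):
        fit = fit_capture_model([(c, 0.1 * c, 0.01) for c in (1, 5, 10)],
                                model="linear")
        with pytest.raises(ValueError, match="hyperbolic"):
            two_step_interpret(fit)

    def test_interpretation_reproduces_fitted_curve(self):
        fit = fit_capture_model(
            [(c, 0.06 * c / (10 + c), 0.001) for c in (1, 5, 10, 50, 100)],
            model="hyperbolic",
        )
        model = two_step_interpret(fit)
        conc = np.array([0.5, 3.0, 30.0, 300.0])
        np.testing.assert_allclose(model.k_ci(conc), fit.predict(conc), rtol=1e-12)


class TestLangmuirFit:
    CONC = np.array([2.0, 5.0, 10.0, 25.0, 50.0, 100.0])

    def test_noiseless_isotherm_recovered_exactly(self):
        pts = [(c, 3.7 * c / (14 + c), 0.05) for c in self.CONC]
        params, ses = langmuir_fit(pts)
        assert params["delta_theta_sat"] == pytest.approx(3.7, rel=1e-6)
        assert params["kd"] == pytest.approx(14.0, rel=1e-6)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            langmuir_fit([(10.0, 1.0, 0.1)])

    def test_flat_shifts_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            langmuir_fit([(c, 0.0, 0.1) for c in self.CONC])

    def test_noisy_recovery_within_two_se_vs_grid_oracle(self):
        rng = np.random.default_rng(13)
        se = 0.3 / np.sqrt(5)
        y = 3.7 * self.CONC / (14 + self.CONC) + se * rng.standard_normal(6)
        pts = list(zip(self.CONC, y, np.full(6, se)))
        params, ses = langmuir_fit(pts)
        assert abs(params["kd"] - 14) < 2 * ses["kd"]
        assert abs(params["delta_theta_sat"] - 3.7) < 2 * ses["delta_theta_sat"]
        grid_sat = np.linspace(2.5, 5.0, 126)
        grid_kd = np.linspace(5, 30, 251)
        sat_g, kd_g = np.meshgrid(grid_sat, grid_kd, indexing="ij")
        pred = sat_g[..., None] * self.CONC / (kd_g[..., None] + self.CONC)
        chi2 = np.sum(((y - pred) / se) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(chi2), chi2.shape)
        assert params["delta_theta_sat"] == pytest.approx(grid_sat[i], abs=0.02)
        assert params["kd"] == pytest.approx(grid_kd[j], abs=0.2)
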