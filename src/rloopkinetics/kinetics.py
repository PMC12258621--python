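"""Transition-rate estimation and capture-model fitting.

Rates follow the occupancy estimator k_ij = N_ij / T_i (number of i->j
transitions over total time in state i), with Poisson standard errors
sqrt(N_ij) / T_i.  Counting starts after the first transition event so
the initial waiting time (which begins before the enzyme is present at
the target) does not bias the rates.

The concentration dependence of the closed-to-intermediate rate k_CI
distinguishes two capture mechanisms:

* linear law, k_CI = kon_eff [RNP] — bimolecular capture far from
  saturation (dCas9-like);
* hyperbolic law, k_CI = kopen [RNP] / (Kd_init + [RNP]) — two-step
  capture, Cfree <-> Cbound <-> I, under rapid equilibrium of the
  initial binding step with dissociation constant Kd_init, followed by
  unwinding at kopen (dSpRY-like).

Baseline twist shifts vs concentration are fit by the Langmuir isotherm
delta_theta0([RNP]) = DTsat [RNP] / (KD + [RNP]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .states import StateSequence

_KINETIC_LABELS = ("C", "I", "O")


@dataclass
class RateSet:
    """Transition counts, occupancies and rate constants over C/I/O."""

    counts: dict  # (i, j) -> int
    occupancy: dict  # i -> s
    metadata: dict = field(default_factory=dict)

    def rate(self, i: str, j: str) -> float:
        t = self.occupancy.get(i, 0.0)
        if t <= 0:
            raise ValueError(f"no occupancy recorded for state {i}")
        return self.counts.get((i, j), 0) / t

    def se(self, i: str, j: str) -> float:
        """Poisson SE; one-sided 1/T_i when no transitions were seen."""
        t = self.occupancy[i]
        n = self.counts.get((i, j), 0)
        return (np.sqrt(n) if n else 1.0) / t

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in _KINETIC_LABELS:
            if self.occupancy.get(i, 0.0) <= 0:
                continue
            for j in _KINETIC_LABELS:
                if i == j:
                    continue
                rows.append(
                    (i, j, self.counts.get((i, j), 0), self.occupancy[i],
                     self.rate(i, j), self.se(i, j))
                )
        return pd.DataFrame(
            rows, columns=["from", "to", "n", "occupancy_s", "rate_per_s", "se_per_s"]
        )


def estimate_rates(seq: StateSequence) -> RateSet:
    """Occupancy rate estimator over a merged C/I/O state sequence.

    The sequence's first state (entered before the first transition) is
    excluded from occupancy; every transition thereafter is counted.
    Labels outside C/I/O (e.g. overwound) are excluded from both counts
    and occupancy.
    """
    kin = [s for s in seq if s.label in _KINETIC_LABELS]
    if len(kin) < 3:
        raise ValueError("need at least 2 transitions to estimate rates")
    counts: dict = {}
    occupancy: dict = {}
    for prev, cur in zip(kin[1:], kin[2:]):
        counts[(prev.label, cur.label)] = counts.get((prev.label, cur.label), 0) + 1
    for s in kin[1:]:
        occupancy[s.label] = occupancy.get(s.label, 0.0) + s.dwell
    return RateSet(counts=counts, occupancy=occupancy)


# ---------------------------------------------------------------------------
# concentration-series models


def _linear(c, kon_eff):
    return kon_eff * c


def _hyperbolic(c, kopen, kd_init):
    return kopen * c / (kd_init + c)


@dataclass
class CaptureModelFit:
    """Fitted concentration dependence of k_CI."""

    model: str  # "linear" or "hyperbolic"
    params: dict  # kon_eff | (kopen, kd_init)
    ses: dict
    cov: np.ndarray
    chi2: float
    ndata: int
    flags: list = field(default_factory=list)

    @property
    def low_conc_slope(self) -> float:
        """Effective bimolecular on-rate, per-nM per-s."""
        if self.model == "linear":
            return self.params["kon_eff"]
        return self.params["kopen"] / self.params["kd_init"]

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        if self.model == "linear":
            return _linear(c, self.params["kon_eff"])
        return _hyperbolic(c, self.params["kopen"], self.params["kd_init"])


def _wls_fit(f, conc, k, se, p0, bounds):
    popt, pcov = optimize.curve_fit(
        f, conc, k, p0=p0, sigma=se, absolute_sigma=True, bounds=bounds,
        maxfev=20000,
    )
    resid = (k - f(conc, *popt)) / se
    return popt, pcov, float(np.sum(resid**2))


def fit_capture_model(points, model: str = "auto", occupancy=None) -> CaptureModelFit:
    """Weighted least-squares fit of k_CI vs [RNP].

    ``points`` is an iterable of (conc_nM, k_ci, se) triples or a
    DataFrame with those columns.  ``model`` is "linear", "hyperbolic"
    or "auto"; auto starts from the linear model and keeps the
    hyperbolic one only if an extra-sum-of-squares F-test prefers it at
    alpha = 0.05.

    When the rates are occupancy estimates N_i / T_i, weighting by the
    observed Poisson errors sqrt(N)/T over-weights points whose count
    happened to come out low, biasing saturation fits.  Passing the
    per-point occupancy times ``occupancy`` (seconds in the source
    state) switches to iteratively reweighted least squares with
    model-expected counts, se_i = sqrt(k_model(c_i) / T_i), which is
    asymptotically the Poisson maximum-likelihood fit.
    """
    if isinstance(points, pd.DataFrame):
        arr = points.iloc[:, :3].to_numpy(dtype=float)
    else:
        arr = np.asarray([tuple(p) for p in points], dtype=float)
    conc, k, se = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.unique(conc).size != conc.size:
        raise ValueError("concentrations must be distinct")
    se = np.where(se > 0, se, np.max(se[se > 0]) if np.any(se > 0) else 1.0)
    n = conc.size
    occ = None if occupancy is None else np.asarray(occupancy, dtype=float)

    def reweighted(f, p0, bounds):
        """IRLS with model-expected Poisson errors (needs occupancy)."""
        popt, pcov, chi2 = _wls_fit(f, conc, k, se, p0, bounds)
        if occ is None:
            return popt, pcov, chi2
        for _ in range(4):
            se_m = np.sqrt(np.maximum(f(conc, *popt), 1e-12) / occ)
            popt, pcov, chi2 = _wls_fit(f, conc, k, se_m, popt, bounds)
        return popt, pcov, chi2

    def fit_linear():
        if n < 2:
            raise ValueError("need >= 2 points for the linear model")
        popt, pcov, chi2 = reweighted(
            _linear, [max(k.max(), 1e-6) / max(conc.max(), 1.0)], (0, np.inf)
        )
        return CaptureModelFit(
            "linear", {"kon_eff": float(popt[0])},
            {"kon_eff": float(np.sqrt(pcov[0, 0]))}, pcov, chi2, n,
        )

    def fit_hyperbolic():
        if n < 3:
            raise ValueError("need >= 3 points for the hyperbolic model")
        p0 = [k.max() * 1.5, np.median(conc)]
        popt, pcov, chi2 = reweighted(
            _hyperbolic, p0, ([0, 0], [np.inf, np.inf])
        )
        fit = CaptureModelFit(
            "hyperbolic",
            {"kopen": float(popt[0]), "kd_init": float(popt[1])},
            {"kopen": float(np.sqrt(pcov[0, 0])), "kd_init": float(np.sqrt(pcov[1, 1]))},
            pcov, chi2, n,
        )
        if fit.params["kd_init"] > 10 * conc.max():
            fit.flags.append(
                "saturation not observed; only kon_eff identifiable, kopen "
                f"is a lower bound (> {k.max():.3g}/s)"
            )
        return fit

    if model == "linear":
        return fit_linear()
    if model == "hyperbolic":
        return fit_hyperbolic()
    if model != "auto":
        raise ValueError("model must be linear, hyperbolic or auto")
    lin = fit_linear()
    try:
        hyp = fit_hyperbolic()
    except (ValueError, RuntimeError):
        return lin
    df1, df2 = 1, n - 2
    if df2 <= 0 or hyp.chi2 >= lin.chi2:
        return lin
    f_stat = (lin.chi2 - hyp.chi2) / df1 / (hyp.chi2 / df2)
    p = stats.f.sf(f_stat, df1, df2)
    return hyp if p < 0.05 else lin


@dataclass
class TwoStepModel:
    """Rapid-equilibrium interpretation of a hyperbolic capture fit.

    Under Cfree <-> Cbound (Kd_init = koff_init / kon_init, fast) and
    Cbound -> I (kopen), the lumped observable obeys
    k_CI([RNP]) = kopen [RNP] / (Kd_init + [RNP]).
    """

    kd_init: float  # nM
    kopen: float  # per-s
    kon_init: float  # per-nM per-s, assumed
    koff_init: float  # per-s = kon_init * Kd_init
    kon_eff: float  # per-nM per-s = kopen / Kd_init (low-conc slope)

    def k_ci(self, conc_nM) -> np.ndarray:
        c = np.asarray(conc_nM, dtype=float)
        return self.kopen * c / (self.kd_init + c)


def two_step_interpret(fit: CaptureModelFit, assumed_kon_init: float = 0.1) -> TwoStepModel:
    """Expand a hyperbolic fit into the two-step capture parameters."""
    if fit.model != "hyperbolic":
        raise ValueError("two-step interpretation requires a hyperbolic fit")
    kd = fit.params["kd_init"]
    kopen = fit.params["kopen"]
    return TwoStepModel(
        kd_init=kd,
        kopen=kopen,
        kon_init=assumed_kon_init,
        koff_init=assumed_kon_init * kd,
        kon_eff=kopen / kd,
    )


def langmuir_fit(points) -> tuple[dict, dict]:
    """Weighted Langmuir-isotherm fit of baseline shift vs [RNP].

    Returns (params, ses) with keys ``delta_theta_sat`` (bp) and
    ``kd`` (nM).
    """
    if isinstance(points, pd.DataFrame):
        arr = points.iloc[:, :3].to_numpy(dtype=float)
    else:
        arr = np.asarray([tuple(p) for p in points], dtype=float)
    conc, y, se = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.unique(conc).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if np.all(np.abs(y) < 1e-12):
        raise ValueError("all shifts are ~0; KD unidentifiable")
    se = np.where(se > 0, se, np.max(se[se > 0]) if np.any(se > 0) else 1.0)

    def iso(c, sat, kd):
        return sat * c / (kd + c)

    popt, pcov = optimize.curve_fit(
        iso, conc, y, p0=[y.max() * 1.2, np.median(conc)],
        sigma=se, absolute_sigma=True, bounds=([-np.inf, 0], [np.inf, np.inf]),
        maxfev=20000,
    )
    params = {"delta_theta_sat": float(popt[0]), "kd": float(popt[1])}
    ses = {
        "delta_theta_sat": float(np.sqrt(pcov[0, 0])),
        "kd": float(np.sqrt(pcov[1, 1])),
    }
    return params, ses
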