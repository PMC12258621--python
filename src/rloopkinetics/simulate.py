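"""Synthetic rotor-bead traces and bulk-assay datasets.

The generator is the statistical twin of the experiment the analysis
pipeline assumes:

* a three-state continuous-time Markov chain over DNA conformations —
  closed (C, 0 bp unwound), R-loop intermediate (I, ~10 bp) and open
  R-loop (O, ~20 bp) — with a concentration-dependent C->I rate that
  follows either a linear (kon_eff * [RNP]) or hyperbolic
  (kopen * [RNP] / (Kd_init + [RNP])) law;
* an Ornstein-Uhlenbeck observation process for the bead angle around
  the state's twist level, discretised exactly as an AR(1) recursion
  (no Euler error), sampled at the camera frame rate;
* an optional Langmuir baseline shift modelling prolonged non-specific
  binding, applied as a constant per-trace offset;
* closed-form bulk datasets (cleavage time courses, 2AP fluorescence,
  binding isotherms, droplet counts, footprinting band tables) with
  additive Gaussian or Poisson noise.

All outputs are bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .trace import TwistTrace

STATES = ("C", "I", "O")


# ---------------------------------------------------------------------------
# rate laws for the concentration-dependent C->I step


@dataclass(frozen=True)
class LinearLaw:
    """k_CI = kon_eff * [RNP]; effective bimolecular capture (dCas9-like)."""

    kon_eff: float  # per-nM per-s

    def rate(self, conc_nM: float) -> float:
        return self.kon_eff * conc_nM


@dataclass(frozen=True)
class HyperbolicLaw:
    """k_CI = kopen * [RNP] / (Kd_init + [RNP]); saturating two-step capture.

    ``Kd_init`` is the dissociation constant of the initial bound
    complex, ``kopen`` the unwinding rate out of it (dSpRY-like).
    """

    kopen: float  # per-s
    kd_init: float  # nM

    def rate(self, conc_nM: float) -> float:
        return self.kopen * conc_nM / (self.kd_init + conc_nM)


@dataclass(frozen=True)
class FixedLaw:
    """Concentration-independent k_CI (for controlled tests)."""

    k_ci: float  # per-s

    def rate(self, conc_nM: float) -> float:
        return self.k_ci


@dataclass(frozen=True)
class LangmuirBaseline:
    """Constant per-trace twist offset from non-specific binding.

    offset([RNP]) = delta_theta_sat * [RNP] / (kd_eff + [RNP]) bp.
    """

    delta_theta_sat: float  # bp
    kd_eff: float  # nM

    def offset(self, conc_nM: float) -> float:
        return self.delta_theta_sat * conc_nM / (self.kd_eff + conc_nM)


@dataclass
class SimulationConfig:
    """Full description of one synthetic rotor-bead experiment."""

    rate_kCI_law: LinearLaw | HyperbolicLaw | FixedLaw
    rate_kIC: float  # per-s
    rate_kIO: float  # per-s
    rate_kOI: float  # per-s
    rate_kCO: float = 0.0  # per-s; direct C<->O transitions are rare
    rate_kOC: float = 0.0  # per-s
    levels_bp: dict = field(default_factory=lambda: {"C": 0.0, "I": 10.0, "O": 20.0})
    helicity: float = 10.5  # bp per turn
    ou_kappa: float = 200.0  # per-s angular relaxation rate
    ou_sigma: float = 1.5  # bp stationary SD
    sample_rate: float = 5000.0  # Hz
    duration: float = 60.0  # s
    rnp_conc: float = 0.0  # nM
    baseline_shift: LangmuirBaseline | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [self.rate_kIC, self.rate_kIO, self.rate_kOI, self.rate_kCO, self.rate_kOC]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be nonnegative")
        if self.helicity <= 0 or self.sample_rate <= 0 or self.ou_kappa <= 0:
            raise ValueError("helicity, sample_rate and ou_kappa must be positive")
        if self.ou_sigma < 0:
            raise ValueError("ou_sigma must be nonnegative")
        if self.duration < 0 or self.rnp_conc < 0:
            raise ValueError("duration and rnp_conc must be nonnegative")
        if self.levels_bp.get("C", None) != 0.0:
            raise ValueError("closed-state level must be 0 bp")

    def k_ci(self, conc_nM: float | None = None) -> float:
        c = self.rnp_conc if conc_nM is None else conc_nM
        return self.rate_kCI_law.rate(c)

    def rate_matrix(self, conc_nM: float | None = None) -> np.ndarray:
        """Generator matrix Q over (C, I, O); rows sum to zero."""
        kci = self.k_ci(conc_nM)
        q = np.array(
            [
                [0.0, kci, self.rate_kCO],
                [self.rate_kIC, 0.0, self.rate_kIO],
                [self.rate_kOC, self.rate_kOI, 0.0],
            ]
        )
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def dspry_config(**overrides) -> SimulationConfig:
    """dSpRY-like preset: hyperbolic capture law (kopen 0.06/s, Kd 10 nM).

    The C<->I law parameters are the printed dSpRY two-step model values;
    the I<->O and I->C rates are package defaults consistent with the
    reported qualitative kinetics (fast intermediate collapse, I<->O
    shared between enzymes) — see docs/methods.md.
    """
    kw = dict(
        rate_kCI_law=HyperbolicLaw(kopen=0.06, kd_init=10.0),
        rate_kIC=0.5,
        rate_kIO=0.2,
        rate_kOI=0.2,
        sample_rate=500.0,
        ou_sigma=1.5,
        ou_kappa=200.0,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def dcas9_config(**overrides) -> SimulationConfig:
    """dCas9-like preset: linear capture law, slower intermediate collapse."""
    kw = dict(
        rate_kCI_law=LinearLaw(kon_eff=0.05),
        rate_kIC=0.1,
        rate_kIO=0.2,
        rate_kOI=0.2,
        sample_rate=500.0,
        ou_sigma=1.5,
        ou_kappa=200.0,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class StatePath:
    """Latent conformational trajectory: state s(t) piecewise constant.

    ``event_times[i]`` is the entry time into ``state_labels[i]``; the
    first entry is at t=0 in the closed state.
    """

    event_times: np.ndarray  # s, strictly increasing, starts at 0
    state_labels: list  # elements of STATES
    duration: float  # s

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.size != len(self.state_labels):
            raise ValueError("event_times and state_labels length mismatch")
        if self.event_times.size and (
            np.any(np.diff(self.event_times) <= 0) or self.event_times[0] < 0
        ):
            raise ValueError("event times must be strictly increasing and nonnegative")
        for a, b in zip(self.state_labels, self.state_labels[1:]):
            if a == b:
                raise ValueError("consecutive labels must differ")

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Index into STATES of the active state at each time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.state_labels) - 1)
        codes = np.array([STATES.index(s) for s in self.state_labels])
        return codes[idx]

    def dwells(self) -> pd.DataFrame:
        """Completed and final (censored) dwell per visit."""
        ends = np.append(self.event_times[1:], self.duration)
        return pd.DataFrame(
            {
                "state": self.state_labels,
                "start_s": self.event_times,
                "dwell_s": ends - self.event_times,
                "censored": [False] * (len(self.state_labels) - 1) + [True]
                if self.state_labels
                else [],
            }
        )


def _check_reachable_exits(q: np.ndarray) -> None:
    """Reject configs where a state reachable from C has zero exit rate."""
    reach = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(3):
            if j != i and q[i, j] > 0 and j not in reach:
                reach.add(j)
                frontier.append(j)
    for i in sorted(reach):
        if -q[i, i] == 0.0 and len(reach) > 1:
            raise ValueError(
                f"state {STATES[i]} is reachable but has zero exit rate"
            )


def simulate_state_path(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> StatePath:
    """Gillespie simulation of the 3-state chain, starting in C.

    Waiting times are exponential with the total exit rate of the
    current state; the successor is chosen proportionally to the
    outgoing rates.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    q = config.rate_matrix()
    _check_reachable_exits(q)
    t = 0.0
    state = 0  # C
    times = [0.0]
    labels = ["C"]
    if config.duration == 0.0:
        return StatePath(np.array([0.0]), ["C"], 0.0)
    while True:
        exit_rate = -q[state, state]
        if exit_rate == 0.0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= config.duration:
            break
        probs = q[state].clip(min=0.0)
        probs[state] = 0.0
        state = rng.choice(3, p=probs / probs.sum())
        times.append(t)
        labels.append(STATES[state])
    return StatePath(np.array(times), labels, config.duration)


def simulate_trace(
    path: StatePath,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TwistTrace:
    """Observe a state path through the OU angular noise process.

    Exact AR(1) discretisation with a = exp(-kappa dt):

        theta_{n+1} = mu_n + (theta_n - mu_n) a + sigma sqrt(1 - a^2) eps_n

    where mu_n is the twist level of the state active at t_n plus any
    Langmuir baseline offset.  Units are bp unwound.
    """
    if abs(path.duration - config.duration) > 1e-9:
        raise ValueError("path and config durations differ")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    dt = 1.0 / config.sample_rate
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) * dt
    levels = np.array([config.levels_bp[s] for s in STATES])
    mu = levels[path.state_at(t)].astype(float)
    offset = 0.0
    if config.baseline_shift is not None:
        offset = config.baseline_shift.offset(config.rnp_conc)
        mu = mu + offset
    dwell_df = path.dwells()
    if len(dwell_df) > 1 and dwell_df["dwell_s"].iloc[:-1].min() < dt:
        warnings.warn(
            "state dwells shorter than the sampling interval; they will be "
            "unresolvable in the sampled trace",
            stacklevel=2,
        )
    a = np.exp(-config.ou_kappa * dt)
    if config.ou_sigma == 0.0:
        theta = mu.copy()
    else:
        eps = rng.standard_normal(n)
        drive = (1.0 - a) * mu + config.ou_sigma * np.sqrt(1.0 - a * a) * eps
        # theta_n = a theta_{n-1} + drive_{n-1}; start in stationarity
        theta0 = mu[0] + config.ou_sigma * rng.standard_normal()
        theta = np.empty(n)
        theta[0] = theta0
        if n > 1:
            theta[1:] = signal.lfilter([1.0], [1.0, -a], drive[:-1], zi=[a * theta0])[0]
    meta = {
        "enzyme": "synthetic",
        "conc_nM": config.rnp_conc,
        "seed": config.seed,
        "baseline_offset_bp": offset,
        "units": "bp",
    }
    return TwistTrace(time=t, theta=theta, sample_rate=config.sample_rate, metadata=meta)


def simulate_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[StatePath, TwistTrace]:
    """Convenience: path + observed trace from one RNG stream."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    path = simulate_state_path(config, rng)
    return path, simulate_trace(path, config, rng)


def simulate_concentration_series(
    config: SimulationConfig,
    concentrations,
    rng: np.random.Generator | None = None,
) -> list[TwistTrace]:
    """One trace per RNP concentration with k_CI evaluated from the law."""
    if isinstance(config.rate_kCI_law, FixedLaw):
        raise ValueError("concentration series needs a linear or hyperbolic law")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    traces = []
    for conc in concentrations:
        if conc < 0:
            raise ValueError("negative concentration")
        from dataclasses import replace as _replace

        cfg = _replace(config, rnp_conc=float(conc))
        _, tr = simulate_experiment(cfg, rng)
        traces.append(tr)
    return traces


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC generator by linear algebra."""
    a = np.vstack([q.T, np.ones(q.shape[0])])
    b = np.zeros(q.shape[0] + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return pi


# ---------------------------------------------------------------------------
# bulk datasets


def simulate_bulk_dataset(
    kind: str, params: dict, noise: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Generative twins of the bulk-assay closed forms.

    kinds
    -----
    cleavage : double-exponential product formation
               Y = Afast (1 - e^{-kfast t}) + Aslow (1 - e^{-kslow t});
               params: afast, kfast, aslow, kslow, times (min);
               Gaussian noise of SD ``noise`` on Y.
    twoap    : Y = y0 + ymax (1 - e^{-kobs t}); params y0, ymax, kobs, times.
    binding  : Langmuir isotherm delta_theta = sat * c / (kd + c); params
               delta_theta_sat, kd, concentrations, n_tethers; Gaussian
               noise per tether.
    droplets : Poisson droplet counts; params n_droplets (mean reference
               count), f_dsb (true broken fraction); noise ignored.
    gel      : footprinting band volumes; params pox (per-thymine
               oxidation probabilities), background (uniform cleavage
               floor), total_volume; Gaussian noise on volumes.
    """
    rng = np.random.default_rng(seed)
    if kind == "cleavage":
        t = np.asarray(params["times"], dtype=float)
        afast, aslow = params["afast"], params.get("aslow", 0.0)
        for amp in (afast, aslow):
            if not 0.0 <= amp <= 1.0:
                raise ValueError("cleavage amplitudes must be within [0, 1]")
        if afast + aslow > 1.0:
            raise ValueError("total amplitude exceeds 1")
        y = afast * (1 - np.exp(-params["kfast"] * t))
        if aslow:
            y = y + aslow * (1 - np.exp(-params["kslow"] * t))
        y = y + noise * rng.standard_normal(t.size)
        return pd.DataFrame({"time_min": t, "fraction_cleaved": y})
    if kind == "twoap":
        t = np.asarray(params["times"], dtype=float)
        y = params["y0"] + params["ymax"] * (1 - np.exp(-params["kobs"] * t))
        y = y + noise * rng.standard_normal(t.size)
        return pd.DataFrame({"time_s": t, "fluorescence_au": y})
    if kind == "binding":
        conc = np.asarray(params["concentrations"], dtype=float)
        n_tethers = int(params.get("n_tethers", 1))
        sat, kd = params["delta_theta_sat"], params["kd"]
        rows = []
        for c in conc:
            mu = sat * c / (kd + c)
            for tether in range(n_tethers):
                rows.append(
                    (c, tether, mu + noise * rng.standard_normal())
                )
        return pd.DataFrame(rows, columns=["conc_nM", "tether", "delta_theta0_bp"])
    if kind == "droplets":
        lam = float(params["n_droplets"])
        f = float(params["f_dsb"])
        if not 0.0 <= f <= 1.0:
            raise ValueError("f_dsb must be within [0, 1]")
        n_ref = rng.poisson(lam)
        n_tgt = rng.poisson(lam * (1.0 - f))
        return pd.DataFrame(
            {"amplicon": ["target", "reference"], "droplets": [n_tgt, n_ref]}
        )
    if kind == "gel":
        pox = np.asarray(params["pox"], dtype=float)
        bg = float(params.get("background", 1.0 / pox.size))
        total = float(params.get("total_volume", 1000.0))
        p_minus = np.full(pox.size, bg)
        p_minus = p_minus / p_minus.sum()
        p_plus = p_minus + pox
        if np.any(p_plus < 0) or abs(p_plus.sum() - 1.0) > 1e-9:
            raise ValueError("pox must keep lane probabilities valid")
        v_plus = total * p_plus * (1 + noise * rng.standard_normal(pox.size))
        v_minus = total * p_minus * (1 + noise * rng.standard_normal(pox.size))
        return pd.DataFrame(
            {
                "band": np.arange(1, pox.size + 1),
                "volume_plusPM": v_plus.clip(min=0.0),
                "volume_minusPM": v_minus.clip(min=0.0),
            }
        )
    raise ValueError(f"unknown bulk dataset kind: {kind!r}")
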