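"""Change-point segmentation of twist traces under OU noise.

The bead angle within a constant-twist level is modelled as an
Ornstein-Uhlenbeck process: mean-reverting with relaxation rate kappa
and stationary SD sigma.  Sampled at interval dt this is exactly an
AR(1) process with coefficient a = exp(-kappa dt) and innovation SD
sigma_eps = sigma sqrt(1 - a^2).  The only free parameters during
segmentation are the per-segment mean level and the change-point times;
kappa and sigma are global, calibrated once from an event-free stretch
of the trace recorded before protein is introduced.

Segmentation is recursive binary splitting with a generalized
likelihood-ratio (GLR) test.  Conditioning each segment's likelihood on
its first sample reduces the model to piecewise-constant means in iid
Gaussian innovations z_i = x_i - a x_{i-1}, so the null distribution of
the scan statistic depends only on the trace length and the minimum
segment length.  The acceptance threshold is calibrated by Monte Carlo
on that parameter-free null to a target expected false change-point
rate per 100 s.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import TwistTrace

_KAPPA_CAP_FRACTION = 0.5  # cap kappa at -ln(a_min)/dt with a_min from here


@dataclass(frozen=True)
class OUParams:
    """Calibrated OU noise model at a given sampling interval."""

    kappa: float  # per-s
    sigma_stat: float  # bp
    dt: float  # s
    kappa_se: float = float("nan")
    sigma_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.sigma_stat <= 0 or self.dt <= 0:
            raise ValueError("kappa, sigma_stat and dt must be positive")

    @property
    def a(self) -> float:
        """AR(1) coefficient; in (0, 1) for a proper OU model."""
        return float(np.exp(-self.kappa * self.dt))

    @property
    def sigma_eps(self) -> float:
        """Innovation SD of the exact AR(1) discretisation."""
        a = self.a
        return self.sigma_stat * float(np.sqrt(1.0 - a * a))

    def at_rate(self, sample_rate: float) -> "OUParams":
        """Same physical parameters expressed at another sampling rate."""
        return OUParams(self.kappa, self.sigma_stat, 1.0 / sample_rate)


@dataclass
class SegControl:
    """Knobs of the segmentation procedure."""

    min_len: int = 5  # samples; 10 ms at 500 Hz
    fp_per_100s: float = 0.1  # target expected false change points per 100 s
    threshold: float | None = None  # explicit GLR threshold overrides calibration
    n_null: int = 200  # Monte-Carlo replicates for calibration
    max_cal_samples: int = 50_000  # calibration trace length cap
    cal_seed: int = 12345


@dataclass
class SegmentedTrace:
    """Piecewise-constant idealization of a twist trace."""

    change_times: np.ndarray  # s; empty if single segment
    level_means: np.ndarray  # bp per segment (one more than change points)
    durations: np.ndarray  # s per segment
    start_times: np.ndarray  # s per segment
    loglik: float  # conditional AR(1) log-likelihood, nats
    sample_rate: float

    def __post_init__(self) -> None:
        if self.level_means.size != self.change_times.size + 1:
            raise ValueError("need one more level than change points")
        if self.change_times.size and np.any(np.diff(self.change_times) <= 0):
            raise ValueError("change times must be strictly increasing")

    def __len__(self) -> int:
        return self.level_means.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.start_times,
                "end_s": self.start_times + self.durations,
                "mean_bp": self.level_means,
            }
        )

    def idealized(self, time: np.ndarray) -> np.ndarray:
        """Step-function reconstruction sampled at the given times."""
        idx = np.searchsorted(self.start_times, time, side="right") - 1
        return self.level_means[np.clip(idx, 0, len(self) - 1)]


def calibrate_ou(baseline: TwistTrace) -> OUParams:
    """Estimate (kappa, sigma) from an event-free baseline stretch.

    kappa comes from the lag-1 autocorrelation a via kappa = -ln(a)/dt,
    sigma from the sample SD.  Both carry asymptotic standard errors.
    A baseline of >= 1e4 samples is recommended.
    """
    x = baseline.theta
    n = x.size
    if n < 100:
        raise ValueError("baseline too short to calibrate the noise model")
    dt = 1.0 / baseline.sample_rate
    xc = x - x.mean()
    var = float(np.mean(xc * xc))
    if var == 0.0:
        raise ValueError("constant baseline: sigma_stat = 0, OU model misfit")
    a = float(np.mean(xc[:-1] * xc[1:]) / var)
    if a <= 0.0:
        a_min = np.exp(-1.0 / _KAPPA_CAP_FRACTION)
        warnings.warn(
            "non-positive lag-1 autocorrelation; noise is white at this "
            "rate, capping kappa",
            stacklevel=2,
        )
        a = a_min
    if a >= 1.0:
        raise ValueError("lag-1 autocorrelation >= 1: OU model misfit")
    kappa = -np.log(a) / dt
    a_se = np.sqrt((1.0 - a * a) / n)
    kappa_se = a_se / (a * dt)
    # effective sample size for the variance of an AR(1) sample SD
    n_eff = n * (1.0 - a) / (1.0 + a)
    sigma = float(np.sqrt(var * n / max(n - 1, 1)))
    sigma_se = sigma / np.sqrt(2.0 * max(n_eff, 2.0))
    return OUParams(kappa=float(kappa), sigma_stat=sigma, dt=dt,
                    kappa_se=float(kappa_se), sigma_se=float(sigma_se))


# ---------------------------------------------------------------------------
# GLR scan machinery (operates on innovations z_i = x_i - a x_{i-1})


def _rss(cs: np.ndarray, cs2: np.ndarray, lo, hi):
    """RSS of innovations z[lo:hi] about their mean, via prefix sums."""
    m = hi - lo
    s = cs[hi] - cs[lo]
    s2 = cs2[hi] - cs2[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s2 - np.where(m > 0, s * s / np.maximum(m, 1), 0.0)
    return np.maximum(out, 0.0)


def _best_split(z, cs, cs2, s, e, min_len):
    """Best single change point within samples [s, e] of the x series.

    A split at k makes segments [s, k-1] and [k, e].  The innovation at
    k (the cross-boundary transition) belongs to neither segment, so the
    GLR compares RSS(z[s+1..e]) against RSS(z[s+1..k-1]) + RSS(z[k+1..e]).
    Returns (k, glr_improvement) with the GLR in units of sigma_eps^2
    left to the caller.
    """
    ks = np.arange(s + min_len, e - min_len + 2)
    if ks.size == 0:
        return -1, -np.inf
    rss0 = float(_rss(cs, cs2, s + 1, e + 1))
    left = _rss(cs, cs2, s + 1, ks)
    right = _rss(cs, cs2, ks + 1, e + 1)
    gain = rss0 - left - right
    i = int(np.argmax(gain))
    return int(ks[i]), float(gain[i])


@functools.lru_cache(maxsize=32)
def _null_threshold(n: int, min_len: int, q: float, n_null: int, seed: int) -> float:
    """Monte-Carlo (1-q)-quantile of the null max-GLR statistic.

    Under the null the innovations are iid Gaussian, so standard normal
    draws suffice; the returned threshold is in innovation-variance
    units and applies for any (kappa, sigma).
    """
    rng = np.random.default_rng(seed)
    stats = np.empty(n_null)
    for r in range(n_null):
        z = rng.standard_normal(n)
        cs = np.concatenate([[0.0], np.cumsum(z)])
        cs2 = np.concatenate([[0.0], np.cumsum(z * z)])
        _, gain = _best_split(z, cs, cs2, 0, n - 1, min_len)
        stats[r] = gain
    return float(np.quantile(stats, 1.0 - q))


def calibrated_threshold(ou: OUParams, n_samples: int, control: SegControl) -> float:
    """GLR threshold (innovation-variance units) for the target FP rate."""
    if control.threshold is not None:
        return control.threshold
    n_cal = int(min(n_samples, control.max_cal_samples))
    cal_seconds = n_cal * ou.dt
    fp_per_trace = control.fp_per_100s * cal_seconds / 100.0
    q = float(np.clip(fp_per_trace, 1.0 / control.n_null, 0.5))
    return _null_threshold(n_cal, control.min_len, q, control.n_null, control.cal_seed)


def segment(
    trace: TwistTrace, ou: OUParams, control: SegControl | None = None
) -> SegmentedTrace:
    """Segment a trace into constant-mean levels under the OU model.

    Recursive binary splitting: each candidate split is accepted iff its
    GLR statistic exceeds the calibrated threshold; accepted splits are
    re-scanned on both sides until no further split passes.  Per-segment
    means are the conditional MLEs mean(z)/(1-a).
    """
    control = control or SegControl()
    if abs(1.0 / trace.sample_rate - ou.dt) > 1e-9 * ou.dt:
        raise ValueError("OU params calibrated at a different sample rate")
    x = trace.theta
    n = x.size
    dt = ou.dt
    a = ou.a
    sig2 = ou.sigma_eps**2
    if n < 2 * control.min_len:
        mean = float(x.mean()) if n else float("nan")
        return SegmentedTrace(
            change_times=np.array([]),
            level_means=np.array([mean]),
            durations=np.array([n * dt]),
            start_times=np.array([0.0]),
            loglik=float("nan"),
            sample_rate=trace.sample_rate,
        )
    z = x[1:] - a * x[:-1]
    z = np.concatenate([[0.0], z])  # z[i] pairs with x[i]; z[0] unused
    cs = np.concatenate([[0.0], np.cumsum(z)])
    cs2 = np.concatenate([[0.0], np.cumsum(z * z)])
    # thresholds are expressed in unit-variance innovation units; scale once
    thr = calibrated_threshold(ou, n, control) * sig2

    breakpoints: list[int] = []
    stack = [(0, n - 1)]
    while stack:
        s, e = stack.pop()
        if e - s + 1 < 2 * control.min_len:
            continue
        k, gain = _best_split(z, cs, cs2, s, e, control.min_len)
        if k >= 0 and gain > thr:
            breakpoints.append(k)
            stack.append((s, k - 1))
            stack.append((k, e))
    breakpoints.sort()
    bounds = [0] + breakpoints + [n]
    means, durs, starts = [], [], []
    loglik = 0.0
    c = 1.0 - a
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        zi = z[lo + 1 : hi]
        if zi.size:
            mu = float(zi.mean() / c)
            rss = float(np.sum((zi - zi.mean()) ** 2))
        else:  # single-sample segment (min_len >= 2 prevents this normally)
            mu = float(x[lo])
            rss = 0.0
        means.append(mu)
        durs.append((hi - lo) * dt)
        starts.append(lo * dt)
        loglik += -0.5 * zi.size * np.log(2 * np.pi * sig2) - rss / (2 * sig2)
    return SegmentedTrace(
        change_times=np.array(breakpoints, dtype=float) * dt,
        level_means=np.array(means),
        durations=np.array(durs),
        start_times=np.array(starts),
        loglik=float(loglik),
        sample_rate=trace.sample_rate,
    )
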