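"""Twist-trace preparation: drift correction, angle unwrapping, filtering.

Rotor-bead tracking reads DNA twist from the in-plane angle of a gold
nanosphere attached to a torsionally constrained tether.  Raw data are
(x, y) bead positions on the detector; the analysis pipeline converts
them to an unwrapped angle in turns, corrects slow stage drift, converts
turns to base pairs unwound via the B-DNA helicity (10.5 bp/turn), and
low-pass filters to the analysis rate (500 Hz by default).

Sign convention: positive theta means DNA *unwinding* (bp unwound), so
``bp = -turns * helicity``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HELICITY_BP_PER_TURN = 10.5


def turns_to_bp(turns, helicity: float = HELICITY_BP_PER_TURN):
    """Convert rotor angle in turns to bp unwound (unwinding positive)."""
    return -np.asarray(turns, dtype=float) * helicity


def bp_to_turns(bp, helicity: float = HELICITY_BP_PER_TURN):
    """Inverse of :func:`turns_to_bp`."""
    return -np.asarray(bp, dtype=float) / helicity


@dataclass
class XYTrajectory:
    """Uniformly sampled bead (x, y) positions in detector units."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.shape == self.x.shape == self.y.shape):
            raise ValueError("time, x, y must have identical shapes")
        if self.time.size >= 3:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("sampling must be uniform")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class TwistTrace:
    """Uniformly sampled twist signal in bp unwound.

    ``zero_reference`` records the offset (bp) subtracted when the trace
    was re-zeroed to the dominant closed state; it is applied exactly
    once and is itself the non-specific baseline shift used by the
    binding analysis.
    """

    time: np.ndarray
    theta: np.ndarray
    sample_rate: float
    zero_reference: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.time.shape != self.theta.shape:
            raise ValueError("time and theta must have identical shapes")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")

    @property
    def duration(self) -> float:
        return self.theta.size / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "theta_bp": self.theta})

    def write(self, path: str | Path) -> None:
        """Write (time_s, theta_bp) TSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = dict(self.metadata)
        meta.update(
            sample_rate_hz=self.sample_rate, zero_reference_bp=self.zero_reference
        )
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "TwistTrace":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        rate = meta.pop("sample_rate_hz", None)
        if rate is None:
            rate = 1.0 / (df["time_s"].iloc[1] - df["time_s"].iloc[0])
        zero = meta.pop("zero_reference_bp", 0.0)
        return cls(
            time=df["time_s"].to_numpy(),
            theta=df["theta_bp"].to_numpy(),
            sample_rate=float(rate),
            zero_reference=float(zero),
            metadata=meta,
        )


def read_xy(path: str | Path) -> XYTrajectory:
    df = pd.read_csv(path, sep="\t")
    return XYTrajectory(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), df.iloc[:, 2].to_numpy())


# ---------------------------------------------------------------------------
# drift correction


def _fit_center(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Center of an algebraic least-squares conic fit, circle fallback.

    Fits a general conic A x^2 + B xy + C y^2 + D x + E y + F = 0 by SVD
    on the design matrix.  If the conic is not an ellipse (discriminant
    B^2 - 4AC >= 0) or the system is ill-conditioned, falls back to a
    Kasa circle fit; degenerate windows fall back to the centroid.
    """
    if x.size < 5:
        logger.warning("drift window with <5 points; using centroid")
        return float(np.mean(x)), float(np.mean(y))
    xm, ym = x.mean(), y.mean()
    xs, ys = x - xm, y - ym
    design = np.column_stack(
        [xs**2, xs * ys, ys**2, xs, ys, np.ones_like(xs)]
    )
    try:
        _, _, vt = np.linalg.svd(design, full_matrices=False)
        A, B, C, D, E, _ = vt[-1]
        disc = B * B - 4 * A * C
        if disc < -1e-12 * max(1.0, A * A + B * B + C * C):
            # proper ellipse: center from the conic gradient zero
            cx = (2 * C * D - B * E) / disc
            cy = (2 * A * E - B * D) / disc
            return float(cx + xm), float(cy + ym)
    except np.linalg.LinAlgError:  # pragma: no cover - numerical corner
        pass
    # Kasa circle fit: minimize |x^2+y^2 + a x + b y + c|
    M = np.column_stack([xs, ys, np.ones_like(xs)])
    b = -(xs**2 + ys**2)
    try:
        sol, *_ = np.linalg.lstsq(M, b, rcond=None)
        return float(-sol[0] / 2 + xm), float(-sol[1] / 2 + ym)
    except np.linalg.LinAlgError:
        logger.warning("degenerate drift window; using centroid")
        return float(xm), float(ym)


def drift_correct(traj: XYTrajectory, window: float = 1.0) -> XYTrajectory:
    """Subtract per-window circle/ellipse centers from an (x, y) trajectory.

    Each ``window``-second block is fit independently; the fitted center
    is subtracted from that block, removing slow stage drift while
    preserving the bead's angular motion about the tether axis.
    """
    n_win = max(1, int(round(window * traj.sample_rate)))
    if n_win < 50:
        warnings.warn(
            "drift window shorter than ~50 samples may not average over "
            "angular diffusion",
            stacklevel=2,
        )
    x = traj.x.copy()
    y = traj.y.copy()
    for start in range(0, traj.x.size, n_win):
        sl = slice(start, min(start + n_win, traj.x.size))
        cx, cy = _fit_center(traj.x[sl], traj.y[sl])
        x[sl] -= cx
        y[sl] -= cy
    return XYTrajectory(traj.time, x, y)


# ---------------------------------------------------------------------------
# angle extraction


def xy_to_angle(traj: XYTrajectory) -> TwistTrace:
    """Four-quadrant angle of each (x, y) pair, unwrapped, in turns.

    (0, 0) samples carry no angle information; they propagate the
    previous sample's angle (logged).  Successive samples never jump by
    more than half a turn after unwrapping.
    """
    r2 = traj.x**2 + traj.y**2
    ang = np.arctan2(traj.y, traj.x) / (2 * np.pi)
    zero = r2 == 0.0
    if np.any(zero):
        logger.warning("%d zero-radius samples; propagating previous angle", zero.sum())
        idx = np.arange(ang.size)
        valid = ~zero
        if not valid.any():
            raise ValueError("all samples at origin")
        last = np.maximum.accumulate(np.where(valid, idx, -1))
        first_valid = idx[valid][0]
        last = np.where(last < 0, first_valid, last)
        ang = ang[last]
    ang = np.unwrap(ang, period=1.0)
    return TwistTrace(
        time=traj.time,
        theta=ang,
        sample_rate=traj.sample_rate,
        metadata={"units": "turns"},
    )


def repair_zero_crossings(turns: np.ndarray, jump: float = 0.75) -> np.ndarray:
    """Automated repair of spurious integer-rotation jumps.

    A jump of at least ``jump`` turns between adjacent samples that is
    undone by an (approximately) equal and opposite jump later is
    treated as a tracking artifact (bead trajectory passing through the
    origin) and removed by offsetting the intervening stretch.
    """
    turns = np.asarray(turns, dtype=float).copy()
    d = np.diff(turns)
    jumps = np.flatnonzero(np.abs(d) >= jump)
    i = 0
    while i < jumps.size - 1:
        j0, j1 = jumps[i], jumps[i + 1]
        if np.sign(d[j0]) != np.sign(d[j1]) and abs(d[j0] + d[j1]) < jump / 2:
            logger.warning(
                "repairing artifact jump of %.2f turns at samples %d-%d",
                d[j0], j0, j1,
            )
            turns[j0 + 1 : j1 + 1] -= d[j0]
            i += 2
        else:
            i += 1
    return turns


def angle_trace_to_bp(trace: TwistTrace, helicity: float = HELICITY_BP_PER_TURN) -> TwistTrace:
    """Convert a turns-unit trace to bp unwound (unwinding positive)."""
    if trace.metadata.get("units", "turns") != "turns":
        raise ValueError("trace is not in turns")
    meta = dict(trace.metadata)
    meta["units"] = "bp"
    meta["helicity_bp_per_turn"] = helicity
    return TwistTrace(
        time=trace.time,
        theta=turns_to_bp(trace.theta, helicity),
        sample_rate=trace.sample_rate,
        zero_reference=trace.zero_reference,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# filtering


def filter_trace(trace: TwistTrace, target_rate: float = 500.0) -> TwistTrace:
    """Boxcar-average and decimate to ``target_rate``.

    The filter is a mean over non-overlapping blocks (e.g. 10 samples
    for 5 kHz -> 500 Hz), which preserves level means exactly and smears
    a step over at most one output sample.
    """
    if target_rate > trace.sample_rate:
        raise ValueError("target_rate exceeds sample rate")
    factor = trace.sample_rate / target_rate
    n = int(round(factor))
    if abs(factor - n) > 1e-6:
        raise ValueError("sample rate must be an integer multiple of target rate")
    if n == 1:
        return trace
    m = trace.theta.size // n
    theta = trace.theta[: m * n].reshape(m, n).mean(axis=1)
    time = trace.time[: m * n].reshape(m, n).mean(axis=1)
    return TwistTrace(
        time=time,
        theta=theta,
        sample_rate=target_rate,
        zero_reference=trace.zero_reference,
        metadata=dict(trace.metadata),
    )


def rezero(trace: TwistTrace, states) -> TwistTrace:
    """Re-zero so the dominant closed state sits at 0 bp.

    ``states`` is a ``StateSequence`` scored on this trace.  The
    lifetime-weighted mean level of the closed cluster is subtracted
    from the whole trace and recorded in ``zero_reference``; the
    recorded offset is the non-specific baseline shift used downstream
    by the Langmuir binding analysis.
    """
    closed = [s for s in states if s.label in ("C", "closed")]
    if not closed:
        raise ValueError("no closed-cluster state found; cannot re-zero")
    dwell = np.array([s.dwell for s in closed])
    level = np.array([s.delta_theta0 for s in closed])
    offset = float(np.sum(dwell * level) / np.sum(dwell))
    return replace(
        trace,
        theta=trace.theta - offset,
        zero_reference=trace.zero_reference + offset,
    )
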