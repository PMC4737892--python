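"""Forward simulators for the candidate gas-exchange models.

Two complementary routes:

* a fine-step continuous integrator for the two-compartment delay
  differential equations (classical fixed-step 4th-order Runge-Kutta with a
  history buffer and linear interpolation for the delayed lookups) -- the
  reference dynamics used to synthesise data;
* the exact discrete-time recursions obtained from the forward-difference
  regression form of each candidate model -- the predictors used for
  identification ("pure" prediction: the recursion is driven only by the
  measured ventilation input and its own past output).

Time-unit convention: record-level APIs take the sampling interval in
seconds; the low-level series operations (`second_difference`,
`build_regressor_m3`, the recursions) take it in the time unit of the rate
parameters, which is minutes throughout the package (5 s = 1/12 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .core import (
    ModelId,
    OmegaVector,
    PhysioParams,
    RespiratoryConstants,
    ThetaParams,
    omega_from_theta,
    theta_from_physio,
)

SEC_PER_MIN = 60.0

#: divergence guard for the discrete recursions, mmHg
_X1_CAP = 1.0e7

#: recursion seed samples per model (second-order needs two, first-order one)
N_SEED = {"M1": 1, "M2": 2, "M3": 2}


class DivergenceError(RuntimeError):
    """A simulated trajectory left the admissible range or became non-finite."""

    def __init__(self, message: str, sample_index: Optional[int] = None):
        super().__init__(message)
        self.sample_index = sample_index


@dataclass
class VentilationRecord:
    """A subject's uniformly sampled PetCO2 / minute-ventilation record.

    ts_s    : sampling interval, s
    t_s     : sample times, s
    petco2  : end-tidal CO2 tension, mmHg
    vdot    : minute ventilation, l/min
    settings: optional per-sample ventilator annotations
              (rr_per_min, tv_ml, ppeak_cmH2O, ie_ratio)
    """

    ts_s: float
    t_s: np.ndarray
    petco2: np.ndarray
    vdot: np.ndarray
    settings: dict = field(default_factory=dict)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.petco2 = np.asarray(self.petco2, dtype=float)
        self.vdot = np.asarray(self.vdot, dtype=float)
        n = len(self.petco2)
        if len(self.vdot) != n or len(self.t_s) != n:
            raise ValueError("t_s, petco2 and vdot must have equal length")
        if n < 10:
            raise ValueError("record must contain at least 10 samples")
        if self.ts_s <= 0:
            raise ValueError("ts_s must be positive")
        dt = np.diff(self.t_s)
        if np.max(np.abs(dt - self.ts_s)) >= 1e-9 * self.ts_s:
            raise ValueError("record is not uniformly sampled at ts_s")
        if np.any(self.vdot < 0):
            raise ValueError("minute ventilation must be non-negative")
        if np.any(self.petco2 <= 0):
            raise ValueError("PetCO2 must be strictly positive")

    def __len__(self) -> int:
        return len(self.petco2)

    @property
    def ts_min(self) -> float:
        return self.ts_s / SEC_PER_MIN

    @property
    def duration_min(self) -> float:
        return (self.t_s[-1] - self.t_s[0]) / SEC_PER_MIN


@dataclass
class SimulationOutput:
    """Simulated trajectories: alveolar (x1) and, for the continuous
    integrator, mixed-venous (x2) CO2 tension, mmHg."""

    t_s: np.ndarray
    x1: np.ndarray
    x2: Optional[np.ndarray]
    method: str


def simulate_continuous_m3(
    p: PhysioParams,
    c: RespiratoryConstants = RespiratoryConstants(),
    u_fn: Callable[[float], float] = lambda t: 2.24,
    x1_0: float = 40.0,
    x2_0: Optional[float] = None,
    duration_s: float = 1440.0,
    dt_s: float = 0.1,
) -> SimulationOutput:
    """Integrate the two-compartment delay ODEs with fixed-step RK4.

        dx1/dt = -theta1*x1*u + theta2*[x2(t - tau1) - x1]
        dx2/dt =  theta3*[x1(t - tau2) - x2] + theta4

    The pre-history is constant: x1(t) = x1_0, x2(t) = x2_0 for t <= 0.
    When x2_0 is omitted it defaults to the steady-state offset
    x1_0 + theta4/theta3 (mixed-venous tension is not measurable).
    Delayed lookups interpolate linearly in the solution history; zero
    delays are substituted with the current stage value (plain ODE
    coupling).
    """
    if dt_s <= 0 or duration_s <= 0:
        raise ValueError("dt_s and duration_s must be positive")
    th = theta_from_physio(p, c, ts_s=1.0)  # delays handled separately here
    # rates per second
    th1 = th.theta1 / SEC_PER_MIN
    th2 = th.theta2 / SEC_PER_MIN
    th3 = th.theta3 / SEC_PER_MIN
    th4 = th.theta4 / SEC_PER_MIN
    tau1, tau2 = p.tau1, p.tau2
    if x2_0 is None:
        x2_0 = x1_0 + th.theta4 / th.theta3

    n_steps = int(round(duration_s / dt_s))
    x1 = [0.0] * (n_steps + 1)
    x2 = [0.0] * (n_steps + 1)
    x1[0], x2[0] = float(x1_0), float(x2_0)

    def hist(buf: list, x_pre: float, t_query: float, i_known: int) -> float:
        if t_query <= 0.0:
            return x_pre
        pos = t_query / dt_s
        i0 = int(pos)
        if i0 >= i_known:
            return buf[i_known]
        frac = pos - i0
        return buf[i0] * (1.0 - frac) + buf[i0 + 1] * frac

    for i in range(n_steps):
        t = i * dt_s

        def rhs(ts: float, y1: float, y2: float) -> tuple[float, float]:
            u = u_fn(ts)
            x2d = y2 if tau1 == 0.0 else hist(x2, x2_0, ts - tau1, i)
            x1d = y1 if tau2 == 0.0 else hist(x1, x1_0, ts - tau2, i)
            return (
                -th1 * y1 * u + th2 * (x2d - y1),
                th3 * (x1d - y2) + th4,
            )

        y1, y2 = x1[i], x2[i]
        k1 = rhs(t, y1, y2)
        k2 = rhs(t + dt_s / 2, y1 + dt_s / 2 * k1[0], y2 + dt_s / 2 * k1[1])
        k3 = rhs(t + dt_s / 2, y1 + dt_s / 2 * k2[0], y2 + dt_s / 2 * k2[1])
        k4 = rhs(t + dt_s, y1 + dt_s * k3[0], y2 + dt_s * k3[1])
        x1[i + 1] = y1 + dt_s / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        x2[i + 1] = y2 + dt_s / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if not (math.isfinite(x1[i + 1]) and math.isfinite(x2[i + 1])):
            raise DivergenceError(
                f"continuous trajectory non-finite at step {i + 1}", i + 1
            )

    t_grid = np.arange(n_steps + 1) * dt_s
    return SimulationOutput(
        t_s=t_grid, x1=np.array(x1), x2=np.array(x2), method="continuous"
    )


def second_difference(x, k: int, ts: float) -> float:
    """Central estimate of the second derivative by forward differences:
    (x[k+2] - 2 x[k+1] + x[k]) / ts**2.  Exact for quadratic sequences;
    annihilates affine ones.  `ts` is in the rate time unit (minutes)."""
    if k < 0 or k + 2 >= len(x):
        raise IndexError(f"second difference needs samples k..k+2, got k={k}")
    return (x[k + 2] - 2.0 * x[k + 1] + x[k]) / (ts * ts)


def build_regressor_m3(x1, u, k: int, tau: int, ts: float) -> np.ndarray:
    """Regression vector psi3(k, tau) of the delayed two-compartment model.

    [-(dx1/dt)(k) u(k) - x1(k) (du/dt)(k), -(dx1/dt)(k), -x1(k) u(k),
     x1(k - tau) - x1(k), 1]

    with forward differences at step `ts` (minutes).  Samples before the
    record start are held at x1[0] (pre-record steady breathing); u at the
    final sample is extrapolated by holding it constant.
    """
    if k < 0 or k + 1 >= len(x1):
        raise IndexError(f"regressor needs x1[k] and x1[k+1], got k={k}")
    if tau < 0:
        raise ValueError("tau must be a non-negative integer sample count")
    d1 = (x1[k + 1] - x1[k]) / ts
    u_next = u[k + 1] if k + 1 < len(u) else u[k]
    du = (u_next - u[k]) / ts
    x1_delayed = x1[k - tau] if k - tau >= 0 else x1[0]
    return np.array(
        [
            -d1 * u[k] - x1[k] * du,
            -d1,
            -x1[k] * u[k],
            x1_delayed - x1[k],
            1.0,
        ]
    )


def build_regressor_m2(x1, u, k: int, ts: float) -> np.ndarray:
    """psi2(k): psi3 without the delay element."""
    psi3 = build_regressor_m3(x1, u, k, 0, ts)
    return np.delete(psi3, 3)


def build_regressor_m1(x1, u, k: int) -> np.ndarray:
    """psi1(k) = [-x1(k) u(k), 1] of the single-compartment model."""
    return np.array([-x1[k] * u[k], 1.0])


def _recursion_second_order(
    w: tuple, u: list, x0: float, x1i: float, tau: int, ts: float, n: int,
    with_delay: bool,
) -> tuple[list, Optional[int]]:
    """Shared M2/M3 second-order pure-prediction recursion over plain floats.

    Returns (series, index of first divergent sample or None); on
    divergence the remainder of the series is held at the capped value.
    """
    xh = [0.0] * n
    xh[0], xh[1] = x0, x1i
    if with_delay:
        w0, w1, w2, w3, w4 = w
    else:
        w0, w1, w2, w4 = w
        w3 = 0.0
    ts2 = ts * ts
    for k in range(2, n):
        j = k - 2
        xj = xh[j]
        d1 = (xh[j + 1] - xj) / ts
        uj = u[j]
        du = (u[j + 1] - uj) / ts
        acc = w0 * (-d1 * uj - xj * du) - w1 * d1 - w2 * xj * uj + w4
        if with_delay:
            jd = j - tau
            xd = xh[jd] if jd >= 0 else xh[0]
            acc += w3 * (xd - xj)
        val = 2.0 * xh[k - 1] - xh[k - 2] + ts2 * acc
        if not math.isfinite(val) or abs(val) > _X1_CAP:
            cap = _X1_CAP if (math.isnan(val) or val > 0) else -_X1_CAP
            for kk in range(k, n):
                xh[kk] = cap
            return xh, k
        xh[k] = val
    return xh, None


def _recursion_first_order(
    w: tuple, u: list, x0: float, ts: float, n: int
) -> tuple[list, Optional[int]]:
    w0, w1 = w
    xh = [0.0] * n
    xh[0] = x0
    for k in range(1, n):
        val = xh[k - 1] + ts * (-w0 * xh[k - 1] * u[k - 1] + w1)
        if not math.isfinite(val) or abs(val) > _X1_CAP:
            cap = _X1_CAP if (math.isnan(val) or val > 0) else -_X1_CAP
            for kk in range(k, n):
                xh[kk] = cap
            return xh, k
        xh[k] = val
    return xh, None


def simulate_discrete(
    model_id: ModelId,
    params: Union[ThetaParams, OmegaVector],
    record: VentilationRecord,
    init: Optional[tuple] = None,
    tau: Optional[int] = None,
    on_divergence: str = "raise",
) -> np.ndarray:
    """Pure-prediction simulation of a candidate model over a record.

    The recursion is seeded with the first one (M1) or two (M2/M3)
    measured PetCO2 samples and thereafter driven only by the measured
    minute-ventilation input and its own past output (infinite-step-ahead
    prediction).  `tau` (integer samples) is required for M3 unless
    `params` is a ThetaParams carrying it.

    on_divergence: "raise" raises :class:`DivergenceError` naming the
    sample; "cap" clamps the remainder of the series at +/-1e7 mmHg.
    """
    if model_id not in ("M1", "M2", "M3"):
        raise ValueError(f"unknown model_id {model_id!r}")
    if isinstance(params, ThetaParams):
        if model_id == "M1":
            raise ValueError("M1 requires an OmegaVector (theta does not determine it)")
        if tau is None:
            tau = params.tau
        w = omega_from_theta(params, model_id).coeffs
    elif isinstance(params, OmegaVector):
        if params.model_id != model_id:
            raise ValueError(
                f"params are for {params.model_id}, requested {model_id}"
            )
        w = params.coeffs
    else:
        raise TypeError("params must be ThetaParams or OmegaVector")

    n = len(record)
    ts = record.ts_min
    u = record.vdot.tolist()
    x1 = record.petco2

    if model_id == "M1":
        x0 = float(init[0]) if init is not None else float(x1[0])
        series, bad = _recursion_first_order(w, u, x0, ts, n)
    else:
        if init is not None:
            x0, x1i = float(init[0]), float(init[1])
        else:
            x0, x1i = float(x1[0]), float(x1[1])
        if model_id == "M3":
            if tau is None or tau < 0 or int(tau) != tau:
                raise ValueError("M3 requires a non-negative integer tau")
            series, bad = _recursion_second_order(
                w, u, x0, x1i, int(tau), ts, n, with_delay=True
            )
        else:
            series, bad = _recursion_second_order(
                w, u, x0, x1i, 0, ts, n, with_delay=False
            )

    if bad is not None and on_divergence == "raise":
        raise DivergenceError(
            f"{model_id} recursion diverged at sample {bad}", bad
        )
    return np.array(series)
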