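"""Subject-wise model identification by pure-prediction-error minimisation.

Each candidate model is fitted to one subject's PetCO2 / minute-ventilation
record by minimising the mean-squared *pure* prediction error

    J(Theta, tau) = (1/N) sum_k [x1(k) - x1_hat(k | Theta, tau)]^2

where x1_hat is the model's infinite-step-ahead prediction (the discrete
recursion driven only by the measured ventilation and its own past output).
The delay tau enters the regression vector non-linearly, so it is handled
by exhaustive search over an integer grid while the rate parameters are
optimised by multi-start bound-constrained non-linear least squares on
log-parameters (the parameters span orders of magnitude across subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares

from .core import (
    ModelId,
    OmegaVector,
    PhysioParams,
    ThetaParams,
    omega_from_theta,
    physio_from_theta,
)
from .simulate import N_SEED, VentilationRecord, simulate_discrete

#: generous positive boxes around all reported subject-level values
DEFAULT_THETA_BOUNDS = (
    (0.01, 100.0),   # theta1, 1/l
    (0.01, 100.0),   # theta2, 1/min
    (0.001, 50.0),   # theta3, 1/min
    (0.01, 500.0),   # theta4, mmHg/min
)

#: bounds for the single-compartment lumped coefficients
DEFAULT_OMEGA1_BOUNDS = (
    (1e-5, 10.0),    # 1/(VL + alpha*lam*VB), 1/l
    (1e-3, 1e4),     # lam*VCO2/(VL + alpha*lam*VB), mmHg/(min*l) * l = mmHg/min
)

_J_INF = float("inf")


class FitFailureError(RuntimeError):
    """Every optimisation start diverged or failed."""

    def __init__(self, message: str, log: list):
        super().__init__(message)
        self.convergence_log = log


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the identification procedure.

    tau_grid : inclusive integer delay grid, samples (M3 only).  Default
        1..12 samples = 5..60 s at 5-s sampling, a physiologically
        plausible circulatory-delay window.
    n_starts : multi-start count; initial points are log-uniform within
        the bounds from a seeded generator.
    """

    tau_grid: tuple = tuple(range(1, 13))
    n_starts: int = 8
    theta_bounds: tuple = DEFAULT_THETA_BOUNDS
    omega1_bounds: tuple = DEFAULT_OMEGA1_BOUNDS
    ftol: float = 1e-14
    xtol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        grid = tuple(int(t) for t in self.tau_grid)
        if any(t < 0 for t in grid):
            raise ValueError("tau_grid entries must be non-negative integers")
        object.__setattr__(self, "tau_grid", grid)
        for lo, hi in self.theta_bounds + self.omega1_bounds:
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < lo < hi")


@dataclass
class FitResult:
    """Identification output for one subject and one candidate model."""

    model_id: ModelId
    omega_star: OmegaVector
    J_star: float
    predicted: np.ndarray
    tau_star: int = 0
    theta_star: Optional[ThetaParams] = None
    physio_star: Optional[PhysioParams] = None
    convergence_log: list = field(default_factory=list)
    tau_profile: Optional[dict] = None
    n_samples: int = 0

    def to_json_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "omega": self.omega_star.to_json_dict(),
            "J_mmHg2": self.J_star,
            "tau_samples": self.tau_star,
            "theta": None if self.theta_star is None else self.theta_star.to_json_dict(),
            "physio": None if self.physio_star is None else self.physio_star.to_json_dict(),
            "tau_profile": None
            if self.tau_profile is None
            else {str(k): v for k, v in self.tau_profile.items()},
            "n_samples": self.n_samples,
            "convergence_log": self.convergence_log,
        }

    @classmethod
    def from_json_dict(cls, d: dict, predicted: Optional[np.ndarray] = None) -> "FitResult":
        return cls(
            model_id=d["model_id"],
            omega_star=OmegaVector.from_json_dict(d["omega"]),
            J_star=d["J_mmHg2"],
            predicted=np.array([]) if predicted is None else predicted,
            tau_star=d["tau_samples"],
            theta_star=None if d["theta"] is None else ThetaParams.from_json_dict(d["theta"]),
            physio_star=None
            if d["physio"] is None
            else PhysioParams.from_json_dict(d["physio"]),
            tau_profile=None
            if d.get("tau_profile") is None
            else {int(k): v for k, v in d["tau_profile"].items()},
            n_samples=d.get("n_samples", 0),
            convergence_log=d.get("convergence_log", []),
        )


def objective_J(
    params: Union[ThetaParams, OmegaVector],
    tau: int,
    record: VentilationRecord,
    model_id: ModelId,
) -> float:
    """Mean-squared pure prediction error, mmHg^2, excluding the recursion
    seed samples.  Divergent simulations return +inf (infeasible point)."""
    xhat = simulate_discrete(
        model_id, params, record, tau=tau, on_divergence="cap"
    )
    if np.max(np.abs(xhat)) >= 1e7 or not np.all(np.isfinite(xhat)):
        return _J_INF
    ns = N_SEED[model_id]
    r = record.petco2[ns:] - xhat[ns:]
    return float(np.mean(r * r))


def _prediction_residuals(
    z: np.ndarray, record: VentilationRecord, model_id: ModelId, tau: int
) -> np.ndarray:
    """Residual vector at log-parameters z (finite even under divergence,
    thanks to the capped recursion, so trust-region steps stay defined)."""
    w = np.exp(z)
    if model_id == "M1":
        params = OmegaVector("M1", tuple(w))
    else:
        params = OmegaVector(
            model_id, tuple(omega_from_theta(_theta_unchecked(w, tau), model_id).coeffs)
        )
    xhat = simulate_discrete(model_id, params, record, tau=tau, on_divergence="cap")
    ns = N_SEED[model_id]
    return record.petco2[ns:] - xhat[ns:]


def _theta_unchecked(w: np.ndarray, tau: int) -> ThetaParams:
    return ThetaParams(float(w[0]), float(w[1]), float(w[2]), float(w[3]), tau=tau)


def _draw_starts(bounds: tuple, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    lo = np.log([b[0] for b in bounds])
    hi = np.log([b[1] for b in bounds])
    return rng.uniform(lo, hi, size=(n_starts, len(bounds)))


def _fit_fixed_tau(
    record: VentilationRecord,
    model_id: ModelId,
    tau: int,
    starts: np.ndarray,
    bounds: tuple,
    opts: FitOptions,
    log: list,
) -> tuple[Optional[np.ndarray], float]:
    """Multi-start bound-constrained least squares at one delay value.
    Returns (best parameter vector in natural scale, best J)."""
    lo = np.log([b[0] for b in bounds])
    hi = np.log([b[1] for b in bounds])
    ns = N_SEED[model_id]
    n_pred = len(record) - ns
    best_w, best_J = None, _J_INF
    for i, z0 in enumerate(starts):
        entry = {"tau": tau, "start": i, "J": None, "success": False, "message": ""}
        try:
            sol = least_squares(
                _prediction_residuals,
                np.clip(z0, lo, hi),
                bounds=(lo, hi),
                args=(record, model_id, tau),
                method="trf",
                ftol=opts.ftol,
                xtol=opts.xtol,
                gtol=opts.gtol,
                max_nfev=opts.max_nfev,
            )
            J = 2.0 * sol.cost / n_pred
            entry.update(
                J=J, success=bool(sol.success), nfev=int(sol.nfev),
                message=str(sol.message),
            )
            if J < best_J:
                best_J, best_w = J, np.exp(sol.x)
        except (ValueError, FloatingPointError) as exc:  # numerical breakdown
            entry["message"] = str(exc)
        log.append(entry)
    return best_w, best_J


def fit_model(
    record: VentilationRecord, model_id: ModelId, opts: FitOptions = FitOptions()
) -> FitResult:
    """Fit one candidate model to one record.

    M1/M2: multi-start minimisation over the lumped coefficients (M1) or
    the four rate parameters (M2).  M3: the inner optimisation is repeated
    for every delay on the grid (exhaustive search) and the pair with the
    minimum objective wins; the previous delay's optimum is recycled as an
    extra warm start.  Deterministic for a given record and options.
    """
    if len(record) * record.ts_s < 300.0:
        raise ValueError("record must cover at least 5 minutes")
    rng = np.random.default_rng(opts.seed)
    log: list = []

    if model_id == "M1":
        starts = _draw_starts(opts.omega1_bounds, opts.n_starts, rng)
        w, J = _fit_fixed_tau(record, "M1", 0, starts, opts.omega1_bounds, opts, log)
        if w is None:
            raise FitFailureError("all M1 starts failed", log)
        omega = OmegaVector("M1", tuple(w))
        predicted = simulate_discrete("M1", omega, record, on_divergence="raise")
        return FitResult(
            model_id="M1", omega_star=omega, J_star=J, predicted=predicted,
            convergence_log=log, n_samples=len(record),
        )

    starts = _draw_starts(opts.theta_bounds, opts.n_starts, rng)

    if model_id == "M2":
        w, J = _fit_fixed_tau(record, "M2", 0, starts, opts.theta_bounds, opts, log)
        if w is None:
            raise FitFailureError("all M2 starts failed", log)
        theta = _theta_unchecked(w, 0)
        omega = omega_from_theta(theta, "M2")
        predicted = simulate_discrete("M2", omega, record, on_divergence="raise")
        return FitResult(
            model_id="M2", omega_star=omega, J_star=J, predicted=predicted,
            theta_star=theta, physio_star=physio_from_theta(theta, ts_s=record.ts_s),
            convergence_log=log, n_samples=len(record),
        )

    if model_id != "M3":
        raise ValueError(f"unknown model_id {model_id!r}")
    if len(opts.tau_grid) == 0:
        raise ValueError("tau_grid must be non-empty for M3")

    profile: dict[int, float] = {}
    best: tuple[Optional[np.ndarray], float, int] = (None, _J_INF, -1)
    prev_w: Optional[np.ndarray] = None
    for tau in sorted(opts.tau_grid):
        tau_starts = starts
        if prev_w is not None:
            tau_starts = np.vstack([starts, np.log(prev_w)])
        w, J = _fit_fixed_tau(record, "M3", tau, tau_starts, opts.theta_bounds, opts, log)
        profile[tau] = J
        if w is not None:
            prev_w = w
            if J < best[1]:
                best = (w, J, tau)
    if best[0] is None:
        raise FitFailureError("all M3 starts failed on every tau", log)
    w, J, tau_star = best
    theta = _theta_unchecked(w, tau_star)
    omega = omega_from_theta(theta, "M3")
    predicted = simulate_discrete(
        "M3", omega, record, tau=tau_star, on_divergence="raise"
    )
    return FitResult(
        model_id="M3", omega_star=omega, J_star=J, predicted=predicted,
        tau_star=tau_star, theta_star=theta,
        physio_star=physio_from_theta(theta, ts_s=record.ts_s),
        convergence_log=log, tau_profile=profile, n_samples=len(record),
    )


def tau_profile(record: VentilationRecord, opts: FitOptions = FitOptions()) -> dict:
    """Per-delay optimal objective J*(tau) over the exhaustive grid (M3).
    Its argmin is fit_model's tau_star."""
    return fit_model(record, "M3", opts).tau_profile
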