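"""Model comparison metrics: RMSE, asymptotic variance, AIC, cohort tests.

Predictive capability is measured by the RMSE between measured and
pure-predicted PetCO2.  Reliability is measured by the Ljung-style
asymptotic parameter variance

    Var[Theta0 - Theta*] ~ (1/N) * lamN * SN,
    SN = [ (1/N) sum_k s(k) s(k)^T ]^{-1},   s(k) = d eps(k) / d Theta,

with lamN the residual variance.  Overall quality is ranked by the
small-sample-corrected Akaike Information Criterion

    AIC = N ln(lamN) + 2K + 2K(K+1)/(N - K - 1).

Residual conventions: the asymptotic variance defaults to *equation
error* residuals on the measured data (second forward difference minus
the regression prediction for M2/M3; first difference for M1) -- the
convention in which the parametric sensitivity has the closed form
s(k) = -(dOmega/dTheta)^T psi(k).  The AIC defaults to *pure prediction*
residuals, which are in mmHg for every model; the natural equation
errors carry different units across model orders (first- vs
second-difference), which would shift the cross-model AIC by an
arbitrary unit factor.  A switch on every metric selects either
convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import ModelId, OmegaVector, ThetaParams, omega_from_theta
from .simulate import (
    N_SEED,
    VentilationRecord,
    build_regressor_m1,
    build_regressor_m3,
    second_difference,
    simulate_discrete,
)

logger = logging.getLogger(__name__)

#: optimised quantities per model: Omega1 entries; Theta; Theta plus tau
DEFAULT_K = {"M1": 2, "M2": 4, "M3": 5}


@dataclass
class AsymptoticVariance:
    """Per-parameter asymptotic variance and percent standard deviation."""

    var: np.ndarray
    sd_pct: np.ndarray
    lam: float
    degenerate: bool = False


@dataclass
class EvaluationReport:
    subject_id: str
    model_id: ModelId
    rmse: float
    aic: float
    n_samples: int
    asym_sd_pct: Optional[np.ndarray] = None


@dataclass
class CohortComparison:
    """Cohort-level model comparison in the style of a median (IQR) table
    plus paired significance tests and AIC minimum-frequency counts."""

    summary: dict
    ttests: dict
    aic_win_counts: dict
    reports: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "summary": self.summary,
            "ttests": self.ttests,
            "aic_win_counts": self.aic_win_counts,
        }


def rmse(observed: np.ndarray, predicted: np.ndarray, n_seed: int = 0) -> float:
    """Root-mean-squared prediction error, mmHg, over the predicted samples
    (optionally excluding the recursion seed samples)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    r = observed[n_seed:] - predicted[n_seed:]
    return float(np.sqrt(np.mean(r * r)))


def _resolve_omega(
    params: Union[ThetaParams, OmegaVector], model_id: ModelId
) -> np.ndarray:
    if isinstance(params, ThetaParams):
        if model_id == "M1":
            raise ValueError("M1 requires an OmegaVector")
        return np.array(omega_from_theta(params, model_id).coeffs)
    if params.model_id != model_id:
        raise ValueError(f"params are for {params.model_id}, requested {model_id}")
    return np.array(params.coeffs)


def regressor_matrix(
    record: VentilationRecord, model_id: ModelId, tau: int = 0
) -> np.ndarray:
    """Stack the measured-data regression vectors psi(k).

    M2/M3 rows k = 0..n-3 (paired with second differences); M1 rows
    k = 0..n-2 (paired with first differences)."""
    x1 = record.petco2
    u = record.vdot
    n = len(record)
    ts = record.ts_min
    if model_id == "M1":
        return np.stack([build_regressor_m1(x1, u, k) for k in range(n - 1)])
    psi = np.stack([build_regressor_m3(x1, u, k, tau, ts) for k in range(n - 2)])
    if model_id == "M2":
        psi = np.delete(psi, 3, axis=1)
    return psi


def equation_error_residuals(
    params: Union[ThetaParams, OmegaVector],
    tau: int,
    record: VentilationRecord,
    model_id: ModelId,
) -> tuple[np.ndarray, float]:
    """Equation-error residual series on measured data and its variance.

    M2/M3: eps(k) = second difference of x1 minus Omega^T psi(k, tau);
    M1: first difference of x1 minus Omega1^T psi1(k).
    """
    if len(record) < 4:
        raise ValueError("record too short for difference residuals")
    w = _resolve_omega(params, model_id)
    x1 = record.petco2
    ts = record.ts_min
    psi = regressor_matrix(record, model_id, tau)
    if model_id == "M1":
        lhs = np.diff(x1) / ts
    else:
        lhs = np.array(
            [second_difference(x1, k, ts) for k in range(len(record) - 2)]
        )
    res = lhs - psi @ w
    return res, float(np.mean(res * res))


def prediction_residuals(
    params: Union[ThetaParams, OmegaVector],
    tau: int,
    record: VentilationRecord,
    model_id: ModelId,
) -> tuple[np.ndarray, float]:
    """Pure-prediction residuals x1 - x1_hat (seed samples excluded)."""
    xhat = simulate_discrete(model_id, params, record, tau=tau, on_divergence="raise")
    ns = N_SEED[model_id]
    res = record.petco2[ns:] - xhat[ns:]
    return res, float(np.mean(res * res))


def omega_jacobian(theta: ThetaParams, model_id: ModelId) -> np.ndarray:
    """Closed-form Jacobian dOmega/dTheta of the lumping (rows follow the
    coefficient order, columns theta1..theta4)."""
    t1, t2, t3, t4 = theta.as_tuple()
    rows = [
        [1.0, 0.0, 0.0, 0.0],   # theta1
        [0.0, 1.0, 1.0, 0.0],   # theta2 + theta3
        [t3, 0.0, t1, 0.0],     # theta1*theta3
        [0.0, t3, t2, 0.0],     # theta2*theta3
        [0.0, t4, 0.0, t2],     # theta2*theta4
    ]
    if model_id == "M3":
        return np.array(rows)
    if model_id == "M2":
        return np.array([rows[0], rows[1], rows[2], rows[4]])
    raise ValueError("omega_jacobian is defined for M2 and M3 only")


def asymptotic_variance(
    params: Union[ThetaParams, OmegaVector],
    tau: int,
    record: VentilationRecord,
    model_id: ModelId,
    residual_kind: str = "equation",
) -> AsymptoticVariance:
    """Ljung-style asymptotic variance of the parameter estimates.

    For M2/M3 the sensitivity of the equation error w.r.t. Theta is the
    closed form -(dOmega/dTheta)^T psi(k, tau); for M1 the parameters are
    the lumped coefficients themselves and the sensitivity is -psi1(k).
    A near-singular sensitivity covariance is handled by pseudo-inverse
    and flagged as degenerate (in this model family the weakly excited
    direction is the metabolic term theta4, whose regressor is constant).
    `residual_kind` selects the residual variance lamN ("equation" or
    "prediction"); sensitivities always use the equation form.
    """
    if residual_kind == "equation":
        _, lam = equation_error_residuals(params, tau, record, model_id)
    elif residual_kind == "prediction":
        _, lam = prediction_residuals(params, tau, record, model_id)
    else:
        raise ValueError("residual_kind must be 'equation' or 'prediction'")

    psi = regressor_matrix(record, model_id, tau)
    n = psi.shape[0]
    if model_id == "M1":
        sens = -psi
        ref = np.abs(_resolve_omega(params, model_id))
    else:
        if not isinstance(params, ThetaParams):
            raise ValueError("asymptotic variance over Theta needs ThetaParams")
        sens = -(psi @ omega_jacobian(params, model_id))
        ref = np.abs(np.array(params.as_tuple()))
    if n <= sens.shape[1]:
        raise ValueError("need more residuals than parameters")

    cov = (sens.T @ sens) / n
    degenerate = False
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > 1e12:
        degenerate = True
        SN = np.linalg.pinv(cov)
    else:
        SN = np.linalg.inv(cov)
    var = lam / n * np.diag(SN)
    var = np.maximum(var, 0.0)
    sd_pct = 100.0 * np.sqrt(var) / ref
    return AsymptoticVariance(var=var, sd_pct=sd_pct, lam=lam, degenerate=degenerate)


def aic(
    params: Union[ThetaParams, OmegaVector],
    tau: int,
    record: VentilationRecord,
    model_id: ModelId,
    K_override: Optional[int] = None,
    residual_kind: str = "prediction",
) -> float:
    """Small-sample-corrected AIC with the module's residual convention.

    K defaults to the number of optimised quantities: 2 (M1), 4 (M2),
    5 (M3: Theta plus the delay)."""
    K = DEFAULT_K[model_id] if K_override is None else int(K_override)
    if residual_kind == "equation":
        res, lam = equation_error_residuals(params, tau, record, model_id)
    elif residual_kind == "prediction":
        res, lam = prediction_residuals(params, tau, record, model_id)
    else:
        raise ValueError("residual_kind must be 'equation' or 'prediction'")
    N = len(res)
    if N <= K + 1:
        raise ValueError(f"AIC correction undefined: N={N} <= K+1={K + 1}")
    if lam <= 0:
        raise ValueError("zero residual variance: AIC is -inf (perfect fit)")
    return float(N * np.log(lam) + 2 * K + 2 * K * (K + 1) / (N - K - 1))


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p)."""
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def evaluate_fit(
    record: VentilationRecord, fit, residual_kind: str = "prediction"
) -> EvaluationReport:
    """Per-subject, per-model metrics for one fit result."""
    ns = N_SEED[fit.model_id]
    params = fit.theta_star if fit.theta_star is not None else fit.omega_star
    av = None
    try:
        av = asymptotic_variance(
            params, fit.tau_star, record, fit.model_id, residual_kind
        )
    except (ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("asymptotic variance unavailable: %s", exc)
    return EvaluationReport(
        subject_id=record.subject_id,
        model_id=fit.model_id,
        rmse=rmse(record.petco2, fit.predicted, n_seed=ns),
        aic=aic(params, fit.tau_star, record, fit.model_id, residual_kind=residual_kind),
        n_samples=len(record),
        asym_sd_pct=None if av is None else av.sd_pct,
    )


def _median_iqr(values: Sequence[float]) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(v)),
        "q25": float(np.percentile(v, 25)),
        "q75": float(np.percentile(v, 75)),
    }


def compare_cohort(
    fits: dict, records: dict, residual_kind: str = "prediction"
) -> CohortComparison:
    """Cohort-level comparison of the fitted candidate models.

    `fits` maps subject_id -> {model_id -> FitResult}; `records` maps
    subject_id -> VentilationRecord.  Produces per-model median (IQR)
    summaries of RMSE and physiologic parameters, two-sided paired t-tests
    on per-subject RMSE for each model pair and on each theta's asymptotic
    variance (M2 vs M3), and AIC minimum-frequency counts.
    """
    subjects = sorted(fits)
    if not subjects:
        raise ValueError("no fits to compare")
    models = sorted({m for s in subjects for m in fits[s]})
    for s in subjects:
        missing = set(models) - set(fits[s])
        if missing:
            raise ValueError(f"subject {s} lacks fits for {sorted(missing)}")

    reports = {
        s: {m: evaluate_fit(records[s], fits[s][m], residual_kind) for m in models}
        for s in subjects
    }

    summary: dict = {}
    for m in models:
        entry = {"rmse_mmHg": _median_iqr([reports[s][m].rmse for s in subjects])}
        if all(fits[s][m].physio_star is not None for s in subjects):
            for attr, key in [
                ("VL", "VL_l"), ("VB", "VB_l"), ("Q", "Q_lpm"), ("VCO2", "VCO2_lpm_STPD"),
            ]:
                entry[key] = _median_iqr(
                    [getattr(fits[s][m].physio_star, attr) for s in subjects]
                )
            entry["tau_s"] = _median_iqr(
                [fits[s][m].tau_star * records[s].ts_s for s in subjects]
            )
        summary[m] = entry

    ttests: dict = {}
    if len(subjects) < 3:
        warnings.warn("fewer than 3 subjects: paired t-tests skipped")
    else:
        for i, ma in enumerate(models):
            for mb in models[i + 1:]:
                t, p = paired_ttest(
                    [reports[s][ma].rmse for s in subjects],
                    [reports[s][mb].rmse for s in subjects],
                )
                ttests[f"rmse_{ma}_vs_{mb}"] = {"t": t, "p": p}
        if "M2" in models and "M3" in models:
            ok = [
                s for s in subjects
                if reports[s]["M2"].asym_sd_pct is not None
                and reports[s]["M3"].asym_sd_pct is not None
            ]
            if len(ok) >= 3:
                for j in range(4):
                    t, p = paired_ttest(
                        [reports[s]["M2"].asym_sd_pct[j] for s in ok],
                        [reports[s]["M3"].asym_sd_pct[j] for s in ok],
                    )
                    ttests[f"asym_var_theta{j + 1}_M2_vs_M3"] = {"t": t, "p": p}

    wins = {m: 0 for m in models}
    for s in subjects:
        best = min(models, key=lambda m: reports[s][m].aic)
        wins[best] += 1
    if len(models) >= 2:
        for name, res in ttests.items():
            logger.info("%s: t=%.3f p=%.4g%s", name, res["t"], res["p"],
                        "  (significant at p<0.05)" if res["p"] < 0.05 else "")

    flat_reports = [reports[s][m] for s in subjects for m in models]
    return CohortComparison(
        summary=summary, ttests=ttests, aic_win_counts=wins, reports=flat_reports
    )
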