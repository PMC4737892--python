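"""End-to-end numerical studies over synthetic cohorts.

Each function runs one self-contained study -- steady-state validation,
discretisation convergence, parameter recovery, cohort model comparison --
and returns plain dictionaries of the quantities a report would table.
The analysis drivers, the test suite, and the acceptance script all call
these; nothing here touches the file system.
"""

from __future__ import annotations

import statistics
from typing import Optional

import numpy as np

from .cohort import (
    PETCO2_TARGET,
    ParamDistribution,
    ProtocolSpec,
    SubjectSpec,
    draw_physio_from_iqr,
    generate_cohort,
    generate_protocol,
    generate_subject,
)
from .core import PhysioParams, RespiratoryConstants, steady_state_petco2, theta_from_physio
from .evaluate import compare_cohort
from .identify import FitOptions, fit_model
from .simulate import VentilationRecord, simulate_continuous_m3, simulate_discrete

PHYSIO_ATTRS = ("VL", "VB", "Q", "VCO2")


def steady_state_study(
    u_lpm: float = 2.24,
    physio: Optional[PhysioParams] = None,
    duration_s: float = 7200.0,
    dt_s: float = 0.1,
) -> dict:
    """Constant-ventilation convergence of the continuous simulator to the
    hyperbolic steady state x1 = lam*VCO2/u.

    The slow cohort-median mode (whole-body CO2 store washout) has a time
    constant of roughly 16 min, so a two-hour horizon is used to resolve
    the 0.1% band.
    """
    if physio is None:
        physio = PhysioParams(VL=2.28, VB=4.67, Q=1.20, VCO2=0.12, tau1=10, tau2=10)
    c = RespiratoryConstants()
    target = steady_state_petco2(physio.VCO2, u_lpm, c)
    out = simulate_continuous_m3(
        physio, c, u_fn=lambda t: u_lpm, x1_0=40.0,
        duration_s=duration_s, dt_s=dt_s,
    )
    final = float(out.x1[-1])
    return {
        "steady_state_mmHg": final,
        "closed_form_mmHg": target,
        "rel_err": abs(final - target) / target,
    }


def convergence_study(
    physio: Optional[PhysioParams] = None,
    protocol_seed: int = 3,
    steps_s: tuple = (5.0, 2.5, 1.25),
    dt_ref_s: float = 0.05,
) -> dict:
    """Discrete-continuous consistency: max discrepancy between the
    forward-difference recursion and the fine-step delay-ODE reference on
    a 3-segment protocol, halving the sampling step."""
    if physio is None:
        physio = PhysioParams(VL=2.28, VB=4.67, Q=1.20, VCO2=0.12, tau1=10, tau2=10)
    prot = generate_protocol(
        ProtocolSpec(seed=protocol_seed, n_segments=3, duration_min=20.0)
    )
    dur = float(prot.t_s[-1])
    ref = simulate_continuous_m3(
        physio, u_fn=prot.u_fn, x1_0=46.0, duration_s=dur, dt_s=dt_ref_s
    )
    errors = []
    for ts in steps_s:
        n = int(dur / ts) + 1
        t = np.arange(n) * ts
        u = np.array([prot.u_fn(ti) for ti in t])
        th = theta_from_physio(physio, ts_s=ts)
        stride = int(round(ts / dt_ref_s))
        x1c = ref.x1[::stride][:n]
        rec = VentilationRecord(ts, t, np.full(n, 46.0), u)
        xh = simulate_discrete("M3", th, rec, init=(x1c[0], x1c[1]), tau=th.tau)
        errors.append(float(np.max(np.abs(xh - x1c))))
    orders = [
        float(np.log2(errors[i] / errors[i + 1])) for i in range(len(errors) - 1)
    ]
    return {"steps_s": list(steps_s), "max_abs_err_mmHg": errors, "orders": orders}


def recovery_study(
    n_subjects: int = 10,
    noise_sd: float = 0.0,
    seed: int = 42,
    fit_opts: Optional[FitOptions] = None,
    dist: ParamDistribution = ParamDistribution(),
) -> dict:
    """Parameter recovery on self-generated subjects.

    Ground-truth physiology is drawn log-uniformly within the reported
    interquartile boxes with delays of 2..10 samples; records are produced
    by the identification recursion itself (plus optional measurement
    noise), so the noiseless case isolates optimiser behaviour and the
    noisy case isolates the information content of the data.
    """
    c = RespiratoryConstants()
    rng = np.random.default_rng(seed)
    if fit_opts is None:
        fit_opts = FitOptions(seed=int(rng.integers(2**31 - 1)))
    subjects = []
    for i in range(n_subjects):
        p = draw_physio_from_iqr(rng, dist)
        spec = SubjectSpec(
            physio=p,
            protocol=ProtocolSpec(seed=int(rng.integers(2**31 - 1))),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
            subject_id=f"R{i:02d}",
            u_mean_target=c.lam * p.VCO2 / PETCO2_TARGET,
        )
        sub = generate_subject(spec, c, method="discrete")
        fr = fit_model(sub.record, "M3", fit_opts)
        rel = {
            a: abs(getattr(fr.physio_star, a) - getattr(p, a)) / getattr(p, a)
            for a in PHYSIO_ATTRS
        }
        theta_rel = [
            abs(e - t) / t
            for e, t in zip(fr.theta_star.as_tuple(), sub.theta.as_tuple())
        ]
        subjects.append(
            {
                "subject_id": spec.subject_id,
                "tau_true": sub.theta.tau,
                "tau_est": fr.tau_star,
                "J_star": fr.J_star,
                "theta_rel_err": theta_rel,
                "physio_rel_err": rel,
            }
        )
    return {
        "subjects": subjects,
        "n_tau_exact": sum(s["tau_est"] == s["tau_true"] for s in subjects),
        "n_tau_within_1": sum(
            abs(s["tau_est"] - s["tau_true"]) <= 1 for s in subjects
        ),
        "n_theta_within_1pct": sum(
            max(s["theta_rel_err"]) < 0.01 for s in subjects
        ),
        "n_J_below_1e10": sum(s["J_star"] < 1e-10 for s in subjects),
        "median_rel_err": {
            a: statistics.median(s["physio_rel_err"][a] for s in subjects)
            for a in PHYSIO_ATTRS
        },
    }


def cohort_comparison_study(
    n_subjects: int = 25,
    seed: int = 7,
    noise_sd: float = 0.5,
    fit_opts: Optional[FitOptions] = None,
    models: tuple = ("M1", "M2", "M3"),
) -> dict:
    """The headline cohort analysis: generate a continuous-simulated M3
    cohort (delays 10-60 s), fit every candidate model per subject, and
    compare by RMSE, paired t-tests, and AIC win counts."""
    if fit_opts is None:
        fit_opts = FitOptions(seed=seed)
    cohort = generate_cohort(
        n_subjects, master_seed=seed, noise_sd=noise_sd, method="continuous"
    )
    fits, records = {}, {}
    for sub in cohort:
        sid = sub.record.subject_id
        records[sid] = sub.record
        fits[sid] = {m: fit_model(sub.record, m, fit_opts) for m in models}
    comparison = compare_cohort(fits, records)
    out = {
        "comparison": comparison,
        "fits": fits,
        "records": records,
        "truth": {s.record.subject_id: s for s in cohort},
        "rmse_median": {
            m: comparison.summary[m]["rmse_mmHg"]["median"] for m in models
        },
        "aic_win_counts": comparison.aic_win_counts,
        "ttests": comparison.ttests,
    }
    return out
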