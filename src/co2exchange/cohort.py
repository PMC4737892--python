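"""Synthetic ventilation protocols and subject cohorts.

The clinical records behind this analysis are not publicly deposited, so
every downstream step is exercised on synthetic subjects that emulate the
study's statistical structure: ~24-min trend records sampled every 5 s,
median PetCO2 near 40.8 mmHg, median minute ventilation near 2.24 lpm, and
large within-subject ventilation excursions (>30 % deviation from the
within-subject mean) driven by caregiver-style changes in respiratory rate
and tidal volume.

Ground truth is the two-compartment delay model: each subject's PetCO2 is
forward-simulated from drawn physiology (log-normal, calibrated to the
reported subject-level medians and IQRs) and corrupted with additive
Gaussian measurement noise.  Ventilation is u = RR * TV with no dead-space
subtraction (the models assume minute ventilation approximates alveolar
ventilation).  The per-subject ventilation level is titrated to a
normocapnic target -- mirroring how caregivers set the ventilator -- so
that the cohort PetCO2 distribution stays in the observed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .core import (
    PhysioParams,
    RespiratoryConstants,
    ThetaParams,
    omega_from_theta,
    steady_state_petco2,
    theta_from_physio,
)
from .simulate import (
    VentilationRecord,
    simulate_continuous_m3,
    simulate_discrete,
)

#: normocapnic end-tidal CO2 target used to titrate ventilation, mmHg
PETCO2_TARGET = 40.8


class ProtocolGenerationError(RuntimeError):
    """The requested ventilation excursion could not be realised."""


@dataclass(frozen=True)
class ProtocolSpec:
    """A caregiver-style ventilator protocol: piecewise settings with
    first-order transitions.

    duration_min         : record length (study records averaged ~24 min)
    n_segments           : number of constant-setting segments
    rr_range             : respiratory rate draw range, 1/min
    tv_range_ml          : tidal volume draw range, ml
    ie_range             : I:E ratio annotation range
    ppeak_range_cmH2O    : peak-pressure annotation range
    transition_tc_s      : first-order smoothing time constant, s
    min_excursion        : required max |u - mean(u)| / mean(u)
    """

    duration_min: float = 24.0
    n_segments: int = 5
    rr_range: tuple = (7.0, 13.0)
    tv_range_ml: tuple = (150.0, 300.0)
    ie_range: tuple = (0.79, 1.23)
    ppeak_range_cmH2O: tuple = (12.5, 13.8)
    transition_tc_s: float = 15.0
    ts_s: float = 5.0
    min_excursion: float = 0.40
    max_attempts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min <= 5.0:
            raise ValueError("duration must exceed 5 minutes")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        for name in ("rr_range", "tv_range_ml", "ie_range", "ppeak_range_cmH2O"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        if self.transition_tc_s <= 0 or self.ts_s <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class Protocol:
    """A realised protocol: the smooth ventilation input u(t) plus the
    per-sample setting annotations."""

    spec: ProtocolSpec
    t_s: np.ndarray
    vdot: np.ndarray
    settings: dict
    u_fn: Callable[[float], float]
    segment_targets_lpm: np.ndarray


def rescale_protocol(prot: Protocol, u_mean_target: float) -> Protocol:
    """Rescale a realised protocol so its mean ventilation hits a target
    (caregiver titration: tidal volumes are adjusted to the patient while
    the relative excursion pattern is preserved)."""
    if u_mean_target <= 0:
        raise ValueError("u_mean_target must be positive")
    s = u_mean_target / float(np.mean(prot.vdot))
    fn = prot.u_fn
    settings = dict(prot.settings)
    settings["tv_ml"] = settings["tv_ml"] * s
    return Protocol(
        spec=prot.spec,
        t_s=prot.t_s,
        vdot=prot.vdot * s,
        settings=settings,
        u_fn=lambda t, _fn=fn, _s=s: _fn(t) * _s,
        segment_targets_lpm=prot.segment_targets_lpm * s,
    )


def _make_u_fn(
    targets: np.ndarray, seg_len_s: float, tc_s: float
) -> Callable[[float], float]:
    """Piecewise first-order relaxation toward each segment's target.
    Continuous across segment boundaries; the first segment starts on
    target (pre-record steady breathing)."""
    starts = np.empty(len(targets))
    starts[0] = targets[0]
    for i in range(1, len(targets)):
        # value reached at the end of the previous segment
        prev = targets[i - 1] + (starts[i - 1] - targets[i - 1]) * math.exp(
            -seg_len_s / tc_s
        )
        starts[i] = prev

    def u_fn(t: float) -> float:
        if t <= 0:
            return float(targets[0])
        i = min(int(t / seg_len_s), len(targets) - 1)
        dt = t - i * seg_len_s
        return float(targets[i] + (starts[i] - targets[i]) * math.exp(-dt / tc_s))

    return u_fn


def generate_protocol(spec: ProtocolSpec, u_scale: float = 1.0) -> Protocol:
    """Draw a ventilation protocol meeting the excursion requirement.

    Per-segment RR and TV are drawn uniformly from the configured ranges and
    combined as u = RR * TV (l/min), optionally scaled by `u_scale`
    (ventilation titration).  Segments are redrawn up to `max_attempts`
    times until max |u - mean(u)| / mean(u) >= min_excursion on the
    sampled series.  Deterministic for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_min * 60.0 / spec.ts_s))
    t = np.arange(n) * spec.ts_s
    seg_len_s = spec.duration_min * 60.0 / spec.n_segments

    for _ in range(spec.max_attempts):
        rr = rng.uniform(*spec.rr_range, size=spec.n_segments)
        tv = rng.uniform(*spec.tv_range_ml, size=spec.n_segments)
        ie = rng.uniform(*spec.ie_range, size=spec.n_segments)
        ppeak = rng.uniform(*spec.ppeak_range_cmH2O, size=spec.n_segments)
        targets = rr * tv / 1000.0 * u_scale
        u_fn = _make_u_fn(targets, seg_len_s, spec.transition_tc_s)
        u = np.array([u_fn(ti) for ti in t])
        mean_u = float(np.mean(u))
        if mean_u > 0 and np.max(np.abs(u - mean_u)) / mean_u >= spec.min_excursion:
            seg_idx = np.minimum((t / seg_len_s).astype(int), spec.n_segments - 1)
            settings = {
                "rr_per_min": rr[seg_idx],
                "tv_ml": tv[seg_idx] * u_scale,
                "ie_ratio": ie[seg_idx],
                "ppeak_cmH2O": ppeak[seg_idx],
            }
            return Protocol(
                spec=spec, t_s=t, vdot=u, settings=settings, u_fn=u_fn,
                segment_targets_lpm=targets,
            )
    raise ProtocolGenerationError(
        f"could not reach {spec.min_excursion:.0%} ventilation excursion in "
        f"{spec.max_attempts} attempts; widen rr_range/tv_range or add segments"
    )


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic subject: ground-truth physiology, a protocol, and the
    measurement-noise level (default 0.5 mmHg, ~1 % of normocapnic
    PetCO2)."""

    physio: PhysioParams
    protocol: ProtocolSpec = ProtocolSpec()
    noise_sd: float = 0.5
    x1_0: Optional[float] = None
    seed: int = 0
    subject_id: str = ""
    #: titrated mean minute ventilation, l/min (None: leave the protocol as drawn)
    u_mean_target: Optional[float] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SubjectData:
    """A generated record together with its generating ground truth."""

    record: VentilationRecord
    physio: PhysioParams
    theta: ThetaParams
    tau_true_s: float


def generate_subject(
    spec: SubjectSpec,
    c: RespiratoryConstants = RespiratoryConstants(),
    method: str = "continuous",
    dt_s: float = 0.1,
) -> SubjectData:
    """Synthesise one subject's record from ground-truth dynamics.

    method="continuous": integrates the delay ODEs at a fine step and
    samples the alveolar tension on the 5-s trend grid (the realistic
    route: the fitted discrete models then face genuine discretisation
    error).  method="discrete": runs the exact identification recursion
    itself (the self-consistent route used by parameter-recovery
    oracles).  Gaussian noise is added to PetCO2 only; ventilation is
    treated as exactly known.
    """
    protocol = generate_protocol(spec.protocol)
    if spec.u_mean_target is not None:
        protocol = rescale_protocol(protocol, spec.u_mean_target)
    p = spec.physio
    theta = theta_from_physio(p, c, ts_s=spec.protocol.ts_s)
    x1_0 = (
        spec.x1_0
        if spec.x1_0 is not None
        else steady_state_petco2(p.VCO2, protocol.u_fn(0.0), c)
    )

    if method == "continuous":
        duration = protocol.t_s[-1]
        out = simulate_continuous_m3(
            p, c, protocol.u_fn, x1_0=x1_0, duration_s=duration, dt_s=dt_s
        )
        stride = int(round(spec.protocol.ts_s / dt_s))
        x1 = out.x1[:: stride][: len(protocol.t_s)]
    elif method == "discrete":
        clean = VentilationRecord(
            ts_s=spec.protocol.ts_s,
            t_s=protocol.t_s,
            petco2=np.full(len(protocol.t_s), x1_0),
            vdot=protocol.vdot,
            subject_id=spec.subject_id,
        )
        x1 = simulate_discrete(
            "M3", omega_from_theta(theta, "M3"), clean,
            init=(x1_0, x1_0), tau=theta.tau, on_divergence="raise",
        )
    else:
        raise ValueError("method must be 'continuous' or 'discrete'")

    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=len(x1)) if spec.noise_sd > 0 else 0.0
    record = VentilationRecord(
        ts_s=spec.protocol.ts_s,
        t_s=protocol.t_s,
        petco2=x1 + noise,
        vdot=protocol.vdot,
        settings=protocol.settings,
        subject_id=spec.subject_id,
    )
    return SubjectData(
        record=record, physio=p, theta=theta, tau_true_s=p.tau_total_s
    )


@dataclass(frozen=True)
class ParamDistribution:
    """Log-normal population of the four physical parameters, calibrated
    so the medians sit at the reported subject-level medians and the
    quartile ratios match the reported IQRs.  Draws are truncated by
    resampling to the central 90 % of each marginal (the unbounded tails
    produce circulation rates that are not physiologic at trend-sampling
    resolution).
    """

    medians: dict = field(
        default_factory=lambda: {"VL": 2.28, "VB": 4.67, "Q": 1.20, "VCO2": 0.12}
    )
    iqrs: dict = field(
        default_factory=lambda: {
            "VL": (1.36, 4.63),
            "VB": (1.56, 9.73),
            "Q": (0.39, 2.95),
            "VCO2": (0.04, 0.15),
        }
    )
    tau_range_s: tuple = (10.0, 60.0)
    truncate_q: tuple = (0.05, 0.95)

    def sigma(self, name: str) -> float:
        q1, q3 = self.iqrs[name]
        if not (0 < q1 < q3):
            raise ValueError(f"invalid IQR for {name}")
        return math.log(q3 / q1) / (2.0 * 0.6744897501960817)

    def draw(self, name: str, rng: np.random.Generator) -> float:
        mu = math.log(self.medians[name])
        sd = self.sigma(name)
        z_lo = _norm_ppf(self.truncate_q[0])
        z_hi = _norm_ppf(self.truncate_q[1])
        while True:
            z = rng.standard_normal()
            if z_lo <= z <= z_hi:
                return math.exp(mu + sd * z)


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def draw_physio_from_iqr(
    rng: np.random.Generator,
    dist: ParamDistribution = ParamDistribution(),
    tau_samples_range: tuple = (2, 10),
    ts_s: float = 5.0,
) -> PhysioParams:
    """Draw ground-truth physiology log-uniformly within the reported
    subject-level interquartile boxes, with an integer-sample transport
    delay.  This is the calibrated parameter range used by the
    parameter-recovery studies (the log-normal population with tails is
    used for full cohort emulation instead)."""
    vals = {}
    for name, (q1, q3) in dist.iqrs.items():
        vals[name] = math.exp(rng.uniform(math.log(q1), math.log(q3)))
    tau = int(rng.integers(tau_samples_range[0], tau_samples_range[1] + 1))
    return PhysioParams(
        VL=vals["VL"], VB=vals["VB"], Q=vals["Q"], VCO2=vals["VCO2"],
        tau1=tau * ts_s / 2.0, tau2=tau * ts_s / 2.0,
    )


def generate_cohort(
    n_subjects: int,
    dist: ParamDistribution = ParamDistribution(),
    master_seed: int = 0,
    protocol: ProtocolSpec = ProtocolSpec(),
    noise_sd: float = 0.5,
    method: str = "continuous",
    titrate: bool = True,
) -> list[SubjectData]:
    """Generate a reproducible cohort of synthetic subjects.

    Physiology is drawn per subject from `dist`; the total transport delay
    is uniform on `dist.tau_range_s` and split evenly between the two
    legs (only the sum is identifiable).  With `titrate=True` each
    subject's tidal-volume scale is set so that ventilation at the
    nominal mid-protocol level targets normocapnia (PetCO2 ~ 40.8 mmHg),
    emulating caregiver titration and keeping the cohort's PetCO2
    distribution in the observed range.  Fully reproducible from
    `master_seed`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(master_seed)
    c = RespiratoryConstants()
    subjects = []
    for i in range(n_subjects):
        physio = PhysioParams(
            VL=dist.draw("VL", rng),
            VB=dist.draw("VB", rng),
            Q=dist.draw("Q", rng),
            VCO2=dist.draw("VCO2", rng),
            tau1=0.0,
            tau2=0.0,
        )
        tau_total = rng.uniform(*dist.tau_range_s)
        physio = replace(physio, tau1=tau_total / 2.0, tau2=tau_total / 2.0)
        u_target = c.lam * physio.VCO2 / PETCO2_TARGET if titrate else None
        spec = SubjectSpec(
            physio=physio,
            protocol=replace(protocol, seed=int(rng.integers(2**31 - 1))),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
            subject_id=f"S{i:02d}",
            u_mean_target=u_target,
        )
        subjects.append(generate_subject(spec, c, method=method))
    return subjects
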