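"""Parameter algebra for the CO2 gas-exchange candidate models.

The two-compartment picture: CO2 is produced in the tissues at a constant
metabolic rate, carried to the lungs by venous blood (cardiac output Q),
and excreted by alveolar ventilation.  Tension and concentration are linked
by the linearised Henry's law C = alpha*P + beta.  Lumping gives four
identifiable rate parameters

    theta1 = 1/VL            [1/l]
    theta2 = alpha*lam*Q/VL  [1/min]
    theta3 = Q/VB            [1/min]
    theta4 = VCO2/(alpha*VB) [mmHg/min]

plus a combined circulatory transport delay tau = tau1 + tau2, which is the
only delay quantity visible in end-tidal CO2 data.  The three candidate
models are:

* M3 -- two compartments with transport delay (5 lumped coefficients),
* M2 -- the same without delay (4 coefficients),
* M1 -- lungs and tissues merged into one compartment (2 coefficients).

This module holds the physiologic constants, the parameter containers, and
the (partially invertible) maps physio <-> theta <-> omega.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

ModelId = Literal["M1", "M2", "M3"]

#: ordered lumped-coefficient count per candidate model
OMEGA_LENGTH = {"M1": 2, "M2": 4, "M3": 5}


class NonPhysicalParameterError(ValueError):
    """A parameter value is outside its physically admissible domain."""


@dataclass(frozen=True)
class RespiratoryConstants:
    """Physiologic constants of the gas-exchange conversion.

    alpha : CO2 solubility slope, l_STPD/(mmHg*l)
    beta  : CO2 concentration offset, l_STPD/l
    lam   : BTPS/STPD tension conversion factor, mmHg
    pi_co2: inspired CO2 tension, mmHg (zero for CO2-free inspirate)
    """

    alpha: float = 0.0065
    beta: float = 0.244
    lam: float = 863.0
    pi_co2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.lam > 0):
            raise NonPhysicalParameterError("alpha and lam must be positive")
        if self.pi_co2 < 0:
            raise NonPhysicalParameterError("pi_co2 must be non-negative")

    def to_json_dict(self) -> dict:
        return {
            "alpha_lSTPD_per_mmHg_l": self.alpha,
            "beta_lSTPD_per_l": self.beta,
            "lam_mmHg": self.lam,
            "pi_co2_mmHg": self.pi_co2,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RespiratoryConstants":
        return cls(
            alpha=d["alpha_lSTPD_per_mmHg_l"],
            beta=d["beta_lSTPD_per_l"],
            lam=d["lam_mmHg"],
            pi_co2=d.get("pi_co2_mmHg", 0.0),
        )


@dataclass(frozen=True)
class PhysioParams:
    """Physical respiratory parameters.

    VL   : effective lung volume, l
    VB   : effective tissue volume, l
    Q    : cardiac output, l/min
    VCO2 : metabolic CO2 production, l_STPD/min
    tau1 : tissue->lung transport delay, s
    tau2 : heart->tissue transport delay, s
    combined_delay_only : True when tau1 carries a combined delay recovered
        from data (tau1 and tau2 are not separately identifiable).
    """

    VL: float
    VB: float
    Q: float
    VCO2: float
    tau1: float = 0.0
    tau2: float = 0.0
    combined_delay_only: bool = False

    def __post_init__(self) -> None:
        for name in ("VL", "VB", "Q", "VCO2"):
            if not getattr(self, name) > 0:
                raise NonPhysicalParameterError(f"{name} must be strictly positive")
        if self.tau1 < 0 or self.tau2 < 0:
            raise NonPhysicalParameterError("delays must be non-negative")

    @property
    def tau_total_s(self) -> float:
        return self.tau1 + self.tau2

    def to_json_dict(self) -> dict:
        return {
            "VL_l": self.VL,
            "VB_l": self.VB,
            "Q_lpm": self.Q,
            "VCO2_lpm_STPD": self.VCO2,
            "tau1_s": self.tau1,
            "tau2_s": self.tau2,
            "combined_delay_only": self.combined_delay_only,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PhysioParams":
        return cls(
            VL=d["VL_l"], VB=d["VB_l"], Q=d["Q_lpm"], VCO2=d["VCO2_lpm_STPD"],
            tau1=d.get("tau1_s", 0.0), tau2=d.get("tau2_s", 0.0),
            combined_delay_only=d.get("combined_delay_only", False),
        )


@dataclass(frozen=True)
class ThetaParams:
    """Identifiable lumped rate parameters plus the combined delay.

    theta1 [1/l], theta2 [1/min], theta3 [1/min], theta4 [mmHg/min];
    tau is the combined transport delay in integer samples.
    """

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    tau: int = 0

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3", "theta4"):
            if not getattr(self, name) > 0:
                raise NonPhysicalParameterError(f"{name} must be strictly positive")
        if self.tau < 0 or int(self.tau) != self.tau:
            raise NonPhysicalParameterError("tau must be a non-negative integer sample count")
        object.__setattr__(self, "tau", int(self.tau))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.theta1, self.theta2, self.theta3, self.theta4)

    def to_json_dict(self) -> dict:
        return {
            "theta1_per_l": self.theta1,
            "theta2_per_min": self.theta2,
            "theta3_per_min": self.theta3,
            "theta4_mmHg_per_min": self.theta4,
            "tau_samples": self.tau,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ThetaParams":
        return cls(
            theta1=d["theta1_per_l"], theta2=d["theta2_per_min"],
            theta3=d["theta3_per_min"], theta4=d["theta4_mmHg_per_min"],
            tau=d.get("tau_samples", 0),
        )


@dataclass(frozen=True)
class OmegaVector:
    """Model-specific lumped regression coefficients.

    M3: [theta1, theta2+theta3, theta1*theta3, theta2*theta3, theta2*theta4]
    M2: [theta1, theta2+theta3, theta1*theta3, theta2*theta4]
    M1: [1/(VL + alpha*lam*VB), lam*VCO2/(VL + alpha*lam*VB)]
    """

    model_id: ModelId
    coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.model_id not in OMEGA_LENGTH:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        coeffs = tuple(float(c) for c in self.coeffs)
        if len(coeffs) != OMEGA_LENGTH[self.model_id]:
            raise ValueError(
                f"{self.model_id} expects {OMEGA_LENGTH[self.model_id]} coefficients, "
                f"got {len(coeffs)}"
            )
        object.__setattr__(self, "coeffs", coeffs)

    def to_json_dict(self) -> dict:
        return {"model_id": self.model_id, "coeffs": list(self.coeffs)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "OmegaVector":
        return cls(model_id=d["model_id"], coeffs=tuple(d["coeffs"]))


def theta_from_physio(
    p: PhysioParams,
    c: RespiratoryConstants = RespiratoryConstants(),
    ts_s: float = 5.0,
) -> ThetaParams:
    """Map physical parameters to the identifiable lumped set.

    The combined delay (tau1 + tau2)/Ts is rounded to the nearest integer
    sample count; sub-sample delays are not representable in the discrete
    models.
    """
    if ts_s <= 0:
        raise ValueError("ts_s must be positive")
    return ThetaParams(
        theta1=1.0 / p.VL,
        theta2=c.alpha * c.lam * p.Q / p.VL,
        theta3=p.Q / p.VB,
        theta4=p.VCO2 / (c.alpha * p.VB),
        tau=int(round((p.tau1 + p.tau2) / ts_s)),
    )


def physio_from_theta(
    t: ThetaParams,
    c: RespiratoryConstants = RespiratoryConstants(),
    ts_s: float = 5.0,
) -> PhysioParams:
    """Recover physical parameters from the lumped set.

    VL = 1/theta1, Q = VL*theta2/(alpha*lam), VB = Q/theta3,
    VCO2 = alpha*VB*theta4.  Only the combined delay tau*Ts is recoverable;
    it is stored in tau1 with tau2 = 0 and flagged.
    """
    VL = 1.0 / t.theta1
    Q = VL * t.theta2 / (c.alpha * c.lam)
    VB = Q / t.theta3
    VCO2 = c.alpha * VB * t.theta4
    return PhysioParams(
        VL=VL, VB=VB, Q=Q, VCO2=VCO2,
        tau1=t.tau * ts_s, tau2=0.0, combined_delay_only=True,
    )


def omega_from_theta(t: ThetaParams, model_id: ModelId) -> OmegaVector:
    """Lump theta into the regression coefficient vector for M2 or M3.

    M1 aggregates lung and tissue volumes irreversibly and therefore needs
    physical parameters; use :func:`omega_m1_from_physio`.
    """
    if model_id == "M3":
        coeffs = (
            t.theta1,
            t.theta2 + t.theta3,
            t.theta1 * t.theta3,
            t.theta2 * t.theta3,
            t.theta2 * t.theta4,
        )
    elif model_id == "M2":
        coeffs = (
            t.theta1,
            t.theta2 + t.theta3,
            t.theta1 * t.theta3,
            t.theta2 * t.theta4,
        )
    elif model_id == "M1":
        raise ValueError(
            "M1 coefficients are not a function of theta alone; "
            "use omega_m1_from_physio(PhysioParams)"
        )
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return OmegaVector(model_id=model_id, coeffs=coeffs)


def omega_m1_from_physio(
    p: PhysioParams, c: RespiratoryConstants = RespiratoryConstants()
) -> OmegaVector:
    """Single-compartment coefficients from physical parameters."""
    denom = p.VL + c.alpha * c.lam * p.VB
    return OmegaVector(model_id="M1", coeffs=(1.0 / denom, c.lam * p.VCO2 / denom))


def theta_from_omega(
    w: OmegaVector, tau: int = 0, consistency_rtol: float = 1e-6
) -> tuple[ThetaParams, float]:
    """Invert the lumping for M2/M3.

    Uses coefficients {0, 1, 2, last}: theta1 = w0, theta3 = w2/w0,
    theta2 = w1 - theta3, theta4 = w_last/theta2.  For M3 the redundant
    coefficient w3 = theta2*theta3 is used as a consistency check; the
    relative residual |w3 - theta2*theta3| / |w3| is returned (0.0 for M2).
    M1 is deliberately unsupported: its lumping is not invertible.
    """
    if w.model_id == "M1":
        raise ValueError("M1 physical parameters are not separable from Omega")
    c = w.coeffs
    if c[0] <= 0:
        raise NonPhysicalParameterError("Omega[0] (= theta1) must be positive")
    theta1 = c[0]
    theta3 = c[2] / c[0]
    theta2 = c[1] - theta3
    if theta2 <= 0:
        raise NonPhysicalParameterError(
            f"non-physical inversion: theta2 = {theta2:.4g} <= 0"
        )
    theta4 = c[-1] / theta2
    theta = ThetaParams(theta1, theta2, theta3, theta4, tau=tau)
    residual = 0.0
    if w.model_id == "M3":
        pred = theta2 * theta3
        scale = abs(c[3]) if c[3] != 0 else 1.0
        residual = abs(c[3] - pred) / scale
        if residual > consistency_rtol:
            import warnings

            warnings.warn(
                f"M3 Omega internal consistency residual {residual:.3g} exceeds "
                f"rtol {consistency_rtol:.3g}",
                stacklevel=2,
            )
    return theta, residual


def concentration_from_tension(
    P: float, c: RespiratoryConstants = RespiratoryConstants()
) -> float:
    """Henry's-law conversion: CO2 concentration [l_STPD/l] at tension P [mmHg]."""
    if P < 0:
        raise NonPhysicalParameterError("tension must be non-negative")
    return c.alpha * P + c.beta


def steady_state_petco2(
    VCO2: float, u: float, c: RespiratoryConstants = RespiratoryConstants()
) -> float:
    """Closed-form steady-state end-tidal CO2 tension at constant ventilation.

    At equilibrium CO2 excretion balances production: x1 = lam*VCO2/u, the
    hyperbolic ventilation-CO2 relation (independent of volumes, Q and
    delays).
    """
    if u <= 0:
        raise NonPhysicalParameterError("constant ventilation u must be positive")
    return c.lam * VCO2 / u
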