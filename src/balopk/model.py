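"""Structural population-PK model of balovaptan.

Balovaptan is an orally bioavailable, brain-penetrant vasopressin V1a
receptor antagonist.  Its plasma kinetics are described here by a
one-compartment disposition model with three non-standard features:

* **Transit-compartment absorption** (TCAM): oral drug reaches the
  absorption compartment through a chain of hypothetical transit
  compartments, producing a gamma-shaped input flux parameterised by a
  mean transit time ``MTT`` and a (non-integer) number of transit
  compartments ``Ntr``.  Food slows absorption by increasing MTT.

* **Dynamic central volume**: the apparent central volume shrinks as the
  amount in the central compartment grows, an empirical stand-in for
  capacity-limited (saturable) peripheral binding.  This makes the
  elimination half-life exposure dependent (short at high amounts, long
  in the terminal washout phase) without an explicit binding compartment.

* **Gut extraction turnover**: a slow hypothetical turnover state ``At``
  (initially 1) scales a pre-systemic loss rate ``Kgut`` acting on the
  absorption compartment.  Drug in the absorption compartment stimulates
  the degradation of ``At``, so with rising dose or repeated dosing the
  extraction shuts itself off.  The result is dose- and time-dependent
  oral bioavailability, lowest for small single doses.

State variables (amounts in **mg**):

``Aa``  amount in the absorption compartment
``Ac``  amount in the central compartment
``At``  gut-extraction turnover state (dimensionless, ``At(0) = 1``)

and the ODE system

``dAa/dt = Input - Ktr*Aa - At*Kgut*Aa``
``dAc/dt = Ktr*Aa - Ke*Ac + IV-infusion rate``
``dAt/dt = Kin - Kout*At*(1 + S*Aa)``

with ``Kin = Kout``, ``Ktr = (Ntr+1)/MTT``, ``Ke = CL/Vc(Ac)`` and
``Vc(Ac) = V0*(1 - VLmax*Ac/(Ac + VL_A50))``.

Covariate models: central volume scales proportionally with body weight
(reference 76 kg); clearance matures with age through a logistic
function reaching 50% of the adult value at ``AGE50`` years.

Concentrations are reported in ng/mL (``1000 * Ac / Vc`` with Ac in mg
and Vc in L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "PopulationParameters",
    "Covariates",
    "IndividualParameters",
    "ModelState",
    "central_volume",
    "maturation_fraction",
    "resolve_individual",
    "transit_input_rate",
    "ode_rhs",
    "ruv_prop_variance",
    "apply_residual_error",
    "LLOQ",
]

#: Lower limit of quantitation of the plasma assay, ng/mL.  The additive
#: residual-error SD (0.025 ng/mL) is half this value.
LLOQ = 0.05

#: Default brain V1a dissociation constant on the free-concentration
#: scale (ng/mL).  Not an assay value: calibrated once, by least squares,
#: against the paired median concentration / median occupancy anchors of
#: the packaged three-infusion reference scenario (see
#: :func:`balopk.ro.calibrate_Kb` and ``balopk.ro.KB_CALIBRATION_ANCHORS``).
DEFAULT_KB = 0.4220


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variability terms and PD constants of the model.

    Defaults are the final published population estimates for balovaptan.
    ``MTT`` is the fasted mean transit time; ``FOOD_MTT`` is the fixed
    food effect on MTT.  With ``food_effect_mode='multiplicative'`` (the
    default) the fed MTT is ``MTT * FOOD_MTT``; ``'absolute'`` reads the
    food effect as the fed MTT itself, in hours.

    ``RUV_early``/``RUV_late``/``RUV_add`` are *variances* (the additive
    one equals 0.025**2, i.e. an SD of half the LLOQ); ``omega_*`` are
    log-normal inter-individual variances.
    """

    CL: float = 8.52          # apparent clearance, L/h
    V0: float = 565.0         # baseline apparent central volume, L
    MTT: float = 0.367        # fasted mean transit time, h
    FOOD_MTT: float = 3.39    # food effect on MTT (fixed)
    VLmax: float = 0.805      # maximum fractional volume decrease
    VL_A50: float = 3.36      # central amount at half-maximal decrease, mg
    Ntr: float = 5.81         # number of transit compartments
    Kgut: float = 1.89        # gut extraction rate constant, 1/h
    Kout: float = 0.00205     # turnover degradation rate, 1/h (fixed)
    S: float = 22.0           # scaling of Aa effect on Kout, 1/mg
    AGE_slope: float = 0.267  # maturation slope, 1/year
    AGE50: float = 5.34       # age at 50% adult CL, years
    WT_ref: float = 76.0      # reference body weight, kg
    WT_V0_exp: float = 1.0    # weight exponent on V0 (fixed)
    omega_CL: float = 0.150   # IIV variance on CL
    omega_V0: float = 0.0944  # IIV variance on V0
    omega_MTT: float = 0.0423  # IIV variance on MTT
    RUV_early: float = 1.20   # proportional RUV variance at TAD = 0
    RUV_late: float = 0.216   # proportional RUV variance at large TAD
    RUV_rate: float = 1.32    # RUV decay rate, 1/h
    RUV_add: float = 0.000625  # additive RUV variance, (ng/mL)^2
    fu: float = 0.13          # plasma free fraction
    Kb: float = DEFAULT_KB    # V1a dissociation constant, ng/mL (free scale)
    food_effect_mode: str = "multiplicative"

    def __post_init__(self) -> None:
        if not 0.0 < self.VLmax < 1.0:
            raise ValueError(f"VLmax must be in (0, 1), got {self.VLmax}")
        for name in ("CL", "V0", "MTT", "FOOD_MTT", "VL_A50", "Ntr", "Kgut",
                     "Kout", "S", "WT_ref", "RUV_rate", "fu", "Kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("omega_CL", "omega_V0", "omega_MTT", "RUV_early",
                     "RUV_late", "RUV_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.food_effect_mode not in ("multiplicative", "absolute"):
            raise ValueError(
                f"unknown food_effect_mode {self.food_effect_mode!r}")
        if not 0 < self.fu <= 1:
            raise ValueError("fu must be in (0, 1]")

    @property
    def Kin(self) -> float:
        """Turnover input rate; constrained equal to ``Kout``."""
        return self.Kout

    @property
    def MTT_fasted(self) -> float:
        return self.MTT

    @property
    def MTT_fed(self) -> float:
        if self.food_effect_mode == "multiplicative":
            return self.MTT * self.FOOD_MTT
        return self.FOOD_MTT

    def mtt(self, fed: bool) -> float:
        return self.MTT_fed if fed else self.MTT_fasted

    @property
    def omegas(self) -> np.ndarray:
        """IIV variances as a (CL, V0, MTT) vector."""
        return np.array([self.omega_CL, self.omega_V0, self.omega_MTT])

    def with_(self, **kwargs) -> "PopulationParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Covariates:
    """Subject-level covariates entering the fixed-effect models."""

    age: float = 30.0     # years
    weight: float = 76.0  # kg
    sex: str = "M"
    fed: bool = True      # default fed status (per-dose override allowed)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class IndividualParameters:
    """Covariate- and eta-resolved parameters for a single subject."""

    CL_i: float
    V0_i: float
    MTT_fasted_i: float
    MTT_fed_i: float
    fed: bool
    Ntr: float
    VLmax: float
    VL_A50: float
    Kgut: float
    Kin: float
    Kout: float
    S: float

    def __post_init__(self) -> None:
        for name in ("CL_i", "V0_i", "MTT_fasted_i", "MTT_fed_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def MTT_i(self) -> float:
        """Mean transit time for the subject's default fed status, h."""
        return self.MTT_fed_i if self.fed else self.MTT_fasted_i

    @property
    def Ktr_i(self) -> float:
        """Transit rate constant ``(Ntr+1)/MTT_i``, 1/h."""
        return (self.Ntr + 1.0) / self.MTT_i

    def mtt(self, fed: bool) -> float:
        return self.MTT_fed_i if fed else self.MTT_fasted_i

    def ktr(self, fed: bool) -> float:
        return (self.Ntr + 1.0) / self.mtt(fed)


@dataclass
class ModelState:
    """Instantaneous amounts of the three-compartment system."""

    Aa: float = 0.0
    Ac: float = 0.0
    At: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Aa, self.Ac, self.At])


def central_volume(Ac, V0, VLmax, VL_A50):
    """Dynamic apparent central volume ``V0*(1 - VLmax*Ac/(Ac+VL_A50))``.

    Decreases monotonically from ``V0`` at ``Ac = 0`` towards the floor
    ``V0*(1 - VLmax)`` as the central amount saturates the hypothetical
    binding sites.  ``Ac`` in mg, volumes in L.
    """
    Ac = np.asarray(Ac, dtype=float)
    if np.any(Ac < 0):
        raise ValueError("central amount Ac must be non-negative")
    out = V0 * (1.0 - VLmax * Ac / (Ac + VL_A50))
    return out if out.ndim else float(out)


def maturation_fraction(age, AGE_slope: float = 0.267, AGE50: float = 5.34):
    """Fraction of adult clearance reached at a given age (years).

    Logistic maturation: exactly 0.5 at ``AGE50``, rising with slope
    ``AGE_slope`` (1/year) towards 1 in adulthood (~90% at 14 years with
    the default estimates, plateau near 20 years).
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    out = expit(AGE_slope * (age - AGE50))
    return out if out.ndim else float(out)


def resolve_individual(
    theta: PopulationParameters,
    cov: Covariates,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
) -> IndividualParameters:
    """Apply covariate models and log-normal etas to population values.

    ``eta`` is the (CL, V0, MTT) random-effect vector on the log scale;
    the same MTT eta applies under fed and fasted conditions.
    """
    e1, e2, e3 = (float(x) for x in eta)
    CL_i = theta.CL * maturation_fraction(cov.age, theta.AGE_slope, theta.AGE50) * math.exp(e1)
    V0_i = theta.V0 * (cov.weight / theta.WT_ref) ** theta.WT_V0_exp * math.exp(e2)
    return IndividualParameters(
        CL_i=CL_i,
        V0_i=V0_i,
        MTT_fasted_i=theta.MTT_fasted * math.exp(e3),
        MTT_fed_i=theta.MTT_fed * math.exp(e3),
        fed=cov.fed,
        Ntr=theta.Ntr,
        VLmax=theta.VLmax,
        VL_A50=theta.VL_A50,
        Kgut=theta.Kgut,
        Kin=theta.Kin,
        Kout=theta.Kout,
        S=theta.S,
    )


def transit_input_rate(t, dose_times, dose_amounts, ktr, Ntr: float):
    """Analytic transit-chain flux (mg/h) reaching the absorption depot.

    Each oral dose contributes a gamma-density-shaped flux
    ``D * ktr^(Ntr+1) * (t-td)^Ntr * exp(-ktr*(t-td)) / Gamma(Ntr+1)``
    which integrates to exactly the dose over ``(td, inf)``.  ``ktr`` may
    be a scalar or a per-dose array (fed and fasted doses mix freely).
    Evaluated through log-gamma for numerical stability at non-integer
    ``Ntr``.
    """
    t = np.asarray(t, dtype=float)
    dose_times = np.atleast_1d(np.asarray(dose_times, dtype=float))
    dose_amounts = np.atleast_1d(np.asarray(dose_amounts, dtype=float))
    if np.any(dose_amounts < 0):
        raise ValueError("dose amounts must be non-negative")
    ktr_arr = np.broadcast_to(np.asarray(ktr, dtype=float), dose_times.shape)

    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    flux = np.zeros_like(tt)
    lg = gammaln(Ntr + 1.0)
    for td, amt, k in zip(dose_times, dose_amounts, ktr_arr):
        dt = tt - td
        mask = dt > 0
        if not np.any(mask) or amt == 0.0:
            continue
        logf = ((Ntr + 1.0) * np.log(k) + Ntr * np.log(dt[mask])
                - k * dt[mask] - lg)
        # skip numerically extinct contributions far in the gamma tail
        flux[mask] += amt * np.exp(np.clip(logf, -745.0, None))
    return float(flux[0]) if scalar else flux


def ode_rhs(
    t: float,
    state,
    ip: IndividualParameters,
    oral_flux: float = 0.0,
    iv_rate: float = 0.0,
    ktr: float | None = None,
):
    """Right-hand side of the structural ODE system.

    ``state`` is ``(Aa, Ac, At)``; ``oral_flux`` is the transit-chain
    input (mg/h), ``iv_rate`` a zero-order infusion rate into the
    central compartment (mg/h).  ``ktr`` defaults to the subject's
    fed-status transit rate constant.
    """
    Aa, Ac, At = float(state[0]), float(state[1]), float(state[2])
    k = ip.Ktr_i if ktr is None else ktr
    Vc = central_volume(max(Ac, 0.0), ip.V0_i, ip.VLmax, ip.VL_A50)
    dAa = oral_flux - k * Aa - At * ip.Kgut * Aa
    dAc = k * Aa - ip.CL_i / Vc * Ac + iv_rate
    dAt = ip.Kin - ip.Kout * At * (1.0 + ip.S * Aa)
    return np.array([dAa, dAc, dAt])


def ruv_prop_variance(tad, RUV_early: float = 1.20, RUV_late: float = 0.216,
                      RUV_rate: float = 1.32):
    """Time-varying proportional residual variance.

    Mono-exponential decay from ``RUV_early`` immediately after dosing to
    ``RUV_late`` (half-life ``ln 2 / RUV_rate``), reflecting the larger
    unexplained variability during the absorption phase.
    """
    tad = np.asarray(tad, dtype=float)
    if np.any(tad < 0):
        raise ValueError("TAD must be non-negative")
    out = RUV_late + (RUV_early - RUV_late) * np.exp(-RUV_rate * tad)
    return out if out.ndim else float(out)


def apply_residual_error(conc, tad, theta: PopulationParameters,
                         rng: np.random.Generator):
    """Sample observed concentrations under the combined error model.

    ``obs = conc*(1 + eps_p) + eps_a`` with Gaussian errors whose
    variances are ``ruv_prop_variance(tad)`` and ``RUV_add``.  Negative
    draws near zero are retained (flagged BLQ downstream), never
    truncated.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("model concentration must be non-negative")
    sd_p = np.sqrt(ruv_prop_variance(
        tad, theta.RUV_early, theta.RUV_late, theta.RUV_rate))
    eps_p = rng.standard_normal(conc.shape) * sd_p
    eps_a = rng.standard_normal(conc.shape) * math.sqrt(theta.RUV_add)
    out = conc * (1.0 + eps_p) + eps_a
    return out if out.ndim else float(out)
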