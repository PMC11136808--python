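"""Virtual-population generation: covariates and random effects.

The trial populations behind the model cannot be redistributed, so this
module draws synthetic covariate tables whose *statistical structure*
matches what the analysis assumes: adult phase-I style fixed or
truncated-normal weights, a mixed pediatric/adult age range (2-25 years)
for dose-selection work, and an age-linked weight model built from a
piecewise-linear median growth curve with log-normal scatter.  The
growth curve is a synthetic stand-in with the qualitative age-weight
coupling the analysis needs, not a reconstruction of any trial
demographic table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "sample_covariates",
    "sample_etas",
    "median_weight_for_age",
]

# knots of the synthetic median weight-for-age curve (years, kg)
_GROWTH_AGES = np.array([2.0, 5.0, 10.0, 14.0, 18.0])
_GROWTH_WEIGHTS = np.array([12.0, 18.0, 32.0, 50.0, 70.0])


def median_weight_for_age(age):
    """Synthetic median body weight (kg) at a given age (years).

    Piecewise-linear through (2 y, 12 kg), (5 y, 18 kg), (10 y, 32 kg),
    (14 y, 50 kg) and (18+ y, 70 kg); flat outside the knot range.
    """
    return np.interp(np.asarray(age, dtype=float), _GROWTH_AGES, _GROWTH_WEIGHTS)


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a virtual population.

    ``age_model``:
        ``fixed`` (params ``(value,)``), ``uniform_range`` (``(lo, hi)``)
        or ``asd_mixture`` -- a 70/30 mixture of pediatric (uniform 2-18)
        and young-adult (uniform 18-25) ages covering the 2-25 year dose
        selection range.
    ``weight_model``:
        ``fixed`` (``(value,)``), ``truncated_normal``
        (``(mean, sd, lo, hi)``) or ``age_linked`` (``(cv,)`` log-normal
        scatter around the median growth curve, default CV 15%).
    """

    n: int = 1000
    age_model: str = "fixed"
    age_params: tuple = (30.0,)
    weight_model: str = "fixed"
    weight_params: tuple = (76.0,)
    sex_fraction_male: float = 0.9
    fed_policy: str = "fed"  # fed | fasted | per_dose

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_model not in ("fixed", "uniform_range", "asd_mixture"):
            raise ValueError(f"unknown age_model {self.age_model!r}")
        if self.weight_model not in ("fixed", "truncated_normal", "age_linked"):
            raise ValueError(f"unknown weight_model {self.weight_model!r}")
        if self.age_model == "uniform_range" and not self.age_params[0] < self.age_params[1]:
            raise ValueError("age range requires lo < hi")
        if self.weight_model == "truncated_normal":
            mean, sd, lo, hi = self.weight_params
            if not (lo < hi and sd > 0):
                raise ValueError("truncated_normal requires sd > 0 and lo < hi")
        if not 0.0 <= self.sex_fraction_male <= 1.0:
            raise ValueError("sex_fraction_male must be in [0, 1]")
        if self.fed_policy not in ("fed", "fasted", "per_dose"):
            raise ValueError(f"unknown fed_policy {self.fed_policy!r}")

    # -- convenience constructors -------------------------------------
    @classmethod
    def fixed_adult(cls, n: int = 2000, weight: float = 76.0,
                    age: float = 30.0, fed: bool = True) -> "PopulationSpec":
        """Reference adult population at a single weight (IV/RO runs)."""
        return cls(n=n, age_model="fixed", age_params=(age,),
                   weight_model="fixed", weight_params=(weight,),
                   fed_policy="fed" if fed else "fasted")

    @classmethod
    def adult_weight_distribution(cls, n: int = 2000) -> "PopulationSpec":
        """Adults with the stroke-population sensitivity weights
        (truncated normal, mean 82.2 kg, SD 20.3 kg, range 41-136 kg)."""
        return cls(n=n, age_model="fixed", age_params=(55.0,),
                   weight_model="truncated_normal",
                   weight_params=(82.2, 20.3, 41.0, 136.0))

    @classmethod
    def pediatric_adult_mixture(cls, n: int = 1000) -> "PopulationSpec":
        """2-25 year mixed population with age-linked weights, used for
        age-banded dose selection."""
        return cls(n=n, age_model="asd_mixture", age_params=(),
                   weight_model="age_linked", weight_params=(0.15,),
                   fed_policy="fed")


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def sample_covariates(spec: PopulationSpec, seed, n: int | None = None) -> pd.DataFrame:
    """Draw a covariate table (age, weight, sex, fed) for ``n`` subjects.

    Reproducible given ``seed`` (an int or a ``SeedSequence``).
    """
    n = spec.n if n is None else int(n)
    rng = np.random.default_rng(_as_seedseq(seed))

    if spec.age_model == "fixed":
        age = np.full(n, float(spec.age_params[0]))
    elif spec.age_model == "uniform_range":
        lo, hi = spec.age_params
        age = rng.uniform(lo, hi, size=n)
    else:  # asd_mixture
        is_child = rng.random(n) < 0.7
        age = np.where(is_child,
                       rng.uniform(2.0, 18.0, size=n),
                       rng.uniform(18.0, 25.0, size=n))

    if spec.weight_model == "fixed":
        weight = np.full(n, float(spec.weight_params[0]))
    elif spec.weight_model == "truncated_normal":
        mean, sd, lo, hi = spec.weight_params
        from scipy.stats import truncnorm
        a, b = (lo - mean) / sd, (hi - mean) / sd
        weight = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    else:  # age_linked
        cv = spec.weight_params[0] if spec.weight_params else 0.15
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        weight = median_weight_for_age(age) * np.exp(rng.standard_normal(n) * sigma)

    sex = np.where(rng.random(n) < spec.sex_fraction_male, "M", "F")
    fed = spec.fed_policy != "fasted"  # per_dose defers to the regimen
    return pd.DataFrame({
        "age": age,
        "weight": weight,
        "sex": sex,
        "fed": np.full(n, fed),
    })


def sample_etas(n: int, omegas, seed) -> np.ndarray:
    """Draw independent zero-mean normal etas with the given variances.

    Returns an ``(n, 3)`` array of (eta_CL, eta_V0, eta_MTT).  Each
    subject uses its own spawned RNG stream so that enlarging ``n``
    leaves earlier subjects' draws unchanged.
    """
    omegas = np.asarray(omegas, dtype=float)
    if np.any(omegas < 0):
        raise ValueError("omega variances must be >= 0")
    sd = np.sqrt(omegas)
    children = _as_seedseq(seed).spawn(n)
    out = np.empty((n, len(omegas)))
    for i, child in enumerate(children):
        out[i] = np.random.default_rng(child).standard_normal(len(omegas)) * sd
    return out
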