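"""NONMEM-style rectangular PK datasets and synthetic-study generation.

A dataset is a flat table of interleaved dosing records (``EVID=1``) and
observation records (``EVID=0``) per subject, with covariate columns
repeated on every row.  Sampling-scheme presets emulate the designs of
the five source studies (rich first-in-human MAD sampling, trough-only
interaction studies, sparse phase-II visits) so that estimation and VPC
code can be exercised without any external data.

Dialect: comma-separated, ``.`` for missing values, header mandatory,
``CMT`` 1 = oral depot, 2 = central.  Observations below the 0.05 ng/mL
LLOQ are *flagged* (``BLQ=1``), never deleted; downstream fitting
excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    LLOQ,
    Covariates,
    PopulationParameters,
    apply_residual_error,
    resolve_individual,
)
from .population import PopulationSpec, sample_covariates, sample_etas
from .simulate import DoseEvent, DosingRegimen, simulate_individual

__all__ = [
    "PKDataset",
    "SamplingScheme",
    "SCHEMES",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]

COLUMNS = ["ID", "TIME", "TAD", "AMT", "RATE", "EVID", "MDV", "CMT",
           "DV", "BLQ", "AGE", "WT", "SEX", "FED"]


@dataclass(frozen=True)
class SamplingScheme:
    """Observation times plus the dosing template of a study design.

    ``obs_times`` are hours since the first dose; ``random_windows`` are
    per-subject uniform TAD windows anchored to a dose time (e.g. an
    at-home sample with no fixed clock time).  ``doses`` are cohort dose
    levels assigned round-robin across subjects.
    """

    name: str
    obs_times: tuple
    n_doses: int
    interval: float = 24.0
    doses: tuple = (10.0,)
    fed: bool = True
    random_windows: tuple = ()  # of (dose_time, lo_tad, hi_tad)

    def __post_init__(self) -> None:
        horizon = (self.n_doses - 1) * self.interval + 14.0 * 24.0
        for t in self.obs_times:
            if not 0.0 <= t <= horizon:
                raise ValueError(f"observation time {t} outside dosing horizon")

    def regimen(self, dose: float) -> DosingRegimen:
        return DosingRegimen.oral_qd(dose, self.n_doses, fed=self.fed,
                                     interval=self.interval)

    def subject_times(self, rng: np.random.Generator) -> np.ndarray:
        times = list(self.obs_times)
        for dose_time, lo, hi in self.random_windows:
            times.append(dose_time + rng.uniform(lo, hi))
        return np.unique(np.asarray(times, dtype=float))


def _mad_times() -> tuple:
    day1 = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 12.0)
    predose = tuple(24.0 * d for d in range(1, 14))
    last = 13 * 24.0
    washout = tuple(last + t for t in (1, 2, 3, 4, 6, 8, 12, 24, 48, 96, 168, 312))
    return day1 + predose + washout


def _trough_times() -> tuple:
    pre = (0.0, 48.0, 96.0, 168.0, 192.0, 216.0)
    day10 = tuple(216.0 + t for t in (1, 2, 3, 4, 5, 6, 8, 10, 12, 16, 24))
    return pre + day10


def _vanilla_times() -> tuple:
    out = []
    for day0 in (0.0, 13 * 24.0, 83 * 24.0):
        out.extend(day0 + t for t in (0.0, 2.0, 4.0, 6.0))
    out.append(41 * 24.0)
    return tuple(sorted(out))


def _aviation_times() -> tuple:
    out = [4.0, 9 * 24.0]                     # day-1 4 h, day-10 pre-dose
    for day0 in (13 * 24.0,):                 # week 2
        out.extend(day0 + t for t in (0.0, 2.0, 4.0, 6.0))
    for day0 in (83 * 24.0, 167 * 24.0):      # weeks 12 and 24
        out.extend(day0 + t for t in (0.0, 2.0, 4.0))
    return tuple(sorted(out))


#: Presets mirroring the five source-study designs.
SCHEMES: dict[str, SamplingScheme] = {
    "phase1_rich": SamplingScheme(
        name="phase1_rich", obs_times=_mad_times(), n_doses=14,
        doses=(12.0, 20.0, 40.0, 52.0), fed=True),
    "phase1_trough": SamplingScheme(
        name="phase1_trough", obs_times=_trough_times(), n_doses=10,
        doses=(5.0, 10.0), fed=True),
    "phase2_sparse_adult": SamplingScheme(
        name="phase2_sparse_adult", obs_times=_vanilla_times(), n_doses=84,
        doses=(1.5, 4.0, 10.0), fed=True),
    # the week-8 at-home sample has no stated clock time; a TAD window of
    # 8-14 h is an arbitrary evening stand-in
    "phase2_sparse_ped": SamplingScheme(
        name="phase2_sparse_ped", obs_times=_aviation_times(), n_doses=168,
        doses=(10.0,), fed=True,
        random_windows=((55 * 24.0, 8.0, 14.0),)),
}


@dataclass
class PKDataset:
    """Validated wrapper around the rectangular record table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        bad = df.index[(df.EVID == 0) & df.AMT.notna()].tolist()
        if bad:
            raise ValueError(f"observation rows with AMT set: rows {bad}")
        bad = df.index[(df.EVID == 1) & df.DV.notna()].tolist()
        if bad:
            raise ValueError(f"dose rows with DV set: rows {bad}")
        bad = df.index[~df.EVID.isin([0, 1])].tolist()
        if bad:
            raise ValueError(f"invalid EVID values: rows {bad}")
        for sid, g in df.groupby("ID"):
            t = g.TIME.to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"TIME not nondecreasing within ID {sid}")
        obs = df[(df.EVID == 0) & df.DV.notna()]
        mismatch = obs.index[(obs.DV < LLOQ) != (obs.BLQ == 1)].tolist()
        if mismatch:
            raise ValueError(f"BLQ flag inconsistent with DV < LLOQ: rows {mismatch}")

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df.EVID == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df.EVID == 1]

    @property
    def n_subjects(self) -> int:
        return self.df.ID.nunique()

    def subject(self, sid) -> pd.DataFrame:
        return self.df[self.df.ID == sid]

    def regimen_for(self, sid) -> DosingRegimen:
        """Reconstruct the dosing regimen from a subject's dose records."""
        g = self.subject(sid)
        events = []
        for _, row in g[g.EVID == 1].iterrows():
            if row.CMT == 2 or (pd.notna(row.RATE) and row.RATE > 0):
                events.append(DoseEvent(row.TIME, row.AMT, "iv_infusion",
                                        duration=row.AMT / row.RATE))
            else:
                events.append(DoseEvent(row.TIME, row.AMT, "oral",
                                        fed=bool(row.FED)))
        return DosingRegimen(tuple(events))

    def covariates_for(self, sid) -> Covariates:
        row = self.subject(sid).iloc[0]
        return Covariates(age=float(row.AGE), weight=float(row.WT),
                          sex="M" if row.SEX == 1 else "F", fed=bool(row.FED))


def _tad(obs_time: float, dose_times: np.ndarray) -> float:
    """Time since the most recent *earlier* dose (pre-dose samples at a
    dose time refer back to the previous dose)."""
    earlier = dose_times[dose_times < obs_time]
    return float(obs_time - earlier[-1]) if len(earlier) else float(obs_time)


def generate_dataset(
    population: PopulationSpec | pd.DataFrame,
    scheme: SamplingScheme | str,
    theta: PopulationParameters | None = None,
    seed: int = 0,
    n: int | None = None,
    dose_for: Callable[[pd.Series], float] | None = None,
    noiseless: bool = False,
    etas: np.ndarray | None = None,
    solver_opts: dict | None = None,
) -> PKDataset:
    """Simulate a synthetic study dataset under a sampling scheme.

    Each subject gets a QD regimen at a cohort dose (round-robin over
    ``scheme.doses``, or from ``dose_for(covariate_row)``), individual
    parameters from log-normal etas, and observations with residual
    error applied (unless ``noiseless``).  Byte-identical for identical
    seeds.
    """
    theta = theta or PopulationParameters()
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    ss = np.random.SeedSequence(seed)
    cov_ss, eta_ss, obs_ss = ss.spawn(3)
    if isinstance(population, pd.DataFrame):
        cov = population.reset_index(drop=True)
        if n is not None and n != len(cov):
            raise ValueError("n conflicts with explicit covariate table")
    else:
        cov = sample_covariates(population, cov_ss, n=n)
    n = len(cov)
    if etas is None:
        etas = sample_etas(n, theta.omegas, eta_ss)
    elif np.asarray(etas).shape != (n, 3):
        raise ValueError(f"etas must have shape ({n}, 3)")
    subject_streams = obs_ss.spawn(n)

    rows = []
    for i in range(n):
        sid = i + 1
        crow = cov.iloc[i]
        rng = np.random.default_rng(subject_streams[i])
        dose = (dose_for(crow) if dose_for is not None
                else scheme.doses[i % len(scheme.doses)])
        regimen = scheme.regimen(dose)
        c = Covariates(age=float(crow.age), weight=float(crow.weight),
                       sex=str(crow.sex), fed=bool(crow.fed))
        ip = resolve_individual(theta, c, etas[i])
        obs_times = scheme.subject_times(rng)
        grid = np.unique(np.concatenate([[0.0], obs_times]))
        prof = simulate_individual(regimen, ip, grid=grid,
                                   solver_opts=solver_opts)
        pred = prof.conc_at(obs_times)
        dose_times = np.array([e.time for e in regimen.events])
        tads = np.array([_tad(t, dose_times) for t in obs_times])
        if noiseless:
            dv = pred
        else:
            dv = apply_residual_error(pred, tads, theta, rng)

        base = dict(ID=sid, AGE=round(c.age, 2), WT=round(c.weight, 2),
                    SEX=1 if c.sex == "M" else 0, FED=int(c.fed))
        for e in regimen.events:
            rows.append(dict(base, TIME=e.time, TAD=0.0, AMT=e.amount,
                             RATE=(e.amount / e.duration
                                   if e.route == "iv_infusion" else 0.0),
                             EVID=1, MDV=1,
                             CMT=2 if e.route == "iv_infusion" else 1,
                             DV=np.nan, BLQ=0))
        for t, td, v in zip(obs_times, tads, dv):
            rows.append(dict(base, TIME=t, TAD=td, AMT=np.nan, RATE=np.nan,
                             EVID=0, MDV=0, CMT=2, DV=v,
                             BLQ=int(v < LLOQ)))
    df = pd.DataFrame(rows)[COLUMNS]
    # observations precede doses at shared times (pre-dose samples)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return PKDataset(df)


def write_dataset(ds: PKDataset, path) -> None:
    """Write as CSV with '.' for missing values."""
    ds.df.to_csv(path, index=False, na_rep=".")


def read_dataset(path) -> PKDataset:
    """Read and validate a CSV in the packaged dialect."""
    df = pd.read_csv(path, na_values=".")
    for col in ("ID", "EVID", "MDV", "CMT", "BLQ", "SEX", "FED"):
        if col in df.columns and df[col].notna().all():
            df[col] = df[col].astype(int)
    return PKDataset(df)
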