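import numpy as np
import pandas as pd
import pytest

from balopk.dataset import COLUMNS, PKDataset
from balopk.model import Covariates, PopulationParameters, resolve_individual
from balopk.simulate import DosingRegimen


@pytest.fixture(scope="session")
def theta():
    return PopulationParameters()


@pytest.fixture(scope="session")
def typical_ip(theta):
    """Typical 76-kg fed adult with all etas at zero."""
    return resolve_individual(theta, Covariates())


@pytest.fixture(scope="session")
def linear_theta(theta):
    """Parameters in the linear limit: no volume saturation, no gut
    extraction -> one-compartment model with gamma-delayed input."""
    return theta.with_(VLmax=1e-12, Kgut=1e-12)


@pytest.fixture(scope="session")
def linear_ip(linear_theta):
    return resolve_individual(linear_theta, Covariates())


@pytest.fixture(scope="session")
def iv_reference_regimen():
    """The packaged reference IV scenario: 50/25/15 mg 60-min infusions
    at 0/24/48 h."""
    return DosingRegimen.iv_infusions([50.0, 25.0, 15.0], [0.0, 24.0, 48.0], 1.0)


@pytest.fixture(scope="session")
def build_pk_dataset():
    """Assemble subject frames into a validated PKDataset."""

    def _build(frames):
        df = (pd.concat(frames)[COLUMNS]
              .sort_values(["ID", "TIME", "EVID"], kind="stable")
              .reset_index(drop=True))
        return PKDataset(df)

    return _build


@pytest.fixture(scope="session")
def subject_frame():
    return _subject_frame


def _subject_frame(regimen, obs_times, dv, sid=1, age=30.0, weight=76.0,
                   sex="M", fed=True):
    """Rows (doses + observations) for one subject, NONMEM layout."""
    rows = []
    base = dict(ID=sid, AGE=age, WT=weight, SEX=1 if sex == "M" else 0,
                FED=int(fed))
    dose_times = np.array([e.time for e in regimen.events])
    for e in regimen.events:
        rows.append(dict(base, TIME=e.time, TAD=0.0, AMT=e.amount,
                         RATE=(e.amount / e.duration
                               if e.route == "iv_infusion" else 0.0),
                         EVID=1, MDV=1,
                         CMT=2 if e.route == "iv_infusion" else 1,
                         DV=np.nan, BLQ=0))
    for t, v in zip(obs_times, dv):
        earlier = dose_times[dose_times < t]
        tad = t - earlier[-1] if len(earlier) else t
        rows.append(dict(base, TIME=t, TAD=tad, AMT=np.nan, RATE=np.nan,
                         EVID=0, MDV=0, CMT=2, DV=v, BLQ=int(v < 0.05)))
    return pd.DataFrame(rows)
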