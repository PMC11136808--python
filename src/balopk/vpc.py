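"""Visual-predictive-check machinery on rectangular PK datasets.

Observed percentiles per time bin are compared against the distribution
of the same percentiles across model-simulated replicates of the exact
study design (same subjects, covariates, dosing and sampling times; new
random effects and residual errors each replicate).  Used here for
self-qualification on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import PKDataset
from .model import LLOQ, PopulationParameters, apply_residual_error, resolve_individual
from .population import sample_etas
from .simulate import simulate_individual

__all__ = ["VPCSummary", "vpc"]

_STATS = (5, 50, 95)


@dataclass
class VPCSummary:
    """Binned observed percentiles with simulated confidence bands."""

    table: pd.DataFrame
    nsim: int
    probs: tuple = _STATS

    @property
    def coverage(self) -> float:
        """Fraction of non-empty bins whose observed median falls inside
        the simulated 95% CI of the median."""
        t = self.table[~self.table.empty_bin]
        return float(np.mean((t.obs_p50 >= t.sim_p50_lo)
                             & (t.obs_p50 <= t.sim_p50_hi)))

    def plot(self, ax=None):
        """Quick matplotlib rendering (median + 90% bands)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table[~self.table.empty_bin]
        ax.fill_between(t.t_mid, t.sim_p50_lo, t.sim_p50_hi, alpha=0.3,
                        label="simulated 95% CI of median")
        ax.plot(t.t_mid, t.obs_p50, "o-", label="observed median")
        ax.plot(t.t_mid, t.obs_p5, "--", color="gray")
        ax.plot(t.t_mid, t.obs_p95, "--", color="gray")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (ng/mL)")
        ax.legend()
        return ax


def _binned_percentiles(times, values, edges):
    idx = np.digitize(times, edges) - 1
    out = np.full((len(edges) - 1, len(_STATS)), np.nan)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            out[b] = np.percentile(values[sel], _STATS)
    return out, counts


def vpc(
    dataset: PKDataset,
    theta: PopulationParameters | None = None,
    nsim: int = 200,
    bins=8,
    seed: int = 0,
    solver_opts: dict | None = None,
) -> VPCSummary:
    """Simulate ``nsim`` replicates of the dataset design and summarise.

    ``bins`` is either an integer (quantile-spaced time bins over the
    observed records) or an explicit array of bin edges.  BLQ handling
    mirrors the estimation convention: flagged records are excluded on
    both the observed and simulated sides.
    """
    if nsim < 100:
        raise ValueError("vpc needs nsim >= 100 replicates")
    theta = theta or PopulationParameters()
    opts = solver_opts or {"method": "LSODA", "rtol": 1e-6, "atol": 1e-9}
    obs = dataset.observations
    obs = obs[obs.BLQ == 0]
    if np.isscalar(bins):
        qs = np.linspace(0, 100, int(bins) + 1)
        edges = np.unique(np.percentile(obs.TIME, qs))
        edges[-1] += 1e-9
    else:
        edges = np.asarray(bins, dtype=float)

    obs_pct, counts = _binned_percentiles(obs.TIME.to_numpy(),
                                          obs.DV.to_numpy(), edges)

    sids = dataset.df.ID.unique()
    preps = []
    for sid in sids:
        g = dataset.observations
        g = g[g.ID == sid]
        times = g.TIME.to_numpy(dtype=float)
        preps.append({
            "regimen": dataset.regimen_for(sid),
            "cov": dataset.covariates_for(sid),
            "times": times,
            "tad": g.TAD.to_numpy(dtype=float),
            "grid": np.unique(np.concatenate([[0.0], times])),
        })

    ss = np.random.SeedSequence(seed)
    rep_streams = ss.spawn(nsim)
    sim_pct = np.empty((nsim, len(edges) - 1, len(_STATS)))
    for r in range(nsim):
        rep_ss = rep_streams[r]
        eta_ss, err_ss = rep_ss.spawn(2)
        etas = sample_etas(len(sids), theta.omegas, eta_ss)
        err_rng = np.random.default_rng(err_ss)
        all_t, all_v = [], []
        for i, prep in enumerate(preps):
            ip = resolve_individual(theta, prep["cov"], etas[i])
            prof = simulate_individual(prep["regimen"], ip,
                                       grid=prep["grid"], solver_opts=opts)
            pred = prof.conc_at(prep["times"])
            dv = apply_residual_error(pred, prep["tad"], theta, err_rng)
            keep = dv >= LLOQ
            all_t.append(prep["times"][keep])
            all_v.append(dv[keep])
        pct, _ = _binned_percentiles(np.concatenate(all_t),
                                     np.concatenate(all_v), edges)
        sim_pct[r] = pct

    rows = []
    for b in range(len(edges) - 1):
        row = {
            "t_lo": edges[b], "t_hi": edges[b + 1],
            "t_mid": 0.5 * (edges[b] + edges[b + 1]),
            "n_obs": int(counts[b]),
            "empty_bin": counts[b] == 0,
        }
        for k, p in enumerate(_STATS):
            row[f"obs_p{p}"] = obs_pct[b, k]
            sims = sim_pct[:, b, k]
            sims = sims[np.isfinite(sims)]
            if len(sims):
                lo, med, hi = np.percentile(sims, [2.5, 50, 97.5])
            else:
                lo = med = hi = np.nan
            row[f"sim_p{p}_lo"] = lo
            row[f"sim_p{p}"] = med
            row[f"sim_p{p}_hi"] = hi
        rows.append(row)
    return VPCSummary(table=pd.DataFrame(rows), nsim=nsim)
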