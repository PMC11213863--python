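"""Convergence diagnostics, DIC model comparison and predictive checking.

The Gelman-Rubin statistic is the classic potential-scale-reduction factor
computed on retained (post burn-in, thinned) draws, without chain splitting
or rank normalisation.  DIC follows the standard decomposition
``DIC = D_bar + pD`` with ``pD = D_bar - D(theta_bar)``, evaluated at the
posterior means of all nodes.  Highest-density regions are the shortest
sample windows containing the requested mass, with ties broken toward the
lower start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import Posterior
from .model import HddmModel
from .synthetic import CELLS
from .wfpt import WienerParams
from . import synthetic

__all__ = ["ConvergenceReport", "DicResult", "gelman_rubin",
           "convergence_report", "dic", "select_model", "hdr_interval",
           "posterior_predictive_check"]

RHAT_THRESHOLD = 1.02


class DiagnosticError(ValueError):
    pass


@dataclass
class ConvergenceReport:
    rhat: dict
    threshold: float = RHAT_THRESHOLD

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def passed(self) -> bool:
        return self.max_rhat < self.threshold

    def to_dict(self) -> dict:
        return {"rhat": {k: float(v) for k, v in self.rhat.items()},
                "max_rhat": float(self.max_rhat),
                "threshold": self.threshold, "passed": bool(self.passed)}


@dataclass
class DicResult:
    mean_deviance: float
    deviance_at_means: float

    @property
    def p_d(self) -> float:
        return self.mean_deviance - self.deviance_at_means

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.p_d

    def to_dict(self) -> dict:
        return {"mean_deviance": self.mean_deviance,
                "deviance_at_means": self.deviance_at_means,
                "p_d": self.p_d, "dic": self.dic}


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic PSRF from an (n_chains, n_draws) array of one node's draws.

    Rhat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the variance of the chain means.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise DiagnosticError("need at least two chains to compute Rhat")
    m, n = chains.shape
    if n < 2:
        raise DiagnosticError("need at least two retained draws per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def convergence_report(posterior: Posterior, nodes=None,
                       threshold: float = RHAT_THRESHOLD) -> ConvergenceReport:
    """Rhat per node (all nodes by default) against the pass threshold."""
    if nodes is None:
        nodes = posterior.node_names
    rhat = {name: gelman_rubin(posterior.node(name)) for name in nodes}
    return ConvergenceReport(rhat=rhat, threshold=threshold)


def dic(posterior: Posterior, model: HddmModel) -> DicResult:
    """Deviance information criterion from the stored deviance trace and
    the model's deviance at the posterior mean of every node."""
    if posterior.deviance is None or posterior.deviance.size == 0:
        raise DiagnosticError("posterior carries no deviance trace")
    d_bar = float(posterior.deviance.mean())
    d_at_means = model.deviance(posterior.mean_vector())
    return DicResult(mean_deviance=d_bar, deviance_at_means=d_at_means)


def select_model(dic_table: dict, substantial_gap: float = 10.0) -> dict:
    """Pick the lowest-DIC variant; the choice is 'substantial' iff the gap
    to the runner-up exceeds the conventional threshold of 10."""
    if len(dic_table) < 2:
        raise DiagnosticError("model selection needs at least two variants")
    items = sorted(dic_table.items(), key=lambda kv: kv[1])
    best, runner = items[0], items[1]
    return {
        "best": best[0], "best_dic": float(best[1]),
        "runner_up": runner[0], "runner_up_dic": float(runner[1]),
        "delta_dic": float(runner[1] - best[1]),
        "substantial": bool(runner[1] - best[1] > substantial_gap),
        "table": {k: float(v) for k, v in items},
    }


def hdr_interval(samples, mass: float = 0.90):
    """Shortest interval containing ceil(mass * n) sorted sample points.

    Ties between equally short windows are broken toward the lower start.
    """
    if not 0 < mass <= 1:
        raise ValueError("mass must lie in (0, 1]")
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = s.size
    if n == 0:
        raise ValueError("samples must be non-empty")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1:] - s[:n - k + 1]
    start = int(np.argmin(widths))  # argmin takes the first = lower start
    return float(s[start]), float(s[start + k - 1])


def _rt_deciles(rt: np.ndarray) -> np.ndarray:
    return np.quantile(rt, np.arange(1, 10) / 10.0)


def posterior_predictive_check(posterior: Posterior, model: HddmModel,
                               trials: pd.DataFrame, n_draws: int, seed: int,
                               mass: float = 0.90, rt_unit: str = "ms") -> dict:
    """Simulate datasets from posterior draws and compare with the data.

    For each of ``n_draws`` retained posterior draws, every participant's
    trials are re-simulated from that draw's participant-level parameters.
    Per condition x coherence cell the report gives observed accuracy and
    signed-RT deciles (incorrect responses on the negative axis, the
    convention of the predictive-check plots) against the simulated
    highest-density regions at the requested mass, flagging any cell whose
    observed statistic falls outside.
    """
    if n_draws < 2:
        raise DiagnosticError("posterior predictive check needs n_draws >= 2")
    scale = 1e-3 if rt_unit == "ms" else 1.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x97C]))
    n_pool = posterior.n_chains * posterior.n_retained
    pick = rng.choice(n_pool, size=min(n_draws, n_pool), replace=False)
    flat = posterior.draws.reshape(n_pool, -1)
    sim_seeds = rng.integers(0, 2**31, size=(len(pick), model.n_participants, 6))

    # observed statistics per cell
    report = {"mass": mass, "cells": {}}
    deadline_ms = 1e12  # predictive simulation is not deadline-censored
    for c, cell in enumerate(CELLS):
        obs = trials[(trials["condition"] == cell[0])
                     & (trials["coherence"] == cell[1])]
        key = f"{cell[0]}/{cell[1]}"
        if len(obs) == 0:
            report["cells"][key] = {"skipped": "no observed trials in cell"}
            continue
        rt_obs = obs["rt"].to_numpy(dtype=float) * scale
        cor_obs = obs["correct"].to_numpy().astype(bool)
        signed_obs = np.where(cor_obs, rt_obs, -rt_obs)
        obs_acc = float(cor_obs.mean())
        obs_dec = _rt_deciles(signed_obs)

        sim_acc = np.empty(len(pick))
        sim_dec = np.empty((len(pick), 9))
        n_cell = len(obs)
        for d, row_idx in enumerate(pick):
            row = flat[row_idx]
            x = model.participant_array(row)
            rts = []
            cors = []
            # allocate each participant its observed share of cell trials
            for i, pid in enumerate(model.participants):
                n_i = int((obs["participant_id"] == pid).sum())
                if n_i == 0:
                    continue
                p = WienerParams(delta=x[i, 0, model.pcol[0, c]],
                                 theta=x[i, 1, model.pcol[1, c]],
                                 tau=x[i, 2, model.pcol[2, c]])
                r, cc, _ = synthetic.simulate_trials(
                    p, n_i, deadline_ms, int(sim_seeds[d, i, c]))
                rts.append(r)
                cors.append(cc)
            r = np.concatenate(rts)
            cc = np.concatenate(cors)
            signed = np.where(cc, r, -r)
            sim_acc[d] = cc.mean()
            sim_dec[d] = _rt_deciles(signed)
        acc_hdr = hdr_interval(sim_acc, mass)
        dec_hdr = [hdr_interval(sim_dec[:, q], mass) for q in range(9)]
        acc_in = acc_hdr[0] <= obs_acc <= acc_hdr[1]
        dec_in = [bool(lo <= v <= hi) for v, (lo, hi) in zip(obs_dec, dec_hdr)]
        report["cells"][key] = {
            "n_trials": n_cell,
            "observed_accuracy": obs_acc,
            "accuracy_hdr": list(acc_hdr),
            "accuracy_inside": bool(acc_in),
            "observed_signed_rt_deciles": obs_dec.tolist(),
            "signed_rt_decile_hdrs": [list(h) for h in dec_hdr],
            "deciles_inside": dec_in,
            "all_inside": bool(acc_in and all(dec_in)),
        }
    checked = [v for v in report["cells"].values() if "all_inside" in v]
    report["n_cells_checked"] = len(checked)
    report["n_cells_all_inside"] = sum(v["all_inside"] for v in checked)
    return report
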