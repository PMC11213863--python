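"""Metropolis-within-Gibbs sampling of the hierarchical diffusion model.

Each sweep updates every participant-level node and every group-level mean
and spread with a normal random-walk proposal.  Proposal scales adapt
towards a 44% acceptance rate during burn-in only and are frozen afterwards,
so detailed balance holds on all retained draws.  The Wiener likelihood is
not conjugate, which is why no exact Gibbs step exists for any node.

Support constraints (theta > 0, 0 <= tau < the participant's minimum RT,
sigma > 0, truncated group means) are enforced by proposal rejection.
A deviance (-2 log likelihood) trace is recorded for every retained draw,
feeding DIC model comparison downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .model import HddmModel, PARAMS
from .wfpt import _loglik_trials

__all__ = ["SamplerSettings", "Posterior", "sample_posterior"]


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC schedule; the defaults follow the study's published protocol:
    5 chains of 11,000 iterations, 1,000 discarded as burn-in, thinning by
    two, leaving 25,000 pooled retained draws."""

    n_chains: int = 5
    n_iter: int = 11_000
    burn_in: int = 1_000
    thin: int = 2
    #: Metropolis proposals per participant-level node per sweep
    n_inner: int = 3
    #: group-node update passes per sweep (likelihood-free, cheap)
    n_group_inner: int = 10

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must lie in [0, n_iter)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @property
    def pooled_retained(self) -> int:
        return self.n_chains * self.retained_per_chain


@dataclass
class Posterior:
    """Retained MCMC draws: chains x draws x nodes, plus a deviance trace."""

    draws: np.ndarray              # (n_chains, n_retained, n_nodes)
    deviance: np.ndarray           # (n_chains, n_retained)
    node_names: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {name: j for j, name in enumerate(self.node_names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def node(self, name: str) -> np.ndarray:
        """Draws of one node, shape (n_chains, n_retained)."""
        return self.draws[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        return self.node(name).reshape(-1)

    def posterior_mean(self, name: str) -> float:
        return float(self.pooled(name).mean())

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.pooled(name)))

    def mean_vector(self) -> np.ndarray:
        """Posterior means of every node, in node order."""
        return self.draws.mean(axis=(0, 1))

    def group_nodes(self) -> list:
        return [n for n in self.node_names if n.startswith(("mu_", "sigma_"))]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format (chain, iteration, node, value)."""
        ch, it, nn = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(ch), it * nn),
            "iteration": np.tile(np.repeat(np.arange(it), nn), ch),
            "node": np.tile(self.node_names, ch * it),
            "value": self.draws.reshape(-1),
        })

    def save(self, csv_path, meta_path) -> None:
        import json
        self.to_dataframe().to_csv(csv_path, index=False)
        with open(meta_path, "w") as fh:
            json.dump({"meta": self.meta,
                       "deviance": self.deviance.tolist()}, fh, indent=1)

    @classmethod
    def load(cls, csv_path, meta_path) -> "Posterior":
        import json
        df = pd.read_csv(csv_path)
        with open(meta_path) as fh:
            side = json.load(fh)
        node_names = list(dict.fromkeys(df["node"]))
        ch = df["chain"].nunique()
        it = df["iteration"].nunique()
        draws = df["value"].to_numpy().reshape(ch, it, len(node_names))
        return cls(draws=draws, deviance=np.asarray(side["deviance"]),
                   node_names=node_names, meta=side["meta"])


@njit(cache=True)
def _cells_loglik(rt, correct, offsets, i, cells, x, pcol, eps):
    """Likelihood of participant i over the given cell indices."""
    total = 0.0
    for cc in range(cells.shape[0]):
        c = cells[cc]
        s, e = offsets[i, c, 0], offsets[i, c, 1]
        if s == e:
            continue
        total += _loglik_trials(rt[s:e], correct[s:e],
                                x[i, 0, pcol[0, c]], x[i, 1, pcol[1, c]],
                                x[i, 2, pcol[2, c]], eps)
        if not np.isfinite(total):
            return -np.inf
    return total


@njit(cache=True)
def _full_deviance(rt, correct, offsets, x, pcol, eps):
    total = 0.0
    all_cells = np.arange(6)
    for i in range(offsets.shape[0]):
        total += _cells_loglik(rt, correct, offsets, i, all_cells, x, pcol, eps)
    return -2.0 * total


@njit(cache=True)
def _run_chain(rt, correct, offsets, min_rt, age_group,
               ncols, pcol, gidx, ngroups,
               mu_loc, mu_scale, sigma_scale, mu_lower,
               n_iter, burn_in, thin, seed, eps,
               x0, mu0, sigma0, n_inner, n_group_inner):
    """One MCMC chain.  Returns (draws, deviance, acceptance log).

    The acceptance log records, per 50-iteration window, the mean
    participant-node proposal scale — constant after burn-in by
    construction, which the tests assert.
    """
    np.random.seed(seed)
    N = offsets.shape[0]
    x = x0.copy()          # (N, 3, 6)
    mu = mu0.copy()        # (3, 12)
    sigma = sigma0.copy()  # (3, 12)

    # per-node random-walk scales
    sx = np.empty((N, 3, 6))
    for k in range(3):
        base = (0.3, 0.15, 0.03)[k]
        for i in range(N):
            for c in range(6):
                sx[i, k, c] = base
    smu = np.full((3, 12), 0.2)
    ssig = np.full((3, 12), 0.2)
    snc_mu = np.full((3, 12), 0.1)
    snc_sig = np.full((3, 12), 0.2)
    ax = np.zeros((N, 3, 6), dtype=np.int64)
    amu = np.zeros((3, 12), dtype=np.int64)
    asig = np.zeros((3, 12), dtype=np.int64)
    anc_mu = np.zeros((3, 12), dtype=np.int64)
    anc_sig = np.zeros((3, 12), dtype=np.int64)
    x_prop = np.empty(N)
    ll_prop_buf = np.empty((N, 6))

    # cache of the current log likelihood per participant x cell; kept in
    # sync on every accepted move so each proposal needs one fresh pass
    # over the affected cells only, and the deviance trace is a cache sum
    all_cells = np.arange(6)
    ll_cell = np.empty((N, 6))
    for i in range(N):
        for c in range(6):
            ll_cell[i, c] = _cells_loglik(rt, correct, offsets, i,
                                          all_cells[c:c + 1], x, pcol, eps)
    tmp_ll = np.empty(6)

    n_retained = (n_iter - burn_in) // thin
    n_nodes = 0
    for k in range(3):
        n_nodes += N * ncols[k]
    for k in range(3):
        n_nodes += 2 * ngroups[k]
    draws = np.empty((n_retained, n_nodes))
    deviance = np.empty(n_retained)
    n_windows = (n_iter + 49) // 50
    scale_log = np.empty(n_windows)

    r = 0
    for it in range(n_iter):
        adapting = it < burn_in
        # --- participant-level nodes (n_inner proposals per node) ---
        for k in range(3):
            nc = ncols[k]
            for i in range(N):
                g_of = age_group[i]
                for c in range(nc):
                    for _rep in range(n_inner):
                        cur = x[i, k, c]
                        prop = cur + sx[i, k, c] * np.random.normal()
                        # support constraints by rejection
                        if k == 1 and prop <= 0.0:
                            continue
                        if k == 2 and (prop < 0.0 or prop >= min_rt[i]):
                            continue
                        if nc == 6:
                            cells = all_cells[c:c + 1]
                        else:
                            cells = all_cells
                        g = gidx[k, g_of, c]
                        sd = sigma[k, g]
                        lp_cur = -0.5 * ((cur - mu[k, g]) / sd) ** 2
                        lp_prop = -0.5 * ((prop - mu[k, g]) / sd) ** 2
                        ll_cur = 0.0
                        for cc in range(cells.shape[0]):
                            ll_cur += ll_cell[i, cells[cc]]
                        x[i, k, c] = prop
                        ll_prop = 0.0
                        for cc in range(cells.shape[0]):
                            cell = cells[cc]
                            tmp_ll[cell] = _cells_loglik(
                                rt, correct, offsets, i,
                                all_cells[cell:cell + 1], x, pcol, eps)
                            ll_prop += tmp_ll[cell]
                        log_alpha = (lp_prop + ll_prop) - (lp_cur + ll_cur)
                        if np.log(np.random.random()) < log_alpha:
                            ax[i, k, c] += 1
                            for cc in range(cells.shape[0]):
                                ll_cell[i, cells[cc]] = tmp_ll[cells[cc]]
                        else:
                            x[i, k, c] = cur
        # --- group-level nodes (likelihood-free, so repeated updates are
        # cheap and sharpen mixing of the hierarchy) ---
        for _rep in range(n_group_inner):
            for k in range(3):
                ng = ngroups[k]
                for g in range(ng):
                    # members: participants (and column) feeding this node
                    if ng == 12:
                        grp = g // 6
                        col = g % 6
                    else:
                        grp = -1  # all participants
                        col = 0
                    # mean update
                    cur = mu[k, g]
                    prop = cur + smu[k, g] * np.random.normal()
                    if prop >= mu_lower[k]:
                        lp = -0.5 * (((prop - mu_loc[k]) / mu_scale[k]) ** 2
                                     - ((cur - mu_loc[k]) / mu_scale[k]) ** 2)
                        sd = sigma[k, g]
                        for i in range(N):
                            if grp >= 0 and age_group[i] != grp:
                                continue
                            v = x[i, k, col]
                            lp += -0.5 * (((v - prop) / sd) ** 2
                                          - ((v - cur) / sd) ** 2)
                        if np.log(np.random.random()) < lp:
                            mu[k, g] = prop
                            amu[k, g] += 1
                    # spread update: random walk on log sigma
                    cur = sigma[k, g]
                    prop = cur * np.exp(ssig[k, g] * np.random.normal())
                    lp = -0.5 * ((prop / sigma_scale[k]) ** 2
                                 - (cur / sigma_scale[k]) ** 2)
                    lp += np.log(prop) - np.log(cur)  # log-walk Jacobian
                    m = mu[k, g]
                    cnt = 0
                    for i in range(N):
                        if grp >= 0 and age_group[i] != grp:
                            continue
                        v = x[i, k, col]
                        lp += -0.5 * ((v - m) ** 2) * (1.0 / prop**2 - 1.0 / cur**2)
                        cnt += 1
                    lp += cnt * (np.log(cur) - np.log(prop))
                    if np.log(np.random.random()) < lp:
                        sigma[k, g] = prop
                        asig[k, g] += 1
        # --- interweaved non-centered moves: rescale / translate all member
        # nodes jointly with their group spread / mean, which de-correlates
        # the hierarchy (funnel) that single-site updates traverse slowly ---
        for k in range(3):
            ng = ngroups[k]
            nc = ncols[k]
            for g in range(ng):
                if ng == 12:
                    grp = g // 6
                    col = g % 6
                else:
                    grp = -1
                    col = 0
                if nc == 6:
                    cells = all_cells[col:col + 1]
                else:
                    cells = all_cells
                for move in range(2):
                    cur_mu = mu[k, g]
                    cur_sig = sigma[k, g]
                    if move == 0:
                        # sigma move: x' = mu + (x - mu) * sigma'/sigma
                        prop_sig = cur_sig * np.exp(
                            snc_sig[k, g] * np.random.normal())
                        ratio = prop_sig / cur_sig
                        lp = -0.5 * ((prop_sig / sigma_scale[k]) ** 2
                                     - (cur_sig / sigma_scale[k]) ** 2)
                        lp += np.log(ratio)  # log-walk Jacobian
                    else:
                        # mu move: x' = x + (mu' - mu)
                        prop_mu = cur_mu + snc_mu[k, g] * np.random.normal()
                        if prop_mu < mu_lower[k]:
                            continue
                        lp = -0.5 * (((prop_mu - mu_loc[k]) / mu_scale[k]) ** 2
                                     - ((cur_mu - mu_loc[k]) / mu_scale[k]) ** 2)
                    ok = True
                    for i in range(N):
                        if grp >= 0 and age_group[i] != grp:
                            continue
                        v = x[i, k, col]
                        if move == 0:
                            vp = cur_mu + (v - cur_mu) * ratio
                        else:
                            vp = v + prop_mu - cur_mu
                        if k == 1 and vp <= 0.0:
                            ok = False
                            break
                        if k == 2 and (vp < 0.0 or vp >= min_rt[i]):
                            ok = False
                            break
                        x_prop[i] = vp
                    if not ok:
                        continue
                    for i in range(N):
                        if grp >= 0 and age_group[i] != grp:
                            continue
                        old_v = x[i, k, col]
                        x[i, k, col] = x_prop[i]
                        for cc in range(cells.shape[0]):
                            cell = cells[cc]
                            ll_prop_buf[i, cell] = _cells_loglik(
                                rt, correct, offsets, i,
                                all_cells[cell:cell + 1], x, pcol, eps)
                            lp += ll_prop_buf[i, cell] - ll_cell[i, cell]
                        x[i, k, col] = old_v
                    if np.log(np.random.random()) < lp:
                        for i in range(N):
                            if grp >= 0 and age_group[i] != grp:
                                continue
                            x[i, k, col] = x_prop[i]
                            for cc in range(cells.shape[0]):
                                ll_cell[i, cells[cc]] = ll_prop_buf[i, cells[cc]]
                        if move == 0:
                            sigma[k, g] = prop_sig
                            anc_sig[k, g] += 1
                        else:
                            mu[k, g] = prop_mu
                            anc_mu[k, g] += 1
        # --- adaptation, burn-in only ---
        if (it + 1) % 50 == 0:
            if adapting:
                for k in range(3):
                    for i in range(N):
                        for c in range(ncols[k]):
                            rate = ax[i, k, c] / (50.0 * n_inner)
                            sx[i, k, c] *= np.exp(1.2 * (rate - 0.44))
                    for g in range(ngroups[k]):
                        smu[k, g] *= np.exp(
                            1.2 * (amu[k, g] / (50.0 * n_group_inner) - 0.44))
                        ssig[k, g] *= np.exp(
                            1.2 * (asig[k, g] / (50.0 * n_group_inner) - 0.44))
                        snc_mu[k, g] *= np.exp(1.2 * (anc_mu[k, g] / 50.0 - 0.30))
                        snc_sig[k, g] *= np.exp(1.2 * (anc_sig[k, g] / 50.0 - 0.30))
            ax[:] = 0
            amu[:] = 0
            asig[:] = 0
            anc_mu[:] = 0
            anc_sig[:] = 0
            scale_log[(it + 1) // 50 - 1] = sx.sum()
        # --- retention ---
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            pos = 0
            for k in range(3):
                for i in range(N):
                    for c in range(ncols[k]):
                        draws[r, pos] = x[i, k, c]
                        pos += 1
            for k in range(3):
                for g in range(ngroups[k]):
                    draws[r, pos] = mu[k, g]
                    pos += 1
            for k in range(3):
                for g in range(ngroups[k]):
                    draws[r, pos] = sigma[k, g]
                    pos += 1
            deviance[r] = -2.0 * ll_cell.sum()
            r += 1
    return draws, deviance, scale_log


def _initial_state(model: HddmModel, rng: np.random.Generator):
    """Group means at prior means; participant nodes at their group mean
    plus a small seeded jitter, respecting support constraints."""
    N = model.n_participants
    pr = model.priors
    mu = np.zeros((3, 12))
    sigma = np.full((3, 12), 0.5)
    for k in range(3):
        mu[k, :] = pr.mu_loc[k]
    x = np.zeros((N, 3, 6))
    for k in range(3):
        for i in range(N):
            for c in range(6):
                val = mu[k, 0] + 0.05 * rng.standard_normal()
                if k == 1:
                    val = max(val, 0.1)
                if k == 2:
                    val = min(max(val, 0.01), 0.8 * model.min_rt[i])
                x[i, k, c] = val
    return x, mu, sigma


def sample_posterior(model: HddmModel, settings: SamplerSettings | None = None,
                     seed: int = 0, eps: float = 1e-7,
                     max_init_attempts: int = 20) -> Posterior:
    """Run the Metropolis-within-Gibbs sampler; deterministic given seed.

    Chains are run sequentially with seeds derived from the root seed.
    Initial states with a non-finite likelihood are re-drawn up to
    ``max_init_attempts`` times before failing.
    """
    if settings is None:
        settings = SamplerSettings()
    ss = np.random.SeedSequence([int(seed), 0xFEED])
    chain_seeds = ss.generate_state(settings.n_chains)
    init_rng = np.random.default_rng(ss.spawn(1)[0])

    node_names = model.node_names()
    all_draws = np.empty((settings.n_chains, settings.retained_per_chain,
                          model.n_nodes()))
    all_dev = np.empty((settings.n_chains, settings.retained_per_chain))
    scale_logs = []
    mu_lower = np.array(model.priors.mu_lower)
    for ch in range(settings.n_chains):
        for attempt in range(max_init_attempts):
            x0, mu0, sigma0 = _initial_state(model, init_rng)
            dev0 = _full_deviance(model.rt, model.correct, model.offsets,
                                  x0, model.pcol, eps)
            if np.isfinite(dev0):
                break
        else:
            raise RuntimeError(
                "could not find a finite-likelihood initial state after "
                f"{max_init_attempts} attempts")
        draws, dev, slog = _run_chain(
            model.rt, model.correct, model.offsets, model.min_rt,
            model.age_group, model.ncols, model.pcol, model.gidx,
            model.ngroups,
            np.array(model.priors.mu_loc), np.array(model.priors.mu_scale),
            np.array(model.priors.sigma_scale), mu_lower,
            settings.n_iter, settings.burn_in, settings.thin,
            int(chain_seeds[ch]) % (2**32), eps,
            x0, mu0, sigma0, settings.n_inner, settings.n_group_inner)
        all_draws[ch] = draws
        all_dev[ch] = dev
        scale_logs.append(slog)
    meta = {
        "variant_id": model.variant.id,
        "variant_label": model.variant.label,
        "n_chains": settings.n_chains, "n_iter": settings.n_iter,
        "burn_in": settings.burn_in, "thin": settings.thin,
        "seed": int(seed),
        "age_threshold": model.age_threshold,
        "priors": model.priors.to_dict(),
        "participants": list(model.participants),
        "ages": [float(a) for a in model.ages],
    }
    post = Posterior(draws=all_draws, deviance=all_dev,
                     node_names=node_names, meta=meta)
    post.meta["scale_trace"] = [s.tolist() for s in scale_logs]
    return post
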