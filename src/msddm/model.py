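"""Hierarchical model graphs for the eight accuracy-coded diffusion variants.

A variant declares which of the three diffusion parameters (drift rate
delta, boundary separation theta, non-decision time tau) are free to vary
across the conditional dependencies: sensory condition (V/A/AV) x stimulus
coherence (HC/LC) at the participant level, additionally crossed with age
group (YA/OA) at the group level — at most 12 group-level means per
parameter family.  Parameters not in ``varies`` are shared across all cells.
The relative starting point is fixed at the midpoint (z = 0.5) and the
trial-to-trial variabilities are fixed to zero throughout.

The eight variants are the 2^3 subsets of {delta, theta, tau}; variant 1
lets nothing vary and variant 8 lets all three vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CELLS
from .wfpt import _loglik_trials

__all__ = ["PARAMS", "ModelVariant", "VARIANTS", "variant_by_id",
           "assign_age_group", "PriorSpec", "HddmModel", "build_model"]

PARAMS = ("delta", "theta", "tau")
AGE_GROUPS = ("YA", "OA")
DEFAULT_AGE_THRESHOLD = 60.0


class ModelConfigError(ValueError):
    """Raised when a model cannot be built from the supplied trials."""


@dataclass(frozen=True)
class ModelVariant:
    """Which parameters vary over the conditional-dependency cells."""

    varies: frozenset

    def __post_init__(self):
        extra = set(self.varies) - set(PARAMS)
        if extra:
            raise ValueError(f"unknown parameters in varies: {sorted(extra)}")
        object.__setattr__(self, "varies", frozenset(self.varies))

    @property
    def id(self) -> int:
        """Stable 1-8 numbering: 1 = nothing varies, 8 = all three vary."""
        return 1 + (4 * ("delta" in self.varies) + 2 * ("theta" in self.varies)
                    + ("tau" in self.varies))

    @property
    def label(self) -> str:
        if not self.varies:
            return "none"
        return "+".join(p for p in PARAMS if p in self.varies)

    def n_group_means(self, param: str) -> int:
        # condition x coherence x age group when varying, else shared
        return 12 if param in self.varies else 1


#: the 8 fitted variants in id order
VARIANTS = tuple(sorted(
    (ModelVariant(frozenset(s)) for s in (
        frozenset(), {"tau"}, {"theta"}, {"theta", "tau"},
        {"delta"}, {"delta", "tau"}, {"delta", "theta"},
        {"delta", "theta", "tau"},
    )),
    key=lambda v: v.id,
))


def variant_by_id(vid: int) -> ModelVariant:
    if not 1 <= vid <= 8:
        raise ValueError(f"variant id must be 1..8, got {vid}")
    return VARIANTS[vid - 1]


def assign_age_group(age: float, threshold: float = DEFAULT_AGE_THRESHOLD) -> str:
    """Deterministic older/younger-adult labelling at a configurable cut."""
    return "OA" if age >= threshold else "YA"


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative, positivity-respecting priors on the group level.

    Group means are normal (truncated positive for theta, truncated at zero
    for tau); group spreads are half-normal.  Participant-level nodes are
    normal about their group mean, truncated to the parameter's support by
    proposal rejection.
    """

    mu_loc: tuple = (0.0, 1.5, 0.3)       # delta, theta, tau
    mu_scale: tuple = (5.0, 2.0, 0.3)
    sigma_scale: tuple = (2.0, 2.0, 2.0)  # half-normal sd of group spreads
    mu_lower: tuple = (-np.inf, 0.0, 0.0)

    def to_dict(self) -> dict:
        return {"mu_loc": list(self.mu_loc), "mu_scale": list(self.mu_scale),
                "sigma_scale": list(self.sigma_scale),
                "mu_lower": [float(x) for x in self.mu_lower]}


@dataclass
class HddmModel:
    """Compiled model: trial data in flat arrays plus node bookkeeping.

    Node layout (the sampler and the posterior container share it):
    participant nodes for delta, then theta, then tau (participant-major,
    cell-column-minor), followed by group means and group spreads per
    parameter family.
    """

    variant: ModelVariant
    participants: list
    ages: np.ndarray
    age_group: np.ndarray          # (N,) 0=YA 1=OA
    age_threshold: float
    rt: np.ndarray                 # (T,) seconds, sorted by (participant, cell)
    correct: np.ndarray            # (T,) int8
    offsets: np.ndarray            # (N, 6, 2) start/stop into rt
    min_rt: np.ndarray             # (N,)
    ncols: np.ndarray              # (3,) participant columns per param
    pcol: np.ndarray               # (3, 6) cell -> participant column
    gidx: np.ndarray               # (3, 2, 6) (param, group, cell) -> group node
    ngroups: np.ndarray            # (3,)
    priors: PriorSpec = field(default_factory=PriorSpec)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return int(self.rt.shape[0])

    def node_names(self) -> list:
        names = []
        for k, pname in enumerate(PARAMS):
            for i, pid in enumerate(self.participants):
                for c in range(self.ncols[k]):
                    if self.ncols[k] == 1:
                        names.append(f"{pname}[{pid}]")
                    else:
                        cond, coh = CELLS[c]
                        names.append(f"{pname}[{pid},{cond},{coh}]")
        for stat in ("mu", "sigma"):
            for k, pname in enumerate(PARAMS):
                for g in range(self.ngroups[k]):
                    if self.ngroups[k] == 1:
                        names.append(f"{stat}_{pname}")
                    else:
                        grp = AGE_GROUPS[g // 6]
                        cond, coh = CELLS[g % 6]
                        names.append(f"{stat}_{pname}[{cond},{coh},{grp}]")
        return names

    def n_nodes(self) -> int:
        npart = sum(int(self.ncols[k]) for k in range(3)) * self.n_participants
        ngrp = 2 * sum(int(self.ngroups[k]) for k in range(3))
        return npart + ngrp

    def participant_value(self, draws_row: np.ndarray, param: str, pid: str,
                          cell=None) -> float:
        """Read one participant-level node out of a flat node vector."""
        k = PARAMS.index(param)
        i = self.participants.index(pid)
        off = 0
        for kk in range(k):
            off += self.n_participants * int(self.ncols[kk])
        if self.ncols[k] == 1:
            c = 0
        else:
            c = CELLS.index(tuple(cell))
        return float(draws_row[off + i * int(self.ncols[k]) + c])

    def deviance(self, node_vector: np.ndarray, eps: float = 1e-7) -> float:
        """-2 log likelihood of the data at a flat node vector."""
        x = self.participant_array(node_vector)
        total = 0.0
        for i in range(self.n_participants):
            for c in range(6):
                s, e = self.offsets[i, c]
                if s == e:
                    continue
                total += _loglik_trials(
                    self.rt[s:e], self.correct[s:e],
                    x[i, 0, self.pcol[0, c]], x[i, 1, self.pcol[1, c]],
                    x[i, 2, self.pcol[2, c]], eps)
        return float(-2.0 * total)

    def participant_array(self, node_vector: np.ndarray) -> np.ndarray:
        """Unflatten the participant-node block into an (N, 3, 6) array."""
        N = self.n_participants
        x = np.zeros((N, 3, 6))
        off = 0
        for k in range(3):
            nc = int(self.ncols[k])
            x[:, k, :nc] = node_vector[off:off + N * nc].reshape(N, nc)
            off += N * nc
        return x


def build_model(variant: ModelVariant, trials: pd.DataFrame,
                age_threshold: float = DEFAULT_AGE_THRESHOLD,
                priors: PriorSpec | None = None,
                rt_unit: str = "ms") -> HddmModel:
    """Compile a preprocessed trial table into a fittable model graph.

    Every participant must contribute at least one trial to each
    condition x coherence cell; an empty cell is a configuration error
    (the cell's parameters would be informed by the prior alone).
    """
    if priors is None:
        priors = PriorSpec()
    if rt_unit not in ("ms", "s"):
        raise ValueError("rt_unit must be 'ms' or 's'")
    if len(trials) == 0:
        raise ModelConfigError("cannot build a model from an empty trial table")
    if trials["rt"].isna().any() or trials["timeout"].astype(bool).any():
        raise ModelConfigError("trial table still contains timeouts; preprocess first")
    scale = 1e-3 if rt_unit == "ms" else 1.0

    participants = list(dict.fromkeys(trials["participant_id"]))
    N = len(participants)
    ages = np.array([float(trials.loc[trials["participant_id"] == p, "age"].iloc[0])
                     for p in participants])
    age_group = np.array([1 if assign_age_group(a, age_threshold) == "OA" else 0
                          for a in ages], dtype=np.int8)

    cell_index = {cell: c for c, cell in enumerate(CELLS)}
    pi = trials["participant_id"].map({p: i for i, p in enumerate(participants)})
    ci = [cell_index[(cond, coh)] for cond, coh in
          zip(trials["condition"], trials["coherence"])]
    order = np.lexsort((np.array(ci), pi.to_numpy()))
    rt = trials["rt"].to_numpy(dtype=float)[order] * scale
    correct = trials["correct"].to_numpy().astype(np.int8)[order]
    pi_s = pi.to_numpy()[order]
    ci_s = np.asarray(ci)[order]

    offsets = np.zeros((N, 6, 2), dtype=np.int64)
    for i in range(N):
        for c in range(6):
            mask = (pi_s == i) & (ci_s == c)
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                cond, coh = CELLS[c]
                raise ModelConfigError(
                    f"participant {participants[i]} has no trials in cell "
                    f"({cond}, {coh})")
            offsets[i, c] = (idx[0], idx[-1] + 1)
    min_rt = np.array([rt[pi_s == i].min() for i in range(N)])

    ncols = np.array([6 if p in variant.varies else 1 for p in PARAMS],
                     dtype=np.int64)
    pcol = np.zeros((3, 6), dtype=np.int64)
    gidx = np.zeros((3, 2, 6), dtype=np.int64)
    ngroups = np.zeros(3, dtype=np.int64)
    for k, p in enumerate(PARAMS):
        if p in variant.varies:
            pcol[k] = np.arange(6)
            for g in range(2):
                for c in range(6):
                    gidx[k, g, c] = g * 6 + c
            ngroups[k] = 12
        else:
            ngroups[k] = 1
    return HddmModel(variant=variant, participants=participants, ages=ages,
                     age_group=age_group, age_threshold=age_threshold,
                     rt=rt, correct=correct, offsets=offsets, min_rt=min_rt,
                     ncols=ncols, pcol=pcol, gidx=gidx, ngroups=ngroups,
                     priors=priors)
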