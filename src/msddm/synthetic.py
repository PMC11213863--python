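"""Synthetic behavioural datasets for the audiovisual categorisation task.

Emulates the experimental design — three sensory conditions (visual V,
auditory A, audiovisual AV) crossed with two phase-coherence levels (HC, LC)
and two stimulus categories (face, car), 216 trials per participant in three
blocks of 72, a 3000 ms response deadline — and an age-structured generative
model for the diffusion parameters: drift rate declines with age in every
cell, boundary separation and non-decision time increase with age in specific
cells, and the audiovisual drift at high coherence sits at the optimal
combination of the unisensory drifts plus an age-increasing benefit.

Ground-truth parameters are returned alongside every simulated dataset so
that recovery of the fitted model can be checked cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .wfpt import WienerParams

__all__ = [
    "CONDITIONS",
    "COHERENCES",
    "CATEGORIES",
    "CELLS",
    "DesignSpec",
    "AgeGenerativeModel",
    "build_design",
    "sample_participant_params",
    "simulate_trial",
    "simulate_trials",
    "simulate_dataset",
]

CONDITIONS = ("V", "A", "AV")
COHERENCES = ("HC", "LC")
CATEGORIES = ("face", "car")
#: the six condition x coherence cells the diffusion parameters live on
CELLS = tuple((cond, coh) for cond in CONDITIONS for coh in COHERENCES)

EULER_DT = 1e-4  # s; step of the first-passage simulator


class DesignError(ValueError):
    """Raised when a design specification cannot be balanced."""


@dataclass(frozen=True)
class DesignSpec:
    """Trial-count layout of the experiment.

    Defaults reproduce the study design: 3 blocks x 72 trials, split equally
    over 3 sensory conditions, 2 coherence levels and 2 stimulus categories,
    with a 3000 ms response deadline.  ``stimulus_duration_ms`` is metadata
    only (the simulator does not model the stimulus interval).
    """

    n_blocks: int = 3
    trials_per_block: int = 72
    conditions: tuple = CONDITIONS
    coherences: tuple = COHERENCES
    categories: tuple = CATEGORIES
    deadline_ms: float = 3000.0
    stimulus_duration_ms: float = 300.0

    @property
    def n_cells(self) -> int:
        return len(self.conditions) * len(self.coherences) * len(self.categories)

    @property
    def trials_per_participant(self) -> int:
        return self.n_blocks * self.trials_per_block

    def validate(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise DesignError("n_blocks and trials_per_block must be positive")
        if self.trials_per_block % self.n_cells != 0:
            raise DesignError(
                f"trials_per_block={self.trials_per_block} is not divisible by "
                f"the {self.n_cells} design cells "
                f"({len(self.conditions)} conditions x {len(self.coherences)} "
                f"coherences x {len(self.categories)} categories)"
            )
        if self.deadline_ms < 0:
            raise DesignError("deadline must be non-negative")


def _default_cell_table(values_by_cell: dict) -> dict:
    return dict(values_by_cell)


def _default_delta_intercepts() -> dict:
    # reference-age (young adult) drift rates; HC > LC, V slightly above A.
    # The AV/HC entry is derived from the optimal-combination rule and is
    # therefore ignored by the sampler; kept for completeness.
    return {
        ("V", "HC"): 2.0, ("A", "HC"): 1.8,
        ("AV", "HC"): float(np.hypot(2.0, 1.8)),
        ("V", "LC"): 1.2, ("A", "LC"): 1.0,
        ("AV", "LC"): float(np.hypot(1.2, 1.0)),
    }


def _default_delta_slopes() -> dict:
    # drift declines with age in every cell; the AV/LC slope matches the
    # age derivative of sqrt(delta_V^2 + delta_A^2) at LC so that the
    # low-coherence optimal-combination gap stays flat in age (the
    # multisensory benefit is age-increasing at high coherence only)
    slopes = {cell: -0.010 for cell in CELLS}
    slopes[("AV", "LC")] = -0.010 * (1.2 + 1.0) / float(np.hypot(1.2, 1.0))
    return slopes


def _default_theta_intercepts() -> dict:
    return {cell: 1.5 for cell in CELLS}


def _default_theta_slopes() -> dict:
    # boundary rises with age in A/LC, AV/LC and V/HC only
    slopes = {cell: 0.0 for cell in CELLS}
    for cell in (("A", "LC"), ("AV", "LC"), ("V", "HC")):
        slopes[cell] = 0.004
    return slopes


def _default_tau_intercepts() -> dict:
    return {cell: 0.35 for cell in CELLS}


def _default_tau_slopes() -> dict:
    # non-decision time rises with age in V/LC only
    slopes = {cell: 0.0 for cell in CELLS}
    slopes[("V", "LC")] = 0.0015
    return slopes


@dataclass(frozen=True)
class AgeGenerativeModel:
    """Age-structured generative model for participant-level diffusion
    parameters.

    Each of delta (drift), theta (boundary) and tau (non-decision time) has,
    per condition x coherence cell, a linear age trend
    ``intercept + slope * (age - reference_age)`` plus independent Gaussian
    between-participant noise (``*_spread``), truncated below at a positivity
    floor.  The AV drift at high coherence is not free: its cell mean is the
    optimal combination sqrt(delta_V^2 + delta_A^2) of the unisensory HC cell
    means plus ``av_benefit_slope * (age - reference_age)``, so that the
    multisensory benefit grows with age at high coherence only.
    """

    reference_age: float = 18.0
    age_range: tuple = (18.0, 90.0)
    delta_intercepts: dict = field(default_factory=_default_delta_intercepts)
    delta_slopes: dict = field(default_factory=_default_delta_slopes)
    theta_intercepts: dict = field(default_factory=_default_theta_intercepts)
    theta_slopes: dict = field(default_factory=_default_theta_slopes)
    tau_intercepts: dict = field(default_factory=_default_tau_intercepts)
    tau_slopes: dict = field(default_factory=_default_tau_slopes)
    delta_spread: float = 0.25
    theta_spread: float = 0.15
    tau_spread: float = 0.05
    delta_floor: float = 0.05
    theta_floor: float = 0.30
    tau_floor: float = 0.10
    av_benefit_slope: float = 0.008

    def cell_means(self, age: float) -> dict:
        """Noise-free parameter means for every cell at the given age."""
        da = age - self.reference_age
        out = {}
        for cell in CELLS:
            delta = self.delta_intercepts[cell] + self.delta_slopes[cell] * da
            theta = self.theta_intercepts[cell] + self.theta_slopes[cell] * da
            tau = self.tau_intercepts[cell] + self.tau_slopes[cell] * da
            out[cell] = [delta, theta, tau]
        # optimal-combination rule for the audiovisual HC drift
        d_v = out[("V", "HC")][0]
        d_a = out[("A", "HC")][0]
        out[("AV", "HC")][0] = float(np.hypot(d_v, d_a)) + self.av_benefit_slope * da
        for cell in CELLS:
            d, t, n = out[cell]
            out[cell] = [
                max(d, self.delta_floor),
                max(t, self.theta_floor),
                max(n, self.tau_floor),
            ]
        return out

    def validate(self) -> None:
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        for spread in (self.delta_spread, self.theta_spread, self.tau_spread):
            if spread < 0:
                raise ValueError("spreads must be non-negative")
        if self.delta_floor <= 0 or self.theta_floor <= 0 or self.tau_floor < 0:
            raise ValueError("floors must respect delta>0, theta>0, tau>=0")


def build_design(spec: DesignSpec, n_participants: int, seed: int) -> pd.DataFrame:
    """Balanced, pseudorandomised trial skeletons (no outcomes).

    Every participant receives an identical cell-count profile: each
    condition x coherence x category cell appears ``trials_per_block /
    n_cells`` times per block, and trial order is shuffled independently per
    participant and block with a stream derived from ``seed``.
    """
    spec.validate()
    if n_participants < 0:
        raise ValueError("n_participants must be non-negative")
    per_cell = spec.trials_per_block // spec.n_cells
    block_cells = [
        (cond, coh, cat)
        for cond in spec.conditions
        for coh in spec.coherences
        for cat in spec.categories
        for _ in range(per_cell)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD51]))
    rows = []
    for i in range(n_participants):
        pid = f"p{i + 1:03d}"
        for b in range(spec.n_blocks):
            order = rng.permutation(len(block_cells))
            for j, idx in enumerate(order):
                cond, coh, cat = block_cells[idx]
                rows.append((pid, b + 1, j + 1, cond, coh, cat))
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "block", "trial", "condition", "coherence",
                 "category"],
    )
    return df


def sample_participant_params(age: float, gen: AgeGenerativeModel,
                              seed) -> dict:
    """Draw one participant's parameter set: cell -> :class:`WienerParams`.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Deterministic
    given the seed; noise is independent across cells and parameters and the
    result respects the generator's positivity floors.
    """
    gen.validate()
    lo, hi = gen.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside generator age_range {gen.age_range}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = gen.cell_means(age)
    out = {}
    for cell in CELLS:
        d, t, n = means[cell]
        d = max(d + rng.normal(0.0, gen.delta_spread) if gen.delta_spread else d,
                gen.delta_floor)
        t = max(t + rng.normal(0.0, gen.theta_spread) if gen.theta_spread else t,
                gen.theta_floor)
        n = max(n + rng.normal(0.0, gen.tau_spread) if gen.tau_spread else n,
                gen.tau_floor)
        out[cell] = WienerParams(delta=float(d), theta=float(t), tau=float(n))
    return out


# continuity-correction constant for discretely monitored barriers,
# -zeta(1/2)/sqrt(2*pi): a barrier checked every dt behaves like a continuous
# barrier shifted outward by this multiple of sigma*sqrt(dt), so the discrete
# barriers are pulled inward by the same amount.
_BGK = 0.5826


@njit(cache=True)
def _euler_fpt_batch(n: int, delta: float, theta: float, tau: float, z: float,
                     deadline_s: float, dt: float, seed: int):
    """First-passage simulation by Euler-Maruyama, unit diffusion coefficient.

    All trials are stepped in parallel with block-generated Gaussian noise;
    finished trials are compacted out of the active set.  Returns
    (rt_s, correct, timeout) arrays; rt is NaN on timeout.  The deadline
    applies to the clock time tau + decision time.
    """
    np.random.seed(seed)
    rt = np.full(n, np.nan)
    correct = np.zeros(n, dtype=np.int8)
    timeout = np.zeros(n, dtype=np.int8)
    sqdt = np.sqrt(dt)
    drift = delta * dt
    up = theta - _BGK * sqdt
    lo = _BGK * sqdt
    if up <= lo:  # boundaries too tight for the correction at this dt
        up = theta
        lo = 0.0
    if tau >= deadline_s:
        for i in range(n):
            timeout[i] = 1
        return rt, correct, timeout
    max_steps = int(np.ceil((deadline_s - tau) / dt))
    x = np.full(n, z * theta)
    active = np.arange(n)
    m = n
    step = 0
    while m > 0 and step < max_steps:
        step += 1
        t_now = tau + step * dt
        noise = np.random.standard_normal(m)
        keep = 0
        for j in range(m):
            xi = x[j] + drift + sqdt * noise[j]
            if xi >= up:
                rt[active[j]] = t_now
                correct[active[j]] = 1
            elif xi <= lo:
                rt[active[j]] = t_now
            else:
                x[keep] = xi
                active[keep] = active[j]
                keep += 1
        m = keep
    for j in range(m):  # deadline reached while still diffusing
        timeout[active[j]] = 1
    return rt, correct, timeout


def simulate_trials(p: WienerParams, n: int, deadline_ms: float, seed: int,
                    dt: float = EULER_DT):
    """Simulate ``n`` independent trials; returns (rt_s, correct, timeout).

    RTs are in seconds (NaN on timeout); ``correct`` marks upper-boundary
    absorption (accuracy coding).
    """
    p.validate()
    if n < 0:
        raise ValueError("n must be non-negative")
    rt, correct, timeout = _euler_fpt_batch(
        int(n), p.delta, p.theta, p.tau, p.z, deadline_ms / 1000.0, dt,
        int(seed) % (2**32),
    )
    return rt, correct.astype(bool), timeout.astype(bool)


@dataclass(frozen=True)
class SimulatedTrial:
    rt_s: float | None
    correct: bool | None
    timeout: bool

    def __iter__(self):
        yield self.rt_s
        yield self.correct


def simulate_trial(p: WienerParams, deadline_ms: float, seed: int,
                   dt: float = EULER_DT) -> SimulatedTrial:
    """Simulate a single trial; timeout if no boundary is hit by the deadline."""
    rt, correct, timeout = simulate_trials(p, 1, deadline_ms, seed, dt)
    if timeout[0]:
        return SimulatedTrial(rt_s=None, correct=None, timeout=True)
    return SimulatedTrial(rt_s=float(rt[0]), correct=bool(correct[0]), timeout=False)


def simulate_dataset(spec: DesignSpec, gen: AgeGenerativeModel,
                     n_participants: int, seed: int,
                     dt: float = EULER_DT):
    """Full synthetic experiment: trial table plus ground-truth parameters.

    Returns ``(trials, truth)`` where ``trials`` has one row per trial with
    RT serialised in ms (empty on timeout) and ``truth`` one row per
    participant x cell with the generating delta/theta/tau.  Byte-identical
    for equal seeds: ages, parameter draws and trial noise all derive from a
    single root seed.
    """
    spec.validate()
    gen.validate()
    design = build_design(spec, n_participants, seed)
    root = np.random.SeedSequence([int(seed), 0x5EED])
    age_ss, param_ss, trial_ss = root.spawn(3)
    rng_age = np.random.default_rng(age_ss)
    rng_param = np.random.default_rng(param_ss)
    lo, hi = gen.age_range
    pids = [f"p{i + 1:03d}" for i in range(n_participants)]
    ages = {pid: float(rng_age.uniform(lo, hi)) for pid in pids}
    truth_rows = []
    params = {}
    for pid in pids:
        params[pid] = sample_participant_params(ages[pid], gen, rng_param)
        for cell in CELLS:
            p = params[pid][cell]
            truth_rows.append((pid, ages[pid], cell[0], cell[1],
                               p.delta, p.theta, p.tau))
    truth = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "age", "condition", "coherence",
                 "delta", "theta", "tau"],
    )
    if n_participants == 0:
        trials = design.assign(age=pd.Series(dtype=float),
                               rt=pd.Series(dtype=float),
                               response=pd.Series(dtype=object),
                               correct=pd.Series(dtype=object),
                               timeout=pd.Series(dtype=bool))
        return trials, truth

    # simulate per participant x cell with derived integer seeds
    trial_seeds = trial_ss.generate_state(n_participants * len(CELLS))
    rt_col = np.full(len(design), np.nan)
    cor_col = np.zeros(len(design), dtype=bool)
    tmo_col = np.zeros(len(design), dtype=bool)
    pid_codes = design["participant_id"].to_numpy()
    for i, pid in enumerate(pids):
        pmask = pid_codes == pid
        for c, cell in enumerate(CELLS):
            mask = pmask & (design["condition"].to_numpy() == cell[0]) \
                & (design["coherence"].to_numpy() == cell[1])
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            sd = int(trial_seeds[i * len(CELLS) + c])
            rt, correct, timeout = simulate_trials(
                params[pid][cell], idx.size, spec.deadline_ms, sd, dt)
            rt_col[idx] = rt
            cor_col[idx] = correct
            tmo_col[idx] = timeout
    trials = design.copy()
    trials["age"] = trials["participant_id"].map(ages)
    trials["rt"] = np.round(rt_col * 1000.0, 6)  # ms
    # response is the chosen category: the presented one if correct
    other = {"face": "car", "car": "face"}
    responses = np.where(
        cor_col, trials["category"],
        trials["category"].map(other),
    ).astype(object)
    responses[tmo_col] = None
    trials["response"] = responses
    trials["correct"] = [None if t else bool(c) for c, t in zip(cor_col, tmo_col)]
    trials["timeout"] = tmo_col
    cols = ["participant_id", "age", "block", "trial", "condition",
            "coherence", "category", "rt", "response", "correct", "timeout"]
    return trials[cols], truth
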