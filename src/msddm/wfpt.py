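"""Exact first-passage-time mathematics of the two-boundary Wiener diffusion.

The decision process is a drifted Brownian motion with unit diffusion
coefficient, drift ``delta`` (evidence/s), absorbing boundaries at 0 and
``theta`` (evidence units), and starting point ``z * theta`` with relative
start ``z`` in (0, 1).  Observed response time is the first-passage time plus
a non-decision offset ``tau`` (s).  Under accuracy coding the upper boundary
is the correct response and the lower boundary the incorrect one.

The joint density of (boundary, t) is evaluated with the classic pair of
series expansions — a small-time expansion in image terms and a large-time
eigenfunction expansion — with the branch chosen per evaluation point by
whichever needs fewer terms for the requested absolute error.  All internal
time units are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, vectorize

__all__ = [
    "WienerParams",
    "wfpt_density",
    "choice_probability",
    "log_likelihood",
    "mean_decision_time",
]

DEFAULT_EPS = 1e-7

#: boundary labels, accuracy coded
UPPER = "upper"
LOWER = "lower"


@dataclass(frozen=True)
class WienerParams:
    """One decision-process parameter set.

    Attributes
    ----------
    delta : float
        Drift rate, evidence per second.  May take either sign.
    theta : float
        Boundary separation, must be positive.
    tau : float
        Non-decision time in seconds, must be non-negative.
    z : float
        Relative starting point in (0, 1); 0.5 is unbiased and is the
        fixed value used throughout the fitting pipeline.
    """

    delta: float
    theta: float
    tau: float
    z: float = 0.5

    def validate(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError(f"drift rate must be finite, got {self.delta}")
        if not (self.theta > 0):
            raise ValueError(f"boundary separation must be positive, got {self.theta}")
        if not (self.tau >= 0):
            raise ValueError(f"non-decision time must be >= 0, got {self.tau}")
        if not (0 < self.z < 1):
            raise ValueError(f"relative starting point must lie in (0,1), got {self.z}")


@njit(cache=True)
def _f0_lower(tt: float, w: float, eps0: float) -> float:
    """Standardised lower-boundary FPT density (drift 0, boundary 1, start w)
    at normalised time tt, truncated so the absolute error is <= eps0.

    Chooses between the small-time image expansion and the large-time
    eigenfunction expansion by the fewer-terms rule.
    """
    if tt <= 0.0:
        return 0.0
    # required terms for the small-time expansion
    if 2.0 * np.sqrt(2.0 * np.pi * tt) * eps0 < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * eps0 * np.sqrt(2.0 * np.pi * tt)))
        ks = max(ks, np.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    # required terms for the large-time expansion
    if np.pi * tt * eps0 < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * eps0) / (np.pi * np.pi * tt))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(tt)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tt))

    if ks < kl:
        K = int(np.ceil(ks))
        acc = 0.0
        for k in range(-((K - 1) // 2), K // 2 + 1):
            arg = w + 2.0 * k
            acc += arg * np.exp(-arg * arg / (2.0 * tt))
        return acc / np.sqrt(2.0 * np.pi * tt**3)
    K = int(np.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * np.exp(-k * k * np.pi * np.pi * tt / 2.0) * np.sin(k * np.pi * w)
    return np.pi * acc


@njit(cache=True)
def _wfpt_pdf(t: float, upper: bool, delta: float, theta: float, tau: float,
              z: float, eps: float) -> float:
    """Joint density of hitting the given boundary at clock time t (s)."""
    u = t - tau
    if u <= 0.0:
        return 0.0
    if upper:
        # reflect: the upper boundary under (delta, z) is the lower
        # boundary under (-delta, 1-z)
        v = -delta
        w = 1.0 - z
    else:
        v = delta
        w = z
    a2 = theta * theta
    tt = u / a2
    pref = np.exp(-v * theta * w - v * v * u / 2.0) / a2
    if pref <= 0.0:
        return 0.0
    # truncation error on the standardised density that keeps the final
    # absolute error below eps
    eps0 = eps * a2 / pref
    if eps0 < 1e-300:
        eps0 = 1e-300
    val = pref * _f0_lower(tt, w, eps0)
    return val if val > 0.0 else 0.0


@njit(cache=True)
def _wfpt_logpdf(t: float, upper: bool, delta: float, theta: float, tau: float,
                 z: float, eps: float) -> float:
    d = _wfpt_pdf(t, upper, delta, theta, tau, z, eps)
    if d <= 0.0:
        return -np.inf
    return np.log(d)


@njit(cache=True)
def _loglik_trials(rt: np.ndarray, correct: np.ndarray, delta: float,
                   theta: float, tau: float, eps: float) -> float:
    """Sum of accuracy-coded log densities over a set of trials (RT in s)."""
    total = 0.0
    for i in range(rt.shape[0]):
        lp = _wfpt_logpdf(rt[i], correct[i] != 0, delta, theta, tau, 0.5, eps)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


def wfpt_density(t, boundary: str, p: WienerParams, eps: float = DEFAULT_EPS):
    """Joint first-passage density of (boundary, t), in 1/s.

    Parameters
    ----------
    t : float or array
        Clock time(s) in seconds (non-decision time included).
    boundary : {"upper", "lower"}
        Which absorbing boundary; "upper" is the correct response under
        accuracy coding.
    p : WienerParams
    eps : float
        Absolute truncation-error tolerance per evaluation.

    Returns zero for ``t <= tau``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if boundary not in (UPPER, LOWER):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    p.validate()
    up = boundary == UPPER
    t_arr = np.asarray(t, dtype=float)
    out = np.empty(t_arr.shape, dtype=float)
    flat_t = t_arr.ravel()
    flat_o = out.ravel()
    for i in range(flat_t.size):
        flat_o[i] = _wfpt_pdf(flat_t[i], up, p.delta, p.theta, p.tau, p.z, eps)
    return out if t_arr.shape else float(out)


def choice_probability(p: WienerParams, boundary: str = UPPER) -> float:
    """Closed-form absorption probability of the drifted diffusion.

    For drift v, boundary separation a, relative start z the probability of
    absorption at the upper boundary is (1 - exp(-2 v a z)) / (1 - exp(-2 v a)),
    degenerating to z at v = 0.  Upper and lower probabilities sum to one.
    """
    if boundary not in (UPPER, LOWER):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    p.validate()
    va = p.delta * p.theta
    if abs(va) < 1e-10:
        p_up = p.z
    else:
        # stable form via expm1
        p_up = np.expm1(-2.0 * va * p.z) / np.expm1(-2.0 * va)
    return float(p_up) if boundary == UPPER else float(1.0 - p_up)


def mean_decision_time(p: WienerParams) -> float:
    """Expected first-passage time (s), excluding non-decision time.

    For the unbiased start (z = 1/2) this is (theta / (2 delta)) *
    tanh(delta * theta / 2); the general closed form is used otherwise.
    """
    p.validate()
    v, a, z = p.delta, p.theta, p.z
    if abs(v) < 1e-10:
        # driftless: E[T] = a^2 z (1 - z)
        return float(a * a * z * (1.0 - z))
    x0 = z * a
    c = 2.0 * v

    def coth_term(x):
        return 1.0 / np.tanh(x)

    # standard two-barrier mean exit time for drifted BM
    num = 1.0 - np.exp(-c * x0)
    den = 1.0 - np.exp(-c * a)
    p_up = num / den
    return float((a * p_up - x0) / v)


def log_likelihood(trials, params_map: dict, rt_unit: str = "ms",
                   eps: float = DEFAULT_EPS) -> float:
    """Total log density of a preprocessed trial table.

    Parameters
    ----------
    trials : pandas.DataFrame
        Must contain ``rt`` (in ``rt_unit``), boolean ``correct``, and the
        cell-label columns ``condition`` and ``coherence``.  Timeout trials
        are not accepted here — they are removed during preprocessing.
    params_map : dict
        Maps ``(condition, coherence)`` to :class:`WienerParams`.
    rt_unit : {"ms", "s"}
        Unit of the ``rt`` column; converted to seconds at this boundary.

    Returns ``-inf`` if any RT is at or below the non-decision time of its
    cell.  The empty table has log likelihood 0.
    """
    if rt_unit not in ("ms", "s"):
        raise ValueError(f"rt_unit must be 'ms' or 's', got {rt_unit!r}")
    if len(trials) == 0:
        return 0.0
    if trials["rt"].isna().any():
        raise ValueError("trial table contains missing RTs; preprocess first")
    scale = 1e-3 if rt_unit == "ms" else 1.0
    total = 0.0
    for (cond, coh), grp in trials.groupby(["condition", "coherence"], sort=False):
        key = (cond, coh)
        if key not in params_map:
            raise KeyError(f"no parameters supplied for cell {key}")
        p = params_map[key]
        p.validate()
        rt = grp["rt"].to_numpy(dtype=float) * scale
        correct = grp["correct"].to_numpy().astype(np.int8)
        total += _loglik_trials(rt, correct, p.delta, p.theta, p.tau, eps)
        if not np.isfinite(total):
            return -np.inf
    return float(total)
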