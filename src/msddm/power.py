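"""A-priori power analysis for a fixed-effects multiple regression F test.

Follows the "R-squared deviation from zero" convention: for ``k``
predictors and ``N`` observations, the test statistic under the alternative
is noncentral F with ``df1 = k``, ``df2 = N - k - 1`` and noncentrality
``lambda = f2 * N`` (Cohen's effect size f-squared times the total sample
size).  Alternative lambda conventions exist and shift the required N by a
participant or two; this one is the G*Power fixed-model default.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "power_at", "required_sample_size"]

N_CAP = 1_000_000


@dataclass(frozen=True)
class PowerSpec:
    n_predictors: int = 3
    f2: float = 0.10
    alpha: float = 0.05
    power: float = 0.95

    def validate(self) -> None:
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")
        if not self.f2 >= 0:
            raise ValueError("f2 must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("target power must lie in (0, 1)")


def power_at(spec: PowerSpec, n: int) -> float:
    """Achieved power of the F test at sample size ``n``."""
    spec.validate()
    df1 = spec.n_predictors
    df2 = n - spec.n_predictors - 1
    if df2 < 1:
        raise ValueError(f"n={n} leaves no error degrees of freedom")
    lam = spec.f2 * n
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    if lam == 0:  # central case; scipy's ncf degenerates at zero
        return float(stats.f.sf(fcrit, df1, df2))
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, n_cap: int = N_CAP) -> int:
    """Smallest N whose achieved power reaches the target.

    The power curve is monotone non-decreasing in N, so a bracketing
    doubling search followed by bisection finds the exact argmin.
    """
    spec.validate()
    if spec.f2 == 0:
        raise ValueError("required sample size undefined for a null effect")
    lo = spec.n_predictors + 2  # smallest valid model
    if power_at(spec, lo) >= spec.power:
        return lo
    hi = lo
    while power_at(spec, hi) < spec.power:
        hi *= 2
        if hi > n_cap:
            raise ValueError(
                f"target power {spec.power} not reachable below N={n_cap}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
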