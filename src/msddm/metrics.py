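"""Derived multisensory statistics on fitted diffusion parameters.

Three families of participant-level quantities, each subsequently
correlated with chronological age across the cohort:

* audiovisual-minus-visual (AV - V) parameter differences, per coherence
  level or collapsed (averaged) across coherence;
* the optimal-combination drift gap  delta_AV - sqrt(delta_V^2 + delta_A^2)
  per coherence level — positive values mean multisensory evidence
  accumulation exceeds the optimal combination of the unisensory rates;
* the measure of inverse effectiveness (MoIE), the difference-of-differences
  (X_LC^MS - X_LC^US) - (X_HC^MS - X_HC^US), where MS is the audiovisual
  cell and US the best unisensory cell at that coherence: highest drift,
  lowest boundary, lowest non-decision time, selected per participant and
  per coherence level.

Age correlations are Pearson R with a two-sided t-test p-value and a 95%
Fisher-z confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PARAMS
from .synthetic import CELLS
from .sampler import Posterior

__all__ = ["ParticipantEstimates", "av_minus_v", "optimal_combination_gap",
           "moie", "age_correlation", "benefit_report",
           "estimates_from_posterior"]


class MissingCellError(KeyError):
    pass


@dataclass(frozen=True)
class ParticipantEstimates:
    """Posterior point estimates for one participant, per cell."""

    participant_id: str
    age: float
    values: dict  # (param, condition, coherence) -> float

    def get(self, param: str, condition: str, coherence: str) -> float:
        key = (param, condition, coherence)
        if key not in self.values:
            raise MissingCellError(
                f"participant {self.participant_id} has no estimate for {key}")
        return float(self.values[key])


def estimates_from_posterior(posterior: Posterior, model,
                             point: str = "mean") -> list:
    """Participant-level point estimates (posterior mean, or median via
    ``point='median'``) for every participant and cell."""
    if point not in ("mean", "median"):
        raise ValueError("point must be 'mean' or 'median'")
    reducer = np.mean if point == "mean" else np.median
    out = []
    for i, pid in enumerate(model.participants):
        values = {}
        for k, param in enumerate(PARAMS):
            for c, (cond, coh) in enumerate(CELLS):
                if model.ncols[k] == 1:
                    name = f"{param}[{pid}]"
                else:
                    name = f"{param}[{pid},{cond},{coh}]"
                values[(param, cond, coh)] = float(reducer(posterior.pooled(name)))
        out.append(ParticipantEstimates(participant_id=pid,
                                        age=float(model.ages[i]),
                                        values=values))
    return out


def av_minus_v(est: ParticipantEstimates, parameter: str,
               mode: str = "per-coherence"):
    """AV minus V parameter difference.

    ``mode='per-coherence'`` returns ``{'HC': ..., 'LC': ...}``;
    ``mode='collapsed'`` returns their mean (collapsing across coherence).
    """
    if parameter not in PARAMS:
        raise ValueError(f"unknown parameter {parameter!r}")
    diffs = {coh: est.get(parameter, "AV", coh) - est.get(parameter, "V", coh)
             for coh in ("HC", "LC")}
    if mode == "per-coherence":
        return diffs
    if mode == "collapsed":
        return (diffs["HC"] + diffs["LC"]) / 2.0
    raise ValueError("mode must be 'per-coherence' or 'collapsed'")


def optimal_combination_gap(delta_av: dict, delta_v: dict, delta_a: dict) -> dict:
    """Drift gap above the optimal unisensory combination, per coherence.

    Each argument maps coherence level ('HC'/'LC') to a drift estimate;
    returns ``delta_AV - sqrt(delta_V^2 + delta_A^2)`` per level.  Squares
    are taken as written, so negative drifts contribute their magnitude.
    """
    out = {}
    for coh in ("HC", "LC"):
        out[coh] = float(delta_av[coh]
                         - np.sqrt(delta_v[coh] ** 2 + delta_a[coh] ** 2))
    return out


def optimal_combination_gap_from_estimates(est: ParticipantEstimates) -> dict:
    return optimal_combination_gap(
        {coh: est.get("delta", "AV", coh) for coh in ("HC", "LC")},
        {coh: est.get("delta", "V", coh) for coh in ("HC", "LC")},
        {coh: est.get("delta", "A", coh) for coh in ("HC", "LC")},
    )


def moie(est: ParticipantEstimates, parameter: str) -> float:
    """Measure of inverse effectiveness for one parameter.

    (X_LC^MS - X_LC^US) - (X_HC^MS - X_HC^US) with the multisensory cell MS
    = AV and the optimal unisensory cell US chosen per coherence level:
    the higher of {V, A} for drift, the lower for boundary and non-decision
    time.  Positive MoIE for drift means the multisensory benefit is larger
    when the stimulus is weaker (low coherence) — inverse effectiveness.
    """
    if parameter not in PARAMS:
        raise ValueError(f"unknown parameter {parameter!r}")
    pick = max if parameter == "delta" else min
    terms = {}
    for coh in ("HC", "LC"):
        us = pick(est.get(parameter, "V", coh), est.get(parameter, "A", coh))
        terms[coh] = est.get(parameter, "AV", coh) - us
    return float(terms["LC"] - terms["HC"])


def age_correlation(values, ages):
    """Pearson R against age, two-sided p, and a 95% Fisher-z CI.

    Requires at least three complete pairs and non-degenerate variance in
    both vectors.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    ok = np.isfinite(v) & np.isfinite(a)
    v, a = v[ok], a[ok]
    n = v.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.std(v) == 0 or np.std(a) == 0:
        raise ValueError("correlation undefined: zero variance input")
    res = stats.pearsonr(v, a)
    r = float(res.statistic)
    p = float(res.pvalue)
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        zr = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zcrit = stats.norm.ppf(0.975)
        ci = (float(np.tanh(zr - zcrit * se)), float(np.tanh(zr + zcrit * se)))
    return r, p, ci


def benefit_report(estimates: list, av_v_mode: str = "per-coherence") -> dict:
    """Cohort-level report: per-participant derived metrics plus age
    correlations for each.  Returns a dict with a per-participant DataFrame
    under ``'per_participant'`` and correlation summaries under
    ``'age_correlations'``."""
    rows = []
    for est in estimates:
        row = {"participant_id": est.participant_id, "age": est.age}
        for param in PARAMS:
            d = av_minus_v(est, param, "per-coherence")
            row[f"av_minus_v_{param}_HC"] = d["HC"]
            row[f"av_minus_v_{param}_LC"] = d["LC"]
            row[f"av_minus_v_{param}_collapsed"] = av_minus_v(est, param,
                                                              "collapsed")
            row[f"moie_{param}"] = moie(est, param)
        gap = optimal_combination_gap_from_estimates(est)
        row["opt_comb_gap_HC"] = gap["HC"]
        row["opt_comb_gap_LC"] = gap["LC"]
        rows.append(row)
    df = pd.DataFrame(rows)
    ages = df["age"].to_numpy()
    correlations = {}
    for col in df.columns:
        if col in ("participant_id", "age"):
            continue
        try:
            r, p, ci = age_correlation(df[col].to_numpy(), ages)
        except ValueError:
            continue
        correlations[col] = {"r": r, "p": p, "ci95": list(ci)}
    return {"per_participant": df, "age_correlations": correlations,
            "av_v_mode": av_v_mode}
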