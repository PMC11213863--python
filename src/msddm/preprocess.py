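"""Participant- and trial-level exclusion rules for behavioural trial tables.

Two stages, applied in order:

1. Participant exclusion: a participant whose overall proportion of correct
   responses (timeouts counted as incorrect) falls below 50% is removed
   entirely.  A participant at exactly 50% is retained; the threshold and a
   per-condition variant are configurable.
2. Trial exclusion, per surviving participant: timeouts are always removed,
   and any RT outside median ± 2.5 MAD is removed, where the median and the
   raw median absolute deviation (no normal-consistency constant) are
   computed over that participant's non-timeout RTs, pooled across
   conditions by default.

Both stages are pure selections: surviving rows are returned unaltered and
in their original order, and every removal is accounted for in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExclusionReport", "exclude_participants", "mad_filter_rts",
           "preprocess"]

MAD_MULTIPLIER = 2.5
ACCURACY_THRESHOLD = 0.5


@dataclass
class ExclusionReport:
    """Accounting of what was removed, by whom, and under which rule."""

    participants_in: int = 0
    participants_out: int = 0
    excluded_participant_ids: list = field(default_factory=list)
    trials_in: int = 0
    trials_out: int = 0
    removed_by_rule: dict = field(default_factory=lambda: {
        "accuracy_criterion": 0, "timeout": 0, "mad_outlier": 0})
    removed_per_participant: dict = field(default_factory=dict)
    all_timeout_participants: list = field(default_factory=list)

    def validate(self) -> None:
        removed = sum(self.removed_by_rule.values())
        if self.trials_out != self.trials_in - removed:
            raise AssertionError("exclusion report does not reconcile")

    def to_dict(self) -> dict:
        return {
            "participants_in": self.participants_in,
            "participants_out": self.participants_out,
            "excluded_participant_ids": list(self.excluded_participant_ids),
            "trials_in": self.trials_in,
            "trials_out": self.trials_out,
            "removed_by_rule": dict(self.removed_by_rule),
            "removed_per_participant": dict(self.removed_per_participant),
            "all_timeout_participants": list(self.all_timeout_participants),
        }


def _accuracy(g: pd.DataFrame) -> float:
    # timeouts count as incorrect
    correct = np.array([bool(v) if pd.notna(v) else False for v in g["correct"]])
    return float(correct.mean())


def exclude_participants(trials: pd.DataFrame,
                         threshold: float = ACCURACY_THRESHOLD,
                         per_condition: bool = False):
    """Remove all trials of participants below the accuracy criterion.

    With ``per_condition=True`` the criterion must be met within every
    sensory condition separately rather than pooled over all trials.
    Returns ``(filtered, report)``; exactly-at-threshold participants are
    retained.
    """
    report = ExclusionReport(trials_in=len(trials), trials_out=len(trials))
    if len(trials) == 0:
        return trials.copy(), report
    report.participants_in = trials["participant_id"].nunique()
    excluded = []
    for pid, g in trials.groupby("participant_id", sort=False):
        if per_condition:
            accs = [_accuracy(gc) for _, gc in g.groupby("condition", sort=False)]
            ok = min(accs) >= threshold
        else:
            ok = _accuracy(g) >= threshold
        if not ok:
            excluded.append(pid)
    keep = ~trials["participant_id"].isin(excluded)
    out = trials[keep]
    report.excluded_participant_ids = excluded
    report.participants_out = report.participants_in - len(excluded)
    report.trials_out = len(out)
    report.removed_by_rule["accuracy_criterion"] = int((~keep).sum())
    for pid in excluded:
        report.removed_per_participant[pid] = int((trials["participant_id"] == pid).sum())
    return out, report


def mad_filter_rts(trials: pd.DataFrame, multiplier: float = MAD_MULTIPLIER,
                   per_condition: bool = False):
    """Remove timeouts and RT outliers for a single participant's trials.

    Bounds are ``median ± multiplier * MAD`` of the participant's non-timeout
    RTs (pooled across conditions unless ``per_condition``); MAD is the raw
    median absolute deviation.  Returns ``(filtered, removals)`` where
    removals is a list of ``(index, rule)`` pairs.
    """
    removals = []
    if len(trials) == 0:
        return trials.copy(), removals
    timeout = trials["timeout"].astype(bool) | trials["rt"].isna()
    for idx in trials.index[timeout]:
        removals.append((idx, "timeout"))
    valid = trials[~timeout]
    if len(valid) == 0:
        return valid.copy(), removals

    def bounds(rts: np.ndarray):
        med = float(np.median(rts))
        mad = float(np.median(np.abs(rts - med)))
        return med - multiplier * mad, med + multiplier * mad

    keep_mask = pd.Series(True, index=valid.index)
    if per_condition:
        for _, g in valid.groupby("condition", sort=False):
            lo, hi = bounds(g["rt"].to_numpy(dtype=float))
            bad = (g["rt"] < lo) | (g["rt"] > hi)
            keep_mask.loc[g.index[bad]] = False
    else:
        lo, hi = bounds(valid["rt"].to_numpy(dtype=float))
        keep_mask = (valid["rt"] >= lo) & (valid["rt"] <= hi)
    for idx in valid.index[~keep_mask]:
        removals.append((idx, "mad_outlier"))
    return valid[keep_mask], removals


def preprocess(trials: pd.DataFrame, accuracy_threshold: float = ACCURACY_THRESHOLD,
               accuracy_per_condition: bool = False,
               mad_multiplier: float = MAD_MULTIPLIER,
               mad_per_condition: bool = False):
    """Full pipeline: participant exclusion first, then per-participant
    timeout and MAD filtering.  Returns ``(filtered, ExclusionReport)``."""
    filtered, report = exclude_participants(
        trials, threshold=accuracy_threshold, per_condition=accuracy_per_condition)
    kept_parts = []
    for pid, g in filtered.groupby("participant_id", sort=False):
        g2, removals = mad_filter_rts(g, multiplier=mad_multiplier,
                                      per_condition=mad_per_condition)
        kept_parts.append(g2)
        n_removed = len(removals)
        if n_removed:
            report.removed_per_participant[pid] = \
                report.removed_per_participant.get(pid, 0) + n_removed
        for _, rule in removals:
            report.removed_by_rule[rule] += 1
        if len(g2) == 0:
            report.all_timeout_participants.append(pid)
    out = pd.concat(kept_parts) if kept_parts else filtered.iloc[0:0]
    out = out.sort_index()  # preserve original trial order
    report.trials_out = len(out)
    report.validate()
    return out, report
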