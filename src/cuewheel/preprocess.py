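"""Trial exclusion and angular-error computation.

The cleaning pipeline mirrors the experiments' preprocessing: drop practice
blocks; drop misses, false alarms and pre-target responses (tallied against
their natural denominators — target trials for misses and pre-target
responses, catch trials for false alarms); then, within each subject-by-
condition cell, exclude trials whose log RT deviates from the cell median by
more than five times the median absolute deviation around the median (MADM,
raw — no normal-consistency scaling). The MADM pass runs exactly once, on
the post-exclusion data. Signed angular errors are wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._angles import angular_error
from .simulate import condition_cell

__all__ = [
    "ExclusionReport",
    "drop_invalid",
    "madm_filter",
    "MADMOutlierFilter",
    "to_clean",
    "clean_pipeline",
    "angular_error",
    "cells_for",
]

E1_CELL_KEYS = ["subject_id", "cue_type"]
E2_CELL_KEYS = ["subject_id", "soa_ms", "cue_type"]


def cells_for(experiment: str) -> list[str]:
    """Per-subject MADM cell keys: cue condition (E1), SOA x cue (E2)."""
    return E1_CELL_KEYS if experiment == "E1" else E2_CELL_KEYS


@dataclass
class ExclusionReport:
    """Per-rule exclusion tallies with the denominators used for each rate.

    Fractions use the post-practice-drop denominators: target trials for
    misses and pre-target responses, catch trials for false alarms, and the
    trials remaining after outcome exclusions for the MADM rule.
    """

    n_input: int = 0
    n_practice_dropped: int = 0
    n_target_trials: int = 0
    n_catch_trials: int = 0
    n_miss: int = 0
    n_false_alarm: int = 0
    n_correct_rejection: int = 0
    n_pre_target: int = 0
    n_before_madm: int = 0
    n_madm_outliers: int = 0

    @property
    def miss_fraction(self) -> float:
        return self.n_miss / self.n_target_trials if self.n_target_trials else 0.0

    @property
    def false_alarm_fraction(self) -> float:
        return self.n_false_alarm / self.n_catch_trials if self.n_catch_trials else 0.0

    @property
    def pre_target_fraction(self) -> float:
        return self.n_pre_target / self.n_target_trials if self.n_target_trials else 0.0

    @property
    def madm_fraction(self) -> float:
        return self.n_madm_outliers / self.n_before_madm if self.n_before_madm else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            miss_fraction=self.miss_fraction,
            false_alarm_fraction=self.false_alarm_fraction,
            pre_target_fraction=self.pre_target_fraction,
            madm_fraction=self.madm_fraction,
        )
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def drop_invalid(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove practice blocks, misses, false alarms and pre-target responses.

    Correct rejections (catch trials without a response) are also removed —
    the modelled dataset contains target hits only — but are tallied
    separately, not as an exclusion rule. Returns the retained trials and an
    :class:`ExclusionReport` (MADM fields unfilled).
    """
    if trials["outcome"].isna().any() or (trials["outcome"] == "").any():
        raise ValueError("outcome flags must be populated before exclusion")
    rep = ExclusionReport(n_input=len(trials))
    test = trials[trials["block"] > 0]
    rep.n_practice_dropped = len(trials) - len(test)
    is_target = test["target_present"].astype(bool)
    rep.n_target_trials = int(is_target.sum())
    rep.n_catch_trials = int((~is_target).sum())
    rep.n_miss = int((test["outcome"] == "miss").sum())
    rep.n_false_alarm = int((test["outcome"] == "false_alarm").sum())
    rep.n_correct_rejection = int((test["outcome"] == "correct_rejection").sum())
    rep.n_pre_target = int((test["outcome"] == "pre_target").sum())
    kept = test[test["outcome"] == "hit"].copy()
    rep.n_before_madm = len(kept)
    return kept, rep


def _madm_outlier_mask(log_rt: np.ndarray, multiplier: float) -> np.ndarray:
    """True where |log_rt - median| strictly exceeds multiplier * MADM."""
    m = np.median(log_rt)
    madm = np.median(np.abs(log_rt - m))
    return np.abs(log_rt - m) > multiplier * madm


def madm_filter(
    trials: pd.DataFrame,
    cell_keys: list[str],
    multiplier: float = 5.0,
    report: ExclusionReport | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop per-cell log-RT outliers by the 5x-MADM rule (strict inequality).

    Cells are the groups defined by ``cell_keys`` (e.g. subject x cue
    condition). MADM is the raw median absolute deviation around the median,
    with no consistency constant; a zero-MADM cell drops nothing, and empty
    cells are a no-op. The decision set is invariant to row order.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    if trials["rt_ms"].isna().any():
        raise ValueError("all trials must carry an RT before MADM filtering")
    rep = report if report is not None else ExclusionReport(n_before_madm=len(trials))
    if len(trials) == 0:
        return trials.copy(), rep
    log_rt = np.log(trials["rt_ms"].to_numpy(dtype=float))
    drop = np.zeros(len(trials), dtype=bool)
    grouped = pd.Series(np.arange(len(trials))).groupby(
        [trials[k].to_numpy() for k in cell_keys]
    )
    for _, idx in grouped:
        pos = idx.to_numpy()
        drop[pos] = _madm_outlier_mask(log_rt[pos], multiplier)
    rep.n_madm_outliers = int(drop.sum())
    return trials.iloc[~drop].copy(), rep


class MADMOutlierFilter(BaseEstimator):
    """Estimator-style wrapper for the per-cell MADM outlier rule.

    ``fit_transform(trials)`` computes each cell's median and MADM on the
    data it is given and drops outliers in one pass — the statistics are not
    carried over to new data, matching the single-pass filtering procedure.

    Parameters
    ----------
    cell_keys : list of str
        Grouping columns defining the filter cells.
    multiplier : float, default 5.0
        Outlier threshold in MADM units (strict inequality).
    """

    def __init__(self, cell_keys=("subject_id", "cue_type"), multiplier: float = 5.0):
        self.cell_keys = cell_keys
        self.multiplier = multiplier

    def fit(self, X: pd.DataFrame, y=None):
        _, self.report_ = madm_filter(X, list(self.cell_keys), self.multiplier)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        kept, self.report_ = madm_filter(X, list(self.cell_keys), self.multiplier)
        return kept

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit_transform(X)


def to_clean(trials: pd.DataFrame, experiment: str | None = None) -> pd.DataFrame:
    """Map retained target trials to the modelling table.

    One row per trial with ``subject_id``, ``cell`` (cue condition for E1,
    SOA x cue for E2), ``cue_type``, ``soa_ms``, ``log_rt`` and ``error_deg``
    in (-180, 180]. Empty input yields an empty frame.
    """
    cols = ["subject_id", "cell", "cue_type", "soa_ms", "log_rt", "error_deg"]
    if len(trials) == 0:
        return pd.DataFrame(columns=cols)
    experiment = experiment or str(trials["experiment"].iloc[0])
    missing = trials["response_colour_deg"].isna() | trials["target_colour_deg"].isna()
    if missing.any():
        raise ValueError("clean rows require both target and response colours")
    out = pd.DataFrame(
        {
            "subject_id": trials["subject_id"].to_numpy(),
            "cell": np.atleast_1d(
                condition_cell(
                    trials["cue_type"].to_numpy(), trials["soa_ms"].to_numpy(), experiment
                )
            ),
            "cue_type": trials["cue_type"].to_numpy(),
            "soa_ms": trials["soa_ms"].to_numpy(),
            "log_rt": np.log(trials["rt_ms"].to_numpy(dtype=float)),
            "error_deg": angular_error(
                trials["target_colour_deg"].to_numpy(),
                trials["response_colour_deg"].to_numpy(),
            ),
        }
    )
    return out[cols]


def clean_pipeline(
    trials: pd.DataFrame,
    experiment: str | None = None,
    madm_multiplier: float = 5.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full preprocessing: outcome exclusions, one MADM pass, clean table."""
    experiment = experiment or str(trials["experiment"].iloc[0])
    kept, rep = drop_invalid(trials)
    kept, rep = madm_filter(kept, cells_for(experiment), madm_multiplier, rep)
    return to_clean(kept, experiment), rep
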