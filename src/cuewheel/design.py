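"""Trial schedules for the two Posner-cueing colour-wheel experiments.

Experiment 1 (E1) uses central symbolic cues ("2"/"5" spatial, "H" neutral)
at a fixed 800 ms SOA. Spatial cues are 80% valid. One block realizes the
factorial design 6 cue slots (4 valid + 1 invalid + 1 neutral) x 2 target
sides x 5 repeats (4 target + 1 catch) = 60 trials.

Experiment 2 (E2) uses uninformative peripheral flashes (left/right/both) at
100 or 800 ms SOA. One block is 3 cue locations x 2 target sides x 2 SOAs x
(4 target + 1 catch) = 60 trials.

Catch trials (no target, 20% of trials) inherit the cue type and SOA of
their factorial cell. Schedules are plain pandas DataFrames with the columns
in :data:`TRIAL_COLUMNS`; response fields are left missing until simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "TrialSchedule",
    "build_block",
    "build_session",
    "design_tabulate",
    "catch_fraction",
    "e1_validity_fraction",
]

#: Canonical column order for trial tables (design + response fields).
TRIAL_COLUMNS = [
    "subject_id",
    "experiment",
    "block",
    "trial_index",
    "cue_type",
    "cue_symbol",
    "soa_ms",
    "target_present",
    "target_side",
    "target_colour_deg",
    "wheel_rotation_deg",
    "response_colour_deg",
    "rt_ms",
    "outcome",
]

E1_SOA_MS = 800
E2_SOAS_MS = (100, 800)

#: E1 counterbalance arms: which symbol indicates the right side.
ARM_2_RIGHT = "2->right"
ARM_2_LEFT = "2->left"


@dataclass
class TrialSchedule:
    """An ordered set of trials for one subject (or a bare design)."""

    experiment: str
    trials: pd.DataFrame
    counterbalance_arm: str | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def test_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["block"] > 0]

    @property
    def practice_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["block"] == 0]


def _e1_symbol(cue_side: str, arm: str) -> str:
    if cue_side == "none":
        return "H"
    if arm == ARM_2_RIGHT:
        return "2" if cue_side == "right" else "5"
    return "2" if cue_side == "left" else "5"


def _e2_symbol(cue_side: str) -> str:
    return {"left": "left-flash", "right": "right-flash", "none": "neutral-flash"}[cue_side]


def _cue_side(cue_type: str, target_side: str) -> str:
    """Side the cue points to, given the cue type and the cell's target side.

    Catch trials have no target on screen but belong to a factorial cell with
    a nominal side; the cue direction follows that cell.
    """
    if cue_type == "neutral":
        return "none"
    if cue_type == "valid":
        return target_side
    return "left" if target_side == "right" else "right"


def _block_cells(experiment: str) -> list[tuple[str, str, int]]:
    """(cue_type, cell_side, soa_ms) for every trial of one unshuffled block."""
    cells: list[tuple[str, str, int]] = []
    if experiment == "E1":
        # 6 cue slots: 4 valid, 1 invalid, 1 neutral; x 2 sides x (4 target + 1 catch)
        cue_slots = ["valid"] * 4 + ["invalid", "neutral"]
        for cue_type in cue_slots:
            for side in ("left", "right"):
                cells.extend([(cue_type, side, E1_SOA_MS)] * 5)
    elif experiment == "E2":
        # cue location x target side x SOA; cue_type derived from the pairing
        for cue_loc in ("left", "right", "none"):
            for side in ("left", "right"):
                if cue_loc == "none":
                    cue_type = "neutral"
                elif cue_loc == side:
                    cue_type = "valid"
                else:
                    cue_type = "invalid"
                for soa in E2_SOAS_MS:
                    cells.extend([(cue_type, side, soa)] * 5)
    else:
        raise ValueError(f"unknown experiment tag: {experiment!r} (expected 'E1' or 'E2')")
    return cells


def _materialize_block(
    experiment: str,
    block: int,
    rng: np.random.Generator,
    counterbalance_arm: str,
) -> pd.DataFrame:
    cells = _block_cells(experiment)
    rows = []
    for i, (cue_type, side, soa) in enumerate(cells):
        # within each 5-repeat run, the 5th is the catch trial
        target_present = (i % 5) != 4
        cue_side = _cue_side(cue_type, side)
        symbol = _e1_symbol(cue_side, counterbalance_arm) if experiment == "E1" else _e2_symbol(cue_side)
        rows.append(
            {
                "experiment": experiment,
                "block": block,
                "cue_type": cue_type,
                "cue_symbol": symbol,
                "soa_ms": soa,
                "target_present": target_present,
                "target_side": side if target_present else "none",
            }
        )
    df = pd.DataFrame(rows)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["target_colour_deg"] = np.where(
        df["target_present"], rng.uniform(0.0, 360.0, size=len(df)), np.nan
    )
    df["wheel_rotation_deg"] = rng.uniform(0.0, 360.0, size=len(df))
    df["response_colour_deg"] = np.nan
    df["rt_ms"] = np.nan
    df["outcome"] = pd.NA
    df["trial_index"] = np.arange(len(df))
    df["subject_id"] = "S00"
    return df[TRIAL_COLUMNS]


def build_block(
    experiment: str,
    seed: int | np.random.Generator = 0,
    counterbalance_arm: str = ARM_2_RIGHT,
    block: int = 1,
) -> TrialSchedule:
    """Build one 60-trial block with exactly the factorial cell counts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = _materialize_block(experiment, block, rng, counterbalance_arm)
    return TrialSchedule(experiment=experiment, trials=df, counterbalance_arm=counterbalance_arm)


def build_session(
    experiment: str,
    n_blocks: int = 7,
    practice: bool = True,
    seed: int | np.random.Generator = 0,
    counterbalance_arm: str = ARM_2_RIGHT,
    subject_id: str = "S00",
) -> TrialSchedule:
    """Build a full session: ``n_blocks`` test blocks of 60 trials, plus an
    optional practice block (block 0) of 30 trials sampled without
    replacement from one full block's 60."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = []
    if practice:
        full = _materialize_block(experiment, 0, rng, counterbalance_arm)
        keep = np.sort(rng.choice(len(full), size=30, replace=False))
        prac = full.iloc[keep].reset_index(drop=True)
        prac["trial_index"] = np.arange(len(prac))
        parts.append(prac)
    for b in range(1, n_blocks + 1):
        parts.append(_materialize_block(experiment, b, rng, counterbalance_arm))
    df = pd.concat(parts, ignore_index=True)
    df["subject_id"] = subject_id
    return TrialSchedule(experiment=experiment, trials=df, counterbalance_arm=counterbalance_arm)


def design_tabulate(schedule: TrialSchedule | pd.DataFrame) -> pd.DataFrame:
    """Trial counts by (cue_type x target_present x soa_ms).

    Returns a tidy frame with a ``count`` column summing to the schedule
    length. Empty input yields an empty (0-row) frame rather than an error.
    """
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    if len(df) == 0:
        return pd.DataFrame(columns=["cue_type", "target_present", "soa_ms", "count"])
    out = (
        df.groupby(["cue_type", "target_present", "soa_ms"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def catch_fraction(schedule: TrialSchedule | pd.DataFrame) -> float:
    """Fraction of trials with no target (catch trials)."""
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    return float((~df["target_present"].astype(bool)).mean())


def e1_validity_fraction(schedule: TrialSchedule | pd.DataFrame) -> float:
    """valid / (valid + invalid) among E1 spatial-cue target trials."""
    df = schedule.trials if isinstance(schedule, TrialSchedule) else schedule
    spatial = df[df["target_present"].astype(bool) & df["cue_type"].isin(["valid", "invalid"])]
    if len(spatial) == 0:
        return float("nan")
    return float((spatial["cue_type"] == "valid").mean())
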