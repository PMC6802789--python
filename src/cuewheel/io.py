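"""CSV/JSON readers and writers for pipeline artifacts.

All text outputs start with a ``# config_sha256=<hash>`` comment line so any
table can be traced back to the configuration that produced it; readers
skip comment lines. The trial CSV uses the documented column set of
:data:`cuewheel.design.TRIAL_COLUMNS`, one row per trial.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .design import TRIAL_COLUMNS

__all__ = ["write_table", "read_trials", "read_table", "write_json"]


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV (ours, or an equivalently structured deposit export).

    Accepts a raw-click representation: if ``response_colour_deg`` is absent
    but ``response_click_deg`` is present, the colour is recovered as
    click - wheel_rotation (mod 360).
    """
    df = read_table(path)
    if "response_colour_deg" not in df.columns and "response_click_deg" in df.columns:
        df["response_colour_deg"] = (
            df["response_click_deg"] - df["wheel_rotation_deg"]
        ) % 360.0
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df[TRIAL_COLUMNS]


def write_json(obj, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_sha256": config_hash, **obj} if isinstance(obj, dict) else obj
    path.write_text(json.dumps(payload, indent=2, default=float))
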