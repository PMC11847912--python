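"""Delimited-text readers/writers with strict schema validation.

The response table is the package's interchange format (comma-delimited,
one row per response; the image list is a ``|``-joined field, empty
meaning no image submitted). Errors name the offending column and the
1-based data row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synth.config import SYMPTOM_ITEMS, TREND_LEVELS
from .synth.cohort import RESPONSE_COLUMNS

_VALID_SYMPTOM = {"absent", "present", *TREND_LEVELS, ""}
_VALID_TRIAGE = {"low", "moderate", "high"}


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read and validate a response table.

    Enforces: all schema columns present; ``postop_day`` in [1, 30];
    ``triage_label`` in {low, moderate, high}; ``ssi48`` in {0, 1};
    symptom values among the known categories (blank = missing, treated
    downstream as absent). An empty ``image_ids`` field means no image.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    def fail(col: str, row: int, msg: str):
        raise ValueError(f"{path}: column {col!r}, row {row + 1}: {msg}")

    for i, v in enumerate(df["postop_day"]):
        try:
            day = int(v)
        except ValueError:
            fail("postop_day", i, f"not an integer: {v!r}")
        if not 1 <= day <= 30:
            fail("postop_day", i, f"must be in [1, 30], got {day}")
    df["postop_day"] = df["postop_day"].astype(int)

    bad = ~df["triage_label"].isin(_VALID_TRIAGE)
    if bad.any():
        i = int(bad.idxmax())
        fail("triage_label", i, f"invalid label {df.loc[i, 'triage_label']!r}")
    bad = ~df["ssi48"].isin({"0", "1"})
    if bad.any():
        i = int(bad.idxmax())
        fail("ssi48", i, f"must be 0 or 1, got {df.loc[i, 'ssi48']!r}")
    df["ssi48"] = df["ssi48"].astype(int)

    for item in SYMPTOM_ITEMS:
        col = f"sym_{item}"
        values = df[col].str.strip().str.lower()
        bad = ~values.isin(_VALID_SYMPTOM)
        if bad.any():
            i = int(bad.idxmax())
            fail(col, i, f"unknown category {df.loc[i, col]!r}")
    if df["response_id"].duplicated().any():
        i = int(df["response_id"].duplicated().idxmax())
        fail("response_id", i, "duplicate response_id")
    return df[list(RESPONSE_COLUMNS)]


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> Path:
    """Write a prediction table keyed by response_id."""
    if "response_id" not in predictions.columns:
        raise ValueError("prediction table must contain a response_id column")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    predictions.to_csv(path, index=False)
    return path


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "response_id" not in df.columns:
        raise ValueError(f"{path}: prediction table must contain response_id")
    prob_cols = [c for c in df.columns if c.startswith("p_")]
    for col in prob_cols:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            bad = df.index[(df[col] < 0) | (df[col] > 1)][0]
            raise ValueError(f"{path}: column {col!r}, row {bad + 1}: probability outside [0, 1]")
    return df
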