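"""Episode-level change-score dataset.

One row per *episode*: a single participant's single 3-month period, labelled
with the module practiced in that period (or ``Retest`` for the control
cohort) and carrying the vector of change scores (post- minus pre-period
score) over the variable panel.  Missing change scores are stored as NaN and
never silently imputed; downstream contrasts use complete cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import CohortDesign, default_design
from .errors import DataValidationError, FormatError, ParseError
from .panel import PanelVariable

__all__ = ["ChangeScoreDataset", "compute_change", "load_dataset", "write_dataset"]

META_COLUMNS = ["participant_id", "cohort", "episode_label", "period"]


def compute_change(pre_score: float, post_score: float) -> float:
    """Change score: post minus pre.  Missing (None/NaN) propagates to NaN."""
    if pre_score is None or post_score is None:
        return math.nan
    pre = float(pre_score)
    post = float(post_score)
    if math.isnan(pre) or math.isnan(post):
        return math.nan
    return post - pre


@dataclass(frozen=True)
class ChangeScoreDataset:
    """Validated episode table.

    ``frame`` holds the metadata columns (:data:`META_COLUMNS`) followed by
    one float column per panel variable; NaN marks a missing change score.
    """

    frame: pd.DataFrame
    panel: tuple[PanelVariable, ...]

    @property
    def variable_ids(self) -> list[str]:
        return [v.variable_id for v in self.panel]

    @property
    def n_episodes(self) -> int:
        return len(self.frame)

    def values(self) -> pd.DataFrame:
        """Change-score matrix (episodes x variables)."""
        return self.frame[self.variable_ids]

    def missing_mask(self) -> pd.DataFrame:
        return self.values().isna()

    def complete_cases(self) -> "ChangeScoreDataset":
        keep = ~self.missing_mask().any(axis=1)
        return ChangeScoreDataset(self.frame.loc[keep].reset_index(drop=True), self.panel)

    def impute_mean(self) -> "ChangeScoreDataset":
        """Replace missing change scores by per-variable means.

        Off the default analysis path (contrasts are complete-case); an
        explicit opt-in for callers who prefer to keep sparse episodes.
        """
        frame = self.frame.copy()
        cols = self.variable_ids
        frame[cols] = frame[cols].fillna(frame[cols].mean())
        return ChangeScoreDataset(frame, self.panel)

    def episodes(self, label: str) -> pd.DataFrame:
        """Rows whose episode_label equals ``label``."""
        return self.frame[self.frame["episode_label"] == label]


def _validate_frame(
    df: pd.DataFrame,
    panel: Sequence[PanelVariable],
    design: CohortDesign,
    source: str = "<frame>",
) -> pd.DataFrame:
    var_ids = [v.variable_id for v in panel]
    missing = [c for c in META_COLUMNS + var_ids if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in META_COLUMNS + var_ids]
    if unknown:
        raise FormatError(f"{source}: unknown columns {unknown}")

    out = df.copy()
    try:
        out["period"] = out["period"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{source}: non-integer period: {exc}") from exc

    for col in var_ids:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna() & (out[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{source}: non-numeric change score at row {row}, column {col!r}: "
                f"{out[col].iloc[row]!r}"
            )
        out[col] = coerced.astype(float)

    # episode labels must match the cohort schedule
    for idx, row in out[META_COLUMNS].iterrows():
        cohort = design.cohort(str(row["cohort"]))
        expected = cohort.episode_label(int(row["period"]))
        if str(row["episode_label"]) != expected:
            raise DataValidationError(
                f"{source}: row {idx}: cohort {cohort.label} period {row['period']} "
                f"must be {expected!r}, got {row['episode_label']!r}"
            )

    dup = out.duplicated(subset=["participant_id", "period"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataValidationError(
            f"{source}: duplicate episode for participant "
            f"{out['participant_id'].iloc[row]!r} period {out['period'].iloc[row]}"
        )
    return out.reset_index(drop=True)


def dataset_from_frame(
    df: pd.DataFrame,
    panel: Sequence[PanelVariable],
    design: CohortDesign | None = None,
) -> ChangeScoreDataset:
    """Validate an in-memory frame against panel and design."""
    design = design or default_design()
    return ChangeScoreDataset(_validate_frame(df, panel, design), tuple(panel))


def load_dataset(
    path: str | Path,
    panel: Sequence[PanelVariable],
    design: CohortDesign | None = None,
) -> ChangeScoreDataset:
    """Load and validate an episode CSV.

    The CSV must have the metadata columns ``participant_id, cohort,
    episode_label, period`` followed by exactly one column per panel
    variable.  Empty cells become NaN (recorded in the missingness mask);
    any other non-numeric cell raises :class:`ParseError` naming the cell.
    """
    design = design or default_design()
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    return ChangeScoreDataset(_validate_frame(df, panel, design, str(path)), tuple(panel))


def write_dataset(dataset: ChangeScoreDataset, path: str | Path) -> None:
    """Write the episode table as CSV (inverse of :func:`load_dataset`)."""
    dataset.frame.to_csv(path, index=False)
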