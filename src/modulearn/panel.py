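"""Variable panel: the distress facets entering the analysis.

The panel is a flat list of questionnaire facets (total scores and
subscales).  Each variable carries an *improvement direction*: ``+1`` when a
decrease of the raw score means less distress (the usual coding for distress
scales), ``-1`` when an increase means improvement (wellbeing-coded scales
such as life satisfaction or the mental-health continuum).  Change scores are
always stored raw (post minus pre); the direction is applied only when
improvement-oriented effect sizes are computed.

The packaged default panel has 68 variables over 16 clinically relevant
instruments.  The exact subscale inventory of the source study is not public,
so the packaged composition is a realistic reconstruction from the named
instruments; it is plain CSV data and can be replaced wholesale by users with
the real inventory (see :func:`load_panel`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataValidationError, FormatError

__all__ = [
    "PanelVariable",
    "default_panel",
    "load_panel",
    "write_panel",
    "panel_frame",
]

_PANEL_COLUMNS = [
    "variable_id",
    "questionnaire",
    "subscale_name",
    "is_total_score",
    "improvement_direction",
]


@dataclass(frozen=True)
class PanelVariable:
    """One distress facet.

    Parameters
    ----------
    variable_id
        Short unique identifier, used as the dataset column name.
    questionnaire
        Instrument code (one of 16 in the default panel).
    subscale_name
        Human-readable facet name.
    is_total_score
        Whether this is the instrument's overall scale score.
    improvement_direction
        ``+1`` if a raw-score decrease means improvement, ``-1`` if an
        increase does.
    """

    variable_id: str
    questionnaire: str
    subscale_name: str
    is_total_score: bool
    improvement_direction: int

    def __post_init__(self) -> None:
        if self.improvement_direction not in (+1, -1):
            raise DataValidationError(
                f"improvement_direction for {self.variable_id!r} must be +1 or "
                f"-1, got {self.improvement_direction!r}"
            )


def _validate(panel: Sequence[PanelVariable]) -> list[PanelVariable]:
    ids = [v.variable_id for v in panel]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DataValidationError(f"duplicate variable_ids in panel: {sorted(dupes)}")
    return list(panel)


def panel_frame(panel: Sequence[PanelVariable]) -> pd.DataFrame:
    """Panel as a DataFrame with one row per variable."""
    return pd.DataFrame([vars(v) for v in panel], columns=_PANEL_COLUMNS)


def _from_frame(df: pd.DataFrame, source: str) -> list[PanelVariable]:
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing panel columns {missing}")
    out = []
    for _, row in df.iterrows():
        raw_flag = row["is_total_score"]
        flag = str(raw_flag).strip().lower() in {"true", "1", "yes"}
        out.append(
            PanelVariable(
                variable_id=str(row["variable_id"]),
                questionnaire=str(row["questionnaire"]),
                subscale_name=str(row["subscale_name"]),
                is_total_score=flag,
                improvement_direction=int(row["improvement_direction"]),
            )
        )
    return _validate(out)


def load_panel(path: str | Path) -> list[PanelVariable]:
    """Read a panel definition from CSV (columns as in the packaged file)."""
    df = pd.read_csv(path, dtype=str)
    return _from_frame(df, str(path))


def write_panel(panel: Iterable[PanelVariable], path: str | Path) -> None:
    panel_frame(list(panel)).to_csv(path, index=False)


def default_panel() -> list[PanelVariable]:
    """The packaged 68-variable, 16-instrument panel."""
    ref = resources.files("modulearn.data").joinpath("panel.csv")
    with resources.as_file(ref) as p:
        return load_panel(p)
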