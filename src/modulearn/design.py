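"""Cohort design: cohort sizes and per-period module schedules.

A study runs over consecutive 3-month periods.  Training cohorts practice one
module per period according to their schedule; the retest control cohort
(RCC) has an empty schedule and is assessed as ``Retest`` in every period.
The number of periods of the study is the longest schedule length (the RCC is
followed for all of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import DataValidationError

__all__ = ["MODULES", "RETEST", "Cohort", "CohortDesign", "default_design", "load_design"]

MODULES = ("Presence", "Affect", "Perspective")
RETEST = "Retest"


@dataclass(frozen=True)
class Cohort:
    label: str
    size: int
    schedule: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise DataValidationError(f"cohort {self.label!r}: size must be >= 1")
        unknown = [m for m in self.schedule if m not in MODULES]
        if unknown:
            raise DataValidationError(
                f"cohort {self.label!r}: unknown modules {unknown} in schedule"
            )
        if len(set(self.schedule)) != len(self.schedule):
            raise DataValidationError(
                f"cohort {self.label!r}: schedule repeats a module"
            )
        if self.label == "RCC" and self.schedule:
            raise DataValidationError("RCC schedule must be empty")

    def episode_label(self, period: int) -> str:
        """Label of this cohort's episode in a 1-based period (Retest for RCC)."""
        if not self.schedule:
            return RETEST
        if not 1 <= period <= len(self.schedule):
            raise DataValidationError(
                f"cohort {self.label!r} has no period {period}"
            )
        return self.schedule[period - 1]

    def n_periods(self, study_periods: int) -> int:
        return study_periods if not self.schedule else len(self.schedule)


@dataclass(frozen=True)
class CohortDesign:
    cohorts: tuple[Cohort, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            raise DataValidationError("duplicate cohort labels")

    @property
    def n_periods(self) -> int:
        """Study length in periods (longest schedule; at least 1)."""
        return max((len(c.schedule) for c in self.cohorts), default=1) or 1

    def cohort(self, label: str) -> Cohort:
        for c in self.cohorts:
            if c.label == label:
                return c
        raise DataValidationError(f"unknown cohort {label!r}")

    @property
    def total_participants(self) -> int:
        return sum(c.size for c in self.cohorts)

    def total_episodes(self) -> int:
        """Episode count of a complete dataset under this design."""
        return sum(c.size * c.n_periods(self.n_periods) for c in self.cohorts)


def _from_mapping(mapping: Mapping[str, Mapping]) -> CohortDesign:
    cohorts = tuple(
        Cohort(label=label, size=int(cfg["size"]), schedule=tuple(cfg.get("schedule") or ()))
        for label, cfg in mapping.items()
    )
    return CohortDesign(cohorts)


def load_design(path: str | Path) -> CohortDesign:
    """Read a cohort design from YAML (``cohort -> {size, schedule}``)."""
    with open(path) as fh:
        return _from_mapping(yaml.safe_load(fh))


def default_design() -> CohortDesign:
    """Packaged design: RCC n=90, TC1 n=80, TC2 n=81, TC3 n=81 (332 total)."""
    ref = resources.files("modulearn.data").joinpath("design.yaml")
    with resources.as_file(ref) as p:
        return load_design(p)
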