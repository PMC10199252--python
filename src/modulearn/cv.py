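"""Contrast construction and repeated cross-validated classification.

A *contrast* turns the episode table into a binary classification problem:

``TrainingVsRetest``
    First-period training episodes (all modules pooled) against first-period
    retest episodes — the shared-effects question.
``PresenceVsAffect`` / ``AffectVsPerspective``
    All episodes of the two named modules — the specific-effects questions.
    Presence and Perspective are never compared directly: the study design
    did not counterbalance those two modules, so that contrast is rejected
    at construction.

Classification performance is estimated by stratified 10-fold
cross-validation repeated 10 times.  Folds never split one participant's
episodes between training and test (participants can contribute episodes to
both classes of a module contrast), and per-repetition balanced accuracies
are tested against the 0.5 chance level with a one-sided Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seeding import child_seed
from .classifiers import ClassifierSpec, balanced_accuracy, fit, predict
from .dataset import ChangeScoreDataset
from .errors import (
    ConfigurationError,
    ContractError,
    DataValidationError,
    DegenerateSampleWarning,
    InsufficientDataError,
)
from .stability import SelectionTrace, _fold_splitter, run_selection, single_filter_pass

__all__ = [
    "CONTRASTS",
    "ContrastSpec",
    "CVResult",
    "build_contrast",
    "run_cv",
    "test_above_chance",
    "default_model_grid",
]

logger = logging.getLogger(__name__)

#: name -> (negative-class episodes, positive-class episodes)
CONTRASTS = {
    "TrainingVsRetest": ("Retest", "Training"),
    "PresenceVsAffect": ("Presence", "Affect"),
    "AffectVsPerspective": ("Perspective", "Affect"),
}


@dataclass(frozen=True)
class ContrastSpec:
    """One of the three study contrasts.

    ``positive_class`` follows the reporting convention of the study's
    coefficient plots: Affect is the positive class in both module
    contrasts, and the pooled training group in the shared-effects contrast.
    ``all_periods`` widens TrainingVsRetest from first-period episodes to
    every period.
    """

    name: str
    all_periods: bool = False

    def __post_init__(self) -> None:
        if self.name in ("PresenceVsPerspective", "PerspectiveVsPresence"):
            raise DataValidationError(
                "Presence and Perspective were not counterbalanced by the "
                "study design and cannot be compared directly"
            )
        if self.name not in CONTRASTS:
            raise DataValidationError(f"unknown contrast {self.name!r}")

    @property
    def negative_class(self) -> str:
        return CONTRASTS[self.name][0]

    @property
    def positive_class(self) -> str:
        return CONTRASTS[self.name][1]


def build_contrast(
    dataset: ChangeScoreDataset, contrast: ContrastSpec
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Assemble (X, y, groups) for a contrast; complete cases only.

    ``y`` is 0/1 with 1 the contrast's positive class; ``groups`` carries
    participant ids for leakage-safe folding.
    """
    complete = dataset.complete_cases()
    df = complete.frame
    if contrast.name == "TrainingVsRetest":
        if not contrast.all_periods:
            df = df[df["period"] == 1]
        is_pos = df["episode_label"] != "Retest"
        keep = np.ones(len(df), dtype=bool)
    else:
        keep = df["episode_label"].isin(
            [contrast.negative_class, contrast.positive_class]
        ).to_numpy()
        df = df[keep]
        is_pos = df["episode_label"] == contrast.positive_class

    y = is_pos.to_numpy().astype(int)
    for cls, count in (("positive", int(y.sum())), ("negative", int((1 - y).sum()))):
        if count < 10:
            raise InsufficientDataError(
                f"{contrast.name}: {cls} class has only {count} episodes"
            )
    X = df[complete.variable_ids].reset_index(drop=True)
    groups = df["participant_id"].to_numpy()
    return X, y, groups


def default_model_grid() -> list[ClassifierSpec]:
    """The four reported classifier configurations.

    Logistic regression and random forest, each with and without the
    four-stage variable filter.  The full 4-family x 2 grid can be built by
    hand from :class:`ClassifierSpec`.
    """
    return [
        ClassifierSpec("logistic_regression", filtered=False),
        ClassifierSpec("logistic_regression", filtered=True),
        ClassifierSpec("random_forest", filtered=False),
        ClassifierSpec("random_forest", filtered=True),
    ]


@dataclass
class CVResult:
    """Per-spec repeated-CV balanced accuracies and summaries."""

    specs: tuple[ClassifierSpec, ...]
    #: (spec label) -> per-repetition mean held-out BAC
    bac_per_repetition: dict[str, np.ndarray]
    n_folds: int
    n_repeats: int
    seed: int
    traces: dict[str, SelectionTrace] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for spec in self.specs:
            bacs = self.bac_per_repetition[spec.label]
            rows.append(
                {
                    "classifier": spec.label,
                    "median_bac": float(np.median(bacs)),
                    "iqr_low": float(np.percentile(bacs, 25)),
                    "iqr_high": float(np.percentile(bacs, 75)),
                    "p_vs_chance": (
                        test_above_chance(bacs) if len(bacs) >= 5 else float("nan")
                    ),
                    "n_repetitions": len(bacs),
                }
            )
        return pd.DataFrame(rows)

    def per_repetition_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.bac_per_repetition)
        out.insert(0, "repetition", np.arange(1, self.n_repeats + 1))
        return out


def _check_group_integrity(train_groups, test_groups) -> None:
    overlap = set(train_groups) & set(test_groups)
    if overlap:
        raise ContractError(
            f"participants in both train and test of one fold: {sorted(overlap)[:5]}"
        )


def run_cv(
    X,
    y,
    groups,
    specs: Sequence[ClassifierSpec],
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified group-aware k-fold CV over classifier specs.

    Filtered specs run the four-stage filter on each training fold and fit
    on the surviving variables, falling back (with a log message) to all
    variables when nothing survives.  The per-repetition score of a spec is
    its mean held-out balanced accuracy over folds.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if groups is not None:
        groups = np.asarray(groups)
        # a fold needs whole groups; the minority class must have enough
        per_class_groups = min(
            pd.Series(groups[y == cls]).nunique() for cls in np.unique(y)
        )
        if n_folds > per_class_groups:
            raise ConfigurationError(
                f"n_folds={n_folds} exceeds minority-class group count "
                f"{per_class_groups}"
            )
    bacs: dict[str, list[list[float]]] = {spec.label: [] for spec in specs}
    for r in range(n_repeats):
        folds = list(_fold_splitter(y, groups, n_folds, child_seed(seed, r)))
        fold_scores: dict[str, list[float]] = {spec.label: [] for spec in specs}
        for f, (train_idx, test_idx) in enumerate(folds):
            if groups is not None:
                _check_group_integrity(groups[train_idx], groups[test_idx])
            X_tr, y_tr = X.iloc[train_idx], y[train_idx]
            X_te, y_te = X.iloc[test_idx], y[test_idx]
            filtered_vars: list[str] | None = None
            for spec in specs:
                cols = list(X.columns)
                if spec.filtered:
                    if filtered_vars is None:  # one filter pass serves all specs
                        picked = single_filter_pass(
                            X_tr, y_tr, child_seed(seed, r, f), 100, {}
                        )
                        if not picked:
                            logger.info(
                                "repetition %d fold %d: no variables survived the "
                                "filter; falling back to all variables", r, f,
                            )
                        filtered_vars = sorted(picked) if picked else cols
                    cols = filtered_vars
                model = fit(spec, X_tr[cols], y_tr, seed=child_seed(seed, r, f, 1))
                y_hat = predict(model, X_te[cols])
                fold_scores[spec.label].append(balanced_accuracy(y_te, y_hat))
        for spec in specs:
            bacs[spec.label].append(fold_scores[spec.label])
    return CVResult(
        specs=tuple(specs),
        bac_per_repetition={
            label: np.array([float(np.mean(rep)) for rep in reps])
            for label, reps in bacs.items()
        },
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
    )


def test_above_chance(bacs: Sequence[float]) -> float:
    """One-sided Wilcoxon signed-rank p-value for median BAC > 0.5.

    Exact null distribution for n <= 25 without ties or zeros; normal
    approximation with continuity correction otherwise.  If every value is
    exactly 0.5 the test is vacuous: returns 1.0 with a
    :class:`DegenerateSampleWarning`.
    """
    bacs = np.asarray(bacs, dtype=float)
    if len(bacs) < 5:
        raise InsufficientDataError("need at least 5 repetition BACs")
    diffs = bacs - 0.5
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn(
            "all repetition BACs equal 0.5; signed-rank test is degenerate",
            DegenerateSampleWarning,
        )
        return 1.0
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nonzero, alternative="greater", method=method, correction=(method == "approx")
    )
    return float(res.pvalue)


# the leading "test_" is domain naming, not a pytest test
test_above_chance.__test__ = False  # type: ignore[attr-defined]


def analyze_contrast(
    dataset: ChangeScoreDataset,
    contrast: ContrastSpec,
    specs: Sequence[ClassifierSpec] | None = None,
    n_folds: int = 10,
    n_repeats: int = 10,
    n_selection_repetitions: int = 200,
    threshold: float = 0.95,
    seed: int = 0,
) -> CVResult:
    """Full contrast analysis: repeated CV plus the stability-selection trace.

    Performance estimation (``n_repeats`` x ``n_folds`` CV) and selection-rate
    estimation (``n_selection_repetitions`` repetitions of the four-stage
    filter) are two separate loops sharing the fold generator, mirroring the
    separate reporting of accuracy boxplots and selection-rate lollipops.
    """
    specs = list(specs) if specs is not None else default_model_grid()
    X, y, groups = build_contrast(dataset, contrast)
    result = run_cv(X, y, groups, specs, n_folds=n_folds, n_repeats=n_repeats, seed=seed)
    if any(spec.filtered for spec in specs):
        trace = run_selection(
            X,
            y,
            n_repetitions=n_selection_repetitions,
            threshold=threshold,
            seed=child_seed(seed, 10_000),
            groups=groups,
            n_folds=n_folds,
        )
        for spec in specs:
            if spec.filtered:
                result.traces[spec.label] = trace
    return result
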