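"""Effect profiles: from a selected variable set to interpretable effects.

The replicably selected variables are attributed to one of the two
contrasted modules by the sign of their coefficient in an exemplary
unpenalized logistic regression on standardized change scores (positive
coefficients point to the positive class of the contrast).  Each attributed
variable then gets post-hoc, improvement-oriented Cohen's d values and
one-sided Welch t-tests against (a) the other module of the contrast and
(b) the retest control cohort.  A variable whose improvement effect is
significantly greater than zero in *both* comparisons belongs to the
module's *specific effect profile*.

Cohen's d here is the two-sample standardized mean difference with the
pooled (n_a + n_b - 2)-denominator standard deviation, multiplied by the
variable's improvement direction so that d > 0 always means more
improvement in the module group than in the comparator, for distress- and
wellbeing-coded variables alike.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cv import ContrastSpec, build_contrast
from .dataset import ChangeScoreDataset
from .errors import (
    ContractError,
    InsufficientDataError,
    SeparationWarning,
    UndefinedEffectError,
)

__all__ = [
    "EffectProfileEntry",
    "fit_final_logistic",
    "cohens_d",
    "welch_t",
    "build_profile",
    "profile_frame",
    "radar_profile",
]

ALPHA = 0.05


@dataclass(frozen=True)
class EffectProfileEntry:
    variable_id: str
    module: str
    coefficient: float
    coefficient_se: float
    coefficient_p: float
    d_vs_other_module: float
    p_vs_other_module: float
    d_vs_retest: float
    p_vs_retest: float
    specific_effect: bool


def _ridge_logit(Xd: np.ndarray, y: np.ndarray, ridge: float = 1e-6):
    """Ridge-IRLS fallback for separated data; SE from the penalized Hessian."""
    n, k = Xd.shape
    beta = np.zeros(k)
    pen = np.full(k, ridge)
    pen[0] = 0.0
    for _ in range(100):
        eta = np.clip(Xd @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (y - p) - pen * beta
        w = np.clip(p * (1 - p), 1e-10, None)
        hess = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta += np.clip(step, -10, 10)
        if np.abs(step).max() < 1e-8:
            break
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def fit_final_logistic(X_selected: pd.DataFrame, y) -> pd.DataFrame:
    """Unpenalized logistic fit on z-standardized selected variables.

    Returns a frame indexed by variable with columns ``coefficient``,
    ``se`` and ``p`` (two-sided Wald).  Positive coefficients point to the
    positive class of ``y``.  Perfect separation triggers a light-ridge
    (1e-6) fallback with a :class:`SeparationWarning`.
    """
    X_selected = pd.DataFrame(X_selected)
    if X_selected.shape[1] == 0:
        raise ContractError("empty selection: nothing to fit")
    if X_selected.isna().any().any():
        raise ContractError("X contains missing values; use complete cases")
    y = np.asarray(y)
    y01 = (y == np.unique(y)[1]).astype(float) if len(np.unique(y)) == 2 else None
    if y01 is None:
        raise ContractError("y must be binary")
    Z = (X_selected - X_selected.mean()) / X_selected.std(ddof=0)
    Xd = sm.add_constant(np.asarray(Z, dtype=float))
    fell_back = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y01, Xd).fit(disp=0, maxiter=200)
            params, bse = np.asarray(fit.params), np.asarray(fit.bse)
            ok = fit.mle_retvals.get("converged", True) and np.all(np.isfinite(bse))
            ok = ok and float(np.abs(params).max()) < 1e3
        except Exception:
            ok = False
    if not ok:
        params, bse = _ridge_logit(Xd, y01)
        fell_back = True
        warnings.warn(
            "perfect separation (or non-convergence) in the exemplary logistic "
            "fit; used a light ridge (1e-6)",
            SeparationWarning,
        )
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {"coefficient": params[1:], "se": bse[1:], "p": p[1:]},
        index=list(X_selected.columns),
    )
    out.attrs["ridge_fallback"] = fell_back
    return out


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("both groups need at least 2 values")
    return a, b


def cohens_d(changes_a, changes_b, direction: int = 1) -> float:
    """Improvement-oriented two-sample Cohen's d.

    ``d = direction * (mean_b - mean_a) / s_pooled`` with the
    (n_a + n_b - 2)-denominator pooled SD; d > 0 means group *a* improved
    more than group *b* given the variable's improvement direction
    (+1 distress-coded, -1 wellbeing-coded).
    """
    a, b = _check_pair(changes_a, changes_b)
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var <= 0:
        raise UndefinedEffectError("zero pooled standard deviation")
    return float(direction * (b.mean() - a.mean()) / math.sqrt(pooled_var))


def welch_t(
    changes_a, changes_b, direction: int = 1, pooled: bool = False
) -> tuple[float, float]:
    """Welch's unequal-variance t-test, one-sided in the improvement direction.

    Tests whether group *a* improved more than group *b*; returns
    ``(t, p)`` where ``t`` is oriented like :func:`cohens_d` (positive =
    more improvement in *a*) and ``p`` is the one-sided tail.
    ``pooled=True`` switches to Student's equal-variance variant.
    """
    a, b = _check_pair(changes_a, changes_b)
    if a.var(ddof=1) + b.var(ddof=1) <= 0:
        raise UndefinedEffectError("zero variance in both groups")
    first, second = (b, a) if direction == 1 else (a, b)
    res = stats.ttest_ind(first, second, equal_var=pooled, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def _retest_episodes(
    dataset: ChangeScoreDataset, module: str, retest_period: str
) -> pd.DataFrame:
    """RCC episodes used as the comparator for a module.

    ``matched`` uses retest episodes from the periods in which the module
    was scheduled in any training cohort; ``first`` uses first-period retest
    episodes only.
    """
    complete = dataset.complete_cases()
    df = complete.frame
    retest = df[df["episode_label"] == "Retest"]
    if retest_period == "first":
        return retest[retest["period"] == 1]
    periods = set(
        df.loc[df["episode_label"] == module, "period"].unique()
    )
    return retest[retest["period"].isin(periods)]


def build_profile(
    dataset: ChangeScoreDataset,
    contrast: ContrastSpec,
    selected: Sequence[str],
    retest_period: str = "matched",
    alpha: float = ALPHA,
    pooled_t: bool = False,
    adjust: str | None = None,
) -> list[EffectProfileEntry]:
    """Attribute selected variables to modules and compute their effects.

    For every selected variable: module attribution by logistic coefficient
    sign, improvement-oriented d and one-sided Welch p versus the other
    module and versus the retest comparator, and the specific-effect flag
    (both p-values below ``alpha``).  ``pooled_t=True`` uses Student's
    equal-variance tests; ``adjust="bh"`` applies a Benjamini-Hochberg
    correction across variables within each comparison (none by default).
    """
    selected = sorted(set(selected))
    if not selected:
        raise ContractError("empty selection: nothing to profile")
    if contrast.name == "TrainingVsRetest":
        raise ContractError("effect profiles are defined for module contrasts")
    X, y, _ = build_contrast(dataset, contrast)
    direction_of = {
        v.variable_id: v.improvement_direction for v in dataset.panel
    }
    # fit on improvement-oriented scores (improvement = -direction * change),
    # so beta > 0 means improvement in the variable points to the positive
    # class — the convention of the study's coefficient plots
    oriented = X[selected] * pd.Series(
        {v: -direction_of[v] for v in selected}
    )
    coefs = fit_final_logistic(oriented, y)

    complete = dataset.complete_cases()
    df = complete.frame
    if adjust not in (None, "bh"):
        raise ContractError(f"unknown p-value adjustment {adjust!r}")
    rows = []
    for var in selected:
        beta = float(coefs.loc[var, "coefficient"])
        module = contrast.positive_class if beta > 0 else contrast.negative_class
        other = (
            contrast.negative_class if beta > 0 else contrast.positive_class
        )
        a = df.loc[df["episode_label"] == module, var]
        b = df.loc[df["episode_label"] == other, var]
        retest = _retest_episodes(dataset, module, retest_period)
        if retest.empty:
            raise InsufficientDataError("no retest episodes available as comparator")
        r = retest[var]
        direction = direction_of[var]
        rows.append(
            {
                "var": var,
                "module": module,
                "beta": beta,
                "d_other": cohens_d(a, b, direction),
                "p_other": welch_t(a, b, direction, pooled=pooled_t)[1],
                "d_retest": cohens_d(a, r, direction),
                "p_retest": welch_t(a, r, direction, pooled=pooled_t)[1],
            }
        )
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        for key in ("p_other", "p_retest"):
            adjusted = multipletests([row[key] for row in rows], method="fdr_bh")[1]
            for row, p in zip(rows, adjusted):
                row[key] = float(p)
    return [
        EffectProfileEntry(
            variable_id=row["var"],
            module=row["module"],
            coefficient=row["beta"],
            coefficient_se=float(coefs.loc[row["var"], "se"]),
            coefficient_p=float(coefs.loc[row["var"], "p"]),
            d_vs_other_module=row["d_other"],
            p_vs_other_module=row["p_other"],
            d_vs_retest=row["d_retest"],
            p_vs_retest=row["p_retest"],
            specific_effect=bool(row["p_other"] < alpha and row["p_retest"] < alpha),
        )
        for row in rows
    ]


def profile_frame(entries: Sequence[EffectProfileEntry]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in entries])


def radar_profile(entries: Sequence[EffectProfileEntry]) -> dict:
    """Machine-readable radar data: module -> variable -> d vs retest
    (specific effects only)."""
    out: dict[str, dict[str, float]] = {}
    for e in entries:
        if e.specific_effect:
            out.setdefault(e.module, {})[e.variable_id] = e.d_vs_retest
    return out


def write_profile(
    entries: Sequence[EffectProfileEntry], tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    profile_frame(entries).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(radar_profile(entries), fh, indent=2, sort_keys=True)
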