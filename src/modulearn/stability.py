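"""Four-stage stability variable selection.

Within one training set the filter runs as:

1. *Per-algorithm informativeness* — each of three importance-producing
   algorithms (elastic net, random forest, sum-of-trees) nominates candidate
   variables via a scale-free cutoff:

   * elastic net: nonzero coefficient at the inner-CV-chosen strength;
   * random forest: impurity importance above the 95th percentile of a
     within-sample label-permutation null (null forests are refit on
     permuted labels; score and null share the importance definition, so
     the cutoff is self-calibrating);
   * sum-of-trees: tree-inclusion proportion, against the same kind of
     label-permutation null.

2. *Majority vote* — variables nominated by at least two of the three
   algorithms survive, decoupling the result from any single algorithm.

3. *Bootstrap forward selection* and 4. *bootstrap backward elimination* —
   a ridge-shrunk logistic model is refit across B shared bootstrap
   resamples; candidates with any marginal held-out signal are swept in
   rank order and enter when they improve the paired out-of-bootstrap
   log-likelihood by more than a small tolerance; kept variables are
   dropped when they are near-collinear with the rest or when their removal
   is essentially free; and the surviving model must beat chance held out
   (see :func:`bootstrap_stepwise` for the rationale of each piece).

The whole filter is repeated over many independent stratified 10-fold
cross-validations; a variable's *selection rate* is the fraction of
repetitions in which it survives the filter in a majority of the folds, and
variables with rate >= 0.95 form the final replicable set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from ._seeding import child_rng, child_seed
from .classifiers import ClassifierSpec, fit, importance
from .errors import ContractError, ParameterError

__all__ = [
    "SelectionTrace",
    "stage1_candidates",
    "majority_vote",
    "bootstrap_stepwise",
    "run_selection",
]


# --------------------------------------------------------------------------
# SelectionTrace

@dataclass(frozen=True)
class SelectionTrace:
    """Per-variable selection rates over repetitions."""

    variables: tuple[str, ...]
    rates: Mapping[str, float]
    n_repetitions: int
    threshold: float = 0.95
    per_repetition_sets: tuple[frozenset, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ParameterError("threshold must be in (0, 1]")

    @property
    def final_set(self) -> frozenset[str]:
        return frozenset(v for v in self.variables if self.rates[v] >= self.threshold)

    def with_threshold(self, threshold: float) -> "SelectionTrace":
        return SelectionTrace(
            self.variables, self.rates, self.n_repetitions, threshold,
            self.per_repetition_sets,
        )

    def to_frame(self) -> pd.DataFrame:
        final = self.final_set
        return pd.DataFrame(
            {
                "variable_id": list(self.variables),
                "selection_rate": [self.rates[v] for v in self.variables],
                "selected_flag": [v in final for v in self.variables],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Stage 1: per-algorithm candidates

def stage1_candidates(
    X,
    y,
    seed: int = 0,
    *,
    rf_trees: int = 50,
    rf_null_permutations: int = 4,
    brt_trees: int = 30,
    brt_null_permutations: int = 2,
    null_quantile: float = 0.95,
) -> dict[str, set[str]]:
    """Candidate variables per importance-producing algorithm.

    Returns a dict keyed by ``elastic_net``, ``random_forest`` and
    ``bayesian_regression_tree``.  The two tree ensembles use label-
    permutation nulls: the same model is refit on permuted labels a few
    times, and a variable is a candidate when its score exceeds the
    ``null_quantile`` of the pooled null scores.  Greedy ensembles chase
    whatever spurious structure a finite sample offers, so their raw scores
    are only interpretable against that self-calibrated null; the elastic
    net needs no null because sparsity is built in (nonzero coefficient at
    the CV-chosen strength).
    """
    if isinstance(X, pd.DataFrame):
        variables = list(X.columns)
        mat = np.asarray(X, dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        variables = [f"x{j}" for j in range(mat.shape[1])]
    y = np.asarray(y)

    out: dict[str, set[str]] = {}

    # elastic net: nonzero standardized coefficient
    enet = fit(ClassifierSpec("elastic_net"), X, y, seed=child_seed(seed, 0))
    scores = importance(enet)
    out["elastic_net"] = {v for v, s in scores.items() if s > 0}

    def _null_cutoff(score_fn, labels, n_perm, key) -> np.ndarray:
        rng = child_rng(seed, key)
        null = np.concatenate(
            [score_fn(rng.permutation(labels), child_seed(seed, key, k))
             for k in range(n_perm)]
        )
        return float(np.quantile(null, null_quantile))

    # sum-of-trees: tree-inclusion proportion vs label-permutation null
    def _brt_inclusions(labels, m_seed):
        model = fit(
            ClassifierSpec(
                "bayesian_regression_tree", hyperparameters={"n_estimators": brt_trees}
            ),
            mat, labels, seed=m_seed,
        )
        return np.array([importance(model)[v] for v in model.variables])

    obs = _brt_inclusions(y, child_seed(seed, 1))
    cutoff = _null_cutoff(_brt_inclusions, y, brt_null_permutations, 2)
    out["bayesian_regression_tree"] = {
        variables[j] for j in np.flatnonzero(obs > cutoff)
    }

    # random forest: impurity importance vs label-permutation null
    def _rf_importances(labels, rf_seed):
        # screening forests: min_samples_leaf bounds tree size, which cuts
        # the cost of the null refits several-fold without changing the
        # importance ranking at screening resolution
        forest = RandomForestClassifier(
            n_estimators=rf_trees, max_features="sqrt", min_samples_leaf=5,
            random_state=rf_seed,
        ).fit(mat, labels)
        return forest.feature_importances_

    obs = _rf_importances(y, child_seed(seed, 3))
    cutoff = _null_cutoff(_rf_importances, y, rf_null_permutations, 4)
    out["random_forest"] = {variables[j] for j in np.flatnonzero(obs > cutoff)}
    return out


# --------------------------------------------------------------------------
# Stage 2: majority vote

def majority_vote(sets: Iterable[set[str]] | Mapping[str, set[str]]) -> set[str]:
    """Variables present in at least two of the three algorithm sets."""
    if isinstance(sets, Mapping):
        sets = list(sets.values())
    sets = [set(s) for s in sets]
    if len(sets) != 3:
        raise ContractError(f"majority vote expects 3 sets, got {len(sets)}")
    counts: dict[str, int] = {}
    for s in sets:
        for v in s:
            counts[v] = counts.get(v, 0) + 1
    return {v for v, c in counts.items() if c >= 2}


# --------------------------------------------------------------------------
# Stages 3-4: bootstrap forward/backward selection

_MAX_IRLS = 25
#: Selection-shrinkage scale: the scorer's ridge is RIDGE_SCALE * n on
#: standardized coefficients (the intercept is never penalized).  The
#: shrinkage keeps fitted probabilities moderate when many strong predictors
#: are in play: an unshrunk near-separated fit is overconfident, its held-out
#: log-likelihood collapses on confident errors, and the conditional signal
#: of late additions becomes invisible.  The final inference model elsewhere
#: in the package is unpenalized; this ridge only serves subset comparison.
RIDGE_SCALE = 0.1


def _fit_logistic_batch(
    Xd: np.ndarray,
    y01: np.ndarray,
    weights: np.ndarray,
    ridge: float,
    beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted ridge-logistic fit for B weight vectors at once (IRLS).

    ``Xd``: (n, k) design incl. leading intercept column; ``weights``:
    (B, n) bootstrap multiplicities.  All B Hessians come from a single
    GEMM on the elementwise product design.  Returns coefficients (B, k).
    """
    B, n = weights.shape
    k = Xd.shape[1]
    beta = np.zeros((B, k)) if beta0 is None else beta0.copy()
    pen = np.full(k, ridge)
    pen[0] = 0.0  # no penalty on the intercept
    eye = np.diag(pen) + 1e-8 * np.eye(k)
    pairs = (Xd[:, :, None] * Xd[:, None, :]).reshape(n, k * k)
    for _ in range(_MAX_IRLS):
        eta = np.clip(Xd @ beta.T, -30, 30)  # (n, B)
        prob = 1.0 / (1.0 + np.exp(-eta))
        resid = weights * (y01[None, :] - prob.T)  # (B, n)
        grad = resid @ Xd - beta * pen[None, :]  # (B, k)
        w_irls = (prob * (1.0 - prob)) * weights.T  # (n, B)
        hess = (pairs.T @ w_irls).T.reshape(B, k, k) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        np.clip(step, -5.0, 5.0, out=step)
        beta += step
        if np.abs(step).max() < 1e-4:
            break
    return beta


def _oob_metrics(
    Xd: np.ndarray, y01: np.ndarray, beta: np.ndarray, oob: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bootstrap (balanced accuracy, mean log-likelihood) per resample."""
    eta = np.clip(Xd @ beta.T, -30, 30)  # (n, B)
    pred = eta > 0
    pos = y01.astype(bool)
    oob_t = oob.T  # (n, B)
    tp = ((pred & oob_t) & pos[:, None]).sum(axis=0)
    npos = (oob_t & pos[:, None]).sum(axis=0)
    tn = ((~pred & oob_t) & ~pos[:, None]).sum(axis=0)
    nneg = (oob_t & ~pos[:, None]).sum(axis=0)
    sens = np.where(npos > 0, tp / np.maximum(npos, 1), 0.5)
    spec = np.where(nneg > 0, tn / np.maximum(nneg, 1), 0.5)
    bac = (sens + spec) / 2.0
    # mean per-observation log-likelihood over the OOB rows
    ll_obs = y01[:, None] * eta - np.log1p(np.exp(eta))  # (n, B)
    n_oob = oob_t.sum(axis=0)
    loglik = np.where(n_oob > 0, (ll_obs * oob_t).sum(axis=0) / np.maximum(n_oob, 1), 0.0)
    return bac, loglik


class _BootstrapScorer:
    """Scores variable subsets on B shared bootstrap resamples.

    For every subset it returns per-resample out-of-bootstrap balanced
    accuracy and mean log-likelihood; sharing the resamples across subsets
    makes comparisons paired.  Internal fits use the selection shrinkage
    ``RIDGE_SCALE * n`` (see module constant).
    """

    def __init__(self, X: np.ndarray, y01: np.ndarray, B: int, seed: int):
        n = len(y01)
        rng = child_rng(seed, 0)
        idx = rng.integers(0, n, size=(B, n))
        self.weights = np.zeros((B, n))
        for b in range(B):  # multiplicity counts per resample
            np.add.at(self.weights[b], idx[b], 1.0)
        self.oob = self.weights == 0
        self.X = X
        self.y01 = y01
        self.B = B
        self.ridge = RIDGE_SCALE * n
        # intercept-only baseline
        base_p = (self.weights * y01[None, :]).sum(1) / self.weights.sum(1)
        base_p = np.clip(base_p, 1e-10, 1 - 1e-10)
        eta0 = np.log(base_p / (1 - base_p))  # (B,)
        ll = y01[None, :] * eta0[:, None] - np.log1p(np.exp(eta0))[:, None]
        n_oob = self.oob.sum(axis=1)
        self.null_loglik = (ll * self.oob).sum(axis=1) / np.maximum(n_oob, 1)
        self.null_bac = np.full(B, 0.5)

    def score(self, cols: Sequence[int], beta0: np.ndarray | None = None):
        """(bac, loglik, beta) for a logistic model on column indices ``cols``."""
        if len(cols) == 0:
            return self.null_bac, self.null_loglik, None
        Xd = np.column_stack([np.ones(len(self.y01)), self.X[:, list(cols)]])
        beta = _fit_logistic_batch(Xd, self.y01, self.weights, self.ridge, beta0)
        bac, loglik = _oob_metrics(Xd, self.y01, beta, self.oob)
        return bac, loglik, beta


_CRITERIA = ("paired_loglik", "paired_bac", "median_bac")


def bootstrap_stepwise(
    X,
    y,
    candidates: Iterable[str],
    B: int = 100,
    seed: int = 0,
    *,
    tolerance: float = 1e-3,
    backward_tolerance: float = 2e-4,
    min_bac: float = 0.52,
    criterion: str = "paired_loglik",
) -> set[str]:
    """Bootstrap-based forward then backward selection over ``candidates``.

    A logistic model is refit on B shared bootstrap resamples for every
    subset considered, and subsets are compared on held-out (out-of-
    bootstrap) rows.  Candidates are ranked by their single-variable score
    and swept in that order (repeated until a sweep adds nothing, so early
    rejections get a second look conditional on the fuller model); one
    enters when it improves the criterion by more than ``tolerance``.  The
    backward pass then removes any kept variable whose removal costs no
    more than ``backward_tolerance`` — deliberately smaller than the entry
    gate, so only demonstrably redundant variables (e.g. near-duplicates)
    are dropped.  Finally the surviving model must beat chance held out:
    if its mean out-of-bootstrap balanced accuracy is at most ``min_bac``
    the whole selection is discarded.

    ``criterion`` selects the comparison scale: ``paired_loglik`` (default)
    compares mean out-of-bootstrap log-likelihood per observation, paired
    across resamples — unlike accuracy it does not saturate, so every
    variable with real conditional signal keeps registering while exact
    duplicates and noise do not; ``paired_bac`` and ``median_bac`` compare
    balanced accuracy (paired mean / unpaired median with strict
    improvement).  Ties break lexicographically; empty candidates give the
    empty set.
    """
    candidates = sorted(set(candidates))
    if not candidates:
        return set()
    if isinstance(X, pd.DataFrame):
        variables = list(X.columns)
        mat = np.asarray(X, dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        variables = [f"x{j}" for j in range(mat.shape[1])]
    missing = [c for c in candidates if c not in variables]
    if missing:
        raise ContractError(f"candidates not in X: {missing}")
    if criterion not in _CRITERIA:
        raise ParameterError(f"unknown stepwise criterion {criterion!r}")
    metric = 1 if criterion == "paired_loglik" else 0
    gate = tolerance if criterion != "median_bac" else 0.0

    y = np.asarray(y)
    y01 = (y == np.unique(y)[1]).astype(float)
    # standardized predictors keep the IRLS well-conditioned
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    mat = (mat - mu) / np.where(sd > 0, sd, 1.0)
    scorer = _BootstrapScorer(mat, y01, B, seed)
    col_of = {v: variables.index(v) for v in candidates}

    def improves(new: np.ndarray, cur: np.ndarray) -> float:
        if criterion == "median_bac":
            return float(np.median(new) - np.median(cur))
        return float(np.mean(new - cur))

    # marginal screen and ranking: a variable is only ever selected if it
    # carries signal on its own (paired single-variable gain over the
    # intercept-only model > 0).  This excludes pure suppressors — variables
    # that improve the joint model only by cancelling noise in a correlated
    # informative variable — which would be defensible for prediction but
    # have no marginal effect to interpret in an effect profile.
    null_vec = scorer.score([])[metric]
    singles = {}
    eligible = []
    for v in candidates:
        vecs = scorer.score([col_of[v]])
        singles[v] = float(np.mean(vecs[metric]))
        if improves(vecs[metric], null_vec) > 0.0:
            eligible.append(v)
    order = sorted(eligible, key=lambda v: (-singles[v], v))

    # forward sweeps in rank order, until a sweep adds nothing
    selected: list[str] = []
    current = scorer.score([])[metric]
    beta = None
    for _sweep in range(3):
        added = False
        for v in [u for u in order if u not in selected]:
            beta0 = None
            if beta is not None:
                beta0 = np.hstack([beta, np.zeros((scorer.B, 1))])
            vecs = scorer.score([col_of[u] for u in (*selected, v)], beta0)
            if improves(vecs[metric], current) > gate:
                selected.append(v)
                current = vecs[metric]
                beta = vecs[2]
                added = True
        if not added:
            break

    # backward pass 1: near-collinear variables carry no information beyond
    # the others; drop them (keeping the higher-ranked of a redundant group)
    # before the performance-based elimination, which cannot see them.
    rank = {v: i for i, v in enumerate(order)}
    for v in sorted(selected, key=lambda u: -rank[u]):
        others = [u for u in selected if u != v]
        if not others:
            continue
        Z = mat[:, [col_of[u] for u in others]]
        target = mat[:, col_of[v]]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(target)), Z]), target, rcond=None
        )
        resid = target - np.column_stack([np.ones(len(target)), Z]) @ coef
        r2 = 1.0 - resid.var() / max(target.var(), 1e-12)
        if r2 > 0.95:
            selected = others
            current = scorer.score([col_of[u] for u in selected])[metric]

    # backward pass 2: drop anything whose removal is (near-)free
    back_gate = backward_tolerance if criterion != "median_bac" else 0.0
    changed = True
    while changed and selected:
        changed = False
        for v in sorted(selected):
            rest = [u for u in selected if u != v]
            vecs = scorer.score([col_of[u] for u in rest])
            if improves(vecs[metric], current) >= -back_gate:
                selected = rest
                current = vecs[metric]
                changed = True
                break

    # the final model must beat chance on held-out rows
    if selected:
        bac = scorer.score([col_of[u] for u in selected])[0]
        if float(np.mean(bac)) <= min_bac:
            return set()
    return set(selected)


# --------------------------------------------------------------------------
# Full repeated selection

def _fold_splitter(y, groups, n_folds: int, seed: int):
    if groups is None:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return cv.split(np.zeros(len(y)), y)
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return cv.split(np.zeros(len(y)), y, groups)


def run_selection(
    X,
    y,
    n_repetitions: int = 200,
    threshold: float = 0.95,
    seed: int = 0,
    *,
    groups=None,
    n_folds: int = 10,
    B: int = 100,
    fold_aggregation: str = "majority",
    stage1_kwargs: dict | None = None,
) -> SelectionTrace:
    """Repeat the four-stage filter and accumulate selection rates.

    Each repetition is one stratified ``n_folds``-fold cross-validation
    (participant-grouped when ``groups`` is given); the filter runs on each
    training fold, and a variable counts as selected in the repetition when
    it survives in a strict majority of folds (``fold_aggregation="any"``
    relaxes this to a single fold).  The final set is every variable whose
    selection rate reaches ``threshold``.
    """
    if n_repetitions < 1:
        raise ParameterError("n_repetitions must be >= 1")
    if fold_aggregation not in ("majority", "any"):
        raise ParameterError(f"unknown fold_aggregation {fold_aggregation!r}")
    if isinstance(X, pd.DataFrame):
        variables = tuple(X.columns)
    else:
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{j}" for j in range(np.asarray(X).shape[1])])
        variables = tuple(X.columns)
    y = np.asarray(y)
    stage1_kwargs = stage1_kwargs or {}

    counts = {v: 0 for v in variables}
    rep_sets: list[frozenset] = []
    for r in range(n_repetitions):
        fold_counts = {v: 0 for v in variables}
        split = _fold_splitter(y, groups, n_folds, child_seed(seed, r))
        for f, (train_idx, _) in enumerate(split):
            Xt = X.iloc[train_idx]
            yt = y[train_idx]
            picked = _single_pass(Xt, yt, child_seed(seed, r, f), B, stage1_kwargs)
            for v in picked:
                fold_counts[v] += 1
        need = 1 if fold_aggregation == "any" else n_folds // 2 + 1
        rep_set = frozenset(v for v, c in fold_counts.items() if c >= need)
        rep_sets.append(rep_set)
        for v in rep_set:
            counts[v] += 1

    rates = {v: counts[v] / n_repetitions for v in variables}
    return SelectionTrace(
        variables=variables,
        rates=rates,
        n_repetitions=n_repetitions,
        threshold=threshold,
        per_repetition_sets=tuple(rep_sets),
    )


def _single_pass(X, y, seed: int, B: int, stage1_kwargs: dict) -> set[str]:
    """One full stage-1..4 filter on a single training set."""
    sets = stage1_candidates(X, y, seed=child_seed(seed, 0), **stage1_kwargs)
    voted = majority_vote(sets)
    return bootstrap_stepwise(X, y, voted, B=B, seed=child_seed(seed, 1))


# re-exported for cv-engine use
single_filter_pass = _single_pass
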