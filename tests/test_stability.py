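"""Four-stage stability selection: stages, trace, and repeated selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modulearn import (
    EffectSpec,
    bootstrap_stepwise,
    generate,
    majority_vote,
    run_selection,
    stage1_candidates,
)
from modulearn.errors import ContractError, ParameterError
from modulearn.stability import SelectionTrace


@pytest.fixture(scope="module")
def one_signal_toy():
    rng = np.random.default_rng(21)
    X = pd.DataFrame(
        rng.standard_normal((200, 8)), columns=[f"v{j}" for j in range(8)]
    )
    y = np.repeat([0, 1], 100)
    X.loc[y == 1, "v1"] += 2.0
    return X, y


class TestStage1:
    def test_signal_variable_in_all_three_sets(self, one_signal_toy):
        X, y = one_signal_toy
        sets = stage1_candidates(X, y, seed=1)
        assert set(sets) == {
            "elastic_net", "random_forest", "bayesian_regression_tree"
        }
        for algorithm, candidates in sets.items():
            assert "v1" in candidates, algorithm

    def test_noise_sets_near_empty(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            rng.standard_normal((200, 20)), columns=[f"v{j:02d}" for j in range(20)]
        )
        y = np.repeat([0, 1], 100)
        sets = stage1_candidates(X, y, seed=2)
        # each cutoff passes ~5% of null variables
        for algorithm, candidates in sets.items():
            assert len(candidates) <= 2, (algorithm, candidates)

    def test_deterministic(self, one_signal_toy):
        X, y = one_signal_toy
        assert stage1_candidates(X, y, seed=7) == stage1_candidates(X, y, seed=7)


class TestMajorityVote:
    def test_worked_examples(self):
        assert majority_vote([{"a", "b"}, {"b", "c"}, {"b", "d"}]) == {"b"}
        assert majority_vote([{"a", "b"}, {"a", "c"}, {"b", "c"}]) == {"a", "b", "c"}
        assert majority_vote([set(), set(), {"a"}]) == set()

    def test_requires_three_sets(self):
        with pytest.raises(ContractError):
            majority_vote([{"a"}, {"b"}])

    @given(
        sets=st.lists(
            st.sets(st.sampled_from("abcdefgh")), min_size=3, max_size=3
        )
    )
    def test_membership_iff_in_two(self, sets):
        voted = majority_vote(sets)
        for v in "abcdefgh":
            assert (v in voted) == (sum(v in s for s in sets) >= 2)


class TestBootstrapStepwise:
    def test_redundant_duplicate_reduced_to_one(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["v1", "v2"])
        y = (X["v1"] + rng.standard_normal(200) * 0.7 > 0).astype(int).to_numpy()
        X["v2"] = X["v1"] + rng.standard_normal(200) * 0.01
        selected = bootstrap_stepwise(X, y, ["v1", "v2"], B=100, seed=1)
        assert len(selected) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pure_noise_candidate_dropped(self, seed):
        rng = np.random.default_rng(100 + seed)
        X = pd.DataFrame(rng.standard_normal((200, 1)), columns=["nv"])
        y = np.random.default_rng(200 + seed).integers(0, 2, 200)
        assert bootstrap_stepwise(X, y, ["nv"], B=100, seed=seed) == set()

    def test_empty_candidates_give_empty_set(self, one_signal_toy):
        X, y = one_signal_toy
        assert bootstrap_stepwise(X, y, [], B=50, seed=0) == set()

    def test_recovers_many_strong_signals(self):
        """All 14 independent d=1.2 signals survive; 2 noise candidates do not."""
        rng = np.random.default_rng(1)
        cols = [f"v{j:02d}" for j in range(68)]
        X = pd.DataFrame(rng.standard_normal((363, 68)), columns=cols)
        y = np.repeat([0, 1], [161, 202])
        X.loc[y == 1, cols[:14]] += 1.2
        selected = bootstrap_stepwise(X, y, cols[:16], B=100, seed=1)
        assert selected == set(cols[:14])

    def test_correlated_true_pair_both_kept(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((363, 4)), columns=list("abcd"))
        X["b"] = 0.4 * X["a"] + np.sqrt(1 - 0.16) * X["b"]
        y = np.repeat([0, 1], [161, 202])
        X.loc[y == 1, ["a", "b"]] += 1.2
        assert bootstrap_stepwise(X, y, ["a", "b"], B=100, seed=0) == {"a", "b"}

    def test_column_order_invariance(self, one_signal_toy):
        X, y = one_signal_toy
        cands = ["v1", "v3", "v5"]
        direct = bootstrap_stepwise(X, y, cands, B=50, seed=4)
        shuffled = bootstrap_stepwise(
            X[list(reversed(X.columns))], y, cands, B=50, seed=4
        )
        assert direct == shuffled

    def test_unknown_candidate_rejected(self, one_signal_toy):
        X, y = one_signal_toy
        with pytest.raises(ContractError):
            bootstrap_stepwise(X, y, ["nope"], B=50, seed=0)

    def test_unknown_criterion_rejected(self, one_signal_toy):
        X, y = one_signal_toy
        with pytest.raises(ParameterError):
            bootstrap_stepwise(X, y, ["v1"], criterion="magic")


class TestSelectionTrace:
    def test_threshold_picks_final_set(self):
        trace = SelectionTrace(
            variables=("a", "b", "c"),
            rates={"a": 1.0, "b": 0.96, "c": 0.90},
            n_repetitions=200,
            threshold=0.95,
        )
        assert trace.final_set == {"a", "b"}

    @given(
        rates=st.lists(
            st.floats(min_value=0, max_value=1), min_size=3, max_size=8
        ),
        t1=st.floats(min_value=0.01, max_value=1.0),
        t2=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_threshold_monotonicity(self, rates, t1, t2):
        lo, hi = sorted((t1, t2))
        names = tuple(f"v{i}" for i in range(len(rates)))
        trace = SelectionTrace(names, dict(zip(names, rates)), 100, threshold=hi)
        assert trace.final_set <= trace.with_threshold(lo).final_set

    def test_invalid_threshold(self):
        with pytest.raises(ParameterError):
            SelectionTrace(("a",), {"a": 1.0}, 10, threshold=0.0)

    def test_tsv_roundtrip(self, tmp_path):
        trace = SelectionTrace(("a", "b"), {"a": 1.0, "b": 0.5}, 10)
        path = tmp_path / "rates.tsv"
        trace.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["variable_id", "selection_rate", "selected_flag"]
        assert df["selected_flag"].tolist() == [True, False]


class TestRunSelection:
    def test_recovers_planted_signals_small(self, small_panel, small_design, iid_noise):
        """Three facets planted at d=1.5 are the ≥95% set; nothing else is."""
        planted = ["qa_1", "qb_0", "qw_1"]
        effects = EffectSpec({("Presence", v): 1.5 for v in planted})
        big = type(small_design)(
            tuple(
                type(c)(c.label, c.size * 2, c.schedule) for c in small_design.cohorts
            )
        )
        ds = generate(big, small_panel, effects, iid_noise, seed=5)
        df = ds.frame[ds.frame.episode_label.isin(["Presence", "Affect"])]
        X = df[[v.variable_id for v in small_panel]]
        y = (df.episode_label == "Presence").astype(int).to_numpy()
        trace = run_selection(
            X, y, n_repetitions=5, threshold=0.95, seed=3,
            groups=df.participant_id.to_numpy(),
        )
        assert trace.final_set == set(planted)

    def test_null_data_selects_nothing(self, small_panel, design):
        """No-effect data yields an empty replicable set across seeds
        (scaled down: 12 facets, 2 repetitions per seed)."""
        for seed in range(6):
            ds = generate(design, small_panel, None, None, seed=30 + seed)
            df = ds.frame[ds.frame.period == 1]
            X = df[[v.variable_id for v in small_panel]]
            y = (df.episode_label != "Retest").astype(int).to_numpy()
            trace = run_selection(
                X, y, n_repetitions=2, threshold=0.95, seed=seed,
                groups=df.participant_id.to_numpy(),
            )
            assert trace.final_set == frozenset(), (seed, dict(trace.rates))

    def test_rates_are_fractions_of_repetitions(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(
            rng.standard_normal((120, 5)), columns=[f"v{j}" for j in range(5)]
        )
        y = np.repeat([0, 1], 60)
        X.loc[y == 1, "v0"] += 2.0
        trace = run_selection(X, y, n_repetitions=3, seed=0, n_folds=5)
        assert trace.n_repetitions == 3
        for v, rate in trace.rates.items():
            hits = sum(v in s for s in trace.per_repetition_sets)
            assert rate == pytest.approx(hits / 3)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(
            rng.standard_normal((100, 4)), columns=[f"v{j}" for j in range(4)]
        )
        y = np.repeat([0, 1], 50)
        X.loc[y == 1, "v2"] += 1.5
        t1 = run_selection(X, y, n_repetitions=2, seed=9, n_folds=5)
        t2 = run_selection(X, y, n_repetitions=2, seed=9, n_folds=5)
        assert dict(t1.rates) == dict(t2.rates)

    def test_invalid_parameters(self):
        X = pd.DataFrame(np.zeros((10, 2)), columns=["a", "b"])
        y = np.repeat([0, 1], 5)
        with pytest.raises(ParameterError):
            run_selection(X, y, n_repetitions=0)
        with pytest.raises(ParameterError):
            run_selection(X, y, n_repetitions=1, fold_aggregation="sometimes")
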