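import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from conftest import brute_force_greedy
from exprnet.selection import (
    CVPartition,
    ForwardConsensusSelector,
    IncrementalConsensusSelector,
    LassoConsensusSelector,
    final_selected,
    forward_select_fold,
    incremental_select,
    make_partition,
)


class TestMakePartition:
    def test_fold_sizes_372(self):
        part = make_partition(372, seed=0)
        sizes = sorted(len(f) for f in part.folds)
        assert sizes == [74, 74, 74, 75, 75]

    def test_fold_sizes_10(self):
        part = make_partition(10, seed=3)
        assert [len(f) for f in part.folds] == [2, 2, 2, 2, 2]

    def test_disjoint_cover_and_determinism(self):
        a = make_partition(53, seed=9)
        b = make_partition(53, seed=9)
        assert a.folds == b.folds
        flat = [i for f in a.folds for i in f]
        assert sorted(flat) == list(range(53))

    def test_different_seed_different_partition(self):
        assert make_partition(53, seed=1).folds != make_partition(53, seed=2).folds

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_partition(9, seed=0)


def _planted_problem(rng, n=200, p=8, coefs=(("x1", 2.0), ("x2", -3.0)), sigma=0.3):
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"x{i + 1}" for i in range(p)]
    )
    y = sum(c * X[f] for f, c in coefs) + sigma * rng.standard_normal(n)
    return X, pd.Series(y, name="y")


class TestForwardSelectFold:
    def test_recovers_planted_pair(self, rng):
        X, y = _planted_problem(rng)
        path, best = forward_select_fold(X, y, X.index[:160], X.index[160:], max_k=6)
        assert best == {"x1", "x2"}
        assert {path[0][0], path[1][0]} == {"x1", "x2"}

    def test_single_candidate(self, rng):
        X, y = _planted_problem(rng, p=1, coefs=(("x1", 1.0),))
        path, best = forward_select_fold(X[["x1"]], y, X.index[:160], X.index[160:], max_k=3)
        assert best == {"x1"} and len(path) == 1

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = 60
            p = int(rng.integers(2, 9))
            X = pd.DataFrame(
                rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)]
            )
            y = pd.Series(
                X.iloc[:, 0] * 1.5 + rng.standard_normal(n), name="y"
            )
            train, test = np.arange(45), np.arange(45, 60)
            path, best = forward_select_fold(X, y, X.index[train], X.index[test], max_k=p)
            opath, obest = brute_force_greedy(X, y, train, test, max_k=p)
            assert [f for f, _ in path] == [f for f, _ in opath]
            assert best == obest
            np.testing.assert_allclose(
                [s for _, s in path], [s for _, s in opath], atol=1e-9
            )

    def test_duplicate_column_skipped_not_fatal(self, rng):
        # an exact copy of a selected feature makes the design singular: skipped
        X, y = _planted_problem(rng, p=3, coefs=(("x1", 2.0),))
        X["x1_copy"] = X["x1"]
        path, best = forward_select_fold(X, y, X.index[:160], X.index[160:], max_k=4)
        names = [f for f, _ in path]
        assert not ({"x1", "x1_copy"} <= set(names[:2])) or best is not None
        assert len(names) == len(set(names))


class TestForwardConsensusSelector:
    def test_consensus_subset_of_every_fold(self, rng):
        X, y = _planted_problem(rng, n=150)
        sel = ForwardConsensusSelector(cv=make_partition(150, seed=5)).fit(X, y)
        for fold in sel.per_fold_:
            assert sel.consensus_ <= fold.best_subset

    def test_strong_signal_in_consensus_and_support(self, rng):
        X, y = _planted_problem(rng, n=300, sigma=0.2)
        sel = ForwardConsensusSelector(cv=make_partition(300, seed=5)).fit(X, y)
        assert {"x1", "x2"} <= sel.consensus_
        assert set(X.columns[sel.get_support()]) == set(sel.consensus_)
        assert sorted(sel.transform(X).columns) == sorted(sel.consensus_)

    def test_sklearn_clone_roundtrip(self):
        sel = ForwardConsensusSelector(cv=make_partition(20, seed=1), max_k=4)
        cloned = clone(sel)
        assert cloned.get_params()["max_k"] == 4


class TestLassoSelector:
    def test_huge_penalty_empty_selection(self, rng):
        X, y = _planted_problem(rng, n=100)
        sel = LassoConsensusSelector(
            cv=make_partition(100, seed=2), alphas=[1e6]
        ).fit(X, y)
        assert sel.consensus_ == frozenset()

    def test_recovers_planted_pair(self, rng):
        X, y = _planted_problem(rng, n=300, sigma=0.2)
        sel = LassoConsensusSelector(cv=make_partition(300, seed=2)).fit(X, y)
        assert {"x1", "x2"} <= sel.consensus_


def _three_group_problem(rng, n=400, sigma=None):
    """One planted regulator per level group, as in the incremental analysis."""
    cols = {f"a{i}": rng.standard_normal(n) for i in range(4)}
    cols.update({f"b{i}": rng.standard_normal(n) for i in range(4)})
    cols.update({f"c{i}": rng.standard_normal(n) for i in range(4)})
    X = pd.DataFrame(cols)
    sigma = sigma if sigma is not None else np.sqrt(0.3)
    y = 0.5 * X["a0"] - 0.5 * X["b0"] + 0.45 * X["c0"] + sigma * rng.standard_normal(n)
    levels = [
        ("M2", [c for c in X.columns if c.startswith("a")]),
        ("M3", [c for c in X.columns if c[0] in "ab"]),
        ("M5", list(X.columns)),
    ]
    return X, pd.Series(y, name="g"), levels


class TestIncrementalSelect:
    def test_candidate_bookkeeping_with_reevaluation(self, rng):
        X, y, levels = _three_group_problem(rng)
        part = make_partition(len(X), seed=0)
        results = incremental_select(X, y, levels, part, "incr_ffs_reeval")
        assert [r.level for r in results] == ["M2", "M3", "M5"]
        step1, step2, step3 = results
        # step-2 candidates = (M3 \ M2) + consensus(step 1), re-evaluated
        expected = sorted(set(c for c in X.columns if c.startswith("b")) | step1.consensus)
        assert list(step2.candidates) == expected
        assert step2.carried_from_prev == step1.consensus
        # planted regulators survive to the final consensus
        assert {"a0", "b0", "c0"} <= final_selected(results)

    def test_empty_consensus_carries_nothing(self, rng):
        n = 120
        X = pd.DataFrame({f"n{i}": rng.standard_normal(n) for i in range(6)})
        y = pd.Series(rng.standard_normal(n), name="g")
        levels = [("M2", ["n0", "n1", "n2"]), ("M3", list(X.columns))]
        part = make_partition(n, seed=1)
        results = incremental_select(X, y, levels, part, "incr_ffs_reeval")
        if not results[0].consensus:  # pure noise: typically empty
            assert set(results[1].candidates) == {"n3", "n4", "n5"}

    def test_no_reevaluation_retains_redundant_feature(self, rng):
        n = 300
        x_new = rng.standard_normal(n)
        x_old = x_new + 0.05 * rng.standard_normal(n)  # nearly the same signal
        X = pd.DataFrame({"old": x_old, "new": x_new})
        y = pd.Series(x_new + 0.05 * rng.standard_normal(n), name="g")
        levels = [("M2", ["old"]), ("M3", ["old", "new"])]
        part = make_partition(n, seed=2)
        no_re = incremental_select(X, y, levels, part, "incr_ffs_noreeval")
        assert final_selected(no_re) == {"old", "new"}  # old kept unchallenged
        with_re = incremental_select(X, y, levels, part, "incr_ffs_reeval")
        assert final_selected(with_re) <= {"old", "new"}

    def test_ffs_all_single_step_recovers_planted(self, rng):
        X, y, levels = _three_group_problem(rng)
        part = make_partition(len(X), seed=3)
        results = incremental_select(X, y, levels, part, "ffs_all")
        assert len(results) == 1
        assert results[0].candidates == tuple(sorted(X.columns)) or set(
            results[0].candidates
        ) == set(X.columns)
        assert {"a0", "b0", "c0"} <= final_selected(results)

    def test_incremental_lasso_recovers_planted(self, rng):
        X, y, levels = _three_group_problem(rng)
        part = make_partition(len(X), seed=4)
        results = incremental_select(X, y, levels, part, "incr_lasso_reeval")
        assert {"a0", "b0", "c0"} <= final_selected(results)

    def test_unknown_strategy_rejected(self, rng):
        X, y, levels = _three_group_problem(rng, n=50)
        part = make_partition(50, seed=0)
        with pytest.raises(ValueError, match="strategy"):
            incremental_select(X, y, levels, part, "stepwise_aic")

    def test_estimator_interface(self, rng):
        X, y, levels = _three_group_problem(rng, n=100)
        est = IncrementalConsensusSelector(
            level_columns=levels, cv=make_partition(100, seed=0)
        )
        est.fit(X, y)
        assert hasattr(est, "consensus_") and hasattr(est, "steps_")
        mask = est.get_support()
        assert mask.sum() == len(est.consensus_)
        assert clone(est).get_params()["reevaluate"] is True
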