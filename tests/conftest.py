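import logging

import numpy as np
import pandas as pd
import pytest

import exprnet as ex

logging.getLogger("exprnet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with planted truth, generated once per session."""
    cfg = ex.CohortConfig(n_samples=120, targets_per_set=4, fillers_per_set=4, tf_pool=10)
    return ex.generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_cohort_data(small_cohort):
    c = small_cohort
    return ex.CohortData(c.annotation, c.peaks, c.probes, c.expression, c.gene_sets)


@pytest.fixture(scope="session")
def small_analysis(small_cohort, small_cohort_data):
    return ex.analyze_cohort(
        small_cohort_data,
        ex.RunConfig(seed=11),
        targets=sorted(small_cohort.truth.coefficients),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_greedy(X: pd.DataFrame, y, train, test, max_k):
    """Independent greedy forward-selection oracle.

    Re-fits every candidate OLS from scratch with numpy lstsq at every step;
    ties broken by lexicographic feature name; best subset is the path prefix
    with maximal held-out R² (first maximum).
    """
    names = sorted(X.columns)
    Xtr = X.iloc[train]
    Xte = X.iloc[test]
    ytr = np.asarray(y)[train]
    yte = np.asarray(y)[test]
    tss = np.sum((yte - yte.mean()) ** 2)
    selected: list[str] = []
    path = []
    remaining = list(names)
    while remaining and len(path) < max_k:
        best_name, best_r2 = None, -np.inf
        for cand in remaining:  # lexicographic order: first strict improvement wins
            cols = selected + [cand]
            A = np.column_stack([np.ones(len(train)), Xtr[cols].to_numpy()])
            beta, _, rank, _ = np.linalg.lstsq(A, ytr, rcond=None)
            if rank < A.shape[1]:
                continue
            pred = np.column_stack([np.ones(len(test)), Xte[cols].to_numpy()]) @ beta
            r2 = 1 - np.sum((yte - pred) ** 2) / tss
            if r2 > best_r2 + 1e-12:
                best_name, best_r2 = cand, r2
        if best_name is None:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        path.append((best_name, best_r2))
    if not path:
        return [], frozenset()
    scores = [s for _, s in path]
    best_len = int(np.argmax(scores)) + 1
    return path, frozenset(n for n, _ in path[:best_len])
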