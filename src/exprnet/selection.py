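"""Cross-validated consensus feature selection.

The central procedure is an incremental forward feature selection with
re-evaluation: candidate regulators arrive in biologically typed groups (the
new columns of M2, then M3, then M5); at each step a greedy forward search is
run independently in each of five cross-validation folds over the new group
plus the features retained from the previous step, and only the features
chosen in *all five* folds (the fold consensus) are carried forward.  The
same random fivefold partition is shared by every gene, step and strategy of
a run so fold effects cancel across models.

Within a fold the greedy search grows the feature subset one feature at a
time, at each size adding the candidate whose OLS fit on the training folds
maximizes R² on the held-out fold, and finally returns the path prefix with
the best held-out R².

Four alternative strategies are provided for benchmarking: incremental
forward selection without re-evaluation, forward selection on all features at
once, and the two analogous variants built on L1-penalized (lasso) fits.

Estimators follow the scikit-learn protocol (``fit``, ``get_support``,
``transform``, ``get_params``/``set_params``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import lasso_path

from ._util import logger

STRATEGIES = (
    "incr_ffs_reeval",
    "incr_ffs_noreeval",
    "ffs_all",
    "incr_lasso_reeval",
    "lasso_all",
)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CVPartition:
    """A fivefold sample partition shared across genes, steps and strategies."""

    seed: int
    folds: tuple[tuple[int, ...], ...]  # positional sample indices per fold
    n: int

    def splits(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_idx, test_idx) pairs; fold i is the test set of split i."""
        out = []
        for i, fold in enumerate(self.folds):
            test = np.asarray(fold, dtype=int)
            train = np.concatenate(
                [np.asarray(f, dtype=int) for j, f in enumerate(self.folds) if j != i]
            )
            out.append((train, test))
        return out


def make_partition(samples, seed: int, n_folds: int = 5) -> CVPartition:
    """Randomly split samples into ``n_folds`` near-equal disjoint groups.

    Deterministic given ``seed``; fold sizes are ⌊n/k⌋ or ⌈n/k⌉.  Requires at
    least 10 samples so every training set can support an OLS fit.
    """
    n = samples if isinstance(samples, int) else len(samples)
    if n < 10:
        raise ValueError(f"need at least 10 samples for cross-validation, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = tuple(tuple(int(i) for i in part) for part in np.array_split(perm, n_folds))
    return CVPartition(seed=seed, folds=folds, n=n)


@dataclass(frozen=True)
class FoldSelection:
    """Greedy path of one fold: features in selection order with the held-out
    R² of each prefix, and the best prefix as the fold's subset."""

    path: tuple[tuple[str, float], ...]
    best_subset: frozenset[str]
    best_score: float


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one analysis step for one target gene."""

    target_gene: str
    level: str
    strategy: str
    candidates: tuple[str, ...]
    per_fold: tuple[FoldSelection, ...]
    consensus: frozenset[str]
    carried_from_prev: frozenset[str]

    def __post_init__(self):
        cand = set(self.candidates)
        if not self.consensus <= cand:
            raise ValueError("consensus contains features outside the candidate set")
        for fold in self.per_fold:
            if not self.consensus <= fold.best_subset:
                raise ValueError("consensus not contained in a fold's best subset")


def default_max_k(n_train: int) -> int:
    """Cap on the greedy path length: min(30, n_train // 10)."""
    return max(1, min(30, n_train // 10))


def _greedy_forward(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    names: Sequence[str],
    max_k: int,
) -> FoldSelection:
    """Greedy forward search in one fold.

    Solves each augmented OLS through cached Gram blocks (one rank-1 Schur
    update per candidate), which keeps a full path over tens of candidates
    cheap.  Candidates whose addition makes the train design singular are
    skipped at that step.  Score ties are broken by lexicographic feature
    name (candidate order is name-sorted, so the first maximum wins).
    """
    order = sorted(range(len(names)), key=lambda i: names[i])
    Xs = X[:, order]
    snames = [names[i] for i in order]

    Xtr = np.column_stack([np.ones(len(train)), Xs[train]])
    Xte = np.column_stack([np.ones(len(test)), Xs[test]])
    ytr, yte = y[train], y[test]
    G = Xtr.T @ Xtr
    b = Xtr.T @ ytr
    gdiag = np.diag(G).copy()
    tss = float(np.sum((yte - yte.mean()) ** 2))

    sel: list[int] = [0]  # intercept column always in
    remaining = list(range(1, Xtr.shape[1]))
    path: list[tuple[str, float]] = []
    max_k = min(max_k, len(remaining))

    while remaining and len(path) < max_k:
        S = np.asarray(sel, dtype=int)
        J = np.asarray(remaining, dtype=int)
        Gss = G[np.ix_(S, S)]
        Gsj = G[np.ix_(S, J)]
        try:
            u = np.linalg.solve(Gss, b[S])
            Z = np.linalg.solve(Gss, Gsj)
        except np.linalg.LinAlgError:  # pragma: no cover - selected set kept regular
            break
        schur = gdiag[J] - np.einsum("ij,ij->j", Gsj, Z)
        valid = schur > 1e-10 * np.maximum(gdiag[J], 1.0)
        if not valid.any():
            logger.warning("greedy step: all remaining candidates singular; stopping")
            break
        beta_j = np.where(valid, (b[J] - Gsj.T @ u) / np.where(valid, schur, 1.0), 0.0)
        beta_s = u[:, None] - Z * beta_j[None, :]
        pred = Xte[:, S] @ beta_s + Xte[:, J] * beta_j[None, :]
        if tss > 0:
            r2 = 1.0 - np.sum((yte[:, None] - pred) ** 2, axis=0) / tss
        else:
            r2 = np.zeros(len(J))
        r2 = np.where(valid, r2, -np.inf)
        best = float(r2.max())
        # remaining is name-sorted, so the first near-tie is the lexicographic winner
        pick = int(np.nonzero(r2 >= best - _TIE_TOL)[0][0])
        chosen = remaining.pop(pick)
        sel.append(chosen)
        path.append((snames[chosen - 1], float(r2[pick])))

    if not path:
        return FoldSelection(path=(), best_subset=frozenset(), best_score=float("nan"))
    scores = [s for _, s in path]
    best_len = int(np.argmax(scores)) + 1  # first maximum -> smallest subset
    subset = frozenset(name for name, _ in path[:best_len])
    return FoldSelection(path=tuple(path), best_subset=subset, best_score=scores[best_len - 1])


def forward_select_fold(
    candidates: pd.DataFrame,
    response: pd.Series,
    train_samples: Sequence,
    test_samples: Sequence,
    max_k: int | None = None,
) -> tuple[list[tuple[str, float]], frozenset]:
    """Run the greedy forward search for one fold (train/test given by sample label)."""
    if candidates.shape[1] == 0:
        raise ValueError("no candidate features")
    train = candidates.index.get_indexer(pd.Index(train_samples))
    test = candidates.index.get_indexer(pd.Index(test_samples))
    if (train < 0).any() or (test < 0).any():
        raise KeyError("train/test samples not all present in the candidate matrix")
    if max_k is None:
        max_k = default_max_k(len(train))
    if len(train) <= max_k + 2:
        raise ValueError("training set too small for the requested path length")
    fold = _greedy_forward(
        candidates.to_numpy(dtype=float),
        response.to_numpy(dtype=float),
        train,
        test,
        list(candidates.columns),
        max_k,
    )
    return list(fold.path), fold.best_subset


class ForwardConsensusSelector(BaseEstimator):
    """Fivefold-consensus greedy forward selector.

    Runs the greedy forward search independently in each fold of ``cv`` and
    intersects the five best subsets.  ``cv`` is a :class:`CVPartition` or a
    list of (train_idx, test_idx) pairs; if None, a partition with seed 0 is
    drawn on the fitted data.

    Attributes after ``fit``: ``per_fold_`` (list of :class:`FoldSelection`),
    ``consensus_`` (frozenset of feature names), ``feature_names_in_``.
    """

    def __init__(self, cv=None, max_k: int | None = None):
        self.cv = cv
        self.max_k = max_k

    def _splits(self, n: int):
        cv = self.cv
        if cv is None:
            cv = make_partition(n, seed=0)
        if hasattr(cv, "splits"):
            return cv.splits()
        return list(cv)

    def _fold_select(self, X, y, train, test, names, max_k) -> FoldSelection:
        return _greedy_forward(X, y, train, test, names, max_k)

    def fit(self, X, y):
        X = pd.DataFrame(X)
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float)
        folds = []
        for train, test in self._splits(len(X)):
            train = np.asarray(train, dtype=int)
            test = np.asarray(test, dtype=int)
            max_k = self.max_k if self.max_k is not None else default_max_k(len(train))
            folds.append(self._fold_select(Xv, yv, train, test, names, max_k))
        self.per_fold_ = folds
        self.consensus_ = frozenset.intersection(*[f.best_subset for f in folds])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self

    def get_support(self, indices: bool = False):
        mask = np.array([n in self.consensus_ for n in self.feature_names_in_])
        return np.nonzero(mask)[0] if indices else mask

    def transform(self, X):
        X = pd.DataFrame(X)
        return X[[n for n in self.feature_names_in_ if n in self.consensus_]]


class LassoConsensusSelector(ForwardConsensusSelector):
    """Fivefold-consensus lasso selector.

    In each fold an L1-penalized linear model is fitted on the training part
    over a logarithmic penalty grid; the penalty maximizing held-out R² is
    kept and the fold's subset is the nonzero-coefficient features.  The fold
    consensus is the intersection, as for the forward variant.
    """

    def __init__(self, cv=None, max_k: int | None = None, alphas=None):
        super().__init__(cv=cv, max_k=max_k)
        self.alphas = alphas

    def _grid(self) -> np.ndarray:
        if self.alphas is not None:
            return np.sort(np.asarray(self.alphas, dtype=float))[::-1]
        return np.logspace(1, -3, 30)

    def _fold_select(self, X, y, train, test, names, max_k) -> FoldSelection:
        Xtr, Xte = X[train], X[test]
        ytr, yte = y[train], y[test]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        alphas = self._grid()
        _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=alphas, max_iter=5000)
        pred = (Xte - xm) @ coefs + ym  # (n_te, n_alphas)
        tss = float(np.sum((yte - yte.mean()) ** 2))
        if tss > 0:
            r2 = 1.0 - np.sum((yte[:, None] - pred) ** 2, axis=0) / tss
        else:
            r2 = np.zeros(coefs.shape[1])
        best = int(np.argmax(r2))  # grid is decreasing: ties favor the sparser fit
        chosen = np.nonzero(np.abs(coefs[:, best]) > 0)[0]
        subset = frozenset(names[i] for i in chosen)
        path = tuple((names[i], float(r2[best])) for i in chosen)
        return FoldSelection(path=path, best_subset=subset, best_score=float(r2[best]))


class IncrementalConsensusSelector(BaseEstimator):
    """Incremental grouped selection over nested candidate levels.

    ``level_columns`` is a sequence of (level_name, cumulative column list)
    pairs, e.g. the columns of M2, M3 and M5.  At step k the candidate pool is
    the columns new at that level plus — with ``reevaluate=True`` — the
    consensus of the previous step, which thereby competes again with the new
    group.  With ``reevaluate=False`` previously selected features are kept
    aside and appended to the final set unchallenged.

    ``base`` is ``"forward"`` or ``"lasso"``.  After ``fit``: ``steps_`` is a
    list of :class:`SelectionResult` and ``consensus_`` the final selected set.
    """

    def __init__(self, level_columns=None, base="forward", reevaluate=True,
                 cv=None, max_k=None, alphas=None, target_gene=""):
        self.level_columns = level_columns
        self.base = base
        self.reevaluate = reevaluate
        self.cv = cv
        self.max_k = max_k
        self.alphas = alphas
        self.target_gene = target_gene

    def _make_base(self):
        if self.base == "forward":
            return ForwardConsensusSelector(cv=self.cv, max_k=self.max_k)
        if self.base == "lasso":
            return LassoConsensusSelector(cv=self.cv, max_k=self.max_k, alphas=self.alphas)
        raise ValueError(f"unknown base selector {self.base!r}")

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if self.level_columns is None:
            raise ValueError("level_columns must be provided")
        strategy = (
            f"incr_{'ffs' if self.base == 'forward' else 'lasso'}_"
            f"{'reeval' if self.reevaluate else 'noreeval'}"
        )
        steps: list[SelectionResult] = []
        carried: frozenset[str] = frozenset()
        kept_aside: frozenset[str] = frozenset()
        prev_cols: set[str] = set()
        for level, cols in self.level_columns:
            cols = [c for c in cols if c in X.columns]
            new = [c for c in cols if c not in prev_cols]
            prev_cols.update(cols)
            if self.reevaluate:
                cand = sorted(set(new) | carried)
            else:
                cand = sorted(new)
            if not cand:
                steps.append(SelectionResult(
                    self.target_gene, level, strategy, tuple(cand),
                    tuple(FoldSelection((), frozenset(), float("nan")) for _ in range(5)),
                    frozenset(), carried if self.reevaluate else kept_aside,
                ))
                continue
            sel = self._make_base().fit(X[cand], y)
            steps.append(SelectionResult(
                self.target_gene, level, strategy, tuple(cand),
                tuple(sel.per_fold_), sel.consensus_,
                carried if self.reevaluate else kept_aside,
            ))
            if self.reevaluate:
                carried = sel.consensus_
            else:
                kept_aside = kept_aside | sel.consensus_
        self.steps_ = steps
        self.consensus_ = carried if self.reevaluate else kept_aside
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, indices: bool = False):
        mask = np.array([n in self.consensus_ for n in self.feature_names_in_])
        return np.nonzero(mask)[0] if indices else mask

    def transform(self, X):
        X = pd.DataFrame(X)
        return X[[n for n in self.feature_names_in_ if n in self.consensus_]]


def incremental_select(
    X: pd.DataFrame,
    y: pd.Series,
    level_columns: Sequence[tuple[str, Sequence[str]]],
    partition: CVPartition,
    strategy: str = "incr_ffs_reeval",
    max_k: int | None = None,
    alphas=None,
    target_gene: str | None = None,
) -> list[SelectionResult]:
    """Run one selection strategy over nested candidate levels.

    ``X`` holds all candidate columns of the largest level (z-scored), ``y``
    the z-scored response; ``level_columns`` gives the cumulative column list
    per analyzed level.  Returns one :class:`SelectionResult` per step (a
    single step for the ``*_all`` strategies).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    gene = target_gene if target_gene is not None else (y.name or "")
    if strategy in ("ffs_all", "lasso_all"):
        last_level, last_cols = level_columns[-1]
        level_columns = [(last_level, list(last_cols))]
        base, reevaluate = ("forward" if strategy == "ffs_all" else "lasso"), True
    else:
        base = "lasso" if "lasso" in strategy else "forward"
        reevaluate = strategy.endswith("_reeval")
    est = IncrementalConsensusSelector(
        level_columns=[(lvl, list(cols)) for lvl, cols in level_columns],
        base=base, reevaluate=reevaluate, cv=partition, max_k=max_k,
        alphas=alphas, target_gene=gene,
    ).fit(X, y)
    results = est.steps_
    if strategy in ("ffs_all", "lasso_all"):
        results = [
            SelectionResult(r.target_gene, r.level, strategy, r.candidates,
                            r.per_fold, r.consensus, r.carried_from_prev)
            for r in results
        ]
    return results


def final_selected(results: Sequence[SelectionResult]) -> frozenset[str]:
    """The final feature set of a strategy run.

    With re-evaluation the last step's consensus is the final set; without
    re-evaluation the per-step consensuses are united.
    """
    if not results:
        return frozenset()
    if results[0].strategy == "incr_ffs_noreeval":
        return frozenset().union(*[r.consensus for r in results])
    return results[-1].consensus


def selection_report(results: Iterable[SelectionResult]) -> pd.DataFrame:
    """Flatten selection results into a tidy per-fold path table."""
    rows = []
    for r in results:
        for fold_i, fold in enumerate(r.per_fold):
            for rank, (feat, score) in enumerate(fold.path, start=1):
                rows.append({
                    "target_gene": r.target_gene, "level": r.level,
                    "strategy": r.strategy, "fold": fold_i, "rank": rank,
                    "feature": feat, "heldout_r2": score,
                    "in_best_subset": feat in fold.best_subset,
                    "in_consensus": feat in r.consensus,
                })
    return pd.DataFrame(rows)
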