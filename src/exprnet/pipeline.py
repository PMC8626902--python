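"""End-to-end orchestration: cohort data -> matrices -> selection -> models.

Ties the modules together under a single run configuration whose defaults are
the study's standard parameters (promoter 2000/1000, methylation window
4000/1000, analysis levels M2/M3/M5, fivefold consensus selection with one
shared partition, adjusted-R² acceptance at 0.6, transfer floor/delta
0.4/0.1).  A single run seed drives the partition; stage seeds are derived
deterministically from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import genomic, matrices, regression, selection
from ._util import derive_seed, logger
from .genomic import GeneAnnotation, TFPeak
from .matrices import FeatureMatrix, GeneSet
from .regression import RegressionModel
from .selection import CVPartition, SelectionResult
from .transfer import apply_model, transfer_report


@dataclass(frozen=True)
class RunConfig:
    """All tunable knobs of a run, with the standard defaults."""

    promoter_upstream: int = genomic.PROMOTER_UPSTREAM
    promoter_downstream: int = genomic.PROMOTER_DOWNSTREAM
    methyl_upstream: int = genomic.METHYL_UPSTREAM
    methyl_downstream: int = genomic.METHYL_DOWNSTREAM
    levels: tuple[str, ...] = ("M2", "M3", "M5")
    strategy: str = "incr_ffs_reeval"
    seed: int = 0
    max_k: int | None = None
    max_missing_frac: float = 0.2
    adj_r2_threshold: float = 0.6
    transfer_floor: float = 0.4
    transfer_delta: float = 0.1


@dataclass
class CohortData:
    """Raw cohort inputs, as read from files or produced by the simulator."""

    annotation: list[GeneAnnotation]
    peaks: list[TFPeak]
    probes: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: list[GeneSet]


def load_cohort(directory: str | Path) -> CohortData:
    """Load a cohort from the fixed flat-file layout the simulator writes."""
    d = Path(directory)
    return CohortData(
        annotation=genomic.read_annotation(d / "annotation.gtf", "gtf"),
        peaks=genomic.read_narrowpeak(d / "peaks.narrowPeak"),
        probes=genomic.read_methyl_probes(d / "methylation.tsv"),
        expression=matrices.read_expression(d / "expression.tsv"),
        gene_sets=matrices.read_gene_sets(d / "gene_sets.tsv"),
    )


@dataclass
class PreparedCohort:
    """Derived per-cohort structures shared by all targets."""

    matrices: dict[str, dict[str, FeatureMatrix]]  # target -> level -> matrix
    tf_map: dict[str, set[str]]
    methyl: pd.DataFrame
    samples: list[str]
    targets: list[str]
    gene_sets: list[GeneSet]


def prepare(
    data: CohortData,
    config: RunConfig | None = None,
    targets: Sequence[str] | None = None,
) -> PreparedCohort:
    """Derive promoters, TF candidates and methylation features; build M1..M5."""
    cfg = config or RunConfig()
    promoters = genomic.promoter_regions(
        data.annotation, cfg.promoter_upstream, cfg.promoter_downstream
    )
    tf_map = genomic.map_tf_candidates(data.peaks, promoters)
    ann = {a.gene_symbol: a for a in data.annotation}
    set_members = {g for s in data.gene_sets for g in s.members}
    areas_by_gene = {
        g: genomic.derive_regions(
            ann[g], cfg.methyl_upstream, cfg.methyl_downstream, "methyl_area"
        )
        for g in sorted(set_members)
        if g in ann
    }
    methyl, _no_feature = genomic.methylation_matrix(data.probes, areas_by_gene)
    if methyl.empty:
        methyl = pd.DataFrame(index=data.expression.index)

    if targets is None:
        targets = [
            g for s in data.gene_sets for g in s.members if g in data.expression.columns
        ]
    mats: dict[str, dict[str, FeatureMatrix]] = {}
    samples: list[str] | None = None
    for t in targets:
        its_set = next(s for s in data.gene_sets if t in s.members)
        others = [s for s in data.gene_sets if s.name != its_set.name]
        mats[t] = matrices.build_matrices(
            t, its_set, others, data.expression, methyl, tf_map
        )
        if samples is None:
            samples = mats[t][matrices.LEVELS[-1]].samples
    return PreparedCohort(
        matrices=mats, tf_map=tf_map, methyl=methyl,
        samples=samples or [], targets=list(targets), gene_sets=data.gene_sets,
    )


def _folds_for_gene(
    partition: CVPartition, cohort_samples: Sequence[str], gene_samples: Sequence[str]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Restrict the shared partition to the samples a gene's matrix retained."""
    pos = {s: i for i, s in enumerate(gene_samples)}
    out = []
    for train, test in [
        (
            [cohort_samples[i] for i in tr],
            [cohort_samples[i] for i in te],
        )
        for tr, te in partition.splits()
    ]:
        out.append((
            np.asarray([pos[s] for s in train if s in pos], dtype=int),
            np.asarray([pos[s] for s in test if s in pos], dtype=int),
        ))
    return out


@dataclass
class TargetAnalysis:
    """Selection path and fitted models for one target gene."""

    target_gene: str
    results: list[SelectionResult]
    step_models: dict[str, RegressionModel | None]  # level -> model (None = no model)
    final_model: RegressionModel | None
    final_selected: frozenset[str]


def analyze_target(
    target_matrices: Mapping[str, FeatureMatrix],
    partition: CVPartition,
    cohort_samples: Sequence[str],
    config: RunConfig,
    strategy: str | None = None,
) -> TargetAnalysis:
    """Select regulators and fit per-step OLS models for one target."""
    strategy = strategy or config.strategy
    last = config.levels[-1]
    cleaned = matrices.handle_missing(target_matrices[last], config.max_missing_frac)
    target = cleaned.target_gene
    X = regression.zscore(cleaned.data)
    y = regression.zscore(cleaned.response)
    level_columns = [
        (lvl, [c for c in target_matrices[lvl].columns if c in X.columns])
        for lvl in config.levels
    ]
    folds = _folds_for_gene(partition, cohort_samples, cleaned.samples)
    results = selection.incremental_select(
        X, y, level_columns, _FoldList(folds), strategy=strategy,
        max_k=config.max_k, target_gene=target,
    )
    step_models: dict[str, RegressionModel | None] = {}
    for r in results:
        if r.consensus:
            step_models[r.level] = regression.fit_ols(
                X[sorted(r.consensus)], y, target_gene=target, level=r.level
            )
        else:
            step_models[r.level] = None
    final = selection.final_selected(results)
    if final:
        final_model = regression.fit_ols(X[sorted(final)], y, target_gene=target, level=last)
    else:
        final_model = None
    return TargetAnalysis(target, results, step_models, final_model, final)


class _FoldList:
    """Adapter: a plain list of (train, test) splits with a CVPartition-like face."""

    def __init__(self, splits):
        self._splits = splits

    def splits(self):
        return self._splits


@dataclass
class CohortAnalysis:
    prepared: PreparedCohort
    partition: CVPartition
    per_target: dict[str, TargetAnalysis]
    strategy: str
    config: RunConfig

    def final_models(self) -> dict[str, RegressionModel | None]:
        return {t: a.final_model for t, a in self.per_target.items()}

    def final_selected(self) -> dict[str, frozenset[str]]:
        return {t: a.final_selected for t, a in self.per_target.items()}

    def models_at(self, level: str) -> list[RegressionModel]:
        return [
            a.step_models[level]
            for a in self.per_target.values()
            if a.step_models.get(level) is not None
        ]


def analyze_cohort(
    data: CohortData,
    config: RunConfig | None = None,
    targets: Sequence[str] | None = None,
    strategy: str | None = None,
    prepared: PreparedCohort | None = None,
    partition: CVPartition | None = None,
) -> CohortAnalysis:
    """Run the full analysis for every target of a cohort under one partition."""
    cfg = config or RunConfig()
    prep = prepared if prepared is not None else prepare(data, cfg, targets)
    part = partition if partition is not None else selection.make_partition(
        len(prep.samples), derive_seed(cfg.seed, "partition")
    )
    strat = strategy or cfg.strategy
    per_target = {}
    for t in prep.targets:
        per_target[t] = analyze_target(prep.matrices[t], part, prep.samples, cfg, strat)
    return CohortAnalysis(prep, part, per_target, strat, cfg)


def compare_selection(
    data: CohortData,
    config: RunConfig | None = None,
    targets: Sequence[str] | None = None,
    strategies: Sequence[str] = selection.STRATEGIES,
) -> pd.DataFrame:
    """Benchmark the selection strategies on one cohort under the shared partition.

    Reports, per strategy, the number of targets with a model (non-empty
    final selection), the total number of selected features, and the mean
    BIC of the final models.
    """
    cfg = config or RunConfig()
    prep = prepare(data, cfg, targets)
    part = selection.make_partition(len(prep.samples), derive_seed(cfg.seed, "partition"))
    summary: dict[str, tuple[int, int, float]] = {}
    for strat in strategies:
        analysis = CohortAnalysis(
            prep, part,
            {
                t: analyze_target(prep.matrices[t], part, prep.samples, cfg, strat)
                for t in prep.targets
            },
            strat, cfg,
        )
        models = [m for m in analysis.final_models().values() if m is not None]
        n_features = sum(len(s) for s in analysis.final_selected().values())
        mean_bic = float(np.mean([m.bic for m in models])) if models else float("nan")
        summary[strat] = (len(models), n_features, mean_bic)
    return regression.strategy_summary(summary)


def transfer_models(
    models: Mapping[str, RegressionModel],
    data_b: CohortData,
    config: RunConfig | None = None,
    targets: Sequence[str] | None = None,
    drop_missing: bool = False,
) -> pd.DataFrame:
    """Apply source-cohort models to cohort B and build the transfer table."""
    cfg = config or RunConfig()
    prep = prepare(data_b, cfg, targets=list(models.keys()) if targets is None else targets)
    last = cfg.levels[-1]
    predictions = []
    for t, model in models.items():
        if model is None or t not in prep.matrices:
            continue
        cleaned = matrices.handle_missing(prep.matrices[t][last], cfg.max_missing_frac)
        X = regression.zscore(cleaned.data)
        y = regression.zscore(cleaned.response)
        predictions.append(apply_model(model, (X, y), drop_missing=drop_missing))
    return transfer_report(predictions, cfg.transfer_floor, cfg.transfer_delta)


def write_manifest(outdir: str | Path, config: RunConfig, inputs: Mapping[str, Path] | None = None) -> None:
    """Record config, seed, input checksums and versions for reproducibility."""
    import exprnet

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {},
        "versions": {
            "exprnet": exprnet.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    for name, path in (inputs or {}).items():
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        manifest["inputs"][name] = {"path": str(path), "sha256": h}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
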