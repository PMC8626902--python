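"""Per-target candidate-regulator matrices M1..M5.

For each target gene five nested feature matrices are assembled (samples ×
typed features, plus the target's expression as response):

* M1 — the target's own promoter methylation and the expression of the other
  genes in its gene set;
* M2 — M1 plus the expression of the TFs binding any promoter of the target;
* M3 — M2 plus the TFs of every gene in the target's set;
* M4 — M3 plus the genes of the other sets;
* M5 — M4 plus the TFs of the other sets' genes.

Union semantics avoid repetitions: a feature entering at several levels keeps
the provenance of its first appearance.  Expression features are named by
gene symbol; the methylation feature of gene g is named ``METH:g``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import logger
from .genomic import METHYL_PREFIX

LEVELS = ("M1", "M2", "M3", "M4", "M5")
ANALYSIS_LEVELS = ("M2", "M3", "M5")

EXPR = "EXPR"
METHYL = "METHYL"


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # EXPR or METHYL
    provenance: str  # own_methyl, same_set_gene, own_tf, same_set_tf, other_set_gene, other_set_tf


@dataclass
class FeatureMatrix:
    """Samples × features values for one target gene at one level, with response."""

    target_gene: str
    level: str
    data: pd.DataFrame  # index = samples, columns = feature names
    response: pd.Series  # target-gene expression, same index
    features: tuple[Feature, ...]

    def __post_init__(self):
        names = [f.name for f in self.features]
        if list(self.data.columns) != names:
            raise ValueError("feature metadata out of sync with matrix columns")
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        if self.target_gene in names:
            raise ValueError("response gene among predictors")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name} has duplicate members")


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from GMT or a two-column (set_name, gene) TSV."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gmt = str(path).endswith(".gmt") or len(first.rstrip("\n").split("\t")) > 2
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0] or fields[0].startswith("#"):
                continue
            if is_gmt:
                name, members = fields[0], fields[2:]  # field 1 is the GMT description
                bucket = sets.setdefault(name, [])
                for m in members:
                    if m and m not in bucket:
                        bucket.append(m)
            else:
                name, member = fields[0], fields[1]
                bucket = sets.setdefault(name, [])
                if member not in bucket:
                    bucket.append(member)
    return [GeneSet(name, tuple(members)) for name, members in sets.items()]


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV: first column sample/aliquot ID, then gene columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def build_matrices(
    target: str,
    its_set: GeneSet,
    other_sets: Sequence[GeneSet],
    expression: pd.DataFrame,
    methyl_features: pd.DataFrame,
    tf_map: Mapping[str, Iterable[str]],
) -> dict[str, FeatureMatrix]:
    """Assemble the five nested matrices for one target gene.

    ``expression`` and ``methyl_features`` are samples × genes; the samples
    used are those present in both.  Member genes missing from the expression
    table are omitted with a warning; a missing target is a hard error.  TFs
    are evaluated through their expression, so TF symbols absent from the
    expression table are dropped with a warning.
    """
    if target not in expression.columns:
        raise KeyError(f"target gene {target} absent from expression matrix")
    samples = expression.index.intersection(methyl_features.index)
    if len(samples) == 0:
        raise ValueError("no samples shared between expression and methylation data")

    def expr_features(genes: Iterable[str], provenance: str) -> list[Feature]:
        out = []
        for g in sorted(set(genes)):
            if g == target:
                continue
            if g not in expression.columns:
                logger.warning(
                    "target %s: %s feature %s absent from expression, omitted",
                    target, provenance, g,
                )
                continue
            out.append(Feature(g, EXPR, provenance))
        return out

    def tfs_of(genes: Iterable[str]) -> list[str]:
        return sorted({tf for g in genes for tf in tf_map.get(g, ())})

    groups: list[tuple[str, list[Feature]]] = []
    own_meth = []
    if target in methyl_features.columns:
        own_meth.append(Feature(METHYL_PREFIX + target, METHYL, "own_methyl"))
    groups.append(("M1", own_meth + expr_features(its_set.members, "same_set_gene")))
    groups.append(("M2", expr_features(tf_map.get(target, ()), "own_tf")))
    groups.append(("M3", expr_features(tfs_of(its_set.members), "same_set_tf")))
    other_members = [g for s in other_sets for g in s.members]
    groups.append(("M4", expr_features(other_members, "other_set_gene")))
    groups.append(("M5", expr_features(tfs_of(other_members), "other_set_tf")))

    response = expression.loc[samples, target].astype(float)
    response.name = target
    matrices: dict[str, FeatureMatrix] = {}
    seen: dict[str, Feature] = {}
    for level, new_features in groups:
        for f in new_features:
            if f.name not in seen:  # first provenance wins
                seen[f.name] = f
        features = tuple(seen.values())
        cols = {}
        for f in features:
            if f.kind == METHYL:
                cols[f.name] = methyl_features.loc[samples, f.name[len(METHYL_PREFIX):]].astype(float)
            else:
                cols[f.name] = expression.loc[samples, f.name].astype(float)
        data = pd.DataFrame(cols, index=samples)
        matrices[level] = FeatureMatrix(target, level, data, response.copy(), features)
    assert_nested(matrices)
    return matrices


def assert_nested(matrices: Mapping[str, FeatureMatrix]) -> None:
    """Assert the column-nesting invariant M1 ⊆ M2 ⊆ ... ⊆ M5."""
    present = [lvl for lvl in LEVELS if lvl in matrices]
    for lo, hi in zip(present, present[1:]):
        if not set(matrices[lo].columns) <= set(matrices[hi].columns):
            raise AssertionError(f"matrix nesting violated: {lo} not within {hi}")


def handle_missing(matrix: FeatureMatrix, max_missing_frac: float = 0.2) -> FeatureMatrix:
    """Apply the missing-data policy to one matrix.

    Samples with a missing response are dropped; columns with more than
    ``max_missing_frac`` missing values are dropped; remaining missing values
    are imputed with the column mean; zero-variance columns are dropped
    (their z-score is undefined).
    """
    data = matrix.data.copy()
    response = matrix.response.copy()
    keep_samples = response.notna()
    if not keep_samples.all():
        logger.warning(
            "target %s: dropping %d samples with missing response",
            matrix.target_gene, int((~keep_samples).sum()),
        )
        data, response = data.loc[keep_samples], response.loc[keep_samples]

    kept: list[Feature] = []
    for f in matrix.features:
        col = data[f.name]
        frac = col.isna().mean()
        if frac > max_missing_frac:
            logger.warning(
                "target %s: dropping feature %s (%.0f%% missing)",
                matrix.target_gene, f.name, 100 * frac,
            )
            continue
        if frac > 0:
            data[f.name] = col.fillna(col.mean())
        if data[f.name].nunique() <= 1:
            logger.warning(
                "target %s: dropping constant feature %s", matrix.target_gene, f.name
            )
            continue
        kept.append(f)
    return FeatureMatrix(
        matrix.target_gene,
        matrix.level,
        data[[f.name for f in kept]],
        response,
        tuple(kept),
    )


def export_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a matrix as TSV (response first) with a JSON provenance sidecar."""
    import json

    out = pd.concat([matrix.response.rename(matrix.target_gene), matrix.data], axis=1)
    out.to_csv(path, sep="\t", index_label="sample")
    sidecar = {
        "target_gene": matrix.target_gene,
        "level": matrix.level,
        "features": [
            {"name": f.name, "kind": f.kind, "provenance": f.provenance}
            for f in matrix.features
        ],
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
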