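"""Cross-cohort model transfer.

A model fitted in a source cohort is applied, coefficients unchanged, to the
z-scored feature values of a target cohort (z-scoring is always within-cohort
for both):  EXPR_g = c1·v_f1 + ... + cn·v_fn (+ the source intercept).  Fit in
the target cohort is scored as R² against the observed z-scored expression —
which can be negative and is reported as computed — and as adjusted R² with
k equal to the number of features applied.  A gene is flagged "similarly
regulated" when its source adjusted R² clears a floor (default 0.4) and the
source/target adjusted R² differ by at most a delta (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrices import FeatureMatrix
from .regression import RegressionModel, adjusted_r2


@dataclass
class TransferPrediction:
    """Result of applying one source-cohort model to a target cohort."""

    target_gene: str
    source_model: RegressionModel
    predicted: pd.Series
    observed: pd.Series
    r2: float
    adj_r2: float
    missing_features: tuple[str, ...] = ()


def apply_model(
    model: RegressionModel,
    matrix: FeatureMatrix | tuple[pd.DataFrame, pd.Series],
    drop_missing: bool = False,
) -> TransferPrediction:
    """Predict a gene's expression in a new cohort with unchanged coefficients.

    ``matrix`` supplies the z-scored features and z-scored observed response
    of the target cohort.  Features absent from the cohort are a hard error
    unless ``drop_missing``, in which case they are omitted from the linear
    combination and listed.
    """
    if isinstance(matrix, FeatureMatrix):
        data, observed = matrix.data, matrix.response
    else:
        data, observed = matrix
    missing = tuple(f for f in model.features if f not in data.columns)
    if missing and not drop_missing:
        raise KeyError(
            f"features {list(missing)} of the {model.target_gene} model are "
            "absent from the target cohort (use drop_missing to omit them)"
        )
    used = [(f, c) for f, c in zip(model.features, model.coefficients) if f not in missing]
    pred = pd.Series(model.intercept, index=data.index, dtype=float)
    for f, c in used:
        pred = pred + c * data[f].astype(float)
    obs = observed.astype(float)
    sse = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else float("nan")
    k = len(used)
    adj = adjusted_r2(r2, len(obs), k) if len(obs) > k + 1 else float("nan")
    return TransferPrediction(
        target_gene=model.target_gene, source_model=model,
        predicted=pred, observed=obs, r2=r2, adj_r2=adj,
        missing_features=missing,
    )


def transfer_report(
    predictions: Iterable[TransferPrediction],
    adj_r2_floor: float = 0.4,
    delta: float = 0.1,
) -> pd.DataFrame:
    """Side-by-side source/target fit table with the similarly-regulated flag."""
    rows = []
    for p in predictions:
        src = p.source_model.adj_r2
        flag = bool(src >= adj_r2_floor and abs(src - p.adj_r2) <= delta)
        rows.append({
            "target_gene": p.target_gene,
            "adj_r2_source": src,
            "adj_r2_target": p.adj_r2,
            "r2_target": p.r2,
            "similarly_regulated": flag,
            "missing_features": ",".join(p.missing_features),
        })
    return pd.DataFrame(
        rows,
        columns=["target_gene", "adj_r2_source", "adj_r2_target", "r2_target",
                 "similarly_regulated", "missing_features"],
    )


def coefficient_comparison(
    models_a: Sequence[RegressionModel],
    models_b: Sequence[RegressionModel],
) -> pd.DataFrame:
    """Coefficients of features shared by two cohorts' models of the same gene."""
    by_gene_b = {m.target_gene: m for m in models_b}
    rows = []
    for ma in models_a:
        mb = by_gene_b.get(ma.target_gene)
        if mb is None:
            continue
        ca = dict(zip(ma.features, ma.coefficients))
        cb = dict(zip(mb.features, mb.coefficients))
        for f in sorted(set(ca) & set(cb)):
            rows.append({
                "target_gene": ma.target_gene, "feature": f,
                "coef_source": ca[f], "coef_target": cb[f],
            })
    return pd.DataFrame(rows, columns=["target_gene", "feature", "coef_source", "coef_target"])
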