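"""Synthetic multi-omic cohorts with a planted sparse regulatory truth.

The generator emulates the shape of a tumor-cohort analysis: a gene
annotation with strands and TSSs, ChIP-seq-style TF binding peaks placed
inside (and, as decoys, outside) promoters, a methylation probe table with
beta values in [0, 1], gene-set definitions, and a continuous expression
matrix.  Each target gene's expression is a sparse linear combination of
z-scored regulator values plus Gaussian noise, and the coefficient map is
emitted alongside the data as the recovery oracle.

Regulators are exogenous (no feedback loops), so the planted model is
identifiable.  By default each target has three planted regulators, one per
analysis step: one visible in M2 (its own promoter methylation — with a
negative coefficient, methylation being repressive — its own TF, or a
same-set gene), one entering at M3 (a TF bound to another same-set gene's
promoter), and one entering at M5 (a gene of the other set).  Planted
standardized coefficients have magnitude in [coef_min, coef_max] and are
scaled so the model's true R² matches ``r2`` (default 0.7); the methylation
signal is injected on the logit scale of the probe betas and clipped to
[0.01, 0.99].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genomic import (
    METHYL_PREFIX,
    GeneAnnotation,
    PromoterRegion,
    TFPeak,
    derive_regions,
)
from .matrices import GeneSet
from .regression import RegressionModel, zscore


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort."""

    n_samples: int = 400
    n_sets: int = 2
    targets_per_set: int = 10
    fillers_per_set: int = 6
    tf_pool: int = 20
    decoy_tfs_per_target: int = 2
    regulators_per_target: int = 3
    coef_min: float = 0.3
    coef_max: float = 0.9
    r2: float = 0.7
    methyl_frac: float = 0.5
    probes_per_gene: int = 5
    n_decoy_peaks: int = 30
    probe_noise_sd: float = 0.3
    methyl_slope: float = 1.0

    def __post_init__(self):
        if self.n_samples < 50:
            raise ValueError("n_samples must be >= 50")
        if self.n_sets < 1:
            raise ValueError("need at least one gene set")
        if not 0 < self.r2 <= 1:
            raise ValueError("r2 must be in (0, 1]")
        if self.regulators_per_target < 0:
            raise ValueError("regulators_per_target must be >= 0")
        m = max(self.regulators_per_target, 1)
        rms = np.sqrt(self.r2 / m)
        if not (self.coef_min <= rms <= self.coef_max):
            raise ValueError(
                "infeasible coefficient configuration: sqrt(r2/m) must lie in "
                f"[coef_min, coef_max], got {rms:.3f}"
            )
        if self.n_sets < 2 and self.regulators_per_target >= 3:
            raise ValueError("an other-set regulator needs n_sets >= 2")


def noise_cohort_config(n_samples: int = 300) -> CohortConfig:
    """An all-noise cohort (no planted regulators, ~30 candidates per target).

    Used to measure selection specificity: with no signal, the fivefold
    consensus should be empty for almost every target.
    """
    return CohortConfig(
        n_samples=n_samples, n_sets=2, targets_per_set=5, fillers_per_set=5,
        tf_pool=12, decoy_tfs_per_target=2, regulators_per_target=0,
    )


@dataclass
class SyntheticTruth:
    """Planted coefficient map and noise level — the recovery oracle."""

    coefficients: dict[str, dict[str, float]]
    noise_sd: float
    seed: int
    config: CohortConfig

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            coefficients={t: dict(c) for t, c in d["coefficients"].items()},
            noise_sd=float(d["noise_sd"]),
            seed=int(d["seed"]),
            config=CohortConfig(**d["config"]),
        )


@dataclass
class SyntheticCohort:
    """In-memory cohort: the same objects the file readers would produce."""

    annotation: list[GeneAnnotation]
    peaks: list[TFPeak]
    probes: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: list[GeneSet]
    truth: SyntheticTruth


def _draw_coefficients(rng, m, r2, cmin, cmax) -> np.ndarray:
    """Magnitudes in [cmin, cmax] rescaled so the squared sum equals r2."""
    for _ in range(10_000):
        u = rng.uniform(cmin, cmax, size=m)
        c = u * np.sqrt(r2 / np.sum(u**2))
        if c.min() >= cmin - 1e-12 and c.max() <= cmax + 1e-12:
            return c
    raise RuntimeError("could not draw a feasible coefficient vector")


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate a full cohort (optionally written to ``outdir``) plus its truth."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)

    set_names = [f"SET{i + 1}" for i in range(cfg.n_sets)]
    targets = {
        s: [f"G{i + 1}{j + 1:02d}" for j in range(cfg.targets_per_set)]
        for i, s in enumerate(set_names)
    }
    fillers = {
        s: [f"F{i + 1}{j + 1:02d}" for j in range(cfg.fillers_per_set)]
        for i, s in enumerate(set_names)
    }
    tf_pool = [f"TF{j + 1:02d}" for j in range(cfg.tf_pool)]
    all_targets = [t for s in set_names for t in targets[s]]
    annotated = [g for s in set_names for g in targets[s] + fillers[s]]

    # --- annotation: one TSS per gene on chr1, 50 kb spacing, random strand
    annotation = []
    tss_of: dict[str, int] = {}
    for i, g in enumerate(annotated):
        tss = 100_000 + i * 50_000
        strand = "+" if rng.random() < 0.5 else "-"
        tss_of[g] = tss
        annotation.append(GeneAnnotation(g, "chr1", strand, (tss,)))
    ann_by_symbol = {a.gene_symbol: a for a in annotation}

    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    # --- methylation probes for every target (latent signal per target)
    probe_rows = []
    latent_m: dict[str, np.ndarray] = {}
    beta_by_probe: dict[str, np.ndarray] = {}
    for t in all_targets:
        area = derive_regions(
            ann_by_symbol[t], 4000, 1000, "methyl_area"
        )[0]
        m = rng.standard_normal(cfg.n_samples)
        latent_m[t] = m
        width = area.end - area.start
        positions = area.start + (np.arange(cfg.probes_per_gene) + 1) * width // (
            cfg.probes_per_gene + 1
        )
        for p_i, pos in enumerate(positions):
            base = rng.uniform(0.3, 0.7)
            noise = rng.normal(0.0, cfg.probe_noise_sd, cfg.n_samples)
            beta = expit(logit(base) + cfg.methyl_slope * m + noise)
            beta = np.clip(beta, 0.01, 0.99)
            pid = f"cg_{t}_{p_i + 1}"
            probe_rows.append((pid, "chr1", int(pos), beta))
            beta_by_probe[pid] = beta
    beta_mat = np.vstack([r[3] for r in probe_rows]) if probe_rows else np.empty((0, cfg.n_samples))
    probes = pd.concat(
        [
            pd.DataFrame(
                {
                    "probe_id": [r[0] for r in probe_rows],
                    "chrom": [r[1] for r in probe_rows],
                    "position": [r[2] for r in probe_rows],
                }
            ),
            pd.DataFrame(beta_mat, columns=samples),
        ],
        axis=1,
    )

    # --- planted regulators, TF binding and peaks
    peaks: list[TFPeak] = []
    bound_tfs: dict[str, set[str]] = {t: set() for t in all_targets}

    def promoter_peak(tf: str, gene: str) -> TFPeak:
        tss = tss_of[gene]
        return TFPeak(tf, "chr1", tss - 50, tss + 50, signal=float(rng.uniform(5, 50)),
                      summit_offset=50)

    planted: dict[str, dict[str, float]] = {}
    dedicated_tfs: list[str] = []
    slot_cycle = ("m2", "m3", "m5")
    for s_i, s in enumerate(set_names):
        other = set_names[(s_i + 1) % len(set_names)] if len(set_names) > 1 else None
        for t in targets[s]:
            # decoy TFs bound to the target's promoter (zero coefficient)
            for tf in rng.choice(tf_pool, size=cfg.decoy_tfs_per_target, replace=False):
                if tf not in bound_tfs[t]:
                    bound_tfs[t].add(str(tf))
                    peaks.append(promoter_peak(str(tf), t))
            features: list[str] = []
            for slot_i in range(cfg.regulators_per_target):
                slot = slot_cycle[slot_i % 3]
                if slot == "m2":
                    if rng.random() < cfg.methyl_frac:
                        features.append(METHYL_PREFIX + t)
                    elif rng.random() < 0.5:
                        tf = f"TFo_{t}"  # own TF, bound to the target's promoter
                        dedicated_tfs.append(tf)
                        bound_tfs[t].add(tf)
                        peaks.append(promoter_peak(tf, t))
                        features.append(tf)
                    else:
                        features.append(str(rng.choice(fillers[s])))
                elif slot == "m3":
                    # TF bound to another same-set target's promoter, not to t's
                    partner_pool = [g for g in targets[s] if g != t] or fillers[s]
                    partner = str(rng.choice(partner_pool))
                    tf = f"TFs_{t}"
                    dedicated_tfs.append(tf)
                    bound_tfs.setdefault(partner, set()).add(tf)
                    peaks.append(promoter_peak(tf, partner))
                    features.append(tf)
                else:  # m5: a gene of the other set
                    features.append(str(rng.choice(fillers[other])))
            # a feature may have been drawn twice; keep unique, order preserved
            features = list(dict.fromkeys(features))
            coefs = _draw_coefficients(
                rng, len(features), cfg.r2, cfg.coef_min, cfg.coef_max
            ) if features else np.array([])
            signs = np.where(rng.random(len(features)) < 0.5, -1.0, 1.0)
            planted[t] = {}
            for f, c, sg in zip(features, coefs, signs):
                planted[t][f] = float(-c if f.startswith(METHYL_PREFIX) else c * sg)

    # decoy peaks well outside any promoter or methylation area
    for _ in range(cfg.n_decoy_peaks):
        g = str(rng.choice(annotated))
        tf = str(rng.choice(tf_pool))
        pos = tss_of[g] + 20_000
        peaks.append(TFPeak(tf, "chr1", pos, pos + 200, signal=float(rng.uniform(5, 50)),
                            summit_offset=100))

    # --- expression: exogenous regulators ~ N(0,1); targets = planted linear map
    expr_cols: dict[str, np.ndarray] = {}
    for g in [f for s in set_names for f in fillers[s]] + tf_pool + sorted(set(dedicated_tfs)):
        expr_cols[g] = rng.standard_normal(cfg.n_samples)

    # aggregated methylation per target, exactly as the pipeline will compute it
    agg_meth: dict[str, np.ndarray] = {}
    for t in all_targets:
        pids = [f"cg_{t}_{i + 1}" for i in range(cfg.probes_per_gene)]
        agg_meth[t] = np.mean([beta_by_probe[p] for p in pids], axis=0)

    noise_sd = float(np.sqrt(max(0.0, 1.0 - cfg.r2)))
    for t in all_targets:
        signal = np.zeros(cfg.n_samples)
        for f, c in planted[t].items():
            if f.startswith(METHYL_PREFIX):
                v = agg_meth[f[len(METHYL_PREFIX):]]
            else:
                v = expr_cols[f]
            vz = (v - v.mean()) / v.std(ddof=1)
            signal += c * vz
        expr_cols[t] = signal + rng.normal(0.0, noise_sd, cfg.n_samples)

    ordered = all_targets + [f for s in set_names for f in fillers[s]] + tf_pool + sorted(
        set(dedicated_tfs)
    )
    expression = pd.DataFrame({g: expr_cols[g] for g in ordered}, index=pd.Index(samples, name="sample"))

    gene_sets = [GeneSet(s, tuple(targets[s] + fillers[s])) for s in set_names]
    truth = SyntheticTruth(coefficients=planted, noise_sd=noise_sd, seed=seed, config=cfg)
    cohort = SyntheticCohort(
        annotation=annotation, peaks=peaks, probes=probes,
        expression=expression, gene_sets=gene_sets, truth=truth,
    )
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort in the same flat-file formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "annotation.gtf", "w") as fh:
        for a in cohort.annotation:
            tss = a.tss_list[0]
            if a.strand == "+":
                start1, end1 = tss + 1, tss + 5000
            else:
                end1 = tss + 1
                start1 = max(1, end1 - 4999)
            attrs = f'gene_id "{a.gene_symbol}"; gene_name "{a.gene_symbol}";'
            fh.write(f"{a.chrom}\texprnet\tgene\t{start1}\t{end1}\t.\t{a.strand}\t.\t{attrs}\n")
            fh.write(
                f"{a.chrom}\texprnet\ttranscript\t{start1}\t{end1}\t.\t{a.strand}\t.\t"
                f'{attrs} transcript_id "{a.gene_symbol}.1";\n'
            )

    with open(outdir / "peaks.narrowPeak", "w") as fh:
        for p in cohort.peaks:
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_symbol}\t0\t.\t"
                f"{p.signal if p.signal is not None else 0:.4f}\t-1\t-1\t{summit}\n"
            )

    cohort.probes.to_csv(outdir / "methylation.tsv", sep="\t", index=False,
                         float_format="%.6f")
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t", index=True,
                             float_format="%.8f")
    with open(outdir / "gene_sets.tsv", "w") as fh:
        for gs in cohort.gene_sets:
            for g in gs.members:
                fh.write(f"{gs.name}\t{g}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_dict(json.load(fh))


def score_recovery(
    selected: Mapping[str, Iterable[str]],
    truth: SyntheticTruth,
    models: Mapping[str, RegressionModel | None] | None = None,
) -> dict:
    """Precision/recall/F1 of selected features against the planted truth.

    Per-target and aggregate; aggregate precision averages over targets with
    at least one selected feature (macro), and pooled counts are reported as
    well.  With fitted models, the RMSE of fitted vs planted coefficients is
    computed over true positives.
    """
    per_target = []
    tp_tot = sel_tot = true_tot = 0
    sq_errs: list[float] = []
    for t, true_map in truth.coefficients.items():
        true_set = set(true_map)
        sel = set(selected.get(t, ()))
        tp = len(sel & true_set)
        precision = tp / len(sel) if sel else float("nan")
        recall = tp / len(true_set) if true_set else float("nan")
        denom = (precision + recall) if sel and true_set else 0
        f1 = 2 * precision * recall / denom if denom else 0.0
        per_target.append({
            "target_gene": t, "n_true": len(true_set), "n_selected": len(sel),
            "tp": tp, "precision": precision, "recall": recall, "f1": f1,
        })
        tp_tot += tp
        sel_tot += len(sel)
        true_tot += len(true_set)
        if models is not None:
            m = models.get(t)
            if m is not None:
                fitted = dict(zip(m.features, m.coefficients))
                for f in sel & true_set:
                    if f in fitted:
                        sq_errs.append((fitted[f] - true_map[f]) ** 2)
    table = pd.DataFrame(per_target)
    return {
        "per_target": table,
        "mean_recall": float(table["recall"].mean()),
        "mean_precision": float(table["precision"].mean()),
        "pooled_recall": tp_tot / true_tot if true_tot else float("nan"),
        "pooled_precision": tp_tot / sel_tot if sel_tot else float("nan"),
        "coef_rmse": float(np.sqrt(np.mean(sq_errs))) if sq_errs else float("nan"),
        "nonempty_fraction": float((table["n_selected"] > 0).mean()),
    }
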