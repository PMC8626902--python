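import json

import numpy as np
import pandas as pd
import pytest

import exprnet as ex
from exprnet.genomic import METHYL_PREFIX
from exprnet.synthetic import (
    CohortConfig,
    SyntheticTruth,
    generate_cohort,
    noise_cohort_config,
    read_truth,
    score_recovery,
    write_cohort,
)


SMALL = CohortConfig(n_samples=80, targets_per_set=3, fillers_per_set=3, tf_pool=8)


class TestGenerateCohort:
    def test_byte_identical_regeneration(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(SMALL, seed=5, outdir=d1)
        generate_cohort(SMALL, seed=5, outdir=d2)
        for name in ["annotation.gtf", "peaks.narrowPeak", "methylation.tsv",
                     "expression.tsv", "gene_sets.tsv", "truth.json"]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self):
        a = generate_cohort(SMALL, seed=1)
        b = generate_cohort(SMALL, seed=2)
        assert not a.expression.equals(b.expression)

    def test_planted_tf_links_recovered_by_peak_mapping(self):
        cohort = generate_cohort(SMALL, seed=3)
        promoters = ex.genomic.promoter_regions(cohort.annotation)
        tf_map = ex.map_tf_candidates(cohort.peaks, promoters)
        union_bound = set().union(*tf_map.values())
        for target, coefs in cohort.truth.coefficients.items():
            for feature in coefs:
                if feature.startswith("TFo_"):
                    assert feature in tf_map[target]  # own TF binds the target
                elif feature.startswith("TFs_"):
                    assert feature in union_bound  # same-set TF binds a partner
                    assert feature not in tf_map.get(target, set())

    def test_planted_features_exist_in_emitted_data(self):
        cohort = generate_cohort(SMALL, seed=4)
        meth_genes = {p.split("_")[1] for p in cohort.probes["probe_id"]}
        for target, coefs in cohort.truth.coefficients.items():
            for feature, c in coefs.items():
                assert abs(c) >= SMALL.coef_min - 1e-9
                if feature.startswith(METHYL_PREFIX):
                    assert feature[len(METHYL_PREFIX):] in meth_genes
                    assert c < 0  # methylation is repressive
                else:
                    assert feature in cohort.expression.columns

    def test_noiseless_limit_perfect_fit(self):
        cfg = CohortConfig(n_samples=80, targets_per_set=3, fillers_per_set=3,
                           tf_pool=8, r2=1.0)
        cohort = generate_cohort(cfg, seed=6)
        assert cohort.truth.noise_sd == 0.0
        t, coefs = next(iter(cohort.truth.coefficients.items()))
        cols = {}
        for f in coefs:
            if f.startswith(METHYL_PREFIX):
                gene = f[len(METHYL_PREFIX):]
                pids = cohort.probes["probe_id"].str.startswith(f"cg_{gene}_")
                sample_cols = cohort.expression.index
                cols[f] = cohort.probes.loc[pids, sample_cols].mean(axis=0).to_numpy()
            else:
                cols[f] = cohort.expression[f].to_numpy()
        X = ex.zscore(pd.DataFrame(cols, index=cohort.expression.index))
        y = ex.zscore(cohort.expression[t])
        with pytest.warns(UserWarning, match="BIC"):
            model = ex.fit_ols(X, y)
        assert model.r2 == pytest.approx(1.0, abs=1e-9)

    def test_roundtrip_through_readers(self, tmp_path):
        cohort = generate_cohort(SMALL, seed=7, outdir=tmp_path)
        data = ex.load_cohort(tmp_path)
        assert {a.gene_symbol for a in data.annotation} == {
            a.gene_symbol for a in cohort.annotation
        }
        assert len(data.peaks) == len(cohort.peaks)
        assert list(data.expression.columns) == list(cohort.expression.columns)
        np.testing.assert_allclose(
            data.expression.to_numpy(), cohort.expression.to_numpy(), atol=1e-7
        )
        truth = read_truth(tmp_path / "truth.json")
        assert truth.coefficients == cohort.truth.coefficients

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(regulators_per_target=30)
        with pytest.raises(ValueError):
            CohortConfig(n_samples=10)
        with pytest.raises(ValueError, match="other-set"):
            CohortConfig(n_sets=1)

    def test_noise_config_has_no_planted_signal(self):
        cohort = generate_cohort(noise_cohort_config(), seed=8)
        assert all(not c for c in cohort.truth.coefficients.values())


class TestScoreRecovery:
    def truth(self, mapping):
        return SyntheticTruth(
            coefficients=mapping, noise_sd=0.5, seed=0,
            config=CohortConfig(n_samples=80, targets_per_set=3,
                                fillers_per_set=3, tf_pool=8),
        )

    def test_perfect_selection(self):
        truth = self.truth({"g": {"a": 0.5, "b": -0.4, "c": 0.3}})
        out = score_recovery({"g": {"a", "b", "c"}}, truth)
        assert out["mean_precision"] == 1.0 and out["mean_recall"] == 1.0

    def test_one_extra_feature(self):
        truth = self.truth({"g": {"a": 0.5, "b": -0.4, "c": 0.3}})
        out = score_recovery({"g": {"a", "b", "c", "junk"}}, truth)
        assert out["mean_precision"] == pytest.approx(0.75)
        assert out["mean_recall"] == 1.0

    def test_exact_coefficients_zero_rmse(self):
        truth = self.truth({"g": {"a": 0.5}})
        model = ex.RegressionModel(
            target_gene="g", level="M5", features=("a",), coefficients=(0.5,),
            ci_low=(0.3,), ci_high=(0.7,), significant=(True,), intercept=0.0,
            r2=0.8, adj_r2=0.79, bic=-10, n=80, k=1,
        )
        out = score_recovery({"g": {"a"}}, truth, {"g": model})
        assert out["coef_rmse"] == 0.0
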