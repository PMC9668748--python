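"""Count filters, normalisation, outlier QC, and covariate regression."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cortex_ari as ca
from cortex_ari.preprocess import CountMatrix, biweight_midcorrelation


def make_counts(values: np.ndarray, lengths=None) -> CountMatrix:
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    if lengths is None:
        lengths = pd.Series(1000.0, index=genes)
    else:
        lengths = pd.Series(lengths, index=genes)
    return CountMatrix(
        counts=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples),
        effective_length=lengths,
    )


class TestCPM:
    def test_single_gene_full_library(self):
        cm = make_counts(np.array([[10]]))
        assert ca.cpm(cm).iloc[0, 0] == pytest.approx(1e6)

    def test_all_zero_gene(self):
        cm = make_counts(np.array([[0, 0], [5, 5]]))
        assert (ca.cpm(cm).iloc[0] == 0).all()

    def test_hand_computed_4x4(self, rng):
        vals = rng.integers(0, 50, size=(4, 4))
        vals[0, 0] += 1  # avoid an all-zero column
        cm = make_counts(vals)
        expected = vals / vals.sum(axis=0, keepdims=True) * 1e6
        np.testing.assert_allclose(ca.cpm(cm).to_numpy(), expected)

    def test_zero_library_rejected(self):
        cm = make_counts(np.array([[0, 1], [0, 2]]))
        with pytest.raises(ValueError, match="zero library"):
            ca.cpm(cm)


class TestFilterFeatures:
    def make_toy(self):
        # 6 genes x 10 samples, library sizes ~1e6 so CPM ~ count.
        # Thresholds: CPM > 0.1 in >= ceil(0.3*10)=3 samples, length >= 15.
        base = np.full((6, 10), 0, dtype=np.int64)
        filler = np.full(10, 1_000_000, dtype=np.int64)
        base[0] = 10          # CPM ~10 in 10 samples, len ok      -> keep
        base[1] = [1] * 3 + [0] * 7   # qualifies in exactly 3     -> keep
        base[2] = [1] * 2 + [0] * 8   # only 2 qualifying          -> drop
        base[3] = 0            # all zero                          -> drop
        base[4] = 5            # qualifies but length 10 < 15      -> drop
        base[5] = [7] * 4 + [0] * 6   # qualifies in 4             -> keep
        lengths = [1000, 1000, 1000, 1000, 10, 15]
        vals = base + 0
        cm = make_counts(np.vstack([vals, filler[None, :]]),
                         lengths=lengths + [1000])
        return cm

    def test_hand_enumerated_retention(self):
        cm = self.make_toy()
        kept = ca.filter_features(cm)
        assert list(kept.gene_ids) == ["g0", "g1", "g5", "g6"]

    def test_idempotent(self):
        cm = self.make_toy()
        once = ca.filter_features(cm)
        twice = ca.filter_features(once)
        assert list(once.gene_ids) == list(twice.gene_ids)

    def test_boundary_is_strict_on_cpm(self):
        # CPM exactly 0.1 must NOT qualify
        vals = np.full((1, 10), 1, dtype=np.int64)
        filler = np.full((1, 10), 9_999_999, dtype=np.int64)  # library 1e7 -> CPM 0.1
        cm = make_counts(np.vstack([vals, filler]))
        kept = ca.filter_features(cm)
        assert "g0" not in list(kept.gene_ids)


class TestLogNormalize:
    def test_known_values(self):
        # CPM 0 with prior 0.5 -> -1; CPM 1.5 -> log2(2) = 1
        cm = make_counts(np.array([[0], [3]]))
        out = ca.log_normalize(cm)
        assert out.iloc[0, 0] == pytest.approx(-1.0)
        cm2 = make_counts(np.array([[15], [9_999_985]]))
        assert ca.log_normalize(cm2).iloc[0, 0] == pytest.approx(np.log2(1.5 + 0.5))

    def test_monotone_in_cpm(self, rng):
        vals = rng.integers(0, 1000, size=(50, 1)).astype(np.int64)
        cm = make_counts(vals)
        out = ca.log_normalize(cm).to_numpy().ravel()
        order = np.argsort(vals.ravel())
        assert (np.diff(out[order]) >= 0).all()


class TestOutliers:
    def planted(self, n_genes=100, seed=9):
        cfg = ca.SimulationConfig(n_control=12, n_case=12, missing_rate=0.0,
                                  n_genes=n_genes, seed=seed)
        expr, meta, _ = ca.generate_dataset(cfg)
        bad = expr.columns[0]
        rng = np.random.default_rng(1)
        expr[bad] = expr[bad] + rng.normal(0, 3, size=n_genes)
        return expr, meta, bad

    def test_planted_outlier_flagged_and_recomputed(self):
        expr, meta, bad = self.planted()
        report = ca.detect_outliers(expr, meta).set_index("sample_id")
        assert report.loc[bad, "outlier"]
        # independent recomputation of both criteria within the bad group
        grp = report.loc[bad, "group"]
        samples = report.index[report["group"] == grp]
        X = expr[list(samples)].to_numpy()
        M = (X - X.mean(axis=1, keepdims=True)).T
        M = M - M.mean(axis=0)
        U, s, _ = np.linalg.svd(M, full_matrices=False)
        scores = U[:, :10] * s[:10]
        z = (scores - scores.mean(0)) / scores.std(0, ddof=1)
        max_z = np.abs(z).max(axis=1)
        j = list(samples).index(bad)
        assert max_z[j] == pytest.approx(report.loc[bad, "max_abs_pc_z"])
        assert max_z[j] > 3
        corr, _ = biweight_midcorrelation(X)
        adj = ((1 + corr) / 2) ** 2
        np.fill_diagonal(adj, 0)
        k = adj.sum(axis=1)
        zk = (k - k.mean()) / k.std(ddof=1)
        assert zk[j] == pytest.approx(report.loc[bad, "zk"])
        assert zk[j] < -2

    def test_flags_invariant_to_sample_order(self):
        expr, meta, bad = self.planted()
        rng = np.random.default_rng(3)
        perm = rng.permutation(expr.shape[1])
        expr2 = expr.iloc[:, perm]
        meta2 = meta.iloc[perm].reset_index(drop=True)
        r1 = ca.detect_outliers(expr, meta).set_index("sample_id")["outlier"]
        r2 = ca.detect_outliers(expr2, meta2).set_index("sample_id")["outlier"]
        assert r1.sort_index().equals(r2.sort_index())

    def test_identical_samples_not_flagged(self):
        genes = [f"g{i}" for i in range(20)]
        base = np.random.default_rng(0).normal(size=20)
        samples = [f"s{j}" for j in range(6)]
        expr = pd.DataFrame({s: base for s in samples}, index=genes)
        meta = pd.DataFrame(
            {"sample_id": samples,
             "subject_id": samples,
             "region": ["BA9"] * 6,
             "diagnosis": ["control"] * 6}
        )
        report = ca.detect_outliers(expr, meta, group_by=("lobe",))
        assert not report["outlier"].any()

    def test_and_rule_requires_both_criteria(self):
        # A sample shifted by a constant moves on PCs but keeps correlation
        # (hence connectivity) with the rest, so it must not be flagged.
        cfg = ca.SimulationConfig(n_control=12, n_case=12, missing_rate=0.0,
                                  n_genes=100, seed=13)
        expr, meta, _ = ca.generate_dataset(cfg)
        target = expr.columns[2]
        expr[target] = expr[target] + 50.0
        report = ca.detect_outliers(expr, meta).set_index("sample_id")
        assert report.loc[target, "max_abs_pc_z"] > 3
        assert not report.loc[target, "outlier"]

    def test_small_groups_skipped_with_warning(self):
        cfg = ca.SimulationConfig(n_control=2, n_case=2, regions=("BA9", "BA17"),
                                  missing_rate=0.0, n_genes=30, seed=4)
        expr, meta, _ = ca.generate_dataset(cfg)
        with pytest.warns(UserWarning, match="skipped"):
            report = ca.detect_outliers(expr, meta)
        assert not report["outlier"].any()


@pytest.fixture(scope="module")
def batch_dataset():
    cfg = ca.SimulationConfig(
        n_control=8, n_case=8, regions=("BA9", "BA7", "BA17"),
        missing_rate=0.0, n_genes=30, gradient_fraction=0.3,
        gradient_effect_sd=0.1, noise_sd=0.1, attenuation=0.5,
        covariate_effects={"batch": 0.5}, seed=4,
    )
    expr, meta, truth = ca.generate_dataset(cfg)
    return cfg, expr, meta, truth


class TestRegression:
    def test_batch_effect_removed_diagnosis_preserved(self, batch_dataset):
        cfg, expr, meta, truth = batch_dataset
        reg = ca.regress_covariates(expr, meta)
        assert set(reg.removed_covariates) == {"age", "sex", "batch"}
        b = meta["batch"].map({"batch1": -0.5, "batch2": 0.5}).to_numpy()
        pre = np.array(
            [np.corrcoef(expr.iloc[i], b)[0, 1] for i in range(expr.shape[0])]
        )
        post = np.array(
            [np.corrcoef(reg.values.iloc[i], b)[0, 1] for i in range(expr.shape[0])]
        )
        # residual correlation is estimation noise (~SE of the batch beta)
        assert np.abs(post).mean() < 0.1
        assert np.abs(post).mean() < 0.25 * np.abs(pre).mean()
        # the regressed diagnosis contrast matches the batch-stratified
        # (de-confounded) contrast, not the raw batch-confounded one
        case = ca.pairwise.is_case(meta["diagnosis"]).to_numpy()
        batch = meta["batch"].to_numpy()
        for i in range(5):
            stratified = np.mean(
                [
                    expr.iloc[i].to_numpy()[case & (batch == b)].mean()
                    - expr.iloc[i].to_numpy()[~case & (batch == b)].mean()
                    for b in np.unique(batch)
                ]
            )
            post_d = reg.values.iloc[i, case].mean() - reg.values.iloc[i, ~case].mean()
            assert post_d == pytest.approx(stratified, abs=0.1)

    def test_zero_nuisance_effects_identity(self):
        # subject_sd kept small: subject-level nuisance covariates (age, sex,
        # batch) are confounded with subject intercepts, so intercept variance
        # leaks into their estimates and bounds how close to the identity the
        # regression can be
        cfg = ca.SimulationConfig(
            n_control=12, n_case=12, regions=("BA9", "BA17"), missing_rate=0.0,
            n_genes=10, noise_sd=0.05, subject_sd=0.05,
            covariate_effects={"batch": 0.0}, seed=6,
        )
        expr, meta, _ = ca.generate_dataset(cfg)
        reg = ca.regress_covariates(expr, meta)
        assert np.abs(reg.values.to_numpy() - expr.to_numpy()).max() < 0.15

    def test_no_nuisance_columns_is_noop(self):
        cfg = ca.SimulationConfig(n_control=4, n_case=4, regions=("BA9", "BA17"),
                                  missing_rate=0.0, n_genes=8, seed=2)
        expr, meta, _ = ca.generate_dataset(cfg)
        meta = meta[["sample_id", "subject_id", "region", "diagnosis"]]
        reg = ca.regress_covariates(expr, meta)
        assert reg.values.equals(expr)
        assert reg.removed_covariates == ()

    def test_collinear_covariates_named(self):
        cfg = ca.SimulationConfig(n_control=4, n_case=4, regions=("BA9", "BA17"),
                                  missing_rate=0.0, n_genes=5, seed=2)
        expr, meta, _ = ca.generate_dataset(cfg)
        meta = meta.copy()
        meta["age2"] = meta["age"]  # exact duplicate column
        with pytest.raises(ValueError, match="collinear"):
            ca.regress_covariates(expr, meta)
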