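"""Feature-frame assembly, correlation, scaled PCA, variable clustering and
centroid covariates."""

import numpy as np
import pandas as pd
import pytest

from metagrad.feature_space import (STRUCTURAL_VARIABLES,
                                    FeatureTable, assemble_features,
                                    centroid_covariates, cluster_variables,
                                    correlation_matrix, feature_vocabulary,
                                    pca_variables)
from metagrad.radiomics import texture_feature_names


def _records(n_studies=4, seed=0):
    rng = np.random.default_rng(seed)
    vocab = feature_vocabulary()
    structural, radiomic, clinical = {}, {}, {}
    for i in range(n_studies):
        sid = f"s{i}"
        structural[sid] = {v: float(rng.normal()) for v in STRUCTURAL_VARIABLES}
        radiomic[sid] = {v: float(rng.normal()) for v in texture_feature_names()}
        clinical[sid] = {"grade": ["low", "intermediate", "high"][i % 3],
                         "volume": float(rng.uniform(5, 100)),
                         "subtype": ["STS", "bone", "cartilage"][i % 3],
                         "age": float(rng.uniform(18, 85)),
                         "sex": "MF"[i % 2],
                         "SUVmax": float(rng.uniform(2, 15)),
                         "SUVmean": float(rng.uniform(1, 8)),
                         "TLG": float(rng.uniform(10, 500))}
    return structural, radiomic, clinical


class TestAssembly:
    def test_full_vocabulary_is_44_variables(self):
        table = assemble_features(*_records())
        assert table.n_variables == 44
        assert table.frame("clinical").shape[1] == 8
        assert table.frame("structural").shape[1] == 8
        assert table.frame("textural").shape[1] == 28

    def test_structural_frame_enumeration(self):
        assert STRUCTURAL_VARIABLES == ["H0", "H1", "g.0.25", "g.0.95",
                                        "g.n.0.25", "g.n.0.95", "g.w.0.25", "g.w.0.95"]

    def test_omitting_clinical_leaves_nan_but_full_vocabulary(self):
        structural, radiomic, _ = _records()
        table = assemble_features(structural, radiomic, None)
        assert table.n_variables == 44
        assert table.data["age"].isna().all()
        assert table.data[STRUCTURAL_VARIABLES].notna().all().all()

    def test_assembly_is_lossless(self):
        structural, radiomic, clinical = _records()
        table = assemble_features(structural, radiomic, clinical)
        for sid in structural:
            for k, v in structural[sid].items():
                assert table.data.loc[sid, k] == v
            for k, v in radiomic[sid].items():
                assert table.data.loc[sid, k] == v

    def test_unknown_variable_rejected(self):
        structural, radiomic, clinical = _records()
        radiomic["s0"]["bogus.FEATURE"] = 1.0
        with pytest.raises(ValueError, match="unknown"):
            assemble_features(structural, radiomic, clinical)

    def test_duplicate_study_ids_rejected(self):
        df = pd.DataFrame({"H0": [1.0, 2.0]}, index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(df, {"H0": "structural"})


class TestCorrelation:
    def test_self_correlation_is_one(self):
        table = assemble_features(*_records(n_studies=6))
        corr = correlation_matrix(table)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_anticorrelated_pair(self):
        x = np.random.default_rng(0).normal(size=30)
        df = pd.DataFrame({"a": x, "b": -x, "c": np.random.default_rng(1).normal(size=30)})
        corr = correlation_matrix(df)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
        assert abs(correlation_matrix(df).loc["x", "y"]) < 0.1

    def test_constant_variable_excluded(self):
        df = pd.DataFrame({"a": np.arange(5.0), "flat": np.ones(5)})
        corr = correlation_matrix(df)
        assert "flat" not in corr.columns


class TestPca:
    def test_eigenvalue_sum_matches_variable_count(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(60, 10)),
                          columns=[f"v{i}" for i in range(10)])
        model = pca_variables(df, var_frac=1.0)
        assert np.all(np.diff(model.explained_fractions) <= 1e-12)
        # z-scored PCA reproduces the correlation eigenstructure: eigenvalues sum to p
        from sklearn.decomposition import PCA
        z = (df - df.mean()) / df.std(ddof=1)
        assert PCA().fit(z).explained_variance_.sum() == pytest.approx(10.0, abs=1e-6)

    def test_dominant_factor_concentrates_variance(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=200)
        df = pd.DataFrame({f"v{i}": f + 0.05 * rng.normal(size=200) for i in range(6)})
        model = pca_variables(df)
        assert model.explained_fractions[0] > 0.9

    def test_isotropic_data_spreads_variance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(4000, 5)), columns=list("abcde"))
        model = pca_variables(df, var_frac=1.0)
        np.testing.assert_allclose(model.explained_fractions, 0.2, atol=0.03)

    def test_retention_rule(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=300)
        df = pd.DataFrame({"a": f, "b": f + 1e-6 * rng.normal(size=300),
                           "c": rng.normal(size=300)})
        model = pca_variables(df, var_frac=0.95)
        assert model.n_components < 3


class TestClustering:
    def test_duplicated_variables_share_cluster(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "a_copy": x.copy(),
                           "b": rng.normal(size=50), "c": rng.normal(size=50)})
        model = cluster_variables(pca_variables(df, var_frac=1.0), k=2, seed=0)
        assert model.assignment["a"] == model.assignment["a_copy"]

    def test_k_equals_p_gives_singletons(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        model = cluster_variables(pca_variables(df, var_frac=1.0), k=4, seed=0)
        assert model.assignment.nunique() == 4

    def test_k_larger_than_p_rejected(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_variables(pca_variables(df, var_frac=1.0), k=5)

    def test_orthogonal_blocks_recovered(self):
        rng = np.random.default_rng(12)
        f1, f2 = rng.normal(size=200), rng.normal(size=200)
        cols = {f"p{i}": f1 + 0.1 * rng.normal(size=200) for i in range(4)}
        cols.update({f"q{i}": f2 + 0.1 * rng.normal(size=200) for i in range(4)})
        df = pd.DataFrame(cols)
        model = cluster_variables(pca_variables(df, var_frac=1.0), k=2, seed=0)
        a = model.assignment
        assert a[[f"p{i}" for i in range(4)]].nunique() == 1
        assert a[[f"q{i}" for i in range(4)]].nunique() == 1
        assert a["p0"] != a["q0"]


class TestCentroidCovariates:
    def test_singleton_cluster_is_zscored_variable(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"a": rng.normal(2, 3, 40), "b": rng.normal(size=40)})
        assignment = pd.Series({"a": 0, "b": 1})
        cents = centroid_covariates(df, assignment)
        z = (df["a"] - df["a"].mean()) / df["a"].std(ddof=1)
        np.testing.assert_allclose(cents["C1"], z, atol=1e-12)

    def test_identical_variables_average_to_one_copy(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x.copy()})
        cents = centroid_covariates(df, pd.Series({"a": 0, "b": 0}))
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(cents["C1"], z, atol=1e-12)

    def test_single_cluster_score_tracks_first_pc(self):
        rng = np.random.default_rng(15)
        f = rng.normal(size=150)
        df = pd.DataFrame({f"v{i}": f + 0.2 * rng.normal(size=150) for i in range(5)})
        cents = centroid_covariates(df, pd.Series({f"v{i}": 0 for i in range(5)}))
        z = (df - df.mean()) / df.std(ddof=1)
        from sklearn.decomposition import PCA
        pc1 = PCA(n_components=1).fit_transform(z).ravel()
        r = np.corrcoef(cents["C1"], pc1)[0, 1]
        assert abs(r) > 0.99

    def test_cluster_relabeling_invariance(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        a1 = pd.Series({"a": 0, "b": 0, "c": 1, "d": 1})
        a2 = pd.Series({"a": 1, "b": 1, "c": 0, "d": 0})
        c1 = centroid_covariates(df, a1)
        c2 = centroid_covariates(df, a2)
        np.testing.assert_allclose(c1["C1"], c2["C2"], atol=1e-12)
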