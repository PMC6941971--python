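"""Feature extraction, signature regression, Cox feature, consistency."""

import numpy as np
import pandas as pd
import pytest

from ttrans.datamodel import SignatureSet, SurvivalTable, ValidationError
from ttrans.signatures import (
    cox_risk_feature,
    extract_features,
    fit_signatures,
    project_signatures,
    signature_consistency,
    standardize_factors,
    supervised_features,
)
from ttrans.synthetic import simulate_survival


def _standardize_oracle(Y):
    out = np.empty_like(Y, dtype=float)
    for j in range(Y.shape[0]):
        row = Y[j].astype(float)
        vals = row[np.isfinite(row)]
        centred = row - vals.mean()
        if not set(np.unique(vals)) <= {0.0, 1.0}:
            centred = centred / vals.std()
        centred[~np.isfinite(row)] = 0.0
        out[j] = centred
    return out


class TestExtractFeatures:
    def test_exact_rank_one_input_reconstructs(self, rng):
        h = rng.normal(size=(5, 1))
        f = rng.normal(size=(1, 12))
        Y = h @ f
        fd = extract_features(Y, 1)
        Ys = _standardize_oracle(Y)
        assert np.linalg.norm(Ys - fd.H @ fd.F) < 1e-8

    def test_full_rank_reconstruction_is_exact(self, rng):
        Y = rng.normal(size=(4, 9))
        fd = extract_features(Y, 4)
        assert np.linalg.norm(_standardize_oracle(Y) - fd.H @ fd.F) < 1e-8

    def test_matches_eigendecomposition_oracle(self, rng):
        Y = rng.normal(size=(6, 10))
        fd = extract_features(Y, 2)
        Ys = _standardize_oracle(Y)
        # oracle: top-2 eigenvectors of the patient Gram matrix Ys' Ys
        evals, evecs = np.linalg.eigh(Ys.T @ Ys)
        V = evecs[:, ::-1][:, :2]
        approx_oracle = Ys @ V @ V.T
        np.testing.assert_allclose(fd.H @ fd.F, approx_oracle, atol=1e-8)

    def test_f_rows_unit_norm_and_orientation(self, rng):
        Y = rng.normal(size=(6, 15))
        fd = extract_features(Y, 3)
        np.testing.assert_allclose(np.linalg.norm(fd.F, axis=1), 1.0,
                                   atol=1e-10)
        for j in range(3):
            assert fd.H[np.abs(fd.H[:, j]).argmax(), j] > 0

    def test_k_beyond_rank_errors(self, rng):
        h = rng.normal(size=(4, 1))
        Y = h @ rng.normal(size=(1, 8))  # rank 1 after standardization
        with pytest.raises(ValidationError, match="rank"):
            extract_features(Y, 3)

    def test_constant_factor_row_errors(self):
        Y = np.vstack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValidationError, match="constant"):
            standardize_factors(Y)


class TestSupervisedFeatures:
    def test_identity_loadings_return_y(self, rng):
        Y = rng.normal(size=(3, 7))
        fd = supervised_features(Y=Y, H=np.eye(3))
        np.testing.assert_allclose(fd.F, Y, atol=1e-12)

    def test_recovers_features_from_well_conditioned_h(self, rng):
        H = rng.normal(size=(6, 2)) + 2 * np.eye(6, 2)
        F_true = rng.normal(size=(2, 20))
        fd = supervised_features(Y=H @ F_true, H=H)
        np.testing.assert_allclose(fd.F, F_true, atol=1e-8)

    def test_single_up_marker_equals_normalized_row(self, rng):
        Z = rng.normal(size=(4, 30))
        fd = supervised_features(
            marker_signatures={"sig": (["g2"], [])}, Z=Z,
            gene_ids=["g1", "g2", "g3", "g4"],
        )
        z = (Z[1] - Z[1].mean()) / Z[1].std()
        np.testing.assert_allclose(fd.F[0], z / np.linalg.norm(z), atol=1e-10)

    def test_rank_deficient_h_errors(self):
        H = np.ones((4, 2))
        with pytest.raises(ValidationError, match="rank"):
            supervised_features(Y=np.zeros((4, 5)), H=H)

    def test_absent_marker_errors_unless_allowed(self, rng):
        Z = rng.normal(size=(2, 10))
        with pytest.raises(ValidationError, match="absent"):
            supervised_features(marker_signatures={"s": (["gX"], ["g1"])},
                                Z=Z, gene_ids=["g1", "g2"])
        fd = supervised_features(marker_signatures={"s": (["gX"], ["g1"])},
                                 Z=Z, gene_ids=["g1", "g2"],
                                 allow_missing=True)
        assert fd.F.shape == (1, 10)


class TestCoxFeature:
    def test_matches_partial_likelihood_grid_search(self):
        # 4 patients, one binary covariate, no censoring, distinct times
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1],
             "x": [1.0, 1.0, 0.0, 0.0]},
            index=["p1", "p2", "p3", "p4"],
        )
        surv = SurvivalTable(table=df)
        lp = cox_risk_feature(surv, penalizer=0.0)
        x = df["x"].to_numpy()
        xs = (x - x.mean()) / x.std()
        order = np.argsort(df["time"].to_numpy())

        def negloglik(beta):
            ll = 0.0
            risk = np.exp(beta * xs)
            for pos, i in enumerate(order):
                ll += beta * xs[i] - np.log(risk[order[pos:]].sum())
            return -ll

        grid = np.linspace(-5, 5, 200001)
        beta_oracle = grid[np.argmin([negloglik(b) for b in grid])]
        lp_oracle = beta_oracle * xs
        lp_oracle = lp_oracle / np.linalg.norm(lp_oracle)
        # linear predictors proportional -> compare after normalization
        np.testing.assert_allclose(lp - lp.mean(),
                                   lp_oracle - lp_oracle.mean(), atol=1e-3)

    def test_null_covariate_gives_small_coefficient(self):
        small = 0
        for seed in range(20):
            surv = simulate_survival(n=200, beta=0.0, censoring_rate=0.2,
                                     seed=seed)
            from lifelines import CoxPHFitter

            cph = CoxPHFitter(penalizer=1e-4)
            cph.fit(surv.table, duration_col="time", event_col="event")
            if abs(float(cph.params_.iloc[0])) < 0.2:
                small += 1
        assert small >= 19  # >= 95% of seeds

    def test_constant_covariate_errors(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4.0], "event": [1, 1, 1, 0],
                           "x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="constant"):
            cox_risk_feature(SurvivalTable(table=df))

    def test_all_censored_errors(self):
        df = pd.DataFrame({"time": [1, 2.0], "event": [0, 0],
                           "x": [0.0, 1.0]})
        with pytest.raises(ValidationError, match="events"):
            cox_risk_feature(SurvivalTable(table=df))


class TestFitSignatures:
    def test_orthonormal_features_simplify_to_projection(self, rng):
        F = np.linalg.qr(rng.normal(size=(10, 3)))[0].T  # 3 orthonormal rows
        Z = rng.normal(size=(6, 10))
        sig = fit_signatures(Z, F)
        np.testing.assert_allclose(sig.B, Z @ F.T, atol=1e-10)

    def test_noise_free_model_recovered_exactly(self, rng):
        B_true = rng.normal(size=(7, 2))
        F = rng.normal(size=(2, 25))
        sig = fit_signatures(B_true @ F, F)
        np.testing.assert_allclose(sig.B, B_true, atol=1e-9)

    def test_matches_pseudo_inverse_oracle(self, rng):
        Z = rng.normal(size=(5, 12))
        F = rng.normal(size=(3, 12))
        sig = fit_signatures(Z, F)
        np.testing.assert_allclose(sig.B, Z @ np.linalg.pinv(F), atol=1e-10)

    def test_residual_orthogonal_to_features(self, rng):
        Z = rng.normal(size=(9, 20))
        F = rng.normal(size=(2, 20))
        sig = fit_signatures(Z, F)
        resid = Z - sig.B @ F
        assert np.abs(resid @ F.T).max() < 1e-8

    def test_scaling_expression_scales_signatures(self, rng):
        Z = rng.normal(size=(6, 14))
        F = rng.normal(size=(2, 14))
        b1 = fit_signatures(Z, F).B
        b3 = fit_signatures(3.0 * Z, F).B
        np.testing.assert_allclose(b3, 3.0 * b1, atol=1e-10)

    def test_singular_gram_matrix_errors(self, rng):
        F = np.vstack([np.ones(8), np.ones(8)])
        with pytest.raises(ValidationError, match="singular"):
            fit_signatures(rng.normal(size=(4, 8)), F)


def _sig(cohort_id, B, genes=None, feats=None):
    p, k = B.shape
    return SignatureSet(
        cohort_id=cohort_id,
        gene_ids=genes or [f"g{i}" for i in range(p)],
        feature_names=feats or [f"feature_{j + 1}" for j in range(k)],
        B=B,
    )


class TestConsistency:
    def test_identical_signatures_fully_consistent(self, rng):
        B = rng.normal(size=(50, 2))
        report = signature_consistency([_sig("a", B), _sig("b", B),
                                        _sig("c", B)])
        np.testing.assert_allclose(report.pairwise["r"], 1.0, atol=1e-12)
        assert report.table["pass"].all()

    def test_independent_signatures_near_zero(self):
        fails = 0
        for seed in range(30):
            g = np.random.default_rng(seed)
            sets = [_sig(c, g.normal(size=(978, 1))) for c in "abc"]
            report = signature_consistency(sets)
            if abs(report.table["mean_r"].iloc[0]) >= 0.1:
                fails += 1
            assert not report.table["pass"].any()
        assert fails == 0

    def test_sign_flip_is_detected_and_recorded(self, rng):
        B = rng.normal(size=(40, 1))
        report = signature_consistency([_sig("a", B), _sig("b", -B)])
        assert report.flips[("b", "feature_1")]
        np.testing.assert_allclose(report.table["mean_r"], 1.0, atol=1e-12)

    def test_threshold_separates_pass_fail(self, rng):
        base = rng.normal(size=(200, 1))
        noisy = base + 1.2 * rng.normal(size=(200, 1))
        r = float(np.corrcoef(base[:, 0], noisy[:, 0])[0, 1])
        report = signature_consistency([_sig("a", base), _sig("b", noisy)])
        assert report.table["pass"].iloc[0] == (r > 0.4)

    def test_requires_two_cohorts(self, rng):
        with pytest.raises(ValidationError, match="2 cohorts"):
            signature_consistency([_sig("a", rng.normal(size=(5, 1)))])


class TestProjection:
    def test_orthogonal_planted_signatures_align_with_pcs(self, rng):
        # two orthogonal zero-mean signatures with distinct scales
        b1 = 2.0 * np.tile([1.0, -1.0], 50)
        b2 = np.r_[np.tile([1.0, -1.0], 25), np.tile([-1.0, 1.0], 25)]
        B = np.column_stack([b1, b2]) + 0.01 * rng.normal(size=(100, 2))
        coords = project_signatures([_sig("a", B), _sig("b", B)])
        feats = coords["features"].to_numpy()
        # each planted signature loads on one PC almost exclusively
        assert np.abs(feats).max(axis=1).min() > 0.99

    def test_duplicated_feature_is_collinear(self, rng):
        v = rng.normal(size=30)
        w = rng.normal(size=30)
        B = np.column_stack([v, v, w])  # feature_2 duplicates feature_1
        coords = project_signatures([_sig("a", B)] * 2)
        f = coords["features"].to_numpy()
        assert abs(abs(f[0] @ f[1]) - 1.0) < 1e-8

    def test_single_feature_errors(self, rng):
        with pytest.raises(ValidationError, match="2 feature"):
            project_signatures([_sig("a", rng.normal(size=(10, 1)))][:1],
                               features=["feature_1"])


class TestRecovery:
    def test_planted_signatures_recovered(self, small_cohorts):
        cohorts, truth = small_cohorts
        for c in cohorts:
            fd = extract_features(c.Y, 2)
            sig = fit_signatures(c.Z, fd, gene_ids=c.gene_ids)
            for j in range(2):
                r = np.corrcoef(sig.B[:, j], truth.B_true[:, j])[0, 1]
                assert r > 0.9

    def test_label_shuffle_destroys_consistency(self, small_cohorts):
        # shuffling Y's patients relative to Z breaks the disease-expression
        # link; without the sign-alignment convention (a selection effect
        # under the null) the control consistency is symmetric about zero
        cohorts, _ = small_cohorts
        means = []
        for shuffle_seed in range(15):
            rng = np.random.default_rng(shuffle_seed)
            sets = []
            for c in cohorts:
                perm = rng.permutation(c.Y.shape[1])
                fd = extract_features(c.Y[:, perm], 2)
                sets.append(fit_signatures(c.Z, fd, cohort_id=c.cohort_id,
                                           gene_ids=c.gene_ids))
            report = signature_consistency(sets, align_signs=False)
            means.extend(report.table["mean_r"].tolist())
        assert abs(np.mean(means)) < 0.1
        # a shuffled control only rarely clears the robustness threshold
        assert np.mean(np.asarray(means) > 0.4) < 0.2
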