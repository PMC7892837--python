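"""OPLS-DA core: standardization, orthogonality, R2Y/Q2, sign stability."""

import numpy as np
import pytest

import uromet as u
from uromet.data import ValidationError
from uromet.oplsda import fit_oplsda, q2_cv, standardize

from conftest import lognormal_matrix, toy_groups, toy_sample_ids


def separable_cohort(rng, n_cases=15, n_controls=39, p=3, fold=10.0):
    raw = lognormal_matrix(rng, n_cases + n_controls, p)
    raw[:n_cases] *= fold
    return raw


class TestStandardize:
    def test_fit_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        raw = lognormal_matrix(rng, 30, 4)
        std = standardize(raw, list("abcd"))
        np.testing.assert_allclose(std.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(std.values.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_transform_with_own_stats_is_idempotent(self):
        rng = np.random.default_rng(1)
        raw = lognormal_matrix(rng, 20, 3)
        std = standardize(raw, list("abc"))
        again = std.transform(raw, list("abc"))
        np.testing.assert_allclose(again, std.values, atol=1e-12)

    def test_constant_column_error_names_metabolite(self):
        raw = np.ones((10, 2))
        raw[:, 0] = np.arange(10)
        with pytest.raises(ValidationError, match="flatline"):
            standardize(raw, ["ok", "flatline"])

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        std = standardize(lognormal_matrix(rng, 10, 2), ["a", "b"])
        with pytest.raises(ValidationError, match="mismatch"):
            std.transform(np.ones((3, 2)), ["b", "a"])


class TestFitOplsda:
    def test_scores_orthogonal_to_ortho_scores(self):
        rng = np.random.default_rng(3)
        raw = separable_cohort(rng)
        std = standardize(raw, ["a", "b", "c"])
        y = u.encode_labels(toy_groups())
        model = fit_oplsda(std, y, k_ortho=1)
        for to in model.ortho_scores:
            assert abs(model.scores @ to) < 1e-8 * np.linalg.norm(
                model.scores
            ) * np.linalg.norm(to)

    def test_coefficients_reproduce_scores(self):
        rng = np.random.default_rng(4)
        raw = separable_cohort(rng, p=5)
        std = standardize(raw, list("abcde"))
        y = u.encode_labels(toy_groups())
        model = fit_oplsda(std, y, k_ortho=2)
        np.testing.assert_allclose(
            std.values @ model.coefficients, model.scores, atol=1e-10
        )

    def test_separable_cohort_scores_ordered(self):
        """Every case predictive score exceeds every control score when the
        planted separation is overwhelming."""
        rng = np.random.default_rng(5)
        raw = separable_cohort(rng, fold=50.0)
        std = standardize(raw, ["a", "b", "c"])
        y = u.encode_labels(toy_groups())
        model = fit_oplsda(std, y, k_ortho=1)
        assert model.scores[:15].min() > model.scores[15:].max()

    def test_noise_free_single_marker_r2y_one(self):
        y = u.encode_labels(toy_groups(5, 5))
        X = y.reshape(-1, 1).copy()
        model = fit_oplsda(X, y, k_ortho=0)
        assert model.r2y == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_cases_positive(self):
        rng = np.random.default_rng(6)
        raw = separable_cohort(rng)
        std = standardize(raw, ["a", "b", "c"])
        y = u.encode_labels(toy_groups())
        model = fit_oplsda(std, y, k_ortho=1)
        assert model.response_loading > 0
        assert model.scores[:15].mean() > 0

    def test_bit_stable_across_repeated_fits(self):
        rng = np.random.default_rng(7)
        raw = separable_cohort(rng)
        std = standardize(raw, ["a", "b", "c"])
        y = u.encode_labels(toy_groups())
        a = fit_oplsda(std, y, k_ortho=1)
        b = fit_oplsda(std, y, k_ortho=1)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.r2y == b.r2y

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValidationError):
            fit_oplsda(np.ones((4, 2)), np.zeros(4), k_ortho=0)

    def test_excessive_k_ortho_rejected(self):
        rng = np.random.default_rng(8)
        y = u.encode_labels(toy_groups(3, 3))
        with pytest.raises(ValidationError):
            fit_oplsda(lognormal_matrix(rng, 6, 2), y, k_ortho=5)


class TestQ2:
    def test_q2_not_above_r2y_on_fixtures(self):
        """Cross-validated predictive ability cannot beat the resubstitution
        fit: Q2 <= R2Y on signal, weak-signal and null cohorts."""
        rng = np.random.default_rng(9)
        for fold in (10.0, 2.0, 1.0):
            raw = separable_cohort(rng, fold=fold)
            ids = ["a", "b", "c"]
            sids = toy_sample_ids(54)
            groups = toy_groups()
            model = fit_oplsda(standardize(raw, ids), u.encode_labels(groups), 1)
            q2 = q2_cv(raw, groups, sids, ids, k_ortho=1, folds=7, seed=0)
            assert q2 <= model.r2y + 1e-12

    def test_null_labels_give_nonpositive_median_q2(self):
        """Q2 penalizes overfitting: with labels independent of X the median
        over 200 simulated cohorts is <= 0."""
        rng = np.random.default_rng(10)
        q2s = []
        for rep in range(200):
            raw = lognormal_matrix(rng, 54, 3)
            q2s.append(
                q2_cv(raw, toy_groups(), toy_sample_ids(54), ["a", "b", "c"],
                      k_ortho=1, folds=7, seed=rep)
            )
        assert np.median(q2s) <= 0

    def test_strong_signal_q2(self):
        """At the published folds (12/11/10) and sigma_log 0.5, the
        three-marker panel reaches median Q2 >= 0.5 across cohort draws,
        with R2Y above Q2 on every draw."""
        markers = tuple(
            m for m in u.DISEASE_MARKERS if m.name in u.THREE_MARKER_PANEL
        )
        q2s = []
        for seed in range(1, 7):
            cfg = u.CohortConfig(
                n_metabolites=60, planted_markers=markers,
                n_exogenous=0, n_unknown_structure=0, seed=seed,
            )
            c = u.generate_cohort(cfg)
            norm = u.normalize_osmolality(c.matrix, c.osmolality)
            panel = c.truth.panel_ids(u.THREE_MARKER_PANEL)
            model = u.fit_marker_model(norm, c.metadata, panel, seed=3)
            assert model.r2y >= model.q2
            q2s.append(model.q2)
        assert np.median(q2s) >= 0.5

    def test_fold_without_both_classes_rejected(self):
        # a single case must land in some test fold, leaving its training
        # fold one-class
        rng = np.random.default_rng(11)
        raw = lognormal_matrix(rng, 8, 2)
        groups = ["case"] * 1 + ["control"] * 7
        with pytest.raises(ValidationError, match="class"):
            q2_cv(raw, groups, toy_sample_ids(8), ["a", "b"], k_ortho=0, folds=5, seed=0)


class TestPermutationTest:
    def test_self_permutation_bound(self):
        """Including the identity among permutations forces at least one
        permuted Q2 >= observed, so p > 1/(n+1) whenever it occurs; the
        smoothed estimator already guarantees p >= 1/(n+1) by construction."""
        rng = np.random.default_rng(12)
        raw = separable_cohort(rng)
        res = u.permutation_test(
            raw, toy_groups(), toy_sample_ids(54), ["a", "b", "c"],
            n_perm=30, seed=0,
        )
        assert res.p_q2 >= 1 / 31
        assert res.p_q2 <= 1.0
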