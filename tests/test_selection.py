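"""Predictive-value scoring and pathway-constrained combination search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uromet as u
from uromet.data import ValidationError

from conftest import lognormal_matrix


def build_cohort(values, n_cases, sub_pathways=None, normalized=True):
    """Wrap a value matrix into (matrix, metadata, annotations)."""
    n, p = values.shape
    ids = [f"m{j:02d}" for j in range(p)]
    matrix = u.IntensityMatrix([f"s{i:03d}" for i in range(n)], ids, values, normalized)
    meta = [
        u.SampleMetadata(f"s{i:03d}", f"s{i:03d}", "case", 2.0, "male", stage="4",
                         residual_tumour="positive")
        if i < n_cases
        else u.SampleMetadata(f"s{i:03d}", f"s{i:03d}", "control", 2.0, "male")
        for i in range(n)
    ]
    sub_pathways = sub_pathways or [f"pw{j}" for j in range(p)]
    annos = [
        u.MetaboliteAnnotation(mid, mid, "Amino acid", pw, False, True)
        for mid, pw in zip(ids, sub_pathways)
    ]
    return matrix, meta, annos


class TestPredictiveValue:
    def test_three_marker_constants_sum(self):
        """The published three constants applied to unit standardized
        intensities give 0.52 + 0.39 + 0.23 = 1.14."""
        assert u.predictive_value([0.52, 0.39, 0.23], [1, 1, 1]) == pytest.approx(1.14)

    def test_two_marker_constants(self):
        """The established-marker pair's constants at z = −1 give −0.91."""
        assert u.predictive_value([0.52, 0.39], [-1, -1]) == pytest.approx(-0.91)

    def test_zero_intensities_boundary_negative(self):
        v = u.predictive_value([0.52, 0.39, 0.23], [0, 0, 0])
        assert v == 0.0
        rec = u.ScoreRecord("s1", v, "positive" if v > 0 else "negative")
        assert rec.call == "negative"  # cutoff 0 itself is not high-risk

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            u.predictive_value([0.5, 0.4], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
        st.floats(-3, 3),
    )
    def test_linearity_in_intensities(self, coeffs, scale):
        z = np.arange(1.0, len(coeffs) + 1.0)
        base = u.predictive_value(coeffs, z)
        scaled = u.predictive_value(coeffs, scale * z)
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-9)


class TestScoreSamples:
    def test_fitting_cohort_separable_all_cases_positive(self):
        rng = np.random.default_rng(0)
        values = lognormal_matrix(rng, 54, 3)
        values[:15] *= 30.0
        matrix, meta, _ = build_cohort(values, 15)
        model = u.fit_marker_model(matrix, meta, ["m00", "m01", "m02"], seed=1)
        records = u.score_samples(model, matrix)
        calls = {r.sample_id: r.call for r in records}
        assert all(calls[f"s{i:03d}"] == "positive" for i in range(15))

    def test_duplicated_row_scores_identically(self):
        rng = np.random.default_rng(1)
        values = lognormal_matrix(rng, 20, 3)
        values[:6] *= 20.0
        matrix, meta, _ = build_cohort(values, 6)
        model = u.fit_marker_model(matrix, meta, ["m00", "m01", "m02"], folds=3, seed=1)
        dup = np.vstack([values, values[7]])
        dup_matrix = u.IntensityMatrix(
            matrix.sample_ids + ["copy"], matrix.metabolite_ids, dup, True
        )
        records = {r.sample_id: r for r in u.score_samples(model, dup_matrix)}
        assert records["copy"].predictive_value == records["s007"].predictive_value

    def test_synthetic_cohort_all_cases_detected(
        self, three_marker_cohort, three_marker_normalized
    ):
        """At the published folds the fitted panel calls 15/15 cases
        positive on the pretreatment cohort."""
        c = three_marker_cohort
        panel = c.truth.panel_ids(u.THREE_MARKER_PANEL)
        model = u.fit_marker_model(three_marker_normalized, c.metadata, panel, seed=3)
        cases = [m.sample_id for m in c.metadata if m.group == "case"]
        records = u.score_samples(model, three_marker_normalized, sample_ids=cases)
        assert sum(r.call == "positive" for r in records) == 15

    def test_missing_marker_rejected(self):
        rng = np.random.default_rng(2)
        values = lognormal_matrix(rng, 20, 3)
        values[:6] *= 20.0
        matrix, meta, _ = build_cohort(values, 6)
        model = u.fit_marker_model(matrix, meta, ["m00", "m01"], folds=3, seed=1)
        small = matrix.subset(metabolite_ids=["m00", "m02"])
        with pytest.raises(ValidationError):
            u.score_samples(model, small)


class TestEvaluateCombination:
    def test_perfect_combination_no_false_negatives(self):
        rng = np.random.default_rng(3)
        values = lognormal_matrix(rng, 54, 4)
        values[:15, :3] *= 30.0
        matrix, meta, annos = build_cohort(values, 15)
        combo = u.evaluate_combination(["m00", "m01", "m02"], matrix, meta, annos, seed=1)
        assert combo.fn_count == 0
        assert combo.q2 > 0.5

    def test_null_combination_weak(self):
        """Markers carrying no separation miss about half the cases and
        cross-validate at or below zero."""
        rng = np.random.default_rng(4)
        values = lognormal_matrix(rng, 54, 3)
        matrix, meta, annos = build_cohort(values, 15)
        combo = u.evaluate_combination(["m00", "m01", "m02"], matrix, meta, annos, seed=1)
        assert combo.q2 <= 0.1
        assert 3 <= combo.fn_count <= 12

    def test_cross_pathway_beats_same_pathway(self):
        """With strongly correlated within-pathway noise, a cross-pathway
        pair recovers more cases and a higher Q2 than a same-pathway pair of
        equal marginal effect."""
        rng = np.random.default_rng(5)
        n, n_cases = 54, 15
        shared_a = rng.normal(0, 0.45, n)  # pathway A latent factor
        eps = lambda: rng.normal(0, 0.1, n)
        fold = np.log(4.0)
        case = np.zeros(n)
        case[:n_cases] = 1.0
        # m00, m01 share pathway A noise; m02 carries independent noise.
        cols = [
            np.exp(3 + shared_a + eps() + fold * case),
            np.exp(3 + shared_a + eps() + fold * case),
            np.exp(3 + rng.normal(0, 0.45, n) + eps() + fold * case),
        ]
        values = np.column_stack(cols)
        matrix, meta, annos = build_cohort(
            values, n_cases, sub_pathways=["pwA", "pwA", "pwB"]
        )
        same = u.evaluate_combination(["m00", "m01"], matrix, meta, annos, seed=1)
        cross = u.evaluate_combination(["m00", "m02"], matrix, meta, annos, seed=1)
        assert cross.fn_count <= same.fn_count
        assert cross.q2 > same.q2


class TestSearchCombinations:
    def test_exhaustive_search_matches_brute_force_oracle(self):
        """Independent oracle: evaluate all C(6,3)=20 subsets directly
        through the model layer and sort; the search must agree."""
        from itertools import combinations as it_combinations

        rng = np.random.default_rng(6)
        values = lognormal_matrix(rng, 40, 6)
        values[:12, 0] *= 8.0
        values[:12, 2] *= 5.0
        values[:12, 4] *= 3.0
        matrix, meta, annos = build_cohort(values, 12)
        ids = matrix.metabolite_ids

        oracle = []
        for subset in it_combinations(sorted(ids), 3):
            model = u.fit_marker_model(matrix, meta, list(subset), seed=1)
            cases = [m.sample_id for m in meta if m.group == "case"]
            recs = u.score_samples(model, matrix, sample_ids=cases)
            fn = sum(r.call == "negative" for r in recs)
            oracle.append((fn, -model.q2, -model.r2y, subset))
        oracle.sort()

        found = u.search_combinations(
            ids, matrix, meta, annos, size=3, pathway_constraint=False, seed=1
        )
        assert [c.marker_ids for c in found] == [o[3] for o in oracle]
        assert len(found) == 20

    def test_pathway_constraint_enforced(self, three_marker_cohort, three_marker_normalized):
        """On the synthetic cohort the top combination draws one marker from
        each of three distinct sub-pathways."""
        c = three_marker_cohort
        candidates = list(c.truth.marker_folds)
        found = u.search_combinations(
            candidates, three_marker_normalized, c.metadata, c.annotations,
            size=3, pathway_constraint=True, seed=1,
        )
        top = found[0]
        assert len(set(top.sub_pathways)) == 3
        for combo in found:
            assert len(set(combo.sub_pathways)) == 3

    def test_size_one_reduces_to_per_marker_evaluation(self):
        rng = np.random.default_rng(7)
        values = lognormal_matrix(rng, 30, 4)
        values[:10, 1] *= 10.0
        matrix, meta, annos = build_cohort(values, 10)
        found = u.search_combinations(
            matrix.metabolite_ids, matrix, meta, annos, size=1,
            pathway_constraint=False, seed=1,
        )
        singles = sorted(
            (
                u.evaluate_combination([mid], matrix, meta, annos, seed=1)
                for mid in matrix.metabolite_ids
            ),
            key=lambda c: c.sort_key,
        )
        assert [c.marker_ids for c in found] == [c.marker_ids for c in singles]

    def test_exclude_ids_removes_known_markers(self):
        rng = np.random.default_rng(8)
        values = lognormal_matrix(rng, 30, 5)
        values[:10] *= 6.0
        matrix, meta, annos = build_cohort(values, 10)
        found = u.search_combinations(
            matrix.metabolite_ids, matrix, meta, annos, size=2,
            pathway_constraint=False, exclude_ids=["m00"], seed=1,
        )
        assert all("m00" not in c.marker_ids for c in found)

    def test_unsatisfiable_constraint_rejected(self):
        rng = np.random.default_rng(9)
        values = lognormal_matrix(rng, 20, 3)
        matrix, meta, annos = build_cohort(values, 6, sub_pathways=["pw", "pw", "pw"])
        with pytest.raises(ValidationError, match="constraint"):
            u.search_combinations(
                matrix.metabolite_ids, matrix, meta, annos, size=2,
                pathway_constraint=True, seed=1,
            )

    def test_deterministic_ranking(self, three_marker_cohort, three_marker_normalized):
        c = three_marker_cohort
        candidates = list(c.truth.marker_folds)
        kwargs = dict(size=3, pathway_constraint=True, seed=1)
        a = u.search_combinations(
            candidates, three_marker_normalized, c.metadata, c.annotations, **kwargs
        )
        b = u.search_combinations(
            candidates, three_marker_normalized, c.metadata, c.annotations, **kwargs
        )
        assert a == b
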