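"""The synthetic-survey generator and ICAR sampling."""

import numpy as np
import pandas as pd
import pytest

import morbmap as m
from morbmap.outcomes import encode_outcomes


class TestSampleICAR:
    def test_zero_variance_gives_zero_vector(self, egypt, rng):
        assert np.array_equal(m.sample_icar(egypt, 0.0, rng), np.zeros(27))

    def test_draws_sum_to_zero(self, egypt, rng):
        for _ in range(20):
            x = m.sample_icar(egypt, 0.7, rng)
            assert abs(x.sum()) < 1e-8

    def test_covariance_matches_pseudo_inverse(self, path3, rng):
        """Empirical covariance over 10,000 draws matches pinv(Q) (the ICAR
        covariance on the constant-orthogonal subspace) within MC error."""
        Q = m.build_icar_precision(path3).Q
        target = np.linalg.pinv(Q)
        draws = np.array([m.sample_icar(path3, 1.0, rng) for _ in range(10_000)])
        emp = np.cov(draws.T, bias=True)
        # MC error on a covariance entry of magnitude ~0.5 at n=1e4 is ~0.01
        assert np.abs(emp - target).max() < 0.05

    def test_reflection_invariance_on_path(self, path3, rng):
        """The path graph's automorphism (node reflection) leaves the draw
        distribution unchanged: reflected draws have the same covariance."""
        draws = np.array([m.sample_icar(path3, 1.0, rng) for _ in range(10_000)])
        emp = np.cov(draws.T, bias=True)
        refl = emp[::-1, ::-1]
        assert np.abs(emp - refl).max() < 0.05

    def test_disconnected_requires_policy(self, rng):
        g = m.AdjacencyGraph.from_edges([1, 2, 3, 4], [(1, 2), (3, 4)])
        with pytest.raises(ValueError, match="disconnected"):
            m.sample_icar(g, 1.0, rng)
        x = m.sample_icar(g, 1.0, rng, disconnected="centre_components")
        assert abs(x[:2].sum()) < 1e-8 and abs(x[2:].sum()) < 1e-8

    def test_negative_variance_rejected(self, egypt, rng):
        with pytest.raises(ValueError):
            m.sample_icar(egypt, -1.0, rng)


class TestGenerateSurvey:
    def test_symmetric_null_frequencies(self):
        """All betas 0, no spatial effects: each of the 8 categories has
        probability 1/8; empirical frequencies within 3 MC standard errors."""
        truth = m.two_binary_truth(seed=3, n_children=80_000,
                                   spatial_var=0.0, unstructured_var=0.0)
        truth.betas = {k: np.zeros(3) for k in range(1, 8)}
        survey = m.generate_survey(truth)
        freq = np.bincount(survey.records["category"], minlength=8) / 80_000
        mcse = np.sqrt(0.125 * 0.875 / 80_000)
        assert np.abs(freq - 0.125).max() < 3 * mcse

    def test_single_intercept_closed_form(self):
        """Intercept of category 7 at +2, all else 0: P(k=7) = e^2/(7+e^2)."""
        truth = m.two_binary_truth(seed=4, n_children=80_000,
                                   spatial_var=0.0, unstructured_var=0.0)
        truth.betas = {k: np.zeros(3) for k in range(1, 8)}
        truth.betas[7][0] = 2.0
        survey = m.generate_survey(truth)
        p7 = np.e**2 / (7 + np.e**2)
        freq = (survey.records["category"] == 7).mean()
        mcse = np.sqrt(p7 * (1 - p7) / 80_000)
        assert abs(freq - p7) < 3 * mcse

    def test_determinism(self, tmp_path):
        truth = m.two_binary_truth(seed=9, n_children=500)
        s1 = m.generate_survey(truth)
        s2 = m.generate_survey(m.two_binary_truth(seed=9, n_children=500))
        pd.testing.assert_frame_equal(s1.records, s2.records)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        m.write_survey(s1, p1)
        m.write_survey(s2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_flags_reencode_to_category(self, small_survey):
        """Back-filled illness flags round-trip through outcome encoding."""
        r = small_survey.records
        ks = encode_outcomes(r["diarrhoea"], r["fever"], r["cough"])
        assert np.array_equal(ks, r["category"].to_numpy())

    def test_theta_true_sums_to_zero(self, small_survey):
        assert np.abs(small_survey.theta_true.sum(axis=1)).max() < 1e-8

    def test_regions_exist_in_graph(self, small_survey, egypt):
        assert set(small_survey.records["region_id"]).issubset(egypt.region_ids)

    def test_written_survey_readable_by_ingest(self, small_survey, tmp_path, egypt):
        p = tmp_path / "synth.csv"
        m.write_survey(small_survey, p)
        records, report = m.read_survey(p, graph=egypt)
        assert report.rows_flagged == 0
        assert len(records) == len(small_survey.records)
        assert (p.with_suffix(".truth.yaml")).exists()

    def test_invalid_truth_rejected(self, egypt):
        with pytest.raises(ValueError, match="sum to"):
            m.CategoricalCovariate("x", ("a", "b"), (0.6, 0.5))
        with pytest.raises(ValueError, match="every category"):
            m.TruthConfig(
                n_children=10,
                betas={1: np.zeros(3)},
                covariates=[m.CategoricalCovariate("x", ("a", "b"), (0.5, 0.5))],
                graph=egypt,
            )
        with pytest.raises(ValueError, match="match the design"):
            m.TruthConfig(
                n_children=10,
                betas={k: np.zeros(5) for k in range(1, 8)},
                covariates=[m.CategoricalCovariate("x", ("a", "b"), (0.5, 0.5))],
                graph=egypt,
            )

    def test_edhs_like_profile_shape(self):
        truth = m.edhs_like_truth(seed=1, n_children=2000)
        survey = m.generate_survey(truth)
        r = survey.records
        assert len(r) == 2000
        assert {"child_age_group", "wealth_quintile", "household_size"} <= set(r.columns)
        # healthy children dominate, as in a real morbidity survey
        assert (r["category"] == 0).mean() > 0.5
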