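"""Spline bases, penalties and the fixed-effect design builder."""

import numpy as np
import pandas as pd
import pytest

import morbmap as m


def cox_de_boor(x, t, i, k):
    """Independent recursive B-spline evaluation (textbook recursion)."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, t, i + 1, k - 1)
    return left + right


class TestSplineBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(0, 60, size=500)
        basis = m.build_spline_basis(x, n_interior_knots=20, degree=3)
        assert np.abs(basis.B.sum(axis=1) - 1).max() <= 1e-10

    def test_penalty_rank_m_minus_2(self, rng):
        x = rng.uniform(0, 1, size=200)
        basis = m.build_spline_basis(x, n_interior_knots=6, degree=3)
        assert basis.m == 10
        lam = np.linalg.eigvalsh(basis.K)
        assert int((lam > 1e-9).sum()) == basis.m - 2
        assert lam.min() > -1e-12  # PSD

    def test_matches_cox_de_boor_recursion(self, rng):
        x = rng.uniform(0, 10, size=100)
        basis = m.build_spline_basis(x, n_interior_knots=5, degree=3)
        pts = rng.uniform(1, 9, size=5)  # interior points
        B = m.build_spline_basis(np.concatenate([x, pts]), n_interior_knots=5, degree=3).B
        for r, p in enumerate(pts):
            oracle = [cox_de_boor(p, basis.knots, i, 3) for i in range(basis.m)]
            assert np.abs(B[len(x) + r] - oracle).max() < 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="min == max"):
            m.build_spline_basis(np.full(10, 3.0))
        with pytest.raises(ValueError, match="distinct"):
            m.build_spline_basis(np.array([0.0, 1.0, 2.0, 0.0]), degree=3)


class TestBuildDesign:
    @pytest.fixture()
    def records(self, rng, egypt):
        n = 50
        return pd.DataFrame(
            {
                "sex": rng.choice(["female", "male"], n),
                "wealth": rng.choice(["poorest", "middle", "richest"], n),
                "age": rng.uniform(0, 60, n),
                "region_id": rng.choice(egypt.region_ids, n),
            }
        )

    def test_reference_cell_coding(self, records, egypt):
        d = m.build_design(records, ["sex", "wealth"], egypt)
        # L levels -> L-1 dummies, plus intercept; reference = first sorted level
        assert d.columns == ["intercept", "sex[male]", "wealth[poorest]", "wealth[richest]"]
        assert d.reference_levels == {"sex": "female", "wealth": "middle"}
        # explicit reference level honoured and recorded
        d2 = m.build_design(records, ["wealth"], egypt, references={"wealth": "poorest"})
        assert d2.columns == ["intercept", "wealth[middle]", "wealth[richest]"]

    def test_two_records_differing_only_in_sex(self, egypt):
        df = pd.DataFrame(
            {"sex": ["male", "female"], "region_id": [1, 1]}
        )
        d = m.build_design(df, ["sex"], egypt)
        diff = d.Z[0] - d.Z[1]
        assert np.count_nonzero(diff) == 1
        assert d.columns[np.flatnonzero(diff)[0]] == "sex[male]"

    def test_numeric_terms_enter_linearly(self, records, egypt):
        d = m.build_design(records, ["age"], egypt)
        assert d.columns == ["intercept", "age"]
        assert np.allclose(d.Z[:, 1], records["age"])

    def test_aliased_columns_reported(self, records, egypt):
        records = records.copy()
        records["sex_copy"] = records["sex"]
        with pytest.raises(ValueError, match="aliased"):
            m.build_design(records, ["sex", "sex_copy"], egypt)

    def test_row_reordering_permutes_all_blocks(self, records, egypt):
        """Z rows, spline rows and region index stay aligned under permutation."""
        d1 = m.build_design(records, ["sex"], egypt, smooth_terms=["age"])
        perm = np.random.default_rng(0).permutation(len(records))
        d2 = m.build_design(records.iloc[perm].reset_index(drop=True), ["sex"], egypt,
                            smooth_terms=["age"])
        assert np.allclose(d2.Z, d1.Z[perm])
        assert np.array_equal(d2.region_index, d1.region_index[perm])
        assert np.allclose(d2.splines[0].B + d2.splines[0].centring,
                           d1.splines[0].B[perm] + d1.splines[0].centring)

    def test_round_trip_with_generator(self, small_survey, egypt):
        """Rebuilding the design from generated records reproduces the
        generator's own design exactly."""
        rebuilt = m.build_design(
            small_survey.records,
            [c.name for c in small_survey.truth.covariates],
            egypt,
        )
        assert rebuilt.columns == small_survey.design.columns
        assert np.array_equal(rebuilt.Z, small_survey.design.Z)
        assert np.array_equal(rebuilt.region_index, small_survey.design.region_index)

    def test_missing_term_raises(self, records, egypt):
        with pytest.raises(ValueError, match="not found"):
            m.build_design(records, ["nonexistent"], egypt)
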