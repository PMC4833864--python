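"""Unit and property tests for the row-adjustment mathematics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mancie import (
    CutoffConfig,
    DegenerateRowError,
    OmicsMatrix,
    adjust_matrix,
    adjust_row,
    first_pc_rows,
    pearson_correlation,
    rescale_to,
    scale_row,
    select_cutoff2,
)

# vectors guaranteed non-degenerate: moderate magnitudes, forced spread
def _vectors(n=8):
    return (
        hnp.arrays(
            float,
            n,
            elements=st.floats(-50, 50, allow_nan=False, allow_infinity=False),
        )
        .map(lambda v: v + np.linspace(0, 1, n))
    )


class TestPearsonCorrelation:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # Σ(xᵢ-x̄)(yᵢ-ȳ)/[(n-1)sₓs_y] by hand
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateRowError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_matches_numpy(self, rng):
        x, y = rng.normal(size=(2, 15))
        assert pearson_correlation(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])


class TestScaleRescale:
    def test_two_level_vector(self):
        out = scale_row([5, 5, 7, 7])
        r3 = np.sqrt(3) / 2  # deviations ±1, sample sd = 2/√3
        assert out == pytest.approx([-r3, -r3, r3, r3], abs=1e-12)

    @given(_vectors())
    def test_unit_moments(self, v):
        out = scale_row(v)
        assert np.mean(out) == pytest.approx(0, abs=1e-9)
        assert np.std(out, ddof=1) == pytest.approx(1, rel=1e-9)

    @given(_vectors(), st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, v, a, b):
        np.testing.assert_allclose(scale_row(a * v + b), scale_row(v), atol=1e-7)
        np.testing.assert_allclose(scale_row(-a * v + b), -scale_row(v), atol=1e-7)

    def test_rescale_known(self):
        assert rescale_to([1, 2, 3], 10, 2) == pytest.approx([8, 10, 12])

    def test_rescale_round_trip(self, rng):
        m = rng.normal(3, 2, size=12)
        back = rescale_to(scale_row(m), m.mean(), m.std(ddof=1))
        np.testing.assert_allclose(back, m, atol=1e-12)

    def test_rescale_identity_params(self, rng):
        x = rng.normal(size=9)
        np.testing.assert_allclose(rescale_to(x, 0, 1), scale_row(x))


def brute_force_pc_scores(rows, reference):
    """Independent oracle: explicit correlation matrix + dense eigensolver."""
    corr = np.corrcoef(rows)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eig(corr)
    lead = evecs[:, np.argmax(evals.real)].real
    z = np.array([(r - r.mean()) / r.std(ddof=1) for r in rows])
    score = lead @ z
    if np.corrcoef(score, reference)[0, 1] < 0:
        score = -score
    return score


class TestFirstPcRows:
    def test_duplicate_rows(self, rng):
        r = rng.normal(size=10)
        out = first_pc_rows(np.vstack([r, r]), reference=r)
        cos = out @ scale_row(r) / (np.linalg.norm(out) * np.linalg.norm(scale_row(r)))
        assert cos == pytest.approx(1, abs=1e-12)

    def test_antipodal_rows_sign_fixed(self, rng):
        r = rng.normal(size=10)
        out = first_pc_rows(np.vstack([r, -r]), reference=r)
        assert pearson_correlation(out, r) == pytest.approx(1, abs=1e-9)

    def test_single_row(self, rng):
        r = rng.normal(size=8)
        np.testing.assert_allclose(first_pc_rows(r[None, :], -r), scale_row(r) * -1, atol=1e-9)

    def test_all_degenerate_raises(self):
        with pytest.raises(DegenerateRowError):
            first_pc_rows(np.ones((3, 5)), np.arange(5.0))

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_eigendecomposition(self, trial):
        rng = np.random.default_rng(1000 + trial)
        k, n = rng.integers(2, 11), rng.integers(4, 21)
        rows = rng.normal(size=(k, n))
        ref = rng.normal(size=n)
        got = first_pc_rows(rows, ref)
        want = brute_force_pc_scores(rows, ref)
        cos = got @ want / (np.linalg.norm(got) * np.linalg.norm(want))
        assert cos == pytest.approx(1, abs=1e-9)


class TestAdjustRow:
    def test_identical_rows_fixed_point(self, rng):
        m = rng.normal(2, 3, size=10)
        out, label = adjust_row(m, m.copy())
        assert label == "scenario3"
        np.testing.assert_allclose(out, m, atol=1e-9)

    def test_nonpositive_correlation_unchanged(self, rng):
        m = rng.normal(size=10)
        out, label = adjust_row(m, -m)
        assert label == "scenario1"
        np.testing.assert_array_equal(out, m)

    def test_scenario2_formula(self):
        # independent straight-line evaluation of the weighted-sum update
        m = np.array([1.0, 2.0, 3.0, 5.0])
        c = np.array([2.0, 1.0, 4.0, 5.0])
        rho = np.corrcoef(c, m)[0, 1]
        cfg = CutoffConfig(0.0, 0.9)  # rho ≈ 0.855 lands in scenario 2
        assert 0 < rho <= 0.9
        zm = (m - m.mean()) / m.std(ddof=1)
        zc = (c - c.mean()) / c.std(ddof=1)
        mixed = zm + rho * zc
        expected = (mixed - mixed.mean()) / mixed.std(ddof=1) * m.std(ddof=1) + m.mean()
        out, label = adjust_row(m, c, cfg)
        assert label == "scenario2"
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_degenerate_skipped(self, rng):
        m = rng.normal(size=6)
        out, label = adjust_row(m, np.full(6, 3.0))
        assert label == "skipped"
        np.testing.assert_array_equal(out, m)

    @given(_vectors(), _vectors())
    def test_moment_conservation(self, m, c):
        out, label = adjust_row(np.asarray(m), np.asarray(c))
        if label not in ("skipped", "scenario1"):
            assert out.mean() == pytest.approx(m.mean(), rel=1e-9, abs=1e-9)
            assert out.std(ddof=1) == pytest.approx(np.std(m, ddof=1), rel=1e-9)

    def test_scenario2_monotonicity(self, rng):
        """Stronger correlation pulls the adjusted row closer to scale(c)."""
        n = 30
        base = rng.normal(size=n)
        c = rng.normal(size=n)
        zc = scale_row(c)
        cfg = CutoffConfig(0.0, 0.999)
        results = []
        for w in np.linspace(0.05, 3.0, 12):
            m = base + w * zc  # increasing alignment with c
            out, label = adjust_row(m, c, cfg)
            if label != "scenario2":
                continue
            results.append((pearson_correlation(c, m), pearson_correlation(out, zc)))
        assert len(results) >= 5
        results.sort()
        achieved = [r for _, r in results]
        assert all(b >= a - 1e-9 for a, b in zip(achieved, achieved[1:]))

    def test_scenario3_closed_form(self, rng):
        """Two-row PC direction equals scale(m)+scale(c) when rho > 0."""
        for _ in range(50):
            m = rng.normal(size=12)
            c = 0.6 * scale_row(m) + 0.4 * rng.normal(size=12)
            rho = pearson_correlation(c, m)
            if rho <= 0.5:
                continue
            out, label = adjust_row(m, c)
            assert label == "scenario3"
            direction = scale_row(m) + scale_row(c)
            got = scale_row(out)
            want = scale_row(direction)
            cos = got @ want / (np.linalg.norm(got) * np.linalg.norm(want))
            assert cos == pytest.approx(1, abs=1e-9)


class TestAdjustMatrix:
    def test_fixed_point(self, rng):
        m = OmicsMatrix(
            [f"f{i}" for i in range(20)],
            [f"s{j}" for j in range(8)],
            rng.normal(size=(20, 8)),
        )
        res = adjust_matrix(m, m.copy())
        np.testing.assert_allclose(res.adjusted.values, m.values, atol=1e-9)
        assert set(res.scenario) == {"scenario3"}

    def test_all_skipped_noop(self, random_pair):
        main, assoc = random_pair
        res = adjust_matrix(main, assoc, skip_mask=np.ones(main.n_features, bool))
        np.testing.assert_array_equal(res.adjusted.values, main.values)
        assert set(res.scenario) == {"skipped"}
        assert np.all(~np.isfinite(res.row_correlation))

    def test_gate_exhaustiveness_and_counts_vs_reference(self, random_pair):
        """Scenario labels match an independent per-row re-application of the gates."""
        main, assoc = random_pair
        cfg = CutoffConfig(0.0, 0.5)
        res = adjust_matrix(main, assoc, cfg)
        for i in range(main.n_features):
            rho = np.corrcoef(assoc.values[i], main.values[i])[0, 1]
            if rho <= cfg.cutoff1:
                expect = "scenario1"
            elif rho <= cfg.cutoff2:
                expect = "scenario2"
            else:
                expect = "scenario3"
            assert res.scenario[i] == expect
        assert sum(res.scenario_counts().values()) == main.n_features

    def test_sample_order_mismatch_names_offender(self, random_pair):
        main, assoc = random_pair
        shuffled = OmicsMatrix(
            assoc.feature_ids, assoc.sample_ids[::-1], assoc.values[:, ::-1]
        )
        with pytest.raises(ValueError, match="s7"):
            adjust_matrix(main, shuffled)

    def test_column_permutation_equivariance(self, random_pair, rng):
        main, assoc = random_pair
        perm = rng.permutation(main.n_samples)
        res = adjust_matrix(main, assoc)
        pm = OmicsMatrix(
            main.feature_ids, [main.sample_ids[j] for j in perm], main.values[:, perm]
        )
        pa = OmicsMatrix(
            assoc.feature_ids, [assoc.sample_ids[j] for j in perm], assoc.values[:, perm]
        )
        res_p = adjust_matrix(pm, pa)
        np.testing.assert_allclose(
            res_p.adjusted.values, res.adjusted.values[:, perm], atol=1e-9
        )


class TestSelectCutoff2:
    def test_equally_spaced_grid(self):
        corrs = np.linspace(0.01, 0.99, 99)
        cut = select_cutoff2(corrs, 1 / 3)
        # linear-interpolation 2/3 quantile of the grid, counted by brute force
        assert cut == pytest.approx(np.quantile(corrs, 2 / 3))
        assert cut == pytest.approx(0.663333, abs=1e-4)
        assert int(np.sum(corrs > cut)) == 33

    def test_identical_correlations(self):
        cut = select_cutoff2([0.4] * 10)
        assert cut == 0.4
        assert np.sum(np.array([0.4] * 10) > cut) == 0

    def test_extreme_target_approaches_minimum(self, rng):
        corrs = rng.uniform(-1, 1, 200)
        assert select_cutoff2(corrs, 0.999) == pytest.approx(corrs.min(), abs=0.05)

    def test_ignores_nan_and_rejects_empty(self):
        assert select_cutoff2([np.nan, 0.2, 0.8, np.nan], 0.5) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            select_cutoff2([np.nan])
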