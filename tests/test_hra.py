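"""High-level ring-artifact detection and inpainting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deringer.hra import (
    HRAParams,
    binarize_gradient,
    candidate_positions,
    detect_hra,
    inpaint_columns,
    remove_hra,
    verify_positions,
    vertical_pattern,
)
from deringer.rtv import RTVParams


def _dense_laplace_oracle(sino, cols):
    """Independent dense solve of the discrete Laplace system.

    Unknowns are the masked pixels in rows 1..M-2; neighbours outside
    the mask (adjacent unflagged columns, first/last rows) contribute
    Dirichlet data, and a lateral image border mirrors (no-flux).
    """
    sino = np.asarray(sino, dtype=float)
    m, n = sino.shape
    cols = sorted(cols)
    unknowns = [(i, c) for c in cols for i in range(1, m - 1)]
    index = {p: k for k, p in enumerate(unknowns)}
    a = np.zeros((len(unknowns), len(unknowns)))
    b = np.zeros(len(unknowns))
    for (i, c), k in index.items():
        degree = 0
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ii, jj = i + di, c + dj
            if jj < 0 or jj >= n:
                continue
            degree += 1
            if (ii, jj) in index:
                a[k, index[(ii, jj)]] = -1.0
            else:
                b[k] += sino[ii, jj]
        a[k, k] = degree
    sol = np.linalg.solve(a, b)
    out = sino.copy()
    for (i, c), k in index.items():
        out[i, c] = sol[k]
    return out


class TestVerticalPattern:
    def test_constant_texture_unchanged(self):
        t = np.full((20, 6), 2.5)
        np.testing.assert_allclose(vertical_pattern(t, 5), t)

    def test_impulse_response_is_box(self):
        t = np.zeros((21, 3))
        t[10, 1] = 5.0
        out = vertical_pattern(t, 5)
        np.testing.assert_allclose(out[8:13, 1], 1.0)
        assert np.allclose(out[:8, 1], 0.0) and np.allclose(out[13:, 1], 0.0)

    def test_vertical_stripe_invariant(self):
        t = np.zeros((30, 8))
        t[:, 3] = 1.0
        np.testing.assert_allclose(vertical_pattern(t, 9), t)

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            vertical_pattern(np.zeros((10, 4)), 4)


class TestBinarizeGradient:
    def test_single_jump_row(self):
        # gradient row [0, 0, 10, 0]: population std 4.330, threshold 8.660
        p = np.array([[1.0, 1.0, 1.0, 11.0, 11.0]])
        b = binarize_gradient(p)
        np.testing.assert_array_equal(b, [[False, False, True, False]])

    def test_constant_row_all_zero(self):
        b = binarize_gradient(np.full((3, 6), 4.0))
        assert not b.any()

    def test_symmetric_stripe_edges_both_flagged(self):
        # column profile [0, d, 0] produces +-d gradients; the absolute
        # value convention must flag both edges (row of 14 gradients,
        # two of magnitude 7: population std 2.646, threshold 5.29 < 7)
        p = np.zeros((4, 15))
        p[:, 7] = 7.0
        b = binarize_gradient(p)
        assert b[:, 6].all() and b[:, 7].all()
        assert b.sum() == 8


class TestCandidatePositions:
    def test_empty_mask_gives_empty_set(self):
        assert candidate_positions(np.zeros((5, 8), bool), r2=1.0, r3=3) == set()

    def test_gap_closing_fills_close_pairs(self):
        mask = np.zeros((10, 20), bool)
        mask[:, 10] = mask[:, 12] = True
        assert candidate_positions(mask, r2=5.0, r3=3) == {10, 11, 12}

    def test_distant_pair_not_bridged(self):
        mask = np.zeros((10, 20), bool)
        mask[:, 10] = mask[:, 14] = True
        assert candidate_positions(mask, r2=5.0, r3=3) == {10, 14}


class TestVerifyPositions:
    def test_zero_texture_verifies_nothing(self):
        assert verify_positions(np.zeros((6, 10)), {2, 5}) == set()

    def test_offset_column_verified_iff_above_derivative_band(self):
        # 16 columns, one offset by 10: derivative std sqrt(200/15) =
        # 3.65, band 7.30 < 10, so the candidate must be verified
        t = np.zeros((4, 16))
        t[:, 7] = 10.0
        col_means = t.mean(axis=0)
        sd = np.diff(col_means).std()
        assert 10.0 > 2 * sd  # sanity of the toy construction
        assert verify_positions(t, {7}) == {7}

    def test_subthreshold_offset_rejected(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0, 1.0, size=(200, 12))
        t[:, 4] += 0.05  # far below 2 sigma of the derivative
        assert verify_positions(t, {4}) == set()

    def test_all_columns_candidates_is_an_error(self):
        with pytest.raises(ValueError, match="artifact-free"):
            verify_positions(np.zeros((3, 4)), {0, 1, 2, 3})


class TestInpaintColumns:
    def test_constant_sinogram_unchanged(self):
        sino = np.full((10, 10), 4.0)
        out = inpaint_columns(sino, [4, 5])
        np.testing.assert_allclose(out, sino)

    def test_linear_ramp_restored_exactly(self):
        ramp = np.tile(np.arange(9.0), (7, 1))
        out = inpaint_columns(ramp, [4])
        np.testing.assert_allclose(out, ramp, atol=1e-9)

    def test_matches_dense_direct_solve(self, rng):
        sino = rng.uniform(0, 100, size=(12, 16))
        cols = [3, 4, 9]
        out = inpaint_columns(sino, cols)
        oracle = _dense_laplace_oracle(sino, cols)
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    @given(seed=st.integers(0, 200), col=st.integers(1, 10))
    def test_maximum_principle_property(self, seed, col):
        rng = np.random.default_rng(seed)
        sino = rng.uniform(-50, 50, size=(8, 12))
        out = inpaint_columns(sino, [col])
        boundary = np.concatenate(
            [sino[:, col - 1], sino[:, col + 1], [sino[0, col], sino[-1, col]]]
        )
        interior = out[1:-1, col]
        assert interior.min() >= boundary.min() - 1e-9
        assert interior.max() <= boundary.max() + 1e-9

    def test_pixels_outside_mask_untouched(self, rng):
        sino = rng.uniform(0, 1, size=(9, 11))
        out = inpaint_columns(sino, [2, 3])
        keep = [c for c in range(11) if c not in (2, 3)]
        np.testing.assert_array_equal(out[:, keep], sino[:, keep])

    def test_all_columns_masked_rejected(self):
        with pytest.raises(ValueError, match="interior boundary"):
            inpaint_columns(np.zeros((4, 3)), [0, 1, 2])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            inpaint_columns(np.zeros((4, 4)), [])


class TestDetectionLoop:
    def test_clean_constant_sinogram_stops_with_no_candidates(self):
        res = detect_hra(np.full((40, 30), 10.0))
        assert res.columns == []
        assert res.stop_reason == "SC2"

    def test_injected_dead_columns_recovered_exactly(self, rng):
        sino = np.tile(np.sin(np.linspace(0, np.pi, 64)) * 100, (64, 1))
        sino += rng.normal(0, 0.5, sino.shape)
        dead = [12, 30, 47]
        corrupted = sino.copy()
        corrupted[:, dead] = 1000.0
        res = detect_hra(corrupted, HRAParams(l_mean=9), RTVParams())
        assert set(res.columns) == set(dead)

    def test_accumulated_columns_untouched_outside_detection(self, rng):
        sino = np.tile(np.sin(np.linspace(0, np.pi, 64)) * 100, (64, 1))
        corrupted = sino.copy()
        corrupted[:, 20] = 800.0
        corrected, res = remove_hra(corrupted)
        assert 20 in res.columns
        keep = [c for c in range(64) if c not in res.columns]
        np.testing.assert_array_equal(corrected[:, keep], corrupted[:, keep])

    def test_artifact_free_input_returned_identically(self):
        sino = np.full((30, 24), 7.0)
        corrected, res = remove_hra(sino)
        np.testing.assert_array_equal(corrected, sino)
        assert res.columns == []

    def test_loop_terminates_within_max_iters(self, rng):
        sino = rng.uniform(0, 1, size=(32, 32))
        res = detect_hra(sino, HRAParams(max_iters=3))
        assert res.n_iterations <= 3
        assert res.stop_reason in {"SC1", "SC2", "SC3", "SC4", "max_iters"}
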