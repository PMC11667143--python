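"""Interpolation kernels: hand-checked values, convexity, bicubic oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mprkit import interpolation_core as ic
from mprkit.errors import ParameterError


def interval(a, b):
    return ic.InterpolationInterval(plane_current=np.atleast_2d(a),
                                    plane_next=np.atleast_2d(b))


def cubic_kernel(s: float, a: float = -0.5) -> float:
    """Keys cubic-convolution kernel; a = -0.5 is Catmull-Rom."""
    s = abs(s)
    if s <= 1:
        return (a + 2) * s**3 - (a + 3) * s**2 + 1
    if s < 2:
        return a * s**3 - 5 * a * s**2 + 8 * a * s - 4 * a
    return 0.0


def kernel_interp_2d(grid, u, v):
    """Direct tensor-product kernel evaluation (independent of basis matrices)."""
    total = 0.0
    for i in range(4):
        for j in range(4):
            total += grid[i][j] * cubic_kernel(u - (i - 1)) * cubic_kernel(v - (j - 1))
    return total


class TestWeightedBilinear:
    def test_hand_case_midweight(self):
        # V_i=(0,4,0), V_{i+1}=(0,8,0), k=1, w=0.5 -> 1 + 2 = 3 (direct Eq. transcription)
        iv = interval([0.0, 4.0, 0.0], [0.0, 8.0, 0.0])
        assert ic.interp_nonedge(iv, 1, 0.5) == pytest.approx(3.0)

    def test_w_zero_still_smooths_laterally(self):
        iv = interval([0.0, 4.0, 0.0], [0.0, 8.0, 0.0])
        assert ic.interp_nonedge(iv, 1, 0.0) == pytest.approx(2.0)  # 4*0.5, not 4

    def test_constant_planes_reproduced(self):
        iv = interval([7.0, 7.0, 7.0], [7.0, 7.0, 7.0])
        for w in (0.1, 0.5, 0.9):
            assert ic.interp_nonedge(iv, 1, w) == pytest.approx(7.0, abs=1e-12)

    def test_boundary_rejected_for_nonedge(self):
        iv = interval([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ParameterError):
            ic.interp_nonedge(iv, 0, 0.5)

    @given(w=st.floats(0.0, 1.0), vals=st.lists(st.floats(-1000, 3000), min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_convex_combination_bounds(self, w, vals):
        """Output lies within [min, max] of the six contributing anchor values."""
        vi, vn = vals[:3], vals[3:]
        iv = interval(vi, vn)
        out = ic.interp_nonedge(iv, 1, w)
        assert min(vals) - 1e-9 <= out <= max(vals) + 1e-9

    def test_affine_in_w(self):
        """Three collinear evaluations: midpoint equals average of endpoints."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            vi, vn = rng.uniform(0, 2000, 5), rng.uniform(0, 2000, 5)
            iv = interval(vi, vn)
            w1, w2 = rng.uniform(0, 1, 2)
            mid = ic.interp_nonedge(iv, 2, (w1 + w2) / 2)
            ends = ic.interp_nonedge(iv, 2, w1), ic.interp_nonedge(iv, 2, w2)
            assert mid == pytest.approx(sum(ends) / 2, abs=1e-9)


class TestBoundaryVariant:
    def test_hand_case_left_edge_w0(self):
        iv = interval([8.0, 4.0, 1.0], [0.0, 0.0, 0.0])
        assert ic.interp_boundary(iv, 0, 0.0) == pytest.approx(7.0)  # 0.75*8 + 0.25*4

    def test_symmetric_hand_case_w1(self):
        iv = interval([0.0, 0.0, 0.0], [8.0, 4.0, 1.0])
        assert ic.interp_boundary(iv, 0, 1.0) == pytest.approx(7.0)

    def test_constant_reproduced_any_boundary(self):
        iv = interval([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        for k in (0, 2):
            for w in (0.0, 0.3, 1.0):
                assert ic.interp_boundary(iv, k, w) == pytest.approx(5.0, abs=1e-12)

    def test_single_pixel_plane_degenerates_to_blend(self):
        iv = interval([[4.0]], [[8.0]])
        assert ic.interp_boundary(iv, 0, 0.25) == pytest.approx(5.0)


class TestEdgeClassification:
    def test_constant_plane_all_false(self):
        mask = ic.classify_edge_pixels(np.full((8, 8), 40.0), 100.0)
        assert not mask.mask.any()

    def test_vertical_step_flags_adjacent_pixels(self):
        plane = np.zeros((6, 6))
        plane[:, 3:] = 1000.0
        mask = ic.classify_edge_pixels(plane, 100.0)
        # brute-force central-difference oracle on the toy grid
        expected = np.zeros((6, 6), dtype=bool)
        for r in range(1, 5):
            for c in range(1, 5):
                gx = 0.5 * (plane[r, c + 1] - plane[r, c - 1])
                gy = 0.5 * (plane[r + 1, c] - plane[r - 1, c])
                expected[r, c] = np.hypot(gx, gy) > 100.0
        np.testing.assert_array_equal(mask.mask, expected)
        assert mask.mask[2, 2] and mask.mask[2, 3]

    def test_infinite_threshold_all_false(self):
        rng = np.random.default_rng(0)
        mask = ic.classify_edge_pixels(rng.uniform(0, 4000, (10, 10)), np.inf)
        assert not mask.mask.any()

    def test_border_always_false(self):
        plane = np.zeros((5, 5))
        plane[:, 2:] = 5000.0
        mask = ic.classify_edge_pixels(plane, 1.0)
        assert not mask.mask[0].any() and not mask.mask[-1].any()
        assert not mask.mask[:, 0].any() and not mask.mask[:, -1].any()


class TestBicubic:
    def test_constant_grid_reproduced(self):
        patch = ic.BicubicPatch(grid=np.full((4, 4), 3.5), u=0.3, v=0.8)
        assert ic.bicubic_eval(patch) == pytest.approx(3.5, abs=1e-12)

    def test_anchor_at_origin(self):
        rng = np.random.default_rng(1)
        grid = rng.uniform(0, 100, (4, 4))
        patch = ic.BicubicPatch(grid=grid, u=0.0, v=0.0)
        assert ic.bicubic_eval(patch) == pytest.approx(grid[1, 1], abs=1e-12)

    def test_linear_function_reproduced(self):
        # grid from f(i,j) = 2i + 3j -> value 2(1+u) + 3(1+v)
        grid = np.fromfunction(lambda i, j: 2 * i + 3 * j, (4, 4))
        for u, v in [(0.2, 0.7), (0.5, 0.5), (1.0, 0.0)]:
            patch = ic.BicubicPatch(grid=grid, u=u, v=v)
            assert ic.bicubic_eval(patch) == pytest.approx(2 * (1 + u) + 3 * (1 + v), abs=1e-10)

    def test_matches_16_coefficient_linear_system_oracle(self):
        """Independent oracle: sample the kernel interpolant on a 4x4 grid of
        (u,v) points, solve the 16-coefficient Vandermonde system for a_ij,
        and evaluate the polynomial at random (u, v)."""
        rng = np.random.default_rng(42)
        ts = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        vand = np.vander(ts, 4, increasing=True)
        system = np.kron(vand, vand)  # rows: (u_a, v_b); cols: a_ij, i-major
        worst = 0.0
        for _ in range(200):
            grid = rng.uniform(0.0, 1.0, (4, 4))
            samples = np.array(
                [kernel_interp_2d(grid, ua, vb) for ua in ts for vb in ts]
            )
            a = np.linalg.solve(system, samples).reshape(4, 4)
            u, v = rng.uniform(0, 1, 2)
            oracle = float(np.array([1, u, u**2, u**3]) @ a @ np.array([1, v, v**2, v**3]))
            ours = ic.bicubic_eval(ic.BicubicPatch(grid=grid, u=u, v=v))
            worst = max(worst, abs(ours - oracle))
        assert worst <= 1e-9

    def test_patch_shape_validation(self):
        with pytest.raises(ParameterError):
            ic.BicubicPatch(grid=np.zeros((3, 4)), u=0.0, v=0.0)
        with pytest.raises(ParameterError):
            ic.BicubicPatch(grid=np.zeros((4, 4)), u=1.2, v=0.0)


class TestInterpolatePlane:
    def test_constant_anchors_constant_output(self):
        plane = np.full((8, 8), 12.0)
        iv = ic.InterpolationInterval(plane_current=plane, plane_next=plane)
        mask = ic.classify_edge_pixels(plane, 100.0)
        for w in (0.1, 0.5, 0.9):
            np.testing.assert_allclose(ic.interpolate_plane(iv, w, mask), 12.0, atol=1e-12)

    def test_flat_fields_blend_linearly(self):
        iv = ic.InterpolationInterval(plane_current=np.zeros((6, 6)),
                                      plane_next=np.full((6, 6), 8.0))
        mask = ic.EdgeMask(mask=np.zeros((6, 6), dtype=bool), threshold=100.0)
        out = ic.interpolate_plane(iv, 0.5, mask)
        np.testing.assert_allclose(out, 4.0, atol=1e-12)

    def test_all_false_mask_is_pure_weighted_bilinear(self):
        rng = np.random.default_rng(3)
        vi, vn = rng.uniform(0, 2000, (7, 7)), rng.uniform(0, 2000, (7, 7))
        iv = ic.InterpolationInterval(plane_current=vi, plane_next=vn)
        mask = ic.EdgeMask(mask=np.zeros((7, 7), dtype=bool), threshold=0.0)
        out = ic.interpolate_plane(iv, 0.37, mask)
        # spot-check interior pixels against the scalar op
        for r, c in [(2, 3), (4, 1), (5, 5)]:
            k = r * 7 + c
            assert out[r, c] == pytest.approx(ic.interp_nonedge(iv, k, 0.37), abs=1e-12)
        # and the column boundaries against the 0.75/0.25 variant
        for r in (0, 3, 6):
            assert out[r, 0] == pytest.approx(
                ic.interp_boundary(iv, r * 7, 0.37, neighbor=r * 7 + 1), abs=1e-12)

    def test_edge_pixels_match_bicubic_patch_eval(self):
        """The vectorized edge path equals bicubic_eval on the assembled 4x4 patch."""
        rng = np.random.default_rng(5)
        vi, vn = rng.uniform(0, 2000, (6, 6)), rng.uniform(0, 2000, (6, 6))
        iv = ic.InterpolationInterval(plane_current=vi, plane_next=vn)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 3] = mask[4, 2] = True
        out = ic.interpolate_plane(iv, 0.42, ic.EdgeMask(mask=mask, threshold=0.0))
        for r, c in [(2, 3), (4, 2)]:
            patch = ic.bicubic_patch_for_pixel(iv, r, c, 0.42)
            assert out[r, c] == pytest.approx(ic.bicubic_eval(patch), abs=1e-9)

    @given(w=st.floats(0.01, 0.99), seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_weight_conservation_all_pixel_classes(self, w, seed):
        """Constant inputs map to the constant for every pixel class and weight."""
        rng = np.random.default_rng(seed)
        c = float(rng.uniform(-1000, 3000))
        plane = np.full((5, 7), c)
        iv = ic.InterpolationInterval(plane_current=plane, plane_next=plane)
        mask = rng.uniform(size=(5, 7)) > 0.5  # random edge mask exercises both paths
        mask[0] = mask[-1] = False
        mask[:, 0] = mask[:, -1] = False
        out = ic.interpolate_plane(iv, w, ic.EdgeMask(mask=mask, threshold=0.0))
        np.testing.assert_allclose(out, c, atol=1e-9)
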