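import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stedcoloc as sc
from stedcoloc.coloc import UndefinedPearsonError

PS = (40.0, 40.0, 40.0)


def make_stack(green, red, ps=PS):
    return sc.TwoChannelStack(
        sc.VoxelGrid(np.asarray(green, float), ps),
        sc.VoxelGrid(np.asarray(red, float), ps),
    )


class TestSlabPartition:
    def test_exact_400nm_sections_at_40nm_pixels(self):
        part = sc.slab_partition(100, 40.0, 400.0)
        assert part.intervals == [(10 * i, 10 * (i + 1)) for i in range(10)]

    def test_short_axis_is_a_single_interval(self):
        assert sc.slab_partition(10, 40.0, 400.0).intervals == [(0, 10)]

    def test_residual_rule_at_60nm_pixels(self):
        # w = round(400/60) = 7; 9 full intervals reach 63, residual 1 < 3.5
        # merges into the last, which ends at 64.
        part = sc.slab_partition(64, 60.0, 400.0)
        assert len(part.intervals) == 9
        assert part.intervals[-1] == (56, 64)

    def test_large_residual_kept_as_own_interval(self):
        part = sc.slab_partition(25, 40.0, 400.0)  # w=10, residual 5 >= 5
        assert part.intervals == [(0, 10), (10, 20), (20, 25)]

    def test_slab_thinner_than_pixel_rejected(self):
        with pytest.raises(ValueError):
            sc.slab_partition(10, 60.0, 40.0)

    @given(
        ny=st.integers(1, 500),
        px=st.sampled_from([40.0, 60.0]),
        slab=st.floats(60.0, 1000.0),
    )
    def test_intervals_disjointly_cover_the_axis(self, ny, px, slab):
        part = sc.slab_partition(ny, px, slab)
        assert part.intervals[0][0] == 0
        assert part.intervals[-1][1] == ny
        for (a0, a1), (b0, b1) in zip(part.intervals, part.intervals[1:]):
            assert a1 == b0 and a0 < a1
        assert part.intervals[-1][0] < part.intervals[-1][1]


class TestSlabMIP:
    def test_width_one_slab_is_the_xz_slice(self, rng):
        stack = make_stack(rng.uniform(0, 1, (4, 6, 5)), rng.uniform(0, 1, (4, 6, 5)))
        roi = sc.CellROI(np.ones((6, 5), bool), "c")
        proj = sc.slab_mip(stack, (2, 3), roi)
        np.testing.assert_array_equal(proj.green_mip, stack.green.data[:, 2, :])

    def test_identical_channels_project_identically(self, rng):
        data = rng.uniform(0, 1, (4, 8, 5))
        stack = make_stack(data, data)
        roi = sc.CellROI(np.ones((8, 5), bool), "c")
        proj = sc.slab_mip(stack, (0, 8), roi)
        np.testing.assert_array_equal(proj.green_mip, proj.red_mip)

    def test_matches_brute_force_in_roi_maximum(self, rng):
        stack = make_stack(rng.uniform(0, 1, (3, 12, 7)), rng.uniform(0, 1, (3, 12, 7)))
        mask = rng.uniform(size=(3, 12, 7)) > 0.4
        mask[:, 5, :] = True  # keep support nonempty
        roi = sc.CellROI(mask, "c")
        for y0, y1 in [(0, 4), (4, 8), (8, 12)]:
            proj = sc.slab_mip(stack, (y0, y1), roi)
            for z in range(3):
                for x in range(7):
                    vals = [
                        stack.green.data[z, y, x]
                        for y in range(y0, y1)
                        if mask[z, y, x]
                    ]
                    if vals:
                        assert proj.support[z, x]
                        assert proj.green_mip[z, x] == max(vals)
                    else:
                        assert not proj.support[z, x]

    def test_slab_outside_roi_is_an_error(self, rng):
        stack = make_stack(rng.uniform(0, 1, (3, 10, 5)), rng.uniform(0, 1, (3, 10, 5)))
        mask = np.zeros((10, 5), bool)
        mask[0:3, :] = True
        with pytest.raises(ValueError, match="outside ROI"):
            sc.slab_mip(stack, (5, 10), sc.CellROI(mask, "c"))


class TestPearson:
    def test_hand_checkable_vectors(self):
        p = sc.pearson(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3]))
        assert abs(p - 0.6) < 1e-12

    def test_identical_channels_give_one(self, rng):
        img = rng.uniform(0, 5, (6, 6))
        assert sc.pearson(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anticorrelation_gives_minus_one(self, rng):
        img = rng.uniform(0, 5, (6, 6))
        assert sc.pearson(img, 10.0 - img) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_channel_is_undefined(self):
        with pytest.raises(UndefinedPearsonError):
            sc.pearson(np.ones((4, 4)), np.arange(16.0).reshape(4, 4))

    def test_support_mask_restricts_the_pixels(self, rng):
        g = rng.uniform(0, 1, (5, 5))
        r = rng.uniform(0, 1, (5, 5))
        support = np.zeros((5, 5), bool)
        support[:2] = True
        p = sc.pearson(g, r, support)
        assert p == pytest.approx(sc.pearson(g[:2].ravel(), r[:2].ravel()), abs=1e-14)

    @given(
        ag=st.floats(0.1, 10), bg=st.floats(-5, 5),
        ar=st.floats(0.1, 10), br=st.floats(-5, 5),
    )
    def test_invariant_under_positive_affine_maps(self, ag, bg, ar, br):
        r = np.random.default_rng(2)
        g = r.uniform(0, 1, 40)
        h = r.uniform(0, 1, 40)
        p0 = sc.pearson(g, h)
        p1 = sc.pearson(ag * g + bg, ar * h + br)
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_negates_under_negative_scaling(self, rng):
        g = rng.uniform(0, 1, 40)
        h = rng.uniform(0, 1, 40)
        assert sc.pearson(g, -2.0 * h + 3.0) == pytest.approx(-sc.pearson(g, h), abs=1e-12)


class TestCellColocScore:
    def test_mean_of_slab_coefficients(self, rng):
        # Two slabs engineered to known p values via direct construction.
        g = rng.uniform(0, 1, (4, 20, 6))
        stack = make_stack(g, g.copy())
        roi = sc.CellROI(np.ones((20, 6), bool), "c")
        res = sc.cell_coloc_score(stack, roi, preprocess_params=None, slab_nm=400.0)
        assert res.mean_pc == pytest.approx(np.mean(res.slab_pcs))
        assert res.mean_pc == pytest.approx(1.0, abs=1e-12)

    def test_identical_channels_noise_free_score_one(self, clean_params):
        import dataclasses

        params = dataclasses.replace(clean_params, coloc_fraction=1.0, pair_jitter_sd=1e-9)
        stack, _ = sc.simulate_stack(params)
        roi = sc.CellROI(np.ones(stack.shape, bool), "c")
        res = sc.cell_coloc_score(stack, roi)
        assert res.mean_pc >= 0.95

    def test_slab_order_does_not_change_the_mean(self, rng):
        pcs = rng.uniform(-1, 1, 9)
        assert np.mean(pcs) == pytest.approx(np.mean(pcs[::-1]))

    def test_degenerate_limit_equals_global_mip_pearson(self, rng):
        data_g = rng.uniform(0, 10, (5, 30, 8))
        data_r = rng.uniform(0, 10, (5, 30, 8))
        stack = make_stack(data_g, data_r)
        roi = sc.CellROI(np.ones((30, 8), bool), "c")
        res = sc.cell_coloc_score(
            stack, roi, preprocess_params=None, slab_nm=30 * 40.0
        )
        global_mip_p = sc.pearson(data_g.max(axis=1), data_r.max(axis=1))
        assert len(res.slab_pcs) == 1
        assert res.mean_pc == pytest.approx(global_mip_p, abs=1e-12)

    def test_unscorable_cell_is_an_error(self):
        stack = make_stack(np.zeros((3, 10, 12)), np.zeros((3, 10, 12)))
        roi = sc.CellROI(np.ones((10, 12), bool), "c")
        with pytest.raises(ValueError, match="not scorable"):
            sc.cell_coloc_score(stack, roi, preprocess_params=None)

    def test_excluded_slabs_are_counted(self, rng):
        g = np.zeros((3, 20, 12))
        r = np.zeros((3, 20, 12))
        g[:, :10, :] = rng.uniform(1, 2, (3, 10, 12))
        r[:, :10, :] = rng.uniform(1, 2, (3, 10, 12))
        stack = make_stack(g, r)  # second slab constant zero -> undefined
        roi = sc.CellROI(np.ones((20, 12), bool), "c")
        res = sc.cell_coloc_score(stack, roi, preprocess_params=None, slab_nm=400.0)
        assert len(res.slab_pcs) == 1
        assert res.excluded_slabs == 1
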