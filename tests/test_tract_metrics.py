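"""Tract metric definitions and the voxel-traversal geometric kernel."""

import numpy as np
import pytest

from clsmverse.core_io import LesionMask, TractDefinition, VolumeGrid
from clsmverse.tract_metrics import (
    METRICS,
    build_matrix,
    disconnection_percentage,
    lesion_percentage,
    mean_scalar,
    streamline_traversal,
    tract_volume,
)


def _mask_grid(shape=(20, 20, 20), voxels=(), affine=None):
    vals = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        vals[v] = 1
    return VolumeGrid(vals, np.eye(4) if affine is None else affine)


def _tract(mask_voxels, streamlines, grid_shape=(20, 20, 20), affine=None):
    return TractDefinition(
        "T", _mask_grid(grid_shape, mask_voxels, affine), [np.asarray(s, float) for s in streamlines]
    )


class TestTraversal:
    def test_axis_aligned_segment_crosses_expected_cells(self, unit_grid):
        sl = np.array([[2.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        got = streamline_traversal(sl, unit_grid)
        assert [tuple(v) for v in got] == [(i, 5, 5) for i in range(2, 7)]

    def test_segment_within_one_voxel(self, unit_grid):
        sl = np.array([[3.1, 3.1, 3.1], [3.3, 3.2, 3.1]])
        assert [tuple(v) for v in streamline_traversal(sl, unit_grid)] == [(3, 3, 3)]

    def test_zero_length_segment_warns_and_skips(self, unit_grid):
        sl = np.array([[1.0, 1, 1], [1.0, 1, 1], [2.0, 1, 1]])
        tg_ok = np.array([[1.0, 1, 1], [2.0, 1, 1]])
        with pytest.warns(UserWarning, match="zero-length"):
            got = streamline_traversal(sl, unit_grid)
        assert np.array_equal(got, streamline_traversal(tg_ok, unit_grid))

    def test_out_of_grid_voxels_dropped(self, unit_grid):
        sl = np.array([[-5.0, 5.0, 5.0], [3.0, 5.0, 5.0]])
        got = streamline_traversal(sl, unit_grid)
        assert got[:, 0].min() == 0
        assert (got[:, 0] <= 3).all()

    def test_matches_exact_box_intersection_oracle(self, aniso_grid):
        """Random segments: traversal equals slab-method segment/cell test."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            p0 = rng.uniform(-15, 15, 3)
            p1 = p0 + rng.uniform(-10, 10, 3)
            got = set(map(tuple, streamline_traversal(np.array([p0, p1]), aniso_grid)))
            assert got == _slab_oracle(p0, p1, aniso_grid)


def _slab_oracle(p0, p1, grid):
    """Exact voxels whose half-open cell the closed segment intersects."""
    u0 = grid.world_to_voxel(p0)[0] + 0.5
    u1 = grid.world_to_voxel(p1)[0] + 0.5
    lo = np.floor(np.minimum(u0, u1)).astype(int)
    hi = np.floor(np.maximum(u0, u1)).astype(int)
    d = u1 - u0
    out = set()
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                tmin, tmax, ok = 0.0, 1.0, True
                for ax, c in enumerate((i, j, k)):
                    if d[ax] == 0:
                        if not c <= u0[ax] < c + 1:
                            ok = False
                            break
                    else:
                        t1 = (c - u0[ax]) / d[ax]
                        t2 = (c + 1 - u0[ax]) / d[ax]
                        if t1 > t2:
                            t1, t2 = t2, t1
                        tmin, tmax = max(tmin, t1), min(tmax, t2)
                if ok and tmin <= tmax:
                    if all(0 <= c < s for c, s in zip((i, j, k), grid.shape)):
                        out.add((i, j, k))
    return out


class TestLesionPercentage:
    def test_quarter_overlap(self):
        tract = _tract([(i, j, 0) for i in range(20) for j in range(10)], [[[0, 0, 0], [1, 0, 0]]])
        lesion = LesionMask(_mask_grid(voxels=[(i, j, 0) for i in range(10) for j in range(5)]))
        assert lesion_percentage(tract, lesion) == pytest.approx(25.0)

    def test_disjoint_and_contained(self):
        tract = _tract([(1, 1, 1), (2, 1, 1)], [[[1, 1, 1], [2, 1, 1]]])
        empty = LesionMask(_mask_grid())
        assert lesion_percentage(tract, empty) == 0.0
        full = LesionMask(_mask_grid(voxels=[(1, 1, 1), (2, 1, 1), (3, 3, 3)]))
        assert lesion_percentage(tract, full) == 100.0

    def test_empty_tract_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _tract([], [[[0, 0, 0], [1, 0, 0]]])


class TestDisconnectionPercentage:
    def test_four_of_ten_streamlines_severed(self, unit_grid):
        # 10 parallel lines along x at y=0..9; lesion covers y=0..3 at x=5
        sls = [[[0.0, y, 0.0], [9.0, y, 0.0]] for y in range(10)]
        tract = _tract([(0, y, 0) for y in range(10)], sls)
        lesion = LesionMask(_mask_grid(voxels=[(5, y, 0) for y in range(4)]))
        assert disconnection_percentage(tract, lesion) == pytest.approx(40.0)

    def test_empty_lesion_gives_zero(self):
        tract = _tract([(0, 0, 0)], [[[0.0, 0, 0], [3.0, 0, 0]]])
        assert disconnection_percentage(tract, LesionMask(_mask_grid())) == 0.0

    def test_no_streamlines_rejected(self):
        tract = TractDefinition("T", _mask_grid(voxels=[(0, 0, 0)]), [])
        with pytest.raises(ValueError, match="no streamlines"):
            disconnection_percentage(tract, LesionMask(_mask_grid()))

    def test_monotone_under_lesion_growth(self, unit_grid):
        rng = np.random.default_rng(9)
        sls = [np.cumsum(rng.uniform(-2, 2, (6, 3)), axis=0) + 10 for _ in range(15)]
        tract = _tract([(0, 0, 0)], sls)
        for _ in range(10):
            small = rng.random((20, 20, 20)) < 0.05
            big = small | (rng.random((20, 20, 20)) < 0.05)
            dp_small = disconnection_percentage(tract, LesionMask(unit_grid.like(small)))
            dp_big = disconnection_percentage(tract, LesionMask(unit_grid.like(big)))
            assert dp_big >= dp_small


class TestScalarAndVolume:
    def test_constant_and_two_voxel_mean(self):
        tract = _tract([(0, 0, 0), (1, 0, 0)], [[[0, 0, 0], [1, 0, 0]]])
        const = VolumeGrid(np.full((20, 20, 20), 0.5), np.eye(4))
        assert mean_scalar(tract, const) == pytest.approx(0.5)
        two = np.zeros((20, 20, 20))
        two[0, 0, 0], two[1, 0, 0] = 0.2, 0.4
        assert mean_scalar(tract, VolumeGrid(two, np.eye(4))) == pytest.approx(0.3)

    def test_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        vox = [tuple(v) for v in rng.integers(0, 20, size=(60, 3))]
        tract = _tract(vox, [[[0, 0, 0], [1, 0, 0]]])
        scal = VolumeGrid(rng.random((20, 20, 20)), np.eye(4))
        total, count = 0.0, 0
        for v in set(vox):
            total += scal.values[v]
            count += 1
        assert mean_scalar(tract, scal) == pytest.approx(total / count, abs=1e-12)

    def test_volume_scales_with_voxel_size(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        vox = [(i, 0, 0) for i in range(10)] + [(i, 1, 0) for i in range(10)] + [
            (i, j, 1) for i in range(10) for j in range(8)
        ]
        tract = _tract(vox, [[[0, 0, 0], [1, 0, 0]]], affine=aff)
        assert tract_volume(tract) == pytest.approx(100 * 8.0)

    def test_volume_one_clinical_voxel(self):
        aff = np.diag([1.9, 1.9, 2.38, 1.0])
        tract = _tract([(0, 0, 0)], [[[0, 0, 0], [1, 0, 0]]], affine=aff)
        assert tract_volume(tract) == pytest.approx(8.5918)


class TestBuildMatrix:
    def test_shape_and_missingness(self):
        from clsmverse.synthetic_cohort import CohortSpec, make_cohort

        cohort = make_cohort(CohortSpec(seed=11, n_participants=4))
        df = build_matrix(cohort)
        assert df.shape == (4, 6 * len(METRICS))
        # DP/LP always defined
        for m in ("DP", "LP"):
            assert not df.xs(m, axis=1, level="metric").isna().any().any()
        # fully disconnected tracts have missing direct metrics and DP = 100
        for i, disc in enumerate(cohort.ground_truth.fully_disconnected):
            for name in disc:
                assert np.isnan(df.iloc[i][(name, "FA")])
                assert df.iloc[i][(name, "DP")] == pytest.approx(100.0)

    def test_rerun_is_identical(self, small_cohort):
        import pandas as pd

        pd.testing.assert_frame_equal(build_matrix(small_cohort), build_matrix(small_cohort))

    def test_severed_streamline_removal_reduces_sn_exactly(self, small_cohort):
        df = build_matrix(small_cohort)
        n_atlas = small_cohort.spec.streamlines_per_bundle
        for tract in small_cohort.tract_defs:
            dp = df[(tract.name, "DP")]
            sn = df[(tract.name, "SN")]
            ok = sn.notna()
            assert np.allclose(sn[ok], n_atlas * (1 - dp[ok] / 100.0))
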