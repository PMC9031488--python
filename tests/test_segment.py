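from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from earlbench.grids import Grid3D, Image3D, Mask
from earlbench.evalmetrics import shape_coefficient
from earlbench.recon import EARL1, EARL2, emulate_recon
from earlbench.resample import ResamplingChain, run_chain
from earlbench.segment import (
    SegmentationParams,
    affinity_propagation,
    build_targets,
    connected_components,
    roi_from_mask,
    threshold_matv,
)


class TestThresholdMATV:
    def test_constant_roi_selects_everything(self, small_grid):
        img = Image3D(small_grid, np.full(small_grid.dims, 5.0), unit="SUV")
        mask = threshold_matv(img, None, 0.41)
        assert mask.data.all()

    def test_two_level_toy(self):
        grid = Grid3D((10, 10, 10), (1.0, 1.0, 1.0))
        vals = np.ones(grid.dims)
        lesion = np.zeros(grid.dims, bool)
        lesion[3:7, 3:7, 3:7] = True
        vals[lesion] = 10.0
        img = Image3D(grid, vals, unit="SUV")
        mask = threshold_matv(img, None, 0.41)  # threshold 4.1 > 1
        np.testing.assert_array_equal(mask.data, lesion)

    def test_roi_restricts_search(self):
        grid = Grid3D((20, 10, 10), (1.0, 1.0, 1.0))
        vals = np.ones(grid.dims)
        vals[2, 5, 5] = 100.0  # outside ROI below
        vals[15, 5, 5] = 10.0
        img = Image3D(grid, vals, unit="SUV")
        roi = ((10.0, 0.0, 0.0), (19.0, 9.0, 9.0))
        mask = threshold_matv(img, roi, 0.41)
        assert mask.data[15, 5, 5]
        assert not mask.data[2, 5, 5]
        assert mask.data.sum() == 1

    def test_idempotent(self, rng):
        grid = Grid3D((12, 12, 12), (1.0, 1.0, 1.0))
        img = Image3D(grid, rng.uniform(0, 10, grid.dims), unit="SUV")
        m1 = threshold_matv(img, None, 0.41)
        # re-threshold the masked region only: max is unchanged, so is the mask
        masked = Image3D(grid, np.where(m1.data, img.values, 0.0), unit="SUV")
        m2 = threshold_matv(masked, None, 0.41)
        np.testing.assert_array_equal(m1.data, m2.data)

    @settings(max_examples=30, deadline=None)
    @given(
        vals=hnp.arrays(
            np.float64,
            (6, 6, 6),
            elements=st.floats(0.01, 100, allow_nan=False),
        ),
        f1=st.floats(0.05, 0.9),
        f2=st.floats(0.05, 0.9),
    )
    def test_monotone_in_fraction(self, vals, f1, f2):
        grid = Grid3D((6, 6, 6), (1.0, 1.0, 1.0))
        img = Image3D(grid, vals, unit="SUV")
        lo, hi = sorted((f1, f2))
        m_lo = threshold_matv(img, None, lo)
        m_hi = threshold_matv(img, None, hi)
        assert np.all(m_lo.data >= m_hi.data)  # raising fraction never enlarges

    def test_all_zero_roi_rejected(self, small_grid):
        img = Image3D(small_grid, np.zeros(small_grid.dims), unit="SUV")
        with pytest.raises(ValueError, match="positive"):
            threshold_matv(img, None, 0.41)

    def test_disjoint_roi_rejected(self, random_image):
        roi = ((50.0, 50.0, 50.0), (60.0, 60.0, 60.0))
        with pytest.raises(ValueError, match="ROI"):
            threshold_matv(random_image, roi, 0.41)


def flood_fill_components(data):
    """Oracle: 26-connected labeling by explicit BFS flood fill."""
    visited = np.zeros_like(data, dtype=bool)
    comps = []
    dims = data.shape
    for start in np.argwhere(data):
        start = tuple(start)
        if visited[start]:
            continue
        comp = np.zeros_like(data, dtype=bool)
        stack = [start]
        visited[start] = True
        while stack:
            i, j, k = stack.pop()
            comp[i, j, k] = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        ni, nj, nk = i + di, j + dj, k + dk
                        if (
                            0 <= ni < dims[0]
                            and 0 <= nj < dims[1]
                            and 0 <= nk < dims[2]
                            and data[ni, nj, nk]
                            and not visited[ni, nj, nk]
                        ):
                            visited[ni, nj, nk] = True
                            stack.append((ni, nj, nk))
        comps.append(comp)
    return comps


class TestConnectedComponents:
    def test_two_disjoint_blobs(self, small_grid):
        data = np.zeros(small_grid.dims, bool)
        data[0, 0, 0] = True
        data[4, 4, 4] = True
        labeled, comps = connected_components(Mask(small_grid, data))
        assert len(comps) == 2

    def test_single_voxel(self, small_grid):
        data = np.zeros(small_grid.dims, bool)
        data[2, 2, 2] = True
        labeled, comps = connected_components(Mask(small_grid, data))
        assert len(comps) == 1
        assert comps[0].volume_ml == pytest.approx(small_grid.voxel_volume_ml)

    def test_sorted_by_volume_descending(self, small_grid):
        data = np.zeros(small_grid.dims, bool)
        data[0:1, 0:1, 0:1] = True  # 1 voxel
        data[3:5, 3:5, 3:5] = True  # 8 voxels
        labeled, comps = connected_components(Mask(small_grid, data))
        assert comps[0].data.sum() == 8
        assert comps[1].data.sum() == 1
        assert (labeled == 1).sum() == 8

    def test_flood_fill_oracle(self, rng):
        grid = Grid3D((8, 8, 8), (1.0, 1.0, 1.0))
        for _ in range(5):
            data = rng.uniform(0, 1, grid.dims) > 0.7
            if not data.any():
                continue
            _, comps = connected_components(Mask(grid, data))
            oracle = flood_fill_components(data)
            assert len(comps) == len(oracle)
            got = {m.data.tobytes() for m in comps}
            want = {c.tobytes() for c in oracle}
            assert got == want

    def test_empty_rejected(self, small_grid):
        with pytest.raises(ValueError):
            connected_components(Mask(small_grid, np.zeros(small_grid.dims, bool)))


class TestAffinityPropagation:
    def test_identical_points_single_cluster(self):
        res = affinity_propagation(np.zeros((5, 3)))
        assert len(res.exemplars) == 1
        assert np.all(res.labels == res.labels[0])

    def test_single_point(self):
        res = affinity_propagation(np.array([[1.0, 2.0]]))
        assert res.exemplars.tolist() == [0]

    def test_two_blobs_found_and_net_similarity_optimal(self, rng):
        pts = np.vstack(
            [rng.normal([0, 0], 0.1, (6, 2)), rng.normal([5, 5], 0.1, (6, 2))]
        )
        res = affinity_propagation(pts)
        assert len(res.exemplars) == 2
        assert res.converged
        # exemplars sit inside their own blobs
        blobs = [set(range(6)), set(range(6, 12))]
        for lbl, blob in zip((0, 1), blobs):
            members = set(np.nonzero(res.labels == res.labels[min(blob)])[0])
            assert members == blob
        # brute force: the exemplar pair maximizes net similarity
        S = -((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        pref = float(np.median(S[~np.eye(len(pts), dtype=bool)]))

        def net(ex):
            ex = list(ex)
            return len(ex) * pref + sum(
                S[i, ex].max() for i in range(len(pts)) if i not in ex
            )

        best = max(combinations(range(len(pts)), 2), key=net)
        assert net(tuple(res.exemplars)) == pytest.approx(net(best))

    def test_damping_robustness(self, rng):
        pts = np.vstack(
            [rng.normal([0, 0], 0.1, (6, 2)), rng.normal([5, 5], 0.1, (6, 2))]
        )
        r1 = affinity_propagation(pts, SegmentationParams(damping=0.5))
        r2 = affinity_propagation(pts, SegmentationParams(damping=0.9))
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_deterministic(self, rng):
        pts = rng.uniform(0, 10, (30, 4))
        r1 = affinity_propagation(pts)
        r2 = affinity_propagation(pts)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.exemplars, r2.exemplars)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            affinity_propagation(np.array([[np.nan, 0.0]]))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SegmentationParams(damping=0.4)
        with pytest.raises(ValueError):
            SegmentationParams(threshold_fraction=1.5)
        with pytest.raises(ValueError):
            SegmentationParams(max_iterations=5, convergence_window=10)


@pytest.fixture(scope="module")
def earl_ct_images(insert_truth, insert_spec):
    """Insert phantom under both protocols, interpolated to the CT grid."""
    out = {}
    for proto in (EARL1, EARL2):
        pet = emulate_recon(
            insert_truth.image,
            proto,
            background_value=insert_spec.background.concentration,
        )
        ct_img, _ = run_chain(pet, ResamplingChain("linear", "linear"))
        out[proto.name] = ct_img
    return out


class TestBuildTargets:
    def test_homogeneous_lesion_flagged(self):
        grid = Grid3D((10, 10, 10), (1.0, 1.0, 1.0))
        vals = np.zeros(grid.dims)
        vals[3:7, 3:7, 3:7] = 5.0
        img = Image3D(grid, vals, unit="SUV")
        matv = threshold_matv(img, None, 0.41)
        res = build_targets(img, matv)
        assert "homogeneous" in res.flags
        assert res.inner.is_empty

    def test_tiny_matv_single_tier(self, small_grid):
        vals = np.zeros(small_grid.dims)
        vals[2, 2, 2] = 10.0
        img = Image3D(small_grid, vals, unit="SUV")
        matv = Mask(small_grid, vals > 5)
        res = build_targets(img, matv)
        assert "single-tier" in res.flags

    def test_empty_matv_rejected(self, small_grid, random_image):
        with pytest.raises(ValueError):
            build_targets(random_image, Mask(small_grid, np.zeros(small_grid.dims, bool)))

    def test_nested_insert_recovers_inner_tube(
        self, earl_ct_images, insert_truth
    ):
        """The hotter nested tube is found as the inner tier at EARL2 resolution."""
        img = earl_ct_images["EARL2"]
        combo = Mask(
            insert_truth.image.grid,
            insert_truth.masks["V2"].data | insert_truth.masks["V3"].data,
        )
        roi = roi_from_mask(combo, margin_mm=2 * EARL2.psf_fwhm_mm)
        matv = threshold_matv(img, roi, 0.41)
        res = build_targets(img, matv)
        assert not res.inner.is_empty
        sc = shape_coefficient(res.inner, insert_truth.masks["V2"])
        assert sc > 0.5
        # sub-labels partition the MATV
        assert np.array_equal(res.sublabels > 0, matv.data)
        assert np.all(res.inner.data <= res.outer.data)

    def test_earl1_tiers_at_least_earl2(self, earl_ct_images, insert_truth):
        vols = {}
        for name, img in earl_ct_images.items():
            combo = Mask(
                insert_truth.image.grid,
                insert_truth.masks["V2"].data | insert_truth.masks["V3"].data,
            )
            roi = roi_from_mask(combo, margin_mm=12.0)
            matv = threshold_matv(img, roi, 0.41)
            vols[name] = matv.volume_ml
        assert vols["EARL1"] >= vols["EARL2"]

    def test_deterministic(self, earl_ct_images, insert_truth):
        img = earl_ct_images["EARL2"]
        combo = Mask(
            insert_truth.image.grid,
            insert_truth.masks["V2"].data | insert_truth.masks["V3"].data,
        )
        roi = roi_from_mask(combo, margin_mm=10.0)
        matv = threshold_matv(img, roi, 0.41)
        r1 = build_targets(img, matv)
        r2 = build_targets(img, matv)
        np.testing.assert_array_equal(r1.sublabels, r2.sublabels)
        np.testing.assert_array_equal(r1.inner.data, r2.inner.data)
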