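"""HU conversion, tissue masks, aorta, vesselness and intersection tracking."""

import numpy as np
import pytest

from stenoreg import ctaseg, evalmetrics, phantom
from stenoreg.phantom import CTAVolume

from conftest import straight_curve


def _volume_from_hu(hu, slope=1.0, intercept=-1024.0):
    raw = np.rint((np.asarray(hu, float) - intercept) / slope).astype(np.int16)
    return CTAVolume(raw=raw, slope=slope, intercept=intercept, spacing=(0.75, 0.5, 0.5))


class TestHounsfield:
    @pytest.mark.parametrize(
        "raw,slope,intercept,expected",
        [(0, 1.0, -1024.0, -1024.0), (1024, 1.0, -1024.0, 0.0), (700, 2.0, -1000.0, 400.0)],
    )
    def test_rescale_arithmetic(self, raw, slope, intercept, expected):
        vol = CTAVolume(
            raw=np.full((3, 4, 4), raw, dtype=np.int16),
            slope=slope, intercept=intercept, spacing=(1, 1, 1),
        )
        assert ctaseg.to_hounsfield(vol)[0, 0, 0] == expected

    def test_clipping_and_zero_slope(self):
        vol = CTAVolume(raw=np.full((3, 2, 2), 4000, np.int16), slope=1.0,
                        intercept=0.0, spacing=(1, 1, 1))
        assert ctaseg.to_hounsfield(vol).max() == 1100.0
        with pytest.raises(ValueError):
            CTAVolume(raw=vol.raw, slope=0.0, intercept=0.0, spacing=(1, 1, 1))


class TestRegions:
    @pytest.mark.parametrize(
        "hu,region",
        [(-500.0, 1), (-226.0, 1), (-225.0, 1), (-224.0, 2), (30.0, 2),
         (31.0, 3), (100.0, 3), (390.0, 3), (391.0, 4), (1000.0, 4), (1050.0, 0)],
    )
    def test_boundaries(self, hu, region):
        assert ctaseg.classify_regions(np.full((3, 2, 2), hu))[0, 0, 0] == region

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        hu = rng.uniform(-1100, 1100, (4, 16, 16))
        region = ctaseg.classify_regions(hu)
        classified = (hu >= -1100) & (hu <= 1000)
        assert np.all((region > 0) == classified)


class TestLungMask:
    def test_all_air_slice_fully_removed(self):
        keep = ctaseg.build_lung_mask(np.full((3, 8, 8), -1000.0))
        assert not keep.any()

    def test_no_region1_keeps_everything(self):
        keep = ctaseg.build_lung_mask(np.full((3, 8, 8), 100.0))
        assert keep.all()

    def test_pulmonary_vessel_hole_filled(self):
        hu = np.full((1, 16, 16), 100.0)
        hu[0, 4:12, 4:12] = -900.0  # lung blob
        hu[0, 7:9, 7:9] = 40.0  # pulmonary vessel inside it
        keep = ctaseg.build_lung_mask(hu)
        assert not keep[0, 7, 8]  # hole filled => vessel pixel removed
        assert keep[0, 0, 0]


class TestAorta:
    def _disk_slice(self, shape, cy, cx, r, hu_val=500.0):
        sl = np.zeros(shape)
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        sl[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = hu_val
        return sl

    def test_circle_center_and_radius_recovered(self):
        hu = np.zeros((3, 64, 64))
        hu[1] = self._disk_slice((64, 64), 30, 34, 15)
        model = ctaseg.segment_aorta(hu, slices=[1], radius_range=(8, 25))
        pts = np.argwhere(model.M[1])
        cy, cx = pts.mean(axis=0)
        r_est = np.sqrt(len(pts) / np.pi)
        assert abs(cy - 30) <= 2 and abs(cx - 34) <= 2
        assert abs(r_est - 15) <= 2

    def test_no_region4_adds_nothing(self):
        with pytest.warns(UserWarning):
            model = ctaseg.segment_aorta(np.zeros((3, 32, 32)), [0, 1],
                                         radius_range=(5, 10))
        assert not model.M.any()

    def test_small_disk_outside_radius_range_excluded(self):
        hu = np.zeros((2, 64, 64))
        hu[0] = self._disk_slice((64, 64), 30, 30, 15)
        hu[0] += self._disk_slice((64, 64), 10, 52, 4)
        model = ctaseg.segment_aorta(hu, slices=[0], radius_range=(8, 25))
        assert model.M[0, 30, 30]
        assert not model.M[0, 10, 52]


class TestVesselness:
    def test_zero_branch_fires_for_negative_l1(self):
        assert ctaseg.vesselness_score(-1.0, 5.0) == 0.0

    def test_hand_value(self):
        v = ctaseg.vesselness_score(0.0, 25.0 * np.sqrt(2.0), phi1=0.75, phi2=25.0)
        assert v == pytest.approx(1.0 - np.exp(-1.0), abs=1e-9)

    def test_monotone_limit_to_one(self):
        vals = [ctaseg.vesselness_score(0.0, l2) for l2 in (10, 50, 200, 1000)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 0.99

    def test_ordering_violations(self):
        with pytest.raises(ValueError):
            ctaseg.vesselness_score(1.0, 0.0)
        assert ctaseg.vesselness_score(0.0, 0.0) == 0.0

    def test_bright_vessel_polarity(self):
        assert ctaseg.vesselness_score(0.1, 5.0, polarity="bright_vessels") == 0.0
        assert ctaseg.vesselness_score(0.1, -5.0, polarity="bright_vessels") > 0.0

    def test_constant_slice_zero_map(self):
        vs = ctaseg.frangi_enhance(np.full((32, 32), 7.0))
        assert np.all(vs.v == 0.0)

    def test_tube_ridge_response(self):
        img = np.zeros((64, 64))
        img[:, 29:35] = 100.0  # bright tube of radius 3
        vs = ctaseg.frangi_enhance(img, polarity="bright_vessels")
        on = vs.v[10:54, 31:33].mean()
        off = vs.v[10:54, 5:20].mean()
        assert on > 5 * off

    def test_nonfinite_input_rejected(self):
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            ctaseg.frangi_enhance(bad)


def dense_hessian_oracle(img, sigma, pixel):
    """Independent Hessian: explicit sampled Gaussian-derivative kernels."""
    from scipy.signal import convolve2d

    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    d1 = -x / sigma**2 * g
    d2 = (x**2 / sigma**4 - 1.0 / sigma**2) * g
    pad = radius
    padded = np.pad(img, pad, mode="edge")

    def sep(krow, kcol):
        out = convolve2d(padded, np.outer(krow, kcol)[::-1, ::-1], mode="same")
        return out[pad:-pad, pad:-pad]

    ixx = sep(g, d2) * sigma**2  # second derivative along columns (x)
    iyy = sep(d2, g) * sigma**2
    ixy = sep(d1, d1) * sigma**2
    r, c = pixel
    h = np.array([[ixx[r, c], ixy[r, c]], [ixy[r, c], iyy[r, c]]])
    ev = np.linalg.eigvalsh(h)
    l1, l2 = sorted(ev, key=abs)
    return l1, l2


class TestFrangiOracle:
    def test_pixel_matches_dense_hessian_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.normal(100.0, 15.0, (40, 40))
        pixel = (20, 17)
        for sigma in (1, 2):
            l1, l2 = dense_hessian_oracle(img, sigma, pixel)
            expected = ctaseg.vesselness_score(l1, l2)
            l1i, l2i = ctaseg.hessian_eigenvalues(img, sigma)
            got = ctaseg.vesselness_score(l1i[pixel], l2i[pixel])
            assert got == pytest.approx(expected, abs=1e-8)


class TestBifurcationDetection:
    def _y_region(self):
        m = np.zeros((40, 40), dtype=bool)
        m[2:22, 18:22] = True  # stem (largest part)
        for i in range(12):  # two diverging arms
            m[22 + i, 14 - i // 2: 18 - i // 2] = True
            m[22 + i, 22 + i // 2: 26 + i // 2] = True
        return m

    def test_y_region_flags_two_distal_branches(self):
        flag, regions = ctaseg.detect_bifurcation(self._y_region())
        assert flag
        assert len(regions) == 2

    def test_convex_disk_no_bifurcation(self):
        yy, xx = np.ogrid[:20, :20]
        disk = (yy - 10) ** 2 + (xx - 10) ** 2 <= 36
        flag, regions = ctaseg.detect_bifurcation(disk)
        assert not flag and regions == []

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            ctaseg.detect_bifurcation(np.zeros((8, 8), dtype=bool))


def _stack_from_specs(curves, shape=(64, 48, 48)):
    spec = phantom.PhantomSpec3D(volume_size=shape, artery_curves=curves)
    vol, truth = phantom.make_cta_phantom(spec)
    hu = ctaseg.to_hounsfield(vol)
    return ctaseg.binarize_slices(hu, method="region4"), truth


class TestTracking:
    def test_straight_tube_recovered_with_keypoints(self):
        curves = (phantom.Branch3D("LAD", straight_curve(10, 40, 24, 24), radius=3.0),)
        stack, truth = _stack_from_specs(curves, shape=(48, 48, 48))
        model = ctaseg.track_artery(stack, ctaseg.Seed(10, 24, 24, "LAD"))
        assert evalmetrics.recall(model.M, truth.label_masks["LAD"]) >= 0.95
        assert model.start.z == 10 and (model.start.row, model.start.col) == (24, 24)
        zs = np.flatnonzero(truth.label_masks["LAD"].any(axis=(1, 2)))
        assert model.end.z == zs[-1]

    def test_terminating_side_branch_removed_with_keypoint(self):
        curves = (
            phantom.Branch3D("RCA", straight_curve(6, 56, 20, 24), radius=3.0),
            phantom.Branch3D("side", straight_curve(20, 25, 20, 24, dy=14, dx=6, n=6),
                             radius=2.0, parent="RCA"),
        )
        stack, truth = _stack_from_specs(curves)
        model = ctaseg.track_artery(stack, ctaseg.Seed(6, 20, 24, "RCA"),
                                    ctaseg.TrackConfig(preserve_len=15))
        # below the separation slice the branch is its own component and
        # must be absent from the model
        sep = _separation_slice(truth, "RCA", "side")
        distal = truth.label_masks["side"] & ~truth.label_masks["RCA"]
        distal[:sep] = False
        assert distal.any() and not (model.M & distal).any()
        bifs = model.bifurcations()
        assert len(bifs) == 1
        assert abs(bifs[0].z - (sep - 1)) <= 1

    def test_one_slice_gap_bridged_by_backtracking(self):
        curves = (phantom.Branch3D("LAD", straight_curve(8, 50, 24, 24), radius=3.0),)
        stack, truth = _stack_from_specs(curves)
        stack[30] = False
        model = ctaseg.track_artery(stack, ctaseg.Seed(8, 24, 24, "LAD"),
                                    ctaseg.TrackConfig(lookahead=3))
        zs = np.flatnonzero(truth.label_masks["LAD"].any(axis=(1, 2)))
        assert model.end.z == zs[-1]
        assert not model.M[30].any()
        assert model.M[31].any()

    def test_long_branch_preserved_by_rca_rule(self):
        curves = (
            phantom.Branch3D("RCA", straight_curve(6, 56, 20, 24), radius=3.0),
            phantom.Branch3D("rpda", straight_curve(20, 50, 20, 24, dy=18, dx=4, n=10),
                             radius=2.0, parent="RCA"),
        )
        stack, truth = _stack_from_specs(curves)
        model = ctaseg.track_artery(stack, ctaseg.Seed(6, 20, 24, "RCA"),
                                    ctaseg.TrackConfig(preserve_len=15))
        distal = truth.label_masks["rpda"] & ~truth.label_masks["RCA"]
        distal[:45] = False  # check the far end of the preserved branch
        assert (model.M & distal).any()

    def test_seed_off_component_rejected(self):
        stack = np.zeros((5, 8, 8), dtype=bool)
        with pytest.raises(ValueError, match="seed"):
            ctaseg.track_artery(stack, ctaseg.Seed(2, 4, 4, "LM"))

    def test_keypoint_order_invariant(self):
        curves = (
            phantom.Branch3D("RCA", straight_curve(6, 56, 20, 24), radius=3.0),
            phantom.Branch3D("side", straight_curve(25, 35, 20, 24, dy=14, dx=6, n=6),
                             radius=2.0, parent="RCA"),
        )
        stack, _ = _stack_from_specs(curves)
        model = ctaseg.track_artery(stack, ctaseg.Seed(6, 20, 24, "RCA"))
        zs = [k.z for k in model.keypoints]
        assert model.start.z == min(zs)
        for b in model.bifurcations():
            assert model.start.z <= b.z <= model.end.z


def _separation_slice(truth, parent, child):
    """First slice where the child's cross-section no longer touches the
    parent's (independent truth for the bifurcation slice)."""
    from scipy import ndimage

    pm, cm = truth.label_masks[parent], truth.label_masks[child]
    for z in range(pm.shape[0]):
        if cm[z].any() and pm[z].any():
            grown = ndimage.binary_dilation(pm[z], np.ones((3, 3), bool))
            if not (cm[z] & ~pm[z] & grown).any() and (cm[z] & ~pm[z]).any():
                return z
    raise AssertionError("branches never separate")


class TestSeedDerivation:
    def _lm_setup(self):
        lm = phantom.Branch3D("LM", straight_curve(5, 20, 24, 24), radius=3.0)
        lad = phantom.Branch3D("LAD", straight_curve(20, 50, 24, 24, dy=12, dx=-10, n=10),
                               radius=2.5, parent="LM")
        lcx = phantom.Branch3D("LCX", straight_curve(20, 50, 24, 24, dy=12, dx=10, n=10),
                               radius=2.5, parent="LM")
        stack, truth = _stack_from_specs((lm, lad, lcx))
        return stack, truth

    def test_seeds_land_inside_their_branches(self):
        stack, truth = self._lm_setup()
        cfg = ctaseg.TrackConfig(stop_at_first_bifurcation=True)
        lm = ctaseg.track_artery(stack, ctaseg.Seed(5, 24, 24, "LM"), cfg)
        lad, lcx = ctaseg.derive_lad_lcx_seeds(lm, stack)
        assert lad.label == "LAD" and lcx.label == "LCX"
        assert stack[lad.z, lad.row, lad.col]
        assert stack[lcx.z, lcx.row, lcx.col]
        assert lad.col < lcx.col  # default: leftmost-in-image is the LAD
        assert truth.label_masks["LAD"][lad.z, lad.row, lad.col] or \
            truth.label_masks["LCX"][lad.z, lad.row, lad.col]

    def test_nonbifurcating_lm_rejected(self):
        curves = (phantom.Branch3D("LM", straight_curve(5, 40, 24, 24), radius=3.0),)
        stack, _ = _stack_from_specs(curves)
        lm = ctaseg.track_artery(stack, ctaseg.Seed(5, 24, 24, "LM"))
        with pytest.raises(ValueError, match="bifurcation|bottom"):
            ctaseg.derive_lad_lcx_seeds(lm, stack)

    def test_three_way_split_reports_candidates(self):
        lm = phantom.Branch3D("LM", straight_curve(5, 20, 24, 24), radius=3.0)
        kids = tuple(
            phantom.Branch3D(f"k{i}", straight_curve(20, 45, 24, 24, dy=dy, dx=dx, n=8),
                             radius=2.0, parent="LM")
            for i, (dy, dx) in enumerate([(14, 0), (-6, 12), (-6, -12)])
        )
        stack, _ = _stack_from_specs((lm,) + kids)
        cfg = ctaseg.TrackConfig(stop_at_first_bifurcation=True)
        lm_model = ctaseg.track_artery(stack, ctaseg.Seed(5, 24, 24, "LM"), cfg)
        with pytest.raises(ValueError, match="ambiguous"):
            ctaseg.derive_lad_lcx_seeds(lm_model, stack)
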