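"""Chan-Vese: energy accounting, descent, and oracle-checked segmentation.

The independent oracle for piecewise-constant images is the midpoint
threshold (c_lesion + c_background)/2, which is exact for two-level images.
"""

import numpy as np
import pytest
from scipy import ndimage as ndi

from fluorocad import chanvese as cv
from fluorocad.simulate import SimConfig, generate_frame


def two_level_image(size=128, r=20, lo=0.3, hi=0.8):
    yy, xx = np.mgrid[:size, :size]
    true = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= r ** 2
    img = np.full((size, size), lo)
    img[true] = hi
    return img, true


def iou(a, b):
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


class TestEnergy:
    def test_zero_residual_at_true_partition(self):
        img, true = two_level_image()
        phi = np.where(true, 1.0, -1.0)
        state = cv.LevelSetState(phi=phi, c1=0.8, c2=0.3, energy=0.0)
        params = cv.ChanVeseParams(mu=0.0, nu=0.0)
        assert cv.energy(img, state, params) == pytest.approx(0.0, abs=1e-12)

    def test_misassigned_pixels_match_brute_force_sum(self):
        img, true = two_level_image()
        shifted = np.roll(true, 5, axis=1)      # misassign a band of pixels
        phi = np.where(shifted, 1.0, -1.0)
        c1, c2 = 0.8, 0.3
        state = cv.LevelSetState(phi=phi, c1=c1, c2=c2, energy=0.0)
        params = cv.ChanVeseParams(mu=0.0, nu=0.0, lambda1=1.3, lambda2=0.7)
        # brute-force direct summation with the same c's
        expected = (1.3 * ((img[shifted] - c1) ** 2).sum()
                    + 0.7 * ((img[~shifted] - c2) ** 2).sum())
        assert cv.energy(img, state, params) == pytest.approx(expected, rel=1e-12)

    def test_lambda1_scales_inside_term_linearly(self):
        img, true = two_level_image()
        phi = np.where(np.roll(true, 3, axis=0), 1.0, -1.0)
        state = cv.LevelSetState(phi=phi, c1=0.7, c2=0.35, energy=0.0)
        e1 = cv.energy(img, state, cv.ChanVeseParams(mu=0, nu=0,
                                                     lambda1=1.0, lambda2=1.0))
        e2 = cv.energy(img, state, cv.ChanVeseParams(mu=0, nu=0,
                                                     lambda1=2.0, lambda2=1.0))
        inside = (e2 - e1)  # the extra copy of the inside term
        e_inside = ((img[phi > 0] - 0.7) ** 2).sum()
        assert inside == pytest.approx(e_inside, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        state = cv.LevelSetState(phi=np.zeros((4, 4)), c1=0, c2=0, energy=0)
        with pytest.raises(ValueError):
            cv.energy(np.zeros((5, 5)), state, cv.ChanVeseParams())


class TestEvolveStep:
    def test_energy_never_increases_on_noiseless_image(self):
        img, _ = two_level_image()
        params = cv.ChanVeseParams()
        phi = cv._init_phi(img.shape, cv.InitScheme.CHECKERBOARD)
        fov = np.ones(img.shape, bool)
        e, c1, c2 = cv._reduced_energy(img, phi > 0, fov, params)
        state = cv.LevelSetState(phi=phi, c1=c1, c2=c2, energy=e)
        prev = state.energy
        for _ in range(60):
            state = cv.evolve_step(img, state, params, fov)
            assert state.energy <= prev + 1e-9
            prev = state.energy

    def test_c_means_recomputed_each_step(self):
        img, _ = two_level_image()
        params = cv.ChanVeseParams()
        phi = cv._init_phi(img.shape, cv.InitScheme.DISK)
        fov = np.ones(img.shape, bool)
        e, c1, c2 = cv._reduced_energy(img, phi > 0, fov, params)
        state = cv.LevelSetState(phi=phi, c1=c1, c2=c2, energy=e)
        state = cv.evolve_step(img, state, params, fov)
        mask = state.phi > 0
        assert state.c1 == pytest.approx(img[mask].mean())
        assert state.c2 == pytest.approx(img[~mask].mean())

    def test_true_rectangle_partition_is_fixed_point(self):
        size = 96
        img = np.full((size, size), 0.3)
        true = np.zeros((size, size), bool)
        true[30:60, 20:70] = True
        img[true] = 0.8
        params = cv.ChanVeseParams()
        phi = cv._init_phi(img.shape, cv.InitScheme.FROM_MASK, true)
        fov = np.ones(img.shape, bool)
        e, c1, c2 = cv._reduced_energy(img, true, fov, params)
        state = cv.LevelSetState(phi=phi, c1=c1, c2=c2, energy=e)
        for _ in range(10):
            state = cv.evolve_step(img, state, params, fov)
        assert np.array_equal(state.phi > 0, true)


class TestSegment:
    def test_disk_recovered_against_threshold_oracle(self):
        img, true = two_level_image()
        mask = cv.segment(img, cv.ChanVeseParams())
        oracle = img > (0.8 + 0.3) / 2
        assert iou(mask, oracle) >= 0.98
        assert iou(mask, true) >= 0.98

    def test_uniform_image_gives_empty_mask_with_warning(self):
        with pytest.warns(cv.DegenerateImageWarning):
            mask = cv.segment(np.full((64, 64), 0.5), cv.ChanVeseParams())
        assert not mask.any()

    def test_two_disjoint_blobs_both_recovered(self):
        size = 128
        yy, xx = np.mgrid[:size, :size]
        t1 = (yy - 40) ** 2 + (xx - 40) ** 2 <= 12 ** 2
        t2 = (yy - 90) ** 2 + (xx - 90) ** 2 <= 15 ** 2
        img = np.full((size, size), 0.3)
        img[t1 | t2] = 0.8
        mask = cv.segment(img, cv.ChanVeseParams())
        labeled, n = ndi.label(mask)
        assert n == 2
        for t in (t1, t2):
            best = max(iou(labeled == i, t) for i in range(1, n + 1))
            assert best >= 0.95

    def test_nonfinite_pixels_rejected(self):
        img = np.full((32, 32), 0.4)
        img[3, 3] = np.nan
        with pytest.raises(ValueError):
            cv.segment(img, cv.ChanVeseParams())

    def test_brighter_region_reported_under_inversion(self):
        img, _ = two_level_image()
        fov = np.ones(img.shape, bool)
        m = cv.segment(img, cv.ChanVeseParams())
        m_inv = cv.segment(1.0 - img, cv.ChanVeseParams())
        assert iou(m_inv, ~m & fov) >= 0.99

    def test_segmentation_restricted_to_fov(self):
        ph = generate_frame(SimConfig(size=96, seed=11), "suspicious")
        mask = cv.segment(ph.fluorescence(), cv.ChanVeseParams(), ph.fov_mask)
        assert not (mask & ~ph.fov_mask).any()

    def test_matches_skimage_reference_on_disk(self):
        """Independent cross-check against an established implementation."""
        from skimage.segmentation import chan_vese as sk_chan_vese
        img, true = two_level_image(size=96, r=18)
        ours = cv.segment(img, cv.ChanVeseParams())
        theirs = sk_chan_vese(img, mu=0.2, lambda1=1.0, lambda2=1.0,
                              max_num_iter=300)
        if img[theirs].mean() < img[~theirs].mean():
            theirs = ~theirs
        assert iou(ours, theirs) >= 0.95

    def test_params_validation(self):
        with pytest.raises(ValueError):
            cv.ChanVeseParams(lambda1=0.0)
        with pytest.raises(ValueError):
            cv.ChanVeseParams(dt=-1.0)
        with pytest.raises(ValueError):
            cv.ChanVeseParams(max_iter=0)
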