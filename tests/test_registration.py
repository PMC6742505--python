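"""Discrete B-spline registration: basis correctness, local mutual
information behaviour, and confidence-modulated recovery on synthetic
distorted/undistorted pairs."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from epiunwarp import phantom as ph
from epiunwarp.registration import (
    BSplineGrid,
    RegConfig,
    cubic_bspline,
    dense_field,
    pairwise_cost,
    project_confidence,
    register,
    semi_data_term,
    semi_histogram,
)
from epiunwarp.volumes import DisplacementFieldPE

SHAPE = (30, 30, 12)


@pytest.fixture(scope="module")
def pair():
    """Textured reference plus a smoothly distorted floating image with a
    known PE field of about two voxels peak."""
    spec = ph.default_spec(grid_shape=SHAPE)
    ref = ph.generate_structural(spec)
    mask = ph.head_mask(spec)
    x, y, z = np.meshgrid(*[np.arange(n, dtype=float) for n in SHAPE], indexing="ij")
    raw = 2.0 * np.sin(np.pi * y / SHAPE[1]) * np.exp(-((x - SHAPE[0] / 2) ** 2) / 150.0)
    true = gaussian_filter(raw * mask, 2.0)
    disp = DisplacementFieldPE(true, pe_axis=1)
    flt = ph.simulate_distorted_epi(ref, disp, modulate_jacobian=True)
    return ref, flt, true, disp, mask


SMALL_CFG = RegConfig(
    grid_spacing=6.0, label_step=0.5, label_range=2.5, bins=32,
    lambda_global=0.5, max_cycles=2, levels=1,
)


class TestBSplineBasis:
    def test_zero_coeffs_give_zero_field(self):
        g = BSplineGrid(image_shape=(15, 11, 9), spacing=(4, 4, 3))
        assert np.all(dense_field(g).data == 0.0)

    def test_partition_of_unity_constant_reproduction(self):
        g = BSplineGrid(image_shape=(17, 13, 9), spacing=(5, 4, 3))
        g.coeffs[:] = 3.0
        assert np.abs(dense_field(g).data - 3.0).max() < 1e-10

    def test_single_coefficient_matches_tensor_basis(self):
        g = BSplineGrid(image_shape=(20, 20, 10), spacing=(5, 5, 5))
        g.coeffs[2, 2, 1] = 1.0
        f = dense_field(g).data
        for vox in [(7, 7, 2), (5, 9, 4), (10, 6, 0)]:
            w = 1.0
            for a, (x, nc) in enumerate(zip(vox, g.n_ctrl)):
                cp = (2, 2, 1)[a]
                w *= cubic_bspline(x / g.spacing[a] - (cp - 1))
            assert f[vox] == pytest.approx(w, abs=1e-12)


class TestSemiHistogram:
    def test_total_mass_equals_gaussian_mass(self, pair):
        ref, flt, *_ = pair
        g = BSplineGrid(image_shape=SHAPE, spacing=(6, 6, 6))
        h = semi_histogram(ref, flt, (3, 3, 2), g, SMALL_CFG)
        # Parzen windows sum to one per sample, so the histogram total is
        # the Gaussian kernel mass over the support region
        from epiunwarp.registration import _SemiEvaluator

        ev = _SemiEvaluator(ref, flt, g, SMALL_CFG)
        sls = ev.region((3, 3, 2))
        assert h.total == pytest.approx(float(ev.gamma((3, 3, 2), sls).sum()), rel=1e-6)

    def test_identical_images_concentrate_near_diagonal(self, pair):
        ref = pair[0]
        g = BSplineGrid(image_shape=SHAPE, spacing=(6, 6, 6))
        h = semi_histogram(ref, ref, (3, 3, 2), g, SMALL_CFG)
        bins = h.joint.shape[0]
        br, bf = np.meshgrid(np.arange(bins), np.arange(bins), indexing="ij")
        near = np.abs(br - bf) <= 2  # Parzen spread is two bins wide
        assert h.joint[near].sum() / h.total > 0.999

    def test_constant_region_is_degenerate_with_nmi_2(self):
        const = np.ones(SHAPE)
        g = BSplineGrid(image_shape=SHAPE, spacing=(6, 6, 6))
        with pytest.warns(UserWarning, match="degenerate"):
            h = semi_histogram(const, const, (3, 3, 2), g, SMALL_CFG)
            assert h.nmi() == 2.0


class TestSemiDataTerm:
    def test_identity_beats_shuffle(self, pair):
        ref = pair[0]
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(ref.ravel()).reshape(ref.shape)
        g = BSplineGrid(image_shape=SHAPE, spacing=(6, 6, 6))
        same = semi_data_term(ref, ref, g, (3, 3, 2), 0.0, SMALL_CFG)
        indep = semi_data_term(ref, shuffled, g, (3, 3, 2), 0.0, SMALL_CFG)
        assert same > 1.4  # strong dependence
        assert 1.0 <= indep < 1.15  # near-independence floor

    def test_true_shift_label_scores_at_least_zero_label(self, pair):
        """For a floating image translated by +2 along PE, offering the
        +2 label must not score worse than staying."""
        ref = pair[0]
        disp = DisplacementFieldPE(np.full(SHAPE, 2.0), pe_axis=1)
        flt = ph.simulate_distorted_epi(ref, disp, modulate_jacobian=True)
        g = BSplineGrid(image_shape=SHAPE, spacing=(6, 6, 6), pe_axis=1)
        cp = (3, 3, 2)  # textured central control point
        assert (
            semi_data_term(ref, flt, g, cp, 2.0, SMALL_CFG)
            >= semi_data_term(ref, flt, g, cp, 0.0, SMALL_CFG)
        )


class TestPairwiseAndProjection:
    def test_pairwise_cost_values(self):
        assert pairwise_cost(0.0, 0.0, 2.0, 2.0) == 0.0
        assert pairwise_cost(0.0, 0.0, 2.0, 3.5) == pytest.approx(1.5)
        assert pairwise_cost(1.0, -0.5, 2.0, 3.5) == pairwise_cost(-0.5, 1.0, 3.5, 2.0)

    def test_uniform_confidence_projects_to_itself(self):
        g = BSplineGrid(image_shape=(20, 16, 10), spacing=(5, 5, 5))
        sigma = project_confidence(np.full((20, 16, 10), 0.37), g)
        assert np.allclose(sigma, 0.37, atol=1e-9)

    def test_checkerboard_projects_strictly_inside(self):
        g = BSplineGrid(image_shape=(20, 16, 10), spacing=(5, 5, 5))
        idx = np.indices((20, 16, 10)).sum(axis=0)
        sigma = project_confidence((idx % 2).astype(float), g)
        assert np.all(sigma > 0.0) and np.all(sigma < 1.0)


@pytest.fixture(scope="module")
def recovery(pair):
    ref, flt, true, disp, mask = pair
    return register(ref, flt, init=None, conf=np.zeros(SHAPE), config=SMALL_CFG)


class TestRegister:
    def test_identical_images_full_confidence_stay_put(self, pair):
        ref = pair[0]
        cfg = RegConfig(grid_spacing=6.0, label_step=1.0, label_range=2.0,
                        lambda_global=1.0, max_cycles=1, levels=1)
        res = register(ref, ref, init=None, conf=np.ones(SHAPE), config=cfg)
        assert np.abs(res.displacement.data).max() == 0.0

    def test_data_driven_recovery_under_half_voxel(self, pair, recovery):
        *_, true, _, mask = pair
        err = np.abs(recovery.displacement.data - true)[mask]
        assert err.mean() < 0.5

    def test_cost_trace_monotone_nonincreasing(self, recovery):
        t = recovery.energy_trace
        assert all(t[i + 1] <= t[i] + 1e-9 for i in range(len(t) - 1))

    def test_full_confidence_freezes_the_fieldmap_init(self, pair):
        ref, flt, true, disp, mask = pair
        res = register(ref, flt, init=disp, conf=np.ones(SHAPE), config=SMALL_CFG)
        assert np.abs(res.displacement.data - true)[mask].mean() < 0.1

    def test_confidence_monotonically_limits_deviation_from_init(self, pair):
        """Mean deviation from the init field must not increase with the
        uniform confidence level."""
        ref, flt, true, disp, mask = pair
        devs = []
        for sigma in (0.0, 0.5, 1.0):
            res = register(ref, flt, init=disp, conf=np.full(SHAPE, sigma), config=SMALL_CFG)
            devs.append(np.abs(res.displacement.data - true)[mask].mean())
        assert devs[2] <= devs[1] + 1e-9 <= devs[0] + 2e-9

    def test_shape_mismatch_rejected(self, pair):
        ref = pair[0]
        with pytest.raises(ValueError, match="shape"):
            register(ref, ref[:-2], init=None, conf=None, config=SMALL_CFG)
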