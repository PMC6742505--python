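"""Phantom generator: wrapping convention, smoothness guarantee, noise
model fidelity and the EPI distortion forward model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from epiunwarp import phantom as ph
from epiunwarp.volumes import DisplacementFieldPE, PhaseVolume, wrap_to_principal

TWO_PI = 2 * np.pi


class TestWrapPhase:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (3 * np.pi / 2, -np.pi / 2),  # single wrap
            (np.pi, np.pi),  # boundary convention: +pi stays
            (-np.pi, np.pi),  # ... and -pi maps to +pi
            (0.3, 0.3),  # identity inside the principal range
        ],
    )
    def test_principal_values(self, value, expected):
        assert wrap_to_principal(value) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-50.0, 50.0), st.integers(-5, 5))
    def test_idempotent_and_congruent(self, x, n):
        w = wrap_to_principal(x)
        assert -np.pi < w <= np.pi + 1e-12
        assert wrap_to_principal(w) == pytest.approx(w, abs=1e-12)
        # wrap(phi + 2*pi*n) == wrap(phi)
        assert wrap_to_principal(x + TWO_PI * n) == pytest.approx(w, abs=1e-9)
        # congruence modulo 2*pi
        assert (x - w) / TWO_PI == pytest.approx(round((x - w) / TWO_PI), abs=1e-9)


class TestTruePhase:
    def test_all_zero_amplitudes_give_constant_zero(self):
        spec = ph.PhantomSpec(grid_shape=(10, 10, 8))
        out = ph.generate_true_phase(spec)
        assert np.all(out.data == 0.0)

    def test_default_phase_spans_more_than_one_cycle(self, small_truth):
        assert small_truth.data.max() - small_truth.data.min() > TWO_PI

    @pytest.mark.parametrize("shape", [(24, 24, 12), (64, 64, 32)])
    def test_smoothness_inside_mask(self, shape):
        """No adjacent 6-neighbour jump reaches pi inside the head mask, so
        wrapping is the only discontinuity in the wrapped image."""
        spec = ph.default_spec(grid_shape=shape)
        data = ph.generate_true_phase(spec).data
        mask = ph.head_mask(spec)
        worst = 0.0
        for a in range(3):
            lo = tuple(slice(0, -1) if i == a else slice(None) for i in range(3))
            hi = tuple(slice(1, None) if i == a else slice(None) for i in range(3))
            both = mask[lo] & mask[hi]
            if both.any():
                worst = max(worst, float(np.abs(data[lo] - data[hi])[both].max()))
        assert worst < np.pi

    def test_invalid_spec_names_field(self):
        with pytest.raises(ValueError, match="grid_shape"):
            ph.PhantomSpec(grid_shape=(4, 10, 10))
        with pytest.raises(ValueError, match="voxel_size"):
            ph.PhantomSpec(grid_shape=(10, 10, 10), voxel_size=(1, -1, 1))
        with pytest.raises(ValueError, match="rim_amplitude"):
            ph.PhantomSpec(
                grid_shape=(32, 32, 16),
                resection=ph.ResectionSpec(centre=(16, 16, 8), radii=(5, 5, 5),
                                           rim_amplitude=50.0, rim_width=1.0),
            )


class TestMagnitude:
    def test_whole_grid_mask_no_resection_is_uniform_plateau(self):
        spec = ph.PhantomSpec(grid_shape=(12, 12, 8), mask_radius=(1e3, 1e3, 1e3))
        mag = ph.generate_magnitude(spec)
        assert np.all(mag.data == spec.plateau)

    def test_resection_core_is_dark(self, small_spec, small_magnitude):
        c = tuple(int(round(v)) for v in small_spec.resection.centre)
        assert small_magnitude.data[c] < 0.1 * small_magnitude.data.max()

    def test_nonnegative(self, small_magnitude):
        assert small_magnitude.data.min() >= 0.0


class TestPhaseNoise:
    def test_zero_variance_is_identity(self, small_truth):
        out = ph.add_phase_noise(small_truth, ph.NoiseSpec("phase_gaussian", variance=0.0, seed=1))
        assert np.array_equal(out.data, small_truth.data)

    def test_gaussian_mode_realises_requested_variance(self):
        """At the clinically measured level (variance 0.71 rad) the empirical
        per-voxel variance matches within 5% over >= 1e5 voxels."""
        spec = ph.default_spec()  # 64x64x32 = 131072 voxels
        truth = ph.generate_true_phase(spec)
        noisy = ph.add_phase_noise(truth, ph.NoiseSpec("phase_gaussian", variance=0.71, seed=0))
        v = float(np.var(noisy.data - truth.data))
        assert abs(v - 0.71) / 0.71 < 0.05

    def test_complex_channel_high_snr_matches_sigma_over_a(self):
        """In the high-SNR regime the angle noise is Gaussian with sd
        sigma/A."""
        A, sigma = 20.0, 1.0
        shape = (64, 64, 32)
        phase = PhaseVolume(np.zeros(shape))
        mag = ph.MagnitudeVolume(np.full(shape, A))
        out = ph.add_phase_noise(
            phase, ph.NoiseSpec("complex_channel", sigma_channel=sigma, seed=2), mag
        )
        sd = float(out.data.std())
        assert abs(sd - sigma / A) / (sigma / A) < 0.10

    def test_complex_channel_pure_noise_is_uniform(self):
        """With zero signal the phase is uniform on (-pi, pi]."""
        shape = (50, 50, 40)  # 1e5 samples
        phase = PhaseVolume(np.zeros(shape))
        mag = ph.MagnitudeVolume(np.zeros(shape))
        out = ph.add_phase_noise(
            phase, ph.NoiseSpec("complex_channel", sigma_channel=1.0, seed=3), mag
        )
        counts, _ = np.histogram(out.data, bins=20, range=(-np.pi, np.pi))
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_complex_channel_requires_magnitude(self, small_truth):
        with pytest.raises(ValueError, match="magnitude"):
            ph.add_phase_noise(small_truth, ph.NoiseSpec("complex_channel", sigma_channel=1.0))

    def test_determinism(self, small_truth):
        spec = ph.NoiseSpec("phase_gaussian", variance=0.2, seed=11)
        a = ph.add_phase_noise(small_truth, spec)
        b = ph.add_phase_noise(small_truth, spec)
        assert np.array_equal(a.data, b.data)


class TestEchoPair:
    def test_zero_field_gives_zero_phase(self):
        e1, e2 = ph.simulate_echo_pair(np.zeros((8, 8, 8)), 0.008, 0.010)
        assert np.all(e1.data == 0.0) and np.all(e2.data == 0.0)

    def test_full_cycle_wraps_to_zero(self):
        """500 Hz over dTE = 2 ms accrues exactly 2*pi: invisible."""
        e1, e2 = ph.simulate_echo_pair(np.full((6, 6, 6), 500.0), 0.008, 0.010)
        diff = wrap_to_principal(e2.data - e1.data)
        assert np.allclose(diff, 0.0, atol=1e-9)

    def test_100hz_gives_0p4pi(self):
        e1, e2 = ph.simulate_echo_pair(np.full((6, 6, 6), 100.0), 0.008, 0.010)
        diff = wrap_to_principal(e2.data - e1.data)
        assert np.allclose(diff, 0.4 * np.pi, atol=1e-9)

    def test_echo_order_validated(self):
        with pytest.raises(ValueError, match="te2 > te1"):
            ph.simulate_echo_pair(np.zeros((6, 6, 6)), 0.010, 0.008)


class TestDistortedEpi:
    def _blob(self, shape=(16, 24, 8)):
        x, y, z = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        c = [(n - 1) / 2 for n in shape]
        return np.exp(-((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) / 12.0)

    def test_zero_displacement_is_identity(self):
        img = self._blob()
        disp = DisplacementFieldPE(np.zeros(img.shape), pe_axis=1)
        out = ph.simulate_distorted_epi(img, disp)
        assert np.allclose(out, img, atol=1e-9)

    def test_constant_shift_translates(self):
        img = self._blob()
        disp = DisplacementFieldPE(np.full(img.shape, 2.0), pe_axis=1)
        out = ph.simulate_distorted_epi(img, disp)
        # signal from y appears at y + 2; interior agrees with a roll
        assert np.allclose(out[:, 4:-2, :], img[:, 2:-4, :], atol=1e-6)

    def test_linear_ramp_conserves_mass_with_jacobian(self):
        img = self._blob()
        y = np.arange(img.shape[1], dtype=float)
        ramp = 0.08 * (y - img.shape[1] / 2)  # |ddelta/dy| well below 1
        disp = DisplacementFieldPE(np.broadcast_to(ramp[None, :, None], img.shape).copy(), pe_axis=1)
        out = ph.simulate_distorted_epi(img, disp, modulate_jacobian=True)
        assert abs(out.sum() - img.sum()) / img.sum() < 0.01

    def test_shape_mismatch_rejected(self):
        img = self._blob()
        disp = DisplacementFieldPE(np.zeros((4, 4, 4)), pe_axis=1)
        with pytest.raises(ValueError, match="shape"):
            ph.simulate_distorted_epi(img, disp)
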