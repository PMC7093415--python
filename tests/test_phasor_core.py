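import numpy as np
import pytest
from hypothesis import given, strategies as st

from phasormix import (
    FLIMImage,
    CalibrationFactors,
    compute_phasor,
    calibrate,
    apply_calibration,
    bin_pixels,
    lifetime_from_phasor,
    fit_decay,
    theoretical_phasor,
)
from conftest import OMEGA, mono_decay


def phasor_of_hist(hist, period_ns=12.5):
    img = FLIMImage(counts=np.round(np.asarray(hist)).reshape(1, 1, -1),
                    n_time_bins=len(hist), repetition_period_ns=period_ns)
    p = compute_phasor(img)
    return float(p.g[0, 0]), float(p.s[0, 0])


class TestComputePhasor:
    def test_delta_decay_maps_to_zero_lifetime_point(self):
        # all photons in the first bin -> (G, S) -> (1, 0) as bin width -> 0
        hist = np.zeros(4096)
        hist[0] = 1e6
        g, s = phasor_of_hist(hist)
        assert g == pytest.approx(1.0, abs=1e-3)
        assert s == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("tau,expected", [
        (1.4, (0.6688, 0.4706)),   # tazarotene-like lifetime
        (0.45, (0.9513, 0.2152)),  # minocycline-like lifetime
    ])
    def test_dense_bin_monoexponential_matches_closed_form(self, tau, expected):
        g, s = phasor_of_hist(mono_decay(tau, n_bins=4096, photons=1e9))
        assert g == pytest.approx(expected[0], abs=1e-3)
        assert s == pytest.approx(expected[1], abs=1e-3)
        gt, st_ = theoretical_phasor(tau, OMEGA)
        assert (gt, st_) == (pytest.approx(expected[0], abs=1e-4),
                             pytest.approx(expected[1], abs=1e-4))

    def test_paper_scale_cube_geometry(self):
        counts = np.ones((8, 8, 256), dtype=np.uint16)
        img = FLIMImage(counts=counts, n_time_bins=256, repetition_period_ns=12.5)
        p = compute_phasor(img)
        assert img.n_time_bins == 256
        assert p.angular_frequency_per_ns == pytest.approx(2 * np.pi / 12.5)
        assert p.mask.all()

    def test_all_zero_image_warns_and_masks(self):
        img = FLIMImage(counts=np.zeros((3, 3, 16), dtype=np.uint16),
                        n_time_bins=16, repetition_period_ns=12.5)
        with pytest.warns(UserWarning, match="masked"):
            p = compute_phasor(img)
        assert not p.mask.any()

    def test_min_photons_threshold(self):
        counts = np.zeros((2, 2, 16), dtype=np.uint16)
        counts[0, 0, 0] = 500
        counts[0, 1, 0] = 10
        img = FLIMImage(counts=counts, n_time_bins=16, repetition_period_ns=12.5)
        p = compute_phasor(img, min_photons=100)
        assert p.mask[0, 0] and not p.mask[0, 1]

    def test_invariant_to_uniform_count_rescaling(self):
        h = np.round(mono_decay(1.0, n_bins=128, photons=1e4))
        g1, s1 = phasor_of_hist(h)
        g2, s2 = phasor_of_hist(10 * h)
        assert (g1, s1) == (pytest.approx(g2, abs=1e-9), pytest.approx(s2, abs=1e-9))

    @given(st.floats(0.2, 4.0), st.floats(0.2, 4.0), st.floats(0.05, 0.95))
    def test_linearity_of_summed_decays(self, tau_a, tau_b, w):
        # phasor of A+B equals the intensity-weighted mean of phasors of A, B
        ha = np.round(mono_decay(tau_a, n_bins=512, photons=1e6 * w))
        hb = np.round(mono_decay(tau_b, n_bins=512, photons=1e6 * (1 - w)))
        ga, sa = phasor_of_hist(ha)
        gb, sb = phasor_of_hist(hb)
        gm, sm = phasor_of_hist(ha + hb)
        ia, ib = ha.sum(), hb.sum()
        assert gm == pytest.approx((ia * ga + ib * gb) / (ia + ib), abs=1e-9)
        assert sm == pytest.approx((ia * sa + ib * sb) / (ia + ib), abs=1e-9)

    @given(st.floats(0.2, 5.0))
    def test_monoexponential_on_universal_semicircle(self, tau):
        g, s = phasor_of_hist(mono_decay(tau, n_bins=4096, photons=1e9))
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-3)


class TestCalibration:
    def _reference_image(self, tau=4.05, n_bins=256):
        hist = mono_decay(tau, n_bins=n_bins, photons=1e7)
        counts = np.tile(np.round(hist), (2, 2, 1))
        img = FLIMImage(counts=counts, n_time_bins=n_bins, repetition_period_ns=12.5)
        return compute_phasor(img)

    def test_reference_at_theoretical_point_yields_identity(self):
        gt, st_ = theoretical_phasor(4.05, OMEGA)
        from phasormix import PhasorImage
        p = PhasorImage(g=np.full((2, 2), gt), s=np.full((2, 2), st_),
                        intensity=np.ones((2, 2)), mask=np.ones((2, 2), bool),
                        angular_frequency_per_ns=OMEGA)
        c = calibrate(p, 4.05)
        assert c.phase_correction_rad == pytest.approx(0.0, abs=1e-12)
        assert c.modulation_correction == pytest.approx(1.0, abs=1e-12)

    def test_fluorescein_reference_round_trip(self):
        p = self._reference_image()
        c = calibrate(p, 4.05)
        # corrections are a discretization-only offset, close to identity
        assert abs(c.phase_correction_rad) < 0.05
        assert c.modulation_correction == pytest.approx(1.0, abs=0.05)
        cal = apply_calibration(p, c)
        z = np.mean(cal.g[cal.mask] + 1j * cal.s[cal.mask])
        gt, st_ = theoretical_phasor(4.05, OMEGA)
        assert z.real == pytest.approx(gt, abs=1e-12)
        assert z.imag == pytest.approx(st_, abs=1e-12)
        # calibrate o apply is idempotent on the reference
        c2 = calibrate(cal, 4.05)
        assert c2.phase_correction_rad == pytest.approx(0.0, abs=1e-9)
        assert c2.modulation_correction == pytest.approx(1.0, abs=1e-9)

    def test_forward_perturbation_inverted(self):
        p = self._reference_image()
        z = (p.g + 1j * p.s) * 0.9 * np.exp(1j * 0.1)
        from phasormix import PhasorImage
        pert = PhasorImage(g=z.real, s=z.imag, intensity=p.intensity, mask=p.mask,
                           angular_frequency_per_ns=p.angular_frequency_per_ns)
        c0 = calibrate(p, 4.05)
        c = calibrate(pert, 4.05)
        assert c.phase_correction_rad - c0.phase_correction_rad == pytest.approx(-0.1, abs=1e-9)
        assert c.modulation_correction / c0.modulation_correction == pytest.approx(1 / 0.9, rel=1e-9)

    def test_half_turn_factors(self):
        from phasormix import PhasorImage
        p = PhasorImage(g=np.array([[0.6]]), s=np.array([[0.3]]),
                        intensity=np.ones((1, 1)), mask=np.ones((1, 1), bool))
        out = apply_calibration(p, CalibrationFactors(4.05, np.pi, 1.0))
        assert out.g[0, 0] == pytest.approx(-0.6)
        assert out.s[0, 0] == pytest.approx(-0.3)

    def test_degenerate_reference_rejected(self):
        from phasormix import PhasorImage
        p = PhasorImage(g=np.zeros((2, 2)), s=np.zeros((2, 2)),
                        intensity=np.ones((2, 2)), mask=np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="degenerate reference"):
            calibrate(p, 4.05)


class TestBinPixels:
    def test_uniform_300_photons_block_gives_2700(self):
        counts = np.zeros((6, 6, 8), dtype=np.uint16)
        counts[..., 0] = 300
        img = FLIMImage(counts=counts, n_time_bins=8, repetition_period_ns=12.5)
        binned = bin_pixels(img, k=3, mode="block")
        assert binned.counts.shape == (2, 2, 8)
        assert (binned.counts.sum(axis=2) == 2700).all()

    def test_k1_is_identity(self, small_flim):
        out = bin_pixels(small_flim, k=1)
        np.testing.assert_array_equal(out.counts, small_flim.counts)

    def test_block_mode_conserves_photons(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, (9, 12, 16)).astype(np.uint16)
        img = FLIMImage(counts=counts, n_time_bins=16, repetition_period_ns=12.5)
        binned = bin_pixels(img, k=3, mode="block")
        assert binned.counts.sum() == counts.sum()

    def test_sliding_interior_equals_neighborhood_sum(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, (7, 7, 4)).astype(np.uint16)
        img = FLIMImage(counts=counts, n_time_bins=4, repetition_period_ns=12.5)
        out = bin_pixels(img, k=3, mode="sliding")
        assert out.counts.shape == counts.shape
        np.testing.assert_array_equal(
            out.counts[3, 3], counts[2:5, 2:5].sum(axis=(0, 1))
        )
        # edge pixel uses the available neighborhood only
        np.testing.assert_array_equal(
            out.counts[0, 0], counts[0:2, 0:2].sum(axis=(0, 1))
        )

    def test_even_k_rejected_in_sliding_mode(self, small_flim):
        with pytest.raises(ValueError, match="odd"):
            bin_pixels(small_flim, k=2, mode="sliding")


class TestLifetimeFromPhasor:
    def test_zero_lifetime_point(self):
        assert lifetime_from_phasor(1.0, 0.0, OMEGA) == (0.0, 0.0)

    def test_semicircle_apex(self):
        tp, tm = lifetime_from_phasor(0.5, 0.5, OMEGA)
        assert tp == pytest.approx(1.9894, abs=1e-4)
        assert tm == pytest.approx(1.9894, abs=1e-4)

    def test_fluorescein_inversion(self):
        g, s = theoretical_phasor(4.05, OMEGA)
        assert (g, s) == (pytest.approx(0.1944, abs=1e-4), pytest.approx(0.3957, abs=1e-4))
        tp, tm = lifetime_from_phasor(g, s, OMEGA)
        assert tp == pytest.approx(4.05, rel=1e-9)
        assert tm == pytest.approx(4.05, rel=1e-9)

    def test_undefined_inversions_flagged_nan(self):
        tp, tm = lifetime_from_phasor(-0.1, 0.3, OMEGA)
        assert np.isnan(tp)
        tp, tm = lifetime_from_phasor(0.9, 0.9, OMEGA)  # outside unit circle
        assert np.isnan(tm)


class TestFitDecay:
    def test_mono_recovery_within_one_percent(self):
        hist = mono_decay(2.0, n_bins=256, photons=1e6)
        fit = fit_decay(hist, n_components=1)
        assert fit.lifetimes_ns[0] == pytest.approx(2.0, rel=0.01)
        assert fit.mean_lifetime_ns == pytest.approx(2.0, rel=0.01)

    def test_double_recovery_within_five_percent(self):
        h = mono_decay(0.45, n_bins=256, photons=5e5) + mono_decay(1.4, n_bins=256, photons=5e5)
        fit = fit_decay(h, n_components=2)
        assert fit.n_components == 2
        assert fit.lifetimes_ns[0] == pytest.approx(0.45, rel=0.05)
        assert fit.lifetimes_ns[1] == pytest.approx(1.4, rel=0.05)
        assert list(fit.lifetimes_ns) == sorted(fit.lifetimes_ns)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="photons"):
            fit_decay(np.zeros(64), n_components=1)
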