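"""Reciprocal/real-space constraints, shrink-wrap schedules, OSS, trials."""

import numpy as np
import pytest

from steerpr.datatypes import DiffractionPattern, PhantomSpec, PhasingConfig
from steerpr.phasing import (
    autocorrelation,
    fourier_residual,
    gaussian_lowpass,
    hio_update,
    initial_support_from_autocorrelation,
    os_ratio,
    oss_eta_schedule,
    oss_update,
    reciprocal_constraint,
    run_trial,
    shrinkwrap_update,
    zeta_adaptive,
    zeta_schedule_ordinary,
)
from steerpr.simulate import forward_diffract, make_disk_aggregate


def brute_force_autocorrelation(rho):
    """Direct periodic correlation sum(rho(r) * rho(r + delta))."""
    m = rho.shape[0]
    ac = np.zeros((m, m))
    for dy in range(m):
        for dx in range(m):
            ac[dy, dx] = (rho * np.roll(rho, (-dy, -dx), axis=(0, 1))).sum()
    return ac


class TestAutocorrelation:
    def test_fft_route_matches_brute_force_8x8(self, rng):
        rho = rng.random((8, 8))
        pat = DiffractionPattern(
            np.abs(np.fft.fftshift(np.fft.fft2(rho))),
            np.ones((8, 8), bool),
        )
        ac = autocorrelation(pat)
        # autocorrelation() is centered: zero lag at (m/2, m/2)
        brute = np.fft.fftshift(brute_force_autocorrelation(rho))
        np.testing.assert_allclose(ac, brute, rtol=1e-8)

    def test_support_is_centrosymmetric_for_off_center_disk(self):
        rho = np.zeros((32, 32))
        rho[5:9, 20:24] = 1.0
        pat = forward_diffract(rho, 2)
        sup = initial_support_from_autocorrelation(pat, 0.04)
        mate = np.roll(sup[::-1, ::-1], 1, axis=(0, 1))
        np.testing.assert_array_equal(sup, mate)

    def test_zero_pattern_rejected(self):
        pat = DiffractionPattern(np.zeros((8, 8)), np.ones((8, 8), bool))
        with pytest.raises(ValueError):
            initial_support_from_autocorrelation(pat)


class TestReciprocalConstraint:
    def _pattern(self, amplitude, valid):
        return DiffractionPattern(np.array(amplitude, float), np.array(valid, bool))

    @pytest.mark.parametrize(
        "G, amp, valid, expected",
        [
            (1 + 0j, 2.0, True, 2 + 0j),  # phase kept
            (3 - 4j, 7.0, False, 3 - 4j),  # missing data float freely
            (3 - 4j, 10.0, True, 6 - 8j),  # rescaled to observed amplitude
            (0 + 0j, 5.0, True, 5 + 0j),  # zero-modulus convention: phase 0
        ],
    )
    def test_pointwise_cases(self, G, amp, valid, expected):
        pat = self._pattern([[amp, 1.0]], [[valid, True]])
        out = reciprocal_constraint(np.array([[G, 1 + 0j]]), pat)
        assert out[0, 0] == pytest.approx(expected)

    def test_idempotence(self, rng):
        G = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        amp = rng.random((16, 16))
        valid = rng.random((16, 16)) > 0.3
        valid[0, 0] = True
        pat = DiffractionPattern(amp, valid)
        once = reciprocal_constraint(G, pat)
        twice = reciprocal_constraint(once, pat)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_shape_mismatch(self, tiny_pattern):
        with pytest.raises(ValueError):
            reciprocal_constraint(np.zeros((4, 4), complex), tiny_pattern)


class TestHIOUpdate:
    def test_constraint_satisfying_pixel_passes(self):
        out = hio_update(
            np.array([[0.7]]), np.array([[0.3]]), np.array([[True]]), 0.9
        )
        assert out[0, 0] == pytest.approx(0.3)

    def test_outside_support_feedback(self):
        out = hio_update(
            np.array([[0.5]]), np.array([[0.2]]), np.array([[False]]), 0.9
        )
        assert out[0, 0] == pytest.approx(0.32)

    def test_negative_density_feedback_inside_support(self):
        out = hio_update(
            np.array([[0.4]]), np.array([[-0.1]]), np.array([[True]]), 0.9
        )
        assert out[0, 0] == pytest.approx(0.49)

    def test_feedback_branch_is_linear(self, rng):
        support = np.zeros((8, 8), bool)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        c, d = rng.random((8, 8)), rng.random((8, 8))
        lhs = hio_update(a + c, b + d, support, 0.9)
        rhs = hio_update(a, b, support, 0.9) + hio_update(c, d, support, 0.9)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestGaussianLowpassAndShrinkwrap:
    def test_mass_conservation(self, rng):
        v = rng.random((32, 32))
        out = gaussian_lowpass(v, 2.0)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-8)

    def test_constant_map_unchanged(self):
        v = np.full((16, 16), 3.3)
        np.testing.assert_allclose(gaussian_lowpass(v, 1.5), v, rtol=1e-10)

    def test_delta_input_matches_closed_form_kernel(self):
        m, zeta = 64, 2.0
        v = np.zeros((m, m))
        v[m // 2, m // 2] = 1.0
        out = gaussian_lowpass(v, zeta)
        # discrete unit-mass Gaussian: value at the center pixel
        x = np.arange(-4 * int(zeta), 4 * int(zeta) + 1)
        g = np.exp(-(x**2) / (2 * zeta**2))
        g /= g.sum()
        assert out[m // 2, m // 2] == pytest.approx(g[len(x) // 2] ** 2, abs=1e-6)

    def test_shrinkwrap_keeps_disk_interior(self):
        v = np.zeros((64, 64))
        rr, cc = np.indices((64, 64))
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 8**2
        v[disk] = 1.0
        sup = shrinkwrap_update(v, zeta=0.9, threshold_frac=0.04)
        assert sup[disk].all()

    def test_delta_support_radius_matches_gaussian_level_set(self):
        m, zeta, frac = 64, 2.0, 0.04
        v = np.zeros((m, m))
        v[m // 2, m // 2] = 1.0
        sup = shrinkwrap_update(v, zeta, frac)
        # blurred delta is a radial Gaussian; the 4% level set has radius
        # zeta * sqrt(2 ln(1/0.04))
        r_expect = zeta * np.sqrt(2 * np.log(1 / frac))
        rr, cc = np.indices((m, m))
        r = np.hypot(rr - m // 2, cc - m // 2)
        assert sup[r <= r_expect - 0.8].all()
        assert not sup[(r > r_expect + 0.8) & (r < 3 * r_expect)].any()

    def test_degenerate_map_rejected(self):
        with pytest.raises(ValueError):
            shrinkwrap_update(np.zeros((8, 8)), 1.0)


class TestZetaSchedules:
    def test_ordinary_schedule(self):
        cfg = PhasingConfig()
        assert zeta_schedule_ordinary(1, cfg) == pytest.approx(2.0)
        assert zeta_schedule_ordinary(2, cfg) == pytest.approx(1.98)
        assert zeta_schedule_ordinary(1000, cfg) == pytest.approx(0.9)
        vals = [zeta_schedule_ordinary(h, cfg) for h in range(1, 200)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_adaptive_truth_table(self):
        cfg = PhasingConfig()
        # large OS-ratio change keeps the wide blur
        assert zeta_adaptive(False, 10.0, 7.0, cfg) == (2.0, False)
        # small change drops to the floor and latches
        assert zeta_adaptive(False, 7.0, 6.5, cfg) == (0.9, True)
        # latched stays latched whatever happens
        assert zeta_adaptive(True, 7.0, 70.0, cfg) == (0.9, True)
        # no previous ratio: stay wide by definition
        assert zeta_adaptive(False, None, 5.0, cfg) == (2.0, False)
        # change of exactly the threshold stays wide
        assert zeta_adaptive(False, 6.0, 4.0, cfg) == (2.0, False)

    def test_latch_is_permanent_along_a_trajectory(self, rng):
        cfg = PhasingConfig()
        latched, prev = False, None
        seen_low = False
        for now in rng.uniform(1, 50, size=100):
            zeta, latched = zeta_adaptive(latched, prev, now, cfg)
            prev = now
            if seen_low:
                assert zeta == cfg.zeta_low
            seen_low = seen_low or zeta == cfg.zeta_low


class TestOSRatio:
    def test_full_field_support(self):
        assert os_ratio(np.ones((8, 8), bool)) == 1.0

    def test_direct_division(self):
        sup = np.zeros((128, 128), bool)
        sup.ravel()[:4096] = True
        assert os_ratio(sup) == pytest.approx(4.0)

    def test_halving_area_doubles_ratio(self):
        sup = np.zeros((32, 32), bool)
        sup.ravel()[:256] = True
        half = sup.copy()
        half.ravel()[:128] = [True] * 128
        half.ravel()[128:256] = False
        assert os_ratio(half) == pytest.approx(2 * os_ratio(sup))

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            os_ratio(np.zeros((4, 4), bool))


class TestOSS:
    def test_full_support_equals_hio(self, rng):
        rho_k = rng.normal(size=(16, 16))
        rho_p = rng.normal(size=(16, 16))
        support = np.ones((16, 16), bool)
        np.testing.assert_allclose(
            oss_update(rho_k, rho_p, support, 0.9, 3.0),
            hio_update(rho_k, rho_p, support, 0.9),
            atol=1e-12,
        )

    def test_huge_eta_approaches_plain_hio(self, rng):
        rho_k = rng.normal(size=(16, 16))
        rho_p = rng.normal(size=(16, 16))
        support = rng.random((16, 16)) > 0.5
        out = oss_update(rho_k, rho_p, support, 0.9, 1e6)
        np.testing.assert_allclose(
            out, hio_update(rho_k, rho_p, support, 0.9), rtol=1e-6, atol=1e-8
        )

    def test_small_eta_reduces_out_of_support_high_frequency_power(self, rng):
        rho_k = rng.normal(size=(32, 32))
        rho_p = rng.normal(size=(32, 32))
        support = np.zeros((32, 32), bool)
        support[12:20, 12:20] = True
        hio = hio_update(rho_k, rho_p, support, 0.9)
        oss = oss_update(rho_k, rho_p, support, 0.9, eta=2.0)

        def hf_var(x):
            F = np.fft.fftshift(np.fft.fft2(x))
            rr, cc = np.indices(x.shape)
            hf = np.hypot(rr - 16, cc - 16) > 8
            return (np.abs(F[hf]) ** 2).sum()

        assert hf_var(np.where(support, 0, oss)) < hf_var(np.where(support, 0, hio))

    def test_eta_schedule_endpoints_and_blocks(self):
        m = 128
        assert oss_eta_schedule(0, 10000, m) == pytest.approx(m)
        assert oss_eta_schedule(9999, 10000, m) == pytest.approx(1 / m)
        values = sorted(
            {oss_eta_schedule(c, 10000, m) for c in range(0, 10000, 500)},
            reverse=True,
        )
        assert len(values) == 10
        steps = np.diff(values)
        np.testing.assert_allclose(steps, -(m - 1 / m) / 9, rtol=1e-12)


class TestRunTrial:
    def test_same_seed_is_bit_identical(self, tiny_pattern):
        cfg = PhasingConfig(n_cycles=300, sw_period=100)
        a = run_trial(tiny_pattern, cfg, "ordinary", seed=5, snapshot_cycles=[150])
        b = run_trial(tiny_pattern, cfg, "ordinary", seed=5, snapshot_cycles=[150])
        np.testing.assert_array_equal(a.final_map, b.final_map)
        np.testing.assert_array_equal(a.snapshots[150], b.snapshots[150])
        np.testing.assert_array_equal(a.final_support, b.final_support)

    def test_residual_decreases_in_most_seeds(self, tiny_pattern):
        cfg = PhasingConfig(n_cycles=200, sw_period=100)
        wins = 0
        for seed in range(10):
            h = run_trial(
                tiny_pattern, cfg, "ordinary", seed,
                snapshot_cycles=[1, 200], track_residuals=True,
            )
            if h.residuals[200] < h.residuals[1]:
                wins += 1
        assert wins >= 8

    def test_oss_mode_requires_support(self, tiny_pattern):
        cfg = PhasingConfig(n_cycles=100)
        with pytest.raises(ValueError):
            run_trial(tiny_pattern, cfg, "oss", seed=0)

    def test_oss_trial_runs_with_given_support(self, tiny_pattern):
        cfg = PhasingConfig(n_cycles=1000, sw_period=100)
        sup = initial_support_from_autocorrelation(tiny_pattern)
        h = run_trial(tiny_pattern, cfg, "oss", seed=0, initial_support=sup)
        assert not h.failed
        np.testing.assert_array_equal(h.final_support, sup)

    def test_unknown_mode_rejected(self, tiny_pattern):
        with pytest.raises(ValueError):
            run_trial(tiny_pattern, PhasingConfig(n_cycles=10), "emc", 0)
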