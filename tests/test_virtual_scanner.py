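"""Bloch oracles, trajectories, reconstruction and parameter recovery."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from mrforge._units import BLOCK_RASTER_NS, GAMMA_HZ_PER_T, ceil_to_raster
from mrforge.hardware_events import ADCEvent, ExecutionBlock, GradientEvent
from mrforge.sequence_library import walsh_hadamard_8
from mrforge.virtual_scanner import (
    RigidTransform,
    VirtualPhantom,
    _resample,
    bloch_simulate,
    estimate_gradient_delay,
    fit_adc,
    grid_reconstruct,
    hadamard_decode,
    hadamard_encode,
    kspace_trajectory,
    mean_voxel_displacement,
    motion_correction_demo,
    radial_density,
    rigid_register,
    shepp_logan_like,
    simulate_radial_echoes,
)
from mrforge.waveforms import make_rf, make_slice_select, make_trapezoid, radial_directions


def _uniform_phantom(n, off_hz=None, spacing=1.0):
    return VirtualPhantom(
        pd=np.ones(n), t1_ms=np.full(n, 1e9), t2_ms=np.full(n, 1e9),
        off_hz=np.zeros(n) if off_hz is None else off_hz,
        d_mm2_s=np.zeros(n), spacing_mm=(spacing,),
    )


class TestBlochOracles:
    def test_hard_90_saturates_mz(self):
        ph = _uniform_phantom(1)
        rf = make_rf("hard", 1.0, 90.0)
        blk = ExecutionBlock(duration=1_000_000, rf=rf)
        _, m = bloch_simulate([blk], ph, return_magnetization=True)
        assert np.hypot(m[0, 0], m[0, 1]) == pytest.approx(1.0, abs=1e-6)
        assert abs(m[0, 2]) < 1e-6

    def test_spin_echo_rephases_offresonance(self):
        """90-tau-180-tau: at 2tau the off-resonance phase dispersion is
        refocused (all isochromats aligned)."""
        from mrforge._units import HardwareLimits

        limits = HardwareLimits(b1_max=300.0)  # short hard pulses
        offs = np.linspace(-200, 200, 21)
        ph = _uniform_phantom(21, off_hz=offs)
        rf90 = make_rf("hard", 0.05, 90.0, limits=limits)
        rf180 = replace(make_rf("hard", 0.05, 180.0, limits=limits), use="refocus",
                        phase_offset=math.pi / 2)
        tau = 5_000_000
        b1 = ExecutionBlock(duration=tau, rf=rf90)
        # block ends exactly at the echo: center90 + 2*tau
        b2 = ExecutionBlock(duration=tau + rf180.center, rf=rf180)
        _, m = bloch_simulate([b1, b2], ph, return_magnetization=True)
        phases = np.arctan2(m[:, 1], m[:, 0])
        spread = np.angle(np.exp(1j * (phases - phases.mean())))
        assert np.abs(spread).max() < 0.02
        assert np.hypot(m[:, 0], m[:, 1]).min() > 0.999

    def test_small_tip_slice_profile_fwhm(self):
        """Sinc TBW-4 excitation: simulated |Mxy(z)| FWHM within 5% of the
        nominal thickness, and consistent with the Fourier small-tip
        oracle."""
        rf = make_rf("sinc", 2.56, 10.0, time_bandwidth=4)
        grad, _ = make_slice_select(rf, 5.0)
        grad = replace(grad, axis="READ")  # 1D phantom lies along axis 0
        rf = replace(rf, start=grad.rise + (grad.flat - rf.duration) // 2)
        n = 241
        ph = _uniform_phantom(n, spacing=12.0 / n)
        blk = ExecutionBlock(duration=0, rf=rf, gradients=(grad,))
        blk = replace(blk, duration=ceil_to_raster(blk.events_end(), BLOCK_RASTER_NS))
        _, m = bloch_simulate([blk], ph, return_magnetization=True)
        prof = np.hypot(m[:, 0], m[:, 1])
        pos = ph.positions_m()[:, 0] * 1e3
        above = np.where(prof >= prof.max() / 2)[0]
        fwhm = pos[above[-1]] - pos[above[0]]
        assert abs(fwhm - 5.0) / 5.0 < 0.05
        # Fourier oracle: FT of the envelope mapped through gamma*G
        env = np.array(rf.envelope).real
        f = np.linspace(-3000, 3000, 1201)
        ft = np.abs([(env * np.exp(-2j * np.pi * fi * np.arange(len(env)) * 1e-6)).sum()
                     for fi in f])
        ab = np.where(ft >= ft.max() / 2)[0]
        fwhm_ft = (f[ab[-1]] - f[ab[0]]) / (GAMMA_HZ_PER_T * grad.amplitude * 1e-3) * 1e3
        assert fwhm == pytest.approx(fwhm_ft, rel=0.03)


class TestTrajectory:
    def test_zero_gradients_zero_k(self):
        blk = ExecutionBlock(duration=1_000_000,
                             adc=ADCEvent(start=0, samples=16, dwell=10_000))
        (adc, k), = kspace_trajectory([blk])
        assert np.allclose(k, 0)

    def test_prephased_readout_crosses_zero_at_center(self):
        rf = make_rf("hard", 0.1, 10.0)
        pre = make_trapezoid("READ", area=-5.5)  # -(rise/2+flat/2)*G
        ro = GradientEvent(axis="READ", start=0, amplitude=10.0,
                           rise=100_000, flat=1_000_000, fall=100_000)
        t0 = rf.duration
        blk = ExecutionBlock(
            duration=0, rf=rf,
            gradients=(replace(pre, start=t0),
                       replace(ro, start=t0 + pre.duration)),
            adc=ADCEvent(start=t0 + pre.duration + ro.rise, samples=100, dwell=10_000))
        blk = replace(blk, duration=ceil_to_raster(blk.events_end(), BLOCK_RASTER_NS))
        (adc, k), = kspace_trajectory([blk])
        kx = k[:, 0]
        assert kx[0] < 0 < kx[-1]
        crossing = np.interp(0, kx, np.arange(len(kx)))
        assert crossing == pytest.approx(49.5, abs=1.0)  # flat center

    def test_ute_ramp_samples_follow_quadratic_integral(self):
        rf = make_rf("hard", 0.1, 10.0)
        ro = GradientEvent(axis="READ", start=rf.duration, amplitude=18.0,
                           rise=120_000, flat=400_000, fall=120_000)
        blk = ExecutionBlock(duration=0, rf=rf, gradients=(ro,),
                             adc=ADCEvent(start=rf.duration, samples=60, dwell=2_000))
        blk = replace(blk, duration=ceil_to_raster(blk.events_end(), BLOCK_RASTER_NS))
        (adc, k), = kspace_trajectory([blk])
        t = adc.sample_times() - ro.start
        on_ramp = t < ro.rise
        expect = GAMMA_HZ_PER_T * (18.0e-3) * (t[on_ramp] * 1e-9) ** 2 / (2 * ro.rise * 1e-9)
        assert np.allclose(k[on_ramp, 0], expect, rtol=1e-9)


class TestGridding:
    def _cartesian(self, n=32, fov=128.0, seed=1):
        ph = shepp_logan_like((n, n), spacing_mm=fov / n, seed=seed)
        ks = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(ph.pd)))
        kx = (np.arange(n) - n // 2) / (fov * 1e-3)
        gx, gy = np.meshgrid(kx, kx, indexing="ij")
        traj = np.stack([gx.ravel(), gy.ravel()], axis=1)
        return ks, traj, n, fov

    def test_cartesian_gridding_matches_fft(self):
        ks, traj, n, fov = self._cartesian()
        rec = grid_reconstruct(ks.ravel(), traj, (n, n), (fov, fov))
        ref = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(ks)))
        nrmse = np.linalg.norm(np.abs(rec) - np.abs(ref)) / np.linalg.norm(np.abs(ref))
        assert nrmse < 0.01

    def test_single_dc_sample_flat_image(self):
        rec = grid_reconstruct(np.array([2.0 + 0j]), np.zeros((1, 2)),
                               (16, 16), (64.0, 64.0))
        v = np.abs(rec)
        assert v.std() / v.mean() < 1e-12
        rec2 = grid_reconstruct(np.array([4.0 + 0j]), np.zeros((1, 2)),
                                (16, 16), (64.0, 64.0))
        assert np.abs(rec2).mean() == pytest.approx(2 * v.mean(), rel=1e-12)

    def test_radial_disk_interior_uniform(self):
        """Fully sampled radial acquisition of an analytic disk: interior
        intensity uniform within 5% after density compensation."""
        from scipy.special import j1

        n, fov, radius = 64, 256.0, 0.05
        nspokes, ns = 101, 65
        ang = np.pi * np.arange(nspokes) / nspokes
        kmax = (n / 2) / (fov * 1e-3)
        kr = np.linspace(-kmax, kmax, ns)
        traj = np.stack([np.outer(np.cos(ang), kr).ravel(),
                         np.outer(np.sin(ang), kr).ravel()], axis=1)
        r = np.linalg.norm(traj, axis=1)
        samples = np.where(r > 0, radius * j1(2 * np.pi * r * radius) / np.maximum(r, 1e-12),
                           np.pi * radius**2)
        rec = grid_reconstruct(samples, traj, (n, n), (fov, fov),
                               density=radial_density(traj))
        xs = (np.arange(n) - n // 2) * fov / n * 1e-3
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        interior = np.hypot(xx, yy) < 0.7 * radius
        mag = np.abs(rec)
        assert mag[interior].std() / mag[interior].mean() < 0.05

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_reconstruct(np.array([]), np.zeros((0, 2)), (8, 8), (64.0, 64.0))


class TestGradientDelay:
    DIRS = radial_directions(540, "calibration_planes", 180)

    def _run(self, delays, offset=(5.0, -3.0, 2.0), seed=2):
        echoes = simulate_radial_echoes(self.DIRS, delays, noise_std=0.002,
                                        object_offset_mm=offset, seed=seed)
        return estimate_gradient_delay(echoes, self.DIRS, 5_000, 10.0, 0.35)

    def test_zero_delay_recovered_within_half_dwell(self):
        est = self._run((0.0, 0.0, 0.0), offset=(0, 0, 0))
        assert np.abs(est).max() < 2.5  # half the 5 us dwell

    def test_uniform_10us_recovered_within_1us(self):
        est = self._run((10.0, 10.0, 10.0))
        assert np.abs(est - 10.0).max() < 1.0

    def test_axis_specific_delay_isolated(self):
        est = self._run((10.0, 0.0, 0.0))
        assert abs(est[0] - 10.0) < 1.0
        assert np.abs(est[1:]).max() < 1.0


class TestFitADC:
    def test_noiseless_two_point_exact(self):
        s0 = np.full((4, 4), 2.0)
        b = 600.0
        d_true = 0.8e-3
        vols = [[s0], [s0 * np.exp(-b * d_true)]]
        d, s0_fit = fit_adc(vols, [0.0, b])
        assert np.allclose(d, d_true, rtol=1e-12)
        assert np.allclose(s0_fit, 2.0, rtol=1e-12)

    def test_known_truth_recovery_at_snr_50(self):
        """Synthetic phantom with white-matter-like D = 0.80e-3 mm^2/s,
        b = [0, 300, 600], SNR 50: mean recovered D within 2%."""
        ph = shepp_logan_like((24, 24), seed=5)
        rng = np.random.default_rng(6)
        bvals = [0.0, 300.0, 600.0]
        vols = []
        for b in bvals:
            clean = ph.pd * np.exp(-b * ph.d_mm2_s)
            noise = clean.max() / 50
            vols.append([np.abs(clean + noise * rng.standard_normal(clean.shape))
                         for _ in range(3)])
        d, _ = fit_adc(vols, bvals)
        mask = (ph.pd > 0.5) & (ph.d_mm2_s > 0)
        assert d[mask].mean() == pytest.approx(ph.d_mm2_s[mask].mean(), rel=0.02)

    def test_single_b_value_rejected(self):
        with pytest.raises(ValueError, match="two distinct"):
            fit_adc([[np.ones((2, 2))]], [0.0])


class TestHadamardDecode:
    H = walsh_hadamard_8()

    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(7)
        sub = [rng.uniform(0, 0.02, (8, 8)) for _ in range(7)]
        enc = hadamard_encode(np.ones((8, 8)), sub, self.H)
        dec = hadamard_decode(enc, self.H)
        assert len(dec) == 7
        for d, s in zip(dec, sub):
            assert np.allclose(d, s, atol=1e-14)

    def test_identical_volumes_decode_to_zero(self):
        dec = hadamard_decode([np.ones((4, 4))] * 8, self.H)
        assert all(np.allclose(d, 0) for d in dec)

    def test_wrong_volume_count(self):
        with pytest.raises(ValueError, match="expected 8"):
            hadamard_decode([np.ones((2, 2))] * 5, self.H)

    def test_noise_propagation_sigma_over_sqrt2(self):
        """i.i.d. noise sigma per volume gives per-subbolus noise of
        sigma/sqrt(2) (Monte-Carlo variance-propagation oracle)."""
        rng = np.random.default_rng(11)
        sigma = 1.0
        pooled = []
        for _ in range(300):
            vols = [sigma * rng.standard_normal((4, 4)) for _ in range(8)]
            pooled.extend(np.ravel(hadamard_decode(vols, self.H)[2]))
        assert np.std(pooled) == pytest.approx(sigma / math.sqrt(2), rel=0.05)


@pytest.fixture(scope="module")
def reg_volume():
    vol = shepp_logan_like((24, 24, 24), spacing_mm=4.0, seed=8).pd
    return ndimage.gaussian_filter(vol, 1.0)


@pytest.fixture(scope="module")
def moco_volume():
    vol = shepp_logan_like((16, 16, 16), spacing_mm=4.0, seed=9).pd
    return ndimage.gaussian_filter(vol, 1.0)


class TestRegistration:

    def test_identity(self, reg_volume):
        tf = rigid_register(reg_volume, reg_volume, 4.0)
        assert np.abs(tf.translation_mm).max() < 0.01
        assert np.abs(tf.rotation_deg).max() < 0.01

    def test_known_translation_within_0p1mm(self, reg_volume):
        true = RigidTransform((0, 0, 0), (3.0, 0, 0))
        moved = _resample(reg_volume, true, (4, 4, 4))
        tf = rigid_register(moved, reg_volume, 4.0)
        assert np.abs(np.array(tf.translation_mm)
                      - np.array(true.inverse().translation_mm)).max() < 0.1

    def test_known_rotation_within_0p1deg(self, reg_volume):
        true = RigidTransform((0, 0, 2.0), (0, 0, 0))
        moved = _resample(reg_volume, true, (4, 4, 4))
        tf = rigid_register(moved, reg_volume, 4.0)
        assert np.abs(np.array(tf.rotation_deg)
                      - np.array(true.inverse().rotation_deg)).max() < 0.1


class TestMeanVoxelDisplacement:
    MASK = np.ones((8, 8, 8), dtype=bool)

    def test_identity_zero(self):
        assert mean_voxel_displacement(RigidTransform(), self.MASK, 4.0) == 0.0

    def test_pure_translation_norm_identity(self):
        tf = RigidTransform((0, 0, 0), (1.0, 2.0, 2.0))
        assert mean_voxel_displacement(tf, self.MASK, 4.0) == pytest.approx(3.0)
        half = np.zeros((8, 8, 8), bool)
        half[:4] = True  # any mask gives the same value for pure translation
        assert mean_voxel_displacement(tf, half, 4.0) == pytest.approx(3.0)

    def test_small_rotation_matches_cross_product(self):
        """MVD of a small rotation about the centroid equals the analytic
        mean ||omega x r|| within 1%."""
        angle = 0.5  # deg about z
        tf = RigidTransform((0, 0, angle), (0, 0, 0))
        got = mean_voxel_displacement(tf, self.MASK, 4.0)
        omega = math.radians(angle)
        idx = np.argwhere(self.MASK).astype(float)
        pts = (idx - 3.5) * 4.0
        expected = np.mean(omega * np.hypot(pts[:, 0], pts[:, 1]))
        assert got == pytest.approx(expected, rel=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_voxel_displacement(RigidTransform(), np.zeros((4, 4), bool), 1.0)


class TestMotionCorrectionDemo:

    def test_static_phantom_arms_identical(self, moco_volume):
        rep = motion_correction_demo(moco_volume, lambda v: RigidTransform(),
                                     n_volumes=3, spacing_mm=4.0)
        assert rep.uncorrected_mvd_mm == rep.corrected_mvd_mm
        assert rep.mean_corrected == 0.0

    def test_step_displacement_realigned_after_latency(self, moco_volume):
        step = RigidTransform((0, 0, 0), (3.0, 0, 0))
        rep = motion_correction_demo(
            moco_volume, lambda v: step if v >= 2 else RigidTransform(),
            n_volumes=6, spacing_mm=4.0)
        # the step hits volume 2; with one volume of feedback latency every
        # volume from 3 onward is realigned within registration tolerance
        assert all(m < 0.15 for m in rep.corrected_mvd_mm[3:])
        assert rep.corrected_mvd_mm[2] == pytest.approx(3.0, abs=0.1)
        assert all(m == pytest.approx(3.0, abs=0.1)
                   for m in rep.uncorrected_mvd_mm[2:])
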