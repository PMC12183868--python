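"""Z-spectrum processing, B0 correction and ratiometric pH mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acidmri.cest import (
    ZSpectrum,
    compute_ph_map,
    delta_st,
    interpolate_b0_correct,
    normalize_zspectrum,
    ratiometric_ph,
    st_contrast,
)
from acidmri.config import AcquisitionConfig, CalibrationModel
from acidmri.synthetic import (
    AGENT_HWHM,
    MT_AMP,
    MT_HWHM,
    WATER_AMP,
    WATER_HWHM,
    PhantomSpec,
    make_phantom,
    simulate_cest_study,
    simulate_zspectrum,
    _agent_amplitudes,
)


def _lorentzian(x, hwhm):
    return hwhm**2 / (hwhm**2 + np.asarray(x, float) ** 2)


class TestNormalize:
    def test_flat_and_zero_and_arithmetic(self):
        z = normalize_zspectrum(np.array([100.0, 100.0]), np.array([-1.0, 1.0]), 100.0)
        assert np.all(z.signal == 1.0)
        z = normalize_zspectrum(np.array([90.0, 45.0]), np.array([-1.0, 1.0]), 100.0)
        assert np.allclose(z.signal, [0.90, 0.45])
        z = normalize_zspectrum(np.array([0.0, 50.0]), np.array([-1.0, 1.0]), 100.0)
        assert z.signal[0] == 0.0

    @pytest.mark.parametrize("s0", [0.0, -5.0, np.nan])
    def test_degenerate_reference_rejected(self, s0):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_zspectrum(np.array([1.0, 2.0]), np.array([-1.0, 1.0]), s0)

    def test_st_invariant_under_joint_rescaling(self, acq, cal):
        z = simulate_zspectrum(6.7, True, acq, cal)
        for scale in (0.5, 7.3):
            z2 = normalize_zspectrum(z.signal * 100.0 * scale, z.offsets, 100.0 * scale)
            assert st_contrast(z2, 4.2) == pytest.approx(st_contrast(z, 4.2), abs=1e-12)


class TestB0Correction:
    def test_centered_spectrum_has_zero_shift(self, symmetric_acq, cal):
        z = simulate_zspectrum(6.7, False, symmetric_acq, cal)
        res = interpolate_b0_correct(z)
        assert res.reliable
        assert abs(res.shift_ppm) < 0.01
        assert np.allclose(res.corrected.signal, z.signal, atol=1e-3)

    @pytest.mark.parametrize("true_shift", [0.2, -0.2, 0.35])
    def test_injected_shift_recovered(self, acq, cal, true_shift):
        z = simulate_zspectrum(6.7, False, acq, cal, b0_shift=true_shift)
        res = interpolate_b0_correct(z)
        assert res.reliable
        assert res.shift_ppm == pytest.approx(true_shift, abs=0.01)

    def test_pure_noise_spectrum_flagged_unreliable(self, acq):
        rng = np.random.default_rng(0)
        # flat spectrum + noise has no water line; minimum can sit anywhere,
        # and a boundary minimum must be flagged. Use a tilted flat spectrum
        # whose minimum is forced to the window edge.
        signal = 1.0 - 0.01 * acq.sat_offsets / 10.0
        z = ZSpectrum(offsets=acq.sat_offsets, signal=signal + rng.normal(0, 1e-4, 46))
        res = interpolate_b0_correct(z)
        assert not res.reliable

    def test_idempotent_correction(self, acq, cal):
        z = simulate_zspectrum(6.7, True, acq, cal, b0_shift=0.3,
                               noise_sigma=0.003, seed=5)
        first = interpolate_b0_correct(z)
        second = interpolate_b0_correct(first.corrected)
        # re-correcting an already corrected spectrum finds ~no residual shift
        assert abs(second.shift_ppm) < 0.025  # grid spacing / 10 near water

    def test_too_few_offsets_rejected(self):
        z = ZSpectrum(offsets=np.linspace(-2, 2, 5), signal=np.ones(5))
        with pytest.raises(ValueError, match=">= 7 offsets"):
            interpolate_b0_correct(z)


class TestSTContrast:
    def test_extreme_z_values(self):
        offsets = np.linspace(-10, 10, 46)
        z1 = ZSpectrum(offsets=offsets, signal=np.ones(46))
        assert st_contrast(z1, 4.2) == pytest.approx(0.0, abs=1e-9)
        z0 = ZSpectrum(offsets=offsets, signal=np.zeros(46))
        assert st_contrast(z0, 4.2) == pytest.approx(1.0, abs=1e-9)

    def test_matches_analytic_lorentzian_on_fine_grid(self):
        # single agent pool of amplitude 0.15 at 4.2 ppm, no other lines
        offsets = np.linspace(-10.0, 10.0, 401)
        signal = 1.0 - 0.15 * _lorentzian(offsets - 4.2, AGENT_HWHM)
        z = ZSpectrum(offsets=offsets, signal=signal)
        assert st_contrast(z, 4.2) == pytest.approx(0.15, abs=1e-4)

    def test_full_forward_model_matches_analytic_within_1e4(self, cal):
        # oracle equivalence: fine-grid noiseless spectrum, spline ST at the
        # agent offsets vs direct closed-form evaluation of the line model
        acq_fine = AcquisitionConfig(sat_offsets=np.linspace(-10, 10, 401))
        ph = 6.65
        z = simulate_zspectrum(ph, True, acq_fine, cal)
        a1, a2 = _agent_amplitudes(np.array([ph]), acq_fine, cal, 0.10)
        for off in (4.2, 5.5):
            analytic = (WATER_AMP * _lorentzian(off, WATER_HWHM)
                        + MT_AMP * _lorentzian(off, MT_HWHM)
                        + a1[0] * _lorentzian(off - 4.2, AGENT_HWHM)
                        + a2[0] * _lorentzian(off - 5.5, AGENT_HWHM))
            assert st_contrast(z, off) == pytest.approx(analytic, abs=1e-4)

    def test_out_of_range_offset_rejected(self):
        z = ZSpectrum(offsets=np.linspace(-5, 5, 11), signal=np.ones(11))
        with pytest.raises(ValueError, match="outside sampled range"):
            st_contrast(z, 8.0)


class TestDeltaST:
    def test_identity_and_arithmetic_and_linearity(self):
        pre = np.array([0.05, 0.10])
        assert np.all(delta_st(pre, pre) == 0.0)
        assert delta_st(np.array([0.05]), np.array([0.20]))[0] == pytest.approx(0.15)
        post = np.array([0.2, 0.3])
        c = 0.07
        assert np.allclose(delta_st(pre, post + c), delta_st(pre, post) + c)

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError, match="geometry"):
            delta_st(np.zeros(3), np.zeros(4))


class TestRatiometric:
    def test_unit_ratio_reads_p0(self, cal):
        ph, flag = ratiometric_ph(0.05, 0.05, cal)
        assert ph == pytest.approx(cal.p0)
        assert flag == "valid"

    def test_closed_form_inverse(self):
        cal = CalibrationModel(p0=6.9, p1=0.8)
        ph, flag = ratiometric_ph(0.5623 * 0.05, 0.05, cal)
        assert ph == pytest.approx(6.9 + 0.8 * np.log10(0.5623), abs=1e-6)
        assert ph == pytest.approx(6.70, abs=1e-3)

    def test_out_of_range_clamped_and_flagged(self):
        cal = CalibrationModel(p0=6.9, p1=1.5)
        # ratio large enough to push pH past 7.4
        ph, flag = ratiometric_ph(0.10, 0.04, cal)
        assert ph == 7.4
        assert flag == "clamped"

    def test_below_detectability_invalid(self, cal):
        ph, flag = ratiometric_ph(0.001, 0.05, cal)
        assert flag == "invalid" and np.isnan(ph)
        ph, flag = ratiometric_ph(0.05, -0.01, cal)
        assert flag == "invalid"

    @given(d1=st.floats(0.01, 0.5), delta=st.floats(0.001, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_numerator(self, d1, delta):
        cal = CalibrationModel()
        d2 = 0.08
        lo, _ = ratiometric_ph(d1, d2, cal)
        hi, _ = ratiometric_ph(d1 + delta, d2, cal)
        assert hi >= lo  # clamping makes it weakly monotone


class TestComputePhMap:
    def test_noisy_phantom_accuracy_and_validity(self, acq, cal):
        spec = PhantomSpec(ph_mean=6.72, seed=1)  # defaults: sd 0.10, noise 0.5%
        p = make_phantom(spec)
        study = simulate_cest_study(p, acq, cal, seed=2)
        ph_map, st_maps, qc = compute_ph_map(
            study.pre, study.post, study.s0_pre, study.s0_post,
            p.tumor_mask, acq, cal)
        err = np.abs(ph_map.ph[ph_map.valid_mask] - p.ph_truth[ph_map.valid_mask])
        assert err.mean() < 0.05
        assert qc.n_invalid / qc.n_mask_voxels < 0.10
        # validity mask is a subset of the tumor mask
        assert not np.any(ph_map.valid_mask & ~p.tumor_mask)
        # valid voxels lie in the calibration range
        vals = ph_map.ph[ph_map.valid_mask]
        assert vals.min() >= 6.0 and vals.max() <= 7.4

    def test_geometry_preserved_for_8_slice_stack(self, acq, cal):
        spec = PhantomSpec(grid_shape=(16, 16, 8), radii=(4.0, 4.0, 3.0),
                           ph_sd=0.0, b0_sd=0.0, noise_sigma=0.0, seed=0)
        p = make_phantom(spec)
        study = simulate_cest_study(p, acq, cal, seed=0)
        geometry = {"voxel_size_mm": [0.234, 0.234, 1.5]}
        ph_map, _, _ = compute_ph_map(study.pre, study.post, study.s0_pre,
                                      study.s0_post, p.tumor_mask, acq, cal,
                                      geometry=geometry)
        assert ph_map.ph.shape == (16, 16, 8)
        assert ph_map.geometry == geometry

    def test_empty_mask_rejected(self, acq, cal):
        shape = (8, 8, 2)
        with pytest.raises(ValueError, match="empty"):
            compute_ph_map(np.ones(shape + (46,)), np.ones(shape + (46,)),
                           np.ones(shape), np.ones(shape),
                           np.zeros(shape, bool), acq, cal)

    def test_bad_reference_voxels_counted_not_fatal(self, acq, cal):
        spec = PhantomSpec(grid_shape=(12, 12, 3), radii=(3.0, 3.0, 1.0),
                           ph_sd=0.0, b0_sd=0.0, noise_sigma=0.0, seed=0)
        p = make_phantom(spec)
        study = simulate_cest_study(p, acq, cal, seed=0)
        idx = tuple(np.argwhere(p.tumor_mask)[0])
        study.s0_pre[idx] = 0.0
        _, _, qc = compute_ph_map(study.pre, study.post, study.s0_pre,
                                  study.s0_post, p.tumor_mask, acq, cal)
        assert qc.n_bad_reference == 1
        assert qc.n_valid == qc.n_mask_voxels - 1
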