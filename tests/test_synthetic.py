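"""Synthetic generators: signals, DTD families, noise, phantom, cohort,
texture images."""

import numpy as np
import pytest

from cortiq.btensor import build_protocol_scheme, make_shape_btensor
from cortiq.qti import dtd_moments
from cortiq.synthetic import (
    DiffusionTensorDistribution,
    EffectConfig,
    PhantomConfig,
    add_rician_noise,
    build_cohort,
    dtd_signal,
    make_cortex_phantom,
    make_dtd,
    make_histology_image,
    simulate_dwi,
    watson_directions,
)

SMALL_PHANTOM = PhantomConfig(n_sticks=10, n_depth_bins=12)


class TestDtdSignal:
    def test_single_isotropic_closed_form(self):
        dtd = DiffusionTensorDistribution(1.2 * np.eye(3)[None], np.ones(1))
        b = make_shape_btensor("spherical", 1500.0)
        s = dtd_signal(dtd, b.matrix / 1000.0, S0=2.0)
        assert s == pytest.approx(2.0 * np.exp(-1.5 * 1.2))

    def test_b0_returns_s0(self, rng):
        dtd = make_dtd("cortex", dict(f_aniso=0.4), rng)
        assert dtd_signal(dtd, np.zeros((3, 3)), S0=3.7) == pytest.approx(3.7)

    def test_two_tensor_mixture_value(self):
        dtd = make_dtd("iso_spheres", dict(diffusivities=(1.0, 3.0)))
        s = dtd_signal(dtd, np.eye(3) / 3.0, S0=1.0)
        assert s == pytest.approx(0.5 * (np.exp(-1) + np.exp(-3)))
        assert s == pytest.approx(0.2089, abs=1e-4)

    def test_unit_mismatch_flagged(self, rng):
        dtd = make_dtd("cortex", dict(), rng)
        with pytest.raises(ValueError, match="ms/um"):
            dtd_signal(dtd, np.eye(3) * 700.0)  # s/mm^2 passed unconverted

    def test_monotone_in_b(self, rng):
        dtd = make_dtd("cortex", dict(f_aniso=0.5, kappa=8), rng)
        n = np.array([0.6, 0.0, 0.8])
        prev = np.inf
        for b in (0.0, 0.2, 0.7, 1.4, 2.0):
            bt = b * np.outer(n, n)
            s = dtd_signal(dtd, bt)
            assert s <= prev + 1e-12
            prev = s


class TestMakeDtd:
    def test_infinite_kappa_collapses(self, rng):
        dtd = make_dtd(
            "watson_sticks",
            dict(ad=2.0, rd=0.2, kappa=np.inf, n=20), rng,
        )
        assert np.allclose(dtd.tensors, dtd.tensors[0])
        _, _, m = dtd_moments(dtd)
        assert float(m.CC) == pytest.approx(1.0)

    def test_isotropic_family_zero_ufa(self):
        dtd = make_dtd("iso_spheres", dict(diffusivities=(1.0, 3.0)))
        _, _, m = dtd_moments(dtd)
        assert float(m.uFA) == pytest.approx(0.0, abs=1e-12)

    def test_ufa_invariant_fa_decreasing_in_dispersion(self, rng):
        """uFA depends only on the compartment shape; FA of the mean
        tensor collapses as orientations disperse."""
        ufas, fas = [], []
        for kappa in (np.inf, 8.0, 2.0, 0.0):
            dtd = make_dtd(
                "watson_sticks",
                dict(ad=2.0, rd=0.2, kappa=kappa, n=3000),
                np.random.default_rng(11),
            )
            _, _, m = dtd_moments(dtd)
            ufas.append(float(m.uFA))
            fas.append(float(m.FA))
        assert np.ptp(ufas) < 1e-9
        assert all(a > b for a, b in zip(fas, fas[1:]))

    def test_negative_kappa_rejected(self, rng):
        with pytest.raises(ValueError, match="kappa"):
            watson_directions((0, 0, 1), -1.0, 10, rng)

    def test_eigenvalue_bound_enforced(self, rng):
        with pytest.raises(ValueError, match="outside"):
            make_dtd("watson_sticks", dict(ad=3.5, rd=0.2), rng)


class TestRicianNoise:
    def test_sigma_zero_identity(self, rng):
        s = np.linspace(0, 1, 50)
        assert np.array_equal(add_rician_noise(s, 0.0, rng), s)

    def test_rayleigh_mean_at_zero_signal(self):
        rng = np.random.default_rng(7)
        noisy = add_rician_noise(np.zeros(10**6), 1.0, rng)
        assert noisy.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=0.01)

    def test_high_snr_limit(self):
        rng = np.random.default_rng(8)
        s = 50.0
        noisy = add_rician_noise(np.full(10**5, s), 1.0, rng)
        assert abs(noisy.mean() - s) / s < 1e-3

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -0.1, rng)


class TestCortexPhantom:
    def test_geometry_and_truth_maps(self, rng):
        ph = make_cortex_phantom(SMALL_PHANTOM, rng=rng)
        inside = ph.cortex_mask
        assert inside.sum() > 50
        assert np.all((ph.depth[inside] >= 0) & (ph.depth[inside] <= 1))
        assert np.all(np.isfinite(ph.truth["uFA"][inside]))
        assert not ph.lesion_mask.any()  # control carries no lesion

    def test_lesion_inside_cortex_and_reduces_ufa(self, rng):
        eff = EffectConfig(
            s_range=(0.3, 0.7), d_range=(0.3, 0.7), f_aniso_scale=0.5
        )
        ph = make_cortex_phantom(
            SMALL_PHANTOM, group="treated", effect=eff, rng=rng, jitter=False
        )
        ctrl = make_cortex_phantom(
            SMALL_PHANTOM, group="control", rng=rng, jitter=False
        )
        assert ph.lesion_mask.any()
        assert np.all(ph.cortex_mask[ph.lesion_mask])
        diff = ctrl.truth["uFA"] - ph.truth["uFA"]
        assert np.nanmean(diff[ph.lesion_mask]) > 0.01
        outside = ph.cortex_mask & ~ph.lesion_mask
        assert np.nanmax(np.abs(diff[outside])) < 1e-12

    def test_ufa_delta_effect_hits_target(self, rng):
        eff = EffectConfig(
            s_range=(0.2, 0.8), d_range=(0.3, 0.7), uFA_delta=0.05
        )
        ph_t = make_cortex_phantom(
            SMALL_PHANTOM, group="treated", effect=eff, rng=rng, jitter=False
        )
        ph_c = make_cortex_phantom(SMALL_PHANTOM, rng=rng, jitter=False)
        diff = ph_c.truth["uFA"] - ph_t.truth["uFA"]
        assert np.nanmean(diff[ph_t.lesion_mask]) == pytest.approx(
            0.05, abs=0.005
        )


class TestCohort:
    def test_null_effect_no_noise_identical_groups(self):
        cfg = PhantomConfig(
            n_sticks=8, n_depth_bins=8, jitter_amplitude=0.0
        )
        scheme = build_protocol_scheme()
        rng = np.random.default_rng(0)
        subjects = build_cohort(cfg, 2, 2, None, scheme, 0.0, rng)
        sig = [s.dwi.signal for s in subjects]
        for other in sig[1:]:
            assert np.allclose(sig[0], other)

    def test_fixed_seed_bit_reproducible(self):
        cfg = PhantomConfig(n_sticks=6, n_depth_bins=6)
        scheme = build_protocol_scheme()
        a = build_cohort(cfg, 2, 2, None, scheme, 1 / 30.0,
                         np.random.default_rng(99))
        b = build_cohort(cfg, 2, 2, None, scheme, 1 / 30.0,
                         np.random.default_rng(99))
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.dwi.signal, sb.dwi.signal)
            assert np.array_equal(sa.boundaries.pial, sb.boundaries.pial)

    def test_single_subject_group_rejected(self):
        scheme = build_protocol_scheme()
        with pytest.raises(ValueError, match="at least 2"):
            build_cohort(SMALL_PHANTOM, 1, 5, None, scheme, 0.0,
                         np.random.default_rng(0))

    def test_signal_nonnegative_and_matches_scheme(self, rng):
        scheme = build_protocol_scheme()
        ph = make_cortex_phantom(SMALL_PHANTOM, rng=rng)
        dwi = simulate_dwi(ph, scheme, sigma=1 / 20.0, rng=rng)
        assert dwi.signal.shape[-1] == len(scheme)
        assert np.all(dwi.signal >= 0)


class TestHistologyImages:
    def test_stripes_ground_truth_orientation(self, rng):
        img, truth = make_histology_image(
            "stripes", dict(angle_deg=30.0, orientation_jitter_deg=0.0), rng
        )
        assert np.allclose(truth["orientation_deg"], 30.0)
        assert img.shape == (256, 256)

    def test_blob_fraction_close_to_target(self, rng):
        _, truth = make_histology_image(
            "blobs", dict(area_fraction=0.15), rng
        )
        assert truth["area_fraction"] == pytest.approx(0.15, abs=0.01)

    def test_unknown_pattern_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown texture"):
            make_histology_image("plaid", None, rng)
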