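"""Synthetic cohort generator: spectral, mechanistic and calibration contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from gboldcsf import SimulationConfig
from gboldcsf._utils import zscore
from gboldcsf.simulate import (
    generate_csf_signal,
    generate_global_signal,
    generate_lesion_mask,
    generate_motion,
    generate_subject,
    generate_wab_cohort,
    make_phantom_labels,
    simulate_coupling_table,
)


class TestGlobalSignal:
    def test_zero_mean_unit_variance(self, rng):
        u = generate_global_signal(SimulationConfig(), rng)
        assert u.size == 185
        assert abs(u.mean()) < 1e-12
        assert abs(u.std() - 1) < 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_band_power_fraction_across_seeds(self, seed):
        """Periodogram oracle: >= 90% of spectral power inside the passband."""
        cfg = SimulationConfig(seed=seed)
        u = generate_global_signal(cfg, np.random.default_rng(seed))
        f, p = periodogram(u, fs=1.0 / cfg.tr_s)
        band = (f >= cfg.band_hz[0]) & (f <= cfg.band_hz[1])
        assert p[band].sum() / p.sum() >= 0.9

    def test_spectral_peak_near_f0(self, rng):
        cfg = SimulationConfig()
        u = generate_global_signal(cfg, rng)
        f, p = periodogram(u, fs=1.0 / cfg.tr_s)
        df = f[1] - f[0]
        assert abs(f[p.argmax()] - cfg.f0_hz) <= df

    def test_pure_mode_is_sinusoid_up_to_phase(self, rng):
        cfg = SimulationConfig(spectral_width_hz=0.0)
        u = generate_global_signal(cfg, rng)
        t = np.arange(cfg.n_timepoints) * cfg.tr_s
        # project onto the f0 quadrature pair; residual should vanish
        basis = np.column_stack(
            [np.ones_like(t),
             np.sin(2 * np.pi * cfg.f0_hz * t), np.cos(2 * np.pi * cfg.f0_hz * t)]
        )
        beta, *_ = np.linalg.lstsq(basis, u, rcond=None)
        assert np.abs(u - basis @ beta).max() < 1e-10

    def test_determinism(self):
        cfg = SimulationConfig()
        u1 = generate_global_signal(cfg, np.random.default_rng(1))
        u2 = generate_global_signal(cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(u1, u2)

    def test_too_short_for_band_resolution(self, rng):
        cfg = SimulationConfig(n_timepoints=10)
        with pytest.raises(ValueError, match="too short"):
            generate_global_signal(cfg, rng)


class TestCsfSignal:
    def test_sine_gives_shifted_cosine(self, rng):
        """Closed form: u = sin(2 pi t / 16) drives c proportional to -cos."""
        t = np.arange(400) * 2.0
        u = np.sin(2 * np.pi * t / 16.0)
        c = generate_csf_signal(u, kappa=1.0, noise_sd=0.0, rng=rng, tr_s=2.0)
        target = -np.cos(2 * np.pi * t / 16.0)
        r = np.corrcoef(c, target)[0, 1]
        assert r > 0.999

    def test_no_coupling_limit_is_constant(self, rng):
        u = np.sin(np.linspace(0, 6, 50))
        c = generate_csf_signal(u, kappa=0.0, noise_sd=0.0, rng=rng, baseline=100.0)
        np.testing.assert_allclose(c, 100.0)

    def test_noiseless_corr_with_negative_derivative_is_one(self, rng):
        cfg = SimulationConfig()
        u = generate_global_signal(cfg, rng)
        c = generate_csf_signal(u, kappa=1.0, noise_sd=0.0, rng=rng, tr_s=cfg.tr_s)
        d = -np.gradient(u, cfg.tr_s)
        assert np.corrcoef(c, d)[0, 1] > 1 - 1e-12

    def test_moderate_noise_keeps_high_corr(self, rng):
        cfg = SimulationConfig()
        u = generate_global_signal(cfg, rng)
        c = generate_csf_signal(u, kappa=1.0, noise_sd=0.3, rng=rng, tr_s=cfg.tr_s)
        d = -np.gradient(u, cfg.tr_s)
        assert np.corrcoef(c, d)[0, 1] > 0.9

    def test_negative_kappa_rejected(self, rng):
        with pytest.raises(ValueError, match="kappa"):
            generate_csf_signal(np.ones(10), kappa=-0.5, noise_sd=0.0, rng=rng)

    def test_positive_signal(self, rng):
        cfg = SimulationConfig()
        u = generate_global_signal(cfg, rng)
        c = generate_csf_signal(u, kappa=1.0, noise_sd=2.5, rng=rng)
        assert (c > 0).all()


class TestGeometry:
    def test_lesion_mask_left_hemisphere_only(self, small_config):
        for seed in range(5):
            mask = generate_lesion_mask(small_config, np.random.default_rng(seed))
            nx = small_config.grid_dims[0]
            assert mask.sum() > 0
            assert not mask[nx // 2 :, :, :].any()

    def test_zero_radius_gives_empty_mask(self, small_config, rng):
        mask = generate_lesion_mask(small_config, rng, radius_mm=0.0)
        assert mask.sum() == 0

    def test_hc_labels_have_no_lesion(self, small_config, rng):
        labels = make_phantom_labels(small_config, rng, with_lesion=False)
        assert not labels.mask("lesion").any()

    def test_classes_disjoint_and_csf_on_bottom_slice(self, small_config, rng):
        labels = make_phantom_labels(small_config, rng, with_lesion=True)
        lab = labels.label_volume
        csf = labels.mask("CSF_bottom")
        assert csf.any() and not csf[:, :, 1:].any()
        for name in ("GM_LN", "GM_SN", "GM_DAN", "GM_DMN"):
            assert labels.mask(name).any()
        # integer labels partition the grid by construction
        assert set(np.unique(lab)) <= set(labels.class_map.values())

    def test_lesion_inside_left_gm_wm(self, small_config):
        labels = make_phantom_labels(
            small_config, np.random.default_rng(2), with_lesion=True
        )
        lesion = labels.mask("lesion")
        nx = small_config.grid_dims[0]
        assert lesion.any()
        assert not lesion[nx // 2 :, :, :].any()


class TestSubject:
    def test_degenerate_phantom_gm_equals_global_signal(self, clean_subject):
        cfg, vol, labels, motion = clean_subject
        gm = labels.gm_mask()
        series = vol.data[gm]
        # all GM voxels carry identical affine copies of u(t)
        z = zscore(series, axis=1)
        np.testing.assert_allclose(z - z[0], 0.0, atol=1e-10)
        assert np.allclose(motion.params, 0.0)

    def test_unknown_condition_rejected(self, small_config, rng):
        with pytest.raises(ValueError, match="condition"):
            generate_subject(small_config, "PSA_followup", rng)

    def test_seeded_regeneration_is_bit_identical(self, small_config, tmp_path):
        from gboldcsf.io import write_nifti

        vols = []
        for _ in range(2):
            vol, _, _ = generate_subject(
                small_config, "HC", np.random.default_rng(99)
            )
            vols.append(vol)
        np.testing.assert_array_equal(vols[0].data, vols[1].data)
        p1 = write_nifti(tmp_path / "a.nii.gz", vols[0])
        p2 = write_nifti(tmp_path / "b.nii.gz", vols[1])
        import gzip

        assert gzip.open(p1).read() == gzip.open(p2).read()

    def test_motion_amplitude_scaling(self, small_config, rng):
        m = generate_motion(small_config, rng)
        assert m.params.shape == (small_config.n_timepoints, 6)
        np.testing.assert_allclose(
            m.params[:, :3].std(axis=0), small_config.motion_amp_mm, rtol=1e-6
        )


class TestWabCohort:
    @staticmethod
    def _delta_table(n, rng):
        return pd.DataFrame(
            {
                "subject_id": [f"sub-{i:04d}" for i in range(n)],
                **{f"delta_{net}": rng.standard_normal(n) * 0.1
                   for net in ("LN", "SN", "DAN", "DMN")},
            }
        )

    def test_null_configuration_mean_change_near_zero(self):
        rng = np.random.default_rng(21)
        cfg = SimulationConfig(
            behavior_effects={k: 0.0 for k in SimulationConfig().behavior_effects},
            assoc_r={"LN": 0.0, "SN": 0.0, "DAN": 0.0, "DMN": 0.0},
        )
        tab = generate_wab_cohort(cfg, self._delta_table(200, rng), rng)
        diff = tab["object_naming_post"] - tab["object_naming_pre"]
        assert abs(diff.mean() / diff.std()) < 0.15

    def test_effect_size_calibration(self):
        """Monte-Carlo check: realized d within 0.15 of the configured 1.35."""
        rng = np.random.default_rng(22)
        cfg = SimulationConfig()
        assert cfg.behavior_effects["object_naming"] == 1.35
        tab = generate_wab_cohort(cfg, self._delta_table(200, rng), rng)
        diff = tab["object_naming_post"] - tab["object_naming_pre"]
        d = diff.mean() / diff.std()
        assert abs(d - 1.35) < 0.15

    def test_association_calibration(self):
        """Realized corr(delta score, delta coupling) near the -0.543 target."""
        rng = np.random.default_rng(23)
        cfg = SimulationConfig()
        delta = self._delta_table(200, rng)
        tab = generate_wab_cohort(cfg, delta, rng)
        diff = (tab["object_naming_post"] - tab["object_naming_pre"]).to_numpy()
        r = np.corrcoef(diff, delta["delta_LN"])[0, 1]
        assert abs(r - (-0.543)) < 0.1

    def test_scores_respect_maxima(self, rng):
        from gboldcsf.config import WAB_SUBTESTS

        cfg = SimulationConfig()
        tab = generate_wab_cohort(cfg, self._delta_table(100, rng), rng)
        for sub, info in WAB_SUBTESTS.items():
            for col in (f"{sub}_pre", f"{sub}_post"):
                assert (tab[col] >= 0).all() and (tab[col] <= info["max"]).all()

    def test_duplicate_subjects_rejected(self, rng):
        tab = self._delta_table(4, rng)
        tab.loc[1, "subject_id"] = tab.loc[0, "subject_id"]
        with pytest.raises(ValueError, match="duplicate"):
            generate_wab_cohort(SimulationConfig(), tab, rng)

    def test_infeasible_association_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationConfig(assoc_r={"LN": -1.0, "SN": 0.0, "DAN": 0.0, "DMN": 0.0})


class TestCouplingTable:
    def test_structure_and_determinism(self):
        cfg = SimulationConfig(n_hc=6, n_psa=5, n_treated=3, seed=9)
        t1 = simulate_coupling_table(cfg)
        t2 = simulate_coupling_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1.query("condition == 'HC'").shape[0] == 6)
        assert (t1.query("condition == 'PSA_pre'").shape[0] == 5)
        assert (t1.query("condition == 'PSA_post'").shape[0] == 3)
        assert (t1.query("group == 'HC'")["lesion_volume_mm3"] == 0).all()
        assert (t1.query("group == 'PSA'")["lesion_volume_mm3"] > 0).all()

    def test_condition_means_follow_config(self):
        cfg = SimulationConfig(n_hc=400, n_psa=400, n_treated=400, seed=10)
        tab = simulate_coupling_table(cfg)
        for cond, mu in cfg.coupling_mean.items():
            got = tab.query("condition == @cond")["coupling"].mean()
            assert abs(got - mu) < 0.015
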