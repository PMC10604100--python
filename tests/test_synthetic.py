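"""Synthetic generators: seed determinism, concentration conservation,
photon statistics, TCSPC mixtures and movie ground-truth bookkeeping."""

import numpy as np
import pytest

from zmwell import (
    ALEXA488,
    NanowellGeometry,
    SimConfig,
    emit_photon_trace,
    make_cell_movie,
    make_layout,
    make_optics_profiles,
    make_tcspc,
    simulate_nanowell_diffusion,
)
from zmwell.optics import evanescent_decay_length
from zmwell.synthetic import DiffusionRun, PropagatingApertureError


class TestOpticsProfiles:
    def test_deterministic(self):
        geom = NanowellGeometry(diameter=140.0, overmill_depth=100.0)
        e1, m1 = make_optics_profiles(geom, ALEXA488, dz_nm=20.0)
        e2, m2 = make_optics_profiles(geom, ALEXA488, dz_nm=20.0)
        assert np.array_equal(e1.intensity, e2.intensity)
        assert np.array_equal(m1.p_total, m2.p_total)

    def test_aperture_decay_matches_closed_form(self):
        geom = NanowellGeometry(diameter=100.0, overmill_depth=100.0)
        exc, _ = make_optics_profiles(geom, ALEXA488, dz_nm=5.0)
        lam = evanescent_decay_length(100.0, ALEXA488.excitation_nm, 1.33)
        inside = (exc.z_nm >= 0) & (exc.z_nm <= 100.0)
        z_in = exc.z_nm[inside]
        i_in = exc.intensity[inside]
        expected = i_in[0] * np.exp(-(z_in - z_in[0]) / lam)
        assert np.allclose(i_in, expected, rtol=1e-9)

    def test_propagating_aperture_flagged(self):
        geom = NanowellGeometry(diameter=280.0, overmill_depth=100.0)
        with pytest.raises(PropagatingApertureError):
            make_optics_profiles(geom, ALEXA488)
        exc, _ = make_optics_profiles(
            geom, ALEXA488, dz_nm=20.0, if_propagating="uniform"
        )
        assert "propagating" in exc.mode

    def test_free_space_limit_far_below_metal(self):
        geom = NanowellGeometry(diameter=140.0, overmill_depth=100.0)
        _, emi = make_optics_profiles(geom, ALEXA488, dz_nm=10.0)
        # far from the film the emission power approaches free space
        far = emi.z_nm < -80.0
        assert np.abs(emi.p_total[far] - 1.0).max() < 0.5


class TestDiffusion:
    def test_seed_determinism(self, well_geometry):
        cfg = SimConfig(seed=3, duration_s=0.05)
        r1 = simulate_nanowell_diffusion(well_geometry, cfg)
        r2 = simulate_nanowell_diffusion(well_geometry, cfg)
        assert np.array_equal(r1.z_nm, r2.z_nm)

    def test_occupancy_matches_concentration(self, well_geometry):
        """Grand-canonical contract: ensemble-mean pore count = c N_A V
        within 3 SE over seeds."""
        occ = []
        for s in range(6):
            run = simulate_nanowell_diffusion(
                well_geometry, SimConfig(seed=s, duration_s=0.25)
            )
            occ.append(run.occupancy())
        expected = run.expected_occupancy()
        se = np.std(occ, ddof=1) / np.sqrt(len(occ))
        assert abs(np.mean(occ) - expected) < 3 * se + 0.05

    def test_zero_concentration_empty(self, well_geometry):
        cfg = SimConfig(seed=1, duration_s=0.01, concentration_molar=0.0)
        run = simulate_nanowell_diffusion(well_geometry, cfg)
        assert run.n_particles == 0
        trace = emit_photon_trace(run)
        assert trace.counts.sum() == 0

    def test_doubling_concentration_doubles_count(self, well_geometry):
        n1 = [
            simulate_nanowell_diffusion(
                well_geometry,
                SimConfig(seed=s, duration_s=0.01, concentration_molar=0.5e-6),
            ).n_particles
            for s in range(8)
        ]
        n2 = [
            simulate_nanowell_diffusion(
                well_geometry,
                SimConfig(seed=100 + s, duration_s=0.01,
                          concentration_molar=1.0e-6),
            ).n_particles
            for s in range(8)
        ]
        assert np.mean(n2) / np.mean(n1) == pytest.approx(2.0, rel=0.25)

    def test_large_step_warns(self):
        geom = NanowellGeometry(diameter=100.0, overmill_depth=100.0)
        with pytest.warns(UserWarning, match="RMS step"):
            simulate_nanowell_diffusion(
                geom, SimConfig(seed=0, duration_s=0.005, time_step_us=1.0)
            )
        with pytest.raises(ValueError):
            simulate_nanowell_diffusion(
                geom,
                SimConfig(seed=0, duration_s=0.005, time_step_us=1.0,
                          strict_step=True),
            )


class TestPhotonTrace:
    def test_poisson_statistics_constant_rate(self, well_geometry):
        """An immobile particle (D = 0) in the pore gives Poisson counts:
        variance/mean ~ 1."""
        cfg = SimConfig(seed=2, duration_s=0.2, diffusion_um2_s=1e-6,
                        concentration_molar=2e-6)
        run = simulate_nanowell_diffusion(well_geometry, cfg)
        trace = emit_photon_trace(run)
        m = trace.counts.mean()
        if m > 0:
            fano = trace.counts.var() / m
            assert fano == pytest.approx(1.0, abs=0.05)

    def test_rate_scales_with_brightness(self, short_run):
        import dataclasses

        t1 = emit_photon_trace(short_run)
        cfg2 = dataclasses.replace(short_run.config, brightness_cpms=60.0)
        t2 = emit_photon_trace(short_run, config=cfg2)
        assert t2.counts.mean() / max(t1.counts.mean(), 1e-9) == pytest.approx(
            2.0, rel=0.05
        )

    def test_leak_brightness_adds_background(self, short_run):
        import dataclasses

        cfg = dataclasses.replace(short_run.config, leak_brightness=0.5)
        t_leak = emit_photon_trace(short_run, config=cfg)
        t_clean = emit_photon_trace(short_run)
        assert t_leak.counts.mean() > t_clean.counts.mean()


class TestTcspcGenerator:
    def test_narrow_irf_histogram_mean_is_tau(self):
        decay = make_tcspc([(3.0, 1.0)], irf_fwhm_ps=1e-3, n_photons=400_000,
                           bin_ps=25.0, window_ns=60.0, irf_center_ns=2.0,
                           seed=4)
        t = decay.t_ns
        mean_t = (t * decay.counts).sum() / decay.counts.sum() - 2.0
        assert mean_t == pytest.approx(3.0, rel=0.02)

    def test_mixture_mean(self):
        decay = make_tcspc([(1.0, 0.5), (5.0, 0.5)], irf_fwhm_ps=1e-3,
                           n_photons=400_000, window_ns=80.0,
                           irf_center_ns=1.0, seed=5)
        t = decay.t_ns
        mean_t = (t * decay.counts).sum() / decay.counts.sum() - 1.0
        assert mean_t == pytest.approx(3.0, rel=0.03)

    def test_seed_reproducibility(self):
        d1 = make_tcspc(ALEXA488, n_photons=50_000, seed=7)
        d2 = make_tcspc(ALEXA488, n_photons=50_000, seed=7)
        assert np.array_equal(d1.counts, d2.counts)

    def test_wide_bin_warns(self):
        with pytest.warns(UserWarning, match="bin width"):
            make_tcspc([(0.04, 1.0)], bin_ps=25.0, n_photons=1000, seed=0)


class TestCellMovie:
    def test_truth_fractions_exact(self):
        layout = make_layout()
        cfg = SimConfig(seed=9, covered_fraction=0.75, high_fraction=0.5)
        mov = make_cell_movie(layout, cfg, n_frames=5)
        truth = mov["truth"]
        n = len(truth)
        assert truth["covered"].sum() == round(0.75 * n)
        n_cov = truth["covered"].sum()
        assert (truth["population"] == "high").sum() == round(0.5 * n_cov)

    def test_spikes_only_on_high_pores(self):
        layout = make_layout()
        mov = make_cell_movie(layout, SimConfig(seed=2), n_frames=20)
        has_spike = mov["spike_states"].any(axis=1)
        is_high = (mov["truth"]["population"] == "high").to_numpy()
        assert np.all(~has_spike | is_high)

    def test_zero_cells_all_negative(self):
        layout = make_layout()
        mov = make_cell_movie(
            layout, SimConfig(seed=1, covered_fraction=0.0), n_frames=5
        )
        assert (mov["truth"]["population"] == "negative").all()

    def test_seed_determinism(self):
        layout = make_layout()
        m1 = make_cell_movie(layout, SimConfig(seed=6), n_frames=4)
        m2 = make_cell_movie(layout, SimConfig(seed=6), n_frames=4)
        assert np.array_equal(m1["channel1"], m2["channel1"])
        assert np.array_equal(m1["brightfield"], m2["brightfield"])

    def test_overlapping_pores_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_layout(pitch_px=2.0, diameters_nm=(280.0,), pixel_nm=100.0)


def test_diffusion_run_realized_concentration(short_run):
    c = short_run.realized_concentration_molar
    assert c == pytest.approx(short_run.config.concentration_molar, rel=0.5)
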