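"""Generator tests: structure geometry, two-state kinetics, rendering,
exchange rounds, fiducials and drift."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from paintbench import siggen
from paintbench.siggen import (
    SimulationConfig,
    EmitterTrace,
    make_filament,
    make_npc,
    make_origami_grid,
    render_localizations,
    simulate_blinking,
    simulate_exchange_experiment,
    add_fiducials_and_drift,
)


def _nn_distances(sites):
    d, _ = cKDTree(sites).query(sites, k=2)
    return d[:, 1]


class TestStructures:
    @pytest.mark.parametrize(
        "rows, cols, pitch, n_expected, nn_expected",
        [(4, 3, 15.0, 12, 15.0), (1, 2, 5.0, 2, 5.0)],
    )
    def test_grid_site_count_and_spacing(self, rows, cols, pitch, n_expected, nn_expected):
        g = make_origami_grid(rows, cols, pitch)
        assert g.n_sites == n_expected
        assert np.allclose(_nn_distances(g.sites[:, :2]), nn_expected)
        assert np.allclose(g.sites[:, 2], 0.0)
        assert np.allclose(g.sites.mean(axis=0), 0.0)  # centered at origin

    def test_single_site_grid_is_origin(self):
        g = make_origami_grid(1, 1, 15.0)
        assert g.n_sites == 1
        assert np.allclose(g.sites, 0.0)

    def test_grid_rejects_bad_pitch(self):
        with pytest.raises(ValueError):
            make_origami_grid(2, 2, 0.0)

    def test_npc_two_rings_of_corner_pairs(self):
        npc = make_npc()
        assert npc.n_sites == 32
        z_levels = np.unique(npc.sites[:, 2])
        assert len(z_levels) == 2
        assert z_levels[1] - z_levels[0] == pytest.approx(50.0)
        # within-pair distance is the pair spacing by construction
        per_ring = 16
        for ring in (npc.sites[:32][npc.sites[:, 2] < 0], npc.sites[npc.sites[:, 2] > 0]):
            pairs = np.linalg.norm(ring[:8, :2] - ring[8:16, :2], axis=1)
            assert np.allclose(pairs, 14.3)
            assert len(ring) == per_ring

    def test_npc_zero_pair_spacing_collapses_corners(self):
        npc = make_npc(pair_spacing=0.0)
        top = npc.sites[npc.sites[:, 2] > 0][:, :2]
        assert len(np.unique(np.round(top, 9), axis=0)) == 8

    def test_npc_rejects_odd_copthan_count(self):
        with pytest.raises(ValueError):
            make_npc(copies_per_ring=15)

    def test_filament_sites_on_cylinder_surface(self, rng):
        f = make_filament(2000.0, 15.0, 100.0, rng=rng)
        assert np.allclose(np.hypot(f.sites[:, 1], f.sites[:, 2]), 15.0)

    def test_short_filament_is_nearly_planar(self, rng):
        f = make_filament(1e-6, 15.0, 1e10, rng=rng)
        assert f.n_sites > 0
        assert np.allclose(f.sites[:, 0], 0.0, atol=1e-6)

    def test_filament_zero_density_warns_and_is_empty(self, rng):
        with pytest.warns(UserWarning, match="empty filament"):
            f = make_filament(1000.0, 15.0, 0.0, rng=rng)
        assert f.n_sites == 0

    def test_filament_site_count_is_poisson(self, rng):
        counts = [make_filament(1000.0, 15.0, 1000.0, rng=rng).n_sites for _ in range(60)]
        mean = np.mean(counts)
        assert abs(mean - 1000.0) < 3.0 * np.sqrt(1000.0 / 60.0)
        assert np.var(counts) == pytest.approx(1000.0, rel=0.5)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"exposure_time": 0.0},
            {"k_on": -1.0},
            {"n_frames": 0},
            {"labeling_efficiency": 1.5},
            {"crosstalk_rate": -0.1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestBlinking:
    def test_interval_means_match_rates(self, rng):
        # law-of-large-numbers oracle: ~1e5 intervals from one site
        cfg = SimulationConfig(
            exposure_time=1.0,
            n_frames=70000,
            imager_concentration=10000.0,  # tau_d = 0.2 s at k_on 5e8
            k_on=5e8,
            k_off=2.0,
        )
        model = make_origami_grid(1, 1)
        (trace,) = simulate_blinking(model, cfg, rng=rng)
        iv = trace.intervals
        assert len(iv) > 9e4
        brights = iv[:, 1] - iv[:, 0]
        darks = iv[1:, 0] - iv[:-1, 1]
        assert brights.mean() == pytest.approx(0.5, rel=0.02)
        assert darks.mean() == pytest.approx(0.2, rel=0.02)

    def test_doubling_concentration_halves_dark_time(self, rng):
        model = make_origami_grid(1, 1)
        means = []
        for c in (5000.0, 10000.0):
            cfg = SimulationConfig(
                exposure_time=1.0, n_frames=40000, imager_concentration=c, k_on=5e8, k_off=2.0
            )
            (trace,) = simulate_blinking(model, cfg, rng=rng)
            iv = trace.intervals
            means.append((iv[1:, 0] - iv[:-1, 1]).mean())
        assert means[1] / means[0] == pytest.approx(0.5, rel=0.05)

    def test_zero_labeling_gives_no_traces(self, rng):
        cfg = SimulationConfig(labeling_efficiency=0.0)
        assert simulate_blinking(make_origami_grid(4, 3), cfg, rng=rng) == []

    def test_intervals_sorted_disjoint_within_acquisition(self, rng):
        cfg = SimulationConfig(n_frames=2000)
        for trace in simulate_blinking(make_origami_grid(2, 2), cfg, rng=rng):
            iv = trace.intervals
            assert (iv[:, 1] >= iv[:, 0]).all()
            assert (iv[1:, 0] >= iv[:-1, 1]).all()
            assert iv[0, 0] >= 0.0 and iv[-1, 1] <= cfg.duration + 1e-9

    def test_per_structure_dark_time_scales_inversely_with_c_and_n(self, rng):
        # union-gap oracle on raw traces over a (c, n) sweep
        gaps_mean = {}
        for c in (50.0, 100.0):
            for n in (6, 12):
                cfg = SimulationConfig(
                    n_frames=100000, imager_concentration=c, k_on=2e8, k_off=1.0
                )
                model = make_origami_grid(2, n // 2)
                traces = simulate_blinking(model, cfg, rng=rng)
                iv = np.concatenate([t.intervals for t in traces])
                iv = iv[np.argsort(iv[:, 0])]
                # merge overlapping bright intervals, collect all-dark gaps
                gaps, end = [], iv[0, 1]
                for s, e in iv[1:]:
                    if s > end:
                        gaps.append(s - end)
                    end = max(end, e)
                gaps_mean[(c, n)] = np.mean(gaps)
        for (c, n), g in gaps_mean.items():
            expected = 1.0 / (n * 2e8 * c * 1e-12)
            assert g == pytest.approx(expected, rel=0.12)


class TestRendering:
    def test_noiseless_interval_renders_expected_frames(self):
        cfg = SimulationConfig(
            n_frames=100, localization_precision_xy=1e-9, localization_precision_z=1e-9
        )
        model = make_origami_grid(1, 1)
        dt = cfg.exposure_time
        traces = [EmitterTrace(0, [[10 * dt, 13 * dt - 1e-12]])]
        table = render_localizations(traces, model, cfg, rng=np.random.default_rng(0))
        assert list(table.frames()) == [10, 11, 12]
        assert np.allclose(table.xy_nm(), model.sites[0, :2], atol=1e-6)

    def test_short_overlap_below_half_frame_not_localized(self):
        cfg = SimulationConfig(n_frames=100)
        dt = cfg.exposure_time
        traces = [EmitterTrace(0, [[10.6 * dt, 10.9 * dt]])]  # 0.3 of a frame
        table = render_localizations(traces, make_origami_grid(1, 1), cfg)
        assert table.n_locs == 0

    def test_at_most_one_localization_per_site_per_frame(self, rng):
        cfg = SimulationConfig(n_frames=5000)
        model = make_origami_grid(1, 1)
        traces = simulate_blinking(model, cfg, rng=rng)
        table = render_localizations(traces, model, cfg, rng=rng)
        assert table.df["frame"].value_counts().max() <= 1

    def test_localization_scatter_matches_precision(self, rng):
        cfg = SimulationConfig(n_frames=20000, localization_precision_xy=3.0)
        model = make_origami_grid(1, 1)
        traces = [EmitterTrace(0, [[0.0, cfg.duration]])]
        table = render_localizations(traces, model, cfg, rng=rng)
        assert table.n_locs == cfg.n_frames
        std = table.xy_nm().std(axis=0)
        assert np.allclose(std, 3.0, rtol=0.05)


class TestExchange:
    def _library(self, n_species=12, per_species=1):
        models = []
        for s in range(1, n_species + 1):
            for i in range(per_species):
                models.append(
                    make_origami_grid(2, 2, 15.0, s, "R" if s <= 6 else "L", instance_id=i)
                )
        return models

    def test_twelve_rounds_activate_only_their_species(self):
        cfg = SimulationConfig(n_frames=1500, rng_seed=4)
        models = siggen.place_on_lattice(self._library(), cfg)
        tables, manifest = simulate_exchange_experiment(
            models, list(range(1, 13)), cfg, n_fiducials=0
        )
        assert len(tables) == 12
        xy_sites, species, _ = manifest.site_array()
        for r, table in enumerate(tables):
            if not table.n_locs:
                continue
            d, idx = cKDTree(xy_sites).query(table.xy_nm())
            assert (d < 5 * cfg.localization_precision_xy).all()
            assert (species[idx] == r + 1).all()

    def test_missing_species_raises(self):
        cfg = SimulationConfig(n_frames=100)
        with pytest.raises(ValueError):
            simulate_exchange_experiment(self._library(3), [99], cfg)

    def test_crosstalk_fraction_matches_rate(self):
        # rate bookkeeping oracle: same-chirality off-target localizations
        # accrue in proportion to the (duty-cycle-corrected) crosstalk rate
        scale = 0.05
        cfg = SimulationConfig(n_frames=20000, crosstalk_rate=scale, rng_seed=9)
        models = []
        for s in (1, 2, 3):
            models.append(make_origami_grid(4, 3, 15.0, s, "R"))
        models = siggen.place_on_lattice(models, cfg)
        tables, manifest = simulate_exchange_experiment(models, [1], cfg, n_fiducials=0)
        xy_sites, species, _ = manifest.site_array()
        d, idx = cKDTree(xy_sites).query(tables[0].xy_nm())
        off = (species[idx] != 1) & (d < 10.0)
        frac = off.sum() / len(off)
        # per-site event-rate ratio including bright-time occupancy
        r = (cfg.tau_dark + cfg.tau_bright) / (cfg.tau_dark / scale + cfg.tau_bright)
        expected = 2 * r / (1 + 2 * r)
        assert frac == pytest.approx(expected, rel=0.3)

    def test_chirality_orthogonality_despite_crosstalk(self):
        cfg = SimulationConfig(n_frames=4000, crosstalk_rate=0.5, rng_seed=2)
        models = siggen.place_on_lattice(self._library(12), cfg)
        tables, manifest = simulate_exchange_experiment(models, [1, 7], cfg, n_fiducials=0)
        xy_sites, species, _ = manifest.site_array()
        for r, active in ((0, 1), (1, 7)):
            d, idx = cKDTree(xy_sites).query(tables[r].xy_nm())
            hit_species = species[idx[d < 10.0]]
            active_chirality = "R" if active <= 6 else "L"
            other = species[np.isin(species, range(1, 7) if active_chirality == "L" else range(7, 13))]
            assert not np.isin(hit_species, other).any()

    def test_identical_seed_gives_identical_tables(self):
        cfg = SimulationConfig(n_frames=1000, drift_step=0.3, rng_seed=77)
        models = siggen.place_on_lattice(self._library(2), cfg)
        t1, _ = simulate_exchange_experiment(models, [1, 2], cfg, n_fiducials=2)
        t2, _ = simulate_exchange_experiment(models, [1, 2], cfg, n_fiducials=2)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.df, b.df)


class TestFiducialsAndDrift:
    def _empty(self, n_frames=500):
        return siggen.render_localizations([], make_origami_grid(1, 1), SimulationConfig(n_frames=n_frames))

    def test_fiducial_count_is_beads_times_frames(self, rng):
        cfg = SimulationConfig(n_frames=500)
        table, _ = add_fiducials_and_drift(self._empty(), 4, cfg, rng=rng)
        assert table.n_locs == 4 * 500

    def test_zero_drift_leaves_structure_locs_untouched(self, rng):
        cfg = SimulationConfig(n_frames=200, drift_step=0.0)
        model = make_origami_grid(1, 1).translate(100 * 130.0, 100 * 130.0)
        base = render_localizations([EmitterTrace(0, [[0.0, cfg.duration]])], model, cfg, rng=rng)
        out, trace = add_fiducials_and_drift(base, 0, cfg, rng=rng)
        pd.testing.assert_frame_equal(out.df, base.df)
        assert np.all(trace.dx == 0.0) and np.all(trace.dy == 0.0)

    def test_injected_drift_trace_is_cumulative_walk(self, rng):
        cfg = SimulationConfig(n_frames=1000, drift_step=1.0)
        _, trace = add_fiducials_and_drift(self._empty(1000), 1, cfg, rng=rng)
        steps = np.diff(trace.dx) * cfg.pixel_size
        assert np.std(steps) == pytest.approx(1.0, rel=0.1)
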