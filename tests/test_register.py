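"""Drift correction, channel alignment and stitching round trips."""

import numpy as np
import pandas as pd
import pytest

from paintbench import register, siggen
from paintbench.register import (
    DriftTrace,
    NoFiducialError,
    align_channels,
    apply_shift,
    merge_tiles,
    stitch_tiles,
    track_fiducials,
    undrift,
)
from paintbench.siggen import SimulationConfig, add_fiducials_and_drift, make_origami_grid

from helpers import table_from_xy

RENDER_BIN_PX = 65.0 / 130.0  # default render bin in pixels


def _fiducial_table(n_frames=2000, drift_step=0.0, sigma_nm=1.0, n_fid=3, seed=3):
    cfg = SimulationConfig(
        n_frames=n_frames,
        drift_step=drift_step,
        fiducial_precision_xy=sigma_nm,
        rng_seed=seed,
    )
    empty = siggen.render_localizations([], make_origami_grid(1, 1), cfg)
    return add_fiducials_and_drift(empty, n_fid, cfg, rng=np.random.default_rng(seed))


class TestDrift:
    def test_zero_drift_noiseless_fiducials_give_zero_trace(self):
        table, _ = _fiducial_table(500, drift_step=0.0, sigma_nm=1e-9)
        trace = track_fiducials(table)
        assert np.allclose(trace.dx, 0.0, atol=1e-9)
        assert np.allclose(trace.dy, 0.0, atol=1e-9)

    def test_injected_random_walk_is_recovered(self):
        # 3 fiducials, 1 nm noise, 2 nm/frame walk; the bound combines the
        # noise floor sigma/sqrt(3 fiducials) with the moving-average
        # smoothing residual ~ step * sqrt(window/3)
        table, injected = _fiducial_table(2000, drift_step=2.0, sigma_nm=1.0)
        rec = track_fiducials(table)
        inj = np.column_stack([injected.dx - injected.dx.mean(), injected.dy - injected.dy.mean()])
        err = np.column_stack([rec.dx, rec.dy]) - inj
        rms = float(np.sqrt((err**2).sum(axis=1).mean()))
        step_px = 2.0 / 130.0
        bound = 1.0 / 130.0 / np.sqrt(3) + step_px * np.sqrt(100 / 3.0)
        assert rms < bound

    def test_correction_reduces_fiducial_variance_90_percent(self):
        # drift step 2 nm >= 2x the 1 nm localization precision
        table, _ = _fiducial_table(3000, drift_step=2.0, sigma_nm=1.0)
        trace = track_fiducials(table)
        corrected = undrift(table, trace)
        members = register.find_fiducials(table)[0]
        var_before = table.xy_px()[members].var(axis=0).sum()
        var_after = corrected.xy_px()[members].var(axis=0).sum()
        assert var_after <= 0.1 * var_before

    def test_undrift_inverts_an_applied_trace_exactly(self, rng):
        table = table_from_xy(rng.uniform(10, 500, (200, 2)), rng.integers(0, 50, 200), n_frames=50)
        trace = DriftTrace(rng.normal(0, 0.3, 50), rng.normal(0, 0.3, 50))
        drifted = table.copy()
        drifted.df["x"] += trace.dx[drifted.frames()]
        drifted.df["y"] += trace.dy[drifted.frames()]
        back = undrift(drifted, trace)
        assert np.allclose(back.df["x"], table.df["x"])
        assert np.allclose(back.df["y"], table.df["y"])
        assert back.metadata["drift_corrected"]

    def test_zero_trace_is_identity(self, rng):
        table = table_from_xy(rng.uniform(10, 500, (50, 2)), rng.integers(0, 20, 50), n_frames=20)
        out = undrift(table, DriftTrace(np.zeros(20), np.zeros(20)))
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_trace_length_mismatch_rejected(self, rng):
        table = table_from_xy([[1, 1]], [0], n_frames=10)
        with pytest.raises(ValueError, match="length"):
            undrift(table, DriftTrace(np.zeros(5), np.zeros(5)))

    def test_table_without_persistent_emitter_raises(self, rng):
        # transient binding only: each emitter present in a handful of frames
        table = table_from_xy(rng.uniform(10, 500, (300, 2)), rng.integers(0, 1000, 300), n_frames=1000)
        with pytest.raises(NoFiducialError):
            track_fiducials(table)


def _structured_table(rng, n_points=300, reps=30):
    pts = rng.uniform(50, 500, size=(n_points, 2))
    locs = np.repeat(pts, reps, axis=0) + rng.normal(0, 0.01, size=(n_points * reps, 2))
    frames = np.tile(np.arange(reps), n_points)
    return table_from_xy(locs, frames, n_frames=reps)


class TestAlignment:
    def test_translation_recovered_within_tenth_bin(self, rng):
        ref = _structured_table(rng)
        mov = ref.copy()
        mov.df["x"] += 0.30
        mov.df["y"] -= 0.70
        shift = align_channels(ref, mov)
        err = np.hypot(shift.dx + 0.30, shift.dy - 0.70)
        assert err < 0.1 * RENDER_BIN_PX
        assert 0.5 < shift.score <= 1.0

    def test_self_alignment_is_zero(self, rng):
        ref = _structured_table(rng)
        shift = align_channels(ref, ref)
        assert abs(shift.dx) < 1e-6 and abs(shift.dy) < 1e-6

    def test_alignment_fixed_point(self, rng):
        ref = _structured_table(rng)
        mov = ref.copy()
        mov.df["x"] += 0.8
        shift = align_channels(ref, mov)
        realigned = align_channels(ref, apply_shift(mov, shift))
        assert np.hypot(realigned.dx, realigned.dy) < 0.05 * RENDER_BIN_PX

    def test_translation_equivariance(self, rng):
        ref = _structured_table(rng)
        mov = ref.copy()
        mov.df["x"] += 0.4
        s1 = align_channels(ref, mov)
        mov2 = mov.copy()
        mov2.df["x"] += 0.9
        mov2.df["y"] += 0.6
        s2 = align_channels(ref, mov2)
        assert s2.dx - s1.dx == pytest.approx(-0.9, abs=0.1 * RENDER_BIN_PX)
        assert s2.dy - s1.dy == pytest.approx(-0.6, abs=0.1 * RENDER_BIN_PX)

    def test_empty_table_rejected(self, rng):
        ref = _structured_table(rng)
        empty = table_from_xy(np.zeros((0, 2)), np.zeros(0, dtype=int), n_frames=10)
        with pytest.raises(ValueError):
            align_channels(ref, empty)


class TestStitching:
    def _cut_tiles(self, rng, offsets, n_channels=2, width=576, overlap_px=10000.0 / 130.0):
        """Cut a 2x2 tile set with overlap from one synthetic field."""
        big = int(2 * width - overlap_px)
        channels = []
        for _ in range(n_channels):
            pts = rng.uniform(20, big - 20, size=(600, 2))
            locs = np.repeat(pts, 25, axis=0) + rng.normal(0, 0.01, size=(600 * 25, 2))
            channels.append((locs, np.tile(np.arange(25), 600)))
        tiles = {}
        for (row, col), (ddx, ddy) in offsets.items():
            ox, oy = col * (width - overlap_px), row * (width - overlap_px)
            per_channel = []
            for locs, frames in channels:
                m = (
                    (locs[:, 0] >= ox)
                    & (locs[:, 0] <= ox + width)
                    & (locs[:, 1] >= oy)
                    & (locs[:, 1] <= oy + width)
                )
                per_channel.append(
                    table_from_xy(
                        locs[m] - (ox - ddx, oy - ddy), frames[m], n_frames=25, width=width, height=width
                    )
                )
            tiles[(row, col)] = per_channel
        return tiles

    def test_injected_tile_offsets_recovered(self, rng):
        offsets = {(0, 0): (0.0, 0.0), (0, 1): (0.9, -0.4), (1, 0): (-0.6, 0.7), (1, 1): (0.3, 1.1)}
        tiles = self._cut_tiles(rng, offsets)
        shifts = stitch_tiles(tiles, overlap_um=10.0)
        for pos, (ddx, ddy) in offsets.items():
            err = np.hypot(shifts[pos].dx + ddx, shifts[pos].dy + ddy)
            assert err < 0.1 * RENDER_BIN_PX, pos

    def test_zero_offsets_give_zero_shifts(self, rng):
        offsets = {(r, c): (0.0, 0.0) for r in (0, 1) for c in (0, 1)}
        tiles = self._cut_tiles(rng, offsets)
        shifts = stitch_tiles(tiles, overlap_um=10.0)
        for pos in offsets:
            assert np.hypot(shifts[pos].dx, shifts[pos].dy) < 0.05 * RENDER_BIN_PX

    def test_shifts_transfer_across_channels(self, rng):
        # registration runs on channel 0; applying the same shifts must bring
        # channel 1's duplicated overlap content into agreement as well
        offsets = {(0, 0): (0.0, 0.0), (0, 1): (1.2, -0.8), (1, 0): (0.0, 0.0), (1, 1): (0.0, 0.0)}
        tiles = self._cut_tiles(rng, offsets)
        shifts = stitch_tiles(tiles, overlap_um=10.0, channel=0)
        merged = merge_tiles(tiles, shifts, overlap_um=10.0)
        ch1 = merged[1]
        from scipy.spatial import cKDTree

        xy = ch1.xy_px()
        frames = ch1.frames()
        sel = frames == 0
        d, _ = cKDTree(xy[sel]).query(xy[sel], k=2)
        # duplicated points from the two tiles of the overlap must coincide
        dup = d[:, 1][d[:, 1] < 0.5]
        assert len(dup) > 10
        assert np.median(dup) < 0.1

    def test_empty_overlap_falls_back_to_coarse_offset(self, rng):
        offsets = {(r, c): (0.0, 0.0) for r in (0, 1) for c in (0, 1)}
        tiles = self._cut_tiles(rng, offsets)
        # wipe the overlap band content of one moving tile
        tiles[(0, 1)] = [
            t.subset((t.df["x"] > 100.0).to_numpy()) for t in tiles[(0, 1)]
        ]
        with pytest.warns(UserWarning):
            shifts = stitch_tiles(tiles, overlap_um=10.0)
        assert shifts[(0, 1)].dx == 0.0 and shifts[(0, 1)].dy == 0.0
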