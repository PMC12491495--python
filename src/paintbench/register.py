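"""Fiducial drift correction, channel alignment and tile stitching.

Gold nanoparticles appear as localization clusters present in essentially
every frame.  Drift is estimated by tracking them, channels are registered by
normalized cross-correlation of rendered images, and multi-tile fields are
stitched by registering their overlap regions and chaining shifts from a
reference tile (top-left anchors its row and column; interior tiles chain to
the tile above).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .locio import LocalizationTable


@dataclass
class DriftTrace:
    """Per-frame (dx, dy) displacement in pixels."""

    dx: np.ndarray
    dy: np.ndarray
    smoothing_window: int = 0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape:
            raise ValueError("dx and dy must have identical length")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("drift trace must be finite")

    def __len__(self) -> int:
        return len(self.dx)


@dataclass
class Shift:
    """Translation (pixels) mapping a moving table onto a reference."""

    dx: float
    dy: float
    score: float = 1.0


class NoFiducialError(RuntimeError):
    pass


def find_fiducials(
    table: LocalizationTable,
    min_presence: float = 0.8,
    search_radius_px: float = 3.0,
    max_fiducials: int = 50,
) -> list[np.ndarray]:
    """Detect fiducials as clusters present in >= ``min_presence`` of frames.

    Returns one member-index array per fiducial.  DNA-PAINT binding sites are
    dark most of the time, so a presence threshold sharply separates beads
    from sites.
    """
    n_frames = table.n_frames
    if n_frames is None:
        raise ValueError("table metadata must carry n_frames")
    if table.n_locs == 0:
        raise NoFiducialError("empty table")
    xy = table.xy_px()
    frames = table.frames()
    tree = cKDTree(xy)
    # coarse candidate bins: a bead contributes ~n_frames locs spread over a
    # few pixels, binding sites two orders of magnitude fewer
    bin_px = 2.0
    ix = np.floor(xy[:, 0] / bin_px).astype(np.int64)
    iy = np.floor(xy[:, 1] / bin_px).astype(np.int64)
    order = np.lexsort((iy, ix))
    keys, counts = np.unique(np.column_stack([ix, iy])[order], axis=0, return_counts=True)
    threshold = min_presence * n_frames
    candidates = keys[counts >= 0.2 * threshold]
    cand_counts = counts[counts >= 0.2 * threshold]
    used = np.zeros(len(xy), dtype=bool)
    fiducials: list[np.ndarray] = []
    for key in candidates[np.argsort(cand_counts)[::-1]]:
        center = (key + 0.5) * bin_px
        members = np.asarray(tree.query_ball_point(center, search_radius_px))
        members = members[~used[members]]
        if len(members) < threshold:
            continue
        # refine about the actual centroid
        center = xy[members].mean(axis=0)
        members = np.asarray(tree.query_ball_point(center, search_radius_px))
        members = members[~used[members]]
        if len(np.unique(frames[members])) < threshold:
            continue
        used[members] = True
        fiducials.append(np.sort(members))
        if len(fiducials) >= max_fiducials:
            break
    if not fiducials:
        raise NoFiducialError(
            "no localization cluster present in enough frames; fiducial-free "
            "drift correction is not supported"
        )
    return fiducials


def track_fiducials(
    table: LocalizationTable,
    min_presence: float = 0.8,
    smoothing_window: int = 100,
    search_radius_px: float = 3.0,
) -> DriftTrace:
    """Estimate per-frame drift from fiducial tracks.

    Per fiducial, the per-frame displacement from its mean position is taken;
    displacements are averaged over fiducials, gap-interpolated, smoothed by a
    centered moving average and returned as a zero-mean trace.
    """
    n_frames = int(table.n_frames)  # validated in find_fiducials
    fiducials = find_fiducials(table, min_presence, search_radius_px)
    frames = table.frames()
    xy = table.xy_px()
    traces = np.full((len(fiducials), n_frames, 2), np.nan)
    for i, members in enumerate(fiducials):
        df = pd.DataFrame(
            {"frame": frames[members], "x": xy[members, 0], "y": xy[members, 1]}
        )
        per_frame = df.groupby("frame").mean()
        rel = per_frame - per_frame.mean()
        traces[i, per_frame.index.to_numpy(), 0] = rel["x"].to_numpy()
        traces[i, per_frame.index.to_numpy(), 1] = rel["y"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_trace = np.nanmean(traces, axis=0)
    trace = pd.DataFrame(mean_trace, columns=["x", "y"]).interpolate(
        limit_direction="both"
    )
    if smoothing_window > 1:
        trace = trace.rolling(smoothing_window, center=True, min_periods=1).mean()
    trace = trace - trace.mean()
    return DriftTrace(
        trace["x"].to_numpy(), trace["y"].to_numpy(), smoothing_window=smoothing_window
    )


def undrift(table: LocalizationTable, trace: DriftTrace) -> LocalizationTable:
    """Subtract the per-frame drift from every localization."""
    n_frames = table.n_frames
    if n_frames is not None and len(trace) != n_frames:
        raise ValueError(f"trace length {len(trace)} != n_frames {n_frames}")
    out = table.copy()
    frames = out.frames()
    out.df["x"] = out.df["x"].to_numpy() - trace.dx[frames]
    out.df["y"] = out.df["y"].to_numpy() - trace.dy[frames]
    out.metadata["drift_corrected"] = True
    return out


# -- rendering and cross-correlation ------------------------------------------


def _render(
    xy_nm: np.ndarray, bin_nm: float, extent_nm: tuple[float, float, float, float]
) -> np.ndarray:
    """Subpixel (bilinearly weighted) 2D rendering, lightly blurred.

    Plain histogramming quantizes sparse structures to bin centers, which
    biases subpixel registration; bilinear deposition preserves fractional
    positions, and a 1-bin Gaussian blur gives the correlation peak a smooth
    near-Gaussian profile for parabolic interpolation.
    """
    x0, x1, y0, y1 = extent_nm
    nx = max(int(np.ceil((x1 - x0) / bin_nm)), 2)
    ny = max(int(np.ceil((y1 - y0) / bin_nm)), 2)
    img = np.zeros((nx, ny))
    bx = (xy_nm[:, 0] - x0) / bin_nm - 0.5
    by = (xy_nm[:, 1] - y0) / bin_nm - 0.5
    ix0 = np.floor(bx).astype(np.int64)
    iy0 = np.floor(by).astype(np.int64)
    fx, fy = bx - ix0, by - iy0
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xi, yi = ix0 + dx, iy0 + dy
            ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
            np.add.at(img, (xi[ok], yi[ok]), (wx * wy)[ok])
    return gaussian_filter(img, sigma=1.0)


def _parabolic(c_m1: float, c_0: float, c_p1: float) -> float:
    # blurred-histogram correlation peaks are near-Gaussian, for which the
    # 3-point parabola is exact in the log domain; fall back to the linear
    # parabola when a neighbor is non-positive
    if c_m1 > 0 and c_0 > 0 and c_p1 > 0:
        c_m1, c_0, c_p1 = np.log(c_m1), np.log(c_0), np.log(c_p1)
    denom = c_m1 - 2.0 * c_0 + c_p1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (c_m1 - c_p1) / denom, -0.5, 0.5))


def _correlate_shift(ref_img: np.ndarray, mov_img: np.ndarray) -> tuple[float, float, float]:
    """Subpixel displacement (in bins) such that moving + shift ~ reference."""
    a = ref_img - ref_img.mean()
    b = mov_img - mov_img.mean()
    corr = fftconvolve(a, b[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    norm = np.sqrt((a**2).sum() * (b**2).sum())
    score = float(corr[peak] / norm) if norm > 0 else 0.0
    shift = []
    for axis, p in enumerate(peak):
        if 0 < p < corr.shape[axis] - 1:
            idx = list(peak)
            idx[axis] = p - 1
            c_m1 = corr[tuple(idx)]
            idx[axis] = p + 1
            c_p1 = corr[tuple(idx)]
            frac = _parabolic(c_m1, corr[peak], c_p1)
        else:
            frac = 0.0
        shift.append(p - (mov_img.shape[axis] - 1) + frac)
    return shift[0], shift[1], score


def align_channels(
    reference: LocalizationTable,
    moving: LocalizationTable,
    render_bin: float = 65.0,
) -> Shift:
    """Register ``moving`` onto ``reference`` by image cross-correlation.

    Both tables are rendered as 2D histograms with ``render_bin`` nm bins over
    the reference field; the normalized correlation peak is located with
    3-point parabolic interpolation per axis.  The returned shift is in pixels
    and maps the moving table onto the reference.
    """
    if reference.n_locs == 0 or moving.n_locs == 0:
        raise ValueError("cannot align an empty table")
    px = reference.pixel_size
    width = reference.metadata.get("width")
    height = reference.metadata.get("height")
    ref_nm = reference.xy_nm()
    mov_nm = moving.xy_nm()
    if width is not None and height is not None:
        extent = (0.0, float(width) * px, 0.0, float(height) * px)
    else:
        lo = np.minimum(ref_nm.min(axis=0), mov_nm.min(axis=0))
        hi = np.maximum(ref_nm.max(axis=0), mov_nm.max(axis=0))
        extent = (lo[0], hi[0], lo[1], hi[1])
    ref_img = _render(ref_nm, render_bin, extent)
    mov_img = _render(mov_nm, render_bin, extent)
    dx_bins, dy_bins, score = _correlate_shift(ref_img, mov_img)
    return Shift(dx=dx_bins * render_bin / px, dy=dy_bins * render_bin / px, score=score)


def apply_shift(table: LocalizationTable, shift: Shift) -> LocalizationTable:
    out = table.copy()
    out.df["x"] = out.df["x"] + shift.dx
    out.df["y"] = out.df["y"] + shift.dy
    return out


# -- stitching -----------------------------------------------------------------


def _tile_origin_nm(
    row: int, col: int, tile_size_nm: tuple[float, float], overlap_nm: float
) -> tuple[float, float]:
    w, h = tile_size_nm
    return col * (w - overlap_nm), row * (h - overlap_nm)


def _chain_parent(pos: tuple[int, int], reference: tuple[int, int]) -> tuple[int, int]:
    """Alignment chain: reference anchors its row and column, interior tiles
    chain to the tile above (e.g. 2x2: bottom-right aligns to top-right)."""
    row, col = pos
    r0, c0 = reference
    if (row, col) == (r0, c0):
        return (r0, c0)
    if row == r0:
        return (row, col - 1 if col > c0 else col + 1)
    return (row - 1 if row > r0 else row + 1, col)


def stitch_tiles(
    tiles: dict[tuple[int, int], list[LocalizationTable]],
    overlap_um: float = 10.0,
    reference_tile: tuple[int, int] = (0, 0),
    render_bin: float = 65.0,
    channel: int = 0,
    min_score: float = 0.1,
) -> dict[tuple[int, int], Shift]:
    """Register a rectangular grid of tiles via their overlap regions.

    ``tiles`` maps (row, col) grid positions to the per-channel tables of that
    tile (local pixel coordinates).  Registration runs on ``channel`` only and
    the per-tile shift applies identically to all channels.  Overlap regions
    empty of structure fall back to the coarse layout offset with a warning.
    Returned shifts are in pixels of the tile's own coordinate system.
    """
    if overlap_um <= 0:
        raise ValueError("overlap must be positive")
    overlap_nm = overlap_um * 1000.0
    ref_tables = tiles[reference_tile]
    px = ref_tables[channel].pixel_size
    width = float(ref_tables[channel].metadata["width"]) * px
    height = float(ref_tables[channel].metadata["height"]) * px
    tile_size = (width, height)

    shifts: dict[tuple[int, int], Shift] = {reference_tile: Shift(0.0, 0.0, 1.0)}
    # process in chain order: increasing distance from the reference
    order = sorted(tiles, key=lambda p: abs(p[0] - reference_tile[0]) + abs(p[1] - reference_tile[1]))
    for pos in order:
        if pos == reference_tile:
            continue
        parent = _chain_parent(pos, reference_tile)
        if parent not in shifts:  # pragma: no cover - non-rectangular layout
            raise ValueError(f"tile {pos}: parent {parent} missing from layout")
        ox, oy = _tile_origin_nm(*pos, tile_size, overlap_nm)
        pox, poy = _tile_origin_nm(*parent, tile_size, overlap_nm)
        # overlap region in global nm, parent already corrected by its shift;
        # a guard band keeps residual tile offsets from moving content across
        # the window border, which would bias the subpixel peak
        guard = 3.0 * px
        lo_x, hi_x = max(ox, pox) + guard, min(ox + width, pox + width) - guard
        lo_y, hi_y = max(oy, poy) + guard, min(oy + height, poy + height) - guard
        extent = (lo_x, hi_x, lo_y, hi_y)
        parent_shift = shifts[parent]
        p_nm = apply_shift(tiles[parent][channel], parent_shift).xy_nm() + (pox, poy)
        m_nm = tiles[pos][channel].xy_nm() + (ox, oy)
        p_in = p_nm[
            (p_nm[:, 0] >= lo_x) & (p_nm[:, 0] <= hi_x) & (p_nm[:, 1] >= lo_y) & (p_nm[:, 1] <= hi_y)
        ]
        m_in = m_nm[
            (m_nm[:, 0] >= lo_x) & (m_nm[:, 0] <= hi_x) & (m_nm[:, 1] >= lo_y) & (m_nm[:, 1] <= hi_y)
        ]
        if len(p_in) < 10 or len(m_in) < 10:
            warnings.warn(f"tile {pos}: overlap region nearly empty, using coarse offset")
            shifts[pos] = Shift(0.0, 0.0, 0.0)
            continue
        ref_img = _render(p_in, render_bin, extent)
        mov_img = _render(m_in, render_bin, extent)
        dx_bins, dy_bins, score = _correlate_shift(ref_img, mov_img)
        if score < min_score:
            warnings.warn(f"tile {pos}: low correlation score {score:.2f}, using coarse offset")
            shifts[pos] = Shift(0.0, 0.0, score)
            continue
        shifts[pos] = Shift(dx_bins * render_bin / px, dy_bins * render_bin / px, score)
    return shifts


def merge_tiles(
    tiles: dict[tuple[int, int], list[LocalizationTable]],
    shifts: dict[tuple[int, int], Shift],
    overlap_um: float = 10.0,
) -> list[LocalizationTable]:
    """Apply per-tile shifts and coarse offsets; return one table per channel
    in the global pixel frame."""
    overlap_nm = overlap_um * 1000.0
    any_tile = next(iter(tiles.values()))
    n_channels = len(any_tile)
    px = any_tile[0].pixel_size
    width = float(any_tile[0].metadata["width"])
    height = float(any_tile[0].metadata["height"])
    tile_size = (width * px, height * px)
    n_rows = max(p[0] for p in tiles) + 1
    n_cols = max(p[1] for p in tiles) + 1
    merged: list[LocalizationTable] = []
    for ch in range(n_channels):
        parts = []
        for pos, tabs in tiles.items():
            ox, oy = _tile_origin_nm(*pos, tile_size, overlap_nm)
            s = shifts[pos]
            df = tabs[ch].df.copy()
            df["x"] = df["x"] + s.dx + ox / px
            df["y"] = df["y"] + s.dy + oy / px
            parts.append(df)
        meta = dict(any_tile[ch].metadata)
        meta["width"] = n_cols * width - (n_cols - 1) * overlap_nm / px
        meta["height"] = n_rows * height - (n_rows - 1) * overlap_nm / px
        df = pd.concat(parts, ignore_index=True).sort_values("frame", kind="stable")
        merged.append(LocalizationTable(df.reset_index(drop=True), meta))
    return merged
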