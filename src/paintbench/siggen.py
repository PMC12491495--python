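"""Synthetic Exchange-PAINT data generation.

The generator builds ground-truth structures (DNA-origami site grids,
nuclear-pore standards with two Nup96 rings, filaments), simulates the
two-state imager binding process at each docking site, renders frame-wise
localizations with Gaussian localization noise, and composes multi-round
exchange experiments with chirality-orthogonal crosstalk, gold-fiducial
tracks and random-walk stage drift.

Binding at a site alternates between dark intervals (exponential, mean
``1/(k_on * c)``) and bright intervals (exponential, mean ``1/k_off``), the
standard DNA-PAINT kinetic model.  Left-handed (L-DNA) imagers never bind
right-handed docking sites and vice versa, so crosstalk between chirality
classes is structurally zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .locio import LocalizationTable
from .register import DriftTrace

PM_TO_M = 1e-12  # picomolar to molar


@dataclass
class SimulationConfig:
    """Acquisition and kinetic parameters of one simulated experiment.

    Defaults follow the benchmark imaging conditions: 75 ms frames, 130 nm
    effective pixels, a 576 x 576 px region of interest and 100 pM imager.
    ``k_on``/``k_off`` default to typical speed-optimized sequence kinetics.
    """

    exposure_time: float = 0.075  # s per frame
    n_frames: int = 15000
    pixel_size: float = 130.0  # nm per px
    imager_concentration: float = 100.0  # pM
    k_on: float = 5.0e8  # /(M s)
    k_off: float = 2.0  # /s
    localization_precision_xy: float = 2.0  # nm (sigma)
    localization_precision_z: float = 10.0  # nm (sigma)
    labeling_efficiency: float = 1.0
    crosstalk_rate: float = 0.0  # relative off-target binding rate
    drift_step: float = 0.0  # nm per frame (random-walk scale)
    rng_seed: int = 0
    fov_width: int = 576  # px
    fov_height: int = 576  # px
    min_on_fraction: float = 0.5  # frame-overlap fraction needed to localize
    fiducial_precision_xy: float = 1.0  # nm; gold beads are bright

    def __post_init__(self) -> None:
        positive = {
            "exposure_time": self.exposure_time,
            "pixel_size": self.pixel_size,
            "imager_concentration": self.imager_concentration,
            "k_on": self.k_on,
            "k_off": self.k_off,
            "localization_precision_xy": self.localization_precision_xy,
            "localization_precision_z": self.localization_precision_z,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name, value in (
            ("labeling_efficiency", self.labeling_efficiency),
            ("crosstalk_rate", self.crosstalk_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.drift_step < 0:
            raise ValueError("drift_step must be non-negative")

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.n_frames * self.exposure_time

    @property
    def tau_dark(self) -> float:
        """Mean single-site dark time at the configured concentration (s)."""
        return 1.0 / (self.k_on * self.imager_concentration * PM_TO_M)

    @property
    def tau_bright(self) -> float:
        return 1.0 / self.k_off


@dataclass
class StructureModel:
    """Ground-truth binding-site coordinates of one structure.

    ``sites`` is an (N, 3) array in nm; all sites of a structure carry the
    same docking species and chirality.
    """

    sites: np.ndarray
    species_id: int = 1
    chirality: str = "R"
    structure_kind: str = "custom"
    structure_instance_id: int = 0

    def __post_init__(self) -> None:
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if self.sites.shape[1] != 3:
            raise ValueError("sites must be (N, 3)")
        if not np.all(np.isfinite(self.sites)):
            raise ValueError("site coordinates must be finite")
        if self.chirality not in ("L", "R"):
            raise ValueError("chirality must be 'L' or 'R'")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def center(self) -> np.ndarray:
        return self.sites.mean(axis=0)

    def translate(self, dx: float, dy: float, dz: float = 0.0) -> "StructureModel":
        return replace(self, sites=self.sites + np.array([dx, dy, dz]))


@dataclass
class EmitterTrace:
    """Bright intervals of one docking site, in seconds."""

    site_index: int
    intervals: np.ndarray  # (K, 2) of (t_start, t_end)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)


# -- structure factories -------------------------------------------------------


def make_origami_grid(
    rows: int,
    cols: int,
    pitch: float = 15.0,
    species_id: int = 1,
    chirality: str = "R",
    instance_id: int = 0,
) -> StructureModel:
    """Rectangular origami site lattice centered at the origin, z = 0."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if not pitch > 0:
        raise ValueError("pitch must be positive")
    xs = (np.arange(cols) - (cols - 1) / 2.0) * pitch
    ys = (np.arange(rows) - (rows - 1) / 2.0) * pitch
    gx, gy = np.meshgrid(xs, ys)
    sites = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(rows * cols)])
    return StructureModel(sites, species_id, chirality, "grid", instance_id)


def make_npc(
    ring_diameter: float = 107.0,
    ring_separation: float = 50.0,
    pair_spacing: float = 14.3,
    copies_per_ring: int = 16,
    species_id: int = 1,
    chirality: str = "R",
    instance_id: int = 0,
) -> StructureModel:
    """Nup96 nuclear-pore standard: two coaxial 8-fold rings of corner pairs.

    Each ring carries ``copies_per_ring / 2`` corners; a corner holds two
    sites ``pair_spacing`` apart along the ring tangent.  Rings sit at
    z = +/- ``ring_separation`` / 2.
    """
    if copies_per_ring % 2:
        raise ValueError("copies_per_ring must be even (sites come in corner pairs)")
    for name, v in (
        ("ring_diameter", ring_diameter),
        ("ring_separation", ring_separation),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    if pair_spacing < 0:
        raise ValueError("pair_spacing must be non-negative")
    n_corners = copies_per_ring // 2
    radius = ring_diameter / 2.0
    angles = 2.0 * np.pi * np.arange(n_corners) / n_corners
    corners = np.column_stack([radius * np.cos(angles), radius * np.sin(angles)])
    tangents = np.column_stack([-np.sin(angles), np.cos(angles)])
    ring_xy = np.concatenate(
        [corners - tangents * pair_spacing / 2.0, corners + tangents * pair_spacing / 2.0]
    )
    sites = []
    for z in (-ring_separation / 2.0, ring_separation / 2.0):
        sites.append(np.column_stack([ring_xy, np.full(len(ring_xy), z)]))
    return StructureModel(np.concatenate(sites), species_id, chirality, "npc", instance_id)


def make_filament(
    length: float = 4000.0,
    radius: float = 15.0,
    sites_per_um: float = 50.0,
    species_id: int = 1,
    chirality: str = "R",
    instance_id: int = 0,
    rng: np.random.Generator | None = None,
) -> StructureModel:
    """Sites uniform on a cylinder surface about a straight axis (the x axis).

    The 15 nm default radius reproduces the ~30 nm effective diameter of an
    antibody-labeled tubulin filament.  Site count is Poisson with mean
    ``sites_per_um * length / 1000``.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    if sites_per_um < 0 or length < 0:
        raise ValueError("density and length must be non-negative")
    rng = np.random.default_rng(0) if rng is None else rng
    mean_sites = sites_per_um * length / 1000.0
    if mean_sites == 0:
        import warnings

        warnings.warn("zero site density: empty filament")
        n = 0
    else:
        n = int(rng.poisson(mean_sites))
    x = rng.uniform(-length / 2.0, length / 2.0, size=n) if length > 0 else np.zeros(n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sites = np.column_stack([x, radius * np.cos(phi), radius * np.sin(phi)])
    if n == 0:
        sites = np.zeros((0, 3))
    return StructureModel(sites, species_id, chirality, "filament", instance_id)


# -- kinetics ------------------------------------------------------------------


def _alternating_intervals(
    rng: np.random.Generator, duration: float, tau_dark: float, tau_bright: float
) -> np.ndarray:
    """Bright intervals of one site over [0, duration], starting dark.

    The initial dark time is a fresh exponential draw, which by memorylessness
    equals the stationary residual dark time.
    """
    intervals = []
    t = 0.0
    n_guess = max(int(duration / (tau_dark + tau_bright) * 1.5) + 10, 16)
    while t < duration:
        darks = rng.exponential(tau_dark, n_guess)
        brights = rng.exponential(tau_bright, n_guess)
        for d, b in zip(darks, brights):
            t += d
            if t >= duration:
                break
            intervals.append((t, min(t + b, duration)))
            t += b
            if t >= duration:
                break
    return np.asarray(intervals, dtype=float).reshape(-1, 2)


def simulate_blinking(
    model: StructureModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    rate_scale: float = 1.0,
) -> list[EmitterTrace]:
    """Two-state binding simulation for every retained site of a structure.

    Sites are independently retained with probability ``labeling_efficiency``
    before simulation.  ``rate_scale`` multiplies the association rate and is
    used for off-target (crosstalk) binding; ``rate_scale = 0`` produces no
    events.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if rate_scale < 0:
        raise ValueError("rate_scale must be non-negative")
    traces: list[EmitterTrace] = []
    if rate_scale == 0.0:
        return traces
    tau_dark = config.tau_dark / rate_scale
    tau_bright = config.tau_bright
    retained = rng.random(model.n_sites) < config.labeling_efficiency
    for site_index in np.flatnonzero(retained):
        intervals = _alternating_intervals(rng, config.duration, tau_dark, tau_bright)
        if len(intervals):
            traces.append(EmitterTrace(int(site_index), intervals))
    return traces


def render_localizations(
    traces: Sequence[EmitterTrace],
    model: StructureModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> LocalizationTable:
    """Convert bright intervals into a frame-wise localization table.

    A frame yields one localization for a site when a bright interval covers
    at least ``min_on_fraction`` of its exposure; the localization is the true
    site position plus isotropic Gaussian noise (sigma =
    ``localization_precision_xy``, z noise ``localization_precision_z``).
    x/y are stored in pixels, z in nm.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    dt = config.exposure_time
    frames_parts, sites_parts = [], []
    for trace in traces:
        if not len(trace.intervals):
            continue
        u = trace.intervals[:, 0] / dt
        v = trace.intervals[:, 1] / dt
        # frame k is hit when its overlap with [u, v] is >= min_on_fraction
        k0 = np.ceil(u - (1.0 - config.min_on_fraction)).astype(np.int64)
        k1 = np.floor(v - config.min_on_fraction).astype(np.int64)
        k0 = np.clip(k0, 0, config.n_frames - 1)
        k1 = np.clip(k1, -1, config.n_frames - 1)
        counts = k1 - k0 + 1
        keep = counts > 0
        k0, counts = k0[keep], counts[keep]
        if not len(k0):
            continue
        total = int(counts.sum())
        offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        frames_parts.append(np.repeat(k0, counts) + offsets)
        sites_parts.append(np.full(total, trace.site_index, dtype=np.int64))
    metadata = {
        "n_frames": config.n_frames,
        "width": config.fov_width,
        "height": config.fov_height,
        "pixel_size": config.pixel_size,
        "exposure": config.exposure_time,
    }
    if not frames_parts:
        df = pd.DataFrame({"frame": np.zeros(0, dtype=np.int64), "x": [], "y": []})
        return LocalizationTable(df, metadata)
    frames = np.concatenate(frames_parts)
    site_idx = np.concatenate(sites_parts)
    pos = model.sites[site_idx].copy()
    pos[:, :2] += rng.normal(0.0, config.localization_precision_xy, size=(len(pos), 2))
    pos[:, 2] += rng.normal(0.0, config.localization_precision_z, size=len(pos))
    df = pd.DataFrame(
        {
            "frame": frames,
            "x": pos[:, 0] / config.pixel_size,
            "y": pos[:, 1] / config.pixel_size,
            "z": pos[:, 2],
            "photons": 0.0,
            "lpx": config.localization_precision_xy / config.pixel_size,
            "lpy": config.localization_precision_xy / config.pixel_size,
        }
    )
    table = LocalizationTable(df, metadata)
    return table.sorted_by_frame()


# -- exchange experiments ------------------------------------------------------


@dataclass
class GroundTruth:
    """Manifest of everything the simulator knows about one experiment."""

    models: list[StructureModel]
    round_species: list[int]
    fiducials_px: np.ndarray  # (F, 2)
    drift_traces: list[DriftTrace] = field(default_factory=list)
    config: SimulationConfig | None = None

    def site_array(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All site xy positions (nm) with species and structure indices."""
        xy = np.concatenate([m.sites[:, :2] for m in self.models])
        species = np.concatenate(
            [np.full(m.n_sites, m.species_id, dtype=int) for m in self.models]
        )
        structure = np.concatenate(
            [np.full(m.n_sites, i, dtype=int) for i, m in enumerate(self.models)]
        )
        return xy, species, structure

    def species_chirality(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for m in self.models:
            prev = out.setdefault(m.species_id, m.chirality)
            if prev != m.chirality:
                raise ValueError(f"species {m.species_id} appears with both chiralities")
        return out


def add_fiducials_and_drift(
    table: LocalizationTable,
    n_fiducials: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    positions_px: np.ndarray | None = None,
) -> tuple[LocalizationTable, DriftTrace]:
    """Append always-on fiducial tracks and apply random-walk drift.

    Fiducials emit exactly one localization per frame.  Drift is a cumulative
    2D Gaussian random walk with per-frame step scale ``drift_step`` (nm),
    applied to every localization; the injected per-frame trace (pixels) is
    returned alongside the table.
    """
    if n_fiducials < 0:
        raise ValueError("n_fiducials must be >= 0")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    px = config.pixel_size
    parts = [table.df]
    if n_fiducials > 0:
        if positions_px is None:
            margin = 16.0
            positions_px = np.column_stack(
                [
                    rng.uniform(margin, config.fov_width - margin, n_fiducials),
                    rng.uniform(margin, config.fov_height - margin, n_fiducials),
                ]
            )
        sigma_px = config.fiducial_precision_xy / px
        for fx, fy in np.asarray(positions_px, dtype=float):
            frames = np.arange(config.n_frames, dtype=np.int64)
            parts.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "x": fx + rng.normal(0.0, sigma_px, config.n_frames),
                        "y": fy + rng.normal(0.0, sigma_px, config.n_frames),
                        "z": 0.0,
                        "photons": 0.0,
                        "lpx": sigma_px,
                        "lpy": sigma_px,
                    }
                )
            )
    df = pd.concat(parts, ignore_index=True)
    if config.drift_step > 0:
        steps = rng.normal(0.0, config.drift_step / px, size=(config.n_frames, 2))
        walk = np.cumsum(steps, axis=0)
    else:
        walk = np.zeros((config.n_frames, 2))
    trace = DriftTrace(walk[:, 0], walk[:, 1])
    frames = df["frame"].to_numpy(dtype=np.int64)
    df["x"] = df["x"].to_numpy(dtype=float) + trace.dx[frames]
    df["y"] = df["y"].to_numpy(dtype=float) + trace.dy[frames]
    out = LocalizationTable(df, dict(table.metadata)).sorted_by_frame()
    return out, trace


def simulate_exchange_experiment(
    models: Sequence[StructureModel],
    round_species: Sequence[int],
    config: SimulationConfig,
    n_fiducials: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[list[LocalizationTable], GroundTruth]:
    """Simulate one localization table per exchange round.

    In round ``s`` sites of species ``s`` bind at the full rate, same-chirality
    off-target sites at ``crosstalk_rate`` times the rate, and opposite
    chirality sites not at all (mirror DNA does not hybridize with natural
    DNA).  Fiducials are shared across rounds; drift is drawn independently
    per round.
    """
    models = list(models)
    present = {m.species_id for m in models}
    missing = [s for s in round_species if s not in present]
    if missing:
        raise ValueError(f"round species absent from models: {missing}")
    chirality_of = GroundTruth(models, [], np.zeros((0, 2))).species_chirality()
    seed_seq = np.random.SeedSequence(config.rng_seed) if rng is None else None
    if rng is None:
        rng = np.random.default_rng(seed_seq)
    margin = 16.0
    fiducial_positions = np.column_stack(
        [
            rng.uniform(margin, config.fov_width - margin, n_fiducials),
            rng.uniform(margin, config.fov_height - margin, n_fiducials),
        ]
    ) if n_fiducials else np.zeros((0, 2))
    tables: list[LocalizationTable] = []
    drift_traces: list[DriftTrace] = []
    for round_index, species in enumerate(round_species):
        round_chirality = chirality_of[species]
        parts: list[pd.DataFrame] = []
        metadata = None
        for model in models:
            if model.species_id == species:
                scale = 1.0
            elif model.chirality != round_chirality:
                scale = 0.0
            else:
                scale = config.crosstalk_rate
            if scale == 0.0:
                continue
            traces = simulate_blinking(model, config, rng=rng, rate_scale=scale)
            tab = render_localizations(traces, model, config, rng=rng)
            metadata = tab.metadata
            if tab.n_locs:
                parts.append(tab.df)
        if parts:
            df = pd.concat(parts, ignore_index=True)
        else:
            df = pd.DataFrame({"frame": np.zeros(0, dtype=np.int64), "x": [], "y": []})
        metadata = metadata or {
            "n_frames": config.n_frames,
            "width": config.fov_width,
            "height": config.fov_height,
            "pixel_size": config.pixel_size,
            "exposure": config.exposure_time,
        }
        metadata = dict(metadata)
        metadata["round_label"] = f"round{round_index:02d}_species{species}"
        table = LocalizationTable(df, metadata)
        table, trace = add_fiducials_and_drift(
            table, n_fiducials, config, rng=rng, positions_px=fiducial_positions
        )
        tables.append(table)
        drift_traces.append(trace)
    manifest = GroundTruth(models, list(round_species), fiducial_positions, drift_traces, config)
    return tables, manifest


def place_on_lattice(
    models: Sequence[StructureModel],
    config: SimulationConfig,
    margin_px: float = 48.0,
    rng: np.random.Generator | None = None,
    jitter_nm: float = 200.0,
) -> list[StructureModel]:
    """Translate structures onto a jittered square lattice spanning the FOV.

    Keeps structures well separated (picks never overlap) and away from the
    border where fiducials live.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(models)
    px = config.pixel_size
    cols = max(int(math.ceil(math.sqrt(n))), 1)
    rows = int(math.ceil(n / cols))
    x_lo, x_hi = margin_px * px, (config.fov_width - margin_px) * px
    y_lo, y_hi = margin_px * px, (config.fov_height - margin_px) * px
    xs = np.linspace(x_lo, x_hi, cols)
    ys = np.linspace(y_lo, y_hi, rows)
    placed = []
    for i, model in enumerate(models):
        r, c = divmod(i, cols)
        jx, jy = rng.uniform(-jitter_nm, jitter_nm, 2)
        placed.append(model.translate(xs[c] + jx - model.center()[0], ys[r] + jy - model.center()[1]))
    return placed
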