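"""End-to-end scenario runner: simulate -> correct -> cluster -> kinetics -> metrics.

Scenarios encode the benchmark experiments at desk scale:

``origami12``
    12-plex exchange imaging of 15-nm-pitch origami site grids (6 R + 6 L
    species), site spacing, crosstalk matrix and per-species kinetics.
``origami5nm``
    Two-site 5-nm origami at 1.4 nm precision; NeNA precision and the
    two-component site-distance fit.
``npc``
    Nup96 nuclear-pore standards: corner-pair spacing, ring separation and
    whole-pore kinetics normalized by 16 copies x ~50% labeling.
``tubulin``
    A surface-labeled filament (~30 nm effective diameter) and its fitted
    cross-section diameter.
``neuron13``
    A 2x2-tile stitched field with 13 exchange rounds plus the
    experiment-time model of the multiplexed atlas.

Every run is fully determined by one integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clustermod
from . import kinetics as kineticsmod
from . import metrics as metricsmod
from . import register as registermod
from . import siggen
from .locio import LocalizationTable

SCENARIOS = ("origami12", "origami5nm", "npc", "tubulin", "neuron13")


@dataclass
class RunConfig:
    """Fully explicit parameter set of one scenario run."""

    scenario: str
    sim: siggen.SimulationConfig
    n_structures: int = 12  # per species
    cluster_radius: float = clustermod.DEFAULT_RADIUS_NM
    cluster_min_locs: int = clustermod.DEFAULT_MIN_LOCS
    pick_radius_px: float = 1.0
    max_gap_frames: int = 0  # simulator produces no mid-event flicker
    nena_min_pairs: int = 500
    n_fiducials: int = 3
    seed: int = 0
    out_dir: Path | None = None

    def to_dict(self) -> dict:
        """Scientific parameters only; the output path is not part of a run's
        identity (summaries of identical runs are byte-identical)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return d


def scenario_config(scenario: str, seed: int = 0, out_dir: str | Path | None = None) -> RunConfig:
    """Scenario defaults resolved to a fully explicit configuration."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    base = dict(rng_seed=seed, drift_step=0.2)
    if scenario == "origami12":
        sim = siggen.SimulationConfig(
            localization_precision_xy=1.5,
            localization_precision_z=5.0,
            labeling_efficiency=0.9,
            **base,
        )
        cfg = RunConfig(scenario, sim, n_structures=12, pick_radius_px=1.0)
    elif scenario == "origami5nm":
        sim = siggen.SimulationConfig(
            exposure_time=0.1,
            n_frames=100_000,
            imager_concentration=50.0,
            localization_precision_xy=1.4,
            localization_precision_z=5.0,
            **base,
        )
        cfg = RunConfig(scenario, sim, n_structures=12, pick_radius_px=1.0)
    elif scenario == "npc":
        sim = siggen.SimulationConfig(
            n_frames=40_000,
            localization_precision_xy=2.0,
            localization_precision_z=10.0,
            labeling_efficiency=0.5,
            **base,
        )
        cfg = RunConfig(scenario, sim, n_structures=120, pick_radius_px=2.0)
    elif scenario == "tubulin":
        sim = siggen.SimulationConfig(
            imager_concentration=25.0,
            localization_precision_xy=2.0,
            localization_precision_z=2.0,
            **base,
        )
        cfg = RunConfig(scenario, sim, n_structures=1)
    else:  # neuron13
        sim = siggen.SimulationConfig(
            n_frames=7500,
            localization_precision_xy=5.0,
            localization_precision_z=10.0,
            drift_step=0.0,
            rng_seed=seed,
        )
        cfg = RunConfig(scenario, sim, n_structures=8, n_fiducials=6)
    cfg.seed = seed
    cfg.out_dir = Path(out_dir) if out_dir else None
    return cfg


# -- shared stages -------------------------------------------------------------


def _strip_fiducials(table: LocalizationTable, manifest: siggen.GroundTruth) -> LocalizationTable:
    if not len(manifest.fiducials_px):
        return table
    from scipy.spatial import cKDTree

    d, _ = cKDTree(manifest.fiducials_px).query(table.xy_px())
    return table.subset(d > 2.0)


def _correct_rounds(
    tables: list[LocalizationTable], config: RunConfig
) -> list[LocalizationTable]:
    """Fiducial drift correction of every round (no-op without drift/fiducials)."""
    if config.n_fiducials == 0:
        return tables
    out = []
    for table in tables:
        trace = registermod.track_fiducials(table)
        out.append(registermod.undrift(table, trace))
    return out


def _species_kinetics(
    picks: list[LocalizationTable],
    config: RunConfig,
    n_sites_override: float | None = None,
) -> tuple[kineticsmod.KineticsSummary, list[clustermod.ClusterSet]]:
    """Cluster each pick, count sites, link events and summarize kinetics."""
    cluster_sets, event_lists, site_counts = [], [], []
    for pick in picks:
        cs = clustermod.cluster_locs(pick, config.cluster_radius, config.cluster_min_locs)
        cluster_sets.append(cs)
        site_counts.append(clustermod.count_sites(cs))
        event_lists.append(kineticsmod.link_events(pick, config.max_gap_frames))
    tau_b, tau_d, n_events, _ = kineticsmod.pooled_bright_dark(
        event_lists, config.sim.exposure_time
    )
    if n_sites_override is not None:
        n_sites = float(n_sites_override)
    else:
        n_sites = float(np.mean([c for c in site_counts if c > 0])) if any(site_counts) else 1.0
    summary = kineticsmod.KineticsSummary.from_times(
        tau_b,
        tau_d,
        config.sim.imager_concentration,
        max(n_sites, 1.0),
        n_picks=len(picks),
        n_events=n_events,
    )
    return summary, cluster_sets


def _pick_centers_px(models: list[siggen.StructureModel], pixel_size: float) -> np.ndarray:
    return np.array([m.center()[:2] / pixel_size for m in models])


# -- scenarios -----------------------------------------------------------------


def _run_origami12(config: RunConfig, rng: np.random.Generator) -> dict:
    sim = config.sim
    species_ids = list(range(1, 13))
    chirality = {s: ("R" if s <= 6 else "L") for s in species_ids}
    models = []
    instance = 0
    for s in species_ids:
        for _ in range(config.n_structures):
            models.append(
                siggen.make_origami_grid(4, 3, 15.0, s, chirality[s], instance_id=instance)
            )
            instance += 1
    models = siggen.place_on_lattice(models, sim, rng=rng)
    tables, manifest = siggen.simulate_exchange_experiment(
        models, species_ids, sim, n_fiducials=config.n_fiducials, rng=rng
    )
    corrected = _correct_rounds(tables, config)

    xtalk = metricsmod.crosstalk_matrix(corrected, manifest)
    nn_all, kinetics_rows = [], []
    for round_index, species in enumerate(species_ids):
        round_models = [m for m in models if m.species_id == species]
        centers = _pick_centers_px(round_models, sim.pixel_size)
        picks = clustermod.pick_regions(corrected[round_index], centers, config.pick_radius_px)
        picks = [p for p in picks if p.n_locs]
        summary, cluster_sets = _species_kinetics(picks, config)
        for cs in cluster_sets:
            if cs.accepted.sum() >= 2:
                _, nn = metricsmod.site_spacing(cs)
                nn_all.append(nn)
        kinetics_rows.append(
            {"species": f"{chirality[species]}{(species - 1) % 6 + 1}", **dataclasses.asdict(summary)}
        )
    nn_all = np.concatenate(nn_all)
    nena = metricsmod.nena_precision(
        _strip_fiducials(corrected[0], manifest), config.nena_min_pairs
    )
    return {
        "site_spacing_nm": {"mean": float(nn_all.mean()), "n_pairs": int(len(nn_all))},
        "kinetics": kinetics_rows,
        "crosstalk": {
            "matrix": xtalk.matrix.tolist(),
            "species": xtalk.species.tolist(),
            "unassigned": xtalk.unassigned.tolist(),
            "max_off_diagonal": float(
                np.max(xtalk.matrix - np.diag(np.diag(xtalk.matrix)))
            ),
            "diagonal_dominant": xtalk.diagonal_dominant(),
        },
        "nena_sigma_nm": nena.sigma,
    }


def _run_origami5nm(config: RunConfig, rng: np.random.Generator) -> dict:
    sim = config.sim
    models = [
        siggen.make_origami_grid(1, 2, 5.0, species_id=12, chirality="L", instance_id=i)
        for i in range(config.n_structures)
    ]
    models = siggen.place_on_lattice(models, sim, rng=rng)
    tables, manifest = siggen.simulate_exchange_experiment(
        models, [12], sim, n_fiducials=config.n_fiducials, rng=rng
    )
    corrected = _correct_rounds(tables, config)
    table = _strip_fiducials(corrected[0], manifest)
    nena = metricsmod.nena_precision(table, config.nena_min_pairs)
    # clustering merges the 5-nm pair at the 6.5-nm radius: measure the site
    # distance with a per-structure two-component mixture fit instead
    centers = _pick_centers_px(models, sim.pixel_size)
    picks = clustermod.pick_regions(table, centers, config.pick_radius_px)
    pair_d = [
        metricsmod.pair_distance_mixture(p.xy_nm(), random_state=config.seed)
        for p in picks
        if p.n_locs >= 100
    ]
    events = [kineticsmod.link_events(p, config.max_gap_frames) for p in picks if p.n_locs]
    tau_b, tau_d, n_events, _ = kineticsmod.pooled_bright_dark(events, sim.exposure_time)
    summary = kineticsmod.KineticsSummary.from_times(
        tau_b, tau_d, sim.imager_concentration, 2.0, n_picks=len(picks), n_events=n_events
    )
    return {
        "nena_sigma_nm": nena.sigma,
        "nena_n_pairs": nena.n_pairs,
        "pair_distance_nm": {"mean": float(np.mean(pair_d)), "n": len(pair_d)},
        "kinetics": [dataclasses.asdict(summary)],
    }


def _run_npc(config: RunConfig, rng: np.random.Generator) -> dict:
    sim = config.sim
    models = [
        siggen.make_npc(species_id=8, chirality="L", instance_id=i)
        for i in range(config.n_structures)
    ]
    models = siggen.place_on_lattice(models, sim, rng=rng)
    tables, manifest = siggen.simulate_exchange_experiment(
        models, [8], sim, n_fiducials=config.n_fiducials, rng=rng
    )
    corrected = _correct_rounds(tables, config)
    table = _strip_fiducials(corrected[0], manifest)
    centers = _pick_centers_px(models, sim.pixel_size)
    picks = clustermod.pick_regions(table, centers, config.pick_radius_px)
    picks = [p for p in picks if p.n_locs]
    n_eff = kineticsmod.npc_site_normalization(16, sim.labeling_efficiency)
    summary, cluster_sets = _species_kinetics(picks, config, n_sites_override=n_eff)
    pair_distances = []
    for cs in cluster_sets:
        pairs = metricsmod.mutual_pair_distances(cs.accepted_centers()[:, :2], max_distance=25.0)
        pair_distances.append(pairs)
    pair_distances = np.concatenate(pair_distances) if pair_distances else np.zeros(0)
    z = np.concatenate([p.df["z"].to_numpy() for p in picks])
    ring = metricsmod.ring_separation(z)
    return {
        "pair_distance_nm": {
            "mean": float(pair_distances.mean()),
            "n_pairs": int(len(pair_distances)),
        },
        "ring_separation_nm": ring.delta_z,
        "ring_fit_degenerate": bool(ring.degenerate),
        "n_eff_sites": n_eff,
        "kinetics": [dataclasses.asdict(summary)],
        "n_npcs": len(picks),
    }


def _run_tubulin(config: RunConfig, rng: np.random.Generator) -> dict:
    sim = config.sim
    model = siggen.make_filament(rng=rng, species_id=1, chirality="L")
    center_nm = np.array([sim.fov_width, sim.fov_height, 0.0]) * sim.pixel_size / 2.0
    model = model.translate(*center_nm[:2])
    tables, manifest = siggen.simulate_exchange_experiment(
        [model], [1], sim, n_fiducials=config.n_fiducials, rng=rng
    )
    corrected = _correct_rounds(tables, config)
    table = _strip_fiducials(corrected[0], manifest)
    # select the filament neighborhood: within 60 nm of the true axis
    pts = table.xyz_nm()
    axis_y = model.center()[1]
    near = np.abs(pts[:, 1] - axis_y) < 60.0
    span = np.abs(pts[:, 0] - model.center()[0]) < (np.ptp(model.sites[:, 0]) / 2.0 + 50.0)
    pts = pts[near & span]
    diameter = metricsmod.filament_diameter(pts)
    return {
        "filament_diameter_nm": diameter,
        "n_points": int(len(pts)),
        "n_sites_true": int(model.n_sites),
    }


def _run_neuron13(config: RunConfig, rng: np.random.Generator) -> dict:
    """Stitched 2x2 multiplexed field plus the atlas time model.

    One oversized field is simulated, cut into four tiles with a 10 um
    overlap, and per-tile sub-pixel offsets are injected; stitching must
    recover them on the reference channel and transfer them to all rounds.
    """
    sim = config.sim
    overlap_um = 10.0
    overlap_px = overlap_um * 1000.0 / sim.pixel_size
    big = replace(
        sim,
        fov_width=int(2 * sim.fov_width - overlap_px),
        fov_height=int(2 * sim.fov_height - overlap_px),
    )
    species_ids = list(range(1, 14))
    chirality = {s: ("R" if s <= 6 or s == 13 else "L") for s in species_ids}
    models = []
    for s in species_ids:
        for i in range(config.n_structures):
            models.append(siggen.make_origami_grid(4, 3, 15.0, s, chirality[s], instance_id=i))
    # uniform random placement, stratified so that every tile-overlap band
    # holds structures to register on (the cellular samples the protocol is
    # built for are dense everywhere; sparse synthetic fields need the help)
    margin = 24.0
    px = big.pixel_size
    w_nm, h_nm = sim.fov_width * px, sim.fov_height * px
    ov_nm = overlap_px * px
    big_w_nm = big.fov_width * px
    bands = [
        ((w_nm - ov_nm, margin * px), (w_nm, h_nm - ov_nm)),  # (0,0)-(0,1)
        ((margin * px, h_nm - ov_nm), (w_nm, h_nm)),  # (0,0)-(1,0)
        ((w_nm, h_nm - ov_nm), (big_w_nm - margin * px, h_nm)),  # (0,1)-(1,1)
    ]
    in_band = rng.choice(len(models), size=5 * len(bands), replace=False)
    for k, m in enumerate(models):
        if k in in_band:
            lo, hi = bands[int(np.flatnonzero(in_band == k)[0]) % len(bands)]
            pos = rng.uniform(lo, hi)
        else:
            pos = rng.uniform(
                [margin * px] * 2,
                [big.fov_width * px - margin * px, big.fov_height * px - margin * px],
            )
        models[k] = m.translate(pos[0] - m.center()[0], pos[1] - m.center()[1])
    tables, manifest = siggen.simulate_exchange_experiment(
        models, species_ids, big, n_fiducials=0, rng=rng
    )
    # cut tiles and inject per-tile offsets
    w, h = sim.fov_width, sim.fov_height
    injected = {
        (0, 0): (0.0, 0.0),
        (0, 1): tuple(rng.uniform(-1.5, 1.5, 2)),
        (1, 0): tuple(rng.uniform(-1.5, 1.5, 2)),
        (1, 1): tuple(rng.uniform(-1.5, 1.5, 2)),
    }
    tiles: dict[tuple[int, int], list[LocalizationTable]] = {}
    for (row, col), (ddx, ddy) in injected.items():
        ox = col * (w - overlap_px)
        oy = row * (h - overlap_px)
        channel_tables = []
        # channel 0 is the pooled registration channel (all rounds combined);
        # the per-tile shift estimated on it is transferred to every round
        pooled = pd.concat([t.df for t in tables], ignore_index=True)
        for df in [pooled] + [t.df for t in tables]:
            mask = (
                (df["x"] >= ox) & (df["x"] <= ox + w) & (df["y"] >= oy) & (df["y"] <= oy + h)
            )
            sub = df.loc[mask].copy()
            sub["x"] = sub["x"] - ox + ddx
            sub["y"] = sub["y"] - oy + ddy
            meta = dict(tables[0].metadata)
            meta.update(width=w, height=h)
            channel_tables.append(LocalizationTable(sub.reset_index(drop=True), meta))
        tiles[(row, col)] = channel_tables
    shifts = registermod.stitch_tiles(tiles, overlap_um=overlap_um, channel=0)
    errors_px = {
        f"{pos}": float(np.hypot(shifts[pos].dx + inj[0], shifts[pos].dy + inj[1]))
        for pos, inj in injected.items()
    }
    render_bin_px = 65.0 / sim.pixel_size
    t_total = kineticsmod.experiment_time(13, 40.0, 12, 2.0)
    return {
        "stitch_error_px": errors_px,
        "stitch_error_bins_max": float(max(errors_px.values()) / render_bin_px),
        "atlas_time_min": t_total,
        "atlas_time_hours": kineticsmod.whole_hours(t_total),
    }


def simulate_and_recover_kinetics(
    k_on: float,
    k_off: float,
    concentration_pm: float,
    grid_shape: tuple[int, int],
    n_structures: int,
    seed: int = 0,
    n_frames: int = 15000,
    exposure: float = 0.075,
    precision_nm: float = 1.5,
) -> dict:
    """Full-pipeline rate recovery on a field of origami grids.

    Simulates ``n_structures`` site grids at the given kinetic parameters,
    picks each structure, clusters to count detected sites, links binding
    events and returns the recovered rates next to the ground truth.  Used
    for parameter-recovery validation of the whole analysis chain.
    """
    sim = siggen.SimulationConfig(
        exposure_time=exposure,
        n_frames=n_frames,
        imager_concentration=concentration_pm,
        k_on=k_on,
        k_off=k_off,
        localization_precision_xy=precision_nm,
        localization_precision_z=5.0,
        rng_seed=seed,
    )
    config = RunConfig("origami12", sim, n_structures=n_structures, seed=seed, n_fiducials=0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = grid_shape
    models = [
        siggen.make_origami_grid(rows, cols, 15.0, species_id=1, chirality="R", instance_id=i)
        for i in range(n_structures)
    ]
    models = siggen.place_on_lattice(models, sim, rng=rng)
    tables, _ = siggen.simulate_exchange_experiment(models, [1], sim, n_fiducials=0, rng=rng)
    centers = _pick_centers_px(models, sim.pixel_size)
    picks = clustermod.pick_regions(tables[0], centers, config.pick_radius_px)
    picks = [p for p in picks if p.n_locs]
    summary, _ = _species_kinetics(picks, config)
    return {
        "k_on_true": k_on,
        "k_off_true": k_off,
        "k_on_est": summary.k_on,
        "k_off_est": summary.k_off,
        "tau_b": summary.tau_b,
        "tau_d_norm": summary.tau_d_norm,
        "n_sites_detected": summary.n_sites,
        "n_events": summary.n_events,
    }


_RUNNERS = {
    "origami12": _run_origami12,
    "origami5nm": _run_origami5nm,
    "npc": _run_npc,
    "tubulin": _run_tubulin,
    "neuron13": _run_neuron13,
}


def run_scenario(config: RunConfig) -> dict:
    """Execute a scenario end to end; returns (and optionally writes) a summary."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    config.sim = replace(config.sim, rng_seed=config.seed)
    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    result = _RUNNERS[config.scenario](config, rng)
    summary = {
        "schema_version": 1,
        "scenario": config.scenario,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "results": result,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True)
        rows = result.get("kinetics")
        if rows:
            pd.DataFrame(rows).to_csv(out / "kinetics.csv", index=False)
    return summary
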