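"""Bright/dark-time extraction, normalization and the throughput model.

Kinetics are evaluated on whole picked structures (an origami or a nuclear
pore): frames carrying localizations are linked into binding events, the
mean event duration is the bright time tau_b = 1/k_off, and the mean
inter-event gap is the raw per-structure dark time.  Because n active sites
share one pick, and the dark time scales inversely with imager
concentration, the raw dark time is converted to a single-site value at the
100 pM reference:

    tau_d_norm = tau_d_raw * (c / 100 pM) * n_sites

For nuclear pores the site count is not taken from clustering but from the
expected 16 Nup96 copies at ~50% labeling efficiency (n_eff = 8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .locio import LocalizationTable

#: reference imager concentration for normalized dark times (pM)
REFERENCE_CONCENTRATION_PM = 100.0
PM_TO_M = 1e-12


@dataclass
class BindingEvent:
    """One contiguous bound interval in frame units (inclusive ends)."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")

    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration(self, exposure: float) -> float:
        return self.n_frames() * exposure


@dataclass
class KineticsSummary:
    """Mean bright/dark times with normalization and implied rates."""

    tau_b: float  # s
    tau_d_raw: float | None  # mean per-pick dark time, s
    c: float  # imager concentration, pM
    n_sites: float  # normalization site count
    tau_d_norm: float | None  # single-site dark time at 100 pM, s
    k_off: float  # 1/s
    k_on: float | None  # 1/(M s)
    n_picks: int = 0
    n_events: int = 0

    @classmethod
    def from_times(
        cls,
        tau_b: float,
        tau_d_raw: float | None,
        c: float,
        n_sites: float,
        n_picks: int = 0,
        n_events: int = 0,
    ) -> "KineticsSummary":
        tau_d_norm = None if tau_d_raw is None else normalize_dark(tau_d_raw, c, n_sites)
        k_off = 1.0 / tau_b
        k_on = None
        if tau_d_norm is not None:
            k_on = 1.0 / (tau_d_norm * REFERENCE_CONCENTRATION_PM * PM_TO_M)
        return cls(tau_b, tau_d_raw, c, n_sites, tau_d_norm, k_off, k_on, n_picks, n_events)


def link_events(
    pick: LocalizationTable | np.ndarray,
    max_gap_frames: int = 1,
) -> list[BindingEvent]:
    """Link localization-bearing frames of a pick into binding events.

    Maximal runs of frames are merged when separated by gaps of at most
    ``max_gap_frames`` empty frames; bridged frames count toward the event
    duration.
    """
    if isinstance(pick, LocalizationTable):
        frames = pick.frames()
    else:
        frames = np.asarray(pick, dtype=np.int64)
    if len(frames) == 0:
        return []
    frames = np.unique(frames)
    breaks = np.flatnonzero(np.diff(frames) > max_gap_frames + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(frames) - 1]])
    return [BindingEvent(int(frames[s]), int(frames[e])) for s, e in zip(starts, ends)]


def event_durations_and_gaps(
    events: Sequence[BindingEvent],
) -> tuple[np.ndarray, np.ndarray]:
    """Durations and exclusive inter-event gaps, both in frames.

    First/last partial dark intervals (before the first and after the last
    event) are not observable and are excluded by construction.
    """
    durations = np.array([e.n_frames() for e in events], dtype=float)
    if len(events) < 2:
        return durations, np.zeros(0)
    starts = np.array([e.start_frame for e in events], dtype=float)
    ends = np.array([e.end_frame for e in events], dtype=float)
    gaps = starts[1:] - ends[:-1] - 1.0
    return durations, gaps


def bright_dark_times(
    events: Sequence[BindingEvent],
    n_frames: int,
    exposure: float,
) -> tuple[float, float | None]:
    """Mean bright time and mean raw dark time of one pick, in seconds.

    With fewer than two events the dark time is undefined and returned as
    ``None``.
    """
    if not events:
        raise ValueError("no events")
    durations, gaps = event_durations_and_gaps(events)
    tau_b = float(durations.mean() * exposure)
    tau_d = float(gaps.mean() * exposure) if len(gaps) else None
    return tau_b, tau_d


def pooled_bright_dark(
    event_lists: Iterable[Sequence[BindingEvent]],
    exposure: float,
) -> tuple[float, float | None, int, int]:
    """Pool all event durations and gaps across picks.

    Returns (tau_b, tau_d_raw, n_events, n_gaps); mirrors extracting the mean
    bright and dark times over many individual structures.
    """
    all_durations, all_gaps = [], []
    for events in event_lists:
        if not events:
            continue
        d, g = event_durations_and_gaps(events)
        all_durations.append(d)
        all_gaps.append(g)
    durations = np.concatenate(all_durations) if all_durations else np.zeros(0)
    gaps = np.concatenate(all_gaps) if all_gaps else np.zeros(0)
    if not len(durations):
        raise ValueError("no events in any pick")
    tau_b = float(durations.mean() * exposure)
    tau_d = float(gaps.mean() * exposure) if len(gaps) else None
    return tau_b, tau_d, len(durations), len(gaps)


def normalize_dark(tau_d_raw: float, c: float, n_sites: float) -> float:
    """Single-site dark time at the 100 pM reference concentration.

    ``tau_d_norm = tau_d_raw * (c / 100 pM) * n_sites``: the measured
    per-structure dark time is shortened both by the number of active sites
    and by concentrations above the reference, so both factors are undone.
    """
    if not tau_d_raw > 0:
        raise ValueError("tau_d_raw must be positive")
    if not c > 0:
        raise ValueError("concentration must be positive")
    if not n_sites >= 1:
        raise ValueError("n_sites must be >= 1")
    return tau_d_raw * (c / REFERENCE_CONCENTRATION_PM) * n_sites


def npc_site_normalization(copies: int = 16, labeling_efficiency: float = 0.5) -> float:
    """Effective binding-site count of one nuclear pore.

    16 Nup96 copies at ~50% labeling efficiency give n_eff = 8, the factor
    that converts whole-pore dark times to single-site kinetics.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ValueError("labeling_efficiency must be in (0, 1]")
    return copies * labeling_efficiency


def estimate_rates(summary: KineticsSummary) -> tuple[float, float]:
    """Invert the two-state relations: k_off = 1/tau_b, k_on = 1/(tau_d_norm * c_ref)."""
    if not summary.tau_b or summary.tau_b <= 0:
        raise ValueError("tau_b must be positive")
    if summary.tau_d_norm is None or summary.tau_d_norm <= 0:
        raise ValueError("tau_d_norm must be positive")
    k_off = 1.0 / summary.tau_b
    k_on = 1.0 / (summary.tau_d_norm * REFERENCE_CONCENTRATION_PM * PM_TO_M)
    return k_off, k_on


def fit_exponential_tail(durations_s: np.ndarray, cutoff_s: float = 0.0) -> float:
    """Cross-check utility: MLE of an exponential mean on values > cutoff.

    For an exponential distribution E[x | x > a] = a + mean, so the mean is
    the truncated average minus the cutoff.
    """
    d = np.asarray(durations_s, dtype=float)
    d = d[d > cutoff_s]
    if not len(d):
        raise ValueError("no durations above cutoff")
    return float(d.mean() - cutoff_s)


def experiment_time(
    n_targets: int,
    t_round_min: float,
    n_exchanges: int,
    t_exchange_min: float,
) -> float:
    """Total multiplexed-experiment wall time in minutes.

    ``n_targets`` sequential acquisition rounds of ``t_round_min`` each plus
    ``n_exchanges`` buffer exchanges of ``t_exchange_min``: for the 13-plex
    atlas (13 x 40 min + 12 x 2 min) this is 544 min.
    """
    if n_targets < 0 or n_exchanges < 0:
        raise ValueError("counts must be non-negative")
    return n_targets * t_round_min + n_exchanges * t_exchange_min


def whole_hours(minutes: float) -> int:
    """Experiment time rounded up to whole hours (544 min -> 10 h)."""
    return int(math.ceil(minutes / 60.0))
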