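"""Shared builders for test tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from paintbench.locio import LocalizationTable


def table_from_xy(
    xy_px: np.ndarray,
    frames: np.ndarray,
    n_frames: int | None = None,
    pixel_size: float = 130.0,
    width: int = 576,
    height: int = 576,
    exposure: float = 0.075,
    z: np.ndarray | float = 0.0,
) -> LocalizationTable:
    xy_px = np.atleast_2d(np.asarray(xy_px, dtype=float))
    frames = np.asarray(frames, dtype=np.int64)
    df = pd.DataFrame({"frame": frames, "x": xy_px[:, 0], "y": xy_px[:, 1]})
    df["z"] = z
    meta = {
        "n_frames": int(n_frames if n_frames is not None else frames.max() + 1),
        "width": width,
        "height": height,
        "pixel_size": pixel_size,
        "exposure": exposure,
    }
    return LocalizationTable(df, meta)


def single_emitter_table(
    rng: np.random.Generator,
    sigma_nm: float,
    n_locs: int,
    center_px: tuple[float, float] = (100.0, 100.0),
    pixel_size: float = 130.0,
) -> LocalizationTable:
    """One always-on emitter localized in every frame: ideal NeNA input."""
    xy = np.array(center_px) + rng.normal(0.0, sigma_nm / pixel_size, size=(n_locs, 2))
    return table_from_xy(xy, np.arange(n_locs), pixel_size=pixel_size)
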