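"""Localization-table I/O.

Localization lists are exchanged in the HDF5 dialect common to DNA-PAINT
software (a structured dataset named ``"locs"`` with a YAML metadata sidecar
next to the file) or as plain CSV.  Coordinates follow the usual convention:
``x``/``y`` in camera pixels with the origin at the top-left corner, ``z`` in
nanometers, frames 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
import yaml

#: canonical column order; frame/x/y are mandatory, the rest optional
COLUMNS = ["frame", "x", "y", "z", "photons", "lpx", "lpy"]
MANDATORY = ["frame", "x", "y"]

#: mapping between metadata keys and the YAML sidecar spelling
_YAML_KEYS = {
    "width": "Width",
    "height": "Height",
    "n_frames": "Frames",
    "pixel_size": "Pixelsize",
    "exposure": "Exposure",
    "round_label": "Round",
}


class LocIOError(ValueError):
    """Malformed localization file or metadata/record inconsistency."""


@dataclass
class LocalizationTable:
    """Per-localization records plus acquisition metadata.

    ``df`` holds one row per localization with at least the mandatory
    columns; unknown extra columns are carried along untouched.  ``metadata``
    holds ``n_frames``, ``width``/``height`` (pixels), ``pixel_size`` (nm),
    ``exposure`` (s) and optionally a round label.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY if c not in self.df.columns]
        if missing:
            raise LocIOError(f"missing mandatory columns: {missing}")
        for col, default in (("z", 0.0), ("photons", 0.0), ("lpx", 0.0), ("lpy", 0.0)):
            if col not in self.df.columns:
                self.df[col] = default

    # -- convenience accessors -------------------------------------------------
    @property
    def n_locs(self) -> int:
        return len(self.df)

    @property
    def pixel_size(self) -> float:
        return float(self.metadata.get("pixel_size", 130.0))

    @property
    def n_frames(self) -> int | None:
        n = self.metadata.get("n_frames")
        return None if n is None else int(n)

    @property
    def exposure(self) -> float | None:
        e = self.metadata.get("exposure")
        return None if e is None else float(e)

    def frames(self) -> np.ndarray:
        return self.df["frame"].to_numpy(dtype=np.int64)

    def xy_px(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def xy_nm(self) -> np.ndarray:
        return self.xy_px() * self.pixel_size

    def xyz_nm(self) -> np.ndarray:
        xy = self.xy_nm()
        z = self.df["z"].to_numpy(dtype=float)
        return np.column_stack([xy, z])

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.df.copy(), dict(self.metadata))

    def sorted_by_frame(self) -> "LocalizationTable":
        df = self.df.sort_values("frame", kind="stable").reset_index(drop=True)
        return LocalizationTable(df, dict(self.metadata))

    def subset(self, mask: np.ndarray) -> "LocalizationTable":
        return LocalizationTable(
            self.df.loc[np.asarray(mask)].reset_index(drop=True), dict(self.metadata)
        )

    def validate(self) -> None:
        """Check record/metadata consistency; raise :class:`LocIOError`."""
        df = self.df
        if len(df) == 0:
            return
        if not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy(dtype=float))):
            raise LocIOError("non-finite coordinates")
        if (df["frame"] < 0).any():
            raise LocIOError("negative frame index")
        n_frames = self.metadata.get("n_frames")
        if n_frames is not None and (df["frame"] >= int(n_frames)).any():
            raise LocIOError(
                f"frame index >= n_frames ({int(n_frames)}): records and metadata disagree"
            )
        if float(self.metadata.get("pixel_size", 130.0)) <= 0:
            raise LocIOError("pixel_size must be positive")
        width = self.metadata.get("width")
        if width is not None and ((df["x"] < 0) | (df["x"] > float(width))).any():
            raise LocIOError("x coordinates outside [0, width]")
        height = self.metadata.get("height")
        if height is not None and ((df["y"] < 0) | (df["y"] > float(height))).any():
            raise LocIOError("y coordinates outside [0, height]")


def concatenate(tables: Iterable[LocalizationTable]) -> LocalizationTable:
    """Merge tables sharing one acquisition; records re-sorted by frame."""
    tables = list(tables)
    if not tables:
        raise ValueError("nothing to concatenate")
    meta = dict(tables[0].metadata)
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return LocalizationTable(df, meta).sorted_by_frame()


# -- readers / writers ---------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _metadata_to_yaml(metadata: dict) -> dict:
    out = {}
    for key, value in metadata.items():
        out[_YAML_KEYS.get(key, key)] = value
    return out


def _metadata_from_yaml(doc: dict) -> dict:
    inverse = {v: k for k, v in _YAML_KEYS.items()}
    return {inverse.get(k, k): v for k, v in doc.items()}


def write_locs(table: LocalizationTable, path: str | Path, format: str | None = None) -> Path:
    """Write a table to HDF5 (``locs`` dataset + YAML sidecar) or CSV.

    The format is inferred from the suffix when not given.  Records are
    written sorted by frame; 64-bit floats are preserved losslessly.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    table.validate()
    table = table.sorted_by_frame()
    extras = [c for c in table.df.columns if c not in COLUMNS]
    cols = COLUMNS + extras
    df = table.df[cols]
    if fmt == "hdf5":
        dtypes = [("frame", np.int64)] + [(c, np.float64) for c in cols if c != "frame"]
        rec = np.zeros(len(df), dtype=dtypes)
        for c in cols:
            rec[c] = df[c].to_numpy()
        with h5py.File(path, "w") as f:
            f.create_dataset("locs", data=rec)
    elif fmt == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    with open(_sidecar_path(path), "w") as f:
        yaml.safe_dump(_metadata_to_yaml(table.metadata), f, sort_keys=True)
    return path


def read_locs(path: str | Path) -> LocalizationTable:
    """Read an HDF5 or CSV localization list, merging sidecar metadata.

    Missing optional columns are filled with defaults; unknown extra columns
    are kept.  Raises :class:`LocIOError` on missing mandatory columns or
    metadata/record inconsistencies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
    else:
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise LocIOError(f"{path}: no 'locs' dataset")
            rec = f["locs"][()]
        df = pd.DataFrame({name: rec[name] for name in rec.dtype.names})
    metadata: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as f:
            doc = yaml.safe_load(f)
        if doc:
            metadata = _metadata_from_yaml(doc)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise LocIOError(f"{path}: missing mandatory columns {missing}")
    if "n_frames" not in metadata and len(df):
        metadata["n_frames"] = int(df["frame"].max()) + 1
    if "pixel_size" not in metadata:
        warnings.warn(f"{path}: no Pixelsize in sidecar, assuming 130 nm")
        metadata["pixel_size"] = 130.0
    table = LocalizationTable(df, metadata)
    table.validate()
    return table
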