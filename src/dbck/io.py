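"""Readers and writers for the on-disk formats, plus run configuration.

All coordinates on disk are in nanometres, never pixels; pixel
conversion happens only at image boundaries. CSV dialect:
comma-separated, UTF-8, '.' decimal, header mandatory. Every writer
here has a matching reader and the pair round-trips.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import cosa
from .neckmetrics import NeckLandmarks, RodPointCloud
from .synthgen import Raster, SpermSpecimen

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_specimens_csv",
    "read_specimens_csv",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_localizations_csv",
    "read_localizations_csv",
    "write_waveforms_csv",
    "read_waveforms_csv",
    "write_image",
    "read_image",
]


@dataclass
class RunConfig:
    """Pipeline configuration; serializes round-trip stable to YAML."""

    pixel_size: float = 100.0     # nm
    a: float = 600.0              # flagellar diameter, nm
    ds: float = 100.0             # arclength grid, nm
    t1: float = cosa.DEFAULT_T1   # straight / mild-bend threshold
    t2: float = cosa.DEFAULT_T2   # mild / sharp threshold
    kink_deg: float = cosa.DEFAULT_KINK_DEG
    bin_nm: float = 20.0          # profile histogram bin
    seed: int = 0
    n_specimens: int = 248
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("pixel_size", "a", "ds", "bin_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        """Stable short hash of the configuration, stamped on outputs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# specimen / truth table
# ---------------------------------------------------------------------------

def write_specimens_csv(specimens: list[SpermSpecimen], path) -> None:
    rows = []
    for sp in specimens:
        row = {"id": sp.specimen_id,
               "category": sp.beat_class_true.category.value,
               "subtype": sp.beat_class_true.subtype.value}
        row.update({f"truth_{k}": v for k, v in asdict(sp.truth).items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_specimens_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# landmarks (long format: id, landmark_name, x_nm, y_nm)
# ---------------------------------------------------------------------------

_TWO_POINT = ("neck_midline", "head_axis", "pc_axis", "rod_left", "rod_right",
              "bars_left", "bars_right")
_SINGLE = ("mt_left", "mt_right", "mt_center")
_CHAIN = ("sc_left", "sc_right")


def _landmark_rows(landmarks: NeckLandmarks) -> list[tuple[str, float, float]]:
    rows = []
    for name in _TWO_POINT:
        arr = getattr(landmarks, name)
        if arr is not None:
            rows.append((f"{name}_rostral", arr[0][0], arr[0][1]))
            rows.append((f"{name}_caudal", arr[1][0], arr[1][1]))
    for name in _SINGLE:
        pt = getattr(landmarks, name)
        if pt is not None:
            rows.append((name, pt[0], pt[1]))
    for name in _CHAIN:
        arr = getattr(landmarks, name)
        if arr is not None:
            for i, pt in enumerate(arr, start=1):
                rows.append((f"{name}_{i}", pt[0], pt[1]))
    return rows


def write_landmarks_csv(landmarks_by_id: dict, path) -> None:
    rows = []
    for sid, lm in landmarks_by_id.items():
        for name, x, y in _landmark_rows(lm):
            rows.append({"id": sid, "landmark_name": name,
                         "x_nm": x, "y_nm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path) -> dict:
    """Parse a landmark table into NeckLandmarks per specimen id.

    Partial landmark sets are allowed (missing fields stay None);
    duplicate landmarks for one specimen raise.
    """
    df = pd.read_csv(path)
    required = {"id", "landmark_name", "x_nm", "y_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    out: dict = {}
    for sid, grp in df.groupby("id", sort=False):
        dup = grp["landmark_name"].duplicated()
        if dup.any():
            name = grp.loc[dup, "landmark_name"].iloc[0]
            raise ValueError(f"duplicate landmark '{name}' for specimen {sid}")
        pts = {row.landmark_name: np.array([row.x_nm, row.y_nm])
               for row in grp.itertuples()}
        kwargs = {}
        for name in _TWO_POINT:
            ro, ca = pts.get(f"{name}_rostral"), pts.get(f"{name}_caudal")
            if ro is not None and ca is not None:
                kwargs[name] = np.array([ro, ca])
        for name in _SINGLE:
            if name in pts:
                kwargs[name] = pts[name]
        for name in _CHAIN:
            chain = []
            i = 1
            while f"{name}_{i}" in pts:
                chain.append(pts[f"{name}_{i}"])
                i += 1
            if chain:
                kwargs[name] = np.array(chain)
        if "neck_midline" not in kwargs or "head_axis" not in kwargs:
            raise ValueError(f"specimen {sid}: neck_midline and head_axis "
                             "are mandatory")
        out[sid] = NeckLandmarks(**kwargs)
    return out


# ---------------------------------------------------------------------------
# localizations (ThunderSTORM-like dialect)
# ---------------------------------------------------------------------------

def write_localizations_csv(clouds_by_id: dict, path) -> None:
    """``clouds_by_id``: specimen id -> {side: RodPointCloud}."""
    rows = []
    for sid, sides in clouds_by_id.items():
        for side, cloud in sides.items():
            for k in range(len(cloud.xyz)):
                rows.append({
                    "id": sid, "side": side, "frame": k + 1,
                    "x_nm": cloud.xyz[k, 0], "y_nm": cloud.xyz[k, 1],
                    "z_nm": cloud.xyz[k, 2],
                    "intensity": cloud.intensity[k]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_localizations_csv(path) -> dict:
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"localization table missing column '{col}'")
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"column '{col}' is not numeric")
    if "id" not in df.columns:
        df["id"] = "specimen"
    if "side" not in df.columns:
        df["side"] = "left"
    z = df["z_nm"] if "z_nm" in df.columns else pd.Series(
        np.zeros(len(df)), index=df.index)
    inten = df["intensity"] if "intensity" in df.columns else pd.Series(
        np.ones(len(df)), index=df.index)
    out: dict = {}
    for (sid, side), grp in df.groupby(["id", "side"], sort=False):
        xyz = np.column_stack([grp["x_nm"], grp["y_nm"], z.loc[grp.index]])
        out.setdefault(sid, {})[side] = RodPointCloud(
            xyz, np.asarray(inten.loc[grp.index], dtype=float), side)
    return out


# ---------------------------------------------------------------------------
# waveform tables and images
# ---------------------------------------------------------------------------

def write_waveforms_csv(waveforms_by_id: dict, path) -> None:
    rows = []
    for sid, wf in waveforms_by_id.items():
        for s, x, y in zip(wf.s, wf.x, wf.y):
            rows.append({"id": sid, "s_nm": s, "x_nm": x, "y_nm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_waveforms_csv(path) -> dict:
    from .waveform import Waveform
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("s_nm")
        out[sid] = Waveform(grp["s_nm"].to_numpy(), grp["x_nm"].to_numpy(),
                            grp["y_nm"].to_numpy())
    return out


def write_image(raster: Raster, path) -> None:
    """Write a rasterized specimen as 16-bit TIFF with nm metadata."""
    px = np.clip(raster.pixels, 0.0, 1.0)
    data = (px * np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path, data,
        metadata={"pixel_size_nm": raster.pixel_size_nm,
                  "origin_x_nm": float(raster.origin_nm[0]),
                  "origin_y_nm": float(raster.origin_nm[1])})


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)
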