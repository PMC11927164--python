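"""Configuration, telemetry IO, result writing, and raster round-trips.

Conventions: timestamps are parsed as UTC and converted to hours since the
first fix of each individual (numeric timestamp columns are taken to be in
hours already); simulation stages use abstract planar units, while the
telemetry reader expects projected (planar) coordinates in meters — no
geodesy is performed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .movement import Track, TrackSegment

__all__ = [
    "RunConfig",
    "read_telemetry",
    "write_results",
    "write_segments",
    "read_segments",
    "write_ndvi_rasters",
    "read_ndvi_rasters",
]

logger = logging.getLogger(__name__)

_TIME_COLS = ("timestamp", "time", "t")
_X_COLS = ("location-long", "location_long", "lon", "x", "utm-easting")
_Y_COLS = ("location-lat", "location_lat", "lat", "y", "utm-northing")
_ID_COLS = ("individual-local-identifier", "individual_id", "individual",
            "id", "segment_id")


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI stages.

    Round-trips losslessly through YAML; unknown keys are rejected so typos
    fail loudly instead of silently using defaults.
    """

    stage: str = "experiment"
    seed: int = 0
    outdir: str = "results"
    scale: float = 1.0
    n_tracks: int = 200
    n_times: int = 50
    ls_k: int = 5
    case_stride: float = 2.0
    case_covariates: str = "fitted"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _pick(columns, candidates, what):
    lower = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise ValueError(f"no {what} column found among {list(columns)}")


def read_telemetry(path) -> dict[str, Track]:
    """Read Movebank-style telemetry CSV into per-individual Tracks.

    Auto-detects timestamp/coordinate/identifier columns, sorts by time,
    and drops duplicate timestamps with a logged count.  Numeric timestamps
    are hours; datetime strings are parsed as UTC and converted to hours
    since each individual's first fix.
    """
    df = pd.read_csv(path)
    tcol = _pick(df.columns, _TIME_COLS, "timestamp")
    xcol = _pick(df.columns, _X_COLS, "x coordinate")
    ycol = _pick(df.columns, _Y_COLS, "y coordinate")
    try:
        icol = _pick(df.columns, _ID_COLS, "individual")
        ids = df[icol].astype(str)
    except ValueError:
        ids = pd.Series(["track"] * len(df))
    if pd.api.types.is_numeric_dtype(df[tcol]):
        hours = df[tcol].astype(float)
    else:
        stamps = pd.to_datetime(df[tcol], utc=True, format="mixed",
                                errors="coerce")
        if stamps.isna().any():
            bad = df[tcol][stamps.isna()].iloc[0]
            raise ValueError(f"unparseable timestamp {bad!r}")
        hours = (stamps - stamps.min()).dt.total_seconds() / 3600.0
    out: dict[str, Track] = {}
    for ind, sub in pd.DataFrame({
            "id": ids, "t": hours, "x": df[xcol], "y": df[ycol]}).groupby("id"):
        sub = sub.sort_values("t")
        dup = sub["t"].duplicated()
        if dup.any():
            logger.info("individual %s: dropped %d duplicate timestamps",
                        ind, int(dup.sum()))
            sub = sub[~dup]
        if len(sub) < 2:
            raise ValueError(f"individual {ind}: fewer than 2 usable fixes")
        t = sub["t"].to_numpy(float)
        out[str(ind)] = Track(t - t[0],
                              sub[["x", "y"]].to_numpy(float))
    return out


def write_segments(segments: list[TrackSegment], outdir) -> tuple[Path, Path]:
    """Movebank-style track CSV plus a collections CSV for a session."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trows, crows = [], []
    for seg in segments:
        for t, (x, y) in zip(seg.track.times, seg.track.positions):
            trows.append((seg.segment_id, t, x, y))
        for t, (cx, cy), a in zip(seg.collect_times, seg.collect_cells,
                                  seg.collect_amounts):
            crows.append((seg.segment_id, t, cx, cy, a))
    tpath = outdir / "tracks.csv"
    cpath = outdir / "collections.csv"
    pd.DataFrame(trows, columns=["segment_id", "timestamp", "x", "y"]
                 ).to_csv(tpath, index=False)
    pd.DataFrame(crows, columns=["segment_id", "time", "cell_x", "cell_y",
                                 "amount"]).to_csv(cpath, index=False)
    return tpath, cpath


def read_segments(tracks_csv) -> dict[str, Track]:
    return read_telemetry(tracks_csv)


def write_results(tables: dict[str, pd.DataFrame], outdir,
                  config: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write result tables as CSV plus a manifest (rows, checksum, config
    hash, seed).  Rerunning with the same config and seed reproduces
    identical checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries.append({"file": path.name, "rows": int(len(df)),
                        "sha256": digest})
    manifest = {"files": entries,
                "config_hash": config.config_hash() if config else None,
                "seed": seed}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_ndvi_rasters(field, outdir) -> tuple[Path, Path]:
    """Raster series to a multi-page TIFF plus a CSV date index."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tif = outdir / "ndvi.tif"
    tifffile.imwrite(tif, field.values.astype(np.float32),
                     photometric="minisblack")
    idx = outdir / "ndvi_dates.csv"
    pd.DataFrame({"band": np.arange(field.days.size), "day": field.days,
                  }).to_csv(idx, index=False)
    return tif, idx


def read_ndvi_rasters(tif_path, dates_csv) -> tuple[np.ndarray, np.ndarray]:
    import tifffile

    values = np.asarray(tifffile.imread(tif_path), dtype=float)
    days = pd.read_csv(dates_csv)["day"].to_numpy(float)
    return values, days
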