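"""File round-trips for scans, reference waveforms, ground-truth fields,
fill-weight tables, calibration models, profiles and maps.

Two scan layouts are supported:

* HDF5 — datasets ``delay`` (ps) and ``amplitudes`` (n_waveforms ×
  n_samples), with ``acquisition_rate`` and ``rotation_speed`` as root
  attributes; the reference waveform, when bundled, is the ``reference``
  dataset.
* flat CSV — leading ``#``-comment header carrying the acquisition
  metadata and the delay axis, then one waveform per row with a leading
  measurement index and the amplitudes in fixed columns.

All other artefacts are plain CSV (one table each) or YAML (persisted
calibration models, run configs).  Every writer/reader pair is an exact
round trip for finite double-precision data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResults
from .mapping import DensityMap
from .signal import AngularProfile, ScanSequence, Waveform
from .specs import DensityField

__all__ = [
    "FileFormatError",
    "write_scan_hdf5",
    "read_scan_hdf5",
    "write_scan_csv",
    "read_scan_csv",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_density_fields_csv",
    "read_density_fields_csv",
    "write_weights_csv",
    "read_weights_csv",
    "write_model_yaml",
    "read_model_yaml",
    "write_profile_csv",
    "read_profile_csv",
    "write_map_csv",
    "read_map_csv",
    "load_config",
    "save_config",
    "config_hash",
]


class FileFormatError(ValueError):
    """A file does not conform to its documented layout."""


# ---------------------------------------------------------------- scans


def write_scan_hdf5(path, scan: ScanSequence,
                    reference: Waveform | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("delay", data=scan.delay)
        f.create_dataset("amplitudes", data=scan.amplitudes)
        f.attrs["acquisition_rate"] = scan.acquisition_rate
        f.attrs["rotation_speed"] = scan.rotation_speed
        if reference is not None:
            f.create_dataset("reference", data=reference.amplitude)


def read_scan_hdf5(path) -> tuple[ScanSequence, Waveform | None]:
    with h5py.File(path, "r") as f:
        for key in ("delay", "amplitudes"):
            if key not in f:
                raise FileFormatError(f"{path}: missing dataset '{key}'")
        delay = f["delay"][:]
        scan = ScanSequence(
            delay=delay,
            amplitudes=f["amplitudes"][:],
            acquisition_rate=float(f.attrs["acquisition_rate"]),
            rotation_speed=float(f.attrs["rotation_speed"]),
        )
        reference = None
        if "reference" in f:
            reference = Waveform(delay, f["reference"][:], index=-1)
    return scan, reference


def write_scan_csv(path, scan: ScanSequence) -> None:
    with open(path, "w") as fh:
        fh.write(f"# acquisition_rate_hz={scan.acquisition_rate!r}\n")
        fh.write(f"# rotation_speed_rpm={scan.rotation_speed!r}\n")
        fh.write("# delay_ps=" + ",".join(repr(float(v)) for v in scan.delay)
                 + "\n")
        fh.write("index," + ",".join(f"a{j}" for j in range(scan.delay.size))
                 + "\n")
        for i, row in enumerate(scan.amplitudes):
            fh.write(f"{i}," + ",".join(repr(float(v)) for v in row) + "\n")


def _read_comment_header(path) -> tuple[dict, int]:
    meta: dict = {}
    n_comments = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            body = line[1:].strip()
            if "=" not in body:
                raise FileFormatError(
                    f"{path}: malformed header line {n_comments}: {body!r}")
            key, val = body.split("=", 1)
            meta[key.strip()] = val.strip()
    return meta, n_comments


def read_scan_csv(path) -> ScanSequence:
    meta, n_comments = _read_comment_header(path)
    for key in ("acquisition_rate_hz", "rotation_speed_rpm", "delay_ps"):
        if key not in meta:
            raise FileFormatError(f"{path}: missing header key '{key}'")
    delay = np.array([float(v) for v in meta["delay_ps"].split(",")])
    try:
        df = pd.read_csv(path, skiprows=n_comments,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    expected = delay.size + 1
    if df.shape[1] != expected:
        raise FileFormatError(
            f"{path}: expected {expected} columns, found {df.shape[1]}")
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0]) + n_comments + 2
        raise FileFormatError(f"{path}: truncated or non-numeric row at line {bad}")
    return ScanSequence(
        delay=delay,
        amplitudes=df.iloc[:, 1:].to_numpy(dtype=float),
        acquisition_rate=float(meta["acquisition_rate_hz"]),
        rotation_speed=float(meta["rotation_speed_rpm"]),
    )


def write_waveform_csv(path, w: Waveform) -> None:
    pd.DataFrame({"delay_ps": w.delay, "amplitude": w.amplitude}).to_csv(
        path, index=False)


def read_waveform_csv(path) -> Waveform:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    for col in ("delay_ps", "amplitude"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column '{col}'")
    return Waveform(df["delay_ps"].to_numpy(), df["amplitude"].to_numpy(),
                    index=-1)


# ------------------------------------------------- sidecars and tables


def write_density_fields_csv(path, fields) -> None:
    rows = []
    for f in fields if not isinstance(fields, DensityField) else [fields]:
        for a, r in zip(f.angle_grid, f.relative_density):
            rows.append({"stage": f.stage_label, "angle_deg": a,
                         "relative_density": r})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_density_fields_csv(path) -> list[DensityField]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    fields = []
    for stage, grp in df.groupby("stage", sort=True):
        grp = grp.sort_values("angle_deg")
        fields.append(DensityField(
            grp["angle_deg"].to_numpy(),
            grp["relative_density"].to_numpy(),
            stage_label=int(stage),
        ))
    return fields


def write_weights_csv(path, weights: pd.DataFrame) -> None:
    weights.to_csv(path, index=False)


def read_weights_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    for col in ("stage", "position", "weight_mg"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column '{col}'")
    return df  # header-only file yields an empty table, not an error


def write_model_yaml(path, results: CalibrationResults) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(results.to_dict(), fh, sort_keys=False)


def read_model_yaml(path) -> CalibrationResults:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    required = {"a0", "a1", "r_squared", "rmse", "n_points",
                "index_min", "index_max"}
    if not isinstance(d, dict) or not required <= set(d):
        raise FileFormatError(f"{path}: not a persisted calibration model")
    return CalibrationResults.from_dict(d)


def write_profile_csv(path, profile: AngularProfile,
                      value_name: str = "value") -> None:
    pd.DataFrame({
        "bin_center_deg": profile.bin_centers,
        value_name: profile.value,
        "n_contributing": profile.n_contributing,
    }).to_csv(path, index=False)


def read_profile_csv(path, value_name: str = "value") -> AngularProfile:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    for col in ("bin_center_deg", value_name, "n_contributing"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column '{col}'")
    return AngularProfile(
        bin_centers=df["bin_center_deg"].to_numpy(),
        value=df[value_name].to_numpy(),
        n_contributing=df["n_contributing"].to_numpy(),
    )


def write_map_csv(path, dmap: DensityMap) -> None:
    df = pd.DataFrame(dmap.values,
                      columns=[f"{c:.4f}" for c in dmap.bin_centers])
    df.insert(0, "rotation", dmap.rotation_ids)
    df.to_csv(path, index=False)
    mask_path = Path(path).with_suffix(".mask.csv")
    pd.DataFrame({"bin_center_deg": dmap.bin_centers,
                  "artifact": dmap.artifact_mask.astype(int)}
                 ).to_csv(mask_path, index=False)


def read_map_csv(path) -> DensityMap:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
    if "rotation" not in df.columns:
        raise FileFormatError(f"{path}: missing 'rotation' column")
    centers = np.array([float(c) for c in df.columns[1:]])
    mask_path = Path(path).with_suffix(".mask.csv")
    mask = None
    if mask_path.exists():
        mask = pd.read_csv(mask_path)["artifact"].to_numpy(dtype=bool)
    return DensityMap(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        bin_centers=centers,
        rotation_ids=df["rotation"].to_numpy(dtype=int),
        artifact_mask=mask,
    )


# --------------------------------------------------------------- config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FileFormatError(f"{path}: config must be a mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, for output provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
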