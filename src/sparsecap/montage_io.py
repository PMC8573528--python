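"""Readers and writers for the package's exchange formats.

* marker CSV — motion-capture export stand-in: ``label,x,y,z[,t]`` in mm,
  optionally many timestamped rows per label (the per-label median over time
  is used, robust to marker flicker);
* template angle tables — ``label,theta_deg,phi_deg``;
* electrode position files — BESA-style ``.sfp``, EEProbe-style ``.elc``,
  or plain CSV;
* epoch arrays — a ``.npy`` payload plus a JSON sidecar (fs, t0 offset,
  channel labels).

All readers reject malformed numeric fields (with line numbers) rather than
silently coercing, and every writer's output is parseable by its own reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .erp import EpochArray
from .errors import ConfigError, FormatError, MissingMarkerError
from .geometry import FIDUCIALS, LabeledPoints
from .head_models import TemplateAngles

__all__ = [
    "read_marker_csv",
    "write_marker_csv",
    "read_template_angles",
    "write_template_angles",
    "read_positions",
    "write_positions",
    "read_epochs",
    "write_epochs",
]

#: common aliases in motion-capture and EEG exports, matched case-insensitively
LABEL_ALIASES = {
    "nas": "Nz", "nasion": "Nz", "nz": "Nz",
    "a1": "LPA", "lpa": "LPA", "leftpa": "LPA",
    "a2": "RPA", "rpa": "RPA", "rightpa": "RPA",
    "fpz": "FPz", "cz": "Cz", "oz": "Oz", "t7": "T7", "t8": "T8",
}


def normalize_label(label: str) -> str:
    return LABEL_ALIASES.get(label.strip().lower(), label.strip())


def _to_float(value, path, line) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path}:{line}: cannot parse {value!r} as a number") from None
    if not np.isfinite(out):
        raise FormatError(f"{path}:{line}: non-finite coordinate {value!r}")
    return out


def read_marker_csv(path, required: Iterable[str] | None = None,
                    normalize: bool = True) -> LabeledPoints:
    """Read a marker export; collapse timestamped duplicates by median.

    Expects a header with ``label,x,y,z`` and optionally ``t``. With
    ``normalize`` (default), common label variants (NAS, A1/A2, ...) are
    mapped to the canonical Nz/LPA/RPA/10-20 names.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("label", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")

    by_label: dict[str, list[np.ndarray]] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        lab = str(row["label"]).strip()
        if not lab or lab.lower() == "nan":
            raise FormatError(f"{path}:{line}: empty label")
        if normalize:
            lab = normalize_label(lab)
        p = np.array([_to_float(row[c], path, line) for c in ("x", "y", "z")])
        by_label.setdefault(lab, []).append(p)

    points = LabeledPoints({lab: np.median(np.array(ps), axis=0) for lab, ps in by_label.items()})
    if required is not None:
        missing = [l for l in required if l not in points]
        if missing:
            raise MissingMarkerError(f"{path}: missing required marker(s): {', '.join(missing)}")
    return points


def write_marker_csv(points: LabeledPoints, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("label,x,y,z\n")
        for lab, p in points.items():
            fh.write(f"{lab},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")
    return path


def read_template_angles(path) -> TemplateAngles:
    """Read a ``label,theta_deg,phi_deg`` table (internal angle convention:
    theta from +z, phi from +x toward +y)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("label", "theta_deg", "phi_deg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows: dict[str, tuple[float, float]] = {}
    for i, row in df.iterrows():
        line = i + 2
        lab = str(row["label"]).strip()
        theta = _to_float(row["theta_deg"], path, line)
        phi = _to_float(row["phi_deg"], path, line)
        if lab in rows:
            raise FormatError(f"{path}:{line}: duplicate label {lab!r}")
        if not (0.0 <= theta <= 180.0):
            raise FormatError(f"{path}:{line}: inclination {theta} outside [0, 180]")
        if not (-180.0 < phi <= 180.0):
            raise FormatError(f"{path}:{line}: azimuth {phi} outside (-180, 180]")
        rows[lab] = (theta, phi)
    return TemplateAngles(rows)


def write_template_angles(angles: TemplateAngles, path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("label,theta_deg,phi_deg\n")
        for lab, (theta, phi) in angles.items():
            fh.write(f"{lab},{theta:.6f},{phi:.6f}\n")
    return path


def _ordered_labels(points: LabeledPoints) -> list[str]:
    """Fiducials first (Nz, LPA, RPA), preserving downstream-tool conventions."""
    fid = [l for l in FIDUCIALS if l in points]
    return fid + [l for l in points.labels if l not in fid]


def write_positions(points: LabeledPoints, path, format: str | None = None) -> Path:
    """Write electrode positions as ``sfp``, ``elc``, or ``csv``.

    Format defaults to the file extension. Coordinates are printed at 1e-4 mm
    precision; read-back reproduces the positions to that precision.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if len(points) == 0:
        raise ConfigError("refusing to write an empty position set")
    labels = _ordered_labels(points)
    if fmt == "sfp":
        with path.open("w") as fh:
            for lab in labels:
                p = points[lab]
                fh.write(f"{lab}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}\n")
    elif fmt == "elc":
        with path.open("w") as fh:
            fh.write(f"NumberPositions=\t{len(labels)}\n")
            fh.write("UnitPosition\tmm\n")
            fh.write("Positions\n")
            for lab in labels:
                p = points[lab]
                fh.write(f"{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}\n")
            fh.write("Labels\n")
            for lab in labels:
                fh.write(f"{lab}\n")
    elif fmt == "csv":
        write_marker_csv(points.subset(labels), path)
    else:
        raise ConfigError(f"unsupported position format {fmt!r} (use sfp, elc, or csv)")
    return path


def read_positions(path, format: str | None = None) -> LabeledPoints:
    """Read positions written by :func:`write_positions`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sfp":
        entries = []
        for i, raw in enumerate(path.read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{i}: expected 'label x y z', got {raw!r}")
            entries.append((parts[0], [_to_float(v, path, i) for v in parts[1:]]))
        return LabeledPoints(entries)
    if fmt == "elc":
        lines = path.read_text().splitlines()
        try:
            ip = next(i for i, l in enumerate(lines) if l.strip().lower().startswith("positions"))
            il = next(i for i, l in enumerate(lines) if l.strip().lower().startswith("labels"))
        except StopIteration:
            raise FormatError(f"{path}: missing Positions/Labels section") from None
        coords = []
        for i in range(ip + 1, il):
            parts = lines[i].split()
            if not parts:
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}:{i + 1}: expected 'x y z', got {lines[i]!r}")
            coords.append([_to_float(v, path, i + 1) for v in parts])
        labels = [l.strip() for l in lines[il + 1:] if l.strip()]
        if len(labels) != len(coords):
            raise FormatError(f"{path}: {len(coords)} positions but {len(labels)} labels")
        return LabeledPoints(zip(labels, coords))
    if fmt == "csv":
        return read_marker_csv(path, normalize=False)
    raise ConfigError(f"unsupported position format {fmt!r} (use sfp, elc, or csv)")


def write_epochs(epochs: EpochArray, stem) -> tuple[Path, Path]:
    """Write an epoch array as ``<stem>.npy`` + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    sidecar = stem.with_suffix(".json")
    np.save(npy, epochs.data)
    sidecar.write_text(json.dumps({
        "fs_hz": epochs.fs,
        "t0_offset_ms": epochs.t0_offset,
        "channel_labels": list(epochs.channel_labels),
        "shape": list(epochs.data.shape),
        "units": "uV",
    }, indent=1))
    return npy, sidecar


def read_epochs(stem) -> EpochArray:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy"))
    if list(data.shape) != meta["shape"]:
        raise FormatError(f"{stem}: payload shape {data.shape} != sidecar {meta['shape']}")
    return EpochArray(data, meta["fs_hz"], meta["t0_offset_ms"], tuple(meta["channel_labels"]))
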