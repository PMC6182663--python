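"""Reading and writing of scan sets and prediction configs.

Two on-disk scan dialects are supported:

* **XL-I text scans** — one file per scan in the style of Beckman XL-I
  absorbance output: a free-text description line; a header line with mode
  letter, cell number, temperature (deg C), rotor speed (rpm), elapsed time
  (s) and omega^2 t; then two whitespace-separated columns of radius (cm,
  5 decimals) and signal (6 decimals).  A trailing third column, present in
  some instrument variants, is ignored on read.
* **CSV matrices** — a single file whose first column is the radius grid and
  whose remaining columns are one scan each, the header row carrying the
  scan times in seconds.  The CSV round trip is exact.

The prediction config is a flat YAML mapping (see :func:`load_config`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bd_engine import ScanSet, SimulationSettings
from .errors import ConfigurationError, ConsistencyError, ScanParseError
from .physics import CellGeometry, RunConditions, SoluteComponent

__all__ = [
    "PredictConfig",
    "load_config",
    "write_scans_xli",
    "read_scans_xli",
    "write_scans_csv",
    "read_scans_csv",
    "add_measurement_noise",
]

_REQUIRED_KEYS = ("rpm", "meniscus_cm", "bottom_cm", "n_part", "n_steps",
                  "n_bins", "components")
_KNOWN_KEYS = set(_REQUIRED_KEYS) | {
    "title", "temperature_C", "temperature_K", "t_run_s", "t_run_h",
    "n_scans", "scan_times_s", "seed", "z0", "substeps_per_scan", "output",
}
_KNOWN_COMPONENT_KEYS = {"s_svedberg", "buoyant_mw_da", "y", "q", "alpha",
                         "c0", "mw_da", "vbar", "rho"}
_KNOWN_OUTPUT_KEYS = {"format", "smooth_window", "smooth_order", "dcdt",
                      "dcdr"}


@dataclass
class PredictConfig:
    """A fully validated simulation request."""

    geometry: CellGeometry
    run: RunConditions
    settings: SimulationSettings
    components: list
    y: np.ndarray
    z0: float = 1.0
    output_format: str = "csv"
    smooth_window: int | None = None
    smooth_order: int = 2
    dcdt: bool = False
    dcdr: bool = False
    title: str = ""


def load_config(path) -> PredictConfig:
    """Parse and validate a YAML prediction config.

    Required keys: rpm, meniscus_cm, bottom_cm, n_part, n_steps, n_bins,
    components (list of mappings with s_svedberg, buoyant_mw_da, y), plus a
    run duration (t_run_s or t_run_h) and a scan schedule (n_scans or
    scan_times_s).  Temperature defaults to 20 deg C.  Unknown keys produce a
    warning; missing required keys raise listing all of them.  Component
    signal fractions are renormalised (with a warning when they are off by
    more than 1e-6).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScanParseError(f"could not parse config: {exc}", path=path)
    if not isinstance(raw, dict):
        raise ScanParseError("config must be a key-value mapping", path=path)

    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if "t_run_s" not in raw and "t_run_h" not in raw:
        missing.append("t_run_s (or t_run_h)")
    if "n_scans" not in raw and "scan_times_s" not in raw:
        missing.append("n_scans (or scan_times_s)")
    if missing:
        raise ConfigurationError(
            "config is missing required keys: " + ", ".join(missing)
        )
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {', '.join(unknown)}",
                      stacklevel=2)

    geometry = CellGeometry(float(raw["meniscus_cm"]), float(raw["bottom_cm"]))
    if "temperature_K" in raw:
        temperature = float(raw["temperature_K"])
    else:
        temperature = float(raw.get("temperature_C", 20.0)) + 273.15
    t_run = (float(raw["t_run_s"]) if "t_run_s" in raw
             else float(raw["t_run_h"]) * 3600.0)
    if "scan_times_s" in raw:
        scan_times = tuple(float(t) for t in raw["scan_times_s"])
    else:
        scan_times = tuple(np.linspace(0.0, t_run, int(raw["n_scans"])))
    run = RunConditions(rpm=float(raw["rpm"]), temperature_K=temperature,
                        t_run=t_run, scan_times=scan_times)
    settings = SimulationSettings(
        n_part=int(raw["n_part"]), n_steps=int(raw["n_steps"]),
        n_bins=int(raw["n_bins"]), seed=int(raw.get("seed", 0)),
        substeps_per_scan=int(raw.get("substeps_per_scan", 1)),
    )

    comp_specs = raw["components"]
    if not isinstance(comp_specs, list) or not comp_specs:
        raise ConfigurationError("components must be a non-empty list")
    components, y = [], []
    for i, spec in enumerate(comp_specs):
        missing = [k for k in ("s_svedberg", "buoyant_mw_da", "y")
                   if k not in spec]
        if missing:
            raise ConfigurationError(
                f"component {i + 1} is missing keys: {', '.join(missing)}"
            )
        unknown = sorted(set(spec) - _KNOWN_COMPONENT_KEYS)
        if unknown:
            warnings.warn(
                f"component {i + 1}: ignoring unknown keys: "
                f"{', '.join(unknown)}", stacklevel=2)
        y.append(float(spec["y"]))
        components.append(SoluteComponent(
            s=float(spec["s_svedberg"]),
            buoyant_mw=float(spec["buoyant_mw_da"]),
            signal_fraction=1.0,   # placeholder; replaced after renormalising
        ))
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ConfigurationError(f"component y values must be positive: {y}")
    if abs(y.sum() - 1.0) > 1e-6:
        warnings.warn(
            f"component signal fractions sum to {y.sum():.6g}; renormalising",
            stacklevel=2)
    y = y / y.sum()
    components = [SoluteComponent(c.s, c.buoyant_mw, signal_fraction=float(f))
                  for c, f in zip(components, y)]

    out = raw.get("output", {}) or {}
    unknown = sorted(set(out) - _KNOWN_OUTPUT_KEYS)
    if unknown:
        warnings.warn(
            f"output: ignoring unknown keys: {', '.join(unknown)}",
            stacklevel=2)
    fmt = str(out.get("format", "csv"))
    if fmt not in ("csv", "xli"):
        raise ConfigurationError(f"output format must be csv or xli, got {fmt}")

    return PredictConfig(
        geometry=geometry, run=run, settings=settings, components=components,
        y=y, z0=float(raw.get("z0", 1.0)), output_format=fmt,
        smooth_window=out.get("smooth_window"),
        smooth_order=int(out.get("smooth_order", 2)),
        dcdt=bool(out.get("dcdt", False)), dcdr=bool(out.get("dcdr", False)),
        title=str(raw.get("title", "")),
    )


# ---------------------------------------------------------------------------
# XL-I style scan files


def write_scans_xli(scan_set: ScanSet, directory, cell: int = 1,
                    description: str | None = None,
                    prefix: str = "scan") -> list:
    """Write one XL-I-style text file per scan; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rpm = float(scan_set.meta.get("rpm", 0.0))
    temperature_K = float(scan_set.meta.get("temperature_K", 293.15))
    omega = 2.0 * math.pi * rpm / 60.0
    if description is None:
        description = scan_set.meta.get("description", "aucbd simulated scan")
    paths = []
    for j, t in enumerate(scan_set.times):
        path = directory / f"{prefix}{j + 1:05d}.ra{cell}"
        lines = [description,
                 f"R {cell} {temperature_K - 273.15:.1f} {int(round(rpm))} "
                 f"{int(round(t))} {omega ** 2 * t:.5E}"]
        for r, z in zip(scan_set.radii, scan_set.z[:, j]):
            lines.append(f"{r:9.5f} {z:12.6f}")
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def _parse_xli_file(path: Path):
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ScanParseError("scan file has fewer than 3 lines", path=path)
    description = lines[0]
    header = lines[1].split()
    if len(header) < 6:
        raise ScanParseError(
            f"malformed header (expected 6 fields, got {len(header)})",
            path=path, line=2)
    try:
        mode = header[0]
        cell = int(header[1])
        temperature_C = float(header[2])
        rpm = int(header[3])
        elapsed = float(header[4])
        w2t = float(header[5])
    except ValueError as exc:
        raise ScanParseError(f"malformed header: {exc}", path=path, line=2)
    radii, signal = [], []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ScanParseError("data line needs at least 2 columns",
                                 path=path, line=lineno)
        try:
            radii.append(float(fields[0]))
            signal.append(float(fields[1]))   # trailing columns ignored
        except ValueError as exc:
            raise ScanParseError(f"malformed data line: {exc}", path=path,
                                 line=lineno)
    return {
        "description": description, "mode": mode, "cell": cell,
        "temperature_C": temperature_C, "rpm": rpm, "elapsed": elapsed,
        "w2t": w2t, "radii": np.array(radii), "signal": np.array(signal),
    }


def read_scans_xli(directory, z0: float = 1.0) -> ScanSet:
    """Read a directory of XL-I-style scan files into a ScanSet.

    All scans must share the radius grid, rotor speed and printed
    temperature; scans are ordered by elapsed time.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ScanParseError("not a directory", path=directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ScanParseError("no scan files found", path=directory)
    scans = [_parse_xli_file(p) for p in files]
    scans.sort(key=lambda s: s["elapsed"])
    first = scans[0]
    for s in scans[1:]:
        if s["rpm"] != first["rpm"]:
            raise ConsistencyError(
                f"rotor speed differs between scans: {first['rpm']} vs "
                f"{s['rpm']}")
        if abs(s["temperature_C"] - first["temperature_C"]) > 0.05:
            raise ConsistencyError("temperature differs between scans")
        if s["radii"].size != first["radii"].size or not np.allclose(
                s["radii"], first["radii"], atol=2e-5, rtol=0):
            raise ConsistencyError("radius grids differ between scans")
    times = np.array([s["elapsed"] for s in scans])
    if np.any(np.diff(times) <= 0):
        raise ConsistencyError(f"scan times are not strictly increasing: {times}")
    z = np.column_stack([s["signal"] for s in scans])
    meta = {
        "rpm": float(first["rpm"]),
        "temperature_K": first["temperature_C"] + 273.15,
        "cell": first["cell"],
        "description": first["description"],
        "source": str(directory),
    }
    return ScanSet(radii=first["radii"], times=times, z=z, z0=z0, meta=meta)


# ---------------------------------------------------------------------------
# CSV matrices


def write_scans_csv(scan_set: ScanSet, path) -> Path:
    """Write the full scan matrix as one CSV (exact round trip)."""
    path = Path(path)
    frame = pd.DataFrame(scan_set.z,
                         columns=[repr(float(t)) for t in scan_set.times])
    frame.insert(0, "radius_cm", scan_set.radii)
    frame.to_csv(path, index=False)
    return path


def read_scans_csv(path, z0: float = 1.0) -> ScanSet:
    """Read a CSV scan matrix written by :func:`write_scans_csv`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ScanParseError(f"could not read CSV: {exc}", path=path)
    if frame.shape[1] < 2 or frame.columns[0] != "radius_cm":
        raise ScanParseError(
            "first column must be 'radius_cm' followed by one column per scan",
            path=path)
    try:
        times = np.array([float(c) for c in frame.columns[1:]])
    except ValueError:
        raise ScanParseError("scan column headers must be times in seconds",
                             path=path)
    if np.any(np.diff(times) <= 0):
        raise ScanParseError(
            f"scan times in header are not strictly increasing: {times}",
            path=path)
    radii = frame["radius_cm"].to_numpy(dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ScanParseError("radii are not strictly increasing", path=path)
    z = frame.iloc[:, 1:].to_numpy(dtype=float)
    return ScanSet(radii=radii, times=times, z=z, z0=z0,
                   meta={"source": str(path)})


def add_measurement_noise(scan_set: ScanSet, sigma: float,
                          seed: int) -> ScanSet:
    """Add i.i.d. Gaussian measurement noise (clipped at zero signal)."""
    if sigma < 0:
        raise ConfigurationError(f"sigma must be non-negative, got {sigma}")
    out = scan_set.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        out.z = np.clip(out.z + rng.normal(0.0, sigma, size=out.z.shape),
                        0.0, None)
    out.meta["measurement_noise"] = {"sigma": float(sigma), "seed": int(seed)}
    return out
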