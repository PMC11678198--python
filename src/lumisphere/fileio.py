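"""Readers and writers for scans, lookup tables and run configuration.

Scans travel as delimited text (a ``# key: value`` header block followed by
long-format ``excitation_nm,emission_nm,counts`` rows) so fixtures diff
cleanly; lookup tables as a versioned JSON document.  Both round-trip
exactly (floats are serialized with ``repr`` precision).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import yaml

from .lut import LookupTable
from .mc_slab import BeamGeometry
from .spectra import SpectralScan
from .sphere_model import SphereGeometry

__all__ = [
    "read_scan",
    "write_scan",
    "read_lut",
    "write_lut",
    "load_config",
    "sphere_from_config",
    "beam_from_config",
]

SCAN_FORMAT_VERSION = 1
LUT_FORMAT_VERSION = 1


class ScanFormatError(ValueError):
    """Malformed scan file (reported with a line number where possible)."""


def _fmt_floats(values) -> str:
    return ",".join(repr(float(v)) for v in np.asarray(values).ravel())


def write_scan(scan: SpectralScan, path) -> None:
    """Write one channel scan as headered long-format delimited text."""
    path = Path(path)
    lines = [
        f"# format_version: {SCAN_FORMAT_VERSION}",
        f"# channel_id: {scan.channel_id}",
        f"# units: {scan.units}",
        f"# n_averages: {scan.n_averages}",
        f"# acquisition_time_s: {_fmt_floats(scan.acquisition_time)}",
        f"# emission_nm: {_fmt_floats(scan.emission_nm)}",
    ]
    if scan.dark_rate is not None:
        lines.append(f"# dark_rate: {_fmt_floats(scan.dark_rate)}")
    lines.append("excitation_nm,emission_nm,counts")
    for i, exc in enumerate(scan.excitation_nm):
        for j, em in enumerate(scan.emission_nm):
            lines.append(
                f"{float(exc)!r},{float(em)!r},{float(scan.counts[i, j])!r}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_scan(path) -> SpectralScan:
    """Read a scan written by :func:`write_scan`; malformed rows are
    reported with their line number."""
    path = Path(path)
    header: dict = {}
    rows = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError as err:
                    raise ScanFormatError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    ) from err
                header[key.strip()] = value.strip()
            elif line.startswith("excitation_nm"):
                continue  # column header
            else:
                parts = line.split(",")
                if len(parts) != 3:
                    raise ScanFormatError(
                        f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                    )
                try:
                    rows.append(tuple(float(p) for p in parts))
                except ValueError as err:
                    raise ScanFormatError(
                        f"{path}:{lineno}: non-numeric value in {line!r}"
                    ) from err
    if int(header.get("format_version", -1)) != SCAN_FORMAT_VERSION:
        raise ScanFormatError(
            f"{path}: unsupported or missing format_version "
            f"{header.get('format_version')!r}"
        )
    if not rows:
        raise ScanFormatError(f"{path}: no data rows (header-only file)")
    data = np.array(rows)
    excitation = np.unique(data[:, 0])
    emission = np.array([float(v) for v in header["emission_nm"].split(",")])
    counts = np.full((excitation.size, emission.size), np.nan)
    exc_idx = {v: i for i, v in enumerate(excitation)}
    em_idx = {v: j for j, v in enumerate(emission)}
    for exc, em, c in rows:
        try:
            counts[exc_idx[exc], em_idx[em]] = c
        except KeyError as err:
            raise ScanFormatError(
                f"{path}: emission wavelength {em} not in the header grid"
            ) from err
    if np.any(np.isnan(counts)):
        raise ScanFormatError(f"{path}: incomplete excitation x emission matrix")
    acq = np.array([float(v) for v in header["acquisition_time_s"].split(",")])
    if np.any(acq <= 0):
        raise ScanFormatError(f"{path}: acquisition times must be positive")
    dark = (
        np.array([float(v) for v in header["dark_rate"].split(",")]) if "dark_rate" in header else None
    )
    return SpectralScan(
        channel_id=header.get("channel_id", "?"),
        excitation_nm=excitation,
        emission_nm=emission,
        counts=counts,
        acquisition_time=acq,
        n_averages=int(header.get("n_averages", 1)),
        dark_rate=dark,
        units=header.get("units", "counts"),
    )


# ---------------------------------------------------------------------------
# lookup tables
# ---------------------------------------------------------------------------


def write_lut(lut: LookupTable, path) -> None:
    """Serialize a lookup table (grids, tables, full metadata) as JSON."""
    doc = {
        "format_version": LUT_FORMAT_VERSION,
        "mua_grid": lut.mua_grid.tolist(),
        "musp_grid": lut.musp_grid.tolist(),
        "R_table": lut.R_table.tolist(),
        "T_table": lut.T_table.tolist(),
        "R_raw": lut.R_raw.tolist(),
        "T_raw": lut.T_raw.tolist(),
        "se_R": lut.se_R.tolist(),
        "se_T": lut.se_T.tolist(),
        "g": lut.g,
        "n_sample": lut.n_sample,
        "thickness_d": lut.thickness_d,
        "rho_cal": lut.rho_cal,
        "n_photons": lut.n_photons,
        "seed": lut.seed,
        "beam": {
            "incidence_angle": lut.beam.incidence_angle,
            "beam_radius": lut.beam.beam_radius,
            "port_radius": None if math.isinf(lut.beam.port_radius) else lut.beam.port_radius,
            "n_ambient": lut.beam.n_ambient,
            "lateral_limit": None
            if math.isinf(lut.beam.lateral_limit)
            else lut.beam.lateral_limit,
        },
        "sphere": None
        if lut.sphere is None
        else {
            "sphere_diameter": lut.sphere.sphere_diameter,
            "wall_reflectance": lut.sphere.wall_reflectance
            if np.isscalar(lut.sphere.wall_reflectance)
            else [list(map(float, a)) for a in lut.sphere.wall_reflectance],
            "port_diameters": dict(lut.sphere.port_diameters),
            "detector_view_diameter": lut.sphere.detector_view_diameter,
            "baffled": lut.sphere.baffled,
        },
    }
    Path(path).write_text(json.dumps(doc))


def read_lut(path) -> LookupTable:
    """Read a lookup table written by :func:`write_lut`."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: not a valid lookup-table file ({err})") from err
    version = doc.get("format_version")
    if version != LUT_FORMAT_VERSION:
        raise ValueError(
            f"{path}: lookup-table format version {version!r} is not supported "
            f"(expected {LUT_FORMAT_VERSION})"
        )
    beam_doc = doc["beam"]
    beam = BeamGeometry(
        incidence_angle=beam_doc["incidence_angle"],
        beam_radius=beam_doc["beam_radius"],
        port_radius=math.inf if beam_doc["port_radius"] is None else beam_doc["port_radius"],
        n_ambient=beam_doc["n_ambient"],
        lateral_limit=math.inf
        if beam_doc["lateral_limit"] is None
        else beam_doc["lateral_limit"],
    )
    sphere = None
    if doc["sphere"] is not None:
        s = doc["sphere"]
        wall = s["wall_reflectance"]
        if not np.isscalar(wall):
            wall = (np.asarray(wall[0], float), np.asarray(wall[1], float))
        sphere = SphereGeometry(
            sphere_diameter=s["sphere_diameter"],
            wall_reflectance=wall,
            port_diameters=s["port_diameters"],
            detector_view_diameter=s["detector_view_diameter"],
            baffled=s["baffled"],
        )
    return LookupTable(
        mua_grid=np.asarray(doc["mua_grid"]),
        musp_grid=np.asarray(doc["musp_grid"]),
        R_table=np.asarray(doc["R_table"]),
        T_table=np.asarray(doc["T_table"]),
        R_raw=np.asarray(doc["R_raw"]),
        T_raw=np.asarray(doc["T_raw"]),
        se_R=np.asarray(doc["se_R"]),
        se_T=np.asarray(doc["se_T"]),
        g=doc["g"],
        n_sample=doc["n_sample"],
        thickness_d=doc["thickness_d"],
        beam=beam,
        sphere=sphere,
        rho_cal=doc["rho_cal"],
        n_photons=doc["n_photons"],
        seed=doc["seed"],
        version=version,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SPHERE_KEYS = {
    "sphere_diameter",
    "wall_reflectance",
    "port_diameters",
    "detector_view_diameter",
    "baffled",
}
_BEAM_KEYS = {"incidence_angle", "beam_radius", "port_radius", "n_ambient", "lateral_limit"}
_PHANTOM_KEYS = {
    "musp_600",
    "scatter_power_b",
    "dye_concentration",
    "dye_peak_nm",
    "dye_bandwidth_nm",
    "dye_mua_per_wt",
    "baseline_mua",
    "pl_peak_nm",
    "pl_bandwidth_nm",
    "pl_yield",
    "thickness_d",
    "n_sample",
    "g",
}


def _check_keys(block: dict, allowed: set, name: str) -> dict:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} config block: {sorted(unknown)}")
    return block


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown block keys."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known_blocks = {"sphere", "beam", "phantom", "noise", "lut", "processing"}
    unknown = set(doc) - known_blocks
    if unknown:
        raise ValueError(f"{path}: unknown config blocks {sorted(unknown)}")
    if "sphere" in doc:
        _check_keys(doc["sphere"], _SPHERE_KEYS, "sphere")
    if "beam" in doc:
        _check_keys(doc["beam"], _BEAM_KEYS, "beam")
    if "phantom" in doc:
        _check_keys(doc["phantom"], _PHANTOM_KEYS, "phantom")
    return doc


def sphere_from_config(block: dict) -> SphereGeometry:
    _check_keys(block, _SPHERE_KEYS, "sphere")
    return SphereGeometry(**block)


def beam_from_config(block: dict) -> BeamGeometry:
    _check_keys(block, _BEAM_KEYS, "beam")
    block = dict(block)
    for key in ("port_radius", "lateral_limit"):
        if block.get(key) is None and key in block:
            block[key] = math.inf
    return BeamGeometry(**block)
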