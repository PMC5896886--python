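"""CSV/JSON formats and run manifests.

Traces are stored as RFC-4180 CSV with ``#``-prefixed ``key: value``
metadata lines before the header row. Two trace formats share one reader,
dispatching on the header:

* pull traces — ``time_min,deflection_px[,force_uN]`` with probe
  calibration metadata;
* relaxation traces — ``time_s,force_uN[,strain]`` with area/strain
  metadata.

Floats are written with ``repr`` so read ∘ write is exact to full stored
precision. Every CLI run emits one JSON manifest (command, config hash,
input digests, seed, package version, timestamp).
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np

from explantmech.force_trace import ForceTrace, ProbeCalibration
from explantmech.morphometrics import MarkerTracks
from explantmech.stress_relaxation import RelaxationTrace

__all__ = [
    "read_trace",
    "write_force_trace",
    "write_relaxation_trace",
    "read_marker_tracks",
    "write_marker_tracks",
    "RunManifest",
    "write_manifest",
]

_FORCE_CAL_KEYS = (
    "spring_constant_uN_per_um",
    "magnification_um_per_px",
)


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def _parse_meta_and_rows(path: Path):
    meta: Dict[str, str] = {}
    rows = []
    header = None
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not line.strip():
                continue
            parsed = next(csv.reader([line]))
            if header is None:
                header = [c.strip() for c in parsed]
            else:
                rows.append((lineno, parsed))
    if header is None:
        raise ValueError(f"{path}: no header row found")
    return meta, header, rows


def _float_cell(raw: str, path: Path, lineno: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"{path}, line {lineno}: malformed {col!r} value {raw!r}")


def _check_sorted(times, path: Path, line_of_row) -> None:
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        bad = int(np.flatnonzero(diffs <= 0)[0]) + 1
        raise ValueError(
            f"{path}, line {line_of_row[bad]}: time column not strictly increasing"
        )


def read_trace(path) -> Union[ForceTrace, RelaxationTrace]:
    """Read a trace CSV, dispatching on its header row.

    ``time_min,deflection_px`` headers produce a :class:`ForceTrace` (probe
    calibration metadata is mandatory); ``time_s,force_uN`` headers produce
    a :class:`RelaxationTrace`. Malformed rows and unsorted time columns are
    reported with their line numbers.
    """
    path = Path(path)
    meta, header, rows = _parse_meta_and_rows(path)

    if header[:2] == ["time_min", "deflection_px"]:
        missing = [k for k in _FORCE_CAL_KEYS if k not in meta]
        if missing:
            raise ValueError(
                f"{path}: missing calibration metadata keys: {', '.join(missing)}"
            )
        cal = ProbeCalibration(
            spring_constant=float(meta["spring_constant_uN_per_um"]),
            magnification=float(meta["magnification_um_per_px"]),
            probe_id=meta.get("probe_id", ""),
        )
        have_force = "force_uN" in header
        t, d, f, lines = [], [], [], []
        f_idx = header.index("force_uN") if have_force else None
        for lineno, row in rows:
            t.append(_float_cell(row[0], path, lineno, "time_min"))
            d.append(_float_cell(row[1], path, lineno, "deflection_px"))
            if have_force:
                f.append(_float_cell(row[f_idx], path, lineno, "force_uN"))
            lines.append(lineno)
        t = np.asarray(t)
        _check_sorted(t, path, lines)

        def _opt(key):
            v = meta.get(key, "")
            return float(v) if v not in ("", "None") else None

        return ForceTrace(
            time_min=t,
            deflection_px=np.asarray(d),
            calibration=cal,
            pre_unstressed_px=_opt("pre_unstressed_px"),
            post_unstressed_px=_opt("post_unstressed_px"),
            force_uN=np.asarray(f) if have_force else None,
        )

    if header[:2] == ["time_s", "force_uN"]:
        missing = [k for k in ("area_mm2", "imposed_strain") if k not in meta]
        if missing:
            raise ValueError(
                f"{path}: missing relaxation metadata keys: {', '.join(missing)}"
            )
        have_strain = "strain" in header
        s_idx = header.index("strain") if have_strain else None
        t, f, s, lines = [], [], [], []
        for lineno, row in rows:
            t.append(_float_cell(row[0], path, lineno, "time_s"))
            f.append(_float_cell(row[1], path, lineno, "force_uN"))
            if have_strain:
                s.append(_float_cell(row[s_idx], path, lineno, "strain"))
            lines.append(lineno)
        t = np.asarray(t)
        _check_sorted(t, path, lines)
        stage = meta.get("stage_time_hr", "")
        return RelaxationTrace(
            time_s=t,
            force_uN=np.asarray(f),
            imposed_strain=float(meta["imposed_strain"]),
            area_mm2=float(meta["area_mm2"]),
            strain=np.asarray(s) if have_strain else None,
            explant_type=meta.get("explant_type", "giant"),
            stage_time_hr=float(stage) if stage not in ("", "None") else None,
        )

    raise ValueError(
        f"{path}: unrecognized header {header!r}; expected a "
        "'time_min,deflection_px' or 'time_s,force_uN' trace"
    )


def write_force_trace(trace: ForceTrace, path) -> None:
    """Write a pull trace with calibration metadata (see module docstring)."""
    path = Path(path)
    buf = _io.StringIO()
    cal = trace.calibration
    buf.write(f"# probe_id: {cal.probe_id}\n")
    buf.write(f"# spring_constant_uN_per_um: {_fmt(cal.spring_constant)}\n")
    buf.write(f"# magnification_um_per_px: {_fmt(cal.magnification)}\n")
    buf.write(f"# pre_unstressed_px: {_fmt(trace.pre_unstressed_px)}\n")
    buf.write(f"# post_unstressed_px: {_fmt(trace.post_unstressed_px)}\n")
    have_force = trace.force_uN is not None
    buf.write("time_min,deflection_px" + (",force_uN" if have_force else "") + "\n")
    for i in range(len(trace)):
        row = [repr(float(trace.time_min[i])), repr(float(trace.deflection_px[i]))]
        if have_force:
            row.append(repr(float(trace.force_uN[i])))
        buf.write(",".join(row) + "\n")
    path.write_text(buf.getvalue())


def write_relaxation_trace(trace: RelaxationTrace, path) -> None:
    """Write a relaxation trace with area/strain metadata."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# area_mm2: {_fmt(trace.area_mm2)}\n")
    buf.write(f"# imposed_strain: {_fmt(trace.imposed_strain)}\n")
    buf.write(f"# explant_type: {trace.explant_type}\n")
    if trace.stage_time_hr is not None:
        buf.write(f"# stage_time_hr: {_fmt(trace.stage_time_hr)}\n")
    have_strain = trace.strain is not None
    buf.write("time_s,force_uN" + (",strain" if have_strain else "") + "\n")
    for i in range(trace.time_s.size):
        row = [repr(float(trace.time_s[i])), repr(float(trace.force_uN[i]))]
        if have_strain:
            row.append(repr(float(trace.strain[i])))
        buf.write(",".join(row) + "\n")
    path.write_text(buf.getvalue())


def write_marker_tracks(tracks: MarkerTracks, path) -> None:
    """Write tracks as ``track_id,time_min,position_um,region`` rows.

    The region column marks boundary tracks: each region label appears on
    the rows of its two bounding tracks (semicolon-separated when a track
    bounds several regions).
    """
    path = Path(path)
    labels: Dict[str, list] = {tid: [] for tid in tracks.tracks}
    for region, (a, b) in tracks.regions.items():
        labels[a].append(region)
        labels[b].append(region)
    buf = _io.StringIO()
    buf.write("track_id,time_min,position_um,region\n")
    for tid, (t, x) in tracks.tracks.items():
        tag = ";".join(labels[tid])
        for i in range(t.size):
            buf.write(f"{tid},{float(t[i])!r},{float(x[i])!r},{tag}\n")
    path.write_text(buf.getvalue())


def read_marker_tracks(path) -> MarkerTracks:
    """Read a tracks CSV written by :func:`write_marker_tracks`."""
    path = Path(path)
    data: Dict[str, list] = {}
    region_tracks: Dict[str, list] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [c.strip() for c in header[:3]] != ["track_id", "time_min", "position_um"]:
            raise ValueError(f"{path}: unrecognized tracks header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            tid = row[0]
            t = _float_cell(row[1], path, lineno, "time_min")
            x = _float_cell(row[2], path, lineno, "position_um")
            data.setdefault(tid, []).append((t, x))
            if len(row) > 3 and row[3]:
                for region in row[3].split(";"):
                    lst = region_tracks.setdefault(region, [])
                    if tid not in lst:
                        lst.append(tid)
    tracks = {}
    for tid, pairs in data.items():
        arr = np.asarray(pairs)
        tracks[tid] = (arr[:, 0], arr[:, 1])
    regions = {}
    for region, tids in region_tracks.items():
        if len(tids) != 2:
            raise ValueError(
                f"{path}: region {region!r} must be bounded by exactly 2 tracks, "
                f"got {tids}"
            )
        regions[region] = (tids[0], tids[1])
    return MarkerTracks(tracks=tracks, regions=regions)


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    package_version: str
    config_sha256: Optional[str]
    input_sha256: Dict[str, str]
    seed: Optional[int]
    timestamp_utc: str

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "package_version": self.package_version,
            "config_sha256": self.config_sha256,
            "input_sha256": self.input_sha256,
            "seed": self.seed,
            "timestamp_utc": self.timestamp_utc,
        }


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_manifest(
    path,
    command: str,
    config_text: Optional[str] = None,
    inputs: Optional[Dict[str, Path]] = None,
    seed: Optional[int] = None,
) -> RunManifest:
    """Hash the config and inputs and write a JSON manifest next to outputs."""
    from explantmech import __version__

    digests = {}
    for name, p in (inputs or {}).items():
        digests[name] = _sha256(Path(p).read_bytes())
    manifest = RunManifest(
        command=command,
        package_version=__version__,
        config_sha256=_sha256(config_text.encode()) if config_text is not None else None,
        input_sha256=digests,
        seed=seed,
        timestamp_utc=_time.strftime("%Y-%m-%dT%H:%M:%SZ", _time.gmtime()),
    )
    Path(path).write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    return manifest
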