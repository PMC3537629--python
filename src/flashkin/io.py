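"""File formats: trace/distribution/profile CSV and YAML reports.

One flat CSV dialect everywhere: comma-separated, dot decimal, ``#``
comment lines of the form ``# key=value`` carrying metadata, numeric
fields written with 17 significant digits so round trips are value-exact
and repeated writes are byte-identical.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import yaml

from .mem import LifetimeDistribution
from .simulate import TimeTrace
from .thermo import FreeEnergyProfile

__all__ = [
    "TraceFormatError",
    "read_trace_csv",
    "write_trace_csv",
    "write_distribution_csv",
    "read_distribution_csv",
    "write_profile_csv",
    "write_fit_report",
    "write_manifest",
]

REQUIRED_METADATA = ("temperature_K",)

_FMT = "%.17g"


class TraceFormatError(ValueError):
    pass


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return _FMT % v
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return str(v)


def _parse_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def _write_header(fh, metadata: dict):
    for key in sorted(metadata):
        fh.write(f"# {key}={_format_value(metadata[key])}\n")


def _read_metadata(lines):
    """Split '# key=value' comment lines from data lines (line numbers kept)."""
    metadata, data = {}, []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = _parse_value(value.strip())
            continue
        data.append((lineno, stripped))
    return metadata, data


def write_trace_csv(trace: TimeTrace, path) -> None:
    """Deterministic trace CSV: sorted metadata header + time_s,signal[,sigma]."""
    if len(trace) == 0:
        raise TraceFormatError("refusing to write an empty trace")
    buf = _io.StringIO()
    _write_header(buf, trace.metadata)
    cols = ["time_s", "signal"] + (["sigma"] if trace.sigma is not None else [])
    buf.write(",".join(cols) + "\n")
    for i in range(len(trace)):
        row = [_FMT % trace.times[i], _FMT % trace.signal[i]]
        if trace.sigma is not None:
            row.append(_FMT % trace.sigma[i])
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_trace_csv(path) -> TimeTrace:
    """Parse a trace CSV; errors carry the offending line number."""
    text = Path(path).read_text()
    metadata, data = _read_metadata(text.splitlines())
    if not data:
        raise TraceFormatError(f"{path}: no data rows")
    header_line, header = data[0]
    cols = [c.strip() for c in next(csv.reader([header]))]
    if cols[:2] != ["time_s", "signal"]:
        raise TraceFormatError(
            f"{path}: line {header_line}: expected columns time_s,signal"
            f"[,sigma], got {header!r}")
    has_sigma = "sigma" in cols
    times, signal, sigma = [], [], []
    for lineno, row_text in data[1:]:
        fields = next(csv.reader([row_text]))
        if len(fields) != len(cols):
            raise TraceFormatError(
                f"{path}: line {lineno}: expected {len(cols)} fields, "
                f"got {len(fields)}")
        try:
            vals = [float(f) for f in fields]
        except ValueError as exc:
            raise TraceFormatError(
                f"{path}: line {lineno}: malformed number ({exc})") from exc
        if times and vals[0] <= times[-1]:
            raise TraceFormatError(
                f"{path}: line {lineno}: time not strictly increasing")
        times.append(vals[0])
        signal.append(vals[1])
        if has_sigma:
            sigma.append(vals[2])
    for key in REQUIRED_METADATA:
        if key not in metadata:
            raise TraceFormatError(
                f"{path}: missing required metadata {key!r}")
    return TimeTrace(np.array(times), np.array(signal),
                     sigma=np.array(sigma) if has_sigma else None,
                     metadata=metadata)


def write_distribution_csv(dist: LifetimeDistribution, path) -> None:
    buf = _io.StringIO()
    md = dict(dist.metadata)
    md["chi2_per_point"] = dist.chi2_per_point
    md["prior_level"] = dist.prior_level
    _write_header(buf, md)
    buf.write("log10_tau_s,amplitude\n")
    for lt, a in zip(dist.log10_tau_grid, dist.amplitudes):
        buf.write(f"{_FMT % lt},{_FMT % a}\n")
    Path(path).write_text(buf.getvalue())


def read_distribution_csv(path) -> LifetimeDistribution:
    text = Path(path).read_text()
    metadata, data = _read_metadata(text.splitlines())
    grid, amps = [], []
    for lineno, row in data[1:]:
        fields = row.split(",")
        grid.append(float(fields[0]))
        amps.append(float(fields[1]))
    return LifetimeDistribution(
        np.array(grid), np.array(amps),
        chi2_per_point=metadata.pop("chi2_per_point", 0.0),
        prior_level=metadata.pop("prior_level", 0.0),
        metadata=metadata)


def write_profile_csv(profile: FreeEnergyProfile, path) -> None:
    buf = _io.StringIO()
    _write_header(buf, {"temperature_K": profile.temperature_K,
                        "reference": profile.reference})
    buf.write("well,label,delta_G_kJmol,barrier_fwd_kJmol,barrier_rev_kJmol\n")
    for i, label in enumerate(profile.wells):
        fwd = (_FMT % profile.barrier_fwd_kJmol[i]
               if i < len(profile.barrier_fwd_kJmol) else "")
        rev = (_FMT % profile.barrier_rev_kJmol[i]
               if i < len(profile.barrier_rev_kJmol) else "")
        buf.write(f"{i},{label},{_FMT % profile.delta_G_kJmol[i]},{fwd},{rev}\n")
    Path(path).write_text(buf.getvalue())


def _native(obj):
    """Recursively convert numpy scalars/arrays to plain Python for YAML."""
    if isinstance(obj, dict):
        return {k: _native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_native(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_fit_report(result, path, units: dict[str, str] | None = None) -> None:
    """YAML fit report mirroring the published rate-constant tables:
    symbol, value, units, stderr (when the covariance is available)."""
    units = units or {}
    stderrs = {}
    if result.covariance is not None:
        diag = np.sqrt(np.maximum(np.diag(result.covariance), 0.0))
        for name, se_log10 in zip(result.param_names, diag):
            if name.startswith("scale@") or "@" in name:
                continue
            value = result.estimates[name]
            stderrs[name] = float(value * np.log(10) * se_log10)
    doc = {
        "temperature_K": result.estimates.temperature_K,
        "chi2": result.chi2,
        "chi2_per_point": result.chi2_per_point,
        "convergence": result.convergence,
        "nuisances": result.nuisances,
        "rates": [
            {"symbol": sym, "value": float(v),
             "units": units.get(sym, "s^-1"),
             **({"stderr": stderrs[sym]} if sym in stderrs else {})}
            for sym, v in sorted(result.estimates.values.items())
        ],
    }
    Path(path).write_text(yaml.safe_dump(_native(doc), sort_keys=False))


def write_manifest(entries: list[dict], path, **top_level) -> None:
    """YAML manifest listing generated files, their seeds and ground truth."""
    doc = dict(top_level)
    doc["files"] = entries
    Path(path).write_text(yaml.safe_dump(_native(doc), sort_keys=False))
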