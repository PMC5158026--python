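"""File formats: curve TSV, cohort manifest JSON, records/stats CSV.

Everything is plain text and diff-able.  A curve file is a tab-separated
table with ``#``-prefixed metadata header lines::

    # schema: tubemech-curve/1
    # tube_id: g003
    # k_sensor_N_per_m: 10.0
    time_s	z_um	force_uN
    0.000000000	0.000000000	-0.0031

Columns are matched by name, so column order is free.  Floats are written
with 9 significant digits, making write -> read lossless at that precision
and repeated runs byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import RawCurve, SCHEMA_VERSION

CURVE_SCHEMA = "tubemech-curve/1"
_REQUIRED_COLUMNS = ("time_s", "z_um", "force_uN")


class CurveParseError(ValueError):
    """Malformed curve file; the message names the offending line."""


def write_curve(curve: RawCurve, path) -> None:
    path = Path(path)
    lines = [f"# schema: {CURVE_SCHEMA}"]
    for key, val in curve.meta.items():
        lines.append(f"# {key}: {val}")
    lines.append("\t".join(_REQUIRED_COLUMNS))
    for t, z, f in zip(curve.time, curve.z_stage, curve.force):
        lines.append(f"{t:.9g}\t{z:.9g}\t{f:.9g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_meta_value(raw: str):
    low = raw.strip()
    if low in ("True", "False"):
        return low == "True"
    try:
        return int(low)
    except ValueError:
        pass
    try:
        return float(low)
    except ValueError:
        return low


def read_curve(path) -> RawCurve:
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    data: list[list[float]] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise CurveParseError(f"{path.name} line {lineno}: metadata "
                                      f"line without 'key: value'")
            key, val = body.split(":", 1)
            meta[key.strip()] = _parse_meta_value(val)
            continue
        if header is None:
            header = line.split("\t")
            missing = set(_REQUIRED_COLUMNS) - set(header)
            if missing:
                raise CurveParseError(
                    f"{path.name} line {lineno}: missing columns {sorted(missing)}"
                )
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise CurveParseError(
                f"{path.name} line {lineno}: expected {len(header)} fields, "
                f"got {len(parts)}"
            )
        try:
            data.append([float(p) for p in parts])
        except ValueError as exc:
            raise CurveParseError(f"{path.name} line {lineno}: {exc}") from None
    if header is None or not data:
        raise CurveParseError(f"{path.name}: no data rows found")
    table = pd.DataFrame(data, columns=header)
    time = table["time_s"].to_numpy()
    if np.any(np.diff(time) < 0):
        raise CurveParseError(f"{path.name}: non-monotone time column")
    meta.pop("schema", None)
    return RawCurve(
        time=time,
        z_stage=table["z_um"].to_numpy(),
        force=table["force_uN"].to_numpy(),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Cohort directories
# ---------------------------------------------------------------------------


def write_cohort(curves: list[RawCurve], manifest: dict, out_dir) -> Path:
    """Write one TSV per curve plus ``manifest.json``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(manifest)
    entries = []
    for curve, entry in zip(curves, manifest["curves"]):
        fname = f"{entry['curve_id']}.tsv"
        write_curve(curve, out / fname)
        entry = dict(entry)
        entry["file"] = fname
        entries.append(entry)
    manifest["curves"] = entries
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out


def read_manifest(in_dir) -> dict:
    path = Path(in_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {in_dir}")
    manifest = json.loads(path.read_text(encoding="utf-8"))
    if manifest.get("schema") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported manifest schema {manifest.get('schema')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    return manifest


def read_cohort(in_dir) -> tuple[list[RawCurve], dict]:
    """Load a cohort directory; every listed file must exist and parse."""
    in_dir = Path(in_dir)
    manifest = read_manifest(in_dir)
    curves = []
    for entry in manifest["curves"]:
        fpath = in_dir / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"curve file listed in manifest missing: {fpath}")
        curves.append(read_curve(fpath))
    return curves, manifest


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """CSV with optional ``#`` metadata header (schema, config hash)."""
    path = Path(path)
    chunks = []
    if header_meta:
        chunks.extend(f"# {k}: {v}" for k, v in header_meta.items())
    chunks.append(df.to_csv(index=False, float_format="%.9g").rstrip("\n"))
    path.write_text("\n".join(chunks) + "\n", encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n",
        encoding="utf-8",
    )
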