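"""Localization-table and line-profile I/O.

Two delimited-text dialects for localization tables:

``generic``
    Header columns ``frame,x_nm,y_nm[,photons,precision_nm]``.
``thunderstorm``
    ThunderSTORM-style export: ``frame``, ``x [nm]``, ``y [nm]``,
    ``intensity [photon]``, ``uncertainty [nm]``; unknown extra columns are
    preserved as opaque metadata.

All coordinates are nanometres after loading.  Delimiter is a comma,
decimal point, UTF-8 — fixed, not sniffed.  Writers are deterministic:
fixed column order, 6-significant-digit formatting, newline-terminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .profiles import LineProfile

__all__ = [
    "LocalizationTable",
    "read_localizations",
    "write_localizations",
    "read_profile",
    "write_profile",
]

_TS_COLUMN_MAP = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "intensity [photon]": "photons",
    "uncertainty [nm]": "precision",
}
_GENERIC_COLUMN_MAP = {
    "frame": "frame",
    "x_nm": "x",
    "y_nm": "y",
    "photons": "photons",
    "precision_nm": "precision",
}
_MANDATORY = ("frame", "x", "y")


@dataclass
class LocalizationTable:
    """Point set of (x, y, frame[, photons, precision]) records, in nm."""

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    photons: np.ndarray | None = None
    precision: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.frame.size
        if self.x.size != n or self.y.size != n:
            raise InvalidParameterError("frame/x/y lengths differ")
        if n and (not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y))):
            raise InvalidParameterError("coordinates must be finite")
        if n and np.any(self.frame < 1):
            raise InvalidParameterError("frame indices must be positive integers")
        for name in ("photons", "precision"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise InvalidParameterError(f"{name} length differs from frame")
                setattr(self, name, v)

    def __len__(self) -> int:
        return int(self.frame.size)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"frame": self.frame, "x_nm": self.x, "y_nm": self.y}
        if self.photons is not None:
            data["photons"] = self.photons
        if self.precision is not None:
            data["precision_nm"] = self.precision
        return pd.DataFrame(data)


def _coerce_numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(
            f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
            f"{col!r} at line {line}"
        )
    if vals.isna().any():
        line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: missing value in column {col!r} at line {line}")
    return vals.to_numpy()


def read_localizations(path, dialect: str = "generic") -> LocalizationTable:
    """Read a localization table; output coordinates are always in nm."""
    path = Path(path)
    colmap = {"generic": _GENERIC_COLUMN_MAP, "thunderstorm": _TS_COLUMN_MAP}.get(dialect)
    if colmap is None:
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, comment="#", skipinitialspace=True)
    df.columns = [c.strip().strip('"') for c in df.columns]
    present = {src: dst for src, dst in colmap.items() if src in df.columns}
    reverse = {dst: src for src, dst in present.items()}
    for needed in _MANDATORY:
        if needed not in reverse:
            src_name = next(s for s, d in colmap.items() if d == needed)
            raise FormatError(
                f"{path}: missing mandatory column {src_name!r} (field {needed!r})"
            )
    fields: dict[str, np.ndarray | None] = {}
    for dst in ("frame", "x", "y", "photons", "precision"):
        src = reverse.get(dst)
        fields[dst] = _coerce_numeric(df, src, path) if src else None
    extra = {c: df[c].tolist() for c in df.columns if c not in present}
    return LocalizationTable(
        frame=fields["frame"],
        x=fields["x"],
        y=fields["y"],
        photons=fields["photons"],
        precision=fields["precision"],
        metadata={"dialect": dialect, "units": "nm", "extra_columns": extra},
    )


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_localizations(table: LocalizationTable, path, dialect: str = "generic") -> None:
    """Write a localization table deterministically (byte-identical per input)."""
    path = Path(path)
    if dialect == "generic":
        headers = ["frame", "x_nm", "y_nm"]
    elif dialect == "thunderstorm":
        headers = ["frame", "x [nm]", "y [nm]"]
    else:
        raise InvalidParameterError(f"unknown dialect {dialect!r}")
    cols: list[np.ndarray] = [table.frame, table.x, table.y]
    if table.photons is not None:
        headers.append("photons" if dialect == "generic" else "intensity [photon]")
        cols.append(table.photons)
    if table.precision is not None:
        headers.append("precision_nm" if dialect == "generic" else "uncertainty [nm]")
        cols.append(table.precision)
    lines = [",".join(headers)]
    for i in range(len(table)):
        parts = [str(int(table.frame[i]))]
        parts += [_fmt(float(c[i])) for c in cols[1:]]
        lines.append(",".join(parts))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


_PROFILE_HEADER_KEYS = ("origin_x_nm", "origin_y_nm", "direction_x", "direction_y", "bin_width_nm")


def write_profile(profile: LineProfile, path) -> None:
    """Write a line profile as two-column CSV with a comment metadata header."""
    path = Path(path)
    ox, oy = profile.origin
    dx, dy = profile.direction
    lines = [
        f"# origin_x_nm={_fmt(ox)}",
        f"# origin_y_nm={_fmt(oy)}",
        f"# direction_x={dx:.12g}",
        f"# direction_y={dy:.12g}",
        f"# bin_width_nm={profile.bin_width:.12g}",
        "bin_center_nm,count",
    ]
    for c, n in zip(profile.bin_centers, profile.counts):
        lines.append(f"{c:.12g},{_fmt(float(n))}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_profile(path) -> LineProfile:
    """Read a line profile written by :func:`write_profile`.

    A missing metadata header falls back to origin (0, 0), direction (1, 0)
    and the median bin spacing, with a warning and a flag in ``metadata``.
    Non-uniform bin spacing (jitter > 1e-6 * bin_width) is a format error.
    """
    path = Path(path)
    meta: dict[str, float] = {}
    data_lines: list[str] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    pass
            continue
        data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: empty profile file")
    if data_lines[0].replace(" ", "") != "bin_center_nm,count":
        raise FormatError(f"{path}: expected header 'bin_center_nm,count'")
    centers, counts = [], []
    for i, line in enumerate(data_lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: expected 2 columns at data line {i}")
        try:
            centers.append(float(parts[0]))
            counts.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value at data line {i}") from exc
    centers = np.asarray(centers)
    counts = np.asarray(counts)

    header_missing = not all(k in meta for k in _PROFILE_HEADER_KEYS)
    if header_missing:
        warnings.warn(f"{path}: missing metadata header; using defaults", stacklevel=2)
    bin_width = meta.get(
        "bin_width_nm",
        float(np.median(np.diff(centers))) if centers.size > 1 else 1.0,
    )
    if centers.size > 1:
        jitter = np.max(np.abs(np.diff(centers) - bin_width))
        if jitter > 1e-6 * bin_width:
            raise FormatError(f"{path}: non-uniform bin spacing (jitter {jitter:g} nm)")
    return LineProfile(
        bin_centers=centers,
        counts=counts,
        bin_width=bin_width,
        origin=(meta.get("origin_x_nm", 0.0), meta.get("origin_y_nm", 0.0)),
        direction=(meta.get("direction_x", 1.0), meta.get("direction_y", 0.0)),
        metadata={"header_missing": header_missing, "path": str(path)},
    )
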