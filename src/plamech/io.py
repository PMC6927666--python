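"""Readers and writers: TIFF channels, force-curve tables, result files.

On-disk conventions:

* images are single- or multi-page grayscale TIFF (8/16-bit or float);
  intensity values are taken as raw counts, never rescaled on read;
* force curves are TSV with a ``# key: value`` metadata header (spring
  constant, sensitivity, segment, probe geometry/parameters) followed by
  ``z_nm`` and ``deflection`` columns; QI grids are one concatenated table
  with additional ``row``/``col`` columns;
* results are CSV tables with a stable column order, float32 TIFF maps
  (NaN-preserving), and a JSON run manifest capturing the full configuration,
  seed and package version so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve, ProbeSpec, QIMap
from .errors import FormatError
from .image_ops import Image2D

__all__ = [
    "read_image_stack",
    "write_image",
    "read_force_table",
    "write_force_curve",
    "write_qi_grid",
    "read_qi_grid",
    "write_results",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image_stack(path, channel_manifest: dict[str, int]) -> dict[str, Image2D]:
    """Read a TIFF and bind its pages to channel roles.

    ``channel_manifest`` maps role names (``"dapi"``, ``"pla"``,
    ``"membrane"``) to page indices.  Bit depth is preserved as-is; RGB input
    is rejected (no silent color conversion).
    """
    data = tifffile.imread(path)
    if data.ndim == 2:
        pages = [data]
    elif data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] not in (3, 4):
        raise FormatError(f"{path}: RGB input requires an explicit grayscale conversion")
    elif data.ndim == 3:
        pages = [data[i] for i in range(data.shape[0])]
    else:
        raise FormatError(f"{path}: unsupported TIFF dimensionality {data.shape}")
    out: dict[str, Image2D] = {}
    for role, page in channel_manifest.items():
        if not 0 <= page < len(pages):
            raise FormatError(
                f"{path}: manifest requires page {page} for role '{role}' "
                f"but the file has {len(pages)} page(s)"
            )
        out[role] = Image2D(np.asarray(pages[page]), channel=role)
    return out


def write_image(img, path) -> None:
    """Write an image, mask or label/float map as TIFF (dtype preserved)."""
    px = img.pixels if hasattr(img, "pixels") else np.asarray(img)
    if px.dtype == bool:
        px = px.astype(np.uint16)
    elif px.dtype.kind == "f" and px.dtype != np.float32:
        px = px.astype(np.float32)
    tifffile.imwrite(path, px)


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

_REQUIRED_META = ("k", "segment")


def _parse_metadata(path) -> dict:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _probe_from_meta(meta: dict) -> ProbeSpec | None:
    geometry = meta.get("probe")
    if geometry is None:
        return None
    return ProbeSpec(
        geometry=geometry,
        R=float(meta["R"]) if "R" in meta else None,
        half_angle=float(meta["half_angle"]) if "half_angle" in meta else None,
        nu=float(meta.get("nu", 0.5)),
    )


def _curve_from_frame(df: pd.DataFrame, meta: dict, path) -> ForceCurve:
    for key in _REQUIRED_META:
        if key not in meta:
            raise FormatError(f"{path}: missing required metadata '{key}'")
    try:
        return ForceCurve(
            z=df["z_nm"].to_numpy(float),
            deflection=df["deflection"].to_numpy(float),
            k=float(meta["k"]),
            segment=meta["segment"],
            sensitivity=float(meta["sensitivity"]) if "sensitivity" in meta else None,
            probe=_probe_from_meta(meta),
        )
    except Exception as exc:  # invariant violations surface as format errors
        raise FormatError(f"{path}: {exc}") from exc


def read_force_table(path) -> ForceCurve:
    """Read one force curve from a TSV file with a metadata header."""
    meta = _parse_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("z_nm", "deflection"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    return _curve_from_frame(df, meta, path)


def write_force_curve(curve: ForceCurve, path) -> None:
    """Write one force curve as TSV with a metadata header."""
    lines = [f"# k: {curve.k!r}", f"# segment: {curve.segment}"]
    if curve.sensitivity is not None:
        lines.append(f"# sensitivity: {curve.sensitivity!r}")
    if curve.probe is not None:
        lines.append(f"# probe: {curve.probe.geometry}")
        if curve.probe.R is not None:
            lines.append(f"# R: {curve.probe.R!r}")
        if curve.probe.half_angle is not None:
            lines.append(f"# half_angle: {curve.probe.half_angle!r}")
        lines.append(f"# nu: {curve.probe.nu!r}")
    df = pd.DataFrame({"z_nm": curve.z, "deflection": curve.deflection})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_qi_grid(grid, path) -> None:
    """Write a rectangular grid of curves as one concatenated TSV table."""
    first = grid[0][0]
    frames = []
    for i, row in enumerate(grid):
        for j, curve in enumerate(row):
            frames.append(
                pd.DataFrame(
                    {"row": i, "col": j, "z_nm": curve.z, "deflection": curve.deflection}
                )
            )
    lines = [f"# k: {first.k!r}", f"# segment: {first.segment}"]
    if first.sensitivity is not None:
        lines.append(f"# sensitivity: {first.sensitivity!r}")
    if first.probe is not None:
        lines.append(f"# probe: {first.probe.geometry}")
        if first.probe.R is not None:
            lines.append(f"# R: {first.probe.R!r}")
        if first.probe.half_angle is not None:
            lines.append(f"# half_angle: {first.probe.half_angle!r}")
        lines.append(f"# nu: {first.probe.nu!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        pd.concat(frames).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_qi_grid(path) -> list[list[ForceCurve]]:
    """Read a concatenated QI table back into a rectangular grid of curves."""
    meta = _parse_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("row", "col", "z_nm", "deflection"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    grid: list[list[ForceCurve]] = []
    for i in range(rows):
        grid_row = []
        for j in range(cols):
            sub = df[(df["row"] == i) & (df["col"] == j)]
            if sub.empty:
                raise FormatError(f"{path}: missing curve at grid position {(i, j)}")
            grid_row.append(_curve_from_frame(sub, meta, path))
        grid.append(grid_row)
    return grid


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(results, out_dir, prefix: str = "results") -> list[Path]:
    """Write pipeline results to ``out_dir``; returns the files written.

    Accepts a pandas DataFrame (written as CSV) or a :class:`QIMap` (written
    as float32 stiffness + height TIFFs, NaN marking failed pixels).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(results, pd.DataFrame):
        path = out_dir / f"{prefix}.csv"
        results.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    elif isinstance(results, QIMap):
        e_path = out_dir / f"{prefix}_stiffness_Pa.tif"
        h_path = out_dir / f"{prefix}_height_nm.tif"
        tifffile.imwrite(e_path, results.E_map.astype(np.float32))
        tifffile.imwrite(h_path, results.height_map.astype(np.float32))
        written.extend([e_path, h_path])
    else:
        raise FormatError(f"unsupported result type {type(results).__name__}")
    return written


def write_manifest(out_dir, config, seed: int | None = None) -> Path:
    """Write a JSON run manifest (full config + seed + package version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    payload = {"version": __version__, "seed": seed, "config": config}
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
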