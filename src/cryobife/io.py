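"""File formats: MRC/MRCS stacks, STAR-like metadata tables, path bundles.

The MRC writer emits standard mode-2 (float32) stacks with a 1024-byte
header; the STAR reader/writer covers the single-loop dialect RELION uses
for particle metadata.  Both are deliberately minimal, self-contained
implementations of well-documented formats.

Conventions: image pixel indices are 0-based with the origin at the top-left
of the array; the box center is at pixel ``(N/2, N/2)``.  All writes are
atomic (write to a temporary file in the same directory, then rename), so an
interrupted run never leaves a truncated output behind.
"""

from __future__ import annotations

import json
import os
import struct
import tempfile
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .path import Conformation, Path, make_path
from .simulate import ImagingParams, ParticleImage, ParticleStack

__all__ = [
    "atomic_write_bytes",
    "atomic_write_text",
    "write_mrc",
    "read_mrc",
    "write_star",
    "read_star",
    "write_particle_stack",
    "read_particle_stack",
    "save_path",
    "load_path",
]

_MRC_HEADER_SIZE = 1024
_MRC_MODE_FLOAT32 = 2


def atomic_write_bytes(path, data: bytes) -> None:
    path = FsPath(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


def write_mrc(path, data: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write an image stack (or single image) as an MRC/MRCS mode-2 file.

    ``data`` may be (ny, nx) or (nz, ny, nx); values are stored as little-
    endian float32 with the pixel size recorded in the cell dimensions.
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = data.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)           # NX, NY, NZ
    struct.pack_into("<i", header, 12, _MRC_MODE_FLOAT32)    # MODE
    struct.pack_into("<3i", header, 28, nx, ny, nz)          # MX, MY, MZ
    struct.pack_into(                                        # CELLA (Angstroms)
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)    # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)             # MAPC, MAPR, MAPS
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    header[208:212] = b"MAP "                                # format id
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])        # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    atomic_write_bytes(path, bytes(header) + data.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC/MRCS mode-2 file; returns ``(data (nz, ny, nx), pixel_size)``."""
    raw = FsPath(path).read_bytes()
    if len(raw) < _MRC_HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if raw[208:212] != b"MAP ":
        raise ValueError(f"{path}: missing MAP format id (corrupt header?)")
    if mode != _MRC_MODE_FLOAT32:
        raise ValueError(f"{path}: only mode 2 (float32) is supported, got mode {mode}")
    if min(nx, ny, nz) < 1:
        raise ValueError(f"{path}: invalid dimensions {(nx, ny, nz)}")
    (cella_x,) = struct.unpack_from("<f", raw, 40)
    pixel_size = cella_x / nx if nx else 1.0
    count = nx * ny * nz
    body = raw[_MRC_HEADER_SIZE : _MRC_HEADER_SIZE + 4 * count]
    if len(body) != 4 * count:
        raise ValueError(f"{path}: data block shorter than the header promises")
    data = np.frombuffer(body, dtype="<f4").reshape(nz, ny, nx).copy()
    return data, float(pixel_size)


def write_star(path, table: pd.DataFrame, block_name: str = "particles") -> None:
    """Write a single-block, single-loop STAR table (RELION dialect)."""
    lines = [f"data_{block_name}", "", "loop_"]
    for i, col in enumerate(table.columns, start=1):
        lines.append(f"{col} #{i}")
    for _, row in table.iterrows():
        lines.append(" ".join(_star_value(v) for v in row))
    lines.append("")
    atomic_write_text(path, "\n".join(lines))


def _star_value(v) -> str:
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def read_star(path) -> pd.DataFrame:
    """Read the first loop of a STAR file into a DataFrame (numeric if possible)."""
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw_line in FsPath(path).read_text().splitlines():
        line = raw_line.strip()
        if not line or line.startswith("#") or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            continue
        if in_loop and line.startswith("_"):
            columns.append(line.split()[0])
            continue
        if in_loop and columns:
            fields = line.split()
            if len(fields) != len(columns):
                raise ValueError(f"{path}: row has {len(fields)} fields, expected {len(columns)}")
            rows.append(fields)
    if not columns:
        raise ValueError(f"{path}: no loop_ block found")
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return df


def write_particle_stack(stack_path, metadata_path, stack: ParticleStack) -> None:
    """Write a ParticleStack as MRCS + STAR metadata + JSON provenance sidecar."""
    write_mrc(stack_path, stack.pixel_array().astype(np.float32), stack.pixel_size)
    write_star(metadata_path, stack.metadata_frame())
    sidecar = FsPath(str(stack_path) + ".json")
    atomic_write_text(sidecar, json.dumps(stack.provenance, indent=2, sort_keys=True))


def read_particle_stack(stack_path, metadata_path) -> ParticleStack:
    """Read an MRC/MRCS stack and its STAR metadata into a ParticleStack.

    Requires one metadata row per image.  Optional columns (SNR, truth node,
    orientation) default to benign values with a warning; defocus defaults
    to 1 um if absent.
    """
    import warnings

    data, pixel_size = read_mrc(stack_path)
    meta = read_star(metadata_path)
    if len(meta) != data.shape[0]:
        raise ValueError(
            f"metadata has {len(meta)} rows but the stack holds {data.shape[0]} images"
        )
    if "_rlnImagePixelSize" in meta.columns:
        pixel_size = float(meta["_rlnImagePixelSize"].iloc[0])
    images = []
    for k in range(data.shape[0]):
        row = meta.iloc[k]
        if "_rlnDefocusU" in meta.columns:
            defocus = float(row["_rlnDefocusU"]) * 1.0e-4  # Angstroms -> um
        else:
            defocus = 1.0
            if k == 0:
                warnings.warn("metadata lacks _rlnDefocusU; defaulting defocus to 1 um")
        if {"_cbifeQuatW", "_cbifeQuatX", "_cbifeQuatY", "_cbifeQuatZ"} <= set(meta.columns):
            quat = np.array(
                [row["_cbifeQuatW"], row["_cbifeQuatX"], row["_cbifeQuatY"], row["_cbifeQuatZ"]],
                dtype=float,
            )
            quat /= np.linalg.norm(quat)
        else:
            quat = np.array([1.0, 0.0, 0.0, 0.0])
        snr = float(row["_cbifeSnr"]) if "_cbifeSnr" in meta.columns else np.inf
        truth = int(row["_cbifeTruthNode"]) if "_cbifeTruthNode" in meta.columns else -1
        params = ImagingParams(
            orientation=quat,
            defocus=defocus,
            pixel_size=pixel_size,
            box_size=data.shape[1],
            snr=snr,
        )
        images.append(
            ParticleImage(
                pixels=data[k].astype(np.float64),
                params=params,
                truth_node=None if truth < 0 else truth,
            )
        )
    provenance = {}
    sidecar = FsPath(str(stack_path) + ".json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    return ParticleStack(images=images, provenance=provenance)


_BEAD_TABLE_VERSION = "zamyatnin-volumes/residue-electrons-1"


def save_path(directory, path: Path) -> None:
    """Serialize a path as per-node coordinate CSVs plus a JSON manifest."""
    directory = FsPath(directory)
    directory.mkdir(parents=True, exist_ok=True)
    node_files = []
    for m, node in enumerate(path.nodes):
        fname = f"node_{m:03d}.csv"
        df = pd.DataFrame(
            {
                "x": node.bead_positions[:, 0],
                "y": node.bead_positions[:, 1],
                "z": node.bead_positions[:, 2],
                "radius": node.bead_radii,
                "electrons": node.bead_electrons,
            }
        )
        atomic_write_text(directory / fname, df.to_csv(index=False))
        node_files.append({"file": fname, "label": node.label})
    manifest = {
        "n_nodes": path.n_nodes,
        "s_values": [float(s) for s in path.s_values],
        "bead_table_version": _BEAD_TABLE_VERSION,
        "nodes": node_files,
    }
    atomic_write_text(directory / "manifest.json", json.dumps(manifest, indent=2))


def load_path(directory) -> Path:
    directory = FsPath(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    nodes = []
    for entry in manifest["nodes"]:
        df = pd.read_csv(directory / entry["file"])
        nodes.append(
            Conformation(
                bead_positions=df[["x", "y", "z"]].to_numpy(),
                bead_radii=df["radius"].to_numpy(),
                bead_electrons=df["electrons"].to_numpy(),
                label=entry.get("label", ""),
            )
        )
    return make_path(nodes)
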