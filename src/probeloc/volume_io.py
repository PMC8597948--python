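"""3D image and annotation volumes: data model, I/O, coordinate conversion, region lookup.

Volumes are scalar grids on a regular lattice with per-axis micron spacing.
The canonical anatomical axis order is (ML, DV, AP) — medial-lateral,
dorsal-ventral, anterior-posterior — and all physical coordinates are in
microns.  Voxel coordinates refer to voxel *centers*; the voxel that owns a
physical point is decided half-open toward increasing index, which makes
boundary lookups deterministic.

Supported on-disk formats:

* single-file TIFF stacks (pages along the third axis) with a JSON sidecar
  ``<file>.json`` carrying ``{"spacing_um": [...], "axis_order": [...]}``;
* NRRD with spacing in the header (``spacings`` or ``space directions``),
  ``raw`` or ``gzip`` encoded.

Spacing metadata is mandatory: a volume without a known physical scale is
useless for localization, so a missing sidecar/field raises instead of
silently assuming 1 um.
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Volume3D",
    "AnnotationVolume",
    "read_volume",
    "write_volume",
    "downsample_volume",
    "lookup_region",
    "read_region_table",
    "write_region_table",
    "OUTSIDE_LABEL",
]

#: Label reserved for "not in the brain"; never present in a region table.
OUTSIDE_LABEL = 0

DEFAULT_AXIS_ORDER = ("ML", "DV", "AP")


class MissingSpacingError(ValueError):
    """Raised when a volume file carries no physical voxel-spacing metadata."""


@dataclass
class Volume3D:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D array (any scalar dtype).
    spacing
        Micron extent of one voxel along each axis; all entries positive.
    axis_order
        Anatomical tag per axis, default ``("ML", "DV", "AP")``.
    origin
        Micron position of the *center* of voxel (0, 0, 0), default zeros.
    space_name
        Name of the coordinate space the volume lives in (e.g. ``"subject"``,
        ``"CCF"``, ``"MRI3D"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: tuple[str, str, str] = DEFAULT_AXIS_ORDER
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    space_name: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("volume dimensions must all be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        self.axis_order = tuple(self.axis_order)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    # ---- coordinate conversion ------------------------------------------------

    def voxel_to_micron(self, idx: np.ndarray) -> np.ndarray:
        """Micron position of voxel center(s) ``idx`` ((..., 3) float ok)."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def micron_to_voxel(self, um: np.ndarray) -> np.ndarray:
        """Fractional voxel coordinates of micron point(s) ``um``."""
        um = np.asarray(um, dtype=float)
        return (um - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains(self, um: np.ndarray) -> np.ndarray:
        """True where point(s) fall inside the half-open voxel-ownership box."""
        # rint ties-to-even would break the half-open rule; use floor(v + .5)
        v = np.floor(self.micron_to_voxel(um) + 0.5).astype(int)
        shape = np.asarray(self.shape)
        return np.all((v >= 0) & (v < shape), axis=-1)


@dataclass
class AnnotationVolume(Volume3D):
    """Integer region-label volume plus a table mapping label -> (acronym, name)."""

    region_table: Mapping[int, tuple[str, str]] = field(default_factory=dict)
    outside_label: int = OUTSIDE_LABEL

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("annotation labels must be an integer grid")
        self.region_table = {int(k): tuple(v) for k, v in self.region_table.items()}
        if self.outside_label in self.region_table:
            raise ValueError(
                f"outside_label {self.outside_label} must not appear in region_table"
            )
        present = set(np.unique(self.data).tolist()) - {self.outside_label}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"labels present in grid but not in region_table: {sorted(missing)}")

    @property
    def labels(self) -> np.ndarray:
        return self.data


# ---- region lookup ---------------------------------------------------------


def lookup_region(annot: AnnotationVolume, point: np.ndarray) -> int | np.ndarray:
    """Region label at micron ``point`` (or (N, 3) points) in ``annot``'s space.

    Uses nearest-voxel-center ownership with the half-open rule
    ``[center - s/2, center + s/2)`` per axis; points outside the grid's
    bounding box map to ``annot.outside_label``.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    v = np.floor(annot.micron_to_voxel(pts) + 0.5).astype(int)
    shape = np.asarray(annot.shape)
    inside = np.all((v >= 0) & (v < shape), axis=-1)
    out = np.full(pts.shape[0], annot.outside_label, dtype=annot.data.dtype)
    vi = v[inside]
    out[inside] = annot.data[vi[:, 0], vi[:, 1], vi[:, 2]]
    if np.asarray(point).ndim == 1:
        return int(out[0])
    return out


# ---- downsampling ----------------------------------------------------------


def downsample_volume(vol: Volume3D, factors: tuple[int, int, int]) -> Volume3D:
    """Block-mean downsample by integer ``factors``; spacing multiplies accordingly.

    Trailing partial blocks are averaged over the voxels actually present, so
    no data is discarded for shapes that are not factor-divisible.
    """
    f = []
    for x in factors:
        if float(x) != int(x) or int(x) < 1:
            raise ValueError(f"downsampling factors must be positive integers, got {factors}")
        f.append(int(x))
    fx, fy, fz = f
    data = np.asarray(vol.data, dtype=float)
    # pad with NaN so partial blocks average over available voxels only
    pad = [(0, (-data.shape[i]) % f[i]) for i in range(3)]
    if any(p[1] for p in pad):
        data = np.pad(data, pad, mode="constant", constant_values=np.nan)
    nx, ny, nz = (data.shape[0] // fx, data.shape[1] // fy, data.shape[2] // fz)
    blocks = data.reshape(nx, fx, ny, fy, nz, fz)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks, axis=(1, 3, 5))
    new_spacing = tuple(s * k for s, k in zip(vol.spacing, f))
    # origin moves to the center of the first block
    new_origin = tuple(
        o + (k - 1) / 2.0 * s for o, s, k in zip(vol.origin, vol.spacing, f)
    )
    return replace(vol, data=out, spacing=new_spacing, origin=new_origin)


# ---- file I/O --------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path: str | Path, format: str | None = None, **kwargs) -> Volume3D:
    """Read a :class:`Volume3D` from a TIFF stack (+JSON sidecar) or NRRD file.

    ``format`` is ``"tiff-stack"`` or ``"nrrd"``; inferred from the suffix when
    omitted.  Raises :class:`MissingSpacingError` if no voxel spacing can be
    found, rather than assuming a default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "nrrd" if path.suffix.lower() == ".nrrd" else "tiff-stack"
    if format == "tiff-stack":
        return _read_tiff(path, **kwargs)
    if format == "nrrd":
        return _read_nrrd(path, **kwargs)
    raise ValueError(f"unknown volume format {format!r}")


def write_volume(vol: Volume3D, path: str | Path, format: str | None = None) -> Path:
    """Write ``vol`` losslessly; TIFF gets a JSON metadata sidecar."""
    path = Path(path)
    if format is None:
        format = "nrrd" if path.suffix.lower() == ".nrrd" else "tiff-stack"
    if format == "tiff-stack":
        # pages along the third axis
        tifffile.imwrite(path, np.moveaxis(vol.data, 2, 0))
        meta = {
            "spacing_um": list(vol.spacing),
            "axis_order": list(vol.axis_order),
            "origin_um": list(vol.origin),
            "space_name": vol.space_name,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif format == "nrrd":
        _write_nrrd(vol, path)
    else:
        raise ValueError(f"unknown volume format {format!r}")
    return path


def _read_tiff(path: Path, space_name: str | None = None) -> Volume3D:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingSpacingError(
            f"TIFF stack {path} has no spacing sidecar {sidecar.name}; "
            "voxel spacing must be provided explicitly"
        )
    meta = json.loads(sidecar.read_text())
    if "spacing_um" not in meta:
        raise MissingSpacingError(f"sidecar {sidecar} lacks 'spacing_um'")
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    return Volume3D(
        data=data,
        spacing=tuple(meta["spacing_um"]),
        axis_order=tuple(meta.get("axis_order", DEFAULT_AXIS_ORDER)),
        origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        space_name=space_name or meta.get("space_name", "subject"),
    )


# minimal NRRD support: text header, raw/gzip encoding, attached data
_NRRD_DTYPES = {
    "signed char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "long long": "i8", "int64": "i8", "uint64": "u8",
    "float": "f4", "double": "f8",
}
_NRRD_TYPE_OF = {
    "int8": "int8", "uint8": "uint8", "int16": "int16", "uint16": "uint16",
    "int32": "int32", "uint32": "uint32", "int64": "int64", "uint64": "uint64",
    "float32": "float", "float64": "double",
}


def _read_nrrd(path: Path, space_name: str | None = None) -> Volume3D:
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if end < 0:
        raise IOError(f"{path}: no NRRD header terminator found")
    header_lines = raw[:end].decode("ascii", errors="replace").splitlines()
    if not header_lines or not header_lines[0].startswith("NRRD"):
        raise IOError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    for line in header_lines[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.lstrip("=").strip()
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if len(sizes) != 3:
        raise IOError(f"{path}: only 3D NRRD volumes are supported, sizes={sizes}")
    dtype = np.dtype(_NRRD_DTYPES[fields["type"]])
    endian = fields.get("endian", "little")
    dtype = dtype.newbyteorder("<" if endian == "little" else ">")
    spacing = _nrrd_spacing(fields)
    if spacing is None:
        raise MissingSpacingError(
            f"{path}: NRRD header has neither 'spacings' nor 'space directions'"
        )
    encoding = fields.get("encoding", "raw")
    blob = raw[end + 2:]
    if encoding in ("gzip", "gz"):
        blob = gzip.decompress(blob)
    elif encoding in ("zlib",):
        blob = zlib.decompress(blob)
    elif encoding != "raw":
        raise IOError(f"{path}: unsupported NRRD encoding {encoding!r}")
    data = np.frombuffer(blob, dtype=dtype, count=int(np.prod(sizes)))
    # NRRD lists sizes fastest-first; numpy C order is slowest-first
    data = data.reshape(sizes[::-1]).transpose(2, 1, 0)
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = tuple(float(x) for x in fields["space origin"].strip("()").split(","))
    labels = fields.get("labels", "").replace('"', "").split()
    axis_order = tuple(labels) if len(labels) == 3 else DEFAULT_AXIS_ORDER
    return Volume3D(
        data=data, spacing=spacing, axis_order=axis_order, origin=origin,
        space_name=space_name or fields.get("content", "subject"),
    )


def _nrrd_spacing(fields: dict[str, str]) -> tuple[float, float, float] | None:
    if "spacings" in fields:
        sp = tuple(float(x) for x in fields["spacings"].split())
        return sp if len(sp) == 3 else None
    if "space directions" in fields:
        sp = []
        for vec in fields["space directions"].split(") ("):
            comps = [float(x) for x in vec.strip("()").split(",")]
            sp.append(float(np.linalg.norm(comps)))
        return tuple(sp) if len(sp) == 3 else None
    return None


def _write_nrrd(vol: Volume3D, path: Path) -> None:
    dtype = np.dtype(vol.data.dtype).newbyteorder("<")
    name = _NRRD_TYPE_OF.get(np.dtype(dtype).name)
    if name is None:
        raise ValueError(f"cannot write dtype {vol.data.dtype} to NRRD")
    header = [
        "NRRD0004",
        "# probeloc volume",
        f"type: {name}",
        "dimension: 3",
        f"sizes: {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}",
        f"spacings: {vol.spacing[0]:.10g} {vol.spacing[1]:.10g} {vol.spacing[2]:.10g}",
        'labels: "%s" "%s" "%s"' % vol.axis_order,
        f"space origin: ({vol.origin[0]:.10g},{vol.origin[1]:.10g},{vol.origin[2]:.10g})",
        f"content: {vol.space_name}",
        "endian: little",
        "encoding: raw",
    ]
    blob = np.ascontiguousarray(vol.data.transpose(2, 1, 0)).astype(dtype).tobytes()
    path.write_bytes(("\n".join(header) + "\n\n").encode("ascii") + blob)


# ---- region tables ---------------------------------------------------------


def read_region_table(path: str | Path) -> dict[int, tuple[str, str]]:
    """Read a label,acronym,name CSV into a region table mapping."""
    df = pd.read_csv(path)
    return {int(r.label): (str(r.acronym), str(r.name)) for r in df.itertuples()}


def write_region_table(table: Mapping[int, tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    rows = [{"label": k, "acronym": v[0], "name": v[1]} for k, v in sorted(table.items())]
    pd.DataFrame(rows, columns=["label", "acronym", "name"]).to_csv(path, index=False)
    return path
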