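"""Multi-channel 3D volume I/O with physical voxel geometry.

All file-format handling lives here so the analysis modules only ever see a
:class:`MultiChannelVolume`: a stack of same-shaped 3D intensity grids, one
per channel role, plus the voxel pitch in μm.  Volumes travel on disk as
OME-TIFF with axes (z, c, y, x), 16-bit unsigned (camera bit depth), physical
pixel sizes in the OME ``PhysicalSizeX/Y/Z`` attributes and channel roles as
OME channel names.  In memory the array order is (c, z, y, x) and intensities
are floating point.

Conventions
-----------
* Voxel indices are 0-based; the physical coordinate of voxel i along an axis
  of pitch p is its centre, (i + 0.5) * p μm.
* Physical coordinates are ordered (z, y, x) to match array indexing; CSV
  outputs relabel them as x_um / y_um / z_um columns.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import tifffile

__all__ = [
    "CHANNEL_ROLES",
    "VoxelGeometry",
    "MultiChannelVolume",
    "read_volume",
    "write_volume",
    "check_volume",
]

#: Valid channel roles: nuclear stain (DRAQ-5-like), cytoplasmic stain
#: (CellTracker-Green-like), membrane stain (DiI-like, visualization only)
#: and label-free elastic scattering.
CHANNEL_ROLES = ("nuclear", "cytoplasm", "membrane", "scatter")


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel pitch in μm along x, y, z.  Anisotropy (dz != dx) allowed."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"voxel pitch {name} must be > 0, got {v}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz

    @property
    def pitch_zyx(self) -> tuple[float, float, float]:
        """Pitch ordered to match array axes (z, y, x)."""
        return (self.dz, self.dy, self.dx)

    def voxel_centers(self, shape_zyx) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates in μm for a (z, y, x) grid."""
        return tuple(
            (np.arange(n) + 0.5) * p for n, p in zip(shape_zyx, self.pitch_zyx)
        )


@dataclass
class MultiChannelVolume:
    """Same-shaped per-channel 3D intensity grids with voxel geometry.

    ``data`` has axes (channel, z, y, x); ``roles[i]`` names channel i.
    """

    data: np.ndarray
    geometry: VoxelGeometry
    roles: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.roles = tuple(self.roles)
        if self.data.ndim != 4:
            raise ValueError(f"expected (c, z, y, x) array, got ndim={self.data.ndim}")
        if len(self.roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.roles)} roles for {self.data.shape[0]} channels"
            )
        for r in self.roles:
            if r not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {r!r}; valid: {CHANNEL_ROLES}")
        if len(set(self.roles)) != len(self.roles):
            raise ValueError(f"duplicate channel roles: {self.roles}")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def has_role(self, role: str) -> bool:
        return role in self.roles

    def channel(self, role: str) -> np.ndarray:
        """3D (z, y, x) grid of the channel with the given role."""
        if role not in self.roles:
            raise KeyError(f"volume has no {role!r} channel; present: {self.roles}")
        return self.data[self.roles.index(role)]


def check_volume(vol: MultiChannelVolume) -> list[str]:
    """Validate type invariants; one human-readable finding per violation.

    Returns an empty list for a valid volume.  Diagnostics, not exceptions:
    shape/role consistency is enforced at construction, so findings here
    concern voxel values and geometry.
    """
    findings: list[str] = []
    for p in ("dx", "dy", "dz"):
        # construction already rejects these, but a geometry may be mutated
        if getattr(vol.geometry, p) <= 0:
            findings.append(f"non-positive voxel pitch {p}")
    for i, role in enumerate(vol.roles):
        chan = vol.data[i]
        if not np.all(np.isfinite(chan)):
            findings.append(f"channel {i} ({role}): non-finite intensities")
        elif np.any(chan < 0):
            findings.append(f"channel {i} ({role}): negative intensities")
        if chan.shape != vol.shape_zyx:
            findings.append(f"channel {i} ({role}): shape mismatch")
    return findings


def write_volume(vol: MultiChannelVolume, path) -> Path:
    """Write an OME-TIFF with (z, c, y, x) planes, uint16 samples.

    Channel names are the roles; physical pixel sizes are embedded in μm.
    Intensities are rounded and clipped to [0, 65535]; for the integer-valued
    volumes the synthetic generator produces the round trip is bit exact.
    """
    path = Path(path)
    arr = np.clip(np.rint(vol.data), 0, 65535).astype("<u2")
    arr = arr.transpose(1, 0, 2, 3)  # (c,z,y,x) -> (z,c,y,x)
    g = vol.geometry
    meta = {
        "axes": "ZCYX",
        "PhysicalSizeX": g.dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": g.dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": g.dz,
        "PhysicalSizeZUnit": "µm",
        "Channel": {"Name": list(vol.roles)},
    }
    if vol.provenance:
        meta["Description"] = vol.provenance
    tifffile.imwrite(path, arr, ome=True, metadata=meta, photometric="minisblack")
    return path


def _parse_ome(ome_xml: str):
    """Extract (VoxelGeometry or None, channel names or None) from OME-XML."""
    root = ET.fromstring(ome_xml)
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None, None
    sizes = [pixels.get(f"PhysicalSize{ax}") for ax in "XYZ"]
    geom = None
    if all(s is not None for s in sizes):
        geom = VoxelGeometry(*(float(s) for s in sizes))
    names = [c.get("Name") for c in pixels.findall(f"{ns}Channel")]
    if not names or any(n is None for n in names):
        names = None
    return geom, names


def read_volume(
    path,
    role_map: Optional[Mapping[int, str]] = None,
    geometry_override: Optional[VoxelGeometry] = None,
) -> MultiChannelVolume:
    """Read a TIFF / OME-TIFF z-stack into a MultiChannelVolume.

    Parameters
    ----------
    path
        TIFF readable as (z, [c], y, x).
    role_map
        channel index -> role.  When omitted, OME channel names are used as
        roles; a file without usable channel names then errors.
    geometry_override
        Voxel geometry to use instead of (or in the absence of) embedded
        OME physical pixel sizes.  Missing metadata without an override is
        an error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            axes = series.axes
            arr = series.asarray()
            ome_xml = tf.ome_metadata
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise IOError(f"unreadable TIFF {path}: {exc}") from exc

    geom = names = None
    if ome_xml:
        geom, names = _parse_ome(ome_xml)

    # normalize axes to (c, z, y, x)
    axes = axes.replace("I", "Z").replace("Q", "Z")
    # a sample axis is a channel axis only when a real Z axis exists;
    # otherwise it is the stack axis of a plain 3D TIFF
    axes = axes.replace("S", "C" if "Z" in axes else "Z")
    if sorted(axes) == sorted("ZYX"):
        arr = arr[np.newaxis]
        axes = "C" + axes
    if sorted(axes) != sorted("CZYX"):
        raise IOError(f"cannot interpret TIFF axes {series.axes!r} as (z,[c],y,x)")
    arr = np.transpose(arr, [axes.index(a) for a in "CZYX"])

    if geometry_override is not None:
        geom = geometry_override
    if geom is None:
        raise ValueError(
            f"missing voxel geometry: {path} has no physical pixel size metadata "
            "and no geometry_override was given"
        )

    n_chan = arr.shape[0]
    if role_map is not None:
        if set(role_map.keys()) != set(range(n_chan)):
            raise ValueError(
                f"role_map covers channels {sorted(role_map)} but file has "
                f"{n_chan} channels"
            )
        roles = tuple(role_map[i] for i in range(n_chan))
    elif names is not None:
        roles = tuple(names)
    else:
        raise ValueError(f"{path}: no channel names in metadata and no role_map given")

    return MultiChannelVolume(arr.astype(np.float32), geom, roles, provenance=str(path))
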