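"""Read, write, mask, threshold, downsample and summarize 3D density volumes.

Two on-disk dialects are supported:

* MRC2014 (``.mrc``/``.map``), mode 2 (float32), handled by :mod:`gemmi`;
* SPIDER single-volume 3D files (``.vol``/``.spi``), float32, IFORM=3,
  written/read directly (the header is a flat float32 record).

Coordinate convention: the physical position (Å) of voxel index
``(ix, iy, iz)`` is ``origin + voxel_size * (ix, iy, iz)``; indices are
0-based and ``data`` has shape ``(nx, ny, nz)`` with ``data[ix, iy, iz]``.
Only isotropic voxel sizes are accepted.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DensityVolume", "BinaryMask", "VolumeFormatError",
    "read_volume", "write_volume", "auto_threshold",
    "apply_threshold_mask", "downsample", "slices_and_projections",
]


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be parsed in the named format."""


@dataclass
class DensityVolume:
    """A 3D scalar density grid with physical voxel size and origin.

    Attributes
    ----------
    data:
        Array of shape ``(nx, ny, nz)``; density in arbitrary units.
    voxel_size:
        Isotropic voxel edge length in Å.
    origin:
        Position (Å) of voxel index ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a non-empty 3D array")
        if np.ndim(self.voxel_size) > 0:
            vs = np.asarray(self.voxel_size, dtype=float)
            if not np.allclose(vs, vs.flat[0], rtol=1e-6, atol=0.0):
                raise ValueError(
                    f"anisotropic voxel sizes {tuple(vs)} are not supported"
                )
            self.voxel_size = float(vs.flat[0])
        self.voxel_size = float(self.voxel_size)
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite densities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates (Å) of voxel centers along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.voxel_size * np.arange(n)


@dataclass
class BinaryMask:
    """A {0,1} grid with the same dimensions as its source volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# Format detection and I/O
# ---------------------------------------------------------------------------

_MRC_EXTS = {".mrc", ".map", ".ccp4"}
_SPIDER_EXTS = {".vol", ".spi", ".spider"}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("mrc", "spider"):
            raise ValueError(f"unknown volume format {fmt!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in _MRC_EXTS:
        return "mrc"
    if ext in _SPIDER_EXTS:
        return "spider"
    raise ValueError(
        f"cannot infer volume format from extension {ext!r}; "
        "pass format='mrc' or format='spider'"
    )


def read_volume(path: str, format: str | None = None) -> DensityVolume:
    """Read an MRC2014 or SPIDER density volume.

    If the header carries no voxel size, 1 Å is assumed and a warning is
    logged. A truncated or garbled file raises :class:`VolumeFormatError`
    naming the offending header field rather than returning a partial grid.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "mrc":
        return _read_mrc(path)
    return _read_spider(path)


def write_volume(vol: DensityVolume, path: str, format: str | None = None) -> None:
    """Write a volume as MRC2014 mode-2 or single-volume 3D SPIDER (float32)."""
    fmt = _infer_format(path, format)
    if fmt == "mrc":
        _write_mrc(vol, path)
    else:
        _write_spider(vol, path)


def _read_mrc(path: str) -> DensityVolume:
    import gemmi

    try:
        m = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise VolumeFormatError(f"cannot parse {path!r} as MRC: {exc}") from exc
    data = np.array(m.grid, copy=True).astype(np.float64)
    spacing = np.asarray(m.grid.spacing, dtype=float)
    if np.any(spacing <= 0):
        logger.warning("%s: header has no voxel size; assuming 1 Å", path)
        voxel = 1.0
    else:
        if not np.allclose(spacing, spacing[0], rtol=1e-4):
            raise VolumeFormatError(
                f"{path!r}: anisotropic voxel size {tuple(spacing)} (CELLA/N headers)"
            )
        voxel = float(spacing[0])
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"{path!r}: non-finite density values in data block")
    return DensityVolume(data, voxel, origin)


def _write_mrc(vol: DensityVolume, path: str) -> None:
    import gemmi

    m = gemmi.Ccp4Map()
    nx, ny, nz = vol.data.shape
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(
        nx * vol.voxel_size, ny * vol.voxel_size, nz * vol.voxel_size, 90, 90, 90
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for i, v in zip((50, 51, 52), vol.origin):
        m.set_header_float(i, float(v))
    m.write_ccp4_map(path)


# SPIDER header slots used (1-based float32 word index, per the SPIDER
# header layout): 1 NSLICE, 2 NROW, 5 IFORM, 12 NSAM, 13 LABREC,
# 18-20 XOFF/YOFF/ZOFF, 21 SCALE, 22 LABBYT, 23 LENBYT, 38 PIXSIZ.
_SPIDER_IFORM_3D = 3.0


def _read_spider(path: str) -> DensityVolume:
    with open(path, "rb") as fh:
        head = np.frombuffer(fh.read(1024), dtype="<f4")
        if head.size < 23:
            raise VolumeFormatError(f"{path!r}: SPIDER header truncated")
        nz, ny = int(head[0]), int(head[1])
        iform = head[4]
        nx = int(head[11])
        labbyt = int(head[21])
        lenbyt = int(head[22])
        if iform != _SPIDER_IFORM_3D:
            raise VolumeFormatError(
                f"{path!r}: IFORM={iform:g}, expected 3 (3D volume)"
            )
        for name, v in (("NSAM", nx), ("NROW", ny), ("NSLICE", nz)):
            if v < 1:
                raise VolumeFormatError(f"{path!r}: invalid {name}={v}")
        if lenbyt != 4 * nx or labbyt % lenbyt != 0 or labbyt < 1024:
            raise VolumeFormatError(
                f"{path!r}: inconsistent LABBYT={labbyt}/LENBYT={lenbyt} for NSAM={nx}"
            )
        fh.seek(0, os.SEEK_END)
        expected = labbyt + 4 * nx * ny * nz
        if fh.tell() != expected:
            raise VolumeFormatError(
                f"{path!r}: file size {fh.tell()} != header-implied {expected} "
                "(truncated or corrupt data block)"
            )
        fh.seek(labbyt)
        raw = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
    head_full = np.frombuffer(open(path, "rb").read(labbyt), dtype="<f4")
    voxel = float(head_full[37]) if head_full.size > 37 else 0.0
    if voxel <= 0:
        logger.warning("%s: header has no voxel size; assuming 1 Å", path)
        voxel = 1.0
    origin = np.array(head_full[17:20], dtype=float) if head_full.size > 19 else np.zeros(3)
    data = raw.reshape(nz, ny, nx).transpose(2, 1, 0).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"{path!r}: non-finite density values in data block")
    return DensityVolume(data, voxel, origin)


def _write_spider(vol: DensityVolume, path: str) -> None:
    nx, ny, nz = vol.data.shape
    lenbyt = 4 * nx
    labrec = int(math.ceil(1024 / lenbyt))
    labbyt = labrec * lenbyt
    head = np.zeros(labbyt // 4, dtype="<f4")
    head[0] = nz
    head[1] = ny
    head[2] = labrec + ny * nz  # IREC: total records
    head[4] = _SPIDER_IFORM_3D
    data32 = vol.data.astype(np.float32)
    head[5] = 1.0  # IMAMI: statistics computed
    head[6] = float(data32.max())
    head[7] = float(data32.min())
    head[8] = float(data32.mean())
    head[9] = float(data32.std())
    head[11] = nx
    head[12] = labrec
    head[17:20] = vol.origin
    head[20] = 1.0  # SCALE
    head[21] = labbyt
    head[22] = lenbyt
    head[37] = vol.voxel_size  # PIXSIZ
    with open(path, "wb") as fh:
        fh.write(head.tobytes())
        fh.write(np.ascontiguousarray(data32.transpose(2, 1, 0)).tobytes())


# ---------------------------------------------------------------------------
# Thresholding, masking, downsampling, summaries
# ---------------------------------------------------------------------------

def auto_threshold(vol: DensityVolume) -> float:
    """First-guess masking threshold: Otsu's method over nonzero voxels.

    The histogram (256 bins) of strictly positive densities is split at the
    threshold maximizing inter-class variance. Raises ``ValueError`` for a
    constant volume, which no threshold can separate.
    """
    from skimage.filters import threshold_otsu

    values = vol.data[vol.data > 0]
    if values.size == 0:
        values = vol.data.ravel()
    if np.unique(values).size < 2:
        raise ValueError("no threshold separates a constant volume")
    t = float(threshold_otsu(values, nbins=256))
    lo, hi = float(values.min()), float(values.max())
    # guard against degenerate bin placement at the extremes
    if not lo < t < hi:
        t = min(max(t, np.nextafter(lo, hi)), np.nextafter(hi, lo))
    return t


def apply_threshold_mask(
    vol: DensityVolume, threshold: float
) -> tuple[DensityVolume, BinaryMask]:
    """Zero all densities below ``threshold``; return the masked volume and mask.

    The mask is 1 exactly where the input density is >= threshold, so the
    masked volume equals the input multiplied elementwise by the mask.
    """
    keep = vol.data >= threshold
    masked = np.where(keep, vol.data, 0.0)
    return (
        DensityVolume(masked, vol.voxel_size, vol.origin.copy()),
        BinaryMask(keep.astype(np.uint8)),
    )


def downsample(vol: DensityVolume, factor: int) -> DensityVolume:
    """Block-average the grid over ``factor``³ blocks; voxel size scales by ``factor``.

    Dimensions not divisible by ``factor`` are zero-padded first (logged).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("downsampling factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return DensityVolume(vol.data.copy(), vol.voxel_size, vol.origin.copy())
    data = vol.data
    pads = [(-n) % factor for n in data.shape]
    if any(pads):
        logger.warning(
            "downsample: dims %s not divisible by %d; zero-padding by %s",
            data.shape, factor, tuple(pads),
        )
        data = np.pad(data, [(0, p) for p in pads])
    nx, ny, nz = (n // factor for n in data.shape)
    blocks = data.reshape(nx, factor, ny, factor, nz, factor)
    out = blocks.mean(axis=(1, 3, 5))
    # block centers shift by (factor-1)/2 voxels relative to the old origin
    shift = vol.voxel_size * (factor - 1) / 2.0
    return DensityVolume(out, vol.voxel_size * factor, vol.origin + shift)


_AXES = {"x": 0, "y": 1, "z": 2}


def slices_and_projections(
    vol: DensityVolume, axis: str = "z"
) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    """2D slices along ``axis`` plus the three orthogonal sum-projections.

    Returns ``(slices, projections)`` where ``slices[k]`` is the k-th plane
    perpendicular to ``axis`` (one per voxel along it) and ``projections``
    maps each axis name to the sum of the volume along that axis.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    ax = _AXES[axis]
    slices = [np.take(vol.data, k, axis=ax) for k in range(vol.data.shape[ax])]
    projections = {name: vol.data.sum(axis=a) for name, a in _AXES.items()}
    return slices, projections
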