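"""Image and table I/O with explicit physical metadata.

The in-memory container for microscopy data is :class:`ImageStack`: a
channel-z-y-x voxel grid with per-axis physical voxel sizes in micrometres.
All distances everywhere in this package are micrometres, all coordinates
are voxel-centred and 0-based, and the axis order is fixed as (c, z, y, x);
a single convention prevents anisotropy bugs.

Stacks are read and written as OME-TIFF via :mod:`tifffile`, with voxel
sizes carried in the OME ``PhysicalSize*`` attributes.  Tabular outputs are
plain CSV; metrics that are undefined for a record (e.g. K_p for a nucleus
with zero puncta) are written as empty fields, never as 0.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, MetadataError

logger = logging.getLogger(__name__)

__all__ = ["ImageStack", "read_stack", "write_stack", "write_tables", "read_table"]


@dataclass
class ImageStack:
    """Multi-channel 3-D image with physical voxel sizes.

    Parameters
    ----------
    voxels
        Array of shape (channels, z, y, x); non-negative intensities (a.u.).
    voxel_size
        (z, y, x) voxel edge lengths in micrometres.
    channel_names
        One label per channel, e.g. ``("protein", "dna")``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...] = ("protein", "dna")

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 4:
            raise ValueError(f"expected (c, z, y, x) voxels, got shape {self.voxels.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.channel_names = tuple(self.channel_names)[: self.voxels.shape[0]]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial (z, y, x) shape."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(np.prod(self.voxel_size))

    def channel(self, which: int | str) -> np.ndarray:
        """Return one channel as a (z, y, x) array."""
        if isinstance(which, str):
            try:
                which = self.channel_names.index(which)
            except ValueError:
                raise KeyError(f"no channel named {which!r}; have {self.channel_names}")
        return self.voxels[which]


def _axes_to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (c, z, y, x), adding singleton axes."""
    axes = axes.upper()
    # squeeze axes we do not model (time, samples of 1)
    for ax in ("T", "S", "Q", "I"):
        while ax in axes:
            i = axes.index(ax)
            if data.shape[i] != 1 and ax in ("T",):
                raise FormatError("time series stacks are not supported")
            data = np.take(data, 0, axis=i) if data.shape[i] == 1 else data.max(axis=i)
            axes = axes[:i] + axes[i + 1 :]
    for ax in "CZYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(data, order)


def _ome_voxel_size(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tf.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        pix = meta["OME"]["Image"]
        if isinstance(pix, list):
            pix = pix[0]
        pix = pix["Pixels"]
        return (
            float(pix["PhysicalSizeZ"]),
            float(pix["PhysicalSizeY"]),
            float(pix["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
    channel_names: Sequence[str] = ("protein", "dna"),
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Voxel size is taken from OME ``PhysicalSize*`` metadata; an explicit
    ``voxel_size_override`` wins over metadata (with a logged notice).
    Missing voxel size with no override raises :class:`MetadataError`.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            meta_vs = _ome_voxel_size(tf)
    except (tifffile.TiffFileError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc

    if voxel_size_override is not None:
        if meta_vs is not None:
            logger.info("voxel size override %s supersedes metadata %s for %s",
                        tuple(voxel_size_override), meta_vs, path.name)
        voxel_size = tuple(float(v) for v in voxel_size_override)
    elif meta_vs is not None:
        voxel_size = meta_vs
    else:
        raise MetadataError(
            f"{path} carries no voxel-size metadata; pass voxel_size_override"
        )
    return ImageStack(_axes_to_czyx(data, axes), voxel_size, tuple(channel_names))


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF with voxel-size metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    return path


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            row = dataclasses.asdict(rec)
        elif isinstance(rec, dict):
            row = dict(rec)
        else:
            raise TypeError(f"cannot tabulate record of type {type(rec)}")
        for key, val in list(row.items()):
            if isinstance(val, (tuple, list, np.ndarray)):
                row[key] = ";".join(format(float(v), ".6g") for v in np.ravel(val))
        rows.append(row)
    return pd.DataFrame(rows)


def write_tables(
    records: Sequence,
    path: str | Path,
    columns: Sequence[str] | None = None,
    allow_empty: bool = False,
) -> Path:
    """Write per-punctum / per-nucleus records to CSV.

    Undefined metrics (``None`` / NaN) become empty fields.  An empty record
    list is only written (as a header-only file) when ``allow_empty`` is set
    together with explicit ``columns``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if len(records) == 0:
        if not allow_empty:
            raise ValueError("no records to write; pass allow_empty=True for a header-only file")
        pd.DataFrame(columns=list(columns or [])).to_csv(path, index=False)
        return path
    frame = _records_to_frame(records)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    frame.to_csv(path, index=False, na_rep="")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_tables` (empty fields → NaN)."""
    return pd.read_csv(path)
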