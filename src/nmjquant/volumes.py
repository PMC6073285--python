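"""Multichannel volume container and TIFF/OME-TIFF input/output.

The whole package works on one in-memory representation: an 8-bit
intensity grid with canonical axis order ``(z, y, x, channel)`` and a
physical voxel size in micrometres.  2D sections are volumes with
z-extent 1, so every downstream operation (segmentation, distances,
region statistics) has a single code path.

Confocal thresholds used throughout the package (30–255 for the
postsynapse mask, 20/6/22–255 for channel binarization) are defined on
the 0–255 grayscale, so data deeper than 8 bit are rejected unless the
caller explicitly asks for a linear rescale.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, ValidationError

#: µm per voxel along (z, y, x) for the cross-section confocal setup.
DEFAULT_VOXEL_SIZE = (1.0, 0.785, 0.785)

# Columns written to every per-NMJ results file, in this fixed order.
# Missing fields are emitted as empty values so CSV layout is stable
# across study modes.
RESULT_COLUMNS = [
    "nmj_id",
    "n_pixels",
    "mean_nmj",
    "sd_nmj",
    "mean_fiber",
    "sd_fiber",
    "positive",
    "flagged",
    "nearest_marker_id",
    "distance_um",
]

_DISTANCE_DECIMALS = 3


@dataclass
class VolumeImage:
    """An n-channel intensity grid with physical voxel geometry.

    Parameters
    ----------
    data:
        ``uint8`` array indexed ``(z, y, x, channel)``.  2D sections use
        z-extent 1.
    voxel_size:
        ``(dz, dy, dx)`` in µm; all strictly positive.
    channel_names:
        One marker label per channel, e.g. ``["BGT", "VAChT"]``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(
                f"expected (z, y, x, channel) data, got {self.data.ndim} axes"
            )
        if self.data.dtype != np.uint8:
            raise ValidationError(
                f"intensities must be uint8 (0-255), got dtype {self.data.dtype}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(
                f"voxel_size must be 3 strictly positive values, got {self.voxel_size}"
            )
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[3]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[3]} channels"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape (z, y, x) without the channel axis."""
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def is_2d(self) -> bool:
        return self.data.shape[0] == 1

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) grid of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[..., idx]


def normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder an array with tifffile-style axis labels to (Z, Y, X, C).

    Missing axes are inserted with extent 1; sample axes ('S') are
    treated as channels.  Applying this to an already-normalized
    (Z, Y, X, C) array is the identity.
    """
    axes = axes.upper().replace("S", "C").replace("I", "Z").replace("Q", "Z")
    if len(axes) != data.ndim:
        raise ValidationError(f"axes {axes!r} do not match {data.ndim}-d data")
    for ax in "ZYXC":
        if axes.count(ax) > 1:
            raise ValidationError(f"duplicate axis {ax!r} in {axes!r}")
    unknown = set(axes) - set("ZYXC")
    if unknown:
        raise ValidationError(f"unsupported axes {sorted(unknown)} in {axes!r}")
    for ax in "ZYXC":
        if ax not in axes:
            data = data[..., np.newaxis]
            axes += ax
    order = [axes.index(ax) for ax in "ZYXC"]
    return np.transpose(data, order)


def _voxel_size_from_ome(xml_text: str) -> tuple[float, float, float] | None:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels" if ns else ".//Pixels", ns)
    if pixels is None:
        return None
    sizes = []
    for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
        val = pixels.get(key)
        if val is None:
            return None
        sizes.append(float(val))
    return tuple(sizes)  # type: ignore[return-value]


def _channel_names_from_ome(xml_text: str, n: int) -> list[str] | None:
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return None
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    chans = root.findall(".//ome:Channel" if ns else ".//Channel", ns)
    names = [c.get("Name") for c in chans]
    if len(names) == n and all(names):
        return list(names)  # type: ignore[arg-type]
    return None


def read_volume(
    path: str | Path,
    voxel_size: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
    rescale: bool = False,
) -> VolumeImage:
    """Read a multichannel TIFF/OME-TIFF into a :class:`VolumeImage`.

    Voxel size is taken from OME metadata when present; a ``voxel_size``
    argument overrides file metadata (acquisition settings are usually
    recorded per experiment rather than trusted from headers).  Data
    deeper than 8 bit raise unless ``rescale=True``, which maps the full
    dtype range linearly onto 0–255.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        ome = tf.ome_metadata

    data = normalize_axes(data, axes)

    if data.dtype != np.uint8:
        if not rescale:
            raise ValidationError(
                f"{path.name}: dtype {data.dtype} is deeper than 8 bit; "
                "pass rescale=True for a linear map onto 0-255"
            )
        info = np.iinfo(data.dtype) if np.issubdtype(data.dtype, np.integer) else None
        top = info.max if info else float(data.max() or 1)
        data = np.clip(np.rint(data.astype(np.float64) * 255.0 / top), 0, 255)
        data = data.astype(np.uint8)

    vs = tuple(voxel_size) if voxel_size is not None else None
    if vs is None and ome:
        vs = _voxel_size_from_ome(ome)
    if vs is None:
        raise ConfigurationError(
            f"{path.name}: no voxel size in metadata; pass voxel_size explicitly"
        )

    names = list(channel_names) if channel_names is not None else None
    if names is None and ome:
        names = _channel_names_from_ome(ome, data.shape[3])
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[3])]

    return VolumeImage(data=data, voxel_size=vs, channel_names=names)


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a :class:`VolumeImage` as OME-TIFF with voxel-size metadata."""
    path = Path(path)
    dz, dy, dx = volume.voxel_size
    # OME layout wants channel before the spatial y/x axes.
    data = np.transpose(volume.data, (0, 3, 1, 2))  # Z, C, Y, X
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": volume.channel_names},
        },
    )
    return path


@dataclass
class ResultsTable:
    """Per-NMJ result rows plus study-level metadata.

    One row per retained postsynaptic object.  Metadata carries the
    reproducibility context (age label, marker, seed, config hash).
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.records, pd.DataFrame):
            self.records = pd.DataFrame(self.records)
        for col in RESULT_COLUMNS:
            if col not in self.records.columns:
                self.records[col] = pd.NA
        self.records = self.records[RESULT_COLUMNS]

    def __len__(self) -> int:
        return len(self.records)


def _format_records(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "distance_um" in out.columns:
        out["distance_um"] = [
            ""
            if pd.isna(d)
            else ("inf" if np.isinf(d) else f"{float(d):.{_DISTANCE_DECIMALS}f}")
            for d in out["distance_um"]
        ]
    return out


def write_results(table: ResultsTable, path: str | Path, format: str = "csv") -> Path:
    """Serialize a results table to CSV or JSON.

    Column order is fixed; distances are written in µm with 3 decimals
    so re-reading reproduces values exactly at that precision.
    """
    if table is None:
        raise ValidationError("results table is required")
    path = Path(path)
    formatted = _format_records(table.records)
    if format == "csv":
        formatted.to_csv(path, index=False, lineterminator="\n")
    elif format == "json":
        payload = {
            "metadata": table.metadata,
            "records": formatted.where(pd.notna(formatted), None).to_dict(
                orient="records"
            ),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ConfigurationError(f"unknown results format {format!r}")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["records"], columns=RESULT_COLUMNS)
    return pd.read_csv(path)
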