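"""Classical 3D segmentation: threshold, label, size-filter, edge-exclude.

Each channel is binarized at inclusive intensity bounds chosen per
marker on the 0–255 scale, connected components are labeled in 3D, and
objects are filtered by voxel count.  Postsynapse (BGT, α-bungarotoxin)
objects touching any volume face are discarded so that truncated
junctions never enter distance statistics; marker channels keep their
edge objects, since a filamentous axon almost always crosses the field
of view.

Default parameters: intensity bounds BGT 20–255, TH 6–255,
neurofilament L 22–255, VAChT 20–255; object sizes 50–20,000,000 voxels
for the postsynapse channel and 3–2,000,000,000 for marker channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ValidationError
from .volumes import VolumeImage

DEFAULT_INTENSITY_BOUNDS: dict[str, tuple[int, int]] = {
    "BGT": (20, 255),
    "TH": (6, 255),
    "NFL": (22, 255),
    "VAChT": (20, 255),
}

DEFAULT_SIZE_BOUNDS: dict[str, tuple[int, int]] = {
    "postsynapse": (50, 20_000_000),
    "marker": (3, 2_000_000_000),
}

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationConfig:
    """Thresholds and filters for the classical segmentation.

    ``intensity_bounds`` maps a marker label to inclusive (lo, hi)
    grayscale bounds; ``size_bounds`` maps the object role
    ('postsynapse' or 'marker') to inclusive (min, max) voxel counts.
    ``exclude_edges`` selects which roles drop objects touching the
    volume faces (postsynapse only, by default).
    """

    intensity_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_BOUNDS)
    )
    size_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_BOUNDS)
    )
    connectivity: int = 26
    exclude_edges: dict[str, bool] = field(
        default_factory=lambda: {"postsynapse": True, "marker": False}
    )

    def __post_init__(self) -> None:
        if self.connectivity not in _STRUCTURES:
            raise ConfigurationError(
                f"connectivity must be one of {sorted(_STRUCTURES)}, "
                f"got {self.connectivity}"
            )
        for name, (lo, hi) in self.intensity_bounds.items():
            if not (0 <= lo <= hi <= 255):
                raise ConfigurationError(
                    f"intensity bounds for {name!r} must satisfy 0<=lo<=hi<=255"
                )
        for role, (mn, mx) in self.size_bounds.items():
            if not (0 < mn <= mx):
                raise ConfigurationError(
                    f"size bounds for {role!r} must satisfy 0<min<=max"
                )

    def bounds_for(self, channel: str) -> tuple[int, int]:
        try:
            return self.intensity_bounds[channel]
        except KeyError:
            raise ConfigurationError(
                f"no intensity bounds configured for channel {channel!r}"
            ) from None


@dataclass(frozen=True)
class ObjectInfo:
    """Summary of one labeled object."""

    id: int
    n_voxels: int
    bbox: tuple[slice, slice, slice]
    touches_edge: bool


@dataclass
class LabeledObjects:
    """An integer label grid (0 = background) plus per-object summaries.

    Labels are consecutive positive integers in raster order of each
    object's first voxel, which makes every downstream report
    deterministic.
    """

    labels: np.ndarray
    objects: list[ObjectInfo]
    connectivity: int = 26

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def ids(self) -> list[int]:
        return [o.id for o in self.objects]

    def mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id

    def voxels(self, object_id: int) -> np.ndarray:
        """(n, 3) integer voxel indices of one object."""
        return np.argwhere(self.labels == object_id)

    def border_voxels(self, object_id: int) -> np.ndarray:
        """(n, 3) indices of object voxels with a face neighbor outside.

        A border voxel is any voxel of the object with at least one of
        its six face neighbors not belonging to the object (volume
        faces count as outside only through the shifted comparison,
        i.e. a voxel on the grid face is a border voxel).
        """
        return np.argwhere(border_mask(self.labels == object_id))


def border_mask(mask: np.ndarray) -> np.ndarray:
    """Face-connectivity border of a boolean mask (edge voxels included)."""
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(mask.ndim, 1),
        border_value=0,
    )
    return mask & ~interior


def binarize(
    volume: VolumeImage, channel: str, bounds: tuple[int, int] | None = None,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Boolean mask: voxel true iff lo <= intensity <= hi (inclusive)."""
    if bounds is None:
        bounds = (config or SegmentationConfig()).bounds_for(channel)
    lo, hi = bounds
    if not (0 <= lo <= hi <= 255):
        raise ConfigurationError(f"invalid intensity bounds {bounds}")
    grid = volume.channel(channel)
    return (grid >= lo) & (grid <= hi)


def label_components(mask: np.ndarray, connectivity: int = 26) -> LabeledObjects:
    """Label maximal connected components of a 3D boolean mask.

    Component ids follow the raster order of each component's first
    voxel (the order scipy's scanning labeler assigns them).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValidationError(f"expected 3D mask, got {mask.ndim}D")
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ConfigurationError(
            f"connectivity must be one of {sorted(_STRUCTURES)}"
        ) from None
    labels, n = ndimage.label(mask, structure=structure)
    labels = labels.astype(np.int32)
    return LabeledObjects(
        labels=labels, objects=_summarize(labels, n), connectivity=connectivity
    )


def _summarize(labels: np.ndarray, n: int) -> list[ObjectInfo]:
    if n == 0:
        return []
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    slices = ndimage.find_objects(labels, max_label=n)
    edge_ids = _edge_label_ids(labels)
    return [
        ObjectInfo(
            id=i,
            n_voxels=int(counts[i]),
            bbox=slices[i - 1],
            touches_edge=i in edge_ids,
        )
        for i in range(1, n + 1)
    ]


def _edge_label_ids(labels: np.ndarray) -> set[int]:
    faces = []
    for axis in range(3):
        if labels.shape[axis] == 0:
            continue
        faces.append(np.take(labels, 0, axis=axis))
        faces.append(np.take(labels, -1, axis=axis))
    ids: set[int] = set()
    for f in faces:
        ids.update(np.unique(f).tolist())
    ids.discard(0)
    return ids


def _rebuild(objects: LabeledObjects, keep_ids: list[int]) -> LabeledObjects:
    """Relabel kept objects compactly, preserving raster order."""
    old = objects.labels
    lut = np.zeros(old.max() + 1 if old.size else 1, dtype=np.int32)
    for new_id, old_id in enumerate(sorted(keep_ids), start=1):
        lut[old_id] = new_id
    new_labels = lut[old]
    return LabeledObjects(
        labels=new_labels,
        objects=_summarize(new_labels, len(keep_ids)),
        connectivity=objects.connectivity,
    )


def filter_by_size(
    objects: LabeledObjects, min_vox: int, max_vox: int
) -> LabeledObjects:
    """Drop objects with voxel count outside [min_vox, max_vox] (inclusive)."""
    if not (0 < min_vox <= max_vox):
        raise ConfigurationError(f"invalid size bounds ({min_vox}, {max_vox})")
    keep = [o.id for o in objects.objects if min_vox <= o.n_voxels <= max_vox]
    return _rebuild(objects, keep)


def exclude_edge_objects(objects: LabeledObjects) -> LabeledObjects:
    """Remove objects touching any x, y or z face of the grid.

    For single-slice data (z-extent 1) every object touches both z
    faces, so z-face contact is ignored there; only lateral faces count.
    """
    labels = objects.labels
    single_slice = labels.shape[0] == 1
    if single_slice:
        # only lateral faces count for a single optical section
        faces = [labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]]
        edge_ids = set()
        for f in faces:
            edge_ids.update(np.unique(f).tolist())
        edge_ids.discard(0)
    else:
        edge_ids = _edge_label_ids(labels)
    keep = [o.id for o in objects.objects if o.id not in edge_ids]
    return _rebuild(objects, keep)


def segment_channel(
    volume: VolumeImage,
    channel: str,
    role: str,
    config: SegmentationConfig | None = None,
) -> tuple[LabeledObjects, dict[str, int]]:
    """Run binarize → label → size-filter → (edge-exclude) for one channel.

    Returns the retained objects and a stage-count dict for the report
    (labeled / size_filtered / edge_filtered object counts).
    """
    cfg = config or SegmentationConfig()
    if role not in cfg.size_bounds:
        raise ConfigurationError(f"unknown object role {role!r}")
    mask = binarize(volume, channel, config=cfg)
    labeled = label_components(mask, cfg.connectivity)
    counts = {"labeled": labeled.n_objects}
    mn, mx = cfg.size_bounds[role]
    labeled = filter_by_size(labeled, mn, mx)
    counts["size_filtered"] = labeled.n_objects
    if cfg.exclude_edges.get(role, False):
        labeled = exclude_edge_objects(labeled)
    counts["edge_filtered"] = labeled.n_objects
    return labeled, counts
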