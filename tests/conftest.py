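import numpy as np
import pytest

from nmjquant import SyntheticParams


@pytest.fixture
def noise_free_params():
    """Factory for blur-free, noise-free synthetic volumes."""

    def make(**overrides):
        base = dict(
            image_shape=(24, 128, 128),
            n_nmjs=6,
            psf_sigma_um=0.0,
            noise=(0.0, 0.0),
            seed=0,
        )
        base.update(overrides)
        return SyntheticParams(**base)

    return make


def match_objects_to_truth(objects, truth, voxel_size):
    """Map each labeled object id to the nearest truth NMJ index."""
    scale = np.asarray(voxel_size, dtype=float)
    mapping = {}
    for obj in objects.objects:
        centroid = objects.voxels(obj.id).mean(axis=0) * scale
        mapping[obj.id] = int(
            np.argmin(np.linalg.norm(truth.nmj_centers - centroid, axis=1))
        )
    return mapping


def bruteforce_min_distance(mask_a, mask_b, voxel_size):
    """All-pairs minimum border-voxel distance, independent of the package.

    Border voxels are found by explicit face-neighbor checks; the
    minimum is taken over the full pairwise distance matrix.  Overlap
    means distance zero.
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if (mask_a & mask_b).any():
        return 0.0

    def border(mask):
        out = np.zeros_like(mask)
        for axis in range(mask.ndim):
            for shift in (1, -1):
                neighbor = np.ones_like(mask)  # outside the grid counts as outside
                sl_src = [slice(None)] * mask.ndim
                sl_dst = [slice(None)] * mask.ndim
                if shift == 1:
                    sl_src[axis] = slice(1, None)
                    sl_dst[axis] = slice(None, -1)
                else:
                    sl_src[axis] = slice(None, -1)
                    sl_dst[axis] = slice(1, None)
                neighbor = np.zeros_like(mask)
                neighbor[tuple(sl_dst)] = mask[tuple(sl_src)]
                out |= mask & ~neighbor
        return out

    scale = np.asarray(voxel_size, float)
    pa = np.argwhere(border(mask_a)) * scale
    pb = np.argwhere(border(mask_b)) * scale
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def bruteforce_flood_fill(mask, connectivity):
    """Reference connected-component labeling by BFS flood fill."""
    mask = np.asarray(mask, bool)
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in np.argwhere(mask):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not labels[nz, ny, nx]
                ):
                    labels[nz, ny, nx] = current
                    stack.append((nz, ny, nx))
    return labels, current
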