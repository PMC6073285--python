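"""Ground-truthed synthetic multichannel fluorescence images.

The generator emulates the stained structures the quantification
pipeline was designed for: plaque-like postsynapses (α-bungarotoxin,
"BGT") clustered in a synapse band, presynaptic marker plaques directly
apposed to postsynapses (VAChT-like), thin filamentous axons partly
routed past junctions (TH/neurofilament-like), and diffuse signal with
perisynaptic enrichment (receptor-like).  Geometry is laid out in
continuous micrometre coordinates first — that analytic layout is the
authoritative ground truth — and only then rasterized onto an
anisotropic voxel grid, blurred with a Gaussian point-spread stand-in,
and degraded with Poisson and Gaussian noise.

Because the truth (object coordinates, surface gaps, per-junction
positivity labels) is recorded before voxelization, every downstream
stage can be tested for parameter recovery with explicit, voxel-scale
tolerances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, PlacementError, ValidationError
from .volumes import DEFAULT_VOXEL_SIZE, VolumeImage

MARKER_MODELS = ("apposed_plaque", "filament", "diffuse_enriched", "none")

#: Fraction of junctions positive for each marker at each postnatal age.
#: P0 and adult values follow the reported developmental time-course
#: (TH rising from ~40% to ~90%, NPY from <10% to ~60%, the β2-adrenergic
#: receptor constant at 80–90% up to P30 then ~70%, VAChT between 90 and
#: 100% throughout); intermediate ages are monotone interpolations.
DEFAULT_TIMECOURSE: dict[str, dict[str, float]] = {
    "TH": {"P0": 0.40, "P7": 0.50, "P14": 0.60, "P21": 0.70, "P30": 0.80, "adult": 0.90},
    "NPY": {"P0": 0.08, "P7": 0.12, "P14": 0.25, "P21": 0.40, "P30": 0.50, "adult": 0.60},
    "B2AR": {"P0": 0.85, "P7": 0.85, "P14": 0.85, "P21": 0.85, "P30": 0.85, "adult": 0.70},
    "VAChT": {"P0": 0.95, "P7": 0.95, "P14": 0.95, "P21": 0.95, "P30": 0.95, "adult": 0.95},
}


@dataclass
class SyntheticParams:
    """Everything that defines one synthetic acquisition.

    Units are µm unless stated otherwise; intensities are on the 0–255
    grayscale.  ``apposition_gap_um`` is the (lo, hi) range the surface
    gap of a positive junction's marker object is drawn from;
    ``far_gap_um`` is the minimum surface gap guaranteed between any
    marker object and a *negative* junction.
    """

    image_shape: tuple[int, int, int] = (24, 160, 160)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_nmjs: int = 12
    nmj_radius_um: float = 3.0
    band_fraction: float = 0.2
    marker_model: str = "apposed_plaque"
    marker_name: str = "VAChT"
    apposition_gap_um: tuple[float, float] = (0.0, 0.5)
    far_gap_um: float = 5.0
    marker_radius_um: float = 1.5
    filament_radius_um: float = 0.4
    axon_density: float = 0.01  # µm of axon per µm² of section area
    positivity_fraction: float = 1.0
    psf_sigma_um: float = 0.5
    noise: tuple[float, float] = (1.0, 2.0)  # (poisson_scale, gaussian_sd)
    # rendering intensities
    plaque_intensity: int = 200
    marker_intensity: int = 200
    filament_intensity: int = 120
    enriched_intensity: int = 120
    diffuse_background: int = 10
    fiber_background: int = 40
    negative_floor: int = 2
    shell_thickness_um: float = 1.0
    min_separation_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_model not in MARKER_MODELS:
            raise ConfigurationError(
                f"marker_model must be one of {MARKER_MODELS}"
            )
        if not (0.0 <= self.positivity_fraction <= 1.0):
            raise ValidationError("positivity_fraction must be in [0, 1]")
        lo, hi = self.apposition_gap_um
        if lo < 0 or hi < lo:
            raise ValidationError("apposition_gap_um must be 0 <= lo <= hi")
        if self.n_nmjs < 1:
            raise ValidationError("n_nmjs must be >= 1")
        for level in (
            self.plaque_intensity,
            self.marker_intensity,
            self.filament_intensity,
            self.enriched_intensity,
            self.diffuse_background,
            self.fiber_background,
            self.negative_floor,
        ):
            if not (0 <= level <= 255):
                raise ValidationError("intensity levels must be within 0-255")

    @property
    def is_2d(self) -> bool:
        return self.image_shape[0] == 1

    @property
    def extent_um(self) -> np.ndarray:
        """Physical span of voxel centers along (z, y, x)."""
        return (np.asarray(self.image_shape) - 1) * np.asarray(self.voxel_size)


@dataclass
class SyntheticGroundTruth:
    """Analytic layout of one synthetic acquisition.

    Coordinates are (z, y, x) in µm on the same lattice the voxel
    centers occupy (voxel (k, j, i) sits at (k·dz, j·dy, i·dx)).
    ``true_gap_um[i]`` is the surface gap from junction i to its
    nearest marker object, computed from the continuous geometry
    (``inf`` when no marker object exists).
    """

    params: SyntheticParams
    nmj_centers: np.ndarray  # (n, 3) µm
    positive: np.ndarray  # (n,) bool
    marker_spheres: list[tuple[np.ndarray, float]] = field(default_factory=list)
    segments: list[tuple[np.ndarray, np.ndarray, float]] = field(default_factory=list)
    true_gap_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    _masks: dict | None = field(default=None, repr=False)

    @property
    def n_nmjs(self) -> int:
        return len(self.nmj_centers)

    def masks(self) -> dict[str, np.ndarray]:
        """Per-channel boolean object masks on the voxel grid (cached)."""
        if self._masks is None:
            self._masks = rasterize_masks(self)
        return self._masks


# ---------------------------------------------------------------------------
# geometry


def _unit_vector(rng: np.random.Generator, planar: bool) -> np.ndarray:
    if planar:
        phi = rng.uniform(0.0, 2.0 * math.pi)
        return np.array([0.0, math.sin(phi), math.cos(phi)])
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-9:
            return v / n


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    v = b - a
    vv = float(v @ v)
    t = 0.0 if vv == 0 else float(np.clip((p - a) @ v / vv, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * v)))


def _place_nmj_centers(params: SyntheticParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping plaque centers inside the band."""
    ext = params.extent_um
    r = params.nmj_radius_um
    margin = r + max(2.0 * params.psf_sigma_um, 1.0)
    lo = np.array([0.0 if params.is_2d else margin, margin, margin])
    hi = np.array([0.0 if params.is_2d else ext[0] - margin, ext[1] - margin, ext[2] - margin])
    band_half = 0.5 * params.band_fraction * ext[1]
    lo[1] = max(lo[1], 0.5 * ext[1] - band_half)
    hi[1] = min(hi[1], 0.5 * ext[1] + band_half)
    if np.any(hi < lo):
        raise PlacementError(
            f"image {params.image_shape} too small for plaques of radius {r} µm"
        )
    min_dist = 2.0 * r + params.min_separation_um
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 1000 * params.n_nmjs
    while len(centers) < params.n_nmjs:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {params.n_nmjs} non-overlapping plaques "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - o) >= min_dist for o in centers):
            centers.append(c)
    return np.asarray(centers)


def _positive_labels(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Deterministic round-half-up count, seeded shuffle of which ones."""
    k = int(math.floor(fraction * n + 0.5))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:k]] = True
    return labels


def _marker_gap_to(
    center: np.ndarray, radius: float, nmj_center: np.ndarray, nmj_radius: float
) -> float:
    return max(
        0.0, float(np.linalg.norm(center - nmj_center)) - radius - nmj_radius
    )


def _place_apposed_markers(
    params: SyntheticParams,
    centers: np.ndarray,
    positive: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, float]]:
    ext = params.extent_um
    r, rm = params.nmj_radius_um, params.marker_radius_um
    margin_m = rm + 0.5
    lo = np.array([0.0 if params.is_2d else margin_m] + [margin_m] * 2)
    hi = ext - margin_m
    if params.is_2d:
        lo[0] = hi[0] = 0.0
    negatives = centers[~positive]
    spheres: list[tuple[np.ndarray, float]] = []
    for i in np.flatnonzero(positive):
        gap = rng.uniform(*params.apposition_gap_um)
        offset = r + gap + rm
        placed = False
        for _ in range(500):
            cm = centers[i] + offset * _unit_vector(rng, params.is_2d)
            if np.any(cm < lo) or np.any(cm > hi):
                continue
            if any(
                _marker_gap_to(cm, rm, cn, r) < params.far_gap_um for cn in negatives
            ):
                continue
            spheres.append((cm, rm))
            placed = True
            break
        if not placed:
            raise PlacementError(
                "could not appose a marker plaque without violating the "
                "far-gap guarantee for negative junctions"
            )
    return spheres


def _segment_gap_to(
    a: np.ndarray, b: np.ndarray, radius: float, nmj_center: np.ndarray, nmj_radius: float
) -> float:
    return max(
        0.0, _point_segment_distance(nmj_center, a, b) - radius - nmj_radius
    )


def _place_filaments(
    params: SyntheticParams,
    centers: np.ndarray,
    positive: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Background axons along x plus one branch routed past each positive."""
    ext = params.extent_um
    r, rf = params.nmj_radius_um, params.filament_radius_um
    negatives = centers[~positive]
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []

    def clear_of_negatives(a: np.ndarray, b: np.ndarray) -> bool:
        return all(
            _segment_gap_to(a, b, rf, cn, r) >= params.far_gap_um for cn in negatives
        )

    # Vessel-aligned background meshwork: polylines running along x with
    # a jittering (z, y) course, total length set by axon_density.
    area = ext[1] * ext[2]
    n_axons = max(0, round(params.axon_density * area / max(ext[2], 1.0)))
    step = 20.0
    for _ in range(n_axons):
        for _ in range(50):  # resample whole axon if it crowds a negative
            z0 = 0.0 if params.is_2d else rng.uniform(0, ext[0])
            y0 = rng.uniform(0, ext[1])
            pts = [np.array([z0, y0, 0.0])]
            x = 0.0
            while x < ext[2]:
                x = min(x + step, ext[2])
                prev = pts[-1]
                zj = 0.0 if params.is_2d else np.clip(prev[0] + rng.normal(0, 2.0), 0, ext[0])
                yj = np.clip(prev[1] + rng.normal(0, 3.0), 0, ext[1])
                pts.append(np.array([zj, yj, x]))
            axon = [(pts[k], pts[k + 1], rf) for k in range(len(pts) - 1)]
            if all(clear_of_negatives(a, b) for a, b, _ in axon):
                segments.extend(axon)
                break

    # One branch per positive junction, closest approach = sampled gap.
    branch_len = 10.0
    for i in np.flatnonzero(positive):
        gap = rng.uniform(*params.apposition_gap_um)
        offset = r + gap + rf
        placed = False
        for _ in range(500):
            u = _unit_vector(rng, params.is_2d)
            p = centers[i] + offset * u
            v = _unit_vector(rng, params.is_2d)
            v = v - (v @ u) * u
            n = np.linalg.norm(v)
            if n < 1e-6:
                continue
            v /= n
            a, b = p - 0.5 * branch_len * v, p + 0.5 * branch_len * v
            if np.any(a < 0) or np.any(b < 0) or np.any(a > ext) or np.any(b > ext):
                a = np.clip(a, 0, ext)
                b = np.clip(b, 0, ext)
                if _segment_gap_to(a, b, rf, centers[i], r) > gap + 1e-6:
                    continue
            if not clear_of_negatives(a, b):
                continue
            segments.append((a, b, rf))
            placed = True
            break
        if not placed:
            raise PlacementError(
                "could not route an axon branch past a positive junction "
                "without violating the far-gap guarantee"
            )
    return segments


def _true_gaps(truth: SyntheticGroundTruth) -> np.ndarray:
    params = truth.params
    r = params.nmj_radius_um
    gaps = np.full(truth.n_nmjs, math.inf)
    if params.marker_model == "diffuse_enriched":
        gaps[truth.positive] = 0.0
        return gaps
    for i, c in enumerate(truth.nmj_centers):
        for cm, rm in truth.marker_spheres:
            gaps[i] = min(gaps[i], _marker_gap_to(cm, rm, c, r))
        for a, b, rf in truth.segments:
            gaps[i] = min(gaps[i], _segment_gap_to(a, b, rf, c, r))
    return gaps


def generate_geometry(params: SyntheticParams) -> SyntheticGroundTruth:
    """Lay out plaques and marker structures in continuous coordinates.

    Plaques are placed without overlap inside the synapse band; a
    deterministic fraction of them receives a marker structure whose
    surface gap is drawn uniformly from ``apposition_gap_um``, while
    every negative junction is guaranteed at least ``far_gap_um`` of
    clearance from all marker structures.  Gaps are recorded from the
    continuous geometry, before any voxelization.
    """
    rng = np.random.default_rng(params.seed)
    centers = _place_nmj_centers(params, rng)
    positive = _positive_labels(params.n_nmjs, params.positivity_fraction, rng)
    truth = SyntheticGroundTruth(
        params=params, nmj_centers=centers, positive=positive
    )
    if params.marker_model == "apposed_plaque":
        truth.marker_spheres = _place_apposed_markers(params, centers, positive, rng)
    elif params.marker_model == "filament":
        truth.segments = _place_filaments(params, centers, positive, rng)
    truth.true_gap_um = _true_gaps(truth)
    return truth


# ---------------------------------------------------------------------------
# rasterization and rendering


def _sphere_voxels(
    shape: tuple[int, int, int],
    voxel: np.ndarray,
    center: np.ndarray,
    radius: float,
    inner_radius: float | None = None,
) -> tuple[tuple[np.ndarray, ...], None] | None:
    """Indices of voxels whose centers fall inside a sphere (or shell)."""
    lo = np.maximum(0, np.ceil((center - radius) / voxel)).astype(int)
    hi = np.minimum(np.asarray(shape) - 1, np.floor((center + radius) / voxel)).astype(int)
    if np.any(hi < lo):
        return None
    zz, yy, xx = np.ogrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    d2 = (
        (zz * voxel[0] - center[0]) ** 2
        + (yy * voxel[1] - center[1]) ** 2
        + (xx * voxel[2] - center[2]) ** 2
    )
    sel = d2 <= radius**2
    if inner_radius is not None:
        sel &= d2 >= inner_radius**2
    kk, jj, ii = np.nonzero(sel)
    return (kk + lo[0], jj + lo[1], ii + lo[2]), None


def _paint_sphere(
    mask: np.ndarray,
    voxel: np.ndarray,
    center: np.ndarray,
    radius: float,
    inner_radius: float | None = None,
) -> None:
    found = _sphere_voxels(mask.shape, voxel, center, radius, inner_radius)
    if found is not None:
        mask[found[0]] = True


def _paint_segment(
    mask: np.ndarray,
    voxel: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    radius: float,
) -> None:
    lo = np.maximum(0, np.ceil((np.minimum(a, b) - radius) / voxel)).astype(int)
    hi = np.minimum(
        np.asarray(mask.shape) - 1, np.floor((np.maximum(a, b) + radius) / voxel)
    ).astype(int)
    if np.any(hi < lo):
        return
    zz = np.arange(lo[0], hi[0] + 1) * voxel[0]
    yy = np.arange(lo[1], hi[1] + 1) * voxel[1]
    xx = np.arange(lo[2], hi[2] + 1) * voxel[2]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    P = np.stack([Z, Y, X], axis=-1)
    v = b - a
    vv = float(v @ v)
    if vv == 0:
        t = np.zeros(P.shape[:-1])
    else:
        t = np.clip((P - a) @ v / vv, 0.0, 1.0)
    closest = a + t[..., None] * v
    d2 = np.sum((P - closest) ** 2, axis=-1)
    sel = d2 <= radius**2
    mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] |= sel


def rasterize_masks(truth: SyntheticGroundTruth) -> dict[str, np.ndarray]:
    """Voxelize the continuous geometry into per-channel boolean masks.

    Postsynaptic plaques are hollow shells in 3D (the marker typically
    outlines the postsynaptic plaque) and filled discs in single-slice
    sections.  The marker channel contains filled spheres, tubes, or
    enrichment discs depending on the marker model.
    """
    params = truth.params
    shape = params.image_shape
    voxel = np.asarray(params.voxel_size, dtype=float)
    r = params.nmj_radius_um

    bgt = np.zeros(shape, dtype=bool)
    inner = None if params.is_2d else max(0.0, r - params.shell_thickness_um)
    for c in truth.nmj_centers:
        _paint_sphere(bgt, voxel, c, r, inner_radius=inner)

    marker = np.zeros(shape, dtype=bool)
    if params.marker_model == "apposed_plaque":
        for cm, rm in truth.marker_spheres:
            _paint_sphere(marker, voxel, cm, rm)
    elif params.marker_model == "filament":
        for a, b, rf in truth.segments:
            _paint_segment(marker, voxel, a, b, rf)
    elif params.marker_model == "diffuse_enriched":
        for c in truth.nmj_centers[truth.positive]:
            _paint_sphere(marker, voxel, c, r)
    return {"BGT": bgt, params.marker_name: marker}


def render_volume(
    truth: SyntheticGroundTruth, params: SyntheticParams | None = None
) -> VolumeImage:
    """Rasterize, blur, and add noise — the forward imaging model.

    Structure voxels are set to their configured intensities on top of
    the channel background, a Gaussian blur of ``psf_sigma_um``
    (converted per axis to voxel units, so anisotropy is respected)
    stands in for the point-spread function, then Poisson noise scaled
    by ``poisson_scale`` and additive Gaussian noise of the configured
    SD are applied and the result is clipped to 0–255.  With zero blur
    and zero noise, voxels at structure centers equal the configured
    intensities exactly.
    """
    from scipy import ndimage

    params = params or truth.params
    if params.image_shape != truth.params.image_shape:
        raise ValidationError("render shape differs from the truth's grid")
    masks = truth.masks()
    voxel = np.asarray(params.voxel_size, dtype=float)

    bgt = np.full(params.image_shape, float(params.diffuse_background))
    bgt[masks["BGT"]] = float(params.plaque_intensity)

    model = params.marker_model
    if model == "none":
        mk_background = float(params.negative_floor)
        mk_level = 0.0
    elif model == "diffuse_enriched":
        mk_background = float(params.fiber_background)
        mk_level = float(params.enriched_intensity)
    elif model == "filament":
        mk_background = float(params.diffuse_background)
        mk_level = float(params.filament_intensity)
    else:
        mk_background = float(params.diffuse_background)
        mk_level = float(params.marker_intensity)
    mk = np.full(params.image_shape, mk_background)
    mk[masks[params.marker_name]] = mk_level

    rng = np.random.default_rng(params.seed + 1)
    channels = []
    for grid in (bgt, mk):
        if params.psf_sigma_um > 0:
            sigma = params.psf_sigma_um / voxel
            if params.is_2d:
                sigma[0] = 0.0
            grid = ndimage.gaussian_filter(grid, sigma=sigma)
        p_scale, g_sd = params.noise
        if p_scale > 0:
            grid = rng.poisson(np.clip(grid, 0, None) * p_scale) / p_scale
        if g_sd > 0:
            grid = grid + rng.normal(0.0, g_sd, size=grid.shape)
        channels.append(np.clip(np.rint(grid), 0, 255).astype(np.uint8))

    data = np.stack(channels, axis=-1)
    return VolumeImage(
        data=data,
        voxel_size=params.voxel_size,
        channel_names=["BGT", params.marker_name],
    )


def simulate(params: SyntheticParams) -> tuple[VolumeImage, SyntheticGroundTruth]:
    """Convenience: geometry plus rendered volume in one call."""
    truth = generate_geometry(params)
    return render_volume(truth, params), truth


# ---------------------------------------------------------------------------
# developmental time-course


def section_params(**overrides) -> SyntheticParams:
    """Defaults for a 2D cross-section accumulation study."""
    base = dict(
        image_shape=(1, 256, 256),
        n_nmjs=30,
        marker_model="diffuse_enriched",
        psf_sigma_um=0.5,
    )
    base.update(overrides)
    return SyntheticParams(**base)


def generate_timecourse(
    ages: list[str],
    marker: str,
    seed: int = 0,
    base_params: SyntheticParams | None = None,
) -> list[tuple[VolumeImage, SyntheticGroundTruth]]:
    """One rendered cross-section per age at the configured positivity.

    The per-(marker, age) positive fractions come from
    :data:`DEFAULT_TIMECOURSE`; an unknown marker or age raises a
    configuration error.  Each age gets an independent seed derived
    from ``seed``.
    """
    try:
        table = DEFAULT_TIMECOURSE[marker]
    except KeyError:
        raise ConfigurationError(
            f"no time-course defaults for marker {marker!r}; "
            f"known markers: {sorted(DEFAULT_TIMECOURSE)}"
        ) from None
    out = []
    for k, age in enumerate(ages):
        try:
            fraction = table[age]
        except KeyError:
            raise ConfigurationError(
                f"no default positivity for ({marker!r}, {age!r}); "
                f"known ages: {list(table)}"
            ) from None
        params = base_params or section_params(marker_name=marker)
        params = replace(
            params,
            marker_name=marker,
            positivity_fraction=fraction,
            seed=seed + k,
        )
        truth = generate_geometry(params)
        out.append((render_volume(truth, params), truth))
    return out
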