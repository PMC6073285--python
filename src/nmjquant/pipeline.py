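"""End-to-end study runners: simulate → segment → quantify → report.

Two study modes mirror the two quantification procedures:

* a **proximity study** segments the postsynapse and marker channels of
  a 3D volume, measures each retained postsynaptic object's edge-to-edge
  distance to the nearest marker object, and summarizes the fraction of
  junctions closer than the 2 µm cutoff plus the distance distribution;
* a **timecourse study** renders replicate 2D cross-sections per
  developmental age at the configured marker positivity and reports the
  recovered percentage of immunopositive junctions as mean ± SEM.

All randomness flows from one integer seed through the synthetic
generator; the analysis stages are deterministic by construction, so a
fixed config + seed reproduces results byte for byte.  Every exclusion
(size filter, edge contact, undefined fiber region, infinite distance)
is counted in the provenance record rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accumulation import AccumulationConfig, accumulation_study
from .errors import ConfigurationError, ValidationError
from .proximity import (
    DistanceDistribution,
    DistanceRecord,
    ProximityConfig,
    distance_distribution,
    nearest_marker,
    proximity_fraction,
)
from .segmentation import SegmentationConfig, segment_channel
from .synthetic import (
    DEFAULT_TIMECOURSE,
    SyntheticGroundTruth,
    SyntheticParams,
    generate_geometry,
    render_volume,
    section_params,
)
from .volumes import ResultsTable, VolumeImage, write_results

STUDY_MODES = ("accumulation", "proximity", "timecourse")


@dataclass
class PipelineConfig:
    """Composition of all stage configurations for one study."""

    mode: str = "proximity"
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    accumulation: AccumulationConfig = field(default_factory=AccumulationConfig)
    postsynapse_channel: str = "BGT"
    marker_channel: str | None = None  # defaults to the synthetic marker name
    ages: list[str] = field(default_factory=lambda: list(DEFAULT_TIMECOURSE["TH"]))
    n_replicates: int = 3
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in STUDY_MODES:
            raise ConfigurationError(f"mode must be one of {STUDY_MODES}")

    @property
    def effective_marker_channel(self) -> str:
        return self.marker_channel or self.synthetic.marker_name


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_")
        }
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration (thresholds, sizes, seed)."""
    canonical = json.dumps(_to_plain(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def log_provenance(cfg: PipelineConfig, stage_counts: dict | None = None) -> dict:
    """Reproducibility record written alongside every results file."""
    return {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "software_version": __version__,
        "stage_counts": dict(stage_counts or {}),
    }


@dataclass
class ProximityStudyResult:
    table: ResultsTable
    records: list[DistanceRecord]
    fraction_below_threshold: float
    distribution: DistanceDistribution
    stage_counts: dict[str, int]
    truth: SyntheticGroundTruth | None = None


def run_proximity_study(
    cfg: PipelineConfig, volume: VolumeImage | None = None
) -> ProximityStudyResult:
    """Segment both channels of a volume and measure nearest distances.

    Without an input volume, one is simulated from ``cfg.synthetic``
    (with the synthetic seed slaved to the pipeline seed).  Aborts with
    a diagnostic if segmentation retains no postsynaptic object.
    """
    truth = None
    if volume is None:
        params = replace(cfg.synthetic, seed=cfg.seed)
        truth = generate_geometry(params)
        volume = render_volume(truth, params)

    seg = cfg.segmentation
    marker_name = cfg.effective_marker_channel
    nmj_objects, nmj_counts = segment_channel(
        volume, cfg.postsynapse_channel, "postsynapse", seg
    )
    marker_objects, marker_counts = segment_channel(volume, marker_name, "marker", seg)
    counts = {f"bgt_{k}": v for k, v in nmj_counts.items()}
    counts.update({f"marker_{k}": v for k, v in marker_counts.items()})

    if nmj_objects.n_objects == 0:
        raise ValidationError(
            "segmentation retained zero postsynaptic objects "
            f"(stage counts: {counts}); check intensity/size bounds"
        )
    records = nearest_marker(nmj_objects, marker_objects, volume.voxel_size)
    if marker_objects.n_objects == 0:
        counts["warning_no_marker_objects"] = 1
    fraction = proximity_fraction(records, cfg.proximity.threshold_um)
    dist = distance_distribution(records, cfg.proximity.bin_width_um)
    counts["infinite_distances"] = dist.overflow

    rows = [
        {
            "nmj_id": r.nmj_id,
            "nearest_marker_id": r.nearest_marker_id,
            "distance_um": r.distance_um,
        }
        for r in records
    ]
    table = ResultsTable(
        records=pd.DataFrame(rows),
        metadata={
            **log_provenance(cfg, counts),
            "marker": marker_name,
            "threshold_um": cfg.proximity.threshold_um,
            "fraction_below_threshold": fraction,
        },
    )
    return ProximityStudyResult(
        table=table,
        records=records,
        fraction_below_threshold=fraction,
        distribution=dist,
        stage_counts=counts,
        truth=truth,
    )


@dataclass
class TimecourseStudyResult:
    summary: pd.DataFrame  # one row per age: mean/SEM of % positive
    per_section: ResultsTable


def run_timecourse_study(
    cfg: PipelineConfig, marker: str | None = None
) -> TimecourseStudyResult:
    """Replicate accumulation studies across developmental ages.

    For each age, ``n_replicates`` independent cross-sections are
    rendered at the marker's configured positive fraction and analyzed;
    the summary holds mean ± SEM of the recovered percentage.
    """
    marker = marker or cfg.effective_marker_channel
    try:
        fractions = DEFAULT_TIMECOURSE[marker]
    except KeyError:
        raise ConfigurationError(
            f"no time-course defaults for marker {marker!r}"
        ) from None

    base = cfg.synthetic
    if not base.is_2d:
        base = section_params(marker_name=marker, n_nmjs=base.n_nmjs)

    summary_rows = []
    section_tables = []
    for a, age in enumerate(cfg.ages):
        if age not in fractions:
            raise ConfigurationError(f"no default positivity for ({marker}, {age})")
        percents = []
        for rep in range(cfg.n_replicates):
            params = replace(
                base,
                marker_name=marker,
                marker_model="diffuse_enriched",
                positivity_fraction=fractions[age],
                seed=cfg.seed + 1000 * a + rep,
            )
            truth = generate_geometry(params)
            volume = render_volume(truth, params)
            result = accumulation_study(
                volume, marker, cfg.accumulation, cfg.postsynapse_channel
            )
            percents.append(result.percent_positive)
            df = result.table.records.copy()
            df.insert(0, "age", age)
            df.insert(1, "replicate", rep)
            section_tables.append(df)
        arr = np.asarray(percents, dtype=float)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
        summary_rows.append(
            {
                "age": age,
                "marker": marker,
                "true_fraction": fractions[age],
                "mean_percent_positive": float(arr.mean()),
                "sem_percent_positive": sem,
                "n_replicates": len(arr),
            }
        )

    per_section = pd.concat(section_tables, ignore_index=True)
    table = ResultsTable(
        records=per_section.drop(columns=["age", "replicate"]),
        metadata=log_provenance(cfg, {"n_sections": len(section_tables)}),
    )
    return TimecourseStudyResult(
        summary=pd.DataFrame(summary_rows), per_section=table
    )


# ---------------------------------------------------------------------------
# result export


def save_distance_outputs(
    result: ProximityStudyResult, out_dir: str | Path, stem: str = "proximity"
) -> dict[str, Path]:
    """Write per-NMJ CSV, histogram CSV, provenance JSON, and a plot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["records"] = write_results(result.table, out_dir / f"{stem}_records.csv")

    dist = result.distribution
    hist = pd.DataFrame(
        {
            "bin_lo_um": dist.bin_edges[:-1],
            "bin_hi_um": dist.bin_edges[1:],
            "count": dist.counts,
        }
    )
    paths["histogram"] = out_dir / f"{stem}_histogram.csv"
    hist.to_csv(paths["histogram"], index=False, lineterminator="\n")

    paths["provenance"] = out_dir / f"{stem}_provenance.json"
    paths["provenance"].write_text(
        json.dumps(_to_plain(result.table.metadata), indent=1, sort_keys=True) + "\n"
    )

    paths["plot"] = plot_distance_distribution(dist, out_dir / f"{stem}_distribution.png")
    return paths


def plot_distance_distribution(
    dist: DistanceDistribution, path: str | Path
) -> Path:
    """Distance histogram with the empirical CDF overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
    width = float(np.diff(dist.bin_edges).mean()) if len(dist.bin_edges) > 1 else 0.5
    ax.bar(centers, dist.counts, width=0.9 * width, color="#4878a8")
    ax.set_xlabel("edge-to-edge distance to nearest marker (µm)")
    ax.set_ylabel("NMJ count")
    ax2 = ax.twinx()
    xs = np.linspace(0, max(float(dist.bin_edges[-1]), 2.0), 200)
    ax2.plot(xs, [dist.cdf(x) for x in xs], color="#a84848")
    ax2.set_ylabel("cumulative fraction")
    ax2.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


# ---------------------------------------------------------------------------
# configuration files


def _update_dataclass(instance, data: dict):
    fields = {f.name for f in dataclasses.fields(instance)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        current = getattr(instance, key)
        if isinstance(current, tuple) and isinstance(value, (list, tuple)):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            merged.update(
                {k: tuple(v) if isinstance(v, list) else v for k, v in value.items()}
            )
            value = merged
        coerced[key] = value
    return replace(instance, **coerced)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file.

    The file mirrors the dataclass structure, e.g.::

        mode: proximity
        seed: 7
        synthetic: {n_nmjs: 50, positivity_fraction: 1.0}
        segmentation: {connectivity: 26}
        proximity: {threshold_um: 2.0}
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    blocks = {
        "synthetic": SyntheticParams(),
        "segmentation": SegmentationConfig(),
        "proximity": ProximityConfig(),
        "accumulation": AccumulationConfig(),
    }
    top = {}
    for key, value in raw.items():
        if key in blocks:
            top[key] = _update_dataclass(blocks[key], value or {})
        else:
            top[key] = value
    return _update_dataclass(cfg, top)
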