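# nmjquant

Quantification of neuromuscular-junction (NMJ) innervation in
multichannel fluorescence microscopy.

Skeletal-muscle postsynapses are labeled with fluorescent
α-bungarotoxin ("BGT"), which binds acetylcholine receptors; a second
channel carries an immunofluorescence marker — a presynaptic protein
such as VAChT, a sympathetic-axon marker such as tyrosine hydroxylase
(TH) or neuropeptide Y, the axonal cytoskeleton (neurofilament L), or a
postsynaptic receptor (β2-adrenergic receptor). Two questions recur in
this setting, and `nmjquant` implements a tested, reproducible pipeline
for each:

1. **Accumulation analysis (2D sections).** Is the marker *enriched* at
   a junction? Each NMJ region of interest is outlined from the
   median-filtered BGT channel (threshold 30–255 on the 0–255
   grayscale, 8-connected components), paired with a surrounding
   muscle-fiber reference region, and called immunopositive iff

   > mean_NMJ  >  mean_fiber + sd_fiber   (strict),

   where both statistics are measured on the marker channel. Percent
   positive junctions per section, replicated across sections and
   developmental ages, gives the innervation time-course.

2. **Proximity analysis (3D volumes).** How *close* is the nearest
   marker structure to each postsynapse? Both channels are binarized at
   inclusive per-marker intensity bounds (BGT 20–255, TH 6–255,
   neurofilament L 22–255, VAChT 20–255), labeled as 3D connected
   components, size-filtered (postsynapses 50–20,000,000 voxels,
   markers 3–2,000,000,000), and BGT objects touching any volume face
   are excluded. For every retained postsynapse the pipeline reports
   the **edge-to-edge distance** to the nearest marker object — the
   minimum anisotropy-weighted Euclidean distance between border-voxel
   centers, in µm — and summarizes the fraction of junctions closer
   than 2 µm plus the full distance distribution.

Because no raw microscopy accompanies the original studies, the package
ships a **synthetic generator** that lays out plaque-like postsynapses
in a synapse band, apposed marker plaques, filamentous axons, or
diffuse perisynaptic enrichment in continuous coordinates (the analytic
ground truth), then rasterizes onto an anisotropic voxel grid
(0.785 × 0.785 × 1 µm by default), applies Gaussian blur and
Poisson + Gaussian noise. Every stage of the pipeline is validated
against this ground truth.

## Worked example

```python
from nmjquant import PipelineConfig, SyntheticParams, run_proximity_study

cfg = PipelineConfig(
    synthetic=SyntheticParams(
        image_shape=(32, 256, 256), n_nmjs=40,
        positivity_fraction=1.0, apposition_gap_um=(0.0, 0.5), seed=3,
    ),
    seed=3,
)
result = run_proximity_study(cfg)
print(result.stage_counts)
print(result.fraction_below_threshold)
```

prints

```
{'bgt_labeled': 15584, 'bgt_size_filtered': 40, 'bgt_edge_filtered': 40,
 'marker_labeled': 15732, 'marker_size_filtered': 241,
 'marker_edge_filtered': 241, 'infinite_distances': 0}
1.0
```

Reading: thresholding the noisy BGT channel yields 15,584 raw
components, of which exactly the 40 simulated postsynaptic plaques
survive the 50-voxel size filter, and none touches a volume face. In
the marker channel the 3-voxel minimum admits some noise specks besides
the 40 true presynaptic plaques, but since every postsynapse has a
directly apposed marker (surface gap ≤ 0.5 µm), all 40 junctions lie
closer than 2 µm to a marker object: the reported fraction is 1.0, the
expected positive-control behavior for a presynaptic marker like VAChT.

The `examples/` directory holds one short script per capability
(simulation, accumulation, proximity, time-course); each prints its
numbers with a note on what they mean. A thin CLI mirrors the same
studies from the shell:

```sh
nmjquant simulate --out vol.ome.tif --seed 7
nmjquant proximity --out-dir results/ --seed 7
nmjquant timecourse --out tc.csv --marker TH --seed 1
```

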