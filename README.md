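# subcelldist

Object-based 3D colocalization analysis for fluorescence microscopy.

Biologists often need to know not whether two labels' pixel intensities
correlate, but *how far* discrete structures are from one another: is an
mRNA enriched at centrosomes, does it hug the nuclear surface, do two
organelles make contact?  `subcelldist` answers such questions from
single-channel z-stack TIFFs.  It segments each labeled structure in 3D,
extracts every object's integrated intensity, volume, centroid, and
surface voxels, measures for each Structure-1 object the distance in
micrometers to the nearest Structure-2 surface (overlapping objects are
0 µm by definition), optionally converts single-molecule fluorescence
(e.g. smFISH) into estimated molecules per object, and summarizes each
image as a cumulative distance-distribution profile.

## Method

For objects ``a`` (Structure 1) and ``b`` (Structure 2) with surface
voxel sets ``S(a)``, ``S(b)`` on a grid with voxel size ``(dz, dy, dx)``
µm, the surface distance is

    d(a, b) = min over p in S(a), q in S(b) of || (p − q) ⊙ (dz, dy, dx) ||₂

and ``d(a, b) = 0`` whenever the objects share a voxel.  Computing this
for every pair is expensive, so each object's targets are first ranked by
centroid distance and the exact surface minimum is evaluated only
against the closest *k* candidates (default *k* = 3; the prefilter can
only overestimate, never underestimate, and an exhaustive mode is one
flag away).

Single-molecule normalization estimates molecules per object as

    n̂ = I_object / Ī₁,   Ī₁ = mean{ I_object : 20 ≤ volume ≤ 100 voxels }

where ``I`` is integrated intensity in the original image and the volume
window selects objects sized like one diffraction-limited molecule
(determine the window empirically for your optics).  Objects with
``n̂ > 4`` are flagged as higher-order granules.

The per-image cumulative profile evaluates, on a fixed grid (default
step 0.05 µm), the percentage of Structure-1 weight — molecules,
intensity, or object count — located within each distance of
Structure 2.

## Worked example

The package ships a fully synthetic two-condition tutorial — a
"localizing" transcript whose spots crowd organelle surfaces versus a
"dispersed" one — with exact ground truth:

```python
from subcelldist import run_tutorial
paths = run_tutorial("tutorial_out", seed=11)
print(open(paths["overlap_summary"]).read())
```

prints

```
image_id,condition,percent_overlapping,percent_in_granules_overlapping
localizing_1,localizing,61.4276,51.1677
localizing_2,localizing,60.3601,35.9508
dispersed_1,dispersed,0.0000,0.0000
dispersed_2,dispersed,15.1641,9.9410
```

i.e. ~60% of the localizing transcript's molecules sit at 0 µm from an
organelle (much of it in >4-molecule granules), versus a low and noisy
baseline for the dispersed transcript.  `profiles.csv` holds the
per-image cumulative curves (distance vs. cumulative percent) used for
mean ± s.d. condition plots.

## Analyzing your own images

Write a YAML config mapping each field of view to its single-channel
TIFFs and voxel size (µm, required — distances are physical):

```yaml
store: results/store.db
images:
  embryo_01:
    voxel_size: [0.3, 0.1, 0.1]   # dz, dy, dx
    condition: control
    structures:
      rna: images/embryo_01_rna.tif
      centrosome: images/embryo_01_cnn.tif
structures:
  rna: {segmentation: {}}          # spot defaults
  centrosome:
    segmentation: {method: intensity, spot_filter_cutoff: 0.5,
                   apply_watershed: false, min_volume_voxels: 30}
pairs:
  - {structure_1: rna, structure_2: centrosome, n_candidates: 3}
calibration: {structures: [rna]}
profile: {step_um: 0.05, max_distance_um: 5.0, weight_mode: molecules}
```

then run the stages (each idempotent, so segmentation can be iterated
without re-measuring distances):

```sh
subcelldist run-all --config config.yaml
subcelldist export-csv --store results/store.db --table profiles --out profiles.csv
```

Results live in an embedded SQLite store (objects per structure,
distances, molecule estimates, profiles) with CSV export and SQL-dump
backup.  Pre-segmented masks from any external tool can be dropped in
place of the built-in segmenter.

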