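# Methods

## Scope and model

`subcelldist` implements object-based colocalization: instead of
correlating pixel intensities, it segments each fluorescence channel
into discrete 3D objects and measures physical distances between their
surfaces.  The quantities it produces per image are (i) a feature table
per structure (integrated intensity in the original image, volume in
voxels, unweighted centroid, surface-voxel coordinates), (ii) one
nearest-surface distance record per Structure-1 object, (iii) optional
molecules-per-object estimates for single-molecule data, and (iv) a
cumulative distance-distribution profile.

All coordinates are held internally in `(z, y, x)` order with the plane
index first; exported tables list `x, y, z` columns, the convention most
feature tables are read in.  Distances are always computed in
micrometers: each axis is scaled by its voxel dimension before the
Euclidean norm, in the centroid prefilter as well as in the surface
refinement, because candidate ranking done in voxel units on an
anisotropic grid would be wrong.

## Segmentation

The spot chain is: percentile normalization → anisotropic Gaussian
smoothing → 3D Laplacian-of-Gaussian (LoG) blob response → two-threshold
classification → optional marker-controlled watershed → minimum-volume
filter.  Every step is deterministic; identical input and parameters
give a bit-identical mask.

The two-threshold rule is the part worth explaining.  A voxel set
becomes an object only if it contains a *seed* — a voxel whose
scale-normalized LoG response exceeds `spot_filter_cutoff` — and the
object then consists of the connected region of voxels whose smoothed
normalized *intensity* exceeds `spot_filter_extend_cutoff`.  Seeding on
the LoG response makes detection robust (white noise is uncorrelated,
spots are not); extending on intensity makes the captured fraction of
each spot's integrated intensity nearly independent of its brightness
class, because spot profiles are self-similar: peak voxel intensity is
roughly constant across multiplicity while width grows, so an intensity
isophote cuts every spot at the same relative level.  Extending on the
LoG response instead systematically truncates wide granules (the filter
scale matches single molecules) and was rejected for that reason.

Defaults (tuned once on the synthetic fixtures, where ground truth is
known, and documented here; they are starting points for real data, not
universal constants):

| parameter | default | meaning |
|---|---|---|
| `normalization_percentiles` | (0, 99.99) | clip window; the high end anchors scaling to bright spot cores, not the single noisiest voxel |
| `smoothing_sigma` | (0.75, 1.0, 1.0) voxels | pre-filter smoothing, z smaller because z-sampling is coarser |
| `spot_filter_scale` | (0.9, 1.2, 1.2) voxels | LoG sigma ≈ single-molecule spot sigma |
| `spot_filter_cutoff` | 0.12 | seed threshold; the measured null (noise-only) response stays below ~0.06 at peak SNR 5 while spot centers exceed ~0.20 |
| `spot_filter_extend_cutoff` | 0.10 | intensity isophote; chosen where the upward bias from rim noise and the downward bias from truncating the spot tail cancel |
| `min_volume_voxels` | 20 | matches the lower edge of the single-molecule volume window |
| `watershed_min_peak_distance` | 3 voxels | marker separation; smaller values oversplit noisy single spots |

A second method, `method="intensity"`, thresholds the smoothed
normalized intensity directly; it is intended for organelle-scale
structures with uniformly bright interiors, where a blob filter would
only outline the rim.  Users may bypass segmentation entirely and
supply label maps from any external tool.

## Object extraction

Connected components use face (6-neighbor) adjacency by default — the
stricter and more reproducible choice; full 26-adjacency is an option.
A surface voxel is a member voxel with at least one face neighbor
outside its object, image borders counting as outside.  Centroids are
unweighted means of member voxel indices; an intensity-weighted centroid
is stored alongside but not used by default, since the weighting choice
is not canonical.  Integrated intensity is summed over member voxels of
the *original* image, never the normalized copy.  The full member-voxel
set of each object is kept (compressed) because the 0 µm overlap rule
needs exact voxel-set intersection — surface sets alone miss the case of
one object wholly inside another, where the two surfaces never meet.

## Distance measurement

For each Structure-1 object, targets are ranked by physical centroid
distance (ties broken by ascending target id, which keeps results
identical under any worker count) and the exact surface-to-surface
minimum is computed against the top `n_candidates` (default 3) via a
k-d tree over scaled surface coordinates.  The k-d tree is an internal
accelerator only; it returns exactly the brute-force minimum.  Overlap
is tested first by voxel-set intersection and short-circuits to exactly
0 µm.  The heuristic can only overestimate the true nearest distance —
pruning can only *miss* smaller values — and setting `n_candidates` to
the target count or `exhaustive=True` recovers the exact answer; for
densely packed or strongly non-convex targets (a crescent whose centroid
is far from its surface) that is the recommended setting.

Distances are measured between surface voxel *centers*; no sub-voxel
interpolation is attempted, so the discretization error is bounded by
one voxel diagonal (0.33 µm at the default 0.3/0.1/0.1 µm voxels).

## Single-molecule normalization and granules

The mean integrated intensity of objects whose volume lies in the
calibration window — default 20 to 100 voxels, both bounds inclusive —
defines the intensity of one molecule.  Estimates are the plain ratio,
deliberately not rounded to integers: downstream profiles weight by the
continuous estimate.  An object is a granule iff its estimate strictly
exceeds 4 molecules; the strict inequality at exactly 4.0 is contract,
not accident.

## Profiles and fractions

`cumulative_profile` evaluates a weighted ECDF on the grid
`0, step, 2·step, …, max` (default step 0.05 µm, max 5 µm): at each grid
distance, 100 × (weight of objects at distance ≤ d) / (total weight over
*all* measured objects).  The weight mode — `molecules`, `intensity`, or
`object_count` — must be stated in any report, because the three
disagree whenever brightness varies between objects; `molecules` is the
default when a calibration exists.  `fraction_by_bin` is the exact
difference of consecutive grid points, and bins plus the beyond-max
remainder sum to 100 by construction.  `fraction_overlapping` restricts
the numerator to distance = 0 (and optionally to granules) while always
keeping the full denominator.  Profiles are first-class per image;
cross-image mean ± s.d. aggregation is a separate export step, so
between-image variability stays visible.

## Storage

An embedded SQLite file holds one object table per structure plus
shared distance, measurement, profile, and run-provenance tables.
Surface and member voxel coordinates are stored as one zlib-compressed
int32 blob per object rather than one row per voxel (organelles can
have 10⁴ surface voxels).  CSV export encodes blobs as base64 and
round-trips losslessly; backup is the backend's native SQL dump.
Upserts are idempotent, and a duplicate key carrying *different*
features is an error rather than a silent overwrite.

## Synthetic scenes and what they do (not) show

The generator renders two channels with exact ground truth.  Spots are
anisotropic Gaussians truncated at 2.5 σ and renormalized so the voxel
sum is exactly n·I₀ (default σ = (0.9, 1.2, 1.2) voxels, I₀ = 600
counts); randomly generated multi-molecule spots get σ scaled by n^⅓ so
granule volume grows with content and falls outside the calibration
window, as real granules do.  Organelles are solid spheres in physical
space, so the closed-form truth distance max(0, ‖Δc‖ − r) is exact on
anisotropic grids (the spot is treated as its center point; a voxel
exactly on the radius is kept via a small tolerance).  Noise is Poisson
shot noise plus Gaussian read noise; the `snr` knob sets the
single-molecule peak SNR including shot noise, whose ceiling at I₀ = 600
is √peak ≈ 5.7, so the default scenes (SNR 5) are shot-noise-limited —
the regime single-molecule imaging actually operates in.  Random scenes
draw centers uniformly with minimum-separation rejection (0.7 µm;
surface-localized spots use 0.45 µm because crowding at organelle
surfaces is the phenomenon of interest), multiplicities 80% singletons /
20% uniform on {2..8}, and blobs disjoint and clear of stack borders.

Deliberately not emulated: a realistic PSF with Airy tails, camera gain
and offset, autofluorescence gradients, z-dependent aberrations,
out-of-focus haze.  Passing tests on these scenes therefore validate
the *measurement chain* — geometry, conservation, normalization
arithmetic, determinism — not segmentation robustness on difficult real
data, for which parameters must be re-tuned per channel and optics.

## Validation studies (problem sizes)

The studies in `subcelldist.validation`, also run by
`scripts/acceptance.py`, use: 100 random scenes (10–50 spots, 2–10
blobs) for the heuristic-vs-brute-force distance comparison; 12
sphere-pair cases on isotropic and anisotropic grids for geometry; 4
scenes of 32 spots with multiplicities 1–10 (14 singletons as the
calibration population) at peak SNR 5 for molecule recovery; 6 scenes of
30 spots at peak SNR 5 for recall/precision; and the four-image
two-condition tutorial for determinism and the golden regression.  These
sizes keep the whole battery under a minute on one CPU while leaving
each estimate's sampling error well inside the margins being asserted.

## Known limitations

- Distances are voxel-center based; structures thinner than a voxel or
  sub-voxel localization shifts are invisible.
- The heuristic prefilter assumes targets are roughly convex; for
  extreme shapes use exhaustive mode.
- Calibration assumes the 20–100-voxel window isolates true single
  molecules; aggregates small enough to fall in the window bias Ī₁
  upward.
- One object table per structure means structure names must be valid
  identifiers after sanitization.
- The watershed splits objects only where intensity maxima are separated
  by at least `watershed_min_peak_distance`; molecules closer than the
  PSF width are fundamentally unresolvable anyway.
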