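"""Seeded synthetic 3D two-structure scenes with exact ground truth.

Structure 1 emulates single-molecule fluorescence spots (e.g. smFISH):
each spot is an anisotropic Gaussian truncated at a fixed number of
sigmas and renormalized so its voxel sum is exactly ``n * I0`` — ``n``
molecules at base integrated intensity ``I0``.  Multi-molecule granules
are brighter, and (when generated randomly) proportionally larger so
they fall outside the single-molecule calibration volume window, as real
granules do.  Structure 2 emulates organelle-scale bodies (centrosomes,
nuclei) as solid spheres in *physical* space, so the analytic
ground-truth distance ``max(0, ||c_spot - c_blob||_phys - r_blob)``
(point-source convention for the spot) is exact on anisotropic grids.

Noise is optional Poisson resampling of the signal plus additive
Gaussian read noise, clipped at zero.  One RNG stream per scene, keyed
by the scene seed; no global state is touched — the same spec always
renders the same volumes.

Not emulated: a realistic optical PSF (spots here have compact support
rather than Airy tails), camera gain/offset structure, autofluorescence
gradients, and z-dependent aberrations.  Tests passing on these scenes
therefore validate the measurement chain, not segmentation robustness on
difficult real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import VoxelGrid

__all__ = [
    "Spot",
    "Blob",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "random_scene",
    "scene_label_maps",
    "sphere_voxels",
    "single_molecule_peak",
    "read_noise_for_snr",
]

DEFAULT_SHAPE = (24, 128, 128)
DEFAULT_VOXEL_SIZE = (0.3, 0.1, 0.1)  # um; spinning-disk-like anisotropy
DEFAULT_SPOT_SIGMA = (0.9, 1.2, 1.2)  # voxels; ~85-voxel support at 2.5 sigma
DEFAULT_I0 = 600.0  # integrated counts per molecule
TRUNC_SIGMA = 2.5  # spot support radius in sigmas


@dataclass
class Spot:
    center: tuple[float, float, float]  # (z, y, x), voxels
    sigma: tuple[float, float, float] = DEFAULT_SPOT_SIGMA
    molecules: int = 1
    base_intensity: float = DEFAULT_I0


@dataclass
class Blob:
    center: tuple[float, float, float]  # (z, y, x), voxels
    radius_um: float = 0.5
    intensity: float = 300.0


@dataclass
class SceneSpec:
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    rng_seed: int = 0
    spots: list[Spot] = field(default_factory=list)
    blobs: list[Blob] = field(default_factory=list)
    gaussian_sd: float = 0.0
    poisson: bool = False

    def __post_init__(self) -> None:
        for s in self.spots:
            if s.molecules < 1:
                raise ValueError("spot multiplicity must be >= 1")
            if not all(0 <= c < d for c, d in zip(s.center, self.shape)):
                raise ValueError(f"spot center {s.center} outside shape {self.shape}")
        for b in self.blobs:
            if b.radius_um <= 0:
                raise ValueError("blob radius must be positive")
            if not all(0 <= c < d for c, d in zip(b.center, self.shape)):
                raise ValueError(f"blob center {b.center} outside shape {self.shape}")


@dataclass
class GroundTruth:
    """Analytic truth for a rendered scene.

    ``spot_table`` has one row per spot: true center, multiplicity, and
    the distance to the nearest blob surface under the point-source
    convention (spot treated as its center point):
    ``max(0, ||c_spot - c_blob||_phys - r_blob)``, minimized over blobs.
    ``pairwise_um[i, j]`` gives that distance for spot i against blob j.
    """

    spot_table: pd.DataFrame
    pairwise_um: np.ndarray


def _spot_kernel(sigma: tuple[float, float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Truncated anisotropic Gaussian kernel offsets and unit-sum weights."""
    radii = [int(np.ceil(TRUNC_SIGMA * s)) for s in sigma]
    zz, yy, xx = np.meshgrid(
        *[np.arange(-r, r + 1) for r in radii], indexing="ij"
    )
    r2 = (zz / sigma[0]) ** 2 + (yy / sigma[1]) ** 2 + (xx / sigma[2]) ** 2
    inside = r2 <= TRUNC_SIGMA**2
    w = np.exp(-0.5 * r2) * inside
    w /= w.sum()
    offsets = np.stack([zz[inside], yy[inside], xx[inside]], axis=1)
    return offsets, w[inside]


def single_molecule_peak(
    sigma: tuple[float, float, float] = DEFAULT_SPOT_SIGMA,
    base_intensity: float = DEFAULT_I0,
) -> float:
    """Peak voxel intensity of a centered single-molecule spot (no noise)."""
    _, w = _spot_kernel(sigma)
    return float(base_intensity * w.max())


def read_noise_for_snr(
    snr: float,
    poisson: bool = True,
    sigma: tuple[float, float, float] = DEFAULT_SPOT_SIGMA,
    base_intensity: float = DEFAULT_I0,
) -> float:
    """Gaussian read-noise sd giving the requested single-molecule peak SNR.

    SNR is defined at the brightest voxel of a one-molecule spot as
    ``peak / sqrt(peak + sd**2)`` when shot (Poisson) noise is on, or
    ``peak / sd`` without it.  With shot noise the achievable SNR is
    capped at ``sqrt(peak)``; asking for more raises.
    """
    peak = single_molecule_peak(sigma, base_intensity)
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not poisson:
        return peak / snr
    var = (peak / snr) ** 2 - peak
    if var < 0:
        raise ValueError(
            f"peak SNR {snr} unreachable with shot noise alone "
            f"(shot-noise limit is {np.sqrt(peak):.2f})"
        )
    return float(np.sqrt(var))


def _physical_distance(a, b, voxel_size) -> float:
    s = np.asarray(voxel_size, dtype=np.float64)
    return float(np.sqrt((((np.asarray(a) - np.asarray(b)) * s) ** 2).sum()))


def sphere_voxels(center, radius_um: float, shape, voxel_size) -> np.ndarray:
    """Voxels whose center lies within ``radius_um`` of ``center`` (physical space)."""
    return _blob_voxels(Blob(center=tuple(center), radius_um=radius_um), shape, voxel_size)


def _blob_voxels(blob: Blob, shape, voxel_size) -> np.ndarray:
    """Voxels whose center lies within radius_um of the blob center (physical)."""
    s = np.asarray(voxel_size, dtype=np.float64)
    r_vox = np.ceil(blob.radius_um / s).astype(int)
    c = np.asarray(blob.center)
    lo = np.maximum(np.floor(c - r_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c + r_vox).astype(int) + 1, shape)
    zz, yy, xx = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    d2 = (((coords - c) * s) ** 2).sum(axis=1)
    # tolerance keeps boundary voxels that land exactly on the radius
    return coords[d2 <= blob.radius_um**2 + 1e-9]


def render_scene(spec: SceneSpec) -> tuple[VoxelGrid, VoxelGrid, GroundTruth]:
    """Render (structure1 spots, structure2 blobs, ground truth).

    Identical spec (including seed) always yields identical volumes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    vol1 = np.zeros(spec.shape, dtype=np.float64)
    vol2 = np.zeros(spec.shape, dtype=np.float64)

    for s in spec.spots:
        offsets, w = _spot_kernel(s.sigma)
        coords = np.round(np.asarray(s.center)).astype(int) + offsets
        if coords.min() < 0 or np.any(coords >= np.asarray(spec.shape)):
            raise ValueError(f"spot at {s.center} extends out of bounds")
        vol1[coords[:, 0], coords[:, 1], coords[:, 2]] += s.molecules * s.base_intensity * w

    for b in spec.blobs:
        vox = _blob_voxels(b, spec.shape, spec.voxel_size)
        if len(vox):
            vol2[vox[:, 0], vox[:, 1], vox[:, 2]] = b.intensity

    for vol in (vol1, vol2):
        if spec.poisson:
            vol[:] = rng.poisson(vol).astype(np.float64)
        if spec.gaussian_sd > 0:
            vol += rng.normal(0.0, spec.gaussian_sd, size=vol.shape)
        np.clip(vol, 0.0, None, out=vol)

    n_s, n_b = len(spec.spots), len(spec.blobs)
    pairwise = np.full((n_s, n_b), np.inf)
    for i, s in enumerate(spec.spots):
        for j, b in enumerate(spec.blobs):
            pairwise[i, j] = max(
                0.0, _physical_distance(s.center, b.center, spec.voxel_size) - b.radius_um
            )
    spot_table = pd.DataFrame(
        {
            "spot_id": np.arange(1, n_s + 1),
            "z": [s.center[0] for s in spec.spots],
            "y": [s.center[1] for s in spec.spots],
            "x": [s.center[2] for s in spec.spots],
            "molecules": [s.molecules for s in spec.spots],
            "nearest_blob_um": pairwise.min(axis=1) if n_b else np.full(n_s, np.nan),
        }
    )
    truth = GroundTruth(spot_table=spot_table, pairwise_um=pairwise)
    g1 = VoxelGrid(vol1, spec.voxel_size, image_id=f"scene{spec.rng_seed}", structure_name="structure1")
    g2 = VoxelGrid(vol2, spec.voxel_size, image_id=f"scene{spec.rng_seed}", structure_name="structure2")
    return g1, g2, truth


def scene_label_maps(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Analytic label maps: spot k -> label k in map 1, blob k -> label k in map 2.

    Spots are labeled over their truncated-Gaussian support, blobs over
    their sphere voxels.  Useful for testing measurement code against
    known object geometry without running the segmenter.
    """
    lab1 = np.zeros(spec.shape, dtype=np.int32)
    lab2 = np.zeros(spec.shape, dtype=np.int32)
    for k, s in enumerate(spec.spots, start=1):
        offsets, _ = _spot_kernel(s.sigma)
        coords = np.round(np.asarray(s.center)).astype(int) + offsets
        keep = (coords.min(axis=1) >= 0) & np.all(coords < np.asarray(spec.shape), axis=1)
        coords = coords[keep]
        lab1[coords[:, 0], coords[:, 1], coords[:, 2]] = k
    for k, b in enumerate(spec.blobs, start=1):
        vox = _blob_voxels(b, spec.shape, spec.voxel_size)
        if len(vox):
            lab2[vox[:, 0], vox[:, 1], vox[:, 2]] = k
    return lab1, lab2


def random_scene(
    n_spots: int,
    n_blobs: int,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    snr: float | None = 5.0,
    poisson: bool = True,
    min_separation_um: float = 0.7,
    blob_radius_um: tuple[float, float] = (0.4, 0.8),
    localized_min_separation_um: float = 0.45,
    singleton_fraction: float = 0.8,
    max_multiplicity: int = 8,
    localized_fraction: float = 0.0,
    max_tries: int = 2000,
) -> SceneSpec:
    """Draw a reproducible random scene specification.

    Spot and blob centers are uniform with minimum-separation rejection
    (within each structure).  Multiplicities: ``singleton_fraction`` of
    spots carry one molecule, the rest are uniform on {2..max_multiplicity};
    multi-molecule spots get sigma scaled by n^(1/3) so granule volume
    grows with content.  ``localized_fraction`` of spots are instead
    placed touching a blob surface (distance 0), emulating a localizing
    transcript; 0 gives a dispersed, non-localizing pattern.  ``snr`` is
    the single-molecule peak SNR including shot noise (see
    :func:`read_noise_for_snr`); ``snr=0``/``None`` renders noiselessly.
    """
    if n_spots < 0 or n_blobs < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    s_arr = np.asarray(voxel_size, dtype=np.float64)
    shape_arr = np.asarray(shape)

    def draw_centers(n, margin_vox, existing):
        centers = list(existing)
        out = []
        tries = 0
        while len(out) < n:
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {n} centers with separation "
                    f"{min_separation_um} um after {max_tries} tries"
                )
            tries += 1
            c = rng.uniform(margin_vox, shape_arr - 1 - margin_vox)
            if all(
                _physical_distance(c, e, voxel_size) >= min_separation_um for e in centers
            ):
                centers.append(c)
                out.append(tuple(float(v) for v in c))
                tries = 0
        return out

    spot_margin = np.ceil(TRUNC_SIGMA * np.asarray(DEFAULT_SPOT_SIGMA) * 2.0) + 1
    # blobs sit far enough from the stack borders that surface-localized
    # spots fit in any direction (organelles mid-stack, as in cortical planes)
    blob_margin = spot_margin + np.ceil(blob_radius_um[1] / s_arr) + 1
    # keep blobs disjoint: centers at least two max radii apart
    blob_sep = max(min_separation_um, 2.0 * blob_radius_um[1] + 0.1)
    blob_centers = []
    tries = 0
    while len(blob_centers) < n_blobs:
        if tries > max_tries:
            raise RuntimeError(f"could not place {n_blobs} disjoint blobs")
        tries += 1
        c = rng.uniform(blob_margin, shape_arr - 1 - blob_margin)
        if all(_physical_distance(c, e, voxel_size) >= blob_sep for e in blob_centers):
            blob_centers.append(tuple(float(v) for v in c))
            tries = 0
    blobs = [
        Blob(center=c, radius_um=float(rng.uniform(*blob_radius_um)), intensity=300.0)
        for c in blob_centers
    ]

    n_localized = int(round(localized_fraction * n_spots)) if blobs else 0
    loc_centers = []
    tries = 0
    while len(loc_centers) < n_localized:
        if tries > max_tries:
            raise RuntimeError("could not place localized spots")
        tries += 1

        b = blobs[rng.integers(len(blobs))]
        # a point on (or just inside) the blob surface, in physical space
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        c = np.asarray(b.center) + u * b.radius_um * rng.uniform(0.7, 1.0) / s_arr
        if np.all(c >= spot_margin) and np.all(c <= shape_arr - 1 - spot_margin):
            if all(
                _physical_distance(c, e, voxel_size) >= localized_min_separation_um
                for e in loc_centers
            ):
                loc_centers.append(tuple(float(v) for v in c))
                tries = 0
    free_centers = draw_centers(n_spots - n_localized, spot_margin, loc_centers)

    spots = []
    for c in loc_centers + free_centers:
        if rng.uniform() < singleton_fraction:
            n = 1
        else:
            n = int(rng.integers(2, max_multiplicity + 1))
        sig = tuple(float(s * n ** (1 / 3)) for s in DEFAULT_SPOT_SIGMA)
        spots.append(Spot(center=c, sigma=sig, molecules=n, base_intensity=DEFAULT_I0))

    noiseless = not snr
    sd = 0.0 if noiseless else read_noise_for_snr(snr, poisson=poisson)
    return SceneSpec(
        shape=tuple(int(v) for v in shape),
        voxel_size=tuple(float(v) for v in voxel_size),
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        spots=spots,
        blobs=blobs,
        gaussian_sd=sd,
        poisson=False if noiseless else poisson,
    )
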