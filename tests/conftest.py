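"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: they
enumerate voxels and pairs directly, so tests compare two independent
routes to the same quantity.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from subcelldist.extraction import SubcellularObject

FACE_NEIGHBORS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def brute_components(mask: np.ndarray, connectivity: str = "face") -> int:
    """Count connected components by breadth-first search."""
    if connectivity == "face":
        neigh = FACE_NEIGHBORS
    else:
        neigh = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    todo = {tuple(c) for c in np.argwhere(mask)}
    n = 0
    while todo:
        n += 1
        stack = [todo.pop()]
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in neigh:
                p = (z + dz, y + dy, x + dx)
                if p in todo:
                    todo.remove(p)
                    stack.append(p)
    return n


def object_from_coords(
    coords,
    object_id: int = 1,
    image_id: str = "img",
    structure: str = "s",
    intensity_per_voxel: float = 1.0,
) -> SubcellularObject:
    """Build an object from explicit voxel coordinates, brute force.

    Surface voxels are those with a face neighbor outside the coordinate
    set (out-of-grid counts as outside).
    """
    coord_set = {tuple(int(v) for v in c) for c in coords}
    surface = [
        c
        for c in sorted(coord_set)
        if any((c[0] + dz, c[1] + dy, c[2] + dx) not in coord_set for dz, dy, dx in FACE_NEIGHBORS)
    ]
    arr = np.array(sorted(coord_set))
    return SubcellularObject(
        object_id=object_id,
        image_id=image_id,
        structure_name=structure,
        total_intensity=intensity_per_voxel * len(coord_set),
        volume_voxels=len(coord_set),
        centroid=tuple(arr.mean(axis=0)),
        surface_coords=np.array(surface),
        voxel_coords=arr,
        bounding_box=tuple((int(arr[:, a].min()), int(arr[:, a].max()) + 1) for a in range(3)),
    )


def brute_surface_distance(a: SubcellularObject, b: SubcellularObject, voxel_size) -> float:
    """Min physical distance over all surface-voxel pairs; 0 on voxel overlap."""
    set_a = {tuple(c) for c in (a.voxel_coords if a.voxel_coords is not None else a.surface_coords)}
    set_b = {tuple(c) for c in (b.voxel_coords if b.voxel_coords is not None else b.surface_coords)}
    if set_a & set_b:
        return 0.0
    dz, dy, dx = voxel_size
    best = math.inf
    for p in a.surface_coords:
        for q in b.surface_coords:
            d = math.sqrt(
                ((p[0] - q[0]) * dz) ** 2 + ((p[1] - q[1]) * dy) ** 2 + ((p[2] - q[2]) * dx) ** 2
            )
            best = min(best, d)
    return best


def weighted_ecdf_percent(distances, weights, grid) -> np.ndarray:
    """Brute-force weighted ECDF evaluated on a grid, in percent."""
    distances = np.asarray(distances, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    return np.array([100.0 * weights[distances <= g].sum() / total for g in grid])


def cube_coords(corner, size):
    """All voxel coordinates of an axis-aligned cube."""
    z0, y0, x0 = corner
    return [
        (z0 + i, y0 + j, x0 + k)
        for i in range(size)
        for j in range(size)
        for k in range(size)
    ]


@pytest.fixture
def iso_voxel():
    return (0.1, 0.1, 0.1)


@pytest.fixture
def aniso_voxel():
    return (0.3, 0.1, 0.1)
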