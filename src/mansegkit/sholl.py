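"""3-D skeletonization and Sholl analysis.

Sholl analysis summarizes dendritic arborization by counting how many
times the neurites cross concentric spheres of increasing radius centred
on the soma. Here the segmented volume is first thinned to a 1-voxel
medial-axis skeleton (topology-preserving 3-D thinning), the skeleton is
turned into a graph over 26-adjacent voxels, and a sphere crossing is an
edge whose endpoints straddle the sphere: d(u) < r <= d(v) in physical
distance from the centre. The classic log-log summary regresses
log10(crossings / sphere volume) on log10(radius).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import skeletonize as _skeletonize_3d

from .stack_io import VoxelGeometry

__all__ = [
    "Skeleton",
    "ShollProfile",
    "skeletonize",
    "soma_center",
    "sholl_profile",
    "sholl_loglog_fit",
    "default_radii",
]

# the 13 lexicographically-positive offsets of the 26-neighbourhood
_HALF_NEIGHBOURHOOD = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off > (0, 0, 0)
]


@dataclass
class Skeleton:
    """1-voxel-thin medial representation of a binary volume.

    ``voxels`` is an (N, 3) integer array of (x, y, z) addresses;
    ``edges`` an (E, 2) array of voxel indices joining 26-adjacent
    skeleton voxels.
    """

    voxels: np.ndarray
    edges: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)

    def physical_coords(self) -> np.ndarray:
        """Voxel centres in µm."""
        return self.voxels * np.array(self.geometry.as_tuple())

    def n_components(self) -> int:
        n = len(self.voxels)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for u, v in self.edges:
            ru, rv = find(int(u)), find(int(v))
            if ru != rv:
                parent[ru] = rv
        return len({find(i) for i in range(n)})


def skeletonize(mask: np.ndarray, geometry: VoxelGeometry | None = None) -> Skeleton:
    """Thin a boolean volume to its medial-axis skeleton.

    Uses topology-preserving 3-D thinning, so the skeleton has the same
    number of 26-connected components as the input and its voxels are a
    subset of the input's foreground. Edges join every 26-adjacent pair
    of skeleton voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    if geometry is None:
        geometry = VoxelGeometry.default()
    skel = _skeletonize_3d(mask)
    yxz = np.argwhere(skel)
    voxels = yxz[:, [1, 0, 2]]  # (y, x, z) -> (x, y, z)
    index = {tuple(v): i for i, v in enumerate(map(tuple, voxels))}
    edges = []
    for off in _HALF_NEIGHBOURHOOD:
        for i, v in enumerate(voxels):
            j = index.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None:
                edges.append((i, j))
    return Skeleton(
        voxels=voxels,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        geometry=geometry,
    )


def soma_center(
    mask: np.ndarray, geometry: VoxelGeometry
) -> tuple[float, float, float]:
    """Locate the soma as the deepest point of the distance transform.

    The soma is the thickest part of the neuron, so the foreground voxel
    farthest from the background under the anisotropic Euclidean distance
    transform is a robust automatic stand-in for the centre an operator
    would click. Ties break toward the smallest (z, y, x). Returned in
    physical µm as (x, y, z); pass an explicit centre downstream to
    override.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot locate a soma in an empty mask")
    # array axes (y, x, z) -> sampling (dy, dx, dz)
    edt = ndimage.distance_transform_edt(
        mask, sampling=(geometry.dy, geometry.dx, geometry.dz)
    )
    peak = edt.max()
    ys, xs, zs = np.nonzero(edt == peak)
    order = np.lexsort((xs, ys, zs))[0]  # smallest (z, y, x)
    y, x, z = int(ys[order]), int(xs[order]), int(zs[order])
    return (x * geometry.dx, y * geometry.dy, z * geometry.dz)


@dataclass
class ShollProfile:
    """Crossing counts per concentric sphere plus the log-log fit."""

    center: tuple[float, float, float]
    radii: np.ndarray
    counts: np.ndarray
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)


def sholl_profile(skeleton: Skeleton, center, radii) -> ShollProfile:
    """Count skeleton-edge crossings of concentric spheres.

    For each edge (u, v) with distances d(u) <= d(v) from the centre
    (physical units), the edge crosses the sphere of radius r exactly
    when d(u) < r <= d(v); a voxel exactly on the sphere counts as
    outside-bound. Each crossing edge contributes once per sphere, which
    is the parameter-free graph reading of "times the neurites intersect
    each sphere".
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0 or np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ValueError("radii must be strictly increasing and positive")
    if len(skeleton.voxels) == 0:
        raise ValueError("empty skeleton")
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(skeleton.physical_coords() - center, axis=1)
    counts = np.zeros(len(radii) + 1, dtype=np.int64)
    if len(skeleton.edges):
        lo = np.minimum(d[skeleton.edges[:, 0]], d[skeleton.edges[:, 1]])
        hi = np.maximum(d[skeleton.edges[:, 0]], d[skeleton.edges[:, 1]])
        # radii k crossed by an edge: lo < r_k <= hi
        start = np.searchsorted(radii, lo, side="right")
        stop = np.searchsorted(radii, hi, side="right")
        np.add.at(counts, start, 1)
        np.add.at(counts, stop, -1)
        counts = np.cumsum(counts)
    return ShollProfile(center=tuple(center), radii=radii, counts=counts[:-1])


def sholl_loglog_fit(profile: ShollProfile) -> ShollProfile:
    """Least-squares line through the log-log normalized profile.

    Regresses y = log10(count / ((4/3) pi r^3)) on x = log10(r) over the
    radii with nonzero counts (the log of zero is undefined), and stores
    slope, intercept and R^2 on the profile. A profile with constant
    counts has slope exactly -3: the count per unit sphere volume then
    falls off as r^-3.
    """
    usable = profile.counts > 0
    if int(usable.sum()) < 2:
        raise ValueError("need at least 2 radii with nonzero counts to fit")
    r = profile.radii[usable]
    c = profile.counts[usable].astype(float)
    x = np.log10(r)
    y = np.log10(c / ((4.0 / 3.0) * np.pi * r**3))
    fit = stats.linregress(x, y)
    profile.slope = float(fit.slope)
    profile.intercept = float(fit.intercept)
    profile.r_squared = float(fit.rvalue**2)
    return profile


def default_radii(skeleton: Skeleton, center) -> np.ndarray:
    """Default sphere grid: step 2·max(dx, dy) out to the farthest voxel."""
    step = 2.0 * max(skeleton.geometry.dx, skeleton.geometry.dy)
    d = np.linalg.norm(
        skeleton.physical_coords() - np.asarray(center, dtype=float), axis=1
    )
    r_max = float(d.max())
    if r_max <= step:
        return np.array([step])
    return np.arange(step, r_max + step, step)
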