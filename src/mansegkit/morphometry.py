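"""Surface extraction and global segmentation metrics.

From a segmented object's boolean volume this module extracts a closed
marching-cubes isosurface in physical units and computes the global
quality measures used to compare raters: isosurface area and volume,
voxel-count volume as a consistency check, and the Gray-level Uniformity
(GU) index, a reference-free goodness-of-segmentation score based on
intensity homogeneity within the segmented regions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .stack_io import ImageStack, VoxelGeometry

__all__ = [
    "TriangleMesh",
    "OpenMeshError",
    "extract_mesh",
    "mesh_area",
    "mesh_volume",
    "voxel_volume",
    "gu_index",
]


class OpenMeshError(ValueError):
    """The mesh is not watertight: some edge is not shared by exactly 2 faces."""


@dataclass
class TriangleMesh:
    """Triangle surface in micrometres: (x, y, z) vertices + index triples."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")

    # -- interop -----------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def to_ply_bytes(self) -> bytes:
        return self.to_trimesh().export(file_type="ply")

    @classmethod
    def from_ply_bytes(cls, blob: bytes) -> "TriangleMesh":
        tm = trimesh.load(io.BytesIO(blob), file_type="ply", process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def export(self, path) -> None:
        """Write PLY or STL, chosen by file extension."""
        self.to_trimesh().export(path)

    # -- topology ----------------------------------------------------------
    def edge_face_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for a, b, c in self.faces:
            for u, v in ((a, b), (b, c), (c, a)):
                key = (min(u, v), max(u, v))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_closed(self) -> bool:
        return all(n == 2 for n in self.edge_face_counts().values())

    def euler_characteristic(self) -> int:
        v = len(np.unique(self.faces))
        e = len(self.edge_face_counts())
        f = len(self.faces)
        return v - e + f


#: smoothing scale of the isosurface field, in voxels (see extract_mesh)
MESH_SMOOTHING_SIGMA = 1.2


def extract_mesh(
    mask: np.ndarray,
    geometry: VoxelGeometry,
    smoothing_sigma: float = MESH_SMOOTHING_SIGMA,
) -> TriangleMesh:
    """Marching-cubes isosurface of a boolean volume, in micrometres.

    Contouring the raw 0/1 volume at level 0.5 yields a staircase surface
    whose area overestimates a smooth object's by a scale-independent
    ~9%, so the isosurface is instead taken at the zero level of a
    regularized signed Euclidean distance field: SDF = EDT(mask) −
    EDT(~mask) in physical units, Gaussian-smoothed (sigma in voxels),
    with the first-order curvature bias of the smoothing removed by one
    inverse-diffusion step (f − σ²/2·∇²f). Foreground voxels whose field
    value the smoothing drove non-positive are clamped slightly positive,
    so no mask voxel ever vanishes from the surface (a single isolated
    voxel still yields a small closed mesh).

    The volume is padded by background on all sides before contouring, so
    the mesh is closed even when the mask touches the stack boundary.
    Vertices are returned as (x, y, z) µm with voxel (x, y, z) at
    physical position (x·dx, y·dy, z·dz). ``smoothing_sigma=0`` falls
    back to the raw binary isosurface.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    g = geometry
    spacing = (g.dy, g.dx, g.dz)  # array axes are (y, x, z)
    pad = max(2, int(np.ceil(3 * smoothing_sigma)))
    padded = np.pad(mask, pad)

    if smoothing_sigma > 0:
        sdf = ndimage.distance_transform_edt(
            padded, sampling=spacing
        ) - ndimage.distance_transform_edt(~padded, sampling=spacing)
        field = ndimage.gaussian_filter(sdf, smoothing_sigma)
        field -= 0.5 * smoothing_sigma**2 * ndimage.laplace(field)
        guard = 0.1 * min(spacing)
        field[padded & (field <= 0)] = guard
        level = 0.0
    else:
        field = padded.astype(np.float32)
        level = 0.5

    verts, faces, _, _ = marching_cubes(field, level=level, spacing=spacing)
    verts -= pad * np.array(spacing)  # undo the pad shift
    verts = verts[:, [1, 0, 2]]  # (y, x, z) -> (x, y, z)
    return TriangleMesh(verts, faces)


def mesh_area(mesh: TriangleMesh) -> float:
    """Total surface area in µm²: half cross-product magnitude per face."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in µm³ via the signed-tetrahedron (divergence) sum.

    Requires a closed mesh — each edge shared by exactly two faces —
    otherwise the signed sum is meaningless and an error names the defect.
    """
    bad = [e for e, n in mesh.edge_face_counts().items() if n != 2]
    if bad:
        raise OpenMeshError(
            f"mesh is not closed: {len(bad)} edge(s) not shared by exactly "
            f"2 faces (first: {bad[0]})"
        )
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    return float(abs(signed.sum()))


def voxel_volume(mask: np.ndarray, geometry: VoxelGeometry) -> float:
    """Volume in µm³ counted voxel-by-voxel: consistency check for the mesh."""
    return float(np.count_nonzero(mask)) * geometry.dx * geometry.dy * geometry.dz


def gu_index(
    stack: ImageStack | np.ndarray,
    mask: np.ndarray,
    foreground_only: bool = False,
) -> float:
    """Gray-level Uniformity of a two-region segmentation, in [0, 1].

    With regions R1 (foreground) and R2 (background), population
    variances sigma_j^2, weights w_j = |R_j| / |Omega| and the normalizer
    sigma_norm^2 = ((f_max - f_min) / 2)^2 taken over the whole stack::

        GU = 1 - sum_j w_j * sigma_j^2 / sigma_norm^2

    GU = 1 when the stack is constant (f_max = f_min); an empty region
    contributes nothing. ``foreground_only=True`` drops the background
    term (same weighting), a variant some workflows report. GU is
    invariant under affine rescaling of the whole stack's intensities.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} != stack shape {data.shape}")
    values = data.astype(float)
    f_min, f_max = float(values.min()), float(values.max())
    if f_max == f_min:
        return 1.0
    sigma_norm2 = ((f_max - f_min) / 2.0) ** 2

    total = values.size
    penalty = 0.0
    regions = [mask] if foreground_only else [mask, ~mask]
    for region in regions:
        n = int(np.count_nonzero(region))
        if n == 0:
            continue
        penalty += (n / total) * float(np.var(values[region]))
    return 1.0 - penalty / sigma_norm2
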