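"""Synthetic neuron phantoms: tree, ground-truth mask, rendered stack.

Every validation path in this package needs an input whose truth is
known. The phantom generator builds a seeded random binary neuron tree
(soma plus tube-like neurites), rasterizes it into an exact boolean
volume as a union of capsules, and renders that volume into a realistic
grayscale stack — foreground/background plateaus blurred by an
anisotropic Gaussian point-spread function with additive Gaussian noise,
emulating a confocal acquisition of a fluorescent neuron. The tree, the
mask and the stack are mutually consistent, so matching, morphometry and
Sholl results on phantoms have analytic or exact expectations.

Defaults emulate the acquisition this kind of data comes from: 0.62 µm
in-plane pixels with a z-step double that, 8-bit intensities around a
dim background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours, label as _cc_label

from .session import Action
from .stack_io import ImageStack, VoxelGeometry
from .swc import SwcNode, SwcTree

__all__ = [
    "PhantomSpec",
    "generate_tree",
    "rasterize_tree",
    "render_stack",
    "generate_phantom",
    "script_from_mask",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic neuron acquisition.

    Lengths and radii are micrometres; intensity levels are in the units
    of the target bit depth. The default geometry follows the common
    confocal convention of an anisotropic grid with the z-step equal to
    twice the in-plane pixel pitch.
    """

    seed: int = 11
    dims: tuple[int, int, int] = (128, 128, 64)  # (M rows, N cols, Z slices)
    geometry: VoxelGeometry = field(
        default_factory=lambda: VoxelGeometry(0.62, 0.62, 1.24)
    )
    n_bifurcations: int = 3
    segment_length_range: tuple[float, float] = (12.0, 25.0)
    tube_radius_range: tuple[float, float] = (1.2, 2.0)
    soma_radius: float = 5.0
    psf_sigma: tuple[float, float, float] = (0.62, 0.62, 1.24)  # (x, y, z) µm
    background_level: int = 30
    foreground_level: int = 200
    noise_sigma: float = 10.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if min(self.segment_length_range) <= 0 or min(self.tube_radius_range) <= 0:
            raise ValueError("lengths and radii must be positive")
        if self.soma_radius <= 0:
            raise ValueError("soma radius must be positive")
        if min(self.psf_sigma) < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        top = 2**self.bit_depth - 1
        if not (0 <= self.background_level <= top and 0 <= self.foreground_level <= top):
            raise ValueError(f"intensity levels must lie in [0, {top}]")
        if self.n_bifurcations < 0:
            raise ValueError("n_bifurcations must be non-negative")


def _physical_extent(spec: PhantomSpec) -> np.ndarray:
    m, n, z = spec.dims
    g = spec.geometry
    return np.array([(n - 1) * g.dx, (m - 1) * g.dy, (z - 1) * g.dz])


def generate_tree(spec: PhantomSpec) -> SwcTree:
    """Grow a seeded random binary neuron tree inside the stack bounds.

    The soma sits at the volume centre; a trunk leaves it in a random
    direction and exactly ``n_bifurcations`` tips split into two children
    with directions jittered around the parent heading, so the tree has
    n_bifurcations + 1 end-points. Node coordinates are written in
    pixel/slice units of the stack (the convention the matching module
    assumes); radii are stored in in-plane pixel units.

    Raises if a segment cannot be placed inside the bounds after 100
    direction/length draws.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.geometry
    extent = _physical_extent(spec)
    center = extent / 2.0

    def to_pixels(p: np.ndarray) -> tuple[float, float, float]:
        return (p[0] / g.dx, p[1] / g.dy, p[2] / g.dz)

    def random_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    nodes: dict[int, SwcNode] = {}
    positions: dict[int, np.ndarray] = {}
    headings: dict[int, np.ndarray] = {}

    cx, cy, cz = to_pixels(center)
    nodes[1] = SwcNode(1, 1, cx, cy, cz, spec.soma_radius / g.dx, -1)
    positions[1] = center
    next_id = 2

    def grow_segment(parent_id: int, heading: np.ndarray) -> int:
        nonlocal next_id
        start = positions[parent_id]
        margin = max(spec.tube_radius_range) + max(g.dx, g.dy, g.dz)
        for _ in range(100):
            length = rng.uniform(*spec.segment_length_range)
            d = heading + 0.6 * random_unit()
            d /= np.linalg.norm(d)
            end = start + length * d
            if np.all(end >= margin) and np.all(end <= extent - margin):
                radius = rng.uniform(*spec.tube_radius_range)
                nid = next_id
                next_id += 1
                ex, ey, ez = to_pixels(end)
                nodes[nid] = SwcNode(nid, 3, ex, ey, ez, radius / g.dx, parent_id)
                positions[nid] = end
                headings[nid] = d
                return nid
            heading = random_unit()  # try a fresh direction
        raise RuntimeError("phantom tree does not fit the stack dimensions")

    trunk_tip = grow_segment(1, random_unit())
    tips = [trunk_tip]
    for _ in range(spec.n_bifurcations):
        tip = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            tips.append(grow_segment(tip, headings[tip]))

    return SwcTree(nodes=nodes).validate()


def rasterize_tree(
    tree: SwcTree, dims: tuple[int, int, int], geometry: VoxelGeometry
) -> np.ndarray:
    """Exact ground-truth mask: union of capsules around every segment.

    A voxel is foreground iff its centre lies within the local radius of
    some parent→child segment (radii linearly interpolated between the
    nodes, physical units) or within the soma ball around a root. The
    voxel-centre distance test makes the mask resolution-independent and
    analytically checkable.
    """
    if not tree.nodes:
        raise ValueError("cannot rasterize an empty tree")
    m, n, z = dims
    g = geometry
    scale = np.array([g.dx, g.dy, g.dz])
    mask = np.zeros((m, n, z), dtype=bool)

    def node_pos(node: SwcNode) -> np.ndarray:
        return np.array([node.x, node.y, node.z]) * scale

    def node_radius(node: SwcNode) -> float:
        return node.radius * g.dx

    def paint_capsule(p0: np.ndarray, r0: float, p1: np.ndarray, r1: float) -> None:
        lo = np.minimum(p0, p1) - max(r0, r1)
        hi = np.maximum(p0, p1) + max(r0, r1)
        x0, x1 = max(0, int(np.floor(lo[0] / g.dx))), min(n - 1, int(np.ceil(hi[0] / g.dx)))
        y0, y1 = max(0, int(np.floor(lo[1] / g.dy))), min(m - 1, int(np.ceil(hi[1] / g.dy)))
        z0, z1 = max(0, int(np.floor(lo[2] / g.dz))), min(z - 1, int(np.ceil(hi[2] / g.dz)))
        if x0 > x1 or y0 > y1 or z0 > z1:
            return
        xs = np.arange(x0, x1 + 1) * g.dx
        ys = np.arange(y0, y1 + 1) * g.dy
        zs = np.arange(z0, z1 + 1) * g.dz
        Y, X, Z = np.meshgrid(ys, xs, zs, indexing="ij")
        axis = p1 - p0
        L2 = float(axis @ axis)
        px, py, pz = X - p0[0], Y - p0[1], Z - p0[2]
        if L2 == 0.0:
            t = np.zeros_like(X)
        else:
            t = np.clip((px * axis[0] + py * axis[1] + pz * axis[2]) / L2, 0.0, 1.0)
        dx_ = px - t * axis[0]
        dy_ = py - t * axis[1]
        dz_ = pz - t * axis[2]
        dist2 = dx_**2 + dy_**2 + dz_**2
        r = r0 + t * (r1 - r0)
        mask[y0 : y1 + 1, x0 : x1 + 1, z0 : z1 + 1] |= dist2 <= r**2

    for node in tree.nodes.values():
        if node.parent_id == -1:
            p = node_pos(node)
            paint_capsule(p, node_radius(node), p, node_radius(node))
        else:
            parent = tree.nodes[node.parent_id]
            paint_capsule(
                node_pos(parent), node_radius(parent), node_pos(node), node_radius(node)
            )
    return mask


def render_stack(mask: np.ndarray, spec: PhantomSpec) -> ImageStack:
    """Render a ground-truth mask into a noisy blurred grayscale stack.

    Intensity = background + (foreground − background)·mask, convolved
    with the anisotropic Gaussian PSF (sigmas in µm, converted to voxel
    units per axis), plus seeded additive Gaussian noise, clipped to the
    bit depth and quantized. Deterministic given the spec's seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(spec.dims):
        raise ValueError(f"mask shape {mask.shape} != spec dims {spec.dims}")
    g = spec.geometry
    img = spec.background_level + (
        spec.foreground_level - spec.background_level
    ) * mask.astype(float)
    sx, sy, sz = spec.psf_sigma
    sigma_vox = (sy / g.dy, sx / g.dx, sz / g.dz)  # array axes are (y, x, z)
    if any(s > 0 for s in sigma_vox):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    top = 2**spec.bit_depth - 1
    img = np.clip(np.floor(img + 0.5), 0, top)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return ImageStack(img.astype(dtype), bit_depth=spec.bit_depth, geometry=g)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, np.ndarray, SwcTree]:
    """One-call phantom: (rendered stack, ground-truth mask, tree)."""
    tree = generate_tree(spec)
    mask = rasterize_tree(tree, spec.dims, spec.geometry)
    stack = render_stack(mask, spec)
    return stack, mask, tree


def _component_boundary_polygons(plane: np.ndarray) -> list[np.ndarray]:
    """Ordered foreground boundary polygons, one per closed 0.5-contour.

    Subpixel 0.5-level contours of the binary plane are snapped onto the
    foreground pixel adjacent to each crossing, yielding closed polygons
    through foreground boundary centres that the polygon rasterizer can
    reproduce without spilling onto background.
    """
    polygons = []
    for contour in find_contours(plane.astype(float), 0.5):
        pts = []
        for r, c in contour:
            rl, rh = int(np.floor(r)), int(np.ceil(r))
            cl, ch = int(np.floor(c)), int(np.ceil(c))
            snapped = None
            for rr, cc in ((rl, cl), (rl, ch), (rh, cl), (rh, ch)):
                if 0 <= rr < plane.shape[0] and 0 <= cc < plane.shape[1] and plane[rr, cc]:
                    snapped = (cc, rr)  # (x, y)
                    break
            if snapped is not None and (not pts or pts[-1] != snapped):
                pts.append(snapped)
        if len(pts) >= 3:
            polygons.append(np.array(pts, dtype=float))
    return polygons


def script_from_mask(mask: np.ndarray, seconds_per_draw: float = 1.0) -> list[Action]:
    """Build a draw script whose replay approximately reproduces a mask.

    Emulates an operator tracing the ground truth: on every slice, each
    8-connected region's boundary is drawn as one freehand polygon (plus
    isolated 1–2 pixel specks as tiny squares). Useful for end-to-end
    exercises where the edited session must agree with a known volume.
    """
    mask = np.asarray(mask, dtype=bool)
    actions = [Action(kind="new_object", t=0.0, name="traced")]
    t = 0.0
    for zi in range(mask.shape[2]):
        plane = mask[:, :, zi]
        if not plane.any():
            continue
        labels = _cc_label(plane, connectivity=2)
        for lab in range(1, labels.max() + 1):
            comp = labels == lab
            polys = _component_boundary_polygons(comp)
            if not polys:
                # specks too small for a contour: draw a snug half-pixel box
                ys, xs = np.nonzero(comp)
                for x, y in zip(xs, ys):
                    t += seconds_per_draw
                    actions.append(
                        Action(
                            kind="draw", t=t, slice=zi,
                            points=(
                                (x - 0.4, y - 0.4), (x + 0.4, y - 0.4),
                                (x + 0.4, y + 0.4), (x - 0.4, y + 0.4),
                            ),
                        )
                    )
                continue
            for poly in polys:
                t += seconds_per_draw
                actions.append(
                    Action(
                        kind="draw", t=t, slice=zi,
                        points=tuple(map(tuple, poly)),
                    )
                )
    actions.append(Action(kind="pause", t=t))
    return actions
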