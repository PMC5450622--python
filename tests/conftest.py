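"""Shared fixtures and independent oracle helpers."""

import numpy as np
import pytest

from mansegkit import ImageStack, VoxelGeometry


def digital_ball(radius: int, margin: int = 4) -> np.ndarray:
    """Boolean ball of the given voxel radius, centred in a snug volume."""
    n = 2 * radius + 2 * margin + 1
    idx = np.indices((n, n, n)) - n // 2
    return (idx**2).sum(axis=0) <= radius * radius


def random_simple_polygon(rng: np.random.Generator, n_max: int = 10,
                          lo: float = 2.0, hi: float = 61.0) -> np.ndarray:
    """Star-shaped (hence simple) polygon with subpixel float vertices."""
    n = int(rng.integers(3, n_max + 1))
    cx, cy = rng.uniform(lo + 10, hi - 10, size=2)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(3.0, 18.0, size=n)
    xs = np.clip(cx + radii * np.cos(angles), lo, hi)
    ys = np.clip(cy + radii * np.sin(angles), lo, hi)
    return np.column_stack([xs, ys])


def polygon_mask_oracle(vertices: np.ndarray, width: int, height: int) -> np.ndarray:
    """Brute-force per-pixel mask: shapely strict interior + Bresenham boundary.

    Independent of the implementation's vectorized even-odd crossing test:
    point-in-polygon is delegated to shapely's geometric predicate, one
    pixel at a time.
    """
    from shapely.geometry import Point, Polygon
    from skimage.draw import line as bresenham

    poly = Polygon(vertices)
    mask = np.zeros((height, width), dtype=bool)
    for y in range(height):
        for x in range(width):
            if poly.contains(Point(float(x), float(y))):
                mask[y, x] = True
    closed = np.vstack([vertices, vertices[:1]])
    for (x0, y0), (x1, y1) in zip(closed[:-1], closed[1:]):
        rr, cc = bresenham(
            int(np.floor(y0 + 0.5)), int(np.floor(x0 + 0.5)),
            int(np.floor(y1 + 0.5)), int(np.floor(x1 + 0.5)),
        )
        keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
        mask[rr[keep], cc[keep]] = True
    return mask


def y_skeleton(branch_len: int = 50):
    """Trunk along +x to 40 voxels, then two diagonal branches.

    With unit geometry the bifurcation sits at 40 µm and the branch tips
    beyond 100 µm, so spheres of radius up to 40 µm see one crossing and
    spheres between 40 and 100 µm see two.
    """
    from mansegkit import Skeleton, VoxelGeometry

    trunk = [(i, 0, 0) for i in range(41)]
    up = [(40 + i, i, 0) for i in range(1, branch_len + 1)]
    down = [(40 + i, -i, 0) for i in range(1, branch_len + 1)]
    voxels = np.array(trunk + up + down)
    edges = [[i, i + 1] for i in range(40)]
    up0, down0 = 41, 41 + branch_len
    edges.append([40, up0])
    edges += [[up0 + i, up0 + i + 1] for i in range(branch_len - 1)]
    edges.append([40, down0])
    edges += [[down0 + i, down0 + i + 1] for i in range(branch_len - 1)]
    return Skeleton(voxels, np.array(edges), VoxelGeometry(1, 1, 1))


def capsule_union_volume(tree, dims, geometry, zoom: int = 3) -> float:
    """Reference volume of a tree's capsule union by fine-grid integration.

    Evaluates the exact point-in-capsule predicate on a grid ``zoom`` times
    finer than the voxel grid (independent numerical integration of the
    true geometry, not a rasterization readback). Bounding boxes keep it
    cheap at full stack size.
    """
    g = geometry
    m, n, z = dims
    fine = np.zeros((m * zoom, n * zoom, z * zoom), dtype=bool)
    xs = ((np.arange(n * zoom) + 0.5) / zoom - 0.5) * g.dx
    ys = ((np.arange(m * zoom) + 0.5) / zoom - 0.5) * g.dy
    zs = ((np.arange(z * zoom) + 0.5) / zoom - 0.5) * g.dz

    segs = []
    for node in tree.nodes.values():
        p = np.array([node.x * g.dx, node.y * g.dy, node.z * g.dz])
        r = node.radius * g.dx
        if node.parent_id == -1:
            segs.append((p, r, p, r))
        else:
            par = tree.nodes[node.parent_id]
            q = np.array([par.x * g.dx, par.y * g.dy, par.z * g.dz])
            segs.append((q, par.radius * g.dx, p, r))

    for p0, r0, p1, r1 in segs:
        lo = np.minimum(p0, p1) - max(r0, r1)
        hi = np.maximum(p0, p1) + max(r0, r1)
        i0 = max(0, np.searchsorted(xs, lo[0]) - 1)
        i1 = min(len(xs), np.searchsorted(xs, hi[0]) + 1)
        j0 = max(0, np.searchsorted(ys, lo[1]) - 1)
        j1 = min(len(ys), np.searchsorted(ys, hi[1]) + 1)
        k0 = max(0, np.searchsorted(zs, lo[2]) - 1)
        k1 = min(len(zs), np.searchsorted(zs, hi[2]) + 1)
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        YY, XX, ZZ = np.meshgrid(ys[j0:j1], xs[i0:i1], zs[k0:k1], indexing="ij")
        ax = p1 - p0
        L2 = float(ax @ ax)
        px, py, pz = XX - p0[0], YY - p0[1], ZZ - p0[2]
        if L2 > 0:
            t = np.clip((px * ax[0] + py * ax[1] + pz * ax[2]) / L2, 0.0, 1.0)
        else:
            t = 0.0
        d2 = (px - t * ax[0]) ** 2 + (py - t * ax[1]) ** 2 + (pz - t * ax[2]) ** 2
        rr = r0 + t * (r1 - r0)
        fine[j0:j1, i0:i1, k0:k1] |= d2 <= rr**2

    return float(fine.sum()) * g.dx * g.dy * g.dz / zoom**3


def sholl_counts_oracle(voxels, edges, geometry, center, radii) -> np.ndarray:
    """Walk every skeleton edge; count interval containments per radius."""
    scale = np.array(geometry.as_tuple())
    d = np.linalg.norm(voxels * scale - np.asarray(center, float), axis=1)
    counts = np.zeros(len(radii), dtype=int)
    for u, v in edges:
        lo, hi = sorted((d[u], d[v]))
        for k, r in enumerate(radii):
            if lo < r <= hi:
                counts[k] += 1
    return counts


def match_oracle(reference, candidates, theta_xy, theta_z):
    """All-pairs nearest-point matching with explicit (z, y, x) tie-break."""
    ref = np.asarray(reference, float)
    cand = np.asarray(candidates, float)
    n_xy = n_z = 0
    for p in ref:
        best = None
        for q in cand:
            d2 = float(((p - q) ** 2).sum())
            key = (d2, q[2], q[1], q[0])
            if best is None or key < best[0]:
                best = (key, q)
        q = best[1]
        if np.hypot(p[0] - q[0], p[1] - q[1]) <= theta_xy:
            n_xy += 1
        if abs(p[2] - q[2]) <= theta_z:
            n_z += 1
    return 100.0 * n_xy / len(ref), 100.0 * n_z / len(ref)


def friedman_permutation_oracle(table) -> tuple[float, float]:
    """Exact permutation null for the tie-corrected Friedman statistic.

    Enumerates every within-block permutation ((k!)^n tables) and returns
    (observed statistic, exact p) where p is the fraction of permuted
    tables whose statistic is >= the observed one. Statistic computed by
    an independent direct summation over mid-ranks.
    """
    from itertools import permutations, product

    from scipy.stats import rankdata

    x = np.asarray(table, dtype=float)
    n, k = x.shape

    def stat(t: np.ndarray) -> float:
        ranks = np.vstack([rankdata(row) for row in t])
        rj = ranks.sum(axis=0)
        chi2 = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
        ties = 0.0
        for row in t:
            _, counts = np.unique(row, return_counts=True)
            ties += float((counts**3 - counts).sum())
        c = 1.0 - ties / (n * k * (k**2 - 1))
        return 0.0 if c <= 0 else chi2 / c

    observed = stat(x)
    perms = list(permutations(range(k)))
    total = hits = 0
    for combo in product(perms, repeat=n):
        t = np.vstack([x[i, list(combo[i])] for i in range(n)])
        total += 1
        if stat(t) >= observed - 1e-12:
            hits += 1
    return observed, hits / total


@pytest.fixture
def unit_geometry() -> VoxelGeometry:
    return VoxelGeometry(1.0, 1.0, 1.0)


@pytest.fixture
def small_stack() -> ImageStack:
    """Deterministic 32x32x6 8-bit stack with mid-gray noise texture."""
    rng = np.random.default_rng(42)
    data = rng.integers(20, 120, size=(32, 32, 6), dtype=np.uint8)
    return ImageStack(data, bit_depth=8, geometry=VoxelGeometry(1.0, 1.0, 2.0))
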