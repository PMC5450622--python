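"""SWC reconstructions and nearest-point segmentation scoring.

Gold-standard neuron tracings come as SWC files: whitespace-separated
7-column records (id, type, x, y, z, radius, parent; parent -1 at a
root), '#' lines being comments. A segmentation that produces a volume
rather than a tracing is scored against such a gold standard by taking
the tracing's points of interest (roots, bifurcations, end-points),
finding for each the segmentation point that minimizes the full 3-D
Euclidean distance, and then checking the in-plane (XY) and axial (Z)
distances separately against thresholds stated in pixels/slices — the
two resolutions usually differ, so one threshold cannot serve both.
Points within threshold are "matched", the rest "missing".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SwcNode",
    "SwcTree",
    "SwcFormatError",
    "MatchReport",
    "read_swc",
    "parse_swc",
    "write_swc",
    "points_of_interest",
    "match_points",
    "mask_points",
    "DEFAULT_THETA_XY",
    "DEFAULT_THETA_Z",
]

# in-plane / axial match thresholds (pixels, slices) for the neocortical
# layer-1 axon dataset of the DIADEM challenge
DEFAULT_THETA_XY = 4.76
DEFAULT_THETA_Z = 17.0


class SwcFormatError(ValueError):
    """Malformed SWC content (bad record, duplicate id, missing parent, cycle)."""


@dataclass(frozen=True)
class SwcNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 at a root

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class SwcTree:
    """An id-indexed forest of SWC nodes with child links."""

    nodes: dict[int, SwcNode] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def roots(self) -> list[SwcNode]:
        return [n for n in self.nodes.values() if n.parent_id == -1]

    def children(self, node_id: int) -> list[SwcNode]:
        return [n for n in self.nodes.values() if n.parent_id == node_id]

    def child_counts(self) -> dict[int, int]:
        counts = {i: 0 for i in self.nodes}
        for n in self.nodes.values():
            if n.parent_id != -1:
                counts[n.parent_id] += 1
        return counts

    def validate(self) -> "SwcTree":
        if not self.nodes:
            raise SwcFormatError("SWC tree has no nodes")
        for n in self.nodes.values():
            if n.parent_id != -1 and n.parent_id not in self.nodes:
                raise SwcFormatError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
        # walk parent chains; any revisit inside the current chain is a cycle
        state: dict[int, int] = {}  # 0 in-progress, 1 done
        for start in self.nodes:
            chain = []
            i = start
            while i != -1 and state.get(i) != 1:
                if state.get(i) == 0:
                    raise SwcFormatError(f"cycle in parent links at node {i}")
                state[i] = 0
                chain.append(i)
                i = self.nodes[i].parent_id
            for i in chain:
                state[i] = 1
        if not self.roots:
            raise SwcFormatError("SWC tree has no root (parent -1) node")
        return self


def parse_swc(text: str) -> SwcTree:
    """Parse SWC text into a validated tree."""
    tree = SwcTree()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SwcFormatError(
                f"line {lineno}: expected 7 fields, got {len(fields)}: {line!r}"
            )
        try:
            nid = int(fields[0])
            node = SwcNode(
                id=nid,
                type_code=int(fields[1]),
                x=float(fields[2]),
                y=float(fields[3]),
                z=float(fields[4]),
                radius=float(fields[5]),
                parent_id=int(fields[6]),
            )
        except ValueError as exc:
            raise SwcFormatError(f"line {lineno}: non-numeric field: {exc}")
        if nid in tree.nodes:
            raise SwcFormatError(f"line {lineno}: duplicate node id {nid}")
        if node.parent_id == nid:
            raise SwcFormatError(f"line {lineno}: node {nid} is its own parent")
        tree.nodes[nid] = node
    return tree.validate()


def read_swc(path) -> SwcTree:
    with open(path) as fh:
        return parse_swc(fh.read())


def write_swc(tree: SwcTree, path) -> None:
    """Write nodes in id order, standard 7-column format."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(tree.nodes):
            n = tree.nodes[nid]
            fh.write(
                f"{n.id} {n.type_code} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                f"{n.radius:.6g} {n.parent_id}\n"
            )


def points_of_interest(tree: SwcTree, mode: str = "poi") -> np.ndarray:
    """Reference coordinates for matching.

    ``mode="poi"`` returns roots, bifurcations (>= 2 children) and
    end-points (0 children), deduplicated by node id; ``mode="all"``
    returns every node. Shape (P, 3), columns x, y, z.
    """
    if not tree.nodes:
        raise SwcFormatError("empty tree has no points of interest")
    if mode == "all":
        ids = sorted(tree.nodes)
    elif mode == "poi":
        counts = tree.child_counts()
        ids = sorted(
            i
            for i, n in tree.nodes.items()
            if n.parent_id == -1 or counts[i] >= 2 or counts[i] == 0
        )
    else:
        raise ValueError(f"mode must be 'poi' or 'all', got {mode!r}")
    return np.array([tree.nodes[i].xyz for i in ids], dtype=float)


def mask_points(mask: np.ndarray) -> np.ndarray:
    """All foreground voxel addresses of a boolean volume as (x, y, z) rows."""
    yxz = np.argwhere(np.asarray(mask, dtype=bool))
    if len(yxz) == 0:
        raise ValueError("mask has no foreground voxels")
    return yxz[:, [1, 0, 2]].astype(float)


def _round2_half_up(v: float) -> float:
    return float(np.floor(v * 100.0 + 0.5) / 100.0)


@dataclass
class MatchReport:
    """Per-point nearest-candidate distances and aggregate match rates."""

    table: pd.DataFrame  # ref_x..ref_z, cand_x..cand_z, d_xy, d_z, matched_xy, matched_z
    theta_xy: float
    theta_z: float

    @property
    def pct_matched_xy(self) -> float:
        return _round2_half_up(100.0 * self.table["matched_xy"].mean())

    @property
    def pct_matched_z(self) -> float:
        return _round2_half_up(100.0 * self.table["matched_z"].mean())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        summary = pd.DataFrame(
            [{
                "d_xy": self.pct_matched_xy,
                "d_z": self.pct_matched_z,
                "matched_xy": self.table["matched_xy"].sum(),
                "matched_z": self.table["matched_z"].sum(),
            }],
            index=["pct_matched"],
        )
        pd.concat([out, summary]).to_csv(path, index_label="point")


def match_points(
    reference,
    candidates,
    theta_xy: float = DEFAULT_THETA_XY,
    theta_z: float = DEFAULT_THETA_Z,
) -> MatchReport:
    """Score candidate points against reference points of interest.

    For each reference point the candidate minimizing the full 3-D
    Euclidean distance is selected (ties break toward the smallest
    (z, y, x)); the pair's in-plane distance d_xy and axial distance d_z
    are then checked separately: matched_xy iff d_xy <= theta_xy,
    matched_z iff d_z <= theta_z. Distances are in raw pixel/slice units,
    the units in which the thresholds are stated. Percentages are
    reported half-up to 2 decimals.
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    cand = np.asarray(candidates, dtype=float).reshape(-1, 3)
    if len(ref) == 0 or len(cand) == 0:
        raise ValueError("reference and candidate sets must be non-empty")
    if theta_xy <= 0 or theta_z <= 0:
        raise ValueError("thresholds must be positive")

    # stable tie-break: pre-sort candidates by (z, y, x); argmin then takes
    # the first minimum, i.e. the lexicographically smallest
    order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))
    cand = cand[order]

    rows = []
    for p in ref:
        d2 = ((cand - p) ** 2).sum(axis=1)
        q = cand[int(np.argmin(d2))]
        d_xy = float(np.hypot(p[0] - q[0], p[1] - q[1]))
        d_z = float(abs(p[2] - q[2]))
        rows.append(
            {
                "ref_x": p[0], "ref_y": p[1], "ref_z": p[2],
                "cand_x": q[0], "cand_y": q[1], "cand_z": q[2],
                "d_xy": d_xy, "d_z": d_z,
                "matched_xy": d_xy <= theta_xy,
                "matched_z": d_z <= theta_z,
            }
        )
    return MatchReport(table=pd.DataFrame(rows), theta_xy=theta_xy, theta_z=theta_z)
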