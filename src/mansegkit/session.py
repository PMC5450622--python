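"""Headless segmentation session engine.

Re-creates the editing core of an interactive slice-by-slice manual
segmentation tool without its GUI: each segmented object is a boolean
volume the same size as the source stack, edited by freehand-polygon
draws, click-to-remove undos and line splits on individual slices.
Mouse gestures are replaced by a replayable script of timestamped
actions, so the per-object active editing time — which the interactive
tool measures with a wall clock gated by a start/stop indicator — is
derived deterministically from the script's timestamps.

The session store (historically called the "datamatrix") holds, per
object: the boolean volume, the elapsed active seconds, and optionally a
cached surface mesh. Sessions persist to a zip container and can be
reloaded to continue editing.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.draw import line as _bresenham_line
from skimage.measure import label as _cc_label

from .stack_io import ImageStack, VoxelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentedObject",
    "Datamatrix",
    "Action",
    "SessionError",
    "SessionFormatError",
    "rasterize_polygon",
    "supercover_line",
    "draw",
    "undo_click",
    "split_line",
    "render_overlay",
    "merge_highlight",
    "replay_script",
    "load_script",
    "save_script",
    "save_session",
    "load_session",
]

SESSION_FORMAT_VERSION = 1


class SessionError(ValueError):
    """Invalid session state or action."""


class SessionFormatError(SessionError):
    """Corrupt or unreadable session container."""


def _round_half_up(v: float) -> int:
    """Deterministic half-up rounding (no banker's rounding)."""
    return int(np.floor(v + 0.5))


# ---------------------------------------------------------------------------
# Rasterization primitives
# ---------------------------------------------------------------------------

def rasterize_polygon(vertices, width: int, height: int) -> np.ndarray:
    """Rasterize a freehand closed contour onto a pixel grid.

    The contour is auto-closed (last vertex joined to the first). A pixel
    is set when its centre lies strictly inside the closed polygon under
    the even-odd rule, or when it lies on the 8-connected rasterized
    boundary of any edge, including the implicit closing edge. Vertices
    may be subpixel and may fall outside the grid; out-of-grid pixels are
    clipped.

    Parameters
    ----------
    vertices : sequence of (x, y)
        At least three contour points, in drawing order.
    width, height : int
        Grid size; the returned mask has shape ``(height, width)``.

    Returns
    -------
    numpy.ndarray of bool, shape (height, width)

    Notes
    -----
    A degenerate (zero-area, all-collinear) contour yields only the
    boundary trace, which is still a valid — if thin — selection.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("a polygon needs at least 3 (x, y) vertices")

    mask = _even_odd_interior(verts, width, height)

    # union with the 8-connected boundary trace of every (closing) edge
    closed = np.vstack([verts, verts[:1]])
    for (x0, y0), (x1, y1) in zip(closed[:-1], closed[1:]):
        rr, cc = _bresenham_line(
            _round_half_up(y0), _round_half_up(x0),
            _round_half_up(y1), _round_half_up(x1),
        )
        keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
        mask[rr[keep], cc[keep]] = True
    return mask


def _even_odd_interior(verts: np.ndarray, width: int, height: int) -> np.ndarray:
    """Even-odd (crossing-number) interior test at integer pixel centres."""
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    inside = np.zeros((height, width), dtype=bool)
    n = len(verts)
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        if y0 == y1:  # horizontal edges never cross a horizontal ray
            continue
        crosses = (y0 > Y) != (y1 > Y)
        x_at_y = x0 + (Y - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (X < x_at_y)
    return inside


def supercover_line(points) -> list[tuple[int, int]]:
    """4-connected rasterization of an open polyline.

    Returns the pixel (x, y) addresses along each segment with diagonal
    steps bridged, so the path is 4-connected end to end. A 4-connected
    cut is what actually separates 8-connected regions — a plain
    8-connected line leaves diagonal leaks. The polyline is NOT closed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("a split line needs at least 2 (x, y) points")
    out: list[tuple[int, int]] = []
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = _bresenham_line(
            _round_half_up(y0), _round_half_up(x0),
            _round_half_up(y1), _round_half_up(x1),
        )
        for k in range(len(rr) - 1):
            out.append((int(cc[k]), int(rr[k])))
            if rr[k + 1] != rr[k] and cc[k + 1] != cc[k]:
                # bridge the diagonal step to keep the path 4-connected
                out.append((int(cc[k + 1]), int(rr[k])))
        out.append((int(cc[-1]), int(rr[-1])))
    return out


# ---------------------------------------------------------------------------
# Session state
# ---------------------------------------------------------------------------

@dataclass
class SegmentedObject:
    """One segmented structure: boolean volume + active editing time.

    ``mask`` is indexed ``[y, x, z]`` and matches the parent stack's
    dimensions. ``elapsed_ms`` only ever increases; it counts the summed
    lengths of the intervals during which this object was actively edited.
    """

    mask: np.ndarray
    elapsed_ms: int = 0
    name: str = ""
    mesh_cache: "object | None" = None  # TriangleMesh, kept loose to avoid a cycle

    @property
    def elapsed_seconds(self) -> float:
        return self.elapsed_ms / 1000.0

    def add_time(self, seconds: float) -> None:
        if seconds < 0:
            raise SessionError("elapsed time cannot decrease")
        self.elapsed_ms += _round_half_up(seconds * 1000.0)


@dataclass
class Datamatrix:
    """A segmentation session: ordered objects over one stack geometry."""

    stack_dims: tuple[int, int, int]
    geometry: VoxelGeometry
    objects: list[SegmentedObject] = field(default_factory=list)
    active_object: int = -1
    timer_running: bool = False
    stack: ImageStack | None = None  # source stack, not persisted

    @classmethod
    def for_stack(cls, stack: ImageStack) -> "Datamatrix":
        return cls(stack_dims=stack.dims, geometry=stack.geometry, stack=stack)

    def new_object(self, name: str = "") -> SegmentedObject:
        obj = SegmentedObject(
            mask=np.zeros(self.stack_dims, dtype=bool),
            name=name or f"object_{len(self.objects)}",
        )
        self.objects.append(obj)
        self.active_object = len(self.objects) - 1
        return obj

    @property
    def active(self) -> SegmentedObject:
        if not (0 <= self.active_object < len(self.objects)):
            raise SessionError("no active object; create or select one first")
        return self.objects[self.active_object]

    def _check_slice(self, z: int) -> None:
        if not (0 <= z < self.stack_dims[2]):
            raise SessionError(
                f"slice {z} out of range [0, {self.stack_dims[2] - 1}]"
            )

    def _require_running(self) -> None:
        if not self.timer_running:
            raise SessionError("edits are only allowed while the session timer runs")


# ---------------------------------------------------------------------------
# Editing operations (slice-local)
# ---------------------------------------------------------------------------

def draw(session: Datamatrix, z: int, vertices) -> Datamatrix:
    """Add a freehand region to the active object on slice ``z``.

    The slice mask becomes the union of its previous value and the
    rasterized polygon; drawing is monotone and idempotent. More than one
    region may be drawn on the same slice by repeated calls.
    """
    session._require_running()
    session._check_slice(z)
    m, n, _ = session.stack_dims
    poly = rasterize_polygon(vertices, width=n, height=m)
    session.active.mask[:, :, z] |= poly
    return session


def undo_click(session: Datamatrix, z: int, point) -> Datamatrix:
    """Remove the 8-connected 2-D region of the active object under a click.

    Only the clicked slice is touched; removal is per-slice so a misplaced
    click cannot silently destroy work on distant slices. Clicking
    background is a warned no-op (a missed click, not corruption).
    """
    session._require_running()
    session._check_slice(z)
    x, y = point
    col, row = _round_half_up(x), _round_half_up(y)
    m, n, _ = session.stack_dims
    if not (0 <= row < m and 0 <= col < n):
        raise SessionError(f"click ({x}, {y}) falls outside the image")
    plane = session.active.mask[:, :, z]
    if not plane[row, col]:
        logger.warning(
            "undo click at (%s, %s) on slice %d hit background; nothing removed",
            x, y, z,
        )
        return session
    labels = _cc_label(plane, connectivity=2)
    plane[labels == labels[row, col]] = False
    return session


def split_line(session: Datamatrix, z: int, polyline) -> Datamatrix:
    """Erase mask pixels along a drawn line to sever touching structures.

    The line is rasterized 4-connected (supercover) so the severed halves
    are genuinely disconnected under 8-connectivity. The polyline is not
    auto-closed, and both halves stay in the same object.
    """
    session._require_running()
    session._check_slice(z)
    m, n, _ = session.stack_dims
    plane = session.active.mask[:, :, z]
    for col, row in supercover_line(polyline):
        if 0 <= row < m and 0 <= col < n:
            plane[row, col] = False
    return session


def render_overlay(
    session: Datamatrix,
    z: int,
    direction: int,
    alpha: float,
    channel: int = 1,
) -> np.ndarray:
    """Blend slice ``z`` of the original stack with an adjacent binary mask.

    Shows the grayscale slice *i* with the active object's mask at slice
    ``i + direction`` alpha-blended onto one colour channel (default
    green), the aid the interactive tool offers for following a structure
    across consecutive planes. Grayscale values are rescaled to 8 bits for
    12/16-bit stacks. Returns an (M, N, 3) uint8 RGB image.
    """
    if session.stack is None:
        raise SessionError("session has no source stack attached")
    if direction not in (-1, +1):
        raise ValueError("direction must be -1 or +1")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    session._check_slice(z)
    zn = z + direction
    if not (0 <= zn < session.stack_dims[2]):
        raise SessionError(f"adjacent slice {zn} out of range")

    g = session.stack.slice(z).astype(float)
    g8 = np.floor(g * 255.0 / session.stack.max_value + 0.5)
    m = session.active.mask[:, :, zn]

    # blend only where the adjacent mask is set; elsewhere the original
    # grayscale shows through on every channel
    rgb = np.repeat(g8[:, :, None], 3, axis=2)
    blended = np.floor((1.0 - alpha) * g8 + alpha * 255.0 + 0.5)
    rgb[:, :, channel] = np.where(m, blended, g8)
    return rgb.astype(np.uint8)


def merge_highlight(stack: ImageStack, obj: SegmentedObject) -> ImageStack:
    """Burn a segmented object into the stack at full intensity.

    Foreground voxels saturate to the bit-depth maximum; everything else
    keeps its original value. The result is an ordinary grayscale stack
    any external 3-D viewer can display.
    """
    if obj.mask.shape != stack.data.shape:
        raise ValueError(
            f"mask shape {obj.mask.shape} != stack shape {stack.data.shape}"
        )
    merged = stack.data.copy()
    merged[obj.mask] = stack.max_value
    return ImageStack(merged, bit_depth=stack.bit_depth, geometry=stack.geometry)


# ---------------------------------------------------------------------------
# Action scripts and replay
# ---------------------------------------------------------------------------

_KINDS = {"new_object", "select_object", "draw", "undo", "split", "pause", "resume"}


@dataclass(frozen=True)
class Action:
    """One timestamped session event in a replayable script.

    ``t`` is seconds since script start. ``slice`` addresses the edited
    plane for draw/undo/split; ``points`` carries the gesture's (x, y)
    coordinates. ``index`` selects the target for select_object.
    """

    kind: str
    t: float
    slice: int | None = None
    points: tuple | None = None
    index: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SessionError(f"unknown action kind {self.kind!r}")
        npts = 0 if self.points is None else len(self.points)
        if self.kind == "draw" and npts < 3:
            raise SessionError("draw requires at least 3 points")
        if self.kind == "split" and npts < 2:
            raise SessionError("split requires at least 2 points")
        if self.kind == "undo" and npts != 1:
            raise SessionError("undo requires exactly 1 point")
        if self.kind in ("draw", "undo", "split") and self.slice is None:
            raise SessionError(f"{self.kind} requires a slice index")
        if self.kind == "select_object" and self.index is None:
            raise SessionError("select_object requires an object index")


def replay_script(stack: ImageStack, script) -> Datamatrix:
    """Apply a timestamped action script to a fresh session.

    Deterministic: identical scripts on identical stacks yield
    bit-identical sessions. Each object's elapsed time is the summed
    length of the intervals during which it was the active object and the
    timer ran; creation starts the timer, ``pause``/``resume`` gate it,
    ``select_object`` reassigns subsequent time, and a script that ends
    while running is closed out at its final timestamp.
    """
    session = Datamatrix.for_stack(stack)
    prev_t = float("-inf")
    interval_start: float | None = None
    last_t = 0.0

    def _close(now: float) -> None:
        nonlocal interval_start
        if interval_start is not None:
            session.active.add_time(now - interval_start)
            interval_start = None

    for act in script:
        if act.t < prev_t:
            raise SessionError(
                f"non-monotone timestamps: {act.t} after {prev_t}"
            )
        prev_t = last_t = act.t

        if act.kind == "new_object":
            if session.timer_running:
                _close(act.t)
            session.new_object(act.name)
            session.timer_running = True
            interval_start = act.t
        elif act.kind == "select_object":
            if not (0 <= act.index < len(session.objects)):
                raise SessionError(f"select_object index {act.index} out of range")
            if session.timer_running:
                _close(act.t)
                session.active_object = act.index
                interval_start = act.t
            else:
                session.active_object = act.index
        elif act.kind == "pause":
            _close(act.t)
            session.timer_running = False
        elif act.kind == "resume":
            session.active  # raises if nothing to resume
            if not session.timer_running:
                session.timer_running = True
                interval_start = act.t
        elif act.kind == "draw":
            draw(session, act.slice, act.points)
        elif act.kind == "undo":
            undo_click(session, act.slice, act.points[0])
        elif act.kind == "split":
            split_line(session, act.slice, act.points)

    if session.timer_running:
        _close(last_t)
        session.timer_running = False
    return session


def load_script(path) -> list[Action]:
    """Read a JSON action script (array of records with kind/slice/points/t)."""
    with open(path) as fh:
        records = json.load(fh)
    script = []
    for rec in records:
        script.append(
            Action(
                kind=rec["kind"],
                t=float(rec["t"]),
                slice=rec.get("slice"),
                points=tuple(map(tuple, rec["points"])) if rec.get("points") else None,
                index=rec.get("index"),
                name=rec.get("name", ""),
            )
        )
    return script


def save_script(script, path) -> None:
    records = []
    for a in script:
        rec: dict = {"kind": a.kind, "t": a.t}
        if a.slice is not None:
            rec["slice"] = a.slice
        if a.points is not None:
            rec["points"] = [list(p) for p in a.points]
        if a.index is not None:
            rec["index"] = a.index
        if a.name:
            rec["name"] = a.name
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


# ---------------------------------------------------------------------------
# Session persistence
# ---------------------------------------------------------------------------

def save_session(session: Datamatrix, path) -> None:
    """Persist a session to a zip container.

    The container holds ``manifest.json`` (dims, geometry, object table
    with names and elapsed milliseconds) plus one multi-page 0/255 TIFF
    mask per object and, where cached, a PLY mesh.
    """
    manifest = {
        "format_version": SESSION_FORMAT_VERSION,
        "stack_dims": list(session.stack_dims),
        "geometry": {
            "dx": session.geometry.dx,
            "dy": session.geometry.dy,
            "dz": session.geometry.dz,
        },
        "mask_dialect": "uint8_0_255",
        "objects": [],
    }
    blobs: list[tuple[str, bytes]] = []
    for k, obj in enumerate(session.objects):
        mask_name = f"mask_{k}.tif"
        buf = io.BytesIO()
        pages = np.moveaxis((obj.mask.astype(np.uint8) * 255), -1, 0)
        tifffile.imwrite(buf, pages, photometric="minisblack")
        blobs.append((mask_name, buf.getvalue()))
        entry = {
            "name": obj.name,
            "elapsed_ms": obj.elapsed_ms,
            "mask": mask_name,
            "mesh": None,
        }
        if obj.mesh_cache is not None:
            mesh_name = f"mesh_{k}.ply"
            entry["mesh"] = mesh_name
            blobs.append((mesh_name, obj.mesh_cache.to_ply_bytes()))
        manifest["objects"].append(entry)

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for name, data in blobs:
            zf.writestr(name, data)


def load_session(path) -> Datamatrix:
    """Reload a session saved by :func:`save_session`.

    The returned session has no source stack attached; attach one (same
    dimensions) before replaying further overlay-dependent actions.
    """
    from .morphometry import TriangleMesh

    try:
        zf = zipfile.ZipFile(path)
    except (zipfile.BadZipFile, OSError) as exc:
        raise SessionFormatError(f"{path}: not a readable session container: {exc}")
    with zf:
        try:
            manifest = json.loads(zf.read("manifest.json"))
        except KeyError:
            raise SessionFormatError(f"{path}: container has no manifest.json")
        except json.JSONDecodeError as exc:
            raise SessionFormatError(f"{path}: corrupt manifest: {exc}")

        dims = tuple(manifest["stack_dims"])
        g = manifest["geometry"]
        session = Datamatrix(
            stack_dims=dims,
            geometry=VoxelGeometry(g["dx"], g["dy"], g["dz"]),
        )
        for entry in manifest["objects"]:
            try:
                pages = tifffile.imread(io.BytesIO(zf.read(entry["mask"])))
            except KeyError:
                raise SessionFormatError(
                    f"{path}: manifest references missing member {entry['mask']!r}"
                )
            if pages.ndim == 2:  # single-slice stack round-trips as one page
                pages = pages[None, :, :]
            mask = np.moveaxis(pages, 0, -1) > 0
            if mask.shape != dims:
                raise SessionFormatError(
                    f"{path}: mask {entry['mask']!r} has shape {mask.shape}, "
                    f"manifest says {dims}"
                )
            obj = SegmentedObject(
                mask=mask,
                elapsed_ms=int(entry["elapsed_ms"]),
                name=entry["name"],
            )
            if entry.get("mesh"):
                obj.mesh_cache = TriangleMesh.from_ply_bytes(zf.read(entry["mesh"]))
            session.objects.append(obj)
        if session.objects:
            session.active_object = 0
    return session
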