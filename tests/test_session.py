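"""Session engine: rasterization, editing semantics, replay, persistence."""

import numpy as np
import pytest
from skimage.measure import label

from mansegkit import (
    Action,
    Datamatrix,
    ImageStack,
    VoxelGeometry,
    draw,
    load_session,
    merge_highlight,
    rasterize_polygon,
    render_overlay,
    replay_script,
    save_session,
    split_line,
    supercover_line,
    undo_click,
)
from mansegkit.session import SessionError, SessionFormatError

from conftest import polygon_mask_oracle, random_simple_polygon

SQUARE = [(10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0)]


def fresh_session(dims=(32, 32, 6)):
    stack = ImageStack(np.zeros(dims, dtype=np.uint8), geometry=VoxelGeometry(1, 1, 2))
    session = Datamatrix.for_stack(stack)
    session.new_object()
    session.timer_running = True
    return session


# ---------------------------------------------------------------------------
# rasterize_polygon
# ---------------------------------------------------------------------------

class TestRasterizePolygon:
    def test_axis_aligned_square_has_121_pixels(self):
        mask = rasterize_polygon(SQUARE, 64, 64)
        assert mask.sum() == 121
        ys, xs = np.nonzero(mask)
        assert xs.min() == ys.min() == 10 and xs.max() == ys.max() == 20

    def test_open_polyline_auto_closes(self):
        open_tri = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0)]
        closed_tri = open_tri + [(0.0, 0.0)]
        np.testing.assert_array_equal(
            rasterize_polygon(open_tri, 64, 64), rasterize_polygon(closed_tri, 64, 64)
        )

    def test_random_polygons_match_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            verts = random_simple_polygon(rng)
            got = rasterize_polygon(verts, 64, 64)
            want = polygon_mask_oracle(verts, 64, 64)
            np.testing.assert_array_equal(got, want)

    def test_degenerate_collinear_polygon_yields_boundary_trace(self):
        mask = rasterize_polygon([(5.0, 5.0), (15.0, 5.0), (25.0, 5.0)], 64, 64)
        ys, xs = np.nonzero(mask)
        assert set(ys) == {5}
        assert set(xs) == set(range(5, 26))

    def test_vertices_outside_grid_are_clipped(self):
        mask = rasterize_polygon([(-10, -10), (5, -10), (5, 5), (-10, 5)], 16, 16)
        assert mask[0, 0] and mask[5, 5]
        assert mask.sum() == 36  # the visible 6x6 quadrant

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            rasterize_polygon([(0, 0), (1, 1)], 16, 16)


# ---------------------------------------------------------------------------
# draw / undo / split
# ---------------------------------------------------------------------------

class TestDraw:
    def test_two_disjoint_squares_give_two_components(self):
        s = fresh_session()
        draw(s, 3, [(2, 2), (8, 2), (8, 8), (2, 8)])
        draw(s, 3, [(20, 20), (28, 20), (28, 28), (20, 28)])
        assert label(s.active.mask[:, :, 3], connectivity=2).max() == 2

    def test_draw_is_idempotent(self):
        s = fresh_session()
        draw(s, 2, SQUARE)
        once = s.active.mask.copy()
        draw(s, 2, SQUARE)
        np.testing.assert_array_equal(s.active.mask, once)

    def test_overlap_obeys_inclusion_exclusion(self):
        a = [(2.0, 2.0), (12.0, 2.0), (12.0, 12.0), (2.0, 12.0)]
        b = [(8.0, 8.0), (18.0, 8.0), (18.0, 18.0), (8.0, 18.0)]
        ma = rasterize_polygon(a, 32, 32)
        mb = rasterize_polygon(b, 32, 32)
        s = fresh_session()
        draw(s, 0, a)
        draw(s, 0, b)
        assert s.active.mask[:, :, 0].sum() == ma.sum() + mb.sum() - (ma & mb).sum()

    def test_draw_requires_running_timer(self):
        s = fresh_session()
        s.timer_running = False
        with pytest.raises(SessionError):
            draw(s, 0, SQUARE)

    def test_invalid_slice_rejected(self):
        with pytest.raises(SessionError):
            draw(fresh_session(), 99, SQUARE)


class TestUndoClick:
    def test_click_center_clears_whole_region(self):
        s = fresh_session()
        draw(s, 1, SQUARE)
        undo_click(s, 1, (15.0, 15.0))
        assert not s.active.mask.any()

    def test_click_in_one_region_leaves_the_other_untouched(self):
        s = fresh_session()
        draw(s, 0, [(2, 2), (8, 2), (8, 8), (2, 8)])
        draw(s, 0, [(20, 20), (28, 20), (28, 28), (20, 28)])
        region_b = s.active.mask[:, :, 0].copy()
        region_b[:15, :15] = False
        undo_click(s, 0, (5.0, 5.0))
        np.testing.assert_array_equal(s.active.mask[:, :, 0], region_b)

    def test_background_click_is_warned_noop(self, caplog):
        s = fresh_session()
        draw(s, 0, SQUARE)
        before = s.active.mask.copy()
        with caplog.at_level("WARNING"):
            undo_click(s, 0, (30.0, 30.0))
        assert "background" in caplog.text
        np.testing.assert_array_equal(s.active.mask, before)


class TestSplitLine:
    def test_vertical_split_of_rectangle_makes_two_components(self):
        s = fresh_session()
        draw(s, 0, [(0, 0), (20, 0), (20, 4), (0, 4)])
        split_line(s, 0, [(10.0, -1.0), (10.0, 5.0)])
        plane = s.active.mask[:, :, 0]
        assert label(plane, connectivity=2).max() == 2
        assert not plane[:, 10].any()

    def test_diagonal_split_leaves_no_diagonal_leak(self):
        s = fresh_session()
        draw(s, 0, [(0, 0), (20, 0), (20, 20), (0, 20)])
        split_line(s, 0, [(-1.0, -1.0), (21.0, 21.0)])
        assert label(s.active.mask[:, :, 0], connectivity=2).max() == 2

    def test_split_over_background_is_noop(self):
        s = fresh_session()
        draw(s, 0, SQUARE)
        before = s.active.mask.copy()
        split_line(s, 0, [(25.0, 0.0), (25.0, 31.0)])
        np.testing.assert_array_equal(s.active.mask, before)

    def test_supercover_path_is_4_connected(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.uniform(0, 30, size=(3, 2))
            path = supercover_line(pts)
            for (x0, y0), (x1, y1) in zip(path[:-1], path[1:]):
                assert abs(x0 - x1) + abs(y0 - y1) <= 1

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            supercover_line([(3.0, 3.0)])


# ---------------------------------------------------------------------------
# locality / monotonicity properties
# ---------------------------------------------------------------------------

def test_edits_are_slice_local_for_random_scripts():
    rng = np.random.default_rng(77)
    for _ in range(100):
        s = fresh_session(dims=(24, 24, 5))
        # seed some content everywhere
        for z in range(5):
            draw(s, z, [(4, 4), (18, 4), (18, 18), (4, 18)])
        kind = rng.choice(["draw", "undo", "split"])
        z = int(rng.integers(5))
        before = s.active.mask.copy()
        if kind == "draw":
            draw(s, z, rng.uniform(0, 23, size=(4, 2)))
            assert (s.active.mask >= before).all()  # monotone
        elif kind == "undo":
            undo_click(s, z, tuple(rng.uniform(0, 23, size=2)))
            assert (s.active.mask <= before).all()  # anti-monotone
        else:
            split_line(s, z, rng.uniform(0, 23, size=(3, 2)))
            assert (s.active.mask <= before).all()
        others = [zz for zz in range(5) if zz != z]
        np.testing.assert_array_equal(
            s.active.mask[:, :, others], before[:, :, others]
        )


# ---------------------------------------------------------------------------
# overlay and merge
# ---------------------------------------------------------------------------

class TestRenderOverlay:
    def test_blend_formula_on_known_values(self):
        stack = ImageStack(np.full((8, 8, 3), 100, dtype=np.uint8))
        s = Datamatrix.for_stack(stack)
        s.new_object()
        s.objects[0].mask[:, :, 2] = True
        rgb = render_overlay(s, 1, +1, 0.4)
        assert rgb[0, 0, 1] == 162  # 0.6*100 + 0.4*255
        assert rgb[0, 0, 0] == rgb[0, 0, 2] == 100

    def test_empty_mask_reproduces_grayscale(self, small_stack):
        s = Datamatrix.for_stack(small_stack)
        s.new_object()
        rgb = render_overlay(s, 0, +1, 0.7)
        for ch in range(3):
            np.testing.assert_array_equal(rgb[:, :, ch], small_stack.slice(0))

    def test_alpha_zero_is_identity(self, small_stack):
        s = Datamatrix.for_stack(small_stack)
        s.new_object()
        s.objects[0].mask[:, :, 1] = True
        rgb = render_overlay(s, 0, +1, 0.0)
        np.testing.assert_array_equal(rgb[:, :, 1], small_stack.slice(0))

    def test_out_of_range_direction_rejected(self, small_stack):
        s = Datamatrix.for_stack(small_stack)
        s.new_object()
        with pytest.raises(SessionError):
            render_overlay(s, 5, +1, 0.4)


class TestMergeHighlight:
    def test_foreground_saturates_to_bit_depth_max(self):
        data = np.full((4, 4, 2), 37, dtype=np.uint8)
        stack = ImageStack(data)
        from mansegkit.session import SegmentedObject

        mask = np.zeros((4, 4, 2), dtype=bool)
        mask[1, 1, 0] = True
        merged = merge_highlight(stack, SegmentedObject(mask=mask))
        assert merged.data[1, 1, 0] == 255
        assert merged.data[0, 0, 0] == 37

    def test_twelve_bit_saturates_to_4095(self):
        stack = ImageStack(np.full((2, 2, 1), 7, dtype=np.uint16), bit_depth=12)
        from mansegkit.session import SegmentedObject

        merged = merge_highlight(stack, SegmentedObject(mask=np.ones((2, 2, 1), bool)))
        assert (merged.data == 4095).all()

    def test_empty_mask_is_identity(self, small_stack):
        from mansegkit.session import SegmentedObject

        merged = merge_highlight(
            small_stack, SegmentedObject(mask=np.zeros(small_stack.data.shape, bool))
        )
        np.testing.assert_array_equal(merged.data, small_stack.data)


# ---------------------------------------------------------------------------
# replay and the activity timer
# ---------------------------------------------------------------------------

class TestReplay:
    def test_pause_resume_interval_arithmetic(self, small_stack):
        script = [
            Action(kind="new_object", t=0.0),
            Action(kind="draw", t=5.0, slice=0, points=tuple(SQUARE)),
            Action(kind="pause", t=10.0),
            Action(kind="resume", t=50.0),
            Action(kind="draw", t=60.0, slice=1, points=tuple(SQUARE)),
            Action(kind="pause", t=70.0),
        ]
        session = replay_script(small_stack, script)
        assert session.objects[0].elapsed_seconds == pytest.approx(30.0, abs=1e-9)

    def test_empty_script_yields_empty_session(self, small_stack):
        session = replay_script(small_stack, [])
        assert session.objects == []

    def test_draw_then_undo_composes_to_empty(self, small_stack):
        script = [
            Action(kind="new_object", t=0.0),
            Action(kind="draw", t=1.0, slice=2, points=tuple(SQUARE)),
            Action(kind="undo", t=2.0, slice=2, points=((15.0, 15.0),)),
        ]
        session = replay_script(small_stack, script)
        assert not session.objects[0].mask.any()

    def test_replay_is_deterministic(self, small_stack):
        rng = np.random.default_rng(3)
        script = [Action(kind="new_object", t=0.0)]
        for i in range(10):
            script.append(
                Action(
                    kind="draw", t=float(i + 1), slice=int(rng.integers(6)),
                    points=tuple(map(tuple, rng.uniform(0, 31, size=(5, 2)))),
                )
            )
        m1 = replay_script(small_stack, script).objects[0].mask
        m2 = replay_script(small_stack, script).objects[0].mask
        np.testing.assert_array_equal(m1, m2)

    def test_select_object_reassigns_time(self, small_stack):
        script = [
            Action(kind="new_object", t=0.0),
            Action(kind="new_object", t=10.0),
            Action(kind="select_object", t=25.0, index=0),
            Action(kind="pause", t=30.0),
        ]
        session = replay_script(small_stack, script)
        assert session.objects[0].elapsed_seconds == pytest.approx(15.0)
        assert session.objects[1].elapsed_seconds == pytest.approx(15.0)

    def test_edit_before_new_object_rejected(self, small_stack):
        with pytest.raises(SessionError):
            replay_script(
                small_stack,
                [Action(kind="draw", t=0.0, slice=0, points=tuple(SQUARE))],
            )

    def test_non_monotone_timestamps_rejected(self, small_stack):
        script = [
            Action(kind="new_object", t=5.0),
            Action(kind="pause", t=1.0),
        ]
        with pytest.raises(SessionError):
            replay_script(small_stack, script)

    def test_action_invariants_enforced(self):
        with pytest.raises(SessionError):
            Action(kind="draw", t=0.0, slice=0, points=((0, 0), (1, 1)))
        with pytest.raises(SessionError):
            Action(kind="undo", t=0.0, slice=0, points=((0, 0), (1, 1)))
        with pytest.raises(SessionError):
            Action(kind="wiggle", t=0.0)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

class TestPersistence:
    def test_round_trip_masks_names_times(self, small_stack, tmp_path):
        s = Datamatrix.for_stack(small_stack)
        s.new_object("soma")
        s.timer_running = True
        draw(s, 0, SQUARE)
        s.objects[0].elapsed_ms = 12345
        s.new_object("dendrite")
        draw(s, 3, [(1, 1), (6, 1), (6, 6)])
        path = tmp_path / "session.zip"
        save_session(s, path)
        back = load_session(path)
        assert [o.name for o in back.objects] == ["soma", "dendrite"]
        assert back.objects[0].elapsed_ms == 12345
        for orig, re in zip(s.objects, back.objects):
            np.testing.assert_array_equal(orig.mask, re.mask)
        assert back.geometry == s.geometry

    def test_mesh_cache_round_trips(self, small_stack, tmp_path):
        from mansegkit import extract_mesh

        s = Datamatrix.for_stack(small_stack)
        s.new_object()
        s.timer_running = True
        draw(s, 2, SQUARE)
        s.objects[0].mesh_cache = extract_mesh(s.objects[0].mask, s.geometry)
        path = tmp_path / "session.zip"
        save_session(s, path)
        back = load_session(path)
        assert len(back.objects[0].mesh_cache.vertices) == len(
            s.objects[0].mesh_cache.vertices
        )
        assert len(back.objects[0].mesh_cache.faces) == len(s.objects[0].mesh_cache.faces)

    def test_truncated_container_rejected(self, small_stack, tmp_path):
        s = Datamatrix.for_stack(small_stack)
        s.new_object()
        path = tmp_path / "session.zip"
        save_session(s, path)
        path.write_bytes(path.read_bytes()[:50])
        with pytest.raises(SessionFormatError):
            load_session(path)

    def test_resume_editing_after_reload(self, small_stack, tmp_path):
        s = Datamatrix.for_stack(small_stack)
        s.new_object()
        s.timer_running = True
        draw(s, 0, SQUARE)
        path = tmp_path / "session.zip"
        save_session(s, path)

        back = load_session(path)
        back.stack = small_stack
        back.timer_running = True
        extra = [(25.0, 25.0), (30.0, 25.0), (30.0, 30.0), (25.0, 30.0)]
        draw(back, 1, extra)
        save_session(back, path)

        final = load_session(path)
        expected = rasterize_polygon(extra, 32, 32)
        np.testing.assert_array_equal(final.objects[0].mask[:, :, 1], expected)
        np.testing.assert_array_equal(
            final.objects[0].mask[:, :, 0], rasterize_polygon(SQUARE, 32, 32)
        )
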