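import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from iriseg.errors import OutOfBoundsError, ParameterError, SessionError
from iriseg.interaction import (
    AffinityConfig,
    ClickEvent,
    EditSession,
    affinity,
    anti_smart_click,
    closing,
    load_session,
    paint,
    replay_session,
    save_session,
    smart_click,
)
from iriseg.volumes import BinaryMask

from conftest import make_mask, slice_volume


def smooth_random_image(seed, n=24):
    rng = np.random.default_rng(seed)
    img = ndi.gaussian_filter(rng.uniform(size=(n, n)), sigma=2.0)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


def seed_mode_oracle(img3d, seed, a, threshold, connectivity=4):
    """Connected component of {v: |I(v) - I(seed)| <= a*(1-threshold)}
    containing the seed, computed by scipy labelling (per clicked slice)."""
    tol = a * (1 - threshold)
    z = seed[0]
    ok = np.abs(img3d[z] - img3d[seed]) <= tol
    structure = ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, _ = ndi.label(ok, structure=structure)
    comp = labels == labels[seed[1], seed[2]]
    out = np.zeros_like(img3d, dtype=bool)
    out[z] = comp
    return out


def grow_dfs(img3d, seed, cfg):
    """Depth-first variant of chain-mode growth (stack instead of queue)."""
    tol = cfg.sensitivity_a * (1 - cfg.threshold)
    offs = [(0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    if cfg.connectivity == 8:
        offs += [(0, -1, -1), (0, -1, 1), (0, 1, -1), (0, 1, 1)]
    if cfg.scope == "3d":
        offs += [(-1, 0, 0), (1, 0, 0)]
    acc = np.zeros(img3d.shape, dtype=bool)
    acc[seed] = True
    stack = [seed]
    while stack:
        z, r, c = stack.pop()
        for dz, dr, dc in offs:
            zz, rr, cc = z + dz, r + dr, c + dc
            if not all(0 <= v < s for v, s in zip((zz, rr, cc), img3d.shape)):
                continue
            if acc[zz, rr, cc]:
                continue
            if abs(img3d[zz, rr, cc] - img3d[z, r, c]) <= tol:
                acc[zz, rr, cc] = True
                stack.append((zz, rr, cc))
    return acc


class TestAffinity:
    def test_equal_intensities_give_unit_affinity(self):
        assert affinity(0.4, 0.4, 0.2) == 1.0

    def test_difference_equal_to_sensitivity_gives_zero(self):
        assert affinity(0.7, 0.5, 0.2) == pytest.approx(0.0)

    def test_formula_value(self):
        assert affinity(0.9, 0.8, 0.4) == pytest.approx(0.75)

    def test_nonpositive_sensitivity_rejected(self):
        with pytest.raises(ParameterError):
            affinity(0.5, 0.5, 0.0)


class TestSmartClick:
    def test_uniform_block_grown_exactly(self):
        img = np.full((7, 7), 0.1)
        img[2:5, 2:5] = 0.9
        vol = slice_volume(img)
        empty = make_mask(np.zeros((1, 7, 7)))
        cfg = AffinityConfig(sensitivity_a=0.3, threshold=0.5, closing_radius=0)
        out = smart_click(vol, empty, (0, 3, 3), cfg)
        # oracle: all voxels chain-connected to the seed under |dI| <= a/2
        expected = np.zeros((1, 7, 7), dtype=bool)
        expected[0, 2:5, 2:5] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_isolated_seed_gives_single_voxel(self):
        img = np.full((5, 5), 0.1)
        img[2, 2] = 0.9
        vol = slice_volume(img)
        cfg = AffinityConfig(sensitivity_a=0.3, closing_radius=0)
        out = smart_click(vol, make_mask(np.zeros((1, 5, 5))), (0, 2, 2), cfg)
        assert out.count() == 1

    def test_closing_fills_interior_hole(self):
        img = np.full((9, 9), 0.9)
        img[4, 4] = 0.1  # dark hole inside the bright lesion
        img[0, :] = img[-1, :] = img[:, 0] = img[:, -1] = 0.1
        vol = slice_volume(img)
        cfg = AffinityConfig(sensitivity_a=0.3, closing_radius=1)
        out = smart_click(vol, make_mask(np.zeros((1, 9, 9))), (0, 2, 2), cfg)
        assert out.data[0, 4, 4]  # hole filled by dilation-then-erosion
        # oracle: direct morphology on the un-closed region
        cfg_off = AffinityConfig(sensitivity_a=0.3, closing_radius=0)
        raw = smart_click(vol, make_mask(np.zeros((1, 9, 9))), (0, 2, 2), cfg_off)
        from skimage.morphology import disk

        oracle = ndi.binary_erosion(
            ndi.binary_dilation(np.pad(raw.data[0], 1), disk(1)), disk(1)
        )[1:-1, 1:-1]
        np.testing.assert_array_equal(out.data[0], oracle)

    def test_never_shrinks_mask(self):
        img = smooth_random_image(0)
        vol = slice_volume(img)
        rng = np.random.default_rng(1)
        mask = make_mask((rng.random((1, 24, 24)) < 0.2))
        out = smart_click(vol, mask, (0, 12, 12), AffinityConfig())
        assert (out.data | mask.data).sum() == out.data.sum()

    def test_out_of_bounds_seed_raises(self):
        vol = slice_volume(np.zeros((4, 4)))
        with pytest.raises(OutOfBoundsError):
            smart_click(vol, make_mask(np.zeros((1, 4, 4))), (0, 4, 0))

    @pytest.mark.parametrize("image_seed", range(8))
    def test_seed_mode_matches_component_oracle(self, image_seed):
        img = smooth_random_image(image_seed)
        vol = slice_volume(img)
        rng = np.random.default_rng(100 + image_seed)
        seed = (0, int(rng.integers(24)), int(rng.integers(24)))
        a = float(rng.uniform(0.05, 0.5))
        cfg = AffinityConfig(
            sensitivity_a=a, comparison_mode="seed", closing_radius=0
        )
        out = smart_click(vol, make_mask(np.zeros((1, 24, 24))), seed, cfg)
        oracle = seed_mode_oracle(vol.data, seed, a, cfg.threshold)
        np.testing.assert_array_equal(out.data, oracle)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(image_seed=st.integers(0, 10_000), conn=st.sampled_from([4, 8]))
    def test_chain_mode_invariant_to_frontier_order(self, image_seed, conn):
        img = smooth_random_image(image_seed, n=16)[None]
        cfg = AffinityConfig(sensitivity_a=0.15, connectivity=conn, closing_radius=0)
        seed = (0, 8, 8)
        bfs = smart_click(
            slice_volume(img[0]),
            make_mask(np.zeros_like(img, dtype=bool)),
            seed,
            cfg,
        )
        dfs = grow_dfs(img, seed, cfg)
        np.testing.assert_array_equal(bfs.data, dfs)


class TestAntiSmartClick:
    def test_removes_only_seeded_component(self):
        # bright tube and bright sphere, disjoint; click in the tube
        img = np.full((11, 11), 0.1)
        img[:, 1:3] = 0.9  # tube
        img[5:8, 6:9] = 0.9  # lesion
        vol = slice_volume(img)
        mask = make_mask((img > 0.5)[None])
        cfg = AffinityConfig(sensitivity_a=0.3, closing_radius=0)
        out = anti_smart_click(vol, mask, (0, 5, 1), cfg)
        expected = np.zeros((1, 11, 11), dtype=bool)
        expected[0, 5:8, 6:9] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_seed_outside_mask_is_warned_noop(self):
        vol = slice_volume(np.zeros((4, 4)))
        mask = make_mask(np.zeros((1, 4, 4)))
        with pytest.warns(RuntimeWarning, match="not inside the mask"):
            out = anti_smart_click(vol, mask, (0, 1, 1))
        np.testing.assert_array_equal(out.data, mask.data)

    @pytest.mark.parametrize("mode", ["chain", "seed"])
    @pytest.mark.parametrize("image_seed", [0, 5, 9])
    def test_inverts_smart_click_from_empty_mask(self, image_seed, mode):
        img = smooth_random_image(image_seed)
        vol = slice_volume(img)
        empty = make_mask(np.zeros((1, 24, 24)))
        cfg = AffinityConfig(
            sensitivity_a=0.2, comparison_mode=mode, closing_radius=0
        )
        seed = (0, 11, 7)
        grown = smart_click(vol, empty, seed, cfg)
        undone = anti_smart_click(vol, grown, seed, cfg)
        np.testing.assert_array_equal(undone.data, empty.data)

    def test_never_grows_mask(self):
        img = smooth_random_image(2)
        vol = slice_volume(img)
        mask = make_mask(np.ones((1, 24, 24)))
        out = anti_smart_click(vol, mask, (0, 3, 3), AffinityConfig())
        assert not (out.data & ~mask.data).any()


class TestPaint:
    def test_radius_zero_sets_single_voxel(self):
        mask = make_mask(np.zeros((2, 5, 5)))
        out = paint(mask, (1, 2, 2), 0, "add")
        assert out.count() == 1 and out.data[1, 2, 2]

    def test_radius_one_disk_has_five_voxels(self):
        mask = make_mask(np.zeros((1, 7, 7)))
        out = paint(mask, (0, 3, 3), 1, "add")
        assert out.count() == 5

    def test_add_then_remove_restores_mask(self):
        rng = np.random.default_rng(4)
        mask = make_mask(rng.random((2, 9, 9)) < 0.0)  # empty
        added = paint(mask, (0, 4, 4), 2, "add")
        removed = paint(added, (0, 4, 4), 2, "remove")
        np.testing.assert_array_equal(removed.data, mask.data)

    def test_changes_only_clicked_disk(self):
        mask = make_mask(np.ones((2, 9, 9)))
        out = paint(mask, (1, 4, 4), 1, "remove")
        diff = mask.data != out.data
        assert diff[1].sum() == 5 and not diff[0].any()

    def test_clipped_at_border(self):
        mask = make_mask(np.zeros((1, 5, 5)))
        out = paint(mask, (0, 0, 0), 1, "add")
        assert out.count() == 3  # center + two in-bounds neighbours


class TestClosing:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(5)
        mask = make_mask(rng.random((2, 8, 8)) < 0.4)
        np.testing.assert_array_equal(closing(mask, 0).data, mask.data)

    def test_fills_center_hole_of_square(self):
        data = np.zeros((1, 7, 7), dtype=bool)
        data[0, 2:5, 2:5] = True
        data[0, 3, 3] = False
        out = closing(make_mask(data), 1)
        expected = data.copy()
        expected[0, 3, 3] = True
        np.testing.assert_array_equal(out.data, expected)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), radius=st.integers(1, 3))
    def test_extensive_and_idempotent(self, seed, radius):
        rng = np.random.default_rng(seed)
        mask = BinaryMask(rng.random((1, 16, 16)) < 0.3, (1.0, 1.0, 1.0))
        once = closing(mask, radius)
        assert (once.data | mask.data).sum() == once.data.sum()  # extensive
        twice = closing(once, radius)
        np.testing.assert_array_equal(once.data, twice.data)  # idempotent

    def test_smart_click_with_closing_contains_without(self):
        img = smooth_random_image(7)
        vol = slice_volume(img)
        empty = make_mask(np.zeros((1, 24, 24)))
        on = smart_click(vol, empty, (0, 12, 12), AffinityConfig(closing_radius=2))
        off = smart_click(vol, empty, (0, 12, 12), AffinityConfig(closing_radius=0))
        assert (on.data | off.data).sum() == on.data.sum()


class TestSessionReplay:
    def test_empty_session_is_identity(self):
        vol = slice_volume(np.zeros((4, 4)))
        mask = make_mask(np.eye(4)[None])
        out = replay_session(vol, mask, EditSession(events=()))
        np.testing.assert_array_equal(out.data, mask.data)

    def test_single_event_equals_direct_call(self):
        img = smooth_random_image(8)
        vol = slice_volume(img)
        empty = make_mask(np.zeros((1, 24, 24)))
        cfg = AffinityConfig()
        session = EditSession(
            events=(ClickEvent(kind="smart_add", coordinate=(0, 12, 12)),),
            defaults=cfg,
        )
        via_session = replay_session(vol, empty, session)
        direct = smart_click(vol, empty, (0, 12, 12), cfg)
        np.testing.assert_array_equal(via_session.data, direct.data)

    def test_replay_is_deterministic(self, default_case):
        from iriseg.phantom import scripted_cleanup_session

        ls = default_case["ls"]
        session = scripted_cleanup_session(
            ls, default_case["vessels"], default_case["cyst_gt"]
        )
        a = replay_session(default_case["normed"], ls, session)
        b = replay_session(default_case["normed"], ls, session)
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_event_reports_index(self):
        vol = slice_volume(np.zeros((4, 4)))
        mask = make_mask(np.zeros((1, 4, 4)))
        session = EditSession(
            events=(
                ClickEvent(kind="paint_add", coordinate=(0, 1, 1), brush_radius=1),
                ClickEvent(kind="smart_add", coordinate=(0, 9, 9)),
            )
        )
        with pytest.raises(SessionError, match="index 1"):
            replay_session(vol, mask, session)
        np.testing.assert_array_equal(mask.data, np.zeros((1, 4, 4), dtype=bool))


class TestSessionSerialization:
    def test_round_trip(self, tmp_path):
        session = EditSession(
            events=(
                ClickEvent(
                    kind="smart_add",
                    coordinate=(1, 2, 3),
                    overrides={"sensitivity_a": 0.4, "scope": "3d"},
                ),
                ClickEvent(kind="paint_remove", coordinate=(0, 1, 1), brush_radius=2),
            ),
            defaults=AffinityConfig(sensitivity_a=0.3, connectivity=8),
        )
        path = tmp_path / "session.json"
        save_session(session, path)
        back = load_session(path)
        assert back.defaults == session.defaults
        assert back.events == session.events

    def test_plain_array_form_accepted(self, tmp_path):
        path = tmp_path / "s.json"
        path.write_text(
            json.dumps([{"kind": "smart_add", "coordinate": [0, 1, 2], "a": 0.25}])
        )
        session = load_session(path)
        assert len(session) == 1
        assert session.events[0].overrides["sensitivity_a"] == 0.25

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps([{"kind": "smart_add", "coordinate": [0, 0, 0], "zap": 1}]))
        with pytest.raises(SessionError, match="zap"):
            load_session(path)

    def test_unknown_kind_rejected(self):
        with pytest.raises(SessionError):
            ClickEvent(kind="mega_click", coordinate=(0, 0, 0))

    def test_paint_event_requires_brush_radius(self):
        with pytest.raises(SessionError):
            ClickEvent(kind="paint_add", coordinate=(0, 0, 0))
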