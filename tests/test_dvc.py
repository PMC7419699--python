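"""DVC engine: grid construction, masked ZNCC, integer search, subpixel
refinement, and the full correlation run against brute-force oracles."""

import numpy as np
import pytest

from peridvc import (
    DvcConfig,
    GeometryError,
    ParameterError,
    Volume,
    WarpSpec,
    apply_warp,
    build_node_grid,
    correlate_subset,
    refine_subpixel,
    run_dvc,
    search_integer,
)


def oracle_zncc(ref, deff, center, offset, half, min_valid=0.5):
    """Independent masked ZNCC (plain numpy, no shared code path)."""
    cz, cy, cx = center
    oz, oy, ox = offset
    r = ref[cz - half:cz + half + 1, cy - half:cy + half + 1, cx - half:cx + half + 1]
    d = deff[cz + oz - half:cz + oz + half + 1,
             cy + oy - half:cy + oy + half + 1,
             cx + ox - half:cx + ox + half + 1]
    both = np.isfinite(r) & np.isfinite(d)
    if both.sum() < min_valid * r.size or both.sum() < 2:
        return np.nan
    rv, dv = r[both], d[both]
    rc, dc = rv - rv.mean(), dv - dv.mean()
    den = np.sqrt((rc ** 2).sum() * (dc ** 2).sum())
    return np.nan if den == 0 else float((rc * dc).sum() / den)


def oracle_search(ref, deff, center, half, search):
    """Exhaustive argmax with smallest-norm-then-lex tie rule."""
    best, best_key = None, None
    for oz in range(-search, search + 1):
        for oy in range(-search, search + 1):
            for ox in range(-search, search + 1):
                s = oracle_zncc(ref, deff, center, (oz, oy, ox), half)
                if np.isnan(s):
                    continue
                key = (-s, oz * oz + oy * oy + ox * ox, (oz, oy, ox))
                if best_key is None or key < best_key:
                    best_key, best = key, ((oz, oy, ox), s)
    return best


class TestNodeGrid:
    def test_count_matches_enumeration(self):
        vol = Volume(np.zeros((64, 64, 64)))
        cfg = DvcConfig()
        axes = build_node_grid(vol, cfg)
        # brute enumeration of admissible multiples of the spacing
        margin = (17 - 1) // 2 + 3
        expected = [c for c in range(0, 64, 4) if c - margin >= 0 and c + margin <= 63]
        for ax in axes:
            assert list(ax) == expected
        assert np.prod([len(a) for a in axes]) == len(expected) ** 3

    def test_spacing_one_every_admissible_voxel(self):
        vol = Volume(np.zeros((40, 40, 40)))
        cfg = DvcConfig(node_spacing_vox=1)
        axes = build_node_grid(vol, cfg)
        assert list(axes[0]) == list(range(cfg.margin, 40 - cfg.margin))

    def test_offset_convention(self):
        vol = Volume(np.zeros((64, 48, 80)))
        axes = build_node_grid(vol, DvcConfig())
        for ax in axes:
            assert (ax % 4 == 0).all()

    def test_too_small_volume_rejected(self):
        with pytest.raises(GeometryError):
            build_node_grid(Volume(np.zeros((16, 16, 16))), DvcConfig())

    @pytest.mark.parametrize("bad", [
        dict(subset_side_vox=16), dict(subset_side_vox=1),
        dict(node_spacing_vox=0), dict(min_valid_fraction=0.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ParameterError):
            DvcConfig(**bad)


class TestCorrelateSubset:
    def test_self_correlation_is_one(self, texture_only):
        cfg = DvcConfig()
        s = correlate_subset(texture_only, texture_only, (32, 32, 32), (0, 0, 0), cfg)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_affine_intensity_invariance(self, texture_only):
        cfg = DvcConfig()
        scaled = texture_only.with_data(3.0 * texture_only.data + 17.0)
        s = correlate_subset(texture_only, scaled, (32, 32, 32), (0, 0, 0), cfg)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_argmax_matches_bruteforce_on_shift(self, rng):
        data = rng.random((32, 32, 32)) * 100
        ref = Volume(data)
        shifted = np.full_like(data, np.nan)
        shifted[1:] = data[:-1]  # shift +1 along z
        deff = Volume(shifted)
        cfg = DvcConfig(search_radius_vox=2, subset_side_vox=9)
        center = (16, 16, 16)
        scores = {
            (oz, oy, ox): correlate_subset(ref, deff, center, (oz, oy, ox), cfg)
            for oz in (-2, -1, 0, 1, 2) for oy in (-2, -1, 0, 1, 2) for ox in (-2, -1, 0, 1, 2)
        }
        best = max(scores, key=lambda k: -np.inf if np.isnan(scores[k]) else scores[k])
        assert best == (1, 0, 0)
        oracle_best, oracle_score = oracle_search(ref.data, deff.data, center, 4, 2)
        assert oracle_best == (1, 0, 0)
        assert scores[best] == pytest.approx(oracle_score, abs=1e-10)


class TestSearchInteger:
    def test_identical_volumes(self, texture_only):
        off, s = search_integer(texture_only, texture_only, (32, 32, 32), DvcConfig())
        assert off == (0, 0, 0)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_constructed_shift(self, texture_only):
        moved = apply_warp(texture_only, WarpSpec(kind="rigid_translation",
                                                  translation_vox=(2, 1, 3)))
        off, _ = search_integer(texture_only, moved, (32, 32, 32), DvcConfig())
        assert off == (2, 1, 3)

    def test_tie_rule_deterministic(self):
        # mirror-symmetric pattern: equal scores at +/- offsets along z
        z = np.cos(np.linspace(0, 6 * np.pi, 40))
        data = np.broadcast_to(z[:, None, None], (40, 40, 40)).copy()
        data += np.linspace(0, 1, 40)[None, :, None]  # y gradient for variance
        vol = Volume(data)
        cfg = DvcConfig(subset_side_vox=9, search_radius_vox=3)
        off1, _ = search_integer(vol, vol, (20, 20, 20), cfg)
        off2, _ = search_integer(vol, vol, (20, 20, 20), cfg)
        assert off1 == off2 == (0, 0, 0)  # zero beats any equal-scoring offset by norm


class TestRefineSubpixel:
    def test_symmetric_neighborhood_zero_correction(self):
        s = np.full((3, 3, 3), 0.5)
        s[1, 1, 1] = 1.0
        assert np.allclose(refine_subpixel(s), 0.0)

    def test_closed_form_parabola(self):
        s = np.full((3, 3, 3), 0.5)
        s[1, 1, 1] = 1.0
        s[0, 1, 1], s[2, 1, 1] = 0.80, 0.90
        corr = refine_subpixel(s)
        assert corr[0] == pytest.approx((0.80 - 0.90) / (2 * (0.80 - 2 * 1.00 + 0.90)))
        assert corr[0] == pytest.approx(0.16667, abs=1e-4)
        assert corr[1] == corr[2] == 0.0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ParameterError):
            refine_subpixel(np.zeros((3, 3)))


class TestRunDvc:
    def test_self_pair_zero_displacement(self, texture_only):
        fld = run_dvc(texture_only, texture_only, DvcConfig(search_radius_vox=2))
        assert fld.ok.all()
        assert np.array_equal(fld.ok_displacements(),
                              np.zeros_like(fld.ok_displacements()))
        assert np.allclose(fld.cc[fld.ok], 1.0, atol=1e-9)

    def test_integer_shift_recovered_exactly(self, texture_only):
        moved = apply_warp(texture_only, WarpSpec(kind="rigid_translation",
                                                  translation_vox=(2, 1, 3)))
        fld = run_dvc(texture_only, moved, DvcConfig())
        assert fld.ok.sum() > 100
        assert np.array_equal(np.unique(fld.ok_displacements(), axis=0),
                              np.array([[2.0, 1.0, 3.0]]))

    def test_matches_bruteforce_oracle_small_volume(self, rng):
        data = rng.random((32, 32, 32)) * 100
        data[14:18, 14:18, 14:18] = np.nan  # masked blob exercises slow path
        ref = Volume(data)
        shifted = np.full_like(data, np.nan)
        shifted[1:, :, :-1] = data[:-1, :, 1:]  # shift (+1, 0, -1)
        deff = Volume(shifted)
        cfg = DvcConfig(node_spacing_vox=4, subset_side_vox=9, search_radius_vox=2,
                        subpixel=False, cc_min=0.0)
        fld = run_dvc(ref, deff, cfg)
        half = cfg.subset_half
        for iz, z in enumerate(fld.coords[0]):
            for iy, y in enumerate(fld.coords[1]):
                for ix, x in enumerate(fld.coords[2]):
                    expected = oracle_search(ref.data, deff.data, (z, y, x), half,
                                             cfg.search_radius_vox)
                    if fld.status[iz, iy, ix] == 0:
                        assert expected is not None
                        off, score = expected
                        assert tuple(fld.u[iz, iy, ix].astype(int)) == off
                        assert fld.cc[iz, iy, ix] == pytest.approx(score, abs=1e-9)
                    else:
                        assert expected is None or expected[1] < cfg.cc_min

    def test_swap_symmetry_on_subpixel_shift(self, texture_only):
        moved = apply_warp(texture_only, WarpSpec(kind="rigid_translation",
                                                  translation_vox=(0.5, 0.0, 0.0)))
        cfg = DvcConfig(search_radius_vox=2)
        fwd = run_dvc(texture_only, moved, cfg)
        rev = run_dvc(moved, texture_only, cfg)
        both = fwd.ok & rev.ok
        diff = np.abs(fwd.u[both] + rev.u[both])
        assert np.median(diff) < 0.1

    def test_subpixel_shift_recovered(self, texture_only):
        moved = apply_warp(texture_only, WarpSpec(kind="rigid_translation",
                                                  translation_vox=(0.5, 0.0, 0.0)))
        fld = run_dvc(texture_only, moved, DvcConfig(search_radius_vox=2))
        err = np.abs(fld.u[fld.ok][:, 0] - 0.5)
        assert (err < 0.1).mean() >= 0.9

    def test_masking_leaves_distant_nodes_unchanged(self, texture_only):
        moved = apply_warp(texture_only, WarpSpec(kind="rigid_translation",
                                                  translation_vox=(1, 0, 0)))
        cfg = DvcConfig(search_radius_vox=2)
        plain = run_dvc(texture_only, moved, cfg)
        masked_ref = texture_only.copy()
        masked_def = moved.copy()
        masked_ref.data[28:36, 28:36, 28:36] = np.nan
        masked_def.data[28:36, 28:36, 28:36] = np.nan
        masked = run_dvc(masked_ref, masked_def, cfg)
        margin = cfg.margin
        for iz, z in enumerate(plain.coords[0]):
            for iy, y in enumerate(plain.coords[1]):
                for ix, x in enumerate(plain.coords[2]):
                    if max(abs(z - 31.5), abs(y - 31.5), abs(x - 31.5)) > margin + 4:
                        assert np.array_equal(plain.u[iz, iy, ix], masked.u[iz, iy, ix])

    def test_shape_mismatch_rejected(self, texture_only):
        other = Volume(np.zeros((48, 64, 64)))
        with pytest.raises(GeometryError):
            run_dvc(texture_only, other, DvcConfig())
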