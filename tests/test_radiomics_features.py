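"""First-order, shape and texture features against brute-force oracles."""

import numpy as np
import pytest

import _oracles as oracle
from radiotsh import radiomics_features as rf
from conftest import random_levels


def _droi(levels, ng=None, spacing=(1.0, 1.0, 1.0)):
    levels = np.asarray(levels, dtype=np.int32)
    ng = ng or int(levels.max())
    return rf.DiscretizedROI(levels, levels > 0, ng, spacing)


class TestDiscretize:
    def test_two_values_two_bins(self):
        vol = np.array([1.0, 5.0, 1.0, 5.0]).reshape(4, 1, 1)
        droi = rf.discretize(vol, np.ones_like(vol, dtype=bool), n_bins=2)
        assert set(droi.levels[droi.mask]) == {1, 2}

    def test_uniform_ramp_near_uniform_histogram(self):
        vol = np.linspace(0, 1, 3200).reshape(40, 40, 2)
        droi = rf.discretize(vol, np.ones_like(vol, dtype=bool), n_bins=32)
        counts = np.bincount(droi.levels[droi.mask], minlength=33)[1:]
        assert counts.min() >= 90 and counts.max() <= 110

    def test_constant_roi_flagged_degenerate(self):
        vol = np.full((3, 3, 1), 4.0)
        with pytest.warns(UserWarning, match="degenerate"):
            droi = rf.discretize(vol, np.ones_like(vol, dtype=bool))
        assert droi.degenerate
        assert set(droi.levels[droi.mask]) == {1}


class TestFirstOrder:
    def test_constant_roi(self):
        vol = np.full((10, 1, 1), 5.0)
        f = rf.first_order(vol, np.ones_like(vol, dtype=bool))
        assert f["mean"] == 5.0
        assert f["variance"] == 0.0
        assert f["range"] == 0.0
        assert f["energy"] == pytest.approx(250.0)

    def test_percentile_convention(self):
        vol = np.arange(1.0, 101.0).reshape(100, 1, 1)
        f = rf.first_order(vol, np.ones_like(vol, dtype=bool))
        assert f["median"] == pytest.approx(50.5)
        assert f["interquartile_range"] == pytest.approx(49.5)

    def test_symmetric_sample_zero_skewness(self):
        vol = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]).reshape(5, 1, 1)
        f = rf.first_order(vol, np.ones_like(vol, dtype=bool))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_shift_covariance_and_order_invariance(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(4, 5, 3))
        mask = np.ones_like(vol, dtype=bool)
        base = rf.first_order(vol, mask)
        shifted = rf.first_order(vol + 3.0, mask)
        assert shifted["mean"] == pytest.approx(base["mean"] + 3.0)
        assert shifted["variance"] == pytest.approx(base["variance"])
        shuffled = vol.ravel().copy()
        rng.shuffle(shuffled)
        re = rf.first_order(shuffled.reshape(vol.shape), mask)
        assert re["median"] == pytest.approx(base["median"])
        assert re["energy"] == pytest.approx(base["energy"])

    def test_names(self):
        vol = np.random.default_rng(1).normal(size=(3, 3, 2))
        f = rf.first_order(vol, np.ones_like(vol, dtype=bool))
        assert tuple(f) == rf.FIRST_ORDER_FEATURES


class TestShape:
    def test_digital_ball(self):
        r = 20
        ax = np.arange(-r - 2, r + 3)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = x**2 + y**2 + z**2 <= r**2
        f = rf.shape_3d(ball, (1.0, 1.0, 1.0))
        assert 0.95 <= f["sphericity"] <= 1.05
        assert 0.97 <= f["flatness"] <= 1.0
        assert f["mesh_volume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
        assert f["maximum_3d_diameter"] == pytest.approx(2 * r, rel=0.05)

    def test_rod_is_flat(self):
        rod = np.zeros((7, 7, 9), dtype=bool)
        rod[3, 3, 2:7] = True
        f = rf.shape_3d(rod, (1.0, 1.0, 1.0))
        assert f["flatness"] < 0.2

    def test_spacing_scale_behaviour(self):
        mask = np.zeros((12, 12, 8), dtype=bool)
        mask[3:9, 3:9, 2:6] = True
        f1 = rf.shape_3d(mask, (1.0, 1.0, 1.0))
        f2 = rf.shape_3d(mask, (2.0, 2.0, 2.0))
        assert f2["mesh_volume"] == pytest.approx(8.0 * f1["mesh_volume"], rel=1e-6)
        assert f2["sphericity"] == pytest.approx(f1["sphericity"], rel=1e-6)
        assert f2["voxel_volume"] == pytest.approx(8.0 * f1["voxel_volume"])

    def test_names(self):
        mask = np.zeros((5, 5, 4), dtype=bool)
        mask[1:4, 1:4, 1:3] = True
        assert tuple(rf.shape_3d(mask)) == rf.SHAPE_FEATURES


class TestGLCM:
    def test_constant_roi_idmn_one(self):
        f = rf.glcm_features(_droi(np.ones((3, 3, 2)), ng=1))
        assert f["idmn"] == pytest.approx(1.0)
        assert f["contrast"] == 0.0

    def test_checkerboard_matches_oracle(self):
        board = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        droi = _droi(board, ng=2)
        assert np.allclose(rf.glcm_matrix(droi), oracle.naive_glcm(droi.levels, 2))

    def test_matrix_matches_oracle_on_random_grids(self):
        rng = np.random.default_rng(10)
        for _ in range(15):
            levels = random_levels(rng)
            droi = _droi(levels, ng=4)
            assert np.allclose(
                rf.glcm_matrix(droi), oracle.naive_glcm(levels, 4), atol=1e-12
            )

    def test_idmn_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            droi = _droi(random_levels(rng, ng=3), ng=3)
            f = rf.glcm_features(droi)
            assert 0.0 < f["idmn"] <= 1.0

    def test_rotation_invariance_in_plane(self):
        rng = np.random.default_rng(12)
        levels = random_levels(rng, shape=(5, 5, 2), ng=4)
        rot = np.rot90(levels, axes=(0, 1)).copy()
        f1 = rf.glcm_features(_droi(levels, ng=4))
        f2 = rf.glcm_features(_droi(rot, ng=4))
        for k in rf.GLCM_FEATURES:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9, abs=1e-12), k


class TestGLRLM:
    def test_single_run_closed_form(self):
        line = np.full((1, 1, 6), 3, dtype=np.int32)
        droi = _droi(line, ng=4)
        mat = rf.glrlm_matrix(droi)
        # along the run axis: one run of length 6; the other 12 directions
        # each contribute 6 runs of length 1
        assert mat[2, 5] == pytest.approx(1 / 13)
        assert mat[2, 0] == pytest.approx(12 * 6 / 13)
        f = rf.glrlm_features(droi)
        nr = mat.sum()
        expected_lrhgle = (9 * (1 * 36 + 72 * 1)) / 13 / nr
        assert f["long_run_high_gray_level_emphasis"] == pytest.approx(expected_lrhgle)

    def test_alternating_levels_short_runs(self):
        line = np.array([1, 2] * 4, dtype=np.int32).reshape(1, 1, 8)
        f = rf.glrlm_features(_droi(line, ng=2))
        assert f["short_run_emphasis"] == pytest.approx(1.0)
        assert f["run_percentage"] == pytest.approx(1.0)

    def test_matches_oracle_on_random_grids(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            levels = random_levels(rng)
            got = rf.glrlm_matrix(_droi(levels, ng=4))
            exp = oracle.naive_glrlm(levels)
            assert np.allclose(got[: exp.shape[0], : exp.shape[1]], exp, atol=1e-12)
            assert got[exp.shape[0] :].sum() == 0

    def test_rotation_invariance_in_plane(self):
        rng = np.random.default_rng(14)
        levels = random_levels(rng, shape=(5, 5, 2), ng=3)
        f1 = rf.glrlm_features(_droi(levels, ng=3))
        f2 = rf.glrlm_features(_droi(np.rot90(levels, axes=(0, 1)).copy(), ng=3))
        for k in rf.GLRLM_FEATURES:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9, abs=1e-12), k


class TestGLSZM:
    def test_single_zone_gln(self):
        droi = _droi(np.full((3, 3, 1), 2, dtype=np.int32), ng=2)
        f = rf.glszm_features(droi)
        assert f["gray_level_non_uniformity"] == pytest.approx(1.0)
        assert f["zone_percentage"] == pytest.approx(1 / 9)

    def test_two_disjoint_zones(self):
        levels = np.zeros((9, 1, 1), dtype=np.int32)
        levels[:3] = 2
        levels[4:] = 2
        droi = rf.DiscretizedROI(levels, levels > 0, 2, (1, 1, 1))
        mat = rf.glszm_matrix(droi)
        assert mat[1, 2] == 1  # size-3 zone
        assert mat[1, 4] == 1  # size-5 zone
        assert mat.sum() == 2

    def test_checkerboard_isolated_zones_via_oracle(self):
        board = (np.indices((4, 4, 2)).sum(axis=0) % 2 + 1).astype(np.int32)
        droi = _droi(board, ng=2)
        got = rf.glszm_matrix(droi)
        exp = oracle.naive_glszm(board)
        assert np.allclose(got[:, : exp.shape[1]], exp)

    def test_matches_oracle_on_random_grids(self):
        rng = np.random.default_rng(15)
        for _ in range(15):
            levels = random_levels(rng)
            got = rf.glszm_matrix(_droi(levels, ng=4))
            exp = oracle.naive_glszm(levels)
            assert np.allclose(got[: exp.shape[0], : exp.shape[1]], exp)


class TestGLDM:
    def test_constant_cube_dependence(self):
        cube = np.ones((3, 3, 3), dtype=np.int32)
        mat = rf.gldm_matrix(_droi(cube, ng=1))
        # the center voxel has all 26 neighbors -> dependence size 27
        assert mat[0, 26] == 1
        assert mat.sum() == 27

    def test_isolated_bright_voxel(self):
        levels = np.ones((3, 3, 1), dtype=np.int32)
        levels[1, 1, 0] = 4
        mat = rf.gldm_matrix(_droi(levels, ng=4), alpha=0)
        assert mat[3, 0] == 1  # zero dependent neighbors -> size 1

    def test_matches_oracle_on_random_grids(self):
        rng = np.random.default_rng(16)
        for alpha in (0, 1):
            for _ in range(10):
                levels = random_levels(rng, shape=(3, 3, 3))
                got = rf.gldm_matrix(_droi(levels, ng=4), alpha=alpha)
                exp = oracle.naive_gldm(levels, alpha=alpha)
                assert np.allclose(got[: exp.shape[0]], exp)

    def test_feature_names(self):
        f = rf.gldm_features(_droi(random_levels(np.random.default_rng(1)), ng=4))
        assert tuple(f) == rf.GLDM_FEATURES


class TestNGTDM:
    def test_constant_roi_zero_contrast(self):
        f = rf.ngtdm_features(_droi(np.ones((4, 4, 2)), ng=1))
        assert f["contrast"] == 0.0

    def test_matches_oracle_on_random_grids(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            levels = random_levels(rng, shape=(3, 3, 3))
            n, p, s, nv = rf.ngtdm_table(_droi(levels, ng=4))
            n2, p2, s2, nv2 = oracle.naive_ngtdm(levels, 4)
            assert np.allclose(n, n2) and np.allclose(s, s2) and nv == nv2

    def test_coarseness_drops_with_frequency(self):
        slow = (np.indices((8, 8, 2))[0] // 4 % 2 + 1).astype(np.int32)
        fast = (np.indices((8, 8, 2)).sum(axis=0) % 2 + 1).astype(np.int32)
        f_slow = rf.ngtdm_features(_droi(slow, ng=2))
        f_fast = rf.ngtdm_features(_droi(fast, ng=2))
        assert f_fast["coarseness"] < f_slow["coarseness"]


class TestExtractAll:
    def test_572_features_and_family_counts(self, phantom_rois, phantom):
        phases, tumor, band = phantom_rois
        vec = rf.extract_all(phases, tumor, band, phantom.series.spacing)
        assert len(vec) == 572
        assert np.isfinite(vec.to_numpy()).all()
        names = list(vec.index)
        assert sum(n.startswith("tumor_shape_") for n in names) == 14
        for region in ("tumor", "stroma"):
            for phase in ("S0", "SI", "SL"):
                block = [n for n in names if n.startswith(f"{region}_{phase}_")]
                assert len(block) == 93
                counts = {
                    fam: sum(f"_{fam}_" in n for n in block)
                    for fam in ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")
                }
                assert counts == {
                    "firstorder": 18, "glcm": 24, "glrlm": 16,
                    "glszm": 16, "gldm": 14, "ngtdm": 5,
                }

    def test_region_swap_permutes_blocks_but_not_shape(self, phantom_rois, phantom):
        phases, tumor, band = phantom_rois
        spacing = phantom.series.spacing
        a = rf.extract_all(phases, tumor, band, spacing)
        b = rf.extract_all(phases, band, tumor, spacing)
        assert a["tumor_S0_firstorder_mean"] == b["stroma_S0_firstorder_mean"]
        assert a["stroma_SI_glcm_idmn"] == b["tumor_SI_glcm_idmn"]
        # shape features follow the tumor-mask argument
        assert a["tumor_shape_mesh_volume"] != b["tumor_shape_mesh_volume"]

    def test_schema_is_stable(self):
        names = rf.feature_names()
        assert len(names) == 572
        assert len(set(names)) == 572
        assert names == rf.feature_names()

    def test_heterogeneous_tumor_has_lower_idmn(self):
        """A more heterogeneous texture lowers GLCM homogeneity (IDMN), the
        ordering seen between good- and poor-survival example tumors."""
        from radiotsh import image_prep
        from radiotsh import synthetic_data as sd

        vals = {}
        for name, sigma_mm in (("homogeneous", 4.0), ("heterogeneous", 0.6)):
            ph = sd.generate_phantom(
                sd.PhantomConfig(
                    shape=(48, 48, 10),
                    tumor_radii_mm=(7, 7, 5),
                    texture_sigma_mm=sigma_mm,
                    tumor_texture_amplitude=0.2,
                    noise_sd=0.0,
                    seed=9,
                )
            )
            phases = image_prep.derive_phases(ph.series)
            droi = rf.discretize(phases.s0, ph.tumor_mask, 32)
            vals[name] = rf.glcm_features(droi)["idmn"]
        assert vals["homogeneous"] > vals["heterogeneous"]
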