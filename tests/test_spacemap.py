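import numpy as np
import pandas as pd
import pytest

from flspace.spacemap import (
    ChemicalSpacePCA,
    Pixel,
    _hue,
    average_molecule,
    colour_pixels,
    export_map,
    fit_pca,
    rasterize,
)


def pad42(cols: np.ndarray) -> np.ndarray:
    """Embed a small matrix into 42 columns (MQN width)."""
    out = np.zeros((cols.shape[0], 42))
    out[:, : cols.shape[1]] = cols
    return out


class TestFit:
    def test_one_dimensional_data_gives_full_pc1(self):
        X = pad42(np.array([[0.0], [2.0], [4.0]]))
        model = fit_pca(X)
        assert model.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, decoy_mqns):
        model = fit_pca(decoy_mqns[:500])
        gram = model.components_ @ model.components_.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_variance_fractions_non_increasing(self, decoy_mqns):
        model = fit_pca(decoy_mqns[:500])
        evr = model.explained_variance_ratio_
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-9 and (evr >= 0).all()

    def test_sign_convention_positive_loading_sums(self, decoy_mqns):
        model = fit_pca(decoy_mqns[:500])
        assert (model.components_.sum(axis=1) >= 0).all()

    def test_size_dominated_pc1(self, decoy_mqns):
        # on MQN count data PC1 tracks molecular size: it dominates the
        # variance and loads positively on the size descriptors
        model = fit_pca(decoy_mqns[:2000])
        assert model.explained_variance_ratio_[0] > 0.5
        names = list(__import__("flspace.mqn", fromlist=["MQN_NAMES"]).MQN_NAMES)
        for key in ("hac", "c", "asb", "adv"):
            assert model.components_[0][names.index(key)] > 0

    def test_known_three_factor_model_recovered(self):
        rng = np.random.default_rng(42)
        # three orthogonal planted directions with decreasing variance
        basis, _ = np.linalg.qr(rng.normal(size=(42, 3)))
        sds = np.array([8.0, 4.0, 2.0])
        scores = rng.normal(size=(500, 3)) * sds
        X = np.rint(scores @ basis.T + 20)
        model = fit_pca(X)
        expected = sds**2 / (sds**2).sum()
        # integer rounding adds isotropic noise, so compare within 0.05
        assert np.allclose(model.explained_variance_ratio_[:3], expected, atol=0.05)

    def test_rank_deficient_input_is_error(self):
        X = pad42(np.ones((5, 1)))  # all rows identical
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X)


class TestProject:
    def test_reference_mean_projects_to_origin(self, decoy_mqns):
        model = fit_pca(decoy_mqns[:300])
        origin = model.transform(decoy_mqns[:300].mean(axis=0, keepdims=True))
        assert np.allclose(origin, 0.0, atol=1e-9)

    def test_refit_free_projection_identity(self, decoy_mqns):
        """Variance fractions of the projected reference equal the model's."""
        X = decoy_mqns[:300].astype(float)
        model = fit_pca(X)
        proj = model.transform(X)
        total_var = (X - X.mean(0)).var(axis=0, ddof=0).sum()
        refit = proj.var(axis=0, ddof=0) / total_var
        assert np.allclose(refit, model.explained_variance_ratio_, atol=1e-8)

    def test_two_point_hand_computed_projection(self):
        X = pad42(np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]]))
        model = fit_pca(X)
        # hand linear algebra: centered row (1, 1, 0, ...) dotted with loadings
        row = pad42(np.array([[2.0, 2.0]]))
        expected = (row[0] - X.mean(0)) @ model.components_.T
        assert np.allclose(model.transform(row)[0], expected)

    def test_save_load_roundtrip(self, decoy_mqns, tmp_path):
        model = fit_pca(decoy_mqns[:200])
        model.save(tmp_path / "pca.json")
        loaded = ChemicalSpacePCA.load(tmp_path / "pca.json")
        assert np.allclose(
            model.transform(decoy_mqns[:50]), loaded.transform(decoy_mqns[:50])
        )


class TestRasterize:
    def test_single_molecule_single_pixel(self):
        pm = rasterize(np.array([[0.3, -0.2]]), ["m1"], grid_size=100)
        assert pm.occupied == 1
        assert next(iter(pm.pixels.values())).members == ["m1"]

    def test_identical_points_share_a_pixel(self):
        pm = rasterize(np.array([[1.0, 1.0], [1.0, 1.0]]), ["a", "b"], grid_size=50)
        assert pm.occupied == 1

    def test_range_extremes_map_to_border_pixels(self):
        ranges = np.array([[0.0, 1.0], [0.0, 1.0]])
        pm = rasterize(
            np.array([[0.0, 0.0], [1.0, 1.0], [2.0, -1.0]]),
            ["lo", "hi", "out"],
            grid_size=1000,
            ranges=ranges,
        )
        assert (0, 0) in pm.pixels and (999, 999) in pm.pixels
        # out-of-range points clamp to the border
        assert pm.pixels[(999, 0)].members == ["out"]

    def test_every_molecule_in_exactly_one_pixel(self, decoy_mqns):
        model = fit_pca(decoy_mqns[:400])
        proj = model.transform(decoy_mqns[:400])
        pm = rasterize(proj, [f"d{i}" for i in range(400)], grid_size=200)
        assert sum(px.count for px in pm.pixels.values()) == 400


class TestAverageMolecule:
    def test_single_member_pixel(self):
        rows = np.array([[1, 2, 3]])
        px = Pixel(members=["only"], rows=[0])
        assert average_molecule(px, rows) == "only"

    def test_symmetric_pair_tie_breaks_to_lower_id(self):
        rows = np.array([[0, 0], [2, 2]])
        px = Pixel(members=["b", "a"], rows=[0, 1])
        assert average_molecule(px, rows) == "a"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 12, size=(50, 42))
        ids = [f"m{i:02d}" for i in range(50)]
        px = Pixel(members=ids, rows=list(range(50)))
        centre = rows.mean(axis=0)
        dists = np.abs(rows - centre).sum(axis=1)
        best = min(zip(dists, ids))[1]
        assert average_molecule(px, rows) == best


class TestColour:
    def test_single_member_pixel_full_saturation(self):
        pm = rasterize(
            np.array([[0.0, 0.0], [1.0, 1.0], [1.01, 1.0]]), ["a", "b", "c"],
            grid_size=4,
        )
        colour_pixels(pm, {"a": 1.0, "b": 5.0, "c": 9.0})
        lone = pm.pixels[(0, 0)]
        assert lone.sd == 0.0 and lone.hsl[1] == 1.0

    def test_minimum_mean_is_blue_and_hue_monotone(self):
        pm = rasterize(
            np.array([[0.0, 0.0], [0.5, 0.5], [1.0, 1.0]]), ["lo", "mid", "hi"],
            grid_size=8,
        )
        colour_pixels(pm, {"lo": 0.0, "mid": 5.0, "hi": 10.0})
        by_mean = sorted(pm.pixels.values(), key=lambda p: p.mean)
        assert by_mean[0].hsl[0] == pytest.approx(240.0)  # blue
        # midpoint of the path sits between green (120) and yellow (60)
        assert by_mean[1].hsl[0] == pytest.approx(90.0)
        assert by_mean[2].hsl[0] == pytest.approx(300.0)  # magenta at max

    def test_hue_path_passes_through_orange(self):
        # between yellow (60) and red (0) the path crosses orange (30)
        assert _hue(0.7) == pytest.approx(30.0, abs=1e-9)

    def test_saturation_fades_with_sd(self):
        proj = np.array([[0.0, 0.0], [0.001, 0.0], [1.0, 1.0], [1.001, 1.0]])
        pm = rasterize(proj, ["a1", "a2", "b1", "b2"], grid_size=2)
        colour_pixels(pm, {"a1": 0.0, "a2": 8.0, "b1": 4.0, "b2": 5.0})
        spread = {px.sd: px.hsl[1] for px in pm.pixels.values()}
        assert spread[max(spread)] < spread[min(spread)]


class TestExport:
    def test_roundtrip_and_counts(self, tmp_path, decoy_mqns):
        model = fit_pca(decoy_mqns[:200])
        proj = model.transform(decoy_mqns[:200])
        ids = [f"d{i}" for i in range(200)]
        pm = rasterize(proj, ids, decoy_mqns[:200], grid_size=100)
        colour_pixels(pm, dict(zip(ids, decoy_mqns[:200, 11].astype(float))))
        png, tsv = tmp_path / "map.png", tmp_path / "map.tsv"
        export_map(pm, png, tsv)
        table = pd.read_csv(tsv, sep="\t")
        assert len(table) == pm.occupied
        for _, row in table.head(20).iterrows():
            assert pm.pixels[(row.x, row.y)].hex_colour == row.colour
        from PIL import Image

        assert Image.open(png).size == (100, 100)

    def test_empty_map_exports_header_only(self, tmp_path):
        pm = rasterize(np.zeros((0, 2)), [], grid_size=10)
        export_map(pm, tmp_path / "e.png", tmp_path / "e.tsv")
        table = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert len(table) == 0
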