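"""Generators: point patterns, lesions, tiles, SC profiles, IOP series."""

import numpy as np
import pytest

from retinaquant.cellmap import CellMap
from retinaquant.geometry import RetinaGeometry, cell_angles_deg
from retinaquant.synthetic import (
    FrameGrid,
    LesionSpec,
    PopulationSpec,
    SCProfileSpec,
    apply_lesion,
    default_spec,
    generate_iop_series,
    generate_population,
    generate_sc_profile,
    render_tiles,
    section_bregmas,
)

from conftest import uniform_disc_cells


class TestGeneratePopulation:
    def test_zero_target_gives_empty_map(self, geom):
        spec = PopulationSpec(target_total=0, seed=1)
        assert len(generate_population(geom, spec)) == 0

    def test_realized_count_near_target(self, geom):
        spec = default_spec("OHSt", seed=42)
        n = len(generate_population(geom, spec))
        assert abs(n - 38_479) <= 3 * np.sqrt(38_479)

    def test_fixed_seed_bit_identical(self, geom):
        spec = PopulationSpec(target_total=5000, seed=7)
        a = generate_population(geom, spec)
        b = generate_population(geom, spec)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_all_points_inside_disc(self, geom):
        cells = generate_population(geom, PopulationSpec(target_total=20_000, seed=3))
        assert np.all(np.hypot(cells.x, cells.y) <= geom.radius_mm)

    def test_uniform_profile_density_matches_histogram_oracle(self, geom):
        """Mean binned density of a uniform pattern equals target/area,
        checked against a direct count-per-bin / bin-area oracle."""
        spec = PopulationSpec(target_total=10_000, density_profile="uniform", seed=11)
        cells = generate_population(geom, spec)
        R = geom.radius_mm
        edges = np.linspace(-R, R, 12)
        counts, _, _ = np.histogram2d(cells.x, cells.y, bins=[edges, edges])
        bin_w = edges[1] - edges[0]
        # interior bins fully inside the disc
        cx = 0.5 * (edges[:-1] + edges[1:])
        XX, YY = np.meshgrid(cx, cx, indexing="ij")
        corner = np.hypot(np.abs(XX) + bin_w / 2, np.abs(YY) + bin_w / 2)
        interior = corner <= R
        dens = counts[interior] / bin_w**2
        expected = 10_000 / geom.area_mm2
        assert np.mean(dens) == pytest.approx(expected, rel=0.05)

    def test_radial_profile_denser_at_centre(self, geom):
        cells = generate_population(geom, default_spec("OHSt", seed=5))
        r = np.hypot(cells.x, cells.y)
        inner = np.sum(r < 1.1) / (np.pi * 1.1**2)
        outer = np.sum(r >= 1.1) / (np.pi * (2.2**2 - 1.1**2))
        assert inner > 1.2 * outer

    def test_melanopsin_dorsotemporal_enrichment(self, geom):
        spec = default_spec("melanopsin", seed=9)
        spec = PopulationSpec(**{**spec.__dict__, "target_total": 20_000})
        cells = generate_population(geom, spec)
        a = cell_angles_deg(cells.x, cells.y)
        dorsotemporal = np.sum((a >= 0) & (a < 90))
        opposite = np.sum((a >= 180) & (a < 270))
        assert dorsotemporal > 1.3 * opposite

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(target_total=-1)
        with pytest.raises(ValueError):
            PopulationSpec(density_profile="bogus")
        with pytest.raises(ValueError):
            PopulationSpec(centre_edge_ratio=0.5)

    def test_mean_count_over_replicates(self, geom):
        """Realised counts over 200 replicates average within 2% of the
        target (uniform profile, target 10,000)."""
        totals = [
            len(generate_population(geom, PopulationSpec(
                target_total=10_000, density_profile="uniform", seed=s)))
            for s in range(200)
        ]
        assert np.mean(totals) == pytest.approx(10_000, rel=0.02)


class TestApplyLesion:
    def test_identity_lesion(self):
        cells = uniform_disc_cells(1000, seed=1)
        out = apply_lesion(cells, LesionSpec(), seed=2)
        np.testing.assert_array_equal(out.x, cells.x)
        np.testing.assert_array_equal(out.y, cells.y)

    def test_total_ablation(self):
        cells = uniform_disc_cells(1000, seed=1)
        out = apply_lesion(cells, LesionSpec(wedges=((0.0, 360.0, 1.0),)), seed=2)
        assert len(out) == 0

    def test_survivors_are_subset_with_unmoved_coordinates(self):
        cells = uniform_disc_cells(5000, seed=3)
        out = apply_lesion(
            cells, LesionSpec(wedges=((30.0, 120.0, 0.7),), diffuse_fraction=0.2), seed=4
        )
        original = set(zip(cells.x.tolist(), cells.y.tolist()))
        assert all((x, y) in original for x, y in zip(out.x, out.y))
        assert len(out) < len(cells)

    def test_quarter_wedge_binomial_survival(self):
        """One fully ablated 90° wedge on a uniform pattern leaves a
        surviving fraction ~0.75 (binomial expectation; wedge membership
        verified by an exact angle-count oracle)."""
        cells = uniform_disc_cells(38_000, seed=5)
        lesion = LesionSpec(wedges=((0.0, 90.0, 1.0),))
        out = apply_lesion(cells, lesion, seed=6)
        frac = len(out) / len(cells)
        sd = np.sqrt(0.75 * 0.25 / 38_000)
        # oracle: exact count of cells outside the wedge
        a = cell_angles_deg(cells.x, cells.y)
        outside = np.sum(~((a >= 0) & (a < 90)))
        assert len(out) == outside  # f=1.0 removal is deterministic
        assert abs(frac - 0.75) <= 3 * sd + 0.01

    def test_overlapping_wedges_compose(self):
        cells = uniform_disc_cells(40_000, seed=7)
        lesion = LesionSpec(wedges=((0.0, 90.0, 0.5), (0.0, 90.0, 0.5)))
        out = apply_lesion(cells, lesion, seed=8)
        # combined in-wedge loss 1 - 0.5*0.5 = 0.75 -> survival 1 - 0.25*0.75
        expected = 1.0 - 0.25 * 0.75
        assert len(out) / len(cells) == pytest.approx(expected, abs=0.01)

    def test_reproducible_under_seed(self):
        cells = uniform_disc_cells(2000, seed=9)
        lesion = LesionSpec(wedges=((10.0, 45.0, 0.6),), diffuse_fraction=0.3)
        a = apply_lesion(cells, lesion, seed=10)
        b = apply_lesion(cells, lesion, seed=10)
        np.testing.assert_array_equal(a.x, b.x)

    def test_invalid_lesions_rejected(self):
        with pytest.raises(ValueError):
            LesionSpec(wedges=((0.0, 0.0, 0.5),))
        with pytest.raises(ValueError):
            LesionSpec(wedges=((0.0, 90.0, 1.5),))
        with pytest.raises(ValueError):
            LesionSpec(diffuse_fraction=-0.1)


class TestRenderTiles:
    def test_empty_cellmap_background_only(self):
        grid = FrameGrid(rows=1, cols=1)
        ts = render_tiles(CellMap(x=[], y=[]), grid, noise_model="none", seed=0)
        tile = ts.frame(0, 0)
        assert np.all(tile == tile.flat[0])  # constant background

    def test_separated_noiseless_blobs_are_local_maxima(self):
        rng = np.random.default_rng(1)
        grid = FrameGrid(rows=1, cols=1, origin_mm=(0.0, 0.34))
        # 50 cells on a jittered lattice, >= 10 px apart, away from edges
        gx, gy = np.meshgrid(np.arange(10), np.arange(5))
        x = 0.03 + gx.ravel() * 0.04 + rng.uniform(-0.004, 0.004, 50)
        y = 0.34 - (0.03 + gy.ravel() * 0.05 + rng.uniform(-0.004, 0.004, 50))
        ts = render_tiles(CellMap(x=x, y=y), grid, noise_model="none", seed=0)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(ts.frame(0, 0).astype(float), min_distance=3,
                               threshold_abs=150)
        assert peaks.shape[0] == 50

    def test_frame_tiling_exact_partition(self):
        grid = FrameGrid(rows=3, cols=4)
        h, w = grid.frame_px
        assert grid.montage_px == (3 * h, 4 * w)
        cells = CellMap(x=[0.1], y=[0.1])
        ts = render_tiles(cells, FrameGrid(rows=2, cols=2, origin_mm=(0.0, 0.68)), seed=1)
        # union of frames reassembles the full canvas exactly (no gap or
        # overlap): total pixel count equals the montage pixel count
        total = sum(t.size for t in ts.tiles.values())
        assert total == np.prod(ts.grid.montage_px)

    def test_rejects_bad_inputs(self):
        grid = FrameGrid(rows=1, cols=1)
        with pytest.raises(ValueError):
            render_tiles(CellMap(x=[], y=[]), grid, psf_sigma_px=0.0)
        with pytest.raises(ValueError):
            render_tiles(CellMap(x=[9.0], y=[0.0]), grid)  # outside region

    def test_ground_truth_sidecar_retained(self):
        grid = FrameGrid(rows=1, cols=1, origin_mm=(0.0, 0.34))
        cells = CellMap(x=[0.1, 0.2], y=[0.1, 0.2])
        ts = render_tiles(cells, grid, seed=3)
        np.testing.assert_array_equal(ts.ground_truth.x, cells.x)


class TestSCProfile:
    def test_constant_baseline(self):
        spec = SCProfileSpec(baseline_area_fn=lambda b: np.full_like(np.asarray(b, float), 0.8))
        df = generate_sc_profile(spec)
        assert np.allclose(df["area_mm2"], 0.8)
        assert df["bregma_mm"].iloc[0] == pytest.approx(-3.08)
        assert np.allclose(np.diff(df["bregma_mm"]), -0.030)

    def test_patch_halves_integral(self):
        base = lambda b: np.full_like(np.asarray(b, float), 0.8)
        full = generate_sc_profile(SCProfileSpec(baseline_area_fn=base))
        lo, hi = -4.72, -3.08
        mid = 0.5 * (lo + hi)
        patched = generate_sc_profile(
            SCProfileSpec(baseline_area_fn=base, patches=((lo - 1, mid, 1.0),))
        )
        ratio = patched["area_mm2"].sum() / full["area_mm2"].sum()
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_unusable_sections_flagged(self):
        spec = SCProfileSpec(unusable_sections=(3, 7, 10))
        df = generate_sc_profile(spec)
        assert (~df["usable"]).sum() == 3
        assert not df.loc[3, "usable"]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SCProfileSpec(bregma_range=(-3.0, -3.0))
        with pytest.raises(ValueError):
            SCProfileSpec(section_thickness_mm=0.0)
        with pytest.raises(ValueError):
            SCProfileSpec(patches=((-4.0, -3.5, 1.5),))


class TestIOPSeries:
    def test_max_at_peak_time(self):
        df = generate_iop_series(30.0, peak_time_h=24.0, baseline_mmHg=15.0, seed=1)
        assert df.loc[df["iop_mmHg"].idxmax(), "time_h"] == 24.0
        assert df["iop_mmHg"].max() == pytest.approx(30.0)

    def test_low_peak_never_exceeds_inclusion_threshold(self):
        for seed in range(10):
            df = generate_iop_series(20.0, seed=seed)
            assert df["iop_mmHg"].max() <= 25.0

    def test_reproducible_and_validated(self):
        a = generate_iop_series(28.0, seed=5)
        b = generate_iop_series(28.0, seed=5)
        np.testing.assert_array_equal(a["iop_mmHg"], b["iop_mmHg"])
        with pytest.raises(ValueError):
            generate_iop_series(-1.0)
        with pytest.raises(ValueError):
            generate_iop_series(30.0, peak_time_h=999.0)
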