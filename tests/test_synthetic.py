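"""Generator tests: geometry, zone placement, rendering semantics and
seeded determinism."""

import numpy as np
import pytest
from scipy import ndimage

from lamina.synthetic import (
    SyntheticConfig,
    _normalised_radius,
    generate,
    generate_cohort,
    make_aggregate_mask,
    place_cells,
    render_image,
)
from tests.conftest import small_config


class TestMakeAggregateMask:
    def test_unperturbed_circle_area(self):
        cfg = small_config(shape_perturbation=0.0, aggregate_radius=50.0)
        mask = make_aggregate_mask(cfg)
        expected = np.pi * 50.0**2
        assert abs(mask.area - expected) / expected < 0.02

    def test_single_component_no_holes(self):
        for seed in (0, 1, 2):
            mask = make_aggregate_mask(small_config(seed=seed, shape_perturbation=0.15))
            _, n = ndimage.label(mask.mask)
            assert n == 1
            assert ndimage.binary_fill_holes(mask.mask).sum() == mask.area

    def test_seed_determinism(self):
        cfg = small_config(seed=7)
        a = make_aggregate_mask(cfg)
        b = make_aggregate_mask(small_config(seed=7))
        assert np.array_equal(a.mask, b.mask)

    def test_oversized_aggregate_rejected(self):
        with pytest.raises(ValueError, match="image_size"):
            make_aggregate_mask(small_config(aggregate_radius=130.0))

    def test_boundary_stays_within_perturbation_budget(self):
        cfg = small_config(shape_perturbation=0.1, seed=3)
        mask = make_aggregate_mask(cfg)
        c = (cfg.image_size - 1) / 2.0
        rows, cols = np.nonzero(mask.mask)
        rho = np.hypot(rows - c, cols - c)
        assert rho.max() <= cfg.aggregate_radius * 1.1 + 1.0


class TestPlaceCells:
    def test_counts_conserved(self):
        cfg = small_config(n_cells_per_class={"CFP": 10, "GFP_RFP": 10, "RFP": 10, "CFP_RFP": 10})
        mask = make_aggregate_mask(cfg)
        cells = place_cells(mask, cfg)
        assert len(cells) == 40
        assert cells["cell_class"].value_counts().to_dict() == {
            "CFP": 10, "GFP_RFP": 10, "RFP": 10, "CFP_RFP": 10
        }

    def test_centres_inside_mask(self):
        cfg = small_config()
        mask = make_aggregate_mask(cfg)
        cells = place_cells(mask, cfg)
        rows = np.round(cells["y"]).astype(int)
        cols = np.round(cells["x"]).astype(int)
        assert mask.mask[rows, cols].all()

    def test_fully_laminated_cfp_cells_in_inner_zone(self):
        cfg = small_config(organization=1.0)
        mask = make_aggregate_mask(cfg)
        cells = place_cells(mask, cfg)
        nr, _ = _normalised_radius(mask.mask)
        cfp = cells[cells["cell_class"].isin(["CFP", "CFP_RFP"])]
        rows = np.round(cfp["y"]).astype(int)
        cols = np.round(cfp["x"]).astype(int)
        assert (nr[rows, cols] < cfg.r_inner + 0.02).all()

    def test_unorganized_cfp_matches_zone_area_fraction(self):
        """At lambda=0 the fraction of CFP cells landing in the inner
        zone equals the zone's pixel-area fraction, to within 3 sd of
        the binomial expectation."""
        n = 2000
        cfg = small_config(
            organization=0.0,
            n_cells_per_class={"CFP": n, "GFP_RFP": 0, "RFP": 0, "CFP_RFP": 0},
            seed=5,
        )
        mask = make_aggregate_mask(cfg)
        nr, _ = _normalised_radius(mask.mask)
        p = (nr[mask.mask] < cfg.r_inner).mean()  # zone area fraction
        cells = place_cells(mask, cfg)
        rows = np.round(cells["y"]).astype(int)
        cols = np.round(cells["x"]).astype(int)
        k = (nr[rows, cols] < cfg.r_inner).sum()
        sd = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 3 * sd

    def test_zero_area_zone_raises(self):
        cfg = small_config(r_inner=0.001, r_outer=0.002)
        mask = make_aggregate_mask(cfg)
        with pytest.raises(ValueError, match="zone"):
            place_cells(mask, cfg)


class TestRenderImage:
    def test_no_cells_no_noise_gives_flat_background(self):
        cfg = small_config(
            n_cells_per_class={"CFP": 0, "GFP_RFP": 0, "RFP": 0, "CFP_RFP": 0},
            noise={"gaussian_sigma": 0.0, "poisson_gain": 0.0},
            dapi_tissue_level=0.0,
        )
        mask = make_aggregate_mask(cfg)
        cells = place_cells(mask, cfg)
        stack = render_image(cells, mask, cfg)
        for ch in ("CFP", "GFP", "RFP", "DAPI"):
            assert np.allclose(stack[ch], cfg.background_level)

    def test_channel_semantics_single_cfp_cell(self):
        cfg = small_config(
            n_cells_per_class={"CFP": 1, "GFP_RFP": 0, "RFP": 0, "CFP_RFP": 0},
            noise={"gaussian_sigma": 0.0, "poisson_gain": 0.0},
            dapi_tissue_level=0.0,
        )
        mask = make_aggregate_mask(cfg)
        cells = place_cells(mask, cfg)
        stack = render_image(cells, mask, cfg)
        assert np.allclose(stack["GFP"], cfg.background_level)
        peak = np.unravel_index(np.argmax(stack["CFP"]), stack.shape)
        assert abs(peak[0] - cells["y"].iloc[0]) <= 1
        assert abs(peak[1] - cells["x"].iloc[0]) <= 1
        # the cell is DAPI-positive too
        assert stack["DAPI"].max() > cfg.background_level

    def test_rpe_core_dark_in_fluorescence_not_dapi(self):
        cfg = small_config(rpe_core=True, core_radius_fraction=0.2,
                           noise={"gaussian_sigma": 0.0, "poisson_gain": 0.0})
        stack, mask, cells = generate(cfg)
        c = (cfg.image_size - 1) / 2.0
        yy, xx = np.mgrid[0:cfg.image_size, 0:cfg.image_size]
        core = np.hypot(yy - c, xx - c) <= 0.5 * cfg.core_radius_fraction * cfg.aggregate_radius
        for ch in ("CFP", "GFP", "RFP"):
            assert np.allclose(stack[ch][core], cfg.background_level)
        assert stack["DAPI"][core].mean() > cfg.background_level

    def test_render_determinism(self):
        cfg = small_config(seed=9)
        a, _, _ = generate(cfg)
        b, _, _ = generate(small_config(seed=9))
        for ch in a.channel_names:
            assert np.array_equal(a[ch], b[ch])

    def test_outputs_nonnegative(self, small_aggregate):
        stack, _, _ = small_aggregate
        for ch in stack.channel_names:
            assert stack[ch].min() >= 0


class TestGenerateCohort:
    def test_cohort_size_and_independence(self):
        cfg = small_config(seed=4)
        cohort = generate_cohort(cfg, 3)
        assert len(cohort) == 3
        a, b = cohort[0][0], cohort[1][0]
        assert not np.array_equal(a["DAPI"], b["DAPI"])

    def test_different_root_seeds_differ(self):
        a = generate_cohort(small_config(seed=1), 1)[0][0]
        b = generate_cohort(small_config(seed=2), 1)[0][0]
        assert not np.array_equal(a["DAPI"], b["DAPI"])

    def test_cohort_reproducible(self):
        a = generate_cohort(small_config(seed=6), 2)
        b = generate_cohort(small_config(seed=6), 2)
        for (sa, ma, _), (sb, mb, _) in zip(a, b):
            assert np.array_equal(ma.mask, mb.mask)
            for ch in sa.channel_names:
                assert np.array_equal(sa[ch], sb[ch])

    def test_single_item_cohort_matches_derived_seed(self):
        from lamina.synthetic import cohort_seeds, generate

        cfg = small_config(seed=8)
        cohort = generate_cohort(cfg, 1)
        derived = cohort_seeds(8, 1)[0]
        direct = generate(small_config(seed=derived))
        assert np.array_equal(cohort[0][0]["DAPI"], direct[0]["DAPI"])

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(small_config(), 0)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(organization=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(r_inner=0.9, r_outer=0.5)
    with pytest.raises(ValueError):
        SyntheticConfig(n_cells_per_class={"CFP": -1})
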