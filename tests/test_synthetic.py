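"""Synthetic-data generators: label geometry, fields, conservation, noise."""

import numpy as np
import pandas as pd
import pytest

from prrtdose.grids import LABEL_TUMOR
from prrtdose.kinetics import dose_rate
from prrtdose.synthetic import (
    CostainedSection,
    TissuePhantomSpec,
    correlated_field,
    default_ground_truth,
    generate_activity_map,
    generate_biodistribution,
    generate_costained_section,
    generate_foci_series,
    generate_tissue,
    generate_volume_curve,
)

SMALL = dict(grid_shape=(24, 24, 16), voxel_size_um=(20.0, 20.0, 20.0),
             expression_correlation_length_um=60.0)


def autocorrelation_length(field: np.ndarray, spacing_um: float) -> float:
    """Oracle estimator: radially averaged FFT autocorrelation, e^{-1/2} lag."""
    f = field - field.mean()
    spec = np.abs(np.fft.fftn(f)) ** 2
    acf = np.fft.ifftn(spec).real
    acf /= acf.flat[0]
    shape = field.shape
    grids = np.meshgrid(*[np.minimum(np.arange(n), n - np.arange(n)) for n in shape],
                        indexing="ij")
    r = np.sqrt(sum(g.astype(float) ** 2 for g in grids)) * spacing_um
    r_flat, a_flat = r.ravel(), acf.ravel()
    bins = np.arange(0.0, r.max() / 2, spacing_um)
    idx = np.digitize(r_flat, bins)
    prof = np.array([a_flat[idx == i].mean() for i in range(1, len(bins))])
    centers = 0.5 * (bins[:-1] + bins[1:])
    target = np.exp(-0.5)
    below = np.nonzero(prof < target)[0]
    i = below[0]
    # linear interpolation across the crossing
    x0, x1 = centers[i - 1], centers[i]
    y0, y1 = prof[i - 1], prof[i]
    return x0 + (target - y0) / (y1 - y0) * (x1 - x0)


class TestTissue:
    def test_full_tumor_fraction_labels_every_tissue_voxel(self):
        grid = generate_tissue(TissuePhantomSpec(tumor_fraction=1.0, seed=1, **SMALL))
        assert np.all(grid.labels[grid.tissue_mask] == LABEL_TUMOR)

    @pytest.mark.parametrize("frac", [0.0, 0.5, 0.94, 0.97])
    def test_tumor_fraction_matches_within_one_voxel(self, frac):
        grid = generate_tissue(TissuePhantomSpec(tumor_fraction=frac, seed=2, **SMALL))
        n_tissue = grid.tissue_mask.sum()
        assert abs(grid.tumor_mask.sum() - frac * n_tissue) <= 1.0

    def test_fixed_seed_reproducible(self):
        spec = TissuePhantomSpec(seed=7, **SMALL)
        g1, g2 = generate_tissue(spec), generate_tissue(spec)
        np.testing.assert_array_equal(g1.labels, g2.labels)
        np.testing.assert_array_equal(g1.expression, g2.expression)

    def test_expression_positive_inside_tissue_zero_outside(self):
        grid = generate_tissue(TissuePhantomSpec(seed=3, tissue_fill=0.8, **SMALL))
        assert np.all(grid.expression[grid.tissue_mask] > 0)
        assert not grid.expression[~grid.tissue_mask].any()

    @pytest.mark.parametrize(
        "bad",
        [dict(grid_shape=(0, 8, 8)), dict(voxel_size_um=(0.0, 5.0, 5.0)),
         dict(tumor_fraction=1.5), dict(expression_correlation_length_um=-1.0)],
    )
    def test_invalid_specs_rejected(self, bad):
        kwargs = {**SMALL, **bad}
        with pytest.raises(ValueError):
            TissuePhantomSpec(seed=0, **kwargs)

    def test_field_correlation_length_within_25_percent(self):
        """50 μm requested on a 128³ grid; empirical radial ACF agrees."""
        field = correlated_field((128, 128, 128), (5.7, 5.7, 5.7), 50.0, seed=12)
        est = autocorrelation_length(field, 5.7)
        assert est == pytest.approx(50.0, rel=0.25)


class TestActivity:
    @pytest.fixture()
    def grid(self):
        return generate_tissue(TissuePhantomSpec(tumor_fraction=0.9, seed=4, **SMALL))

    def test_conserves_total_exactly(self, grid):
        amap = generate_activity_map(grid, 1e6, specificity=0.7)
        assert amap.total == pytest.approx(1e6, rel=1e-9)

    def test_fully_specific_activity_only_in_tumor(self, grid):
        amap = generate_activity_map(grid, 1e6, specificity=1.0)
        assert not amap.values[~grid.tumor_mask].any()
        assert amap.total == pytest.approx(1e6, rel=1e-9)

    def test_uniform_expression_gives_uniform_tumor_activity(self, grid):
        grid.expression = np.where(grid.tissue_mask, 1.0, 0.0)
        amap = generate_activity_map(grid, 1000.0, specificity=1.0)
        vals = amap.values[grid.tumor_mask]
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-15)

    def test_unspecific_only_is_uniform_over_tissue(self, grid):
        amap = generate_activity_map(grid, 500.0, specificity=0.0)
        tissue_vals = amap.values[grid.tissue_mask]
        np.testing.assert_allclose(tissue_vals, 500.0 / grid.tissue_mask.sum())
        assert not amap.values[~grid.tissue_mask].any()

    def test_negative_total_rejected(self, grid):
        with pytest.raises(ValueError):
            generate_activity_map(grid, -1.0)


class TestTimeSeries:
    def test_noiseless_biodistribution_is_exact_curve(self):
        truth = default_ground_truth()
        t = [0.0, 12.0, 48.0, 120.0]
        table = generate_biodistribution(truth, t, noise_cv=0.0)
        np.testing.assert_allclose(
            table["value_mgy_per_h"], dose_rate(truth.kinetics, np.array(t))
        )
        assert table["value_mgy_per_h"][0] == pytest.approx(truth.kinetics.r0)

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            generate_biodistribution(default_ground_truth(), [])

    def test_foci_halve_at_repair_half_life(self):
        truth = default_ground_truth()
        table = generate_foci_series(truth, [0.0, truth.t_mu_h], exact=True)
        assert table["foci_per_cell"][1] == pytest.approx(
            table["foci_per_cell"][0] / 2.0, rel=1e-12
        )

    def test_nonpositive_cells_rejected(self):
        with pytest.raises(ValueError):
            generate_foci_series(default_ground_truth(), [0.0, 1.0], n_cells=0)

    def test_volume_without_shrinkage_grows_exponentially(self):
        truth = default_ground_truth()
        truth.k1_per_d = 0.0
        truth.k2_per_d = 0.0
        t = np.linspace(0, 20, 8)
        table = generate_volume_curve(truth, t)
        np.testing.assert_allclose(
            table["volume_mm3"], truth.v0_mm3 * np.exp(truth.k0_per_d * t), rtol=1e-12
        )

    def test_noiseless_volume_refit_recovers_rates(self):
        """Closed loop: generator → growth fit, 4 significant digits."""
        from prrtdose.survival import fit_growth

        truth = default_ground_truth()
        t = np.arange(0.0, 42.1, 3.0)
        table = generate_volume_curve(truth, t)
        fit = fit_growth(table["t_d"], table["volume_mm3"], t0_d=truth.t0_d)
        assert fit.k0 == pytest.approx(truth.k0_per_d, rel=1e-4)
        assert fit.k1 == pytest.approx(truth.k1_per_d, rel=1e-4)
        assert fit.k2 == pytest.approx(truth.k2_per_d, rel=1e-4)


class TestCostainedSection:
    spec = TissuePhantomSpec(grid_shape=(64, 64, 1), voxel_size_um=(0.325, 0.325, 1.3),
                             expression_correlation_length_um=5.0, seed=0)

    def test_zero_yield_gives_zero_counts(self):
        truth = default_ground_truth()
        truth.dsb_yield_per_mgy = 0.0
        sec = generate_costained_section(self.spec, truth, np.full((64, 64), 1700.0),
                                         n_cells=200, seed=1)
        assert not sec.cells["dsb_count"].any()

    def test_uniform_dose_counts_follow_poisson_mean(self):
        truth = default_ground_truth()
        d, y, n = 1700.0, truth.dsb_yield_per_mgy, 10_000
        sec = generate_costained_section(self.spec, truth, np.full((64, 64), d),
                                         n_cells=n, seed=2)
        mean = sec.cells["dsb_count"].mean()
        se = np.sqrt(y * d / n)
        assert abs(mean - y * d) < 3 * se
        assert sec.mean_dose_mgy == pytest.approx(d)

    def test_fixed_seed_reproducible(self):
        truth = default_ground_truth()
        kw = dict(n_cells=100, seed=9)
        s1 = generate_costained_section(self.spec, truth, np.full((64, 64), 1000.0), **kw)
        s2 = generate_costained_section(self.spec, truth, np.full((64, 64), 1000.0), **kw)
        assert isinstance(s1, CostainedSection)
        np.testing.assert_array_equal(s1.image, s2.image)
        pd.testing.assert_frame_equal(s1.cells, s2.cells)

    def test_dose_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            generate_costained_section(self.spec, default_ground_truth(),
                                       np.zeros((32, 32)), seed=0)

    def test_image_is_16bit_with_positive_signal(self):
        sec = generate_costained_section(self.spec, default_ground_truth(),
                                         np.full((64, 64), 500.0), n_cells=10, seed=3)
        assert sec.image.dtype == np.uint16
        assert sec.image.max() > 0
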