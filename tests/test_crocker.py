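"""Gaussian CROCKER assembly, GCCD differencing, grid selection, fixtures."""

import numpy as np
import pytest

from gccd import (
    AlphaCarbonCloud,
    EpsilonGrid,
    ResidueDistanceScheme,
    gaussian_betti_vector,
    gaussian_crocker,
    gccd_from_crocker,
    make_chain_loop,
    make_two_chain_ring,
    rips_barcode,
    select_epsilon_grid,
)
from gccd.crocker import (
    GaussianCrockerMatrix,
    crocker_from_gccd,
    matrix_to_frame,
    read_matrix_csv,
    write_matrix_csv,
)
from gccd.errors import ParameterError, SelectionError
from gccd.filtration import euclidean_matrix
from gccd.fixtures import effective_gap, polygon_edge_length

RECONSTRUCTION_TOL = 1.0001e-10


def loop_grid(n, radius):
    """Grid kept below the polygon's second-chord scale for exact localization."""
    chord2 = 2 * radius * np.sin(2 * np.pi / n)
    return EpsilonGrid.regular(0.1, np.floor((chord2 - 0.05) * 10) / 10, 0.1)


class TestGridSelection:
    def test_single_square_bar_gives_3_to_10(self, square_cloud_side):
        # side-5 square: one loop [5, 5*sqrt(2) ~ 7.07) -> floor 5, ceil 8, buffer 2
        grid = select_epsilon_grid([square_cloud_side(5.0)], sigma_max=0.5)
        assert grid.values[0] == pytest.approx(3.0)
        assert grid.values[-1] == pytest.approx(10.0)

    def test_fc_like_births_and_deaths_give_1_to_30(self, square_cloud_side):
        # min birth 3.9 floors to 3; max death 19.6*sqrt(2) ~ 27.7 ceils to 28
        sample = [square_cloud_side(3.9), square_cloud_side(19.6)]
        grid = select_epsilon_grid(sample, sigma_max=0.5)
        assert grid.values[0] == pytest.approx(1.0)
        assert grid.values[-1] == pytest.approx(30.0)

    def test_lower_end_clamped_at_spacing(self, square_cloud_side):
        grid = select_epsilon_grid([square_cloud_side(2.0)], sigma_max=0.5)
        assert grid.values[0] >= grid.spacing

    def test_empty_sample_raises(self):
        with pytest.raises(SelectionError):
            select_epsilon_grid([], sigma_max=0.5)

    def test_all_empty_barcodes_raise(self):
        tiny = AlphaCarbonCloud(
            chain_ids=np.array(["A", "A"], dtype=object),
            residue_numbers=np.array([1, 2]),
            coords=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
        )
        with pytest.raises(SelectionError):
            select_epsilon_grid([tiny], sigma_max=0.5)


class TestCrockerAndGCCD:
    def test_first_column_is_zero_for_dimension_one(self):
        cloud = make_chain_loop(10, radius=2.0, gap=3, noise_sd=0.3, seed=5)
        grid = EpsilonGrid.regular(0.2, 3.0, 0.2)
        C = gaussian_crocker(cloud, grid, sigma=0.2)
        assert np.all(C.values[:, 0] == 0)

    def test_telescoping_reconstruction_is_exact(self):
        cloud = make_two_chain_ring(6, radius=2.0, noise_sd=0.1, seed=1)
        grid = EpsilonGrid.regular(0.2, 4.0, 0.1)
        C = gaussian_crocker(cloud, grid, sigma=0.25)
        G = gccd_from_crocker(C)
        err = np.abs(crocker_from_gccd(G).values - C.values).max()
        assert err <= RECONSTRUCTION_TOL

    def test_summed_gccd_columns_equal_full_cloud_vector(self):
        cloud = make_two_chain_ring(6, radius=2.0, noise_sd=0.1, seed=2)
        grid = EpsilonGrid.regular(0.2, 4.0, 0.1)
        sigma = 0.25
        G = gccd_from_crocker(gaussian_crocker(cloud, grid, sigma))
        cutoff = grid.values[-1] + 0.001
        full = rips_barcode(euclidean_matrix(cloud), {1}, cutoff)[1]
        independent = gaussian_betti_vector(full, grid, sigma).values
        np.testing.assert_allclose(
            G.values.sum(axis=1), independent, atol=RECONSTRUCTION_TOL
        )

    def test_incremental_and_scratch_paths_agree(self):
        cloud = make_two_chain_ring(5, radius=2.0, noise_sd=0.15, seed=4)
        grid = EpsilonGrid.regular(0.2, 4.0, 0.1)
        a = gaussian_crocker(cloud, grid, sigma=0.25, incremental=True)
        b = gaussian_crocker(cloud, grid, sigma=0.25, incremental=False)
        assert np.abs(a.values - b.values).max() <= RECONSTRUCTION_TOL

    def test_constant_crocker_gives_first_column_then_zeros(self):
        grid = EpsilonGrid.regular(0.5, 2.0, 0.5)
        col = np.array([1.0, 2.0, 0.5, 0.25])
        C = GaussianCrockerMatrix(
            grid=grid, rhos=np.arange(1, 4), sigma=0.2, dimension=1,
            values=np.column_stack([col] * 3),
        )
        G = gccd_from_crocker(C)
        np.testing.assert_allclose(G.values[:, 0], col)
        np.testing.assert_allclose(G.values[:, 1:], 0.0)

    def test_chain_order_does_not_change_matrix(self):
        ring = make_two_chain_ring(4, radius=2.0, noise_sd=0.1, seed=8)
        swapped = AlphaCarbonCloud(
            chain_ids=np.concatenate([ring.chain_ids[4:], ring.chain_ids[:4]]),
            residue_numbers=np.concatenate(
                [ring.residue_numbers[4:], ring.residue_numbers[:4]]
            ),
            coords=np.vstack([ring.coords[4:], ring.coords[:4]]),
        )
        grid = EpsilonGrid.regular(0.2, 4.0, 0.2)
        a = gaussian_crocker(ring, grid, sigma=0.25)
        b = gaussian_crocker(swapped, grid, sigma=0.25)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_cutoff_below_grid_top_rejected(self):
        cloud = make_two_chain_ring(4, radius=2.0)
        grid = EpsilonGrid.regular(0.2, 4.0, 0.2)
        with pytest.raises(ParameterError):
            gaussian_crocker(cloud, grid, sigma=0.25, cutoff=2.0)


class TestPlantedFeatures:
    @pytest.mark.parametrize("gap", [2, 4, 7])
    def test_chain_loop_mass_first_appears_at_planted_gap(self, gap):
        n, radius = 12, 2.0
        cloud = make_chain_loop(n, radius, gap=gap)
        grid = loop_grid(n, radius)
        G = gccd_from_crocker(gaussian_crocker(cloud, grid, sigma=0.1))
        col_mass = np.abs(G.values).sum(axis=0)
        g = effective_gap(gap)
        assert np.all(col_mass[: g - 1] == 0)
        assert col_mass[g - 1] > 0

    def test_chain_loop_mass_sits_at_the_loop_scale(self):
        n, radius = 12, 2.0
        cloud = make_chain_loop(n, radius, gap=4)
        grid = loop_grid(n, radius)
        G = gccd_from_crocker(gaussian_crocker(cloud, grid, sigma=0.1))
        onset_eps = grid.values[np.argmax(G.values[:, 3] >= 0.5)]
        assert onset_eps == pytest.approx(polygon_edge_length(n, radius), abs=0.1)

    def test_two_chain_ring_mass_only_in_final_column(self):
        G = gccd_from_crocker(
            gaussian_crocker(
                make_two_chain_ring(8, radius=2.0), EpsilonGrid.regular(0.1, 4.0, 0.1),
                sigma=0.25,
            )
        )
        col_mass = np.abs(G.values).sum(axis=0)
        assert np.all(col_mass[:-1] == 0)
        assert col_mass[-1] > 0

    def test_degenerate_two_point_chains_give_all_zero(self):
        ring = make_two_chain_ring(2, radius=1.0)
        grid = EpsilonGrid.regular(0.1, 1.0, 0.1)
        G = gccd_from_crocker(gaussian_crocker(ring, grid, sigma=0.1))
        assert np.abs(G.values).max() < 0.6  # at most faint capped-loop mass


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        cloud = make_two_chain_ring(4, radius=2.0, noise_sd=0.05, seed=9)
        grid = EpsilonGrid.regular(0.2, 4.0, 0.2)
        G = gccd_from_crocker(gaussian_crocker(cloud, grid, sigma=0.25))
        path = tmp_path / "gccd.csv"
        write_matrix_csv(G, path)
        back = read_matrix_csv(path, sigma=0.25)
        np.testing.assert_allclose(back.values, np.round(G.values, 10))
        np.testing.assert_allclose(back.grid.values, grid.values)

    def test_layout_rows_epsilon_columns_rho(self):
        cloud = make_two_chain_ring(4, radius=2.0)
        grid = EpsilonGrid.regular(0.2, 4.0, 0.2)
        C = gaussian_crocker(cloud, grid, sigma=0.25)
        df = matrix_to_frame(C)
        assert df.shape == (len(grid), 4)
        assert list(df.columns) == [1, 2, 3, 4]
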