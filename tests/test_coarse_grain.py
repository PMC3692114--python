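import numpy as np
import pytest

from volnma import coarse_grain as cg
from volnma import volume_io as vio
from volnma.coarse_grain import (
    FitConfig,
    PseudoAtomModel,
    approximation_error,
    fit_pseudo_atoms,
    nn_distance_histogram,
    render_model,
    suggest_cutoff,
)


def _brute_force_render(model, dims, voxel_size):
    """Untruncated direct per-voxel evaluation of the Gaussian sum."""
    grids = np.meshgrid(
        *[voxel_size * np.arange(d) for d in dims], indexing="ij"
    )
    out = np.zeros(dims)
    for i in range(model.n_atoms):
        d2 = sum((g - model.positions[i, k]) ** 2 for k, g in enumerate(grids))
        out += model.weights[i] * np.exp(-d2 / (2 * model.sigma ** 2))
    return out


class TestRender:
    def test_single_atom_center_value_is_weight(self):
        model = PseudoAtomModel([[8.0, 8.0, 8.0]], [3.7], sigma=1.5)
        vol = render_model(model, (16, 16, 16), 1.0)
        assert vol.data[8, 8, 8] == pytest.approx(3.7, rel=1e-12)

    def test_linearity_of_distant_atoms(self):
        m1 = PseudoAtomModel([[5.0, 5.0, 5.0]], [2.0], sigma=1.0)
        m2 = PseudoAtomModel([[20.0, 20.0, 20.0]], [1.5], sigma=1.0)
        both = PseudoAtomModel(
            np.vstack([m1.positions, m2.positions]), [2.0, 1.5], sigma=1.0
        )
        dims = (26, 26, 26)
        np.testing.assert_allclose(
            render_model(both, dims, 1.0).data,
            render_model(m1, dims, 1.0).data + render_model(m2, dims, 1.0).data,
            rtol=1e-12, atol=1e-15,
        )

    def test_matches_untruncated_brute_force(self):
        rng = np.random.default_rng(2)
        model = PseudoAtomModel(
            rng.uniform(3, 13, size=(6, 3)), rng.uniform(0.5, 2, 6), sigma=1.2
        )
        vol = render_model(model, (16, 16, 16), 1.0)
        ref = _brute_force_render(model, (16, 16, 16), 1.0)
        assert np.abs(vol.data - ref).max() <= 1e-3 * ref.max()

    def test_rendered_mass_matches_gaussian_integral(self):
        """Grid sum of a one-atom render ≈ w·(2π)^{3/2}·σ³/voxel³."""
        w, sigma, voxel = 2.0, 1.5, 1.0
        model = PseudoAtomModel([[12.0, 12.0, 12.0]], [w], sigma=sigma)
        vol = render_model(model, (24, 24, 24), voxel)
        expected = w * (2 * np.pi) ** 1.5 * sigma ** 3 / voxel ** 3
        assert vol.data.sum() == pytest.approx(expected, rel=1e-3)

    def test_values_nonnegative(self):
        rng = np.random.default_rng(4)
        model = PseudoAtomModel(
            rng.uniform(0, 16, size=(10, 3)), rng.uniform(0.1, 1, 10), sigma=2.0
        )
        assert (render_model(model, (16, 16, 16), 1.0).data >= 0).all()


class TestApproximationError:
    def test_exact_model_gives_zero(self):
        model = PseudoAtomModel([[8.0, 8.0, 8.0]], [5.0], sigma=2.0)
        vol = render_model(model, (16, 16, 16), 1.0)
        mask = vio.BinaryMask(np.ones((16, 16, 16), dtype=np.uint8))
        assert approximation_error(vol, model, mask) == pytest.approx(0.0, abs=1e-12)

    def test_model_far_outside_mask_gives_one(self):
        vol = render_model(
            PseudoAtomModel([[8.0, 8.0, 8.0]], [5.0], sigma=1.0), (16, 16, 16), 1.0
        )
        far = PseudoAtomModel([[1000.0, 1000.0, 1000.0]], [5.0], sigma=1.0)
        mask = vio.BinaryMask((vol.data > 1e-6).astype(np.uint8))
        assert approximation_error(vol, far, mask) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_masked_volume_errors(self):
        vol = vio.DensityVolume(np.zeros((8, 8, 8)))
        model = PseudoAtomModel([[4.0, 4.0, 4.0]], [1.0], sigma=1.0)
        with pytest.raises(ValueError, match="zero"):
            approximation_error(vol, model)


class TestFit:
    def test_recovers_single_gaussian(self):
        """A volume that is exactly one σ-Gaussian is recovered by a tiny
        model at sub-percent error."""
        gt = PseudoAtomModel([[12.0, 12.0, 12.0]], [5.0], sigma=2.0)
        vol = render_model(gt, (24, 24, 24), 1.0)
        mask = vio.BinaryMask((vol.data > 1e-8).astype(np.uint8))
        fit = fit_pseudo_atoms(
            vol, mask,
            FitConfig(sigma_voxels=2, target_error=0.01, initial_atoms=1,
                      seed=1, max_outer_iters=25),
        )
        assert fit.achieved_error < 0.01
        assert fit.n_atoms <= 2
        np.testing.assert_allclose(fit.positions[0], [12, 12, 12], atol=0.2)

    def test_termination_contract(self, fitted_phantom):
        _, _, model = fitted_phantom
        assert model.n_atoms < cg.MAX_ATOM_CAP
        assert model.achieved_error <= 0.06

    def test_reproducible_for_fixed_seed(self):
        gt = PseudoAtomModel(
            [[8.0, 8.0, 8.0], [16.0, 16.0, 16.0]], [3.0, 2.0], sigma=2.0
        )
        vol = render_model(gt, (24, 24, 24), 1.0)
        mask = vio.BinaryMask((vol.data > 1e-8).astype(np.uint8))
        cfg = FitConfig(sigma_voxels=2, target_error=0.05, seed=42,
                        initial_atoms=4, max_outer_iters=10)
        a = fit_pseudo_atoms(vol, mask, cfg)
        b = fit_pseudo_atoms(vol, mask, cfg)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.achieved_error == b.achieved_error

    def test_error_history_non_increasing(self, fitted_phantom):
        _, _, model = fitted_phantom
        h = model.error_history
        assert len(h) >= 1
        assert all(b <= a * (1 + 1e-9) for a, b in zip(h, h[1:]))

    def test_empty_mask_errors(self):
        vol = vio.DensityVolume(np.ones((8, 8, 8)))
        mask = vio.BinaryMask(np.zeros((8, 8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            fit_pseudo_atoms(vol, mask, FitConfig())

    def test_weights_all_positive(self, fitted_phantom):
        _, _, model = fitted_phantom
        assert (model.weights > 0).all()


class TestDistances:
    def test_two_atoms_nn_distance(self):
        model = PseudoAtomModel(
            [[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]], [1.0, 1.0], sigma=1.0
        )
        hist = nn_distance_histogram(model, n_bins=4)
        assert hist.counts.sum() == 2
        centers = hist.bin_centers
        assert centers[hist.counts > 0] == pytest.approx(5.0, abs=hist.bin_edges[1] - hist.bin_edges[0])

    def test_equilateral_triangle(self):
        s = 3.0
        model = PseudoAtomModel(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]],
            [1, 1, 1], sigma=1.0,
        )
        nn = cg._nn_distances(model.positions)
        np.testing.assert_allclose(nn, s, rtol=1e-12)

    def test_counts_sum_to_n(self, small_model):
        hist = nn_distance_histogram(small_model, n_bins=12)
        assert hist.counts.sum() == small_model.n_atoms

    def test_single_atom_errors(self):
        model = PseudoAtomModel([[0.0, 0.0, 0.0]], [1.0], sigma=1.0)
        with pytest.raises(ValueError):
            nn_distance_histogram(model)


class TestSuggestCutoff:
    def test_collinear_chain_connectivity(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = 5.0 * np.arange(10)
        model = PseudoAtomModel(pos, np.ones(10), sigma=1.0)
        cutoff = suggest_cutoff(model)
        assert cutoff >= 5.0

    def test_fraction_one_is_max_nn_distance(self, small_model):
        cutoff = suggest_cutoff(small_model, fraction=1.0)
        nn = cg._nn_distances(small_model.positions)
        assert cutoff >= nn.max()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coverage_at_least_95_percent(self, seed):
        rng = np.random.default_rng(seed)
        model = PseudoAtomModel(
            rng.uniform(0, 50, size=(200, 3)), np.ones(200), sigma=1.0
        )
        cutoff = suggest_cutoff(model, fraction=0.95)
        nn = cg._nn_distances(model.positions)
        assert np.mean(nn < cutoff) >= 0.95

    def test_two_far_clusters_bridged(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 5, size=(20, 3))
        b = rng.uniform(0, 5, size=(20, 3)) + [40.0, 0.0, 0.0]
        model = PseudoAtomModel(np.vstack([a, b]), np.ones(40), sigma=1.0)
        cutoff = suggest_cutoff(model)
        assert cg._is_connected(model.positions, cutoff)
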