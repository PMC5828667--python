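"""Generators: planted MVAR networks, the spherical forward model, gaze
clouds, phenotype scores. Every assertion is against an independent
oracle (closed form, eigenvalue check, finite differences, Monte Carlo)."""

import numpy as np
import pytest
from scipy.special import eval_legendre

from pdcflow.mvar import MVARModel, simulate_mvar_epochs
from pdcflow.synthetic import (
    GroundTruthNetwork,
    assign_rois_to_points,
    hub_network,
    make_random_stable_mvar,
    make_spherical_leadfield,
    project_to_sensors,
    simulate_gaze_dataset,
    simulate_phenotypes,
    spherical_gain,
)


def companion_spectral_radius(coeffs):
    """Independent companion-matrix eigenvalue oracle (built by hand)."""
    p, n, _ = coeffs.shape
    C = np.zeros((n * p, n * p))
    for r in range(p):
        C[:n, r * n : (r + 1) * n] = coeffs[r]
    if p > 1:
        C[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return np.abs(np.linalg.eigvals(C)).max()


class TestMakeRandomStableMVAR:
    def test_empty_network_zero_diagonal_gives_zero_model(self):
        net = GroundTruthNetwork(n_rois=3, edges=[])
        m = make_random_stable_mvar(3, 1, net, osc_damping=0.0, seed=0)
        assert np.all(m.coeffs == 0.0)
        assert m.is_stable()

    def test_single_planted_edge_is_forced_analytically(self):
        net = GroundTruthNetwork(n_rois=3, edges=[(0, 1, 0.5, 1)])
        m = make_random_stable_mvar(3, 1, net, osc_damping=0.0, seed=0)
        assert m.coeffs[0][1, 0] == 0.5
        # a pure feed-forward edge is nilpotent: spectral radius 0 < 1
        assert companion_spectral_radius(m.coeffs) < 1e-12
        assert m.is_stable()

    def test_hub_network_stability_via_eigenvalue_oracle(self):
        net = hub_network(20, hub=0, targets=list(range(1, 7)), strength=0.4)
        m = make_random_stable_mvar(20, 5, net, offdiag_strength=0.05, seed=3)
        assert companion_spectral_radius(m.coeffs) <= 0.95 + 1e-9

    def test_rejects_bad_inputs(self):
        net = GroundTruthNetwork(n_rois=2, edges=[])
        with pytest.raises(ValueError):
            make_random_stable_mvar(1, 1, GroundTruthNetwork(n_rois=1))
        with pytest.raises(ValueError):
            make_random_stable_mvar(
                2, 1, GroundTruthNetwork(n_rois=2, edges=[(0, 1, 0.3, 2)])
            )
        with pytest.raises(ValueError):
            make_random_stable_mvar(2, 1, net, offdiag_strength=-0.1)

    def test_self_edges_refused_in_network(self):
        with pytest.raises(ValueError):
            GroundTruthNetwork(n_rois=3, edges=[(1, 1, 0.5, 1)])


class TestSimulateMVAREpochs:
    def test_white_noise_unit_variance(self):
        m = MVARModel(coeffs=np.zeros((1, 4, 4)), noise_cov=np.eye(4))
        x = simulate_mvar_epochs(m, n_epochs=120, n_samples=125, seed=0)
        # SE of a variance estimate from N iid samples is sqrt(2/N)
        n_tot = 125 * 120
        assert np.allclose(x.var(axis=(1, 2)), 1.0, atol=3 * np.sqrt(2 / n_tot))

    def test_ar1_lag_one_autocorrelation(self):
        m = MVARModel(coeffs=np.array([[[0.5]]]), noise_cov=np.eye(1))
        x = simulate_mvar_epochs(m, n_epochs=120, n_samples=125, seed=1)[0]
        ac = np.mean(
            [np.corrcoef(x[:-1, e], x[1:, e])[0, 1] for e in range(x.shape[1])]
        )
        bartlett_se = np.sqrt((1 - 0.25) / 125 / 120)
        assert abs(ac - 0.5) < 4 * bartlett_se

    def test_same_seed_bitwise_identical(self):
        m = MVARModel(coeffs=np.array([[[0.3]]]), noise_cov=np.eye(1))
        a = simulate_mvar_epochs(m, 5, 50, seed=42)
        b = simulate_mvar_epochs(m, 5, 50, seed=42)
        assert np.array_equal(a, b)

    def test_unstable_model_refused(self):
        m = MVARModel(coeffs=np.array([[[1.1]]]), noise_cov=np.eye(1))
        with pytest.raises(ValueError, match="unstable"):
            simulate_mvar_epochs(m, 1, 50, seed=0)


class TestSphericalGain:
    def test_centre_dipole_matches_textbook_law(self):
        # V = 3 (p . u) / (4 pi sigma R^2) for a dipole at the centre
        u = np.array([[0, 0, 1.0], [1.0, 0, 0], [0.6, 0.8, 0]])
        g = spherical_gain(u, np.zeros((1, 3)))
        expect = 3.0 * u / (4 * np.pi)
        assert np.allclose(g[:, 0, :], expect, atol=1e-12)

    def test_mirror_symmetry_of_tangential_dipoles(self):
        # reflecting dipole position and moment through the x-y plane
        # mirrors the potential pattern across that plane
        elec = np.array([[0.0, 0.6, 0.8], [0.0, 0.6, -0.8]])
        pos = np.array([[0.0, 0.3, 0.4], [0.0, 0.3, -0.4]])
        g = spherical_gain(elec, pos)
        # tangential moment along y (unchanged by the reflection)
        v_up = g[:, 0, 1]
        v_dn = g[:, 1, 1]
        assert np.isclose(v_up[0], v_dn[1], atol=1e-10)
        assert np.isclose(v_up[1], v_dn[0], atol=1e-10)

    def test_agrees_with_finite_difference_oracle(self, rng):
        # independent route: numerically differentiate the series
        # potential built from scipy's Legendre evaluation
        def potential(x, u, nmax=150):
            b = np.linalg.norm(x)
            t = float(x @ u) / b
            n = np.arange(1, nmax + 1)
            return float(
                np.sum((2 * n + 1) / n * b**n * eval_legendre(n, t))
            ) / (4 * np.pi)

        h = 1e-6
        for _ in range(10):
            x = rng.standard_normal(3)
            x = x / np.linalg.norm(x) * (0.2 + 0.5 * rng.random())
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            grad = np.array(
                [
                    (potential(x + h * e, u) - potential(x - h * e, u)) / (2 * h)
                    for e in np.eye(3)
                ]
            )
            mine = spherical_gain(u[None, :], x[None, :])[0, 0]
            assert np.allclose(grad, mine, atol=1e-8)

    def test_point_on_or_outside_sphere_refused(self):
        u = np.array([[0, 0, 1.0]])
        with pytest.raises(ValueError):
            spherical_gain(u, np.array([[0, 0, 1.0]]))
        with pytest.raises(ValueError):
            spherical_gain(u, np.array([[0, 0, 1.4]]))

    def test_leadfield_has_no_dead_electrode(self):
        lf = make_spherical_leadfield(16, 40, seed=0)
        assert not np.any(np.all(lf.gain.reshape(16, -1) == 0, axis=1))
        # neighbor graph symmetric
        assert np.array_equal(lf.point_neighbors, lf.point_neighbors.T)


class TestProjectToSensors:
    def test_zero_sources_give_mean_zero_noise(self, small_leadfield):
        pl = assign_rois_to_points(small_leadfield, 4, seed=0)
        src = np.zeros((4, 50, 3))
        sens = project_to_sensors(src, small_leadfield, pl, snr=5.0, seed=0)
        assert np.allclose(sens.mean(axis=0), 0.0, atol=1e-12)
        assert sens.std() > 0

    def test_infinite_snr_equals_noiseless_projection(self, small_leadfield, rng):
        from pdcflow.synthetic import placement_gain

        pl = assign_rois_to_points(small_leadfield, 4, seed=1)
        src = rng.standard_normal((4, 60, 2))
        sens = project_to_sensors(src, small_leadfield, pl, snr=np.inf, seed=0)
        G = placement_gain(small_leadfield, pl)
        clean = np.einsum("cr,rte->cte", G, src)
        clean -= clean.mean(axis=0, keepdims=True)
        assert np.allclose(sens, clean, atol=1e-12)

    def test_empirical_snr_matches_request(self, small_leadfield, rng):
        from pdcflow.synthetic import placement_gain

        pl = assign_rois_to_points(small_leadfield, 4, seed=2)
        src = rng.standard_normal((4, 125, 120))
        sens = project_to_sensors(src, small_leadfield, pl, snr=5.0, seed=3)
        G = placement_gain(small_leadfield, pl)
        clean = np.einsum("cr,rte->cte", G, src)
        noise = (sens + clean.mean(axis=0, keepdims=True)) - clean
        snr_emp = np.mean(clean**2) / np.mean(noise**2)
        assert abs(snr_emp - 5.0) / 5.0 < 0.10

    def test_source_placement_mismatch_raises(self, small_leadfield, rng):
        pl = assign_rois_to_points(small_leadfield, 4, seed=0)
        with pytest.raises(ValueError, match="placement"):
            project_to_sensors(
                rng.standard_normal((5, 20, 1)), small_leadfield, pl, snr=1.0
            )


class TestGazeSimulator:
    def test_zero_deviation_exchangeable_with_reference(self):
        from pdcflow.stats import mann_whitney

        ds = simulate_gaze_dataset(
            n_td=12, n_test=3, n_frames=120, deviation=[0.0, 0.0, 0.0], seed=5
        )
        # distance of each sample to the frame's reference centroid
        cent = np.nanmean(
            np.where(ds.reference[:, :, 2:] > 0.5, ds.reference[:, :, :2], np.nan),
            axis=1,
        )
        ref_d = np.linalg.norm(ds.reference[:, :, :2] - cent[:, None, :], axis=2)
        test_d = np.linalg.norm(
            ds.test_tracks[:, :, :2] - cent[None, :, :], axis=2
        )
        res = mann_whitney(
            test_d.mean(axis=1), ref_d.mean(axis=0)
        )
        assert res.p > 0.01

    def test_large_deviation_orders_above_every_reference_subject(self):
        for s in range(20):
            ds = simulate_gaze_dataset(
                n_td=10, n_test=1, n_frames=80, deviation=[6.0], seed=100 + s
            )
            cent = ds.reference[:, :, :2].mean(axis=1)
            ref_d = np.linalg.norm(
                ds.reference[:, :, :2] - cent[:, None, :], axis=2
            ).mean(axis=0)
            test_d = np.linalg.norm(
                ds.test_tracks[0, :, :2] - cent, axis=1
            ).mean()
            assert test_d > ref_d.max()

    def test_deterministic_for_fixed_seed(self):
        a = simulate_gaze_dataset(5, 2, 30, [0.5, 1.0], seed=9)
        b = simulate_gaze_dataset(5, 2, 30, [0.5, 1.0], seed=9)
        assert np.array_equal(a.reference, b.reference)
        assert np.array_equal(a.test_tracks, b.test_tracks)

    def test_every_frame_in_exactly_one_film(self):
        ds = simulate_gaze_dataset(5, 1, 31, [0.0], seed=0, n_films=2)
        assert set(ds.film_ids) == {0, 1}
        assert len(ds.film_ids) == 31


class TestSimulatePhenotypes:
    def test_rho_one_gives_exact_monotone_scores(self, rng):
        from scipy.stats import spearmanr

        x = rng.standard_normal(12)
        ph = simulate_phenotypes(x, rho=1.0, seed=0)
        assert spearmanr(x, ph["score"]).statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("rho,tol", [(0.0, 0.05), (0.75, 0.1)])
    def test_mean_recovered_spearman_over_seeds(self, rho, tol, rng):
        from scipy.stats import spearmanr

        vals = []
        for s in range(200):
            x = np.random.default_rng(1000 + s).standard_normal(18)
            ph = simulate_phenotypes(x, rho=rho, seed=s)
            vals.append(spearmanr(x, ph["score"]).statistic)
        assert abs(np.mean(vals) - rho) < tol
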