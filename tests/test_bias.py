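"""OPES-explore bias: kernels, density, normalization, bound, compression."""

import numpy as np
import pytest
from scipy import integrate

from erbs.bias import (
    BiasParameters,
    EmptyStoreError,
    KernelStore,
    bias_energy,
    bias_forces,
    density,
    deposit_kernel,
    kernel_eval,
    load_kernel_store,
    normalization,
    save_kernel_store,
)
from erbs.cv import ReferenceSet, fit_projection, project
from erbs.descriptor import DescriptorSettings, DescriptorState
from erbs.system import AtomicConfiguration
from erbs.units import KB


def store_from_points(points, sigma, threshold=0.0, barrier=5.0):
    points = np.atleast_2d(points)
    params = BiasParameters(barrier=barrier, bandwidth=sigma,
                            k=points.shape[1], deposition_stride=1,
                            compression_threshold=threshold)
    store = KernelStore(points.shape[1], sigma)
    for p in points:
        deposit_kernel(store, p, np.zeros(3), params)
    return store, params


class TestKernelEval:
    def test_mode_value_1d(self):
        assert np.isclose(kernel_eval([0.0], [0.0], [1.0]), 1 / np.sqrt(2 * np.pi))

    def test_far_field_vanishes(self):
        assert kernel_eval([50.0], [0.0], [1.0]) < 1e-300

    def test_matches_scalar_formula_2d(self):
        sigma = 0.5
        val = kernel_eval([0.5, 0.0], [0.0, 0.0], [sigma ** 2, sigma ** 2])
        expected = 1 / (2 * np.pi * sigma ** 2) * np.exp(-0.5 * (0.5 / sigma) ** 2)
        assert np.isclose(val, expected, rtol=1e-12)

    def test_nonpositive_covariance_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval([0.0], [0.0], [0.0])

    @pytest.mark.parametrize("k", [1, 2])
    def test_integrates_to_one(self, k):
        sigma2 = [0.3 ** 2] * k
        if k == 1:
            val, _ = integrate.quad(lambda x: kernel_eval([x], [0.1], sigma2), -5, 5)
        else:
            val, _ = integrate.dblquad(
                lambda y, x: kernel_eval([x, y], [0.0, 0.1], sigma2),
                -4, 4, -4, 4,
            )
        assert np.isclose(val, 1.0, atol=1e-6)


class TestDensityAndNormalization:
    def test_empty_store_errors(self):
        store = KernelStore(1, 0.5)
        with pytest.raises(EmptyStoreError):
            density([0.0], store)
        with pytest.raises(EmptyStoreError):
            normalization(store)

    def test_single_kernel_density_at_center(self):
        store, _ = store_from_points([[0.3]], 0.5)
        assert np.isclose(density([0.3], store), kernel_eval([0.3], [0.3], [0.25]))

    def test_duplicate_kernels_average(self):
        s1, _ = store_from_points([[0.0]], 0.5)
        s2, _ = store_from_points([[0.0], [0.0]], 0.5)
        assert np.isclose(density([0.2], s1), density([0.2], s2))

    def test_density_matches_naive_average(self, rng):
        centers = rng.normal(size=(5, 2))
        store, _ = store_from_points(centers, 0.4)
        q = rng.normal(size=2)
        naive = np.mean([kernel_eval(q, c, [0.16, 0.16]) for c in centers])
        assert np.isclose(density(q, store), naive, rtol=1e-12)

    def test_single_kernel_normalization_is_mode(self):
        store, _ = store_from_points([[1.0]], 0.3)
        assert np.isclose(normalization(store), kernel_eval([1.0], [1.0], [0.09]))

    def test_two_distant_kernels_halve_z(self):
        store, _ = store_from_points([[0.0], [100.0]], 0.5)
        mode = kernel_eval([0.0], [0.0], [0.25])
        assert np.isclose(normalization(store), mode / 2, rtol=1e-10)

    def test_normalization_matches_double_loop(self, rng):
        centers = rng.normal(scale=0.5, size=(4, 2))
        store, _ = store_from_points(centers, 0.4)
        z = np.mean([
            np.mean([kernel_eval(ci, cj, [0.16, 0.16]) for cj in centers])
            for ci in centers
        ])
        assert np.isclose(normalization(store), z, rtol=1e-12)

    def test_z_grows_only_on_overlap(self, rng):
        # far-away deposits leave Z (nearly) unchanged; overlapping ones raise it
        store, params = store_from_points([[0.0]], 0.5)
        z0 = normalization(store)
        deposit_kernel(store, np.array([500.0]), np.zeros(3), params)
        z_far = normalization(store)
        assert z_far <= z0 + 1e-12
        deposit_kernel(store, np.array([0.1]), np.zeros(3), params)
        assert normalization(store) > z_far


class TestBiasEnergy:
    def test_far_field_approaches_minus_barrier(self):
        params = BiasParameters(barrier=5.0, temperature=300.0, bandwidth=0.5,
                                k=1, deposition_stride=1)
        store, _ = store_from_points([[0.0]], 0.5, barrier=5.0)
        v = bias_energy([1e3], store, params)
        assert np.isclose(v, -5.0, atol=1e-9)

    def test_at_single_kernel_center(self):
        params = BiasParameters(barrier=5.0, temperature=300.0, bandwidth=0.5,
                                k=1, deposition_stride=1)
        store, _ = store_from_points([[0.0]], 0.5, barrier=5.0)
        expected = (params.gamma - 1) * KB * 300.0 * np.log(1 + params.epsilon)
        assert np.isclose(bias_energy([0.0], store, params), expected, rtol=1e-12)

    def test_epsilon_formula(self):
        # gamma = dE/(kB T), eps = exp(-gamma/(gamma-1))
        params = BiasParameters(barrier=20.0, temperature=300.0, bandwidth=0.1,
                                k=2, deposition_stride=1)
        gamma = 20.0 / (8.617333e-5 * 300.0)
        assert np.isclose(params.gamma, gamma, rtol=1e-12)
        assert np.isclose(params.epsilon, np.exp(-gamma / (gamma - 1)), rtol=1e-12)

    def test_lower_bound_over_random_stores(self, rng):
        # V >= -dE for any store and query
        for barrier in (1.0, 5.0, 20.0):
            params = BiasParameters(barrier=barrier, temperature=300.0,
                                    bandwidth=0.3, k=2, deposition_stride=1)
            for _ in range(30):
                centers = rng.normal(scale=rng.uniform(0.1, 5), size=(rng.integers(1, 8), 2))
                store, _ = store_from_points(centers, 0.3, barrier=barrier)
                q = rng.normal(scale=10, size=2)
                assert bias_energy(q, store, params) >= -barrier - 1e-12


class TestBiasForces:
    def _setup(self, rng, n_kernels=3):
        settings = DescriptorSettings(cutoff=4.0, n_radial=3)
        pos = rng.normal(scale=1.0, size=(4, 3))
        cfg = AtomicConfiguration(pos, [6] * 4)
        refs = ReferenceSet(settings.dimension)
        for _ in range(5):
            p = rng.normal(scale=1.0, size=(4, 3))
            from erbs.descriptor import global_descriptor

            refs.append(global_descriptor(AtomicConfiguration(p, [6] * 4), settings).values)
        basis = fit_projection(refs, k=2)
        params = BiasParameters(barrier=2.0, temperature=300.0, bandwidth=0.05,
                                k=2, deposition_stride=1, compression_threshold=0.0)
        store = KernelStore(2, params.bandwidth)
        for i in range(n_kernels):
            full = refs.matrix[i]
            deposit_kernel(store, project(full, basis), full, params)
        return cfg, settings, basis, params, store

    def test_matches_finite_differences(self, rng):
        cfg, settings, basis, params, store = self._setup(rng)
        forces, v0, s = bias_forces(cfg, store, basis, params, settings)
        h = 1e-5
        from erbs.descriptor import global_descriptor

        for m in range(cfg.n_atoms):
            for d in range(3):
                pp, pm = cfg.positions.copy(), cfg.positions.copy()
                pp[m, d] += h
                pm[m, d] -= h
                vp = bias_energy(
                    project(global_descriptor(AtomicConfiguration(pp, [6] * 4), settings).values, basis),
                    store, params)
                vm = bias_energy(
                    project(global_descriptor(AtomicConfiguration(pm, [6] * 4), settings).values, basis),
                    store, params)
                fd = -(vp - vm) / (2 * h)
                assert np.isclose(forces[m, d], fd, rtol=1e-5, atol=1e-9)

    def test_zero_jacobian_gives_zero_force(self, rng):
        _, settings, basis, params, store = self._setup(rng)
        dilute = AtomicConfiguration(
            [[0, 0, 0], [50, 0, 0], [100, 0, 0], [150, 0, 0]], [6] * 4
        )
        forces, _, _ = bias_forces(dilute, store, basis, params, settings)
        assert np.allclose(forces, 0.0)

    def test_isolated_kernel_center_is_stationary(self):
        # query exactly at the only kernel's center: density extremum
        settings = DescriptorSettings(cutoff=4.0, n_radial=2)
        cfg = AtomicConfiguration([[0, 0, 0], [1.4, 0, 0]], [6, 6])
        from erbs.descriptor import global_descriptor

        refs = ReferenceSet(settings.dimension)
        full0 = global_descriptor(cfg, settings).values
        refs.append(full0)
        refs.append(full0 * 1.1 + 0.05)
        basis = fit_projection(refs, 1)
        params = BiasParameters(barrier=2.0, bandwidth=0.1, k=1, deposition_stride=1)
        store = KernelStore(1, 0.1)
        deposit_kernel(store, project(full0, basis), full0, params)
        forces, _, _ = bias_forces(cfg, store, basis, params, settings)
        assert np.allclose(forces, 0.0, atol=1e-10)


class TestDepositAndCompression:
    def test_far_deposit_appends(self):
        store, params = store_from_points([[0.0]], 0.5, threshold=1.0)
        deposit_kernel(store, np.array([10.0]), np.zeros(3), params)
        assert len(store) == 2
        assert store.weights[-1] == 1.0

    def test_deposit_atop_merges(self):
        store, params = store_from_points([[1.0]], 0.5, threshold=1.0)
        deposit_kernel(store, np.array([1.0]), np.zeros(3), params)
        assert len(store) == 1
        assert store.weights[0] == 2.0
        assert np.isclose(store.centers[0, 0], 1.0)
        assert np.isclose(store.variances[0, 0], 0.25)

    def test_merge_updates_weighted_moments(self):
        store, params = store_from_points([[0.0]], 1.0, threshold=1.0)
        deposit_kernel(store, np.array([0.5]), np.zeros(3), params)
        assert len(store) == 1
        assert np.isclose(store.centers[0, 0], 0.25)
        # weighted second moment: (1*(1+0) + (1+0.25))/2 - 0.0625
        assert np.isclose(store.variances[0, 0], (1.0 + 1.25) / 2 - 0.0625)

    def test_compressed_density_tracks_uncompressed(self, rng):
        # 20 deposits from two separated Gaussians: densities agree within 5%
        pts = np.concatenate([
            rng.normal(loc=0.0, scale=0.3, size=(10, 1)),
            rng.normal(loc=5.0, scale=0.3, size=(10, 1)),
        ])
        compressed, _ = store_from_points(pts, 0.5, threshold=1.0)
        uncompressed, _ = store_from_points(pts, 0.5, threshold=0.0)
        assert len(compressed) < len(uncompressed) == 20
        for p in pts:
            a = density(p, compressed)
            b = density(p, uncompressed)
            assert abs(a - b) / b < 0.05

    def test_threshold_zero_is_exact_naive_formula(self, rng):
        centers = rng.normal(size=(12, 2))
        store, params = store_from_points(centers, 0.4, threshold=0.0)
        assert len(store) == 12
        q = rng.normal(size=2)
        naive_p = np.mean([kernel_eval(q, c, [0.16] * 2) for c in centers])
        naive_z = np.mean([
            np.mean([kernel_eval(ci, cj, [0.16] * 2) for cj in centers])
            for ci in centers
        ])
        assert np.isclose(density(q, store), naive_p, rtol=1e-13)
        assert np.isclose(normalization(store), naive_z, rtol=1e-15)
        v = bias_energy(q, store, params)
        expected = (params.gamma - 1) * KB * params.temperature * np.log(
            naive_p / naive_z + params.epsilon
        )
        assert np.isclose(v, expected, rtol=1e-12)


def test_kernel_store_checkpoint_roundtrip(tmp_path, rng):
    centers = rng.normal(size=(6, 2))
    store, params = store_from_points(centers, 0.4, threshold=1.0)
    store.full_descriptors = [rng.normal(size=5) for _ in range(len(store))]
    path = tmp_path / "kernels.json"
    save_kernel_store(path, store, params)
    store2, params2 = load_kernel_store(path)
    assert np.array_equal(store2.centers, store.centers)
    assert np.array_equal(store2.variances, store.variances)
    assert np.array_equal(store2.weights, store.weights)
    assert store2.Z == store.Z
    assert params2 == params
    for a, b in zip(store2.full_descriptors, store.full_descriptors):
        assert np.array_equal(a, b)
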