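"""OPES-explore bias: on-the-fly well-tempered kernel density in CV space.

Gaussian kernels are deposited at the current CV position at fixed intervals.
Their average models the well-tempered probability density p_WT(s); the bias

    V_n(s) = (gamma - 1) * kB*T * log(p_WT(s)/Z_n + eps)

with gamma = beta*dE, eps = exp(-gamma/(gamma-1)) is bounded below by -dE,
the barrier parameter.  Z_n is estimated by averaging the density over the
kernel centers; it grows only when kernels overlap, which rewards placing
new kernels in unexplored regions.

Nearby kernels are merged on deposition (weighted first and second moments,
an incoming deposit carrying the nominal isotropic bandwidth), so the store
stays compact while its density tracks the uncompressed estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cv import ProjectionBasis, project
from .descriptor import DescriptorSettings, DescriptorState
from .units import KB


class EmptyStoreError(RuntimeError):
    """The bias is undefined before the first kernel is deposited."""


@dataclass(frozen=True)
class BiasParameters:
    """Parameters of the OPES-explore bias.

    barrier : float, eV — soft lower bound -barrier on the bias.
    temperature : float, K
    bandwidth : float — isotropic kernel sigma in CV units.
    k : int — number of principal components used as CVs.
    deposition_stride : int — MD steps between kernel deposits.
    compression_threshold : float — merge radius in units of the kernel
        bandwidth (Mahalanobis); 0 disables compression.
    """

    barrier: float = 20.0
    temperature: float = 300.0
    bandwidth: float = 0.05
    k: int = 4
    deposition_stride: int = 10_000
    compression_threshold: float = 1.0

    def __post_init__(self):
        if self.barrier <= 0 or self.temperature <= 0 or self.bandwidth <= 0:
            raise ValueError("barrier, temperature and bandwidth must be positive")
        if self.k < 1 or self.deposition_stride < 1:
            raise ValueError("k and deposition_stride must be >= 1")
        if self.gamma <= 1:
            raise ValueError(
                "barrier must exceed kB*T so the bias factor gamma = "
                f"barrier/(kB*T) > 1; got gamma = {self.gamma:.3g}"
            )

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    @property
    def gamma(self) -> float:
        return self.barrier * self.beta

    @property
    def epsilon(self) -> float:
        g = self.gamma
        return float(np.exp(-g / (g - 1.0)))


def kernel_eval(s, center, variances) -> float:
    """Normalized diagonal-covariance Gaussian density at ``s``."""
    s = np.atleast_2d(np.asarray(s, dtype=float))
    center = np.asarray(center, dtype=float).ravel()
    variances = np.asarray(variances, dtype=float).ravel()
    if s.shape[-1] != center.size or center.size != variances.size:
        raise ValueError("dimension mismatch between point, center and covariance")
    if np.any(variances <= 0):
        raise ValueError("kernel covariance entries must be positive")
    norm = 1.0 / np.sqrt(np.prod(2.0 * np.pi * variances))
    q = np.sum((s - center) ** 2 / variances, axis=-1)
    out = norm * np.exp(-0.5 * q)
    return float(out[0]) if out.size == 1 else out


class KernelStore:
    """Compressed kernel set: centers in CV space + their full descriptors."""

    def __init__(self, k: int, sigma0: float):
        self.k = int(k)
        self.sigma0 = float(sigma0)
        self.centers = np.empty((0, self.k))
        self.full_descriptors: list[np.ndarray] = []
        self.variances = np.empty((0, self.k))
        self.weights = np.empty((0,))
        self.Z = None

    def __len__(self):
        return self.centers.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def _density_batch(self, s: np.ndarray) -> np.ndarray:
        """Weighted-average kernel density at a batch of CV points (n, k)."""
        s = np.atleast_2d(s)
        diff = s[:, None, :] - self.centers[None, :, :]
        q = np.sum(diff ** 2 / self.variances[None], axis=-1)
        norms = 1.0 / np.sqrt(np.prod(2.0 * np.pi * self.variances, axis=-1))
        kv = norms[None, :] * np.exp(-0.5 * q)
        return (kv * self.weights[None, :]).sum(axis=-1) / self.total_weight

    def recompute_normalization(self):
        self.Z = float(np.mean(self._density_batch(self.centers)))

    def reproject(self, basis: ProjectionBasis):
        """Re-express kernel centers in a freshly fitted CV basis.

        Centers come from the stored full-space descriptors; per-kernel
        variances are kept along surviving dimensions and new dimensions
        start at the nominal bandwidth.
        """
        k_new = basis.k
        if len(self) > 0:
            full = np.vstack(self.full_descriptors)
            self.centers = project(full, basis)
            old = self.variances
            var = np.full((len(self), k_new), self.sigma0 ** 2)
            keep = min(old.shape[1], k_new)
            var[:, :keep] = old[:, :keep]
            self.variances = var
        else:
            self.centers = np.empty((0, k_new))
            self.variances = np.empty((0, k_new))
        self.k = k_new
        if len(self) > 0:
            self.recompute_normalization()


def density(s, store: KernelStore) -> float:
    """Well-tempered density estimate p_WT at CV point ``s``."""
    if len(store) == 0:
        raise EmptyStoreError("no kernels deposited yet")
    out = store._density_batch(np.asarray(s, dtype=float))
    return float(out[0]) if np.asarray(s).ndim == 1 else out


def normalization(store: KernelStore) -> float:
    """Z: mean of the density over the kernel centers (quadrature points)."""
    if len(store) == 0:
        raise EmptyStoreError("no kernels deposited yet")
    if store.Z is None:
        store.recompute_normalization()
    return store.Z


def bias_energy(s, store: KernelStore, params: BiasParameters) -> float:
    """OPES-explore bias V_n(s) in eV; bounded below by -barrier."""
    p = density(s, store)
    z = normalization(store)
    pref = (params.gamma - 1.0) / params.beta
    return pref * np.log(p / z + params.epsilon)


def _bias_cv_gradient(s, store: KernelStore, params: BiasParameters) -> np.ndarray:
    """dV_n/ds at CV point ``s`` (length-k array)."""
    if len(store) == 0:
        raise EmptyStoreError("no kernels deposited yet")
    s = np.asarray(s, dtype=float).ravel()
    diff = s[None, :] - store.centers
    q = np.sum(diff ** 2 / store.variances, axis=-1)
    norms = 1.0 / np.sqrt(np.prod(2.0 * np.pi * store.variances, axis=-1))
    kv = norms * np.exp(-0.5 * q)
    w = store.weights / store.total_weight
    p = float(np.sum(w * kv))
    dp = -np.sum((w * kv)[:, None] * diff / store.variances, axis=0)
    z = normalization(store)
    pref = (params.gamma - 1.0) / params.beta
    return pref * dp / (z * (p / z + params.epsilon))


def bias_forces(
    config,
    store: KernelStore,
    basis: ProjectionBasis,
    params: BiasParameters,
    settings: DescriptorSettings,
    state: DescriptorState | None = None,
):
    """Atomic bias forces -dV_n/dR in eV/Å, plus the bias energy and CVs.

    The chain rule runs through the CV projection and the descriptor
    adjoint: dV/dR = (dV/ds) V^(k)T (ds'/dR).

    Returns ``(forces (N,3), V_n, s)``.
    """
    if state is None:
        state = DescriptorState(config, settings)
    s = project(state.values, basis)
    dvds = _bias_cv_gradient(s, store, params)
    v_n = bias_energy(s, store, params)
    w = basis.components @ dvds  # co-vector in descriptor space
    grad = state.vjp(w)
    return -grad, v_n, s


def deposit_kernel(
    store: KernelStore,
    s_new: np.ndarray,
    full_descriptor: np.ndarray,
    params: BiasParameters,
) -> KernelStore:
    """Deposit a kernel at ``s_new``, merging into a close neighbor if any.

    A deposit closer (Mahalanobis, under the neighbor's covariance) than
    ``compression_threshold`` merges: weights add, the center becomes the
    weighted mean, and the per-dimension variances the weighted second
    moment, the incoming deposit contributing the nominal bandwidth
    sigma0.  Otherwise a fresh isotropic kernel is appended.  Z is
    recomputed either way.
    """
    s_new = np.asarray(s_new, dtype=float).ravel()
    if not np.all(np.isfinite(s_new)):
        raise ValueError("CV position must be finite")
    full_descriptor = np.asarray(full_descriptor, dtype=float).ravel()
    sig0sq = store.sigma0 ** 2

    merged = False
    if len(store) > 0 and params.compression_threshold > 0 and s_new.size == store.k:
        d2 = np.sum((s_new[None, :] - store.centers) ** 2 / store.variances, axis=-1)
        j = int(np.argmin(d2))
        if np.sqrt(d2[j]) <= params.compression_threshold:
            w_old = store.weights[j]
            w_new = w_old + 1.0
            c_old = store.centers[j]
            m1 = (w_old * c_old + s_new) / w_new
            m2 = (
                w_old * (store.variances[j] + c_old ** 2)
                + (sig0sq + s_new ** 2)
            ) / w_new
            store.centers[j] = m1
            store.variances[j] = m2 - m1 ** 2
            store.weights[j] = w_new
            # the merged kernel represents the newest structure too
            store.full_descriptors[j] = full_descriptor
            merged = True
    if not merged:
        store.centers = np.vstack([store.centers, s_new[None, :]]) if len(store) else s_new[None, :].copy()
        store.variances = (
            np.vstack([store.variances, np.full((1, s_new.size), sig0sq)])
            if len(store.weights)
            else np.full((1, s_new.size), sig0sq)
        )
        store.weights = np.append(store.weights, 1.0)
        store.full_descriptors.append(full_descriptor)
        store.k = s_new.size
    store.recompute_normalization()
    return store


# ---------------------------------------------------------------------------
# checkpointing


def save_kernel_store(path, store: KernelStore, params: BiasParameters):
    payload = {
        "k": store.k,
        "sigma0": store.sigma0,
        "centers": store.centers.tolist(),
        "full_descriptors": [fd.tolist() for fd in store.full_descriptors],
        "variances": store.variances.tolist(),
        "weights": store.weights.tolist(),
        "Z": store.Z,
        "params": {
            "barrier": params.barrier,
            "temperature": params.temperature,
            "bandwidth": params.bandwidth,
            "k": params.k,
            "deposition_stride": params.deposition_stride,
            "compression_threshold": params.compression_threshold,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_kernel_store(path):
    with open(path) as fh:
        payload = json.load(fh)
    store = KernelStore(payload["k"], payload["sigma0"])
    n = len(payload["weights"])
    store.centers = np.array(payload["centers"], dtype=float).reshape(n, store.k)
    store.full_descriptors = [np.array(fd, dtype=float) for fd in payload["full_descriptors"]]
    store.variances = np.array(payload["variances"], dtype=float).reshape(n, store.k)
    store.weights = np.array(payload["weights"], dtype=float)
    store.Z = payload["Z"]
    params = BiasParameters(**payload["params"])
    return store, params
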