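"""Collective variables from PCA of accumulated global descriptors.

Reference descriptors collected along a trajectory are stacked into a matrix,
centered by the per-feature mean, and decomposed by SVD.  The top-k principal
directions define the linear reduction phi(s') = (s' - mu) V^(k) whose image
is the collective-variable (CV) space in which the bias operates.

Two usage modes exist: a *fixed* basis fitted once on an existing set, and a
*variable* basis refitted every time a reference is appended (the default in
sampling runs).  Because kernels of the bias live in CV space but the basis
moves, kernel centers store their full-dimensional descriptors and are
re-projected after every refit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class InsufficientDataError(ValueError):
    """Raised when a PCA basis is requested from fewer than two references."""


@dataclass
class ReferenceSet:
    """Append-only stack of global descriptors with their simulation steps."""

    dimension: int
    matrix: np.ndarray = None
    timestamps: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.matrix is None:
            self.matrix = np.empty((0, self.dimension))
        else:
            self.matrix = np.asarray(self.matrix, dtype=float).reshape(-1, self.dimension)

    def __len__(self):
        return self.matrix.shape[0]

    def append(self, descriptor: np.ndarray, step: int = 0):
        descriptor = np.asarray(descriptor, dtype=float).ravel()
        if descriptor.shape != (self.dimension,):
            raise ValueError("descriptor dimension mismatch")
        if not np.all(np.isfinite(descriptor)):
            raise ValueError("reference descriptor must be finite")
        self.matrix = np.vstack([self.matrix, descriptor])
        self.timestamps.append(int(step))


@dataclass
class ProjectionBasis:
    """Centered truncated-PCA projection: s = (s' - mu) V^(k)."""

    mean: np.ndarray
    components: np.ndarray  # (D, k), orthonormal columns
    singular_values: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[1]


def fit_projection(refs: ReferenceSet, k: int) -> ProjectionBasis:
    """Fit the top-k principal directions of the centered reference matrix.

    The effective dimension is min(k, N_ref - 1, D); columns are ordered by
    decreasing singular value and each column's largest-magnitude entry is
    made positive so refits are deterministic.
    """
    n_ref = len(refs)
    if n_ref < 2:
        raise InsufficientDataError(
            f"PCA needs at least 2 reference descriptors, have {n_ref}"
        )
    X = refs.matrix
    mu = X.mean(axis=0)
    k_eff = min(k, n_ref - 1, X.shape[1])
    _, s, vt = np.linalg.svd(X - mu, full_matrices=False)
    V = vt[:k_eff].T
    # fix the sign of each component
    pivot = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[pivot, np.arange(k_eff)])
    signs[signs == 0] = 1.0
    return ProjectionBasis(mu, V * signs, s[:k_eff])


def project(s_prime: np.ndarray, basis: ProjectionBasis) -> np.ndarray:
    """Map a descriptor (or a stack of them) into CV space."""
    s_prime = np.asarray(s_prime, dtype=float)
    if s_prime.shape[-1] != basis.mean.shape[0]:
        raise ValueError(
            f"descriptor dimension {s_prime.shape[-1]} does not match basis "
            f"dimension {basis.mean.shape[0]}"
        )
    return (s_prime - basis.mean) @ basis.components


def refresh_variable_basis(refs: ReferenceSet, k: int, store):
    """Refit the basis on the full reference set and re-project the kernels.

    Returns the new (basis, store); the store's densities and normalization
    are recomputed in the new CV coordinates from the kernels' stored
    full-space descriptors.
    """
    basis = fit_projection(refs, k)
    store.reproject(basis)
    return basis, store


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, refs: ReferenceSet, basis: ProjectionBasis | None):
    payload = {
        "dimension": refs.dimension,
        "matrix": refs.matrix.tolist(),
        "timestamps": list(refs.timestamps),
        "basis": None
        if basis is None
        else {
            "mean": basis.mean.tolist(),
            "components": basis.components.tolist(),
            "singular_values": basis.singular_values.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    with open(path) as fh:
        payload = json.load(fh)
    refs = ReferenceSet(
        payload["dimension"],
        np.array(payload["matrix"], dtype=float),
        list(payload["timestamps"]),
    )
    basis = None
    if payload["basis"] is not None:
        b = payload["basis"]
        basis = ProjectionBasis(
            np.array(b["mean"]), np.array(b["components"]), np.array(b["singular_values"])
        )
    return refs, basis
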