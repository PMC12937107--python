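"""Atomic configurations and minimum-image geometry."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import NUMBERS, SYMBOLS


@dataclass
class AtomicConfiguration:
    """A snapshot of an atomic system.

    Parameters
    ----------
    positions : (N, 3) float array, Å
    atomic_numbers : (N,) int array
    cell : (3, 3) float array, Å, rows are lattice vectors; optional
    pbc : length-3 bool array; any True requires an invertible cell
    """

    positions: np.ndarray
    atomic_numbers: np.ndarray
    cell: np.ndarray | None = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int).ravel()
        self.pbc = np.asarray(self.pbc, dtype=bool).ravel()
        if self.positions.shape[0] < 1:
            raise ValueError("configuration needs at least one atom")
        if self.positions.shape[0] != self.atomic_numbers.shape[0]:
            raise ValueError("positions and atomic_numbers disagree in length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.pbc.shape != (3,):
            raise ValueError("pbc must have three flags")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if self.pbc.any():
            if self.cell is None or abs(np.linalg.det(self.cell)) < 1e-12:
                raise ValueError("periodic configuration requires an invertible cell")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def symbols(self) -> list[str]:
        return [SYMBOLS.get(z, f"X{z}") for z in self.atomic_numbers]

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            self.positions.copy(),
            self.atomic_numbers.copy(),
            None if self.cell is None else self.cell.copy(),
            self.pbc.copy(),
        )


def from_symbols(symbols, positions, cell=None, pbc=(False, False, False)):
    numbers = [NUMBERS[s] if isinstance(s, str) else int(s) for s in symbols]
    return AtomicConfiguration(np.asarray(positions, float), np.asarray(numbers), cell, np.asarray(pbc))


def mic_displacements(config: AtomicConfiguration, vectors: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to an array of displacement vectors.

    Non-periodic directions pass through unchanged.  Valid for cells where
    the cutoff is below half the smallest periodic box height.
    """
    if not config.pbc.any():
        return vectors
    inv = np.linalg.inv(config.cell)
    frac = vectors @ inv
    shift = np.where(config.pbc, np.round(frac), 0.0)
    return (frac - shift) @ config.cell


def neighbor_pairs(config: AtomicConfiguration, cutoff: float):
    """All directed pairs (i, j), i != j, with |r_ij| < cutoff under minimum image.

    Returns
    -------
    idx_i, idx_j : (P,) int arrays
    rij : (P, 3) displacement vectors R_j - R_i, Å
    dist : (P,) distances, Å
    """
    pos = config.positions
    n = pos.shape[0]
    diff = pos[None, :, :] - pos[:, None, :]
    diff = mic_displacements(config, diff.reshape(-1, 3)).reshape(n, n, 3)
    d = np.linalg.norm(diff, axis=-1)
    mask = (d < cutoff) & ~np.eye(n, dtype=bool)
    idx_i, idx_j = np.nonzero(mask)
    return idx_i, idx_j, diff[idx_i, idx_j], d[idx_i, idx_j]
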