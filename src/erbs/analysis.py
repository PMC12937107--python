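"""Exploration and transport observables.

Coverage of a two-dihedral (Ramachandran-style) space on a fixed tile grid,
time-origin-averaged mean squared displacements, diffusion coefficients with
block-averaged errors and the Yeh-Hummer finite-size correction, and
descriptor-PCA projections of trajectories for visual clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cv import ReferenceSet, fit_projection, project
from .descriptor import DescriptorSettings, global_descriptor
from .geometry import dihedral_batch
from .system import AtomicConfiguration, mic_displacements
from .units import KB

#: geometry constant of the cubic-box hydrodynamic self-interaction
XI_CUBIC = 2.837297


@dataclass(frozen=True)
class DihedralSpec:
    """A named dihedral: four distinct atom indices, wrap [-180, 180)."""

    indices: tuple
    name: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) != 4 or len(set(idx)) != 4:
            raise ValueError("a dihedral needs four distinct atom indices")
        object.__setattr__(self, "indices", idx)


def _position_frames(trajectory) -> np.ndarray:
    """Normalize trajectory-like inputs to an (F, N, 3) array."""
    if hasattr(trajectory, "position_array"):
        return trajectory.position_array()
    if isinstance(trajectory, np.ndarray):
        return trajectory
    if len(trajectory) and isinstance(trajectory[0], AtomicConfiguration):
        return np.array([f.positions for f in trajectory])
    return np.asarray(trajectory, dtype=float)


def dihedral_angles(trajectory, spec: DihedralSpec) -> np.ndarray:
    """Per-frame dihedral in degrees, wrapped to [-180, 180)."""
    pos = _position_frames(trajectory)
    ang = np.rad2deg(dihedral_batch(pos, [spec.indices])[:, 0])
    return (ang + 180.0) % 360.0 - 180.0


def dihedral_coverage(trajectory, specs, tile_deg: float = 15.0) -> float:
    """Fraction of the 2-D dihedral space's tiles visited by the trajectory.

    The (wrapped) plane is tiled into squares of ``tile_deg`` degrees;
    coverage = visited / total, so a 15° grid has 24 x 24 = 576 tiles.
    """
    pos = _position_frames(trajectory)
    if pos.shape[0] == 0:
        raise ValueError("trajectory is empty")
    if len(specs) != 2:
        raise ValueError("coverage is defined over a pair of dihedrals")
    if not np.isclose(360.0 % tile_deg, 0.0):
        raise ValueError(f"tile size {tile_deg} must divide 360 degrees")
    n_tiles = int(round(360.0 / tile_deg))
    a = dihedral_angles(pos, specs[0])
    b = dihedral_angles(pos, specs[1])
    ia = np.clip(((a + 180.0) / tile_deg).astype(int), 0, n_tiles - 1)
    ib = np.clip(((b + 180.0) / tile_deg).astype(int), 0, n_tiles - 1)
    visited = len(set(zip(ia.tolist(), ib.tolist())))
    return visited / n_tiles ** 2


# ---------------------------------------------------------------------------
# transport


@dataclass
class MsdCurve:
    """Time-origin-averaged MSD with per-block curves for error estimates."""

    lags: np.ndarray  # fs
    msd: np.ndarray  # Å²
    group: object = None
    block_msd: np.ndarray | None = None  # (n_blocks, n_block_lags)
    block_lags: np.ndarray | None = None

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag times must be strictly increasing")


def unwrap_trajectory(frames) -> np.ndarray:
    """Remove periodic jumps by accumulating minimum-image displacements."""
    if not len(frames) or not isinstance(frames[0], AtomicConfiguration):
        raise ValueError("unwrapping needs AtomicConfiguration frames with cells")
    out = [frames[0].positions.copy()]
    for prev, cur in zip(frames[:-1], frames[1:]):
        step = mic_displacements(cur, cur.positions - prev.positions)
        out.append(out[-1] + step)
    return np.array(out)


def _group_centers(pos, masses, group):
    """(F, G, 3) centers: atoms individually or per-molecule mass centers."""
    if group is None:
        return pos
    group = list(group)
    if np.isscalar(group[0]):
        return pos[:, np.asarray(group, dtype=int), :]
    centers = []
    for mol in group:
        mol = np.asarray(mol, dtype=int)
        w = masses[mol] / masses[mol].sum()
        centers.append(np.einsum("fnd,n->fd", pos[:, mol, :], w))
    return np.stack(centers, axis=1)


def mean_squared_displacement(
    trajectory, group=None, dt_frame: float = 1.0, n_blocks: int = 5, masses=None
) -> MsdCurve:
    """Time-origin-averaged MSD of the group centers.

    ``trajectory`` must hold unwrapped coordinates: periodic frames are
    unwrapped by minimum-image accumulation when cells are available, and
    rejected otherwise.  ``group`` selects atoms (flat index list) or
    molecules (list of index lists, mass-weighted centers).
    """
    if (
        not isinstance(trajectory, np.ndarray)
        and len(trajectory)
        and isinstance(trajectory[0], AtomicConfiguration)
        and trajectory[0].pbc.any()
    ):
        if trajectory[0].cell is None:
            raise ValueError(
                "periodic trajectory without cell data: provide unwrapped "
                "coordinates (images tracked across boundaries)"
            )
        pos = unwrap_trajectory(trajectory)
        if masses is None:
            from .units import mass_of

            masses = np.array([mass_of(z) for z in trajectory[0].atomic_numbers])
    else:
        pos = _position_frames(trajectory)
    if masses is None:
        masses = np.ones(pos.shape[1])
    centers = _group_centers(pos, np.asarray(masses, dtype=float), group)
    f = centers.shape[0]
    if f < 2:
        raise ValueError("need at least two frames")

    def _msd_of(seg):
        m = seg.shape[0]
        lags = np.arange(1, m)
        vals = np.empty(m - 1)
        for li, lag in enumerate(lags):
            d = seg[lag:] - seg[:-lag or None]
            vals[li] = np.mean(np.sum(d * d, axis=-1))
        return lags * dt_frame, vals

    lags, msd = _msd_of(centers)
    block_msd = block_lags = None
    if n_blocks >= 2 and f // n_blocks >= 2:
        size = f // n_blocks
        curves = [_msd_of(centers[b * size : (b + 1) * size]) for b in range(n_blocks)]
        block_lags = curves[0][0]
        block_msd = np.array([c[1] for c in curves])
    return MsdCurve(lags, msd, group=group, block_msd=block_msd, block_lags=block_lags)


def _fit_slope(lags, msd, fit_window):
    lo, hi = fit_window
    tmax = lags[-1]
    lo_t = lo * tmax if lo <= 1.0 else lo
    hi_t = hi * tmax if hi <= 1.0 else hi
    mask = (lags >= lo_t) & (lags <= hi_t)
    if mask.sum() < 2:
        raise ValueError("fit window must contain at least two MSD points")
    slope, _ = np.polyfit(lags[mask], msd[mask], 1)
    return slope


def diffusion_coefficient(
    curve: MsdCurve, fit_window=(0.1, 0.5), n_blocks: int = 5
):
    """Einstein-relation diffusion coefficient D = slope/6, Å²/fs.

    The slope comes from a least-squares line over the fit window (given as
    fractions of the maximum lag, or absolute lag times if > 1).  The
    standard error is the scatter of per-block estimates over the
    trajectory's contiguous segments.
    """
    d = _fit_slope(curve.lags, curve.msd, fit_window) / 6.0
    stderr = 0.0
    if curve.block_msd is not None and len(curve.block_msd) >= 2:
        try:
            db = np.array(
                [
                    _fit_slope(curve.block_lags, bm, fit_window) / 6.0
                    for bm in curve.block_msd
                ]
            )
            stderr = float(np.std(db, ddof=1) / np.sqrt(len(db)))
        except ValueError:
            stderr = float("nan")
    return float(d), stderr


def yeh_hummer_correct(d_finite: float, box_length: float, temperature: float,
                       viscosity: float) -> float:
    """Infinite-size diffusion: D(inf) = D(L) + xi kB T / (6 pi eta L).

    ``viscosity`` in eV·fs/Å³ for a result in Å²/fs (any self-consistent
    unit system works since the correction is D-additive).
    """
    if box_length <= 0 or viscosity <= 0:
        raise ValueError("box length and viscosity must be positive")
    return d_finite + XI_CUBIC * KB * temperature / (6.0 * np.pi * viscosity * box_length)


# ---------------------------------------------------------------------------
# descriptor-space projection


def descriptor_pca_projection(
    trajectory, settings: DescriptorSettings, k: int = 2, atomic_numbers=None
):
    """Project a trajectory into the common top-k descriptor-PCA plane.

    Computes the global descriptor of every frame, fits a PCA basis on the
    full set, and returns (coordinates (F, k_eff), timestamps).
    """
    if len(trajectory) and isinstance(trajectory[0], AtomicConfiguration):
        frames = trajectory
        steps = [f.info.get("step", i) if hasattr(f, "info") else i
                 for i, f in enumerate(frames)]
    else:
        pos = _position_frames(trajectory)
        if atomic_numbers is None:
            raise ValueError("raw position arrays need atomic_numbers")
        frames = [AtomicConfiguration(p, atomic_numbers) for p in pos]
        steps = list(range(len(frames)))
    if len(frames) < 2:
        raise ValueError("need at least two frames for a PCA projection")
    refs = ReferenceSet(settings.dimension)
    for i, f in enumerate(frames):
        refs.append(global_descriptor(f, settings).values, steps[i])
    basis = fit_projection(refs, k)
    return project(refs.matrix, basis), np.asarray(steps)
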