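"""Langevin dynamics with optional ERBS or uncertainty-driven biasing.

The integrator is a BAOAB splitting with one force evaluation per step:
half-kick, half-drift, Ornstein-Uhlenbeck velocity refresh, half-drift, with
the next step's half-kick completing the cycle.  With zero friction it
reduces to velocity Verlet.  Units: eV, Å, fs, amu, K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bias import BiasParameters, KernelStore, bias_forces, deposit_kernel
from .cv import InsufficientDataError, ReferenceSet, project, refresh_variable_basis
from .descriptor import DescriptorSettings, DescriptorState
from .system import AtomicConfiguration
from .units import ACC, KB, mass_of


class UnstableTrajectoryError(RuntimeError):
    pass


@dataclass
class SimulationState:
    configuration: AtomicConfiguration
    momenta: np.ndarray  # (N, 3), amu·Å/fs
    step: int = 0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self):
        self.momenta = np.asarray(self.momenta, dtype=float).reshape(
            self.configuration.positions.shape
        )

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(z) for z in self.configuration.atomic_numbers])

    def kinetic_temperature(self) -> float:
        m = self.masses[:, None]
        ke = 0.5 * np.sum(self.momenta ** 2 / m) / ACC  # eV
        dof = 3 * self.configuration.n_atoms
        return 2.0 * ke / (dof * KB)


def maxwell_boltzmann_momenta(config, temperature, rng) -> np.ndarray:
    m = np.array([mass_of(z) for z in config.atomic_numbers])[:, None]
    sigma_v = np.sqrt(KB * temperature / m * ACC)  # Å/fs
    return m * sigma_v * rng.standard_normal((config.n_atoms, 3))


def initialize_state(config, temperature, seed=0) -> SimulationState:
    rng = np.random.default_rng(seed)
    return SimulationState(
        config.copy(), maxwell_boltzmann_momenta(config, temperature, rng), 0, rng
    )


def langevin_step(
    state: SimulationState,
    total_forces: np.ndarray,
    temperature: float,
    friction: float,
    dt: float,
) -> SimulationState:
    """Advance one step in place; ``total_forces`` are at the current positions.

    friction is in 1/fs.  The randomness comes from ``state.rng`` so a fixed
    seed reproduces the trajectory bitwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if friction < 0:
        raise ValueError("friction must be non-negative")
    if not np.all(np.isfinite(total_forces)):
        raise UnstableTrajectoryError(
            f"non-finite forces at step {state.step}; the trajectory is unstable"
        )
    m = state.masses[:, None]
    p = state.momenta
    x = state.configuration.positions
    p += dt * total_forces * ACC  # eV/Å -> amu·Å/fs²
    x += 0.5 * dt * p / m
    if friction > 0:
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt((1.0 - c1 ** 2) * KB * temperature * ACC * m)  # momentum units
        p *= c1
        p += c2 * state.rng.standard_normal(p.shape)
    x += 0.5 * dt * p / m
    state.step += 1
    return state


# ---------------------------------------------------------------------------
# uncertainty machinery


def udd_bias(uncertainty_output, A, B, n_atoms, n_ens, convention="product"):
    """Uncertainty-driven bias E_UDD = A (exp(-sigma_E^2 c) - 1) and forces.

    ``c`` depends on the chosen exponent convention:
    "product": c = 1/(n_ens * n_atoms * B^2); "ratio": c = n_ens/(n_atoms * B^2).
    Forces follow from the ensemble energy/force covariance.
    """
    if uncertainty_output is None or uncertainty_output.get("member_energies") is None:
        raise ValueError("udd_bias needs per-member ensemble energies and forces")
    es = np.asarray(uncertainty_output["member_energies"], dtype=float)
    fs = np.asarray(uncertainty_output["member_forces"], dtype=float)
    sig2 = float(np.mean((es - es.mean()) ** 2))
    if convention == "product":
        c = 1.0 / (n_ens * n_atoms * B ** 2)
    elif convention == "ratio":
        c = n_ens / (n_atoms * B ** 2)
    else:
        raise ValueError(f"unknown UDD exponent convention {convention!r}")
    e_udd = A * (np.exp(-sig2 * c) - 1.0)
    # d sigma^2/dR = -(2/M) sum_m (E_m - Ebar)(F_m - Fbar)
    dsig2 = -2.0 * np.mean((es - es.mean())[:, None, None] * (fs - fs.mean(axis=0)), axis=0)
    f_udd = A * c * np.exp(-sig2 * c) * dsig2
    return float(e_udd), f_udd


def uncertainty_guard(state, backend, threshold, initial_state, log=None,
                      temperature=None):
    """Reset to the initial geometry when force uncertainty spikes.

    If any per-atom force uncertainty exceeds ``threshold`` (eV/Å), positions
    revert to the initial configuration and momenta are redrawn from the
    Maxwell-Boltzmann distribution (at ``temperature`` when given, else the
    initial state's kinetic temperature).  Reset steps are appended to
    ``log`` when given.
    """
    if not hasattr(backend, "uncertainty"):
        raise ValueError("backend does not provide uncertainty estimates")
    unc = backend.uncertainty(state.configuration)
    if np.any(unc["force_uncertainty"] >= threshold):
        if temperature is None:
            temperature = initial_state.kinetic_temperature()
        state.configuration.positions[:] = initial_state.configuration.positions
        state.momenta[:] = maxwell_boltzmann_momenta(
            state.configuration, max(temperature, 1e-12), state.rng
        )
        if log is not None:
            log.append(state.step)
    return state


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Per-frame record of a run; energies in eV, positions in Å."""

    positions: list = field(default_factory=list)
    steps: list = field(default_factory=list)
    potential_energies: list = field(default_factory=list)
    bias_energies: list = field(default_factory=list)
    cvs: list = field(default_factory=list)
    stable: bool = True
    reset_steps: list = field(default_factory=list)

    def total_energies(self):
        return np.asarray(self.potential_energies) + np.asarray(self.bias_energies)

    def position_array(self):
        return np.asarray(self.positions)

    def to_frames(self, atomic_numbers, cell=None, pbc=(False, False, False)):
        frames = []
        for i, pos in enumerate(self.positions):
            cfg = AtomicConfiguration(pos, atomic_numbers, cell, np.asarray(pbc))
            cfg.info = {
                "step": float(self.steps[i]),
                "energy": self.potential_energies[i],
                "bias_energy": self.bias_energies[i],
            }
            if self.cvs[i] is not None and np.size(self.cvs[i]):
                cfg.info["cv"] = np.asarray(self.cvs[i])
            frames.append(cfg)
        return frames


@dataclass
class ErbsResult:
    trajectory: Trajectory
    store: KernelStore
    references: ReferenceSet
    basis: object  # ProjectionBasis | None


def run_erbs(
    system: AtomicConfiguration,
    backend,
    params: BiasParameters,
    settings: DescriptorSettings,
    n_steps: int,
    seed=0,
    dt=0.5,
    friction=0.01,
    record_stride=10,
    bias_enabled=True,
    deposit_at_start=True,
    guard_threshold=None,
    energy_limit=1e6,
) -> ErbsResult:
    """Biased (or plain, with ``bias_enabled=False``) Langevin sampling run.

    Every ``params.deposition_stride`` steps (and at step 0 when
    ``deposit_at_start``) the global descriptor is appended to the reference
    set, the PCA basis is refreshed, existing kernels are re-projected, and
    a new kernel is deposited at the current CVs.  Until two references
    exist no CV basis is defined and the bias is zero.

    A non-finite energy terminates the run early with the partial
    trajectory flagged unstable.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    state = SimulationState(
        system.copy(),
        maxwell_boltzmann_momenta(system, params.temperature, rng),
        0,
        rng,
    )
    initial_state = SimulationState(
        system.copy(), state.momenta.copy(), 0, np.random.default_rng(0)
    )
    refs = ReferenceSet(settings.dimension)
    store = KernelStore(params.k, params.bandwidth)
    basis = None
    pending_descriptors: list[np.ndarray] = []
    traj = Trajectory()

    def collect(desc_state):
        nonlocal basis
        refs.append(desc_state.values, state.step)
        pending_descriptors.append(desc_state.values.copy())
        if len(refs) >= 2:
            try:
                basis, _ = refresh_variable_basis(refs, params.k, store)
            except InsufficientDataError:
                return
            while pending_descriptors:
                full = pending_descriptors.pop(0)
                deposit_kernel(store, project(full, basis), full, params)

    for step in range(n_steps):
        try:
            e_pot, f_pot = backend.energy_forces(state.configuration)
        except AttributeError:
            e_pot = backend.energy(state.configuration)
            f_pot = backend.forces(state.configuration)
        if (
            not np.isfinite(e_pot)
            or not np.all(np.isfinite(f_pot))
            or abs(e_pot) > energy_limit
        ):
            # dissociation / numerical blow-up: keep the partial trajectory
            traj.stable = False
            break

        desc_state = None
        deposit_now = bias_enabled and (
            (step == 0 and deposit_at_start)
            or (step > 0 and step % params.deposition_stride == 0)
        )
        if deposit_now:
            desc_state = DescriptorState(state.configuration, settings)
            collect(desc_state)

        e_bias = 0.0
        f_bias = 0.0
        s = None
        if bias_enabled and basis is not None and len(store) > 0:
            if desc_state is None:
                desc_state = DescriptorState(state.configuration, settings)
            f_bias, e_bias, s = bias_forces(
                state.configuration, store, basis, params, settings, state=desc_state
            )

        if step % record_stride == 0:
            traj.positions.append(state.configuration.positions.copy())
            traj.steps.append(step)
            traj.potential_energies.append(float(e_pot))
            traj.bias_energies.append(float(e_bias))
            traj.cvs.append(None if s is None else np.asarray(s).copy())

        total = f_pot + f_bias
        try:
            langevin_step(state, total, params.temperature, friction, dt)
        except UnstableTrajectoryError:
            traj.stable = False
            break
        if guard_threshold is not None:
            uncertainty_guard(
                state, backend, guard_threshold, initial_state,
                traj.reset_steps, temperature=params.temperature,
            )

    return ErbsResult(traj, store, refs, basis)


def run_md(
    system, backend, temperature, n_steps, seed=0, dt=0.5, friction=0.01,
    record_stride=10, guard_threshold=None,
):
    """Plain unbiased Langevin MD with the same bookkeeping as run_erbs."""
    params = BiasParameters(
        barrier=max(10.0 * KB * temperature, 1.0),
        temperature=temperature,
        bandwidth=1.0,
        k=1,
        deposition_stride=10 ** 9,
    )
    settings = DescriptorSettings(n_radial=1, max_moment_order=1, contractions=("0",))
    return run_erbs(
        system, backend, params, settings, n_steps, seed=seed, dt=dt,
        friction=friction, record_stride=record_stride, bias_enabled=False,
        guard_threshold=guard_threshold,
    ).trajectory
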