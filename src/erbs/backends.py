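"""Potential-energy backends.

Anything with ``energy(config) -> eV`` and ``forces(config) -> (N, 3) eV/Å``
can drive the dynamics; backends may additionally expose
``uncertainty(config)`` returning ensemble statistics (used by the
uncertainty-driven bias and the reset guard).

Shipped here: analytic toy landscapes (1-D double well, a Müller–Brown-style
2-D surface, Lennard-Jones clusters), a bonded force-field engine
(bonds/angles/torsions/impropers/LJ/Coulomb) used for the torsional chain
and for an Amber-class all-atom model of alanine dipeptide (ACE-ALA-NME),
and mock ensemble wrappers for exercising uncertainty-based machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import place_atom
from .system import AtomicConfiguration, mic_displacements
from .units import COULOMB, KCAL_MOL


class PotentialBackend:
    """Contract: ``energy`` in eV, ``forces`` in eV/Å."""

    def energy(self, config: AtomicConfiguration) -> float:
        return self.energy_forces(config)[0]

    def forces(self, config: AtomicConfiguration) -> np.ndarray:
        return self.energy_forces(config)[1]

    def energy_forces(self, config: AtomicConfiguration):
        raise NotImplementedError


class UnsupportedBackendError(RuntimeError):
    """Raised when uncertainty machinery is asked of a plain backend."""


@dataclass
class ToyBackendSpec:
    kind: str
    parameters: dict = field(default_factory=dict)


def make_toy_backend(spec: ToyBackendSpec) -> PotentialBackend:
    """Instantiate a named analytic toy backend."""
    kinds = {
        "double_well_1d": DoubleWell1D,
        "mueller_like_2d": MuellerLike2D,
        "lennard_jones_cluster": LennardJonesCluster,
        "torsional_chain": TorsionalChain,
    }
    if spec.kind not in kinds:
        raise ValueError(f"unknown toy backend kind {spec.kind!r}")
    return kinds[spec.kind](**spec.parameters)


# ---------------------------------------------------------------------------
# simple analytic landscapes


class DoubleWell1D(PotentialBackend):
    """Diatomic with a double-well bond-length potential.

    E(r) = h ((r - r0)^2 - w^2)^2 / w^4 has minima at r0 - w and r0 + w
    separated by a barrier of height ``h`` (eV).  The first atom is
    harmonically tethered to the origin so the dimer cannot drift away.
    """

    def __init__(self, h=0.3, r0=1.5, w=0.5, k_tether=5.0):
        self.h, self.r0, self.w, self.k_tether = h, r0, w, k_tether

    def initial_configuration(self) -> AtomicConfiguration:
        return AtomicConfiguration(
            [[0.0, 0.0, 0.0], [self.r0 - self.w, 0.0, 0.0]], [18, 18]
        )

    def minima(self):
        return self.r0 - self.w, self.r0 + self.w

    def energy_forces(self, config):
        p = config.positions
        d = p[1] - p[0]
        r = np.linalg.norm(d)
        u = d / r
        q = (r - self.r0) ** 2 - self.w ** 2
        e = self.h * q ** 2 / self.w ** 4
        dedr = 4.0 * self.h * q * (r - self.r0) / self.w ** 4
        f = np.zeros_like(p)
        f[1] = -dedr * u
        f[0] = dedr * u
        e += 0.5 * self.k_tether * np.dot(p[0], p[0])
        f[0] -= self.k_tether * p[0]
        return float(e), f


class MuellerLike2D(PotentialBackend):
    """Müller–Brown-style 2-D surface felt by the second atom's (x, y).

    The classic four-Gaussian surface, scaled into eV; the first atom is a
    stiffly tethered anchor so descriptors (which see interatomic geometry
    only) can resolve the particle's position.
    """

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def __init__(self, scale=0.005, k_z=5.0, k_tether=20.0):
        self.scale, self.k_z, self.k_tether = scale, k_z, k_tether

    def initial_configuration(self) -> AtomicConfiguration:
        # near the deepest minimum of the Müller-Brown surface
        return AtomicConfiguration([[0.0, 0.0, 0.0], [-0.558, 1.442, 0.0]], [18, 18])

    def energy_forces(self, config):
        p = config.positions
        x, y, z = p[1]
        dx, dy = x - self.x0, y - self.y0
        terms = self.A * np.exp(self.a * dx ** 2 + self.b * dx * dy + self.c * dy ** 2)
        e = self.scale * terms.sum()
        dedx = self.scale * np.sum(terms * (2 * self.a * dx + self.b * dy))
        dedy = self.scale * np.sum(terms * (self.b * dx + 2 * self.c * dy))
        f = np.zeros_like(p)
        f[1] = [-dedx, -dedy, -self.k_z * z]
        e += 0.5 * self.k_z * z ** 2
        e += 0.5 * self.k_tether * np.dot(p[0], p[0])
        f[0] = -self.k_tether * p[0]
        return float(e), f


class LennardJonesCluster(PotentialBackend):
    """Plain 12-6 Lennard-Jones between all pairs (minimum image if periodic)."""

    def __init__(self, epsilon=0.0104, sigma=3.4):
        self.epsilon, self.sigma = epsilon, sigma

    def initial_configuration(self, n=4) -> AtomicConfiguration:
        # tetrahedral-ish seed at the pair minimum distance
        d = 2 ** (1 / 6) * self.sigma
        base = np.array(
            [[0, 0, 0], [1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float
        ) * d / np.sqrt(2)
        return AtomicConfiguration(base[:n], [18] * n)

    def energy_forces(self, config):
        p = config.positions
        n = p.shape[0]
        iu = np.triu_indices(n, 1)
        d = p[iu[1]] - p[iu[0]]
        d = mic_displacements(config, d)
        r2 = np.sum(d * d, axis=1)
        s6 = (self.sigma ** 2 / r2) ** 3
        e = 4.0 * self.epsilon * np.sum(s6 * (s6 - 1.0))
        # dE/dr2 per pair
        dedr2 = 4.0 * self.epsilon * (-6 * s6 * s6 + 3 * s6) / r2
        fpair = -2.0 * dedr2[:, None] * d  # force on atom j of the pair
        f = np.zeros_like(p)
        np.add.at(f, iu[1], fpair)
        np.subtract.at(f, iu[0], fpair)
        return float(e), f


# ---------------------------------------------------------------------------
# bonded force-field engine


class ForceField(PotentialBackend):
    """Vectorized bonded + nonbonded molecular-mechanics energy.

    Terms: harmonic bonds and angles, cosine torsions/impropers
    k (1 + cos(n phi - phase)), 12-6 LJ (Rmin/epsilon convention) and
    Coulomb with per-pair scale factors, optional harmonic tethers.
    All parameters in eV, Å, radians.
    """

    def __init__(self, bonds=(), angles=(), torsions=(), pairs=(), tethers=()):
        def arr(x, dtype=float):
            return np.asarray(x, dtype=dtype)

        bonds = list(bonds)
        self.bond_idx = arr([b[:2] for b in bonds], int).reshape(-1, 2)
        self.bond_k = arr([b[2] for b in bonds])
        self.bond_r0 = arr([b[3] for b in bonds])
        angles = list(angles)
        self.ang_idx = arr([a[:3] for a in angles], int).reshape(-1, 3)
        self.ang_k = arr([a[3] for a in angles])
        self.ang_t0 = arr([a[4] for a in angles])
        torsions = list(torsions)
        self.tor_idx = arr([t[:4] for t in torsions], int).reshape(-1, 4)
        self.tor_k = arr([t[4] for t in torsions])
        self.tor_n = arr([t[5] for t in torsions])
        self.tor_phase = arr([t[6] for t in torsions])
        pairs = list(pairs)
        self.pair_idx = arr([p[:2] for p in pairs], int).reshape(-1, 2)
        self.pair_eps = arr([p[2] for p in pairs])
        self.pair_rmin = arr([p[3] for p in pairs])
        self.pair_qq = arr([p[4] for p in pairs])
        self.pair_ljscale = arr([p[5] for p in pairs])
        tethers = list(tethers)
        self.tether_idx = arr([t[0] for t in tethers], int).reshape(-1)
        self.tether_k = arr([t[1] for t in tethers])
        self.tether_x0 = arr([t[2] for t in tethers]).reshape(-1, 3)
        self._scatter_cache = {}

    def _scatter(self, n_atoms):
        """Signed one-hot matrices turning per-term gradients into forces."""
        cached = self._scatter_cache.get(n_atoms)
        if cached is not None:
            return cached

        def signed(plus, minus):
            m = np.zeros((n_atoms, plus.size))
            m[plus, np.arange(plus.size)] += 1.0
            m[minus, np.arange(minus.size)] -= 1.0
            return m

        def onehot(idx):
            m = np.zeros((n_atoms, idx.size))
            m[idx, np.arange(idx.size)] = 1.0
            return m

        cached = {
            "bond": signed(self.bond_idx[:, 0], self.bond_idx[:, 1])
            if len(self.bond_idx) else None,
            "ang": tuple(onehot(self.ang_idx[:, c]) for c in range(3))
            if len(self.ang_idx) else None,
            "tor": tuple(onehot(self.tor_idx[:, c]) for c in range(4))
            if len(self.tor_idx) else None,
            "pair": signed(self.pair_idx[:, 0], self.pair_idx[:, 1])
            if len(self.pair_idx) else None,
        }
        self._scatter_cache[n_atoms] = cached
        return cached

    @staticmethod
    def _cross(a, b):
        out = np.empty_like(a)
        out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
        out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
        out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        return out

    def energy_forces(self, config):
        p = config.positions
        e = 0.0
        f = np.zeros_like(p)
        scatter = self._scatter(p.shape[0])

        if len(self.bond_idx):
            d = p[self.bond_idx[:, 1]] - p[self.bond_idx[:, 0]]
            r = np.sqrt(np.sum(d * d, axis=1))
            dr = r - self.bond_r0
            e += np.sum(self.bond_k * dr ** 2)
            g = (2.0 * self.bond_k * dr / r)[:, None] * d
            f += scatter["bond"] @ g

        if len(self.ang_idx):
            i, j, k = self.ang_idx.T
            u = p[i] - p[j]
            v = p[k] - p[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            c = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
            s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
            theta = np.arccos(c)
            dt = theta - self.ang_t0
            e += np.sum(self.ang_k * dt ** 2)
            dedt = 2.0 * self.ang_k * dt
            gi = (c[:, None] * uh - vh) / (nu * s)[:, None]
            gk = (c[:, None] * vh - uh) / (nv * s)[:, None]
            si, sj, sk = scatter["ang"]
            f += (sj - si) @ (dedt[:, None] * gi) + (sj - sk) @ (dedt[:, None] * gk)

        if len(self.tor_idx):
            i, j, k, l = self.tor_idx.T
            b1 = p[j] - p[i]
            b2 = p[k] - p[j]
            b3 = p[l] - p[k]
            n1 = self._cross(b1, b2)
            n2 = self._cross(b2, b3)
            nb2 = np.sqrt(np.sum(b2 * b2, axis=1))
            y = np.sum(self._cross(n1, n2) * (b2 / nb2[:, None]), axis=1)
            phi = np.arctan2(y, np.sum(n1 * n2, axis=1))
            arg = self.tor_n * phi - self.tor_phase
            e += np.sum(self.tor_k * (1.0 + np.cos(arg)))
            dedphi = -self.tor_k * self.tor_n * np.sin(arg)
            sq1 = np.sum(n1 * n1, axis=1)
            sq2 = np.sum(n2 * n2, axis=1)
            g1 = -(nb2 / sq1)[:, None] * n1
            g4 = (nb2 / sq2)[:, None] * n2
            f12 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)[:, None]
            f32 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)[:, None]
            g2 = -(1.0 + f12) * g1 + f32 * g4
            g3 = f12 * g1 - (1.0 + f32) * g4
            dp = dedphi[:, None]
            si, sj, sk, sl = scatter["tor"]
            f -= si @ (dp * g1) + sj @ (dp * g2) + sk @ (dp * g3) + sl @ (dp * g4)

        if len(self.pair_idx):
            d = p[self.pair_idx[:, 1]] - p[self.pair_idx[:, 0]]
            r2 = np.sum(d * d, axis=1)
            r = np.sqrt(r2)
            x6 = (self.pair_rmin ** 2 / r2) ** 3
            elj = self.pair_ljscale * self.pair_eps * (x6 * x6 - 2.0 * x6)
            ecoul = self.pair_qq / r
            e += np.sum(elj) + np.sum(ecoul)
            dedr2 = (
                self.pair_ljscale * self.pair_eps * (-6.0 * x6 * x6 + 6.0 * x6) / r2
            ) - 0.5 * ecoul / r2
            g = 2.0 * dedr2[:, None] * d
            f += scatter["pair"] @ g

        if len(self.tether_idx):
            d = p[self.tether_idx] - self.tether_x0
            e += np.sum(self.tether_k * np.sum(d * d, axis=1) / 2.0)
            np.subtract.at(f, self.tether_idx, self.tether_k[:, None] * d)

        return float(e), f


# ---------------------------------------------------------------------------
# torsional chain


class TorsionalChain(ForceField):
    """Carbon chain with harmonic bonds/angles and threefold torsions.

    Each inner dihedral carries E = (h/2)(1 + cos 3 phi) with barrier
    ``torsion_barrier`` = h (eV) and minima at 60°, 180° and 300°.  With no
    nonbonded terms, the torsions are nearly independent and their marginal
    Boltzmann distribution is exp(-beta (h/2)(1 + cos 3 phi)) up to the weak
    bond/angle coupling.
    """

    def __init__(self, n_atoms=5, torsion_barrier=0.25, bond_k=13.5, angle_k=2.7):
        if n_atoms < 4:
            raise ValueError("a torsional chain needs at least 4 atoms")
        self.n_atoms = n_atoms
        self.torsion_barrier = torsion_barrier
        theta0 = np.deg2rad(111.0)
        bonds = [(i, i + 1, bond_k, 1.526) for i in range(n_atoms - 1)]
        angles = [(i, i + 1, i + 2, angle_k, theta0) for i in range(n_atoms - 2)]
        self.torsion_quads = [(i, i + 1, i + 2, i + 3) for i in range(n_atoms - 3)]
        # (h/2)(1 + cos 3 phi) is minimal at 60, 180 and 300 degrees
        torsions = [
            (i, j, k, l, torsion_barrier / 2.0, 3.0, 0.0)
            for (i, j, k, l) in self.torsion_quads
        ]
        super().__init__(bonds=bonds, angles=angles, torsions=torsions)

    def torsion_energy(self, phi):
        """Closed-form single-torsion potential, eV."""
        return self.torsion_barrier / 2.0 * (1.0 + np.cos(3.0 * np.asarray(phi)))

    def initial_configuration(self, seed=0) -> AtomicConfiguration:
        rng = np.random.default_rng(seed)
        pos = np.zeros((self.n_atoms, 3))
        pos[1] = [1.526, 0.0, 0.0]
        theta = np.deg2rad(111.0)
        pos[2] = pos[1] + 1.526 * np.array([-np.cos(theta), np.sin(theta), 0.0])
        minima = np.deg2rad([60.0, 180.0, 300.0])
        for m in range(3, self.n_atoms):
            phi = rng.choice(minima)
            pos[m] = place_atom(pos[m - 3], pos[m - 2], pos[m - 1], 1.526, theta, phi)
        return AtomicConfiguration(pos, [6] * self.n_atoms)


def make_torsional_chain(n_atoms=5, torsion_barrier=0.25, seed=0):
    """Seeded chain fixture: returns (configuration, backend)."""
    backend = TorsionalChain(n_atoms=n_atoms, torsion_barrier=torsion_barrier)
    return backend.initial_configuration(seed=seed), backend


# ---------------------------------------------------------------------------
# alanine dipeptide, Amber-class


_AMBER_LJ = {  # type: (Rmin/2 Å, epsilon kcal/mol)
    "CT": (1.9080, 0.1094),
    "C": (1.9080, 0.0860),
    "O": (1.6612, 0.2100),
    "N": (1.8240, 0.1700),
    "H": (0.6000, 0.0157),
    "H1": (1.3870, 0.0157),
    "HC": (1.4870, 0.0157),
}

_AMBER_BONDS = {  # (k kcal/mol/Å², r0 Å), harmonic k(r-r0)^2 convention
    ("CT", "HC"): (340.0, 1.090),
    ("CT", "H1"): (340.0, 1.090),
    ("CT", "CT"): (310.0, 1.526),
    ("C", "CT"): (317.0, 1.522),
    ("C", "O"): (570.0, 1.229),
    ("C", "N"): (490.0, 1.335),
    ("H", "N"): (434.0, 1.010),
    ("CT", "N"): (337.0, 1.449),
}

_AMBER_ANGLES = {  # (k kcal/mol/rad², theta0 deg)
    ("HC", "CT", "HC"): (35.0, 109.50),
    ("H1", "CT", "H1"): (35.0, 109.50),
    ("CT", "C", "O"): (80.0, 120.40),
    ("CT", "C", "N"): (70.0, 116.60),
    ("N", "C", "O"): (80.0, 122.90),
    ("C", "N", "H"): (50.0, 120.00),
    ("C", "N", "CT"): (50.0, 121.90),
    ("CT", "N", "H"): (38.0, 118.04),
    ("C", "CT", "N"): (63.0, 110.10),
    ("CT", "CT", "N"): (80.0, 109.70),
    ("C", "CT", "CT"): (63.0, 111.10),
}
_ANGLE_DEFAULT = (50.0, 109.50)


class AmberDipeptide(ForceField):
    """All-atom ACE-ALA-NME with an Amber-type functional form.

    Harmonic bonds/angles, cosine proper and improper torsions, 12-6 LJ and
    Coulomb point charges with the Amber 1-4 scalings (LJ x 1/2,
    electrostatics x 1/1.2); parameters follow the ff99 family.  Backbone
    dihedrals PHI = C-N-CA-C and PSI = N-CA-C-N are exposed as index
    quadruples for Ramachandran analysis.
    """

    PHI = (1, 3, 5, 11)
    PSI = (3, 5, 11, 13)

    _types = [
        "CT", "C", "O", "N", "H", "CT", "H1", "CT", "HC", "HC", "HC",
        "C", "O", "N", "H", "CT", "H1", "H1", "H1", "HC", "HC", "HC",
    ]
    _elements = [6, 6, 8, 7, 1, 6, 1, 6, 1, 1, 1, 6, 8, 7, 1, 6, 1, 1, 1, 1, 1, 1]
    _charges = [
        -0.3662, 0.5972, -0.5679, -0.4157, 0.2719, 0.0337, 0.0823, -0.1825,
        0.0603, 0.0603, 0.0603, 0.5973, -0.5679, -0.4157, 0.2719, -0.1490,
        0.0976, 0.0976, 0.0976, 0.1123, 0.1123, 0.1123,
    ]
    _bond_list = [
        (0, 1), (1, 2), (1, 3), (3, 4), (3, 5), (5, 6), (5, 7), (7, 8), (7, 9),
        (7, 10), (5, 11), (11, 12), (11, 13), (13, 14), (13, 15), (15, 16),
        (15, 17), (15, 18), (0, 19), (0, 20), (0, 21),
    ]

    def __init__(self):
        ty = self._types
        kc = KCAL_MOL

        bonds = []
        for i, j in self._bond_list:
            key = tuple(sorted((ty[i], ty[j])))
            k, r0 = _AMBER_BONDS[tuple(sorted((ty[i], ty[j])))] if key in _AMBER_BONDS else (340.0, 1.09)
            bonds.append((i, j, k * kc, r0))

        nbr = {i: set() for i in range(22)}
        for i, j in self._bond_list:
            nbr[i].add(j)
            nbr[j].add(i)

        angles = []
        for j in range(22):
            ns = sorted(nbr[j])
            for a in range(len(ns)):
                for b in range(a + 1, len(ns)):
                    i, k = ns[a], ns[b]
                    key = (ty[i], ty[j], ty[k])
                    par = _AMBER_ANGLES.get(key) or _AMBER_ANGLES.get(key[::-1]) or _ANGLE_DEFAULT
                    angles.append((i, j, k, par[0] * kc, np.deg2rad(par[1])))

        torsions = []
        for j, k in self._bond_list:
            for i in nbr[j] - {k}:
                for l in nbr[k] - {j}:
                    for kk, n, ph in self._proper_terms(ty[i], ty[j], ty[k], ty[l], (i, j, k, l)):
                        torsions.append((i, j, k, l, kk * kc, n, np.deg2rad(ph)))
        # impropers keep the sp2 centers planar (center third in the quad)
        for quad, kk in [
            ((0, 3, 1, 2), 10.5), ((5, 13, 11, 12), 10.5),
            ((1, 5, 3, 4), 1.1), ((11, 15, 13, 14), 1.1),
        ]:
            torsions.append((*quad, kk * kc, 2.0, np.deg2rad(180.0)))

        pairs = []
        ke = COULOMB
        for i in range(22):
            for j in range(i + 1, 22):
                if j in nbr[i]:
                    continue
                if any(j in nbr[m] for m in nbr[i]):
                    continue  # 1-3
                is14 = any(
                    j in nbr[n] for m in nbr[i] for n in nbr[m] if n != i
                ) and not any(j in nbr[m] for m in nbr[i])
                ljscale = 0.5 if is14 else 1.0
                qqscale = 1.0 / 1.2 if is14 else 1.0
                r1, e1 = _AMBER_LJ[ty[i]]
                r2, e2 = _AMBER_LJ[ty[j]]
                pairs.append(
                    (
                        i, j,
                        np.sqrt(e1 * e2) * kc,
                        r1 + r2,
                        qqscale * ke * self._charges[i] * self._charges[j],
                        ljscale,
                    )
                )
        super().__init__(bonds=bonds, angles=angles, torsions=torsions, pairs=pairs)

    @staticmethod
    def _proper_terms(ti, tj, tk, tl, quad):
        """Cosine terms (k kcal, n, phase deg) for one torsion path."""
        mid = tuple(sorted((tj, tk)))
        if quad in (AmberDipeptide.PHI, AmberDipeptide.PHI[::-1]):
            return [(0.27, 1.0, 0.0), (1.00, 2.0, 180.0), (0.42, 3.0, 0.0)]
        if quad in (AmberDipeptide.PSI, AmberDipeptide.PSI[::-1]):
            return [(0.45, 1.0, 180.0), (1.58, 2.0, 180.0), (0.55, 3.0, 180.0)]
        if mid == ("C", "N"):
            return [(2.5, 2.0, 180.0)]  # amide planarity, 4 paths x 2.5
        if mid == ("CT", "CT"):
            return [(1.40 / 9.0, 3.0, 0.0)]
        if mid == ("CT", "N"):
            return [(0.0, 2.0, 0.0)]
        if mid == ("C", "CT"):
            return [(0.0, 2.0, 0.0)]
        return [(0.0, 2.0, 0.0)]

    def initial_configuration(self, phi_deg=-80.0, psi_deg=75.0, relax=True):
        """Build from internal coordinates at the given backbone dihedrals."""
        d = np.deg2rad
        pos = np.zeros((22, 3))
        pos[1] = [1.522, 0.0, 0.0]
        pos[2] = pos[1] + 1.229 * np.array([-np.cos(d(120.4)), np.sin(d(120.4)), 0.0])

        def put(idx, c, b, a, r, theta, phi):
            pos[idx] = place_atom(pos[a], pos[b], pos[c], r, d(theta), d(phi))

        put(3, 1, 0, 2, 1.335, 116.6, 180.0)
        put(4, 3, 1, 2, 1.010, 118.0, 180.0)
        put(5, 3, 1, 2, 1.449, 121.9, 0.0)
        put(11, 5, 3, 1, 1.522, 110.1, phi_deg)
        put(7, 5, 3, 1, 1.526, 109.7, phi_deg + 122.0)
        put(6, 5, 3, 1, 1.090, 109.5, phi_deg - 119.0)
        put(8, 7, 5, 3, 1.090, 109.5, 60.0)
        put(9, 7, 5, 3, 1.090, 109.5, 180.0)
        put(10, 7, 5, 3, 1.090, 109.5, 300.0)
        put(13, 11, 5, 3, 1.335, 116.6, psi_deg)
        put(12, 11, 5, 3, 1.229, 120.4, psi_deg + 180.0)
        put(14, 13, 11, 12, 1.010, 118.0, 180.0)
        put(15, 13, 11, 12, 1.449, 121.9, 0.0)
        put(16, 15, 13, 11, 1.090, 109.5, 60.0)
        put(17, 15, 13, 11, 1.090, 109.5, 180.0)
        put(18, 15, 13, 11, 1.090, 109.5, 300.0)
        put(19, 0, 1, 2, 1.090, 109.5, 60.0)
        put(20, 0, 1, 2, 1.090, 109.5, 180.0)
        put(21, 0, 1, 2, 1.090, 109.5, 300.0)
        cfg = AtomicConfiguration(pos, np.array(self._elements))
        if relax:
            cfg = self.relax(cfg)
        return cfg

    def relax(self, config, maxiter=500):
        from scipy.optimize import minimize

        shape = config.positions.shape

        def fun(x):
            c = AtomicConfiguration(x.reshape(shape), config.atomic_numbers)
            e, f = self.energy_forces(c)
            return e, -f.ravel()

        res = minimize(fun, config.positions.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        return AtomicConfiguration(res.x.reshape(shape), config.atomic_numbers)


# ---------------------------------------------------------------------------
# mock ensembles


class MockEnsembleBackend(PotentialBackend):
    """Wrap a backend with analytic per-member perturbations.

    Member m predicts E_m = E + a_m * sum_i sin(b x_i + c_m) over atom x
    coordinates; energies and forces stay mutually consistent, so ensemble
    disagreement (and hence the uncertainty-driven bias) has exact
    derivatives.
    """

    def __init__(self, base: PotentialBackend, amplitudes=(0.02, -0.02, 0.01, -0.01),
                 wavevector=1.3):
        self.base = base
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.wavevector = float(wavevector)
        self.phases = np.linspace(0.0, np.pi, len(self.amplitudes))

    @property
    def n_members(self):
        return len(self.amplitudes)

    def member_energies_forces(self, config):
        e0, f0 = self.base.energy_forces(config)
        x = config.positions[:, 0]
        b = self.wavevector
        es, fs = [], []
        for a_m, c_m in zip(self.amplitudes, self.phases):
            es.append(e0 + a_m * np.sum(np.sin(b * x + c_m)))
            fm = f0.copy()
            fm[:, 0] -= a_m * b * np.cos(b * x + c_m)
            fs.append(fm)
        return np.array(es), np.array(fs)

    def energy_forces(self, config):
        es, fs = self.member_energies_forces(config)
        return float(es.mean()), fs.mean(axis=0)

    def uncertainty(self, config):
        es, fs = self.member_energies_forces(config)
        fbar = fs.mean(axis=0)
        sig2 = float(np.mean((es - es.mean()) ** 2))
        per_atom = np.sqrt(np.mean(np.sum((fs - fbar) ** 2, axis=-1), axis=0))
        return {
            "sigma2_energy": sig2,
            "member_energies": es,
            "member_forces": fs,
            "force_uncertainty": per_atom,
        }


class ScheduledUncertaintyBackend(PotentialBackend):
    """Backend whose reported force uncertainty follows a call-indexed script.

    Useful for testing the reset guard: ``schedule(call_index)`` returns the
    per-atom force uncertainty reported on the guard's n-th query.
    """

    def __init__(self, base: PotentialBackend, schedule):
        self.base = base
        self.schedule = schedule
        self.calls = 0

    def energy_forces(self, config):
        return self.base.energy_forces(config)

    def uncertainty(self, config):
        value = float(self.schedule(self.calls))
        self.calls += 1
        n = config.n_atoms
        return {
            "sigma2_energy": value ** 2,
            "member_energies": None,
            "member_forces": None,
            "force_uncertainty": np.full(n, value),
        }
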