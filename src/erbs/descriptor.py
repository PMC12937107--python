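"""Element-agnostic Gaussian-moment descriptors.

Per-atom moments are radially-weighted tensor powers of unit bond vectors,

    Psi_{i,L,n} = sum_{j != i} R_n(r_ij) * rhat_ij^(x L),

and invariant per-atom features G_i are obtained by fully contracting the
moments.  The global descriptor s' is the mean of G_i over all atoms; it is
invariant under rigid rotations, translations and atom relabeling, and is
differentiable with respect to the positions (analytic chain rule).

Contraction patterns are named by the moment orders they combine:
``"0"`` (radial channel sums), ``"1,1"`` (vector dot products over channel
pairs n1 <= n2), ``"1,3,2"`` (vector x rank-3 x rank-2 full contraction over
all channel triples), plus the optional ``"2,2"``, ``"3,3"``, ``"1,1,2"``
and ``"2,2,2"`` invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import AtomicConfiguration, neighbor_pairs

_SUPPORTED_PATTERNS = ("0", "1,1", "2,2", "3,3", "1,1,2", "1,3,2", "2,2,2")
DEFAULT_CONTRACTIONS = ("0", "1,1", "1,3,2")


def _pattern_orders(pattern: str) -> tuple[int, ...]:
    return tuple(int(t) for t in pattern.split(","))


@dataclass(frozen=True)
class DescriptorSettings:
    """Hyperparameters of the Gaussian-moment descriptor.

    Parameters
    ----------
    cutoff : float
        Radial cutoff in Å; basis functions and their derivatives vanish
        smoothly at this distance.
    n_radial : int
        Number of radial basis functions (radial channels).
    basis_kind : {"gaussian", "bessel"}
        Gaussians with evenly spaced centers in [0, cutoff], or
        sine-type (zeroth spherical Bessel) functions; both carry a cosine
        cutoff envelope.
    max_moment_order : int
        Highest tensor rank L of the Cartesian moments (L <= 3).
    contractions : tuple of str
        Contraction patterns building the invariants.
    scale : float
        Overall normalization: every invariant is divided by this constant.
        It fixes the unit of CV space (and hence the meaning of kernel
        bandwidths); choose it so thermal fluctuations of the leading CVs
        land on the bandwidth scale the bias is configured with.
    """

    cutoff: float = 5.0
    n_radial: int = 5
    basis_kind: str = "gaussian"
    max_moment_order: int = 3
    contractions: tuple[str, ...] = DEFAULT_CONTRACTIONS
    scale: float = 1.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.n_radial < 1:
            raise ValueError("n_radial must be >= 1")
        if self.basis_kind not in ("gaussian", "bessel"):
            raise ValueError(f"unknown basis_kind {self.basis_kind!r}")
        if not 0 <= self.max_moment_order <= 3:
            raise ValueError("max_moment_order must be in 0..3")
        object.__setattr__(self, "contractions", tuple(self.contractions))
        for pat in self.contractions:
            if pat not in _SUPPORTED_PATTERNS:
                raise ValueError(f"unsupported contraction pattern {pat!r}")
            if max(_pattern_orders(pat)) > self.max_moment_order:
                raise ValueError(
                    f"contraction {pat!r} references a moment order above "
                    f"max_moment_order={self.max_moment_order}"
                )

    @property
    def orders(self) -> tuple[int, ...]:
        """Moment orders required by the configured contractions."""
        needed = sorted({o for pat in self.contractions for o in _pattern_orders(pat)})
        return tuple(needed)

    def pattern_dimension(self, pattern: str) -> int:
        n = self.n_radial
        tri = n * (n + 1) // 2
        return {
            "0": n, "1,1": tri, "2,2": tri, "3,3": tri,
            "1,1,2": tri * n, "1,3,2": n ** 3, "2,2,2": n ** 3,
        }[pattern]

    @property
    def dimension(self) -> int:
        """Length D of the invariant feature vector."""
        return sum(self.pattern_dimension(p) for p in self.contractions)


@dataclass
class GlobalDescriptor:
    """System-averaged invariant feature vector, optionally with its Jacobian.

    ``jacobian[f, 3*m + d]`` is the derivative of feature ``f`` with respect
    to Cartesian component ``d`` of atom ``m`` (units 1/Å).
    """

    values: np.ndarray
    jacobian: np.ndarray | None = None


# ---------------------------------------------------------------------------
# radial basis


def _envelope(r: np.ndarray, cutoff: float):
    """Cosine cutoff envelope and its derivative; zero at and beyond cutoff."""
    inside = r < cutoff
    x = np.pi * r / cutoff
    f = np.where(inside, 0.5 * (1.0 + np.cos(x)), 0.0)
    df = np.where(inside, -0.5 * np.pi / cutoff * np.sin(x), 0.0)
    return f, df


def _radial_raw(r: np.ndarray, settings: DescriptorSettings):
    """Bare basis functions and derivatives, shape (..., n_radial)."""
    n = settings.n_radial
    c = settings.cutoff
    r = r[..., None]
    if settings.basis_kind == "gaussian":
        centers = np.linspace(0.0, c, n) if n > 1 else np.array([0.0])
        width = c / n
        arg = (r - centers) / width
        g = np.exp(-0.5 * arg ** 2)
        dg = -arg / width * g
        return g, dg
    # sine-type Bessel basis: sqrt(2/c) sin(k r)/r with k = n pi / c
    k = np.arange(1, n + 1) * np.pi / c
    norm = np.sqrt(2.0 / c)
    small = r < 1e-10
    rsafe = np.where(small, 1.0, r)
    val = np.where(small, norm * k, norm * np.sin(k * rsafe) / rsafe)
    dval = np.where(
        small, 0.0, norm * (k * np.cos(k * rsafe) * rsafe - np.sin(k * rsafe)) / rsafe ** 2
    )
    return val, dval


def radial_basis(r, settings: DescriptorSettings) -> np.ndarray:
    """Evaluate the radial basis (with cutoff envelope) at distance(s) ``r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    raw, _ = _radial_raw(r, settings)
    env, _ = _envelope(r, settings.cutoff)
    return raw * env[..., None]


def radial_basis_with_derivative(r, settings: DescriptorSettings):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    raw, draw = _radial_raw(r, settings)
    env, denv = _envelope(r, settings.cutoff)
    return raw * env[..., None], draw * env[..., None] + raw * denv[..., None]


# ---------------------------------------------------------------------------
# moments


def _pair_data(config: AtomicConfiguration, settings: DescriptorSettings):
    idx_i, idx_j, rij, dist = neighbor_pairs(config, settings.cutoff)
    if idx_i.size == 0:
        return idx_i, idx_j, None
    rb, drb = radial_basis_with_derivative(dist, settings)
    u = rij / dist[:, None]
    return idx_i, idx_j, (rb, drb, u, dist)


def _center_onehot(n_atoms, idx):
    onehot = np.zeros((n_atoms, idx.size))
    onehot[idx, np.arange(idx.size)] = 1.0
    return onehot


def _stack_moments(config, settings, pair_data, onehot=None):
    """Per-atom moments {L: (N, n, 3^L ...)} from directed pair data.

    Accumulation over pairs runs as a single dense matmul against the
    central-atom one-hot matrix (pair counts here are small).
    """
    n_atoms = config.n_atoms
    n = settings.n_radial
    idx_i, idx_j, payload = pair_data
    moments = {}
    shapes = {0: (), 1: (3,), 2: (3, 3), 3: (3, 3, 3)}
    if payload is None:
        for L in settings.orders:
            moments[L] = np.zeros((n_atoms, n) + shapes[L])
        return moments
    rb, _, u, _ = payload
    p = idx_i.size
    # radial weights folded in at the lowest rank, higher ranks by one
    # outer product each
    terms = {}
    if 0 in settings.orders:
        terms[0] = rb
    t1 = rb[:, :, None] * u[:, None, :]
    terms[1] = t1
    if 2 in settings.orders or 3 in settings.orders:
        t2 = t1.reshape(p, -1, 3, 1) * u[:, None, None, :]
        terms[2] = t2
        if 3 in settings.orders:
            terms[3] = t2.reshape(p, -1, 9, 1) * u[:, None, None, :]
    blocks = [terms[L].reshape(p, -1) for L in settings.orders]
    widths = [b.shape[1] for b in blocks]
    if onehot is None:
        onehot = _center_onehot(n_atoms, idx_i)
    stacked = onehot @ np.concatenate(blocks, axis=1)
    offset = 0
    for L, width in zip(settings.orders, widths):
        moments[L] = stacked[:, offset : offset + width].reshape(
            (n_atoms, n) + shapes[L]
        )
        offset += width
    return moments


def cartesian_moments(
    config: AtomicConfiguration, i: int, settings: DescriptorSettings
) -> dict[int, np.ndarray]:
    """Moments Psi_{i,L,n} of atom ``i`` for every order the settings need.

    Returns a dict mapping order L to an array of shape (n_radial, 3, ..., 3)
    with L trailing Cartesian axes.  An isolated atom yields all zeros.
    """
    moments = _stack_moments(config, settings, _pair_data(config, settings))
    return {L: m[i] for L, m in moments.items()}


# ---------------------------------------------------------------------------
# contractions

def _tri_indices(n):
    return np.triu_indices(n)


def _contract_stack(moments: dict[int, np.ndarray], settings: DescriptorSettings):
    """Invariants G for a stack of per-atom moments -> (N, D)."""
    pieces = []
    n = settings.n_radial
    iu = _tri_indices(n)
    for pat in settings.contractions:
        if pat == "0":
            pieces.append(moments[0])
        elif pat == "1,1":
            f = np.einsum("xna,xma->xnm", moments[1], moments[1])
            pieces.append(f[:, iu[0], iu[1]])
        elif pat == "2,2":
            f = np.einsum("xnab,xmab->xnm", moments[2], moments[2])
            pieces.append(f[:, iu[0], iu[1]])
        elif pat == "3,3":
            f = np.einsum("xnabc,xmabc->xnm", moments[3], moments[3])
            pieces.append(f[:, iu[0], iu[1]])
        elif pat == "1,1,2":
            f = np.einsum("xna,xmb,xqab->xnmq", moments[1], moments[1], moments[2])
            pieces.append(f[:, iu[0], iu[1], :].reshape(f.shape[0], -1))
        elif pat == "1,3,2":
            f = np.einsum("xna,xmabc,xqbc->xnmq", moments[1], moments[3], moments[2])
            pieces.append(f.reshape(f.shape[0], -1))
        elif pat == "2,2,2":
            f = np.einsum("xnab,xmbc,xqca->xnmq", moments[2], moments[2], moments[2])
            pieces.append(f.reshape(f.shape[0], -1))
    return np.concatenate(pieces, axis=1) / settings.scale


def contract_moments(
    moments: dict[int, np.ndarray], settings: DescriptorSettings
) -> np.ndarray:
    """Fully contract one atom's moments into its invariant feature vector."""
    for pat in settings.contractions:
        for o in _pattern_orders(pat):
            if o not in moments:
                raise ValueError(
                    f"contraction {pat!r} needs moment order {o}, not provided"
                )
    stacked = {L: m[None] for L, m in moments.items()}
    return _contract_stack(stacked, settings)[0]


# ---------------------------------------------------------------------------
# derivatives

_EYE3 = np.eye(3)


def _pair_moment_derivatives(payload, orders):
    """d/d(g_d) of one pair's moment contribution, g = R_j - R_i.

    Returns {L: array (P, n, [3]*L, 3)} with the last axis the derivative
    direction d.
    """
    rb, drb, u, dist = payload
    inv_r = 1.0 / dist
    # pi[p, a, d] = (delta_ad - u_a u_d) / r
    pi = (_EYE3[None] - u[:, :, None] * u[:, None, :]) * inv_r[:, None, None]
    out = {}
    if 0 in orders:
        out[0] = drb[:, :, None] * u[:, None, :]
    if 1 in orders:
        out[1] = (
            np.einsum("pn,pa,pd->pnad", drb, u, u)
            + rb[:, :, None, None] * pi[:, None]
        )
    if 2 in orders:
        uu = u[:, :, None] * u[:, None, :]
        t = np.einsum("pad,pb->pabd", pi, u)
        sym2 = t + t.transpose(0, 2, 1, 3)
        out[2] = (
            np.einsum("pn,pab,pd->pnabd", drb, uu, u)
            + rb[:, :, None, None, None] * sym2[:, None]
        )
    if 3 in orders:
        uu = u[:, :, None] * u[:, None, :]
        t = np.einsum("pad,pb,pc->pabcd", pi, u, u)
        sym3 = t + t.transpose(0, 2, 1, 3, 4) + t.transpose(0, 2, 3, 1, 4)
        uuu = uu[:, :, :, None] * u[:, None, None, :]
        out[3] = (
            np.einsum("pn,pabc,pd->pnabcd", drb, uuu, u)
            + rb[:, :, None, None, None, None] * sym3[:, None]
        )
    return out


def _pattern_pair_jacobian(pat, Pm, dT):
    """Per-pair derivative of the central atom's invariants, (P, D_pat, 3).

    ``Pm`` holds the central atom's total moments gathered per pair.
    """
    P = next(iter(dT.values())).shape[0]
    if pat == "0":
        return dT[0]
    if pat in ("1,1", "2,2", "3,3"):
        spec = {"1,1": "xnad,xma->xnmd", "2,2": "xnabd,xmab->xnmd",
                "3,3": "xnabcd,xmabc->xnmd"}[pat]
        L = _pattern_orders(pat)[0]
        d = np.einsum(spec, dT[L], Pm[L])
        d = d + d.transpose(0, 2, 1, 3)
        n = d.shape[1]
        iu = _tri_indices(n)
        return d[:, iu[0], iu[1]]
    if pat == "1,1,2":
        t1 = np.einsum("xnad,xmb,xqab->xnmqd", dT[1], Pm[1], Pm[2])
        t3 = np.einsum("xna,xmb,xqabd->xnmqd", Pm[1], Pm[1], dT[2])
        d = t1 + t1.transpose(0, 2, 1, 3, 4) + t3
        n = d.shape[1]
        iu = _tri_indices(n)
        return d[:, iu[0], iu[1]].reshape(P, -1, 3)
    if pat == "1,3,2":
        d = (
            np.einsum("xnad,xmabc,xqbc->xnmqd", dT[1], Pm[3], Pm[2])
            + np.einsum("xna,xmabcd,xqbc->xnmqd", Pm[1], dT[3], Pm[2])
            + np.einsum("xna,xmabc,xqbcd->xnmqd", Pm[1], Pm[3], dT[2])
        )
        return d.reshape(P, -1, 3)
    if pat == "2,2,2":
        d = (
            np.einsum("xnabd,xmbc,xqca->xnmqd", dT[2], Pm[2], Pm[2])
            + np.einsum("xnab,xmbcd,xqca->xnmqd", Pm[2], dT[2], Pm[2])
            + np.einsum("xnab,xmbc,xqcad->xnmqd", Pm[2], Pm[2], dT[2])
        )
        return d.reshape(P, -1, 3)
    raise ValueError(pat)


def global_descriptor(
    config: AtomicConfiguration,
    settings: DescriptorSettings,
    with_jacobian: bool = False,
) -> GlobalDescriptor:
    """Mean invariant feature vector s' of the whole system (and Jacobian)."""
    pair_data = _pair_data(config, settings)
    moments = _stack_moments(config, settings, pair_data)
    G = _contract_stack(moments, settings)
    values = G.mean(axis=0)
    if not with_jacobian:
        return GlobalDescriptor(values)

    n_atoms = config.n_atoms
    D = settings.dimension
    jac = np.zeros((D, n_atoms, 3))
    idx_i, idx_j, payload = pair_data
    if payload is not None:
        dT = _pair_moment_derivatives(payload, settings.orders)
        Pm = {L: moments[L][idx_i] for L in settings.orders}
        offset = 0
        for pat in settings.contractions:
            dG = _pattern_pair_jacobian(pat, Pm, dT)  # (P, Dp, 3)
            Dp = dG.shape[1]
            block = np.zeros((n_atoms, Dp, 3))
            np.add.at(block, idx_j, dG)
            np.subtract.at(block, idx_i, dG)
            jac[offset : offset + Dp] = block.transpose(1, 0, 2)
            offset += Dp
    jac /= n_atoms * settings.scale
    return GlobalDescriptor(values, jac.reshape(D, 3 * n_atoms))


def _pattern_adjoints(pat, w, moments, n):
    """Per-atom d(w . G)/dPsi_L for one pattern; returns {L: (N, n, ...)}.

    ``w`` is the weight slice for this pattern's features.
    """
    iu = _tri_indices(n)
    out = {}
    if pat == "0":
        out[0] = np.broadcast_to(w, moments[0].shape)
        return out
    if pat in ("1,1", "2,2", "3,3"):
        W = np.zeros((n, n))
        W[iu] = w
        W = W + W.T  # doubles the diagonal: d(Psi.Psi)/dPsi = 2 Psi
        L = _pattern_orders(pat)[0]
        spec = {1: "nm,xma->xna", 2: "nm,xmab->xnab", 3: "nm,xmabc->xnabc"}[L]
        out[L] = np.einsum(spec, W, moments[L])
        return out
    if pat == "1,1,2":
        Wt = np.zeros((n, n, n))
        Wt[iu[0], iu[1], :] = w.reshape(-1, n)
        Wsym = Wt + Wt.transpose(1, 0, 2)
        out[1] = np.einsum("nmq,xmb,xqab->xna", Wsym, moments[1], moments[2])
        out[2] = np.einsum("nmq,xna,xmb->xqab", Wt, moments[1], moments[1])
        return out
    if pat == "1,3,2":
        W = w.reshape(n, n, n)
        out[1] = np.einsum("nmq,xmabc,xqbc->xna", W, moments[3], moments[2])
        out[3] = np.einsum("nmq,xna,xqbc->xmabc", W, moments[1], moments[2])
        out[2] = np.einsum("nmq,xna,xmabc->xqbc", W, moments[1], moments[3])
        return out
    if pat == "2,2,2":
        W = w.reshape(n, n, n)
        out[2] = (
            np.einsum("nmq,xmbc,xqca->xnab", W, moments[2], moments[2])
            + np.einsum("nmq,xnab,xqca->xmbc", W, moments[2], moments[2])
            + np.einsum("nmq,xnab,xmbc->xqca", W, moments[2], moments[2])
        )
        return out
    raise ValueError(pat)


class DescriptorState:
    """Moments of one configuration, reusable for value and gradient queries.

    Computing the moments once and asking for several vector-Jacobian
    products against them is what the MD loop needs: the descriptor value
    feeds the CV projection, and the bias chain rule then asks for the
    gradient of a single linear functional of s'.
    """

    def __init__(self, config: AtomicConfiguration, settings: DescriptorSettings):
        self.config = config
        self.settings = settings
        self._pair_data = _pair_data(config, settings)
        idx_i, idx_j, payload = self._pair_data
        if payload is not None:
            self._onehot_i = _center_onehot(config.n_atoms, idx_i)
            self._onehot_j = _center_onehot(config.n_atoms, idx_j)
        else:
            self._onehot_i = self._onehot_j = None
        self._moments = _stack_moments(
            config, settings, self._pair_data, onehot=self._onehot_i
        )
        self.values = _contract_stack(self._moments, settings).mean(axis=0)

    def vjp(self, weights: np.ndarray) -> np.ndarray:
        """Gradient of ``weights . s'`` w.r.t. positions, shape (N, 3).

        The pair contraction is evaluated algebraically: for each moment
        order the adjoint tensor is contracted with powers of the unit bond
        vector, so no rank-4 per-pair derivative tensors are materialized.
        """
        settings = self.settings
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (settings.dimension,):
            raise ValueError("weights length must equal the descriptor dimension")
        n_atoms = self.config.n_atoms
        idx_i, idx_j, payload = self._pair_data
        if payload is None:
            return np.zeros((n_atoms, 3))
        adjoint = {L: 0.0 for L in settings.orders}
        offset = 0
        for pat in settings.contractions:
            Dp = settings.pattern_dimension(pat)
            for L, a in _pattern_adjoints(
                pat, weights[offset : offset + Dp], self._moments, settings.n_radial
            ).items():
                adjoint[L] = adjoint[L] + a
            offset += Dp

        rb, drb, u, dist = payload
        inv_r = 1.0 / dist
        radial = np.zeros(idx_i.size)  # coefficient of u_d from dR_n/dr terms
        angular = np.zeros((idx_i.size, 3))  # (delta - u u)/r terms
        rb_m = rb[:, None, :]  # (P, 1, n) for batched channel contraction
        drb_m = drb[:, None, :]
        for L in settings.orders:
            aL = adjoint[L]
            if isinstance(aL, float):
                continue
            # per-pair adjoint with the radial channel contracted away first
            ap = aL[idx_i].reshape(idx_i.size, settings.n_radial, -1)
            a_rb = (rb_m @ ap)[:, 0]  # (P, 3^L)
            a_drb = (drb_m @ ap)[:, 0]
            if L == 0:
                radial += a_drb[:, 0]
                continue
            if L == 1:
                radial += np.einsum("pa,pa->p", a_drb, u)
                s_rb = np.einsum("pa,pa->p", a_rb, u)
                w_sum = a_rb
                n_slots = 1
            elif L == 2:
                a_rb = a_rb.reshape(-1, 3, 3)
                a_drb = a_drb.reshape(-1, 3, 3)
                radial += np.einsum("pab,pa,pb->p", a_drb, u, u)
                t_a = np.einsum("pab,pb->pa", a_rb, u)
                t_b = np.einsum("pab,pa->pb", a_rb, u)
                s_rb = np.einsum("pa,pa->p", t_a, u)
                w_sum = t_a + t_b
                n_slots = 2
            else:  # L == 3
                a_rb = a_rb.reshape(-1, 3, 3, 3)
                a_drb = a_drb.reshape(-1, 3, 3, 3)
                radial += np.einsum("pabc,pa,pb,pc->p", a_drb, u, u, u)
                b3 = np.einsum("pabc,pc->pab", a_rb, u)
                f3 = np.einsum("pabc,pa->pbc", a_rb, u)
                c3 = np.einsum("pab,pb->pa", b3, u)
                d3 = np.einsum("pab,pa->pb", b3, u)
                e3 = np.einsum("pbc,pb->pc", f3, u)
                s_rb = np.einsum("pa,pa->p", c3, u)
                w_sum = c3 + d3 + e3
                n_slots = 3
            angular += (w_sum - n_slots * s_rb[:, None] * u) * inv_r[:, None]
        v = radial[:, None] * u + angular
        grad = self._onehot_j @ v - self._onehot_i @ v
        grad /= n_atoms * settings.scale
        return grad


def global_descriptor_vjp(
    config: AtomicConfiguration,
    settings: DescriptorSettings,
    weights: np.ndarray,
):
    """Value of s' together with the gradient of ``weights . s'``.

    Adjoint (vector-Jacobian product) path: for a fixed co-vector
    ``weights`` of length D it returns ``(s', d(weights . s')/dR)`` with the
    gradient of shape (N, 3), never materializing the full Jacobian.
    """
    state = DescriptorState(config, settings)
    return state.values, state.vjp(weights)
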