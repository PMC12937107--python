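"""Internal-coordinate geometry: angles, dihedrals, their gradients, NeRF."""

from __future__ import annotations

import numpy as np


def dihedral(positions: np.ndarray, quad) -> float:
    """Signed dihedral (IUPAC, atan2 construction) in radians, [-pi, pi)."""
    return dihedral_batch(positions[None], [quad])[0, 0]


def dihedral_batch(positions: np.ndarray, quads) -> np.ndarray:
    """Dihedrals for frames (F, N, 3) and quadruples (Q, 4) -> (F, Q) rad."""
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    p = positions[:, quads, :]  # (F, Q, 4, 3)
    b1 = p[:, :, 1] - p[:, :, 0]
    b2 = p[:, :, 2] - p[:, :, 1]
    b3 = p[:, :, 3] - p[:, :, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2h = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2h, axis=-1)
    return np.arctan2(y, x)


def dihedral_gradient(positions: np.ndarray, quad):
    """Dihedral angle and its gradient w.r.t. the four atoms.

    Returns (phi, grad (4, 3)); grads sum to zero (translation invariance).
    """
    i, j, k, l = quad
    b1 = positions[j] - positions[i]
    b2 = positions[k] - positions[j]
    b3 = positions[l] - positions[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2))
    sq1 = np.dot(n1, n1)
    sq2 = np.dot(n2, n2)
    g1 = -nb2 / sq1 * n1
    g4 = nb2 / sq2 * n2
    f12 = np.dot(b1, b2) / nb2 ** 2
    f32 = np.dot(b3, b2) / nb2 ** 2
    g2 = -(1.0 + f12) * g1 + f32 * g4
    g3 = f12 * g1 - (1.0 + f32) * g4
    return phi, np.array([g1, g2, g3, g4])


def bend_angle_gradient(positions: np.ndarray, triple):
    """Bond angle i-j-k (vertex j) and its gradient, (theta, grad (3, 3))."""
    i, j, k = triple
    u = positions[i] - positions[j]
    v = positions[k] - positions[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = np.clip(np.dot(uh, vh), -1.0, 1.0)
    s = np.sqrt(max(1.0 - c * c, 1e-14))
    theta = np.arccos(c)
    gi = (c * uh - vh) / (nu * s)
    gk = (c * vh - uh) / (nv * s)
    return theta, np.array([gi, -(gi + gk), gk])


def place_atom(a, b, c, r, theta, phi):
    """NeRF: position a new atom at distance ``r`` from ``c``, angle ``theta``
    (new-c-b) and dihedral ``phi`` (new-c-b-a).  Angles in radians."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n
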