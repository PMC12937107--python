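"""Extended-XYZ reading and writing.

The dialect understood here is the common one: a per-frame comment line of
``key=value`` tokens (values quoted if they contain spaces), a ``Lattice``
key holding nine numbers (row-major lattice vectors), a ``pbc`` key of three
T/F flags, and a ``Properties=species:S:1:pos:R:3`` column declaration.
Additional scalar comment keys round-trip through each configuration's
``info`` dict at full floating precision.
"""

from __future__ import annotations

import re

import numpy as np

from .system import AtomicConfiguration
from .units import NUMBERS


class ExtxyzError(ValueError):
    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_TOKEN = re.compile(r'(\S+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict:
    out = {}
    for m in _TOKEN.finditer(comment):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3)
        out[key] = val
    return out


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    if isinstance(x, (np.ndarray, list, tuple)):
        return '"' + " ".join(repr(float(v)) for v in np.ravel(x)) + '"'
    return str(x)


def read_extxyz(path) -> list[AtomicConfiguration]:
    """Read all frames; per-frame comment keys land in each ``info`` dict."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ExtxyzError(f"expected atom count, got {lines[ln]!r}", ln + 1)
        if ln + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise ExtxyzError("truncated frame", ln + 1)
        fields = _parse_comment(lines[ln + 1])
        cell = None
        pbc = np.zeros(3, dtype=bool)
        if "Lattice" in fields:
            vals = [float(v) for v in fields.pop("Lattice").split()]
            if len(vals) != 9:
                raise ExtxyzError("Lattice needs nine numbers", ln + 2)
            cell = np.array(vals).reshape(3, 3)
            pbc = np.ones(3, dtype=bool)
        if "pbc" in fields:
            pbc = np.array([t in ("T", "True", "1") for t in fields.pop("pbc").split()])
        fields.pop("Properties", None)
        info = {}
        for key, val in fields.items():
            try:
                parts = val.split()
                info[key] = (
                    float(parts[0]) if len(parts) == 1 else np.array([float(p) for p in parts])
                )
            except ValueError:
                info[key] = val
        symbols, positions = [], []
        for a in range(natoms):
            row = lines[ln + 2 + a].split()
            if len(row) < 4:
                raise ExtxyzError("atom line needs symbol and xyz", ln + 3 + a)
            symbols.append(row[0])
            try:
                positions.append([float(row[1]), float(row[2]), float(row[3])])
            except ValueError:
                raise ExtxyzError("non-numeric coordinate", ln + 3 + a)
        try:
            numbers = [NUMBERS[s] if s in NUMBERS else int(s) for s in symbols]
        except ValueError:
            raise ExtxyzError("unknown chemical symbol", ln + 3)
        cfg = AtomicConfiguration(np.array(positions), np.array(numbers), cell, pbc)
        cfg.info = info
        frames.append(cfg)
        ln += 2 + natoms
    return frames


def write_extxyz(path, frames, mode="w"):
    """Write configurations (each optionally carrying an ``info`` dict)."""
    if isinstance(frames, AtomicConfiguration):
        frames = [frames]
    with open(path, mode) as fh:
        for cfg in frames:
            tokens = []
            if cfg.cell is not None:
                tokens.append("Lattice=" + _fmt(cfg.cell))
            tokens.append('pbc="' + " ".join("T" if f else "F" for f in cfg.pbc) + '"')
            tokens.append("Properties=species:S:1:pos:R:3")
            for key, val in getattr(cfg, "info", {}).items():
                tokens.append(f"{key}=" + _fmt(val))
            fh.write(f"{cfg.n_atoms}\n")
            fh.write(" ".join(tokens) + "\n")
            for sym, p in zip(cfg.symbols, cfg.positions):
                fh.write(
                    f"{sym} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n"
                )
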