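"""Idealized phospholipid templates.

Each template lists atom names, elements, hydrogen->heavy bonding, rough
reference geometry (head at z=0, tails extending toward −z) and the
hydrogen-bond / hydrophobicity / formal-charge typing of every atom.  The
DPPC-like template has the 130 atoms of 1,2-dipalmitoyl-phosphatidylcholine
(C40 H80 N O8 P); the POPE-like template the 125 atoms of
1-palmitoyl-2-oleoyl-phosphatidylethanolamine (C39 H76 N O8 P, one cis
double bond in the sn-2 chain).  Head-group heavy atoms carry the PDB-style
names used throughout (P, N, O11–O14, O21, O22, O31, O32, C11, C12, ...).

Geometry here is schematic — only atom counts, names, typing and the
head/tail arrangement matter for the analyses; no conformational realism is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LipidTemplate:
    resname: str
    names: list
    elements: list
    offsets: np.ndarray          # (n_atoms, 3), Å, head at z=0
    h_parent: list               # index of bonded heavy atom, -1 for heavy
    donors: set                  # heavy-atom names that donate H-bonds
    acceptors: set
    hydrophobic: set
    charges: dict                # name -> formal charge class
    head_names: set = field(default_factory=set)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def head_mask(self) -> np.ndarray:
        return np.array([n in self.head_names for n in self.names])


#: hydrogen directions relative to the parent heavy atom (Å); chosen so the
#: nearest heavy atom of every hydrogen is unambiguously its parent
_H_DIRS = ((0.0, 0.62, 0.15), (0.0, -0.62, 0.15), (0.55, 0.30, 0.35))


class _Builder:
    def __init__(self):
        self.names, self.elements, self.h_parent = [], [], []
        self.offsets = []

    def heavy(self, name, element, x, y, z, n_h=0):
        i = len(self.names)
        self.names.append(name)
        self.elements.append(element)
        self.h_parent.append(-1)
        self.offsets.append((x, y, z))
        for k in range(n_h):
            dx, dy, dz = _H_DIRS[k]
            self.names.append(f"H{len(self.names)}")
            self.elements.append("H")
            self.h_parent.append(i)
            self.offsets.append((x + dx, y + dy, z + dz))
        return i


def _glycerol_backbone(b):
    b.heavy("C1", "C", 0.0, 0.0, -4.0, n_h=2)
    b.heavy("C2", "C", 0.8, 0.3, -4.9, n_h=1)
    b.heavy("C3", "C", -0.8, 0.3, -5.8, n_h=2)
    b.heavy("O21", "O", 2.1, 0.0, -5.2)
    b.heavy("C21", "C", 2.8, 0.0, -6.1)
    b.heavy("O22", "O", 4.0, 0.2, -6.1)
    b.heavy("O31", "O", -2.1, 0.0, -6.5)
    b.heavy("C31", "C", -2.8, 0.0, -7.3)
    b.heavy("O32", "O", -4.0, 0.2, -7.3)


def _phosphate(b):
    b.heavy("P", "P", 0.0, 0.0, -2.6)
    b.heavy("O11", "O", 1.2, 0.2, -2.2)
    b.heavy("O12", "O", -1.2, 0.2, -2.2)
    b.heavy("O13", "O", 1.2, 0.8, -3.3)
    b.heavy("O14", "O", -1.2, -0.8, -3.3)


def _tail(b, prefix, first, last, x0, z0, double_bond=()):
    """Zigzag acyl chain ``{prefix}{first}..{prefix}{last}`` descending in z."""
    for k in range(first, last + 1):
        if k == last:
            n_h = 3                       # terminal methyl
        elif k in double_bond:
            n_h = 1                       # CH of a cis double bond
        else:
            n_h = 2
        b.heavy(f"{prefix}{k}", "C", x0 + 0.55 * (-1.0) ** k, 0.0,
                z0 - 0.85 * (k - first), n_h=n_h)


def dppc_template() -> LipidTemplate:
    b = _Builder()
    b.heavy("N", "N", 0.0, 0.0, 0.0)
    b.heavy("C13", "C", 1.5, 0.8, 0.4, n_h=3)
    b.heavy("C14", "C", -1.5, 0.8, 0.4, n_h=3)
    b.heavy("C15", "C", 0.0, -1.6, 0.4, n_h=3)
    b.heavy("C12", "C", 0.8, 0.4, -0.9, n_h=2)
    b.heavy("C11", "C", 0.0, 0.9, -1.7, n_h=2)
    _phosphate(b)
    _glycerol_backbone(b)
    _tail(b, "C2", 2, 16, 2.8, -7.3)      # sn-2 palmitoyl
    _tail(b, "C3", 2, 16, -2.8, -8.5)     # sn-1 palmitoyl
    t = LipidTemplate(
        resname="DPPC",
        names=b.names, elements=b.elements,
        offsets=np.array(b.offsets, dtype=float),
        h_parent=b.h_parent,
        donors=set(),
        acceptors={"O11", "O12", "O13", "O14", "O21", "O22", "O31", "O32"},
        hydrophobic={f"C2{k}" for k in range(2, 17)}
        | {f"C3{k}" for k in range(2, 17)},
        charges={"N": 1, "O13": -1, "O14": -1},
        head_names={"N", "C13", "C14", "C15", "C12", "C11", "P", "O11",
                    "O12", "O13", "O14", "C1", "C2", "C3", "O21", "C21",
                    "O22", "O31", "C31", "O32"},
    )
    assert t.n_atoms == 130
    return t


def pope_template() -> LipidTemplate:
    b = _Builder()
    b.heavy("N", "N", 0.0, 0.0, 0.0, n_h=3)       # protonated ethanolamine
    b.heavy("C12", "C", 0.8, 0.4, -0.9, n_h=2)
    b.heavy("C11", "C", 0.0, 0.9, -1.7, n_h=2)
    _phosphate(b)
    _glycerol_backbone(b)
    _tail(b, "C2", 2, 16, 2.8, -7.3)                       # palmitoyl
    _tail(b, "C3", 2, 18, -2.8, -8.5, double_bond=(9, 10))  # oleoyl
    t = LipidTemplate(
        resname="POPE",
        names=b.names, elements=b.elements,
        offsets=np.array(b.offsets, dtype=float),
        h_parent=b.h_parent,
        donors={"N"},
        acceptors={"O11", "O12", "O13", "O14", "O21", "O22", "O31", "O32"},
        hydrophobic={f"C2{k}" for k in range(2, 17)}
        | {f"C3{k}" for k in range(2, 19)},
        charges={"N": 1, "O13": -1, "O14": -1},
        head_names={"N", "C12", "C11", "P", "O11", "O12", "O13", "O14",
                    "C1", "C2", "C3", "O21", "C21", "O22", "O31", "C31",
                    "O32"},
    )
    assert t.n_atoms == 125
    return t


def minimal_template(n_atoms: int = 12) -> LipidTemplate:
    """Hydrogen-free miniature lipid with the canonical head-atom names."""
    if n_atoms < 7:
        raise ValueError("minimal template needs at least 7 atoms")
    b = _Builder()
    b.heavy("N", "N", 0.0, 0.0, 0.0)
    b.heavy("C12", "C", 0.8, 0.4, -1.2)
    b.heavy("C11", "C", 0.0, 0.9, -2.2)
    b.heavy("P", "P", 0.0, 0.0, -3.4)
    b.heavy("O13", "O", 1.2, 0.6, -4.2)
    b.heavy("O14", "O", -1.2, -0.6, -4.2)
    b.heavy("O22", "O", 1.4, 0.0, -5.4)
    for k in range(2, n_atoms - 7 + 2):
        b.heavy(f"C2{k}", "C", 0.55 * (-1.0) ** k, 0.1, -6.2 - 1.1 * (k - 2))
    t = LipidTemplate(
        resname="MLIP",
        names=b.names, elements=b.elements,
        offsets=np.array(b.offsets, dtype=float),
        h_parent=b.h_parent,
        donors=set(),
        acceptors={"O13", "O14", "O22"},
        hydrophobic={n for n in b.names if n.startswith("C2") and n != "C2"},
        charges={"N": 1, "O13": -1},
        head_names={"N", "C12", "C11", "P", "O13", "O14", "O22"},
    )
    assert t.n_atoms == n_atoms
    return t


_TEMPLATES = {"DPPC": dppc_template, "POPE": pope_template}


def lipid_template(kind: str, minimal_atoms: int = 12) -> LipidTemplate:
    """Look up a template by kind: ``DPPC``, ``POPE`` or ``minimal``."""
    kind = kind.upper()
    if kind in _TEMPLATES:
        return _TEMPLATES[kind]()
    if kind == "MINIMAL":
        return minimal_template(minimal_atoms)
    raise ValueError(f"unknown lipid template {kind!r}")
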