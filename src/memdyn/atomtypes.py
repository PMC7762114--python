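"""Table-driven atom typing.

Typing decides, per atom, whether it can donate or accept a hydrogen bond,
whether it counts as hydrophobic (carbon with no covalent bond to N/O/P),
and its formal charge class (+1, −1, 0).  Tables are keyed by residue name
and atom name; lipid entries are generated from the lipid templates so the
synthetic generator and the file reader agree by construction.  Tables are
plain dicts and can be exported to / loaded from JSON for editing.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from .lipid_templates import dppc_template, minimal_template, pope_template

log = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}
ION_RESNAMES = {"NA", "K", "CL"}

# backbone defaults shared by all amino acids
_BACKBONE = {"donors": {"N"}, "acceptors": {"O", "OXT"},
             "hydrophobic": set(), "charges": {}}

_SIDE_CHAINS = {
    "GLY": {},
    "ALA": {"hydrophobic": {"CB"}},
    "LEU": {"hydrophobic": {"CB", "CG", "CD1", "CD2"}},
    "PHE": {"hydrophobic": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}},
    "TRP": {"donors": {"NE1"},
            "hydrophobic": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}},
    "SER": {"donors": {"OG"}, "acceptors": {"OG"}},
    "THR": {"donors": {"OG1"}, "acceptors": {"OG1"}, "hydrophobic": {"CG2"}},
    "TYR": {"donors": {"OH"}, "acceptors": {"OH"},
            "hydrophobic": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"}},
    "ASP": {"acceptors": {"OD1", "OD2"}, "charges": {"OD1": -1, "OD2": -1},
            "hydrophobic": {"CB"}},
    "LYS": {"donors": {"NZ"}, "charges": {"NZ": 1},
            "hydrophobic": {"CB", "CG", "CD"}},
}

AMINO_RESNAMES = set(_SIDE_CHAINS)


def _amino_entry(resname):
    e = {k: set(v) if isinstance(v, set) else dict(v)
         for k, v in _BACKBONE.items()}
    for k, v in _SIDE_CHAINS[resname].items():
        if k == "charges":
            e[k].update(v)
        else:
            e[k] |= v
    return e


def _lipid_entry(template):
    return {"donors": set(template.donors),
            "acceptors": set(template.acceptors),
            "hydrophobic": set(template.hydrophobic),
            "charges": dict(template.charges)}


def default_typing_tables() -> dict:
    """Typing tables keyed by residue name."""
    tables = {r: _amino_entry(r) for r in AMINO_RESNAMES}
    tables["DPPC"] = _lipid_entry(dppc_template())
    tables["POPE"] = _lipid_entry(pope_template())
    tables["MLIP"] = _lipid_entry(minimal_template(20))
    for w in WATER_RESNAMES:
        tables[w] = {"donors": {"O", "OW", "OH2"},
                     "acceptors": {"O", "OW", "OH2"},
                     "hydrophobic": set(), "charges": {}}
    tables["NA"] = {"donors": set(), "acceptors": set(), "hydrophobic": set(),
                    "charges": {"NA": 1}}
    tables["K"] = {"donors": set(), "acceptors": set(), "hydrophobic": set(),
                   "charges": {"K": 1}}
    tables["CL"] = {"donors": set(), "acceptors": set(), "hydrophobic": set(),
                    "charges": {"CL": -1}}
    return tables


def tables_to_json(tables: dict, path) -> None:
    ser = {r: {"donors": sorted(e["donors"]),
               "acceptors": sorted(e["acceptors"]),
               "hydrophobic": sorted(e["hydrophobic"]),
               "charges": e["charges"]} for r, e in tables.items()}
    with open(path, "w") as fh:
        json.dump(ser, fh, indent=1)


def tables_from_json(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {r: {"donors": set(e["donors"]), "acceptors": set(e["acceptors"]),
                "hydrophobic": set(e["hydrophobic"]),
                "charges": {k: int(v) for k, v in e["charges"].items()}}
            for r, e in raw.items()}


def infer_element(name: str, resname: str) -> str:
    """Guess the element from a PDB atom name (orthodox two-pass heuristic)."""
    resname = resname.upper()
    if resname in ION_RESNAMES:
        return resname
    stripped = name.strip().upper()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0] in "0123456789":
        stripped = stripped.lstrip("0123456789")
    if stripped.startswith("H"):
        return "H"
    for two in ("CL", "NA"):
        if stripped.startswith(two):
            return two
    return stripped[0]


def classify_atoms(names, resnames, tables: dict | None = None):
    """Per-atom typing arrays ``(is_donor, is_acceptor, is_hydrophobic,
    charge_class)`` from residue+atom-name tables.

    Unknown residue names yield an all-neutral, non-donor classification and
    one logged warning per residue name.
    """
    if tables is None:
        tables = default_typing_tables()
    n = len(names)
    is_donor = np.zeros(n, dtype=bool)
    is_acceptor = np.zeros(n, dtype=bool)
    is_hydrophobic = np.zeros(n, dtype=bool)
    charge = np.zeros(n, dtype=np.int8)
    warned = set()
    for i, (name, res) in enumerate(zip(names, resnames)):
        res = str(res).upper()
        entry = tables.get(res)
        if entry is None:
            if res not in warned:
                log.warning("unknown residue %r: neutral typing applied", res)
                warned.add(res)
            continue
        nm = str(name).strip()
        is_donor[i] = nm in entry["donors"]
        is_acceptor[i] = nm in entry["acceptors"]
        is_hydrophobic[i] = nm in entry["hydrophobic"]
        charge[i] = entry["charges"].get(nm, 0)
    return is_donor, is_acceptor, is_hydrophobic, charge


def molecule_kind_of_resname(resname: str) -> str:
    resname = str(resname).upper()
    if resname in AMINO_RESNAMES:
        return "protein"
    if resname in WATER_RESNAMES:
        return "water"
    if resname in ION_RESNAMES:
        return "ion"
    return "lipid"
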