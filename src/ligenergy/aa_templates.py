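"""Connectivity and typing templates for the standard amino acids.

Each residue template lists its intra-residue heavy-atom bonds and, per atom,
the hybridization, the number of riding polar hydrogens to add, the formal
charge seed for electronegativity equalization, and the force-field type.
Charges follow standard pH-7 conventions: Asp/Glu carboxylates deprotonated
(-1/2 on each oxygen), Lys/Arg protonated, His neutral with the hydrogen on
NE2.  Resonance-delocalized charges are seeded fractionally over the
equivalent atoms so that symmetry survives the charge iteration.
"""

from __future__ import annotations

# (hybridization, n_polar_H, formal_charge, ff_type, aromatic)
AtomInfo = tuple[int, int, float, str, bool]

_BB: dict[str, AtomInfo] = {
    "N":   (2, 1, 0.0, "N", False),
    "CA":  (3, 0, 0.0, "C", False),
    "C":   (2, 0, 0.0, "C", False),
    "O":   (2, 0, 0.0, "OA", False),
    "OXT": (2, 0, -0.5, "OA", False),
}

_BB_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_THIRD = 1.0 / 3.0

# Side-chain atom info per residue.
_SIDE: dict[str, dict[str, AtomInfo]] = {
    "ALA": {"CB": (3, 0, 0.0, "C", False)},
    "ARG": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "CD": (3, 0, 0.0, "C", False),
        "NE": (2, 1, _THIRD, "N", False), "CZ": (2, 0, 0.0, "C", False),
        "NH1": (2, 2, _THIRD, "N", False), "NH2": (2, 2, _THIRD, "N", False),
    },
    "ASN": {
        "CB": (3, 0, 0.0, "C", False), "CG": (2, 0, 0.0, "C", False),
        "OD1": (2, 0, 0.0, "OA", False), "ND2": (2, 2, 0.0, "N", False),
    },
    "ASP": {
        "CB": (3, 0, 0.0, "C", False), "CG": (2, 0, 0.0, "C", False),
        "OD1": (2, 0, -0.5, "OA", False), "OD2": (2, 0, -0.5, "OA", False),
    },
    "CYS": {"CB": (3, 0, 0.0, "C", False), "SG": (3, 1, 0.0, "SA", False)},
    "GLN": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "CD": (2, 0, 0.0, "C", False),
        "OE1": (2, 0, 0.0, "OA", False), "NE2": (2, 2, 0.0, "N", False),
    },
    "GLU": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "CD": (2, 0, 0.0, "C", False),
        "OE1": (2, 0, -0.5, "OA", False), "OE2": (2, 0, -0.5, "OA", False),
    },
    "GLY": {},
    "HIS": {
        "CB": (3, 0, 0.0, "C", False), "CG": (2, 0, 0.0, "A", True),
        "ND1": (2, 0, 0.0, "NA", True), "CD2": (2, 0, 0.0, "A", True),
        "CE1": (2, 0, 0.0, "A", True), "NE2": (2, 1, 0.0, "N", True),
    },
    "ILE": {
        "CB": (3, 0, 0.0, "C", False), "CG1": (3, 0, 0.0, "C", False),
        "CG2": (3, 0, 0.0, "C", False), "CD1": (3, 0, 0.0, "C", False),
    },
    "LEU": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "CD1": (3, 0, 0.0, "C", False), "CD2": (3, 0, 0.0, "C", False),
    },
    "LYS": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "CD": (3, 0, 0.0, "C", False), "CE": (3, 0, 0.0, "C", False),
        "NZ": (3, 3, 1.0, "N", False),
    },
    "MET": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "SD": (3, 0, 0.0, "SA", False), "CE": (3, 0, 0.0, "C", False),
    },
    "MSE": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "SE": (3, 0, 0.0, "SA", False), "CE": (3, 0, 0.0, "C", False),
    },
    "PHE": {
        "CB": (3, 0, 0.0, "C", False), "CG": (2, 0, 0.0, "A", True),
        "CD1": (2, 0, 0.0, "A", True), "CD2": (2, 0, 0.0, "A", True),
        "CE1": (2, 0, 0.0, "A", True), "CE2": (2, 0, 0.0, "A", True),
        "CZ": (2, 0, 0.0, "A", True),
    },
    "PRO": {
        "CB": (3, 0, 0.0, "C", False), "CG": (3, 0, 0.0, "C", False),
        "CD": (3, 0, 0.0, "C", False),
    },
    "SER": {"CB": (3, 0, 0.0, "C", False), "OG": (3, 1, 0.0, "OA", False)},
    "THR": {
        "CB": (3, 0, 0.0, "C", False), "OG1": (3, 1, 0.0, "OA", False),
        "CG2": (3, 0, 0.0, "C", False),
    },
    "TRP": {
        "CB": (3, 0, 0.0, "C", False), "CG": (2, 0, 0.0, "A", True),
        "CD1": (2, 0, 0.0, "A", True), "NE1": (2, 1, 0.0, "N", True),
        "CE2": (2, 0, 0.0, "A", True), "CD2": (2, 0, 0.0, "A", True),
        "CE3": (2, 0, 0.0, "A", True), "CZ2": (2, 0, 0.0, "A", True),
        "CZ3": (2, 0, 0.0, "A", True), "CH2": (2, 0, 0.0, "A", True),
    },
    "TYR": {
        "CB": (3, 0, 0.0, "C", False), "CG": (2, 0, 0.0, "A", True),
        "CD1": (2, 0, 0.0, "A", True), "CD2": (2, 0, 0.0, "A", True),
        "CE1": (2, 0, 0.0, "A", True), "CE2": (2, 0, 0.0, "A", True),
        "CZ": (2, 0, 0.0, "A", True), "OH": (3, 1, 0.0, "OA", False),
    },
    "VAL": {
        "CB": (3, 0, 0.0, "C", False), "CG1": (3, 0, 0.0, "C", False),
        "CG2": (3, 0, 0.0, "C", False),
    },
}

_SIDE_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "MSE": [("CA", "CB"), ("CB", "CG"), ("CG", "SE"), ("SE", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CE2", "CZ2"),
            ("CZ2", "CH2"), ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

# Aromatic/double-bond orders inside side chains, for valence bookkeeping.
def _is_aromatic_atom(res: str, atom: str) -> bool:
    info = _SIDE.get(res, {}).get(atom)
    return bool(info and info[4])


_SIDE_ORDERS: dict[tuple[str, str, str], float] = {}
for _res, _bonds in _SIDE_BONDS.items():
    for _a, _b in _bonds:
        if _is_aromatic_atom(_res, _a) and _is_aromatic_atom(_res, _b):
            _SIDE_ORDERS[(_res, _a, _b)] = 1.5


# Localized double bonds and resonance orders in side chains.
_SIDE_DOUBLE: dict[tuple[str, str, str], float] = {
    ("ASN", "CG", "OD1"): 2.0,
    ("GLN", "CD", "OE1"): 2.0,
    ("ASP", "CG", "OD1"): 1.5, ("ASP", "CG", "OD2"): 1.5,
    ("GLU", "CD", "OE1"): 1.5, ("GLU", "CD", "OE2"): 1.5,
    ("ARG", "NE", "CZ"): 4.0 / 3.0, ("ARG", "CZ", "NH1"): 4.0 / 3.0,
    ("ARG", "CZ", "NH2"): 4.0 / 3.0,
}


def residue_template(name: str) -> dict[str, AtomInfo] | None:
    """Full atom-info table (backbone + side chain) or None if unknown."""
    side = _SIDE.get(name)
    if side is None:
        return None
    table = dict(_BB)
    table.update(side)
    if name == "PRO":
        table["N"] = (2, 0, 0.0, "N", False)
    return table


def residue_bonds(name: str) -> list[tuple[str, str]] | None:
    side = _SIDE_BONDS.get(name)
    if side is None:
        return None
    return _BB_BONDS + side


def bond_order(res: str, a: str, b: str) -> float:
    """Intra-residue bond order; carbonyl C=O double, ring bonds aromatic."""
    if (a, b) in (("C", "O"), ("O", "C")):
        return 2.0
    return (_SIDE_DOUBLE.get((res, a, b)) or _SIDE_DOUBLE.get((res, b, a))
            or _SIDE_ORDERS.get((res, a, b)) or _SIDE_ORDERS.get((res, b, a))
            or 1.0)
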