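"""Chemical preparation: connectivity, polar hydrogens, PEOE charges, typing.

The energy model needs, for every protein and ligand atom, a force-field type,
a partial charge and — for donors — explicitly placed polar hydrogens.  This
module builds a covalent bond graph (templates for standard amino acids,
distance/valence perception or a component-dictionary template for ligands),
adds hydrogens, and runs the Gasteiger-Marsili partial equalization of
orbital electronegativities (PEOE) to obtain charges.

Charges are computed on the complete hydrogen topology: apolar C-H hydrogens
participate in the equalization as coordinate-free graph nodes and their
charges are then merged into the parent carbon (united-atom convention), so
that only polar hydrogens — the ones that matter for hydrogen bonding — carry
coordinates into scoring.  PEOE is a pure topology method, so virtual
hydrogens need no geometry.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from . import aa_templates
from .structure import Atom, LigandInstance, Structure

__all__ = [
    "BondGraph",
    "TypedAtom",
    "infer_ligand_bonds",
    "protein_connectivity",
    "place_polar_hydrogens",
    "compute_peoe_charges",
    "assign_atom_types",
    "prepare_protein",
    "prepare_ligand",
    "load_ccd_template",
]

# Covalent radii (Angstrom) for bond perception.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20, "B": 0.84,
}
BOND_TOLERANCE = 0.45  # added to the radius sum

# Standard valences for implicit-hydrogen counting.
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 5, "F": 1, "CL": 1,
            "BR": 1, "I": 1, "SE": 2, "B": 3, "H": 1}

# Gasteiger-Marsili electronegativity coefficients a, b, c (chi = a + b*q + c*q^2)
# keyed by (element, hybridization).
_PEOE_PARAMS: dict[tuple[str, int], tuple[float, float, float]] = {
    ("H", 3): (7.17, 6.24, -0.56),
    ("C", 3): (7.98, 9.18, 1.88),
    ("C", 2): (8.79, 9.32, 1.51),
    ("C", 1): (10.39, 9.45, 0.73),
    ("N", 3): (11.54, 10.82, 1.36),
    ("N", 2): (12.87, 11.15, 0.85),
    ("N", 1): (15.68, 11.70, -0.27),
    ("O", 3): (14.18, 12.92, 1.39),
    ("O", 2): (17.07, 13.79, 0.47),
    ("F", 3): (14.66, 13.85, 2.31),
    ("CL", 3): (11.00, 9.69, 1.35),
    ("BR", 3): (10.08, 8.47, 1.16),
    ("I", 3): (9.90, 7.96, 0.96),
    ("S", 3): (10.14, 9.13, 1.38),
    ("S", 2): (10.14, 9.13, 1.38),
    ("SE", 3): (10.14, 9.13, 1.38),
    ("P", 3): (8.90, 8.24, 0.96),
    ("B", 3): (5.98, 6.82, 0.70),
}
# Cation electronegativity of hydrogen used as the damping denominator.
_H_CATION_CHI = 20.02

_H_BOND_LENGTH = {"N": 1.00, "O": 0.96, "S": 1.34}


@dataclass
class TypedAtom:
    """Atom decorated with everything the pairwise energy terms need."""

    atom: Atom
    ff_type: str
    partial_charge: float
    is_polar_h: bool = False
    is_donor_h: bool = False
    is_acceptor: bool = False
    parent_coords: Optional[np.ndarray] = None  # donor heavy atom, for H only

    @property
    def coords(self) -> np.ndarray:
        return self.atom.coords

    def __repr__(self) -> str:
        return f"TypedAtom({self.atom!r}, {self.ff_type}, q={self.partial_charge:+.3f})"


class BondGraph:
    """Undirected covalent graph over integer node ids.

    Node attributes: ``atom`` (:class:`~ligenergy.structure.Atom` or None for
    virtual hydrogens), ``element``, ``hyb`` (1, 2 or 3), ``charge`` (formal
    charge seed, possibly fractional for resonance-delocalized groups),
    ``aromatic``, ``n_polar_h`` (riding hydrogens still to be added),
    ``ff_type`` (set by templates or typing), ``parent`` (heavy-atom node for
    hydrogens).  Edge attribute: ``order``.
    """

    def __init__(self) -> None:
        self.g = nx.Graph()
        self._next_id = 0

    # -- construction ------------------------------------------------------
    def add_atom(self, atom: Optional[Atom], element: str, *, hyb: int = 3,
                 charge: float = 0.0, aromatic: bool = False,
                 n_polar_h: int = 0, ff_type: Optional[str] = None,
                 parent: Optional[int] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.g.add_node(nid, atom=atom, element=element.upper(), hyb=hyb,
                        charge=float(charge), aromatic=aromatic,
                        n_polar_h=n_polar_h, ff_type=ff_type, parent=parent)
        return nid

    def add_bond(self, i: int, j: int, order: float = 1.0) -> None:
        if i == j:
            raise ValueError("self-bond")
        self.g.add_edge(i, j, order=float(order))

    # -- queries -----------------------------------------------------------
    def nodes(self) -> list[int]:
        return list(self.g.nodes)

    def neighbors(self, i: int) -> list[int]:
        return list(self.g.neighbors(i))

    def element(self, i: int) -> str:
        return self.g.nodes[i]["element"]

    def atom(self, i: int) -> Optional[Atom]:
        return self.g.nodes[i]["atom"]

    def order_sum(self, i: int) -> float:
        return sum(self.g.edges[i, j]["order"] for j in self.g.neighbors(i))

    def heavy_nodes(self) -> list[int]:
        return [i for i in self.g.nodes if self.element(i) != "H"]

    def hydrogen_nodes(self) -> list[int]:
        return [i for i in self.g.nodes if self.element(i) == "H"]


# ---------------------------------------------------------------------------
# Ligand connectivity
# ---------------------------------------------------------------------------

def load_ccd_template(path: str) -> dict:
    """Read a chemical-component-dictionary-style mmCIF ligand template.

    Returns ``{"atoms": {name: (element, charge)}, "bonds": [(a, b, order)]}``
    with aromatic bonds encoded as order 1.5.
    """
    import gemmi

    block = gemmi.cif.read(path).sole_block()
    atoms: dict[str, tuple[str, float]] = {}
    tab = block.find("_chem_comp_atom.", ["atom_id", "type_symbol", "charge"])
    for row in tab:
        charge = row[2]
        atoms[row.str(0)] = (row.str(1).upper(),
                             0.0 if charge in ("?", ".") else float(charge))
    bonds: list[tuple[str, str, float]] = []
    order_map = {"SING": 1.0, "DOUB": 2.0, "TRIP": 3.0, "AROM": 1.5}
    btab = block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_order"])
    for row in btab:
        bonds.append((row.str(0), row.str(1), order_map.get(row.str(2).upper(), 1.0)))
    return {"atoms": atoms, "bonds": bonds}


def _builtin_template_dir() -> str:
    return os.path.join(os.path.dirname(__file__), "data", "ccd")


def _find_template(het_code: str, template_dir: Optional[str]) -> Optional[dict]:
    for d in filter(None, [template_dir, _builtin_template_dir()]):
        p = os.path.join(d, f"{het_code.upper()}.cif")
        if os.path.exists(p):
            return load_ccd_template(p)
    return None


def _ring_is_planar(coords: np.ndarray, tol: float = 0.12) -> bool:
    centered = coords - coords.mean(axis=0)
    # smallest singular direction = plane normal; residual = out-of-plane spread
    _, s, _ = np.linalg.svd(centered, full_matrices=False)
    return s[-1] / math.sqrt(len(coords)) < tol


def _perceive_aromatic_rings(bg: BondGraph) -> None:
    """Mark planar 5/6-membered C/N/O/S rings aromatic (geometry-based)."""
    heavy = bg.g.subgraph(bg.heavy_nodes())
    for ring in nx.cycle_basis(heavy):
        if len(ring) not in (5, 6):
            continue
        if not all(bg.element(i) in ("C", "N", "O", "S") for i in ring):
            continue
        if any(len(bg.neighbors(i)) > 3 for i in ring):
            continue
        coords = np.array([bg.atom(i).coords for i in ring])
        if not _ring_is_planar(coords):
            continue
        for i in ring:
            bg.g.nodes[i]["aromatic"] = True
            if bg.g.nodes[i]["hyb"] == 3:
                bg.g.nodes[i]["hyb"] = 2
        for a, b in zip(ring, ring[1:] + ring[:1]):
            if bg.g.has_edge(a, b):
                bg.g.edges[a, b]["order"] = 1.5


def _assign_heuristic_orders(bg: BondGraph) -> None:
    """Valence-satisfaction heuristics for double bonds and formal charges.

    Handles the common crystallographic ligand chemistry: carbonyls,
    carboxylates, phosphates/sulfates (fully deprotonated, resonance orders
    and charges spread over the terminal oxygens) and short C=C / C=N bonds.
    """
    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(bg.atom(i).coords - bg.atom(j).coords))

    def terminal_oxygens(i: int) -> list[int]:
        return [j for j in bg.neighbors(i)
                if bg.element(j) == "O" and len(bg.neighbors(j)) == 1]

    # Phosphate / sulfate groups: distribute the remaining valence and the
    # pH-7 negative charge over the k terminal oxygens.
    for i in bg.heavy_nodes():
        el = bg.element(i)
        if el not in ("P", "S"):
            continue
        term = terminal_oxygens(i)
        if not term or (el == "S" and len(term) < 3):
            continue
        valence = 5.0 if el == "P" else 6.0
        bridging = len(bg.neighbors(i)) - len(term)
        per_bond = (valence - bridging) / len(term)
        group_charge = -(len(term) - (2 if el == "S" else 1))
        for j in term:
            bg.g.edges[i, j]["order"] = per_bond
            bg.g.nodes[j]["charge"] = group_charge / len(term)
            bg.g.nodes[j]["hyb"] = 2

    # Carboxylate (two terminal O on one sp2 C) and carbonyl/short C-O.
    for i in bg.heavy_nodes():
        if bg.element(i) != "C":
            continue
        term = terminal_oxygens(i)
        if len(term) >= 2:
            for j in term[:2]:
                bg.g.edges[i, j]["order"] = 1.5
                bg.g.nodes[j]["charge"] = -0.5
                bg.g.nodes[j]["hyb"] = 2
            bg.g.nodes[i]["hyb"] = 2
        elif len(term) == 1:
            j = term[0]
            if dist(i, j) < 1.28:
                bg.g.edges[i, j]["order"] = 2.0
                bg.g.nodes[j]["hyb"] = 2
                bg.g.nodes[i]["hyb"] = 2

    # Short nonaromatic C=C / C=N from geometry, capped by valence.
    thresholds = {("C", "C"): 1.38, ("C", "N"): 1.32, ("N", "N"): 1.28}
    for i, j, data in bg.g.edges(data=True):
        if data["order"] != 1.0:
            continue
        pair = tuple(sorted((bg.element(i), bg.element(j))))
        thr = thresholds.get(pair)  # type: ignore[arg-type]
        if thr is None or dist(i, j) >= thr:
            continue
        if bg.order_sum(i) + 1 <= _VALENCE.get(bg.element(i), 4) and \
           bg.order_sum(j) + 1 <= _VALENCE.get(bg.element(j), 4):
            data["order"] = 2.0
            bg.g.nodes[i]["hyb"] = min(bg.g.nodes[i]["hyb"], 2)
            bg.g.nodes[j]["hyb"] = min(bg.g.nodes[j]["hyb"], 2)

    # Quaternary / iminium-style nitrogens carry +1.
    for i in bg.heavy_nodes():
        if bg.element(i) == "N" and bg.order_sum(i) > 3.01 and bg.g.nodes[i]["charge"] == 0:
            bg.g.nodes[i]["charge"] = 1.0


def infer_ligand_bonds(lig: LigandInstance,
                       template_dir: Optional[str] = None) -> BondGraph:
    """Build the ligand's covalent graph from geometry (or a CCD template).

    Heavy atoms are bonded when closer than the covalent-radius sum plus
    0.45 Angstrom.  If a component-dictionary template for the het code is
    available (bundled or in ``template_dir``) its bond orders and formal
    charges are used; otherwise orders and pH-7 charges come from a
    valence-satisfaction heuristic and planar-ring aromaticity perception.
    """
    bg = BondGraph()
    idx: dict[str, int] = {}
    for a in lig.heavy_atoms:
        idx[a.name] = bg.add_atom(a, a.element)

    template = _find_template(lig.het_code, template_dir)

    nodes = list(idx.values())
    coords = np.array([bg.atom(i).coords for i in nodes])
    for ii in range(len(nodes)):
        for jj in range(ii + 1, len(nodes)):
            ei, ej = bg.element(nodes[ii]), bg.element(nodes[jj])
            rmax = (COVALENT_RADII.get(ei, 0.77) + COVALENT_RADII.get(ej, 0.77)
                    + BOND_TOLERANCE)
            if np.linalg.norm(coords[ii] - coords[jj]) < rmax:
                bg.add_bond(nodes[ii], nodes[jj])

    if template is not None:
        applied = False
        for a, b, order in template["bonds"]:
            if a in idx and b in idx:
                if not bg.g.has_edge(idx[a], idx[b]):
                    bg.add_bond(idx[a], idx[b], order)
                else:
                    bg.g.edges[idx[a], idx[b]]["order"] = order
                applied = True
        if applied:
            for name, (el, charge) in template["atoms"].items():
                if name in idx and charge:
                    bg.g.nodes[idx[name]]["charge"] = charge
            for i in bg.nodes():
                if any(bg.g.edges[i, j]["order"] >= 1.5 for j in bg.neighbors(i)):
                    bg.g.nodes[i]["hyb"] = 2
                if any(bg.g.edges[i, j]["order"] == 1.5 for j in bg.neighbors(i)):
                    bg.g.nodes[i]["aromatic"] = True
        else:
            template = None

    if template is None:
        _perceive_aromatic_rings(bg)
        _assign_heuristic_orders(bg)

    for i in bg.nodes():
        if any(bg.g.edges[i, j]["order"] >= 3 for j in bg.neighbors(i)):
            bg.g.nodes[i]["hyb"] = 1
        if bg.order_sum(i) > _VALENCE.get(bg.element(i), 4) + 1.01:
            warnings.warn(
                f"atom {bg.atom(i)!r} exceeds typical valence "
                f"({bg.order_sum(i):.1f}); keeping best-effort graph")
    _set_implicit_h(bg)
    return bg


def _set_implicit_h(bg: BondGraph) -> None:
    """Fill ``n_polar_h`` / ``n_apolar_h`` from standard valences."""
    for i in bg.nodes():
        el = bg.element(i)
        if el == "H":
            continue
        if bg.g.nodes[i].get("template_h") is not None:
            continue
        valence = _VALENCE.get(el)
        if valence is None:
            bg.g.nodes[i]["n_polar_h"] = 0
            bg.g.nodes[i]["n_apolar_h"] = 0
            continue
        charge = bg.g.nodes[i]["charge"]
        if el == "N":
            valence += max(0.0, charge)  # ammonium-style N gets a 4th bond
        elif el in ("O", "S"):
            valence += min(0.0, charge)  # anionic O/S loses its hydrogen
        n_h = max(0, int(round(valence - bg.order_sum(i))))
        if el == "C":
            bg.g.nodes[i]["n_polar_h"] = 0
            bg.g.nodes[i]["n_apolar_h"] = n_h
        else:
            bg.g.nodes[i]["n_polar_h"] = n_h if el in ("N", "O", "S") else 0
            bg.g.nodes[i]["n_apolar_h"] = 0


# ---------------------------------------------------------------------------
# Protein connectivity
# ---------------------------------------------------------------------------

PEPTIDE_BOND_MAX = 1.8
DISULFIDE_MAX = 2.3


def protein_connectivity(s: Structure) -> BondGraph:
    """Covalent graph of the protein heavy atoms.

    Intra-residue bonds come from amino-acid templates (with hybridization,
    polar-H counts, pH-7 formal charges and force-field types); peptide bonds
    are added for C(i)-N(i+1) pairs below 1.8 Angstrom, disulfides for SG-SG
    pairs below 2.3 Angstrom.  Chain breaks simply omit the peptide edge.
    Nonstandard polymer residues fall back to distance-based perception.
    Waters and monoatomic ions are excluded.
    """
    bg = BondGraph()
    residues: list[tuple[tuple, list[tuple[int, Atom]]]] = []
    groups: dict[tuple, list[tuple[int, Atom]]] = {}
    order: list[tuple] = []
    for a in s.polymer_atoms():
        if not a.is_heavy or a.is_water:
            continue
        key = a.residue_key()
        if key not in groups:
            groups[key] = []
            order.append(key)
        nid = bg.add_atom(a, a.element)
        groups[key].append((nid, a))
    residues = [(k, groups[k]) for k in order]

    n_term_keys: set[tuple] = set()
    prev_chain = None
    for key, _atoms in residues:
        if key[0] != prev_chain:
            n_term_keys.add(key)
            prev_chain = key[0]

    for key, atom_list in residues:
        res_name = key[1]
        byname = {a.name: nid for nid, a in atom_list}
        template = aa_templates.residue_template(res_name)
        if template is None:
            # unknown residue: distance-based fallback
            ids = [nid for nid, _ in atom_list]
            for x in range(len(ids)):
                for y in range(x + 1, len(ids)):
                    ei, ej = bg.element(ids[x]), bg.element(ids[y])
                    rmax = (COVALENT_RADII.get(ei, 0.77)
                            + COVALENT_RADII.get(ej, 0.77) + BOND_TOLERANCE)
                    d = np.linalg.norm(bg.atom(ids[x]).coords - bg.atom(ids[y]).coords)
                    if d < rmax:
                        bg.add_bond(ids[x], ids[y])
            for nid, _ in atom_list:
                bg.g.nodes[nid]["template_h"] = None
            continue
        has_oxt = "OXT" in byname
        for name, nid in byname.items():
            info = template.get(name)
            if info is None:
                continue  # e.g. stray atoms; stay with defaults
            hyb, n_h, charge, ff_type, aromatic = info
            if name == "N" and key in n_term_keys:
                # protonated amino terminus
                hyb, n_h, charge = 3, (2 if res_name == "PRO" else 3), 1.0
            if name == "O" and has_oxt:
                charge = -0.5  # C-terminal carboxylate, delocalized
            bg.g.nodes[nid].update(hyb=hyb, charge=charge, ff_type=ff_type,
                                   aromatic=aromatic, n_polar_h=n_h,
                                   template_h=n_h, n_apolar_h=0)
        for a_name, b_name in aa_templates.residue_bonds(res_name) or []:
            if a_name in byname and b_name in byname:
                bg.add_bond(byname[a_name], byname[b_name],
                            aa_templates.bond_order(res_name, a_name, b_name))

    # peptide bonds between consecutive residues of the same chain
    for (key_a, atoms_a), (key_b, atoms_b) in zip(residues, residues[1:]):
        if key_a[0] != key_b[0]:
            continue
        c = next((nid for nid, a in atoms_a if a.name == "C"), None)
        n = next((nid for nid, a in atoms_b if a.name == "N"), None)
        if c is None or n is None:
            continue
        d = np.linalg.norm(bg.atom(c).coords - bg.atom(n).coords)
        if d < PEPTIDE_BOND_MAX:
            bg.add_bond(c, n, 1.0)

    # disulfides
    sg = [i for i in bg.nodes() if bg.atom(i).name == "SG"
          and bg.atom(i).residue_name == "CYS"]
    for x in range(len(sg)):
        for y in range(x + 1, len(sg)):
            d = np.linalg.norm(bg.atom(sg[x]).coords - bg.atom(sg[y]).coords)
            if d < DISULFIDE_MAX:
                bg.add_bond(sg[x], sg[y], 1.0)
                bg.g.nodes[sg[x]]["n_polar_h"] = 0
                bg.g.nodes[sg[y]]["n_polar_h"] = 0

    _set_implicit_h(bg)
    return bg


# ---------------------------------------------------------------------------
# Hydrogen placement
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(_unit(v), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


_ELEMENT_MASS = {"H": 1, "C": 12, "N": 14, "O": 16, "P": 31, "S": 32}


def _h_positions(bg: BondGraph, parent: int) -> list[np.ndarray]:
    """Idealized riding positions for the polar hydrogens of ``parent``."""
    node = bg.g.nodes[parent]
    n_h = node["n_polar_h"]
    if n_h == 0:
        return []
    p = bg.atom(parent).coords
    length = _H_BOND_LENGTH.get(node["element"], 1.0)
    heavy_nb = [j for j in bg.neighbors(parent) if bg.element(j) != "H"
                and bg.atom(j) is not None]
    nb_coords = [bg.atom(j).coords for j in heavy_nb]
    units = [_unit(c - p) for c in nb_coords]
    out: list[np.ndarray] = []

    if not units:
        # isolated atom: no geometric context
        warnings.warn(f"no geometric context to place H on {bg.atom(parent)!r}")
        return []

    if len(units) >= 3 and n_h == 1:
        out.append(p + length * _unit(-sum(units)))
    elif len(units) == 2:
        bisector = _unit(-(units[0] + units[1]))
        if node["hyb"] == 2 or n_h == 1:
            out.append(p + length * bisector)
        else:
            normal = _unit(np.cross(units[0], units[1]))
            half = math.radians(109.47 / 2.0)
            for sign in (1.0, -1.0)[:n_h]:
                d = _unit(math.cos(half) * bisector + sign * math.sin(half) * normal)
                out.append(p + length * d)
    elif len(units) == 1:
        b = heavy_nb[0]
        axis = -units[0]  # from neighbor through parent, pointing outward
        # torsion reference: heaviest substituent of the neighbor
        subs = [k for k in bg.neighbors(b) if k != parent and bg.atom(k) is not None]
        if subs:
            ref_node = max(subs, key=lambda k: (_ELEMENT_MASS.get(bg.element(k), 50),
                                                -k))
            ref_vec = bg.atom(ref_node).coords - bg.atom(b).coords
            perp = _unit(ref_vec - np.dot(ref_vec, axis) * axis)
            if np.linalg.norm(ref_vec - np.dot(ref_vec, axis) * axis) < 1e-6:
                perp = _any_perpendicular(axis)
        else:
            perp = _any_perpendicular(axis)
        if node["hyb"] == 2:
            # in-plane positions at +-120 degrees from the parent-neighbor axis
            plane_normal = _unit(np.cross(axis, perp))
            angles = [120.0, -120.0][:n_h]
            for ang in angles:
                rad = math.radians(ang)
                d = _unit(math.cos(rad) * (-axis)
                          + math.sin(rad) * _unit(np.cross(plane_normal, -axis)))
                out.append(p + length * d)
        else:
            theta = math.radians(180.0 - 109.47)  # from outward axis
            # anti to the heaviest substituent: torsion 180 deg from ref
            start = math.pi
            for m in range(n_h):
                phi = start + m * 2.0 * math.pi / max(n_h, 1) if n_h > 1 else start
                d = _unit(math.cos(theta) * axis
                          + math.sin(theta) * (math.cos(phi) * perp
                                               + math.sin(phi) * np.cross(axis, perp)))
                out.append(p + length * d)
    else:  # >=3 neighbors and n_h > 1: overloaded center, skip
        warnings.warn(f"cannot place {n_h} H on crowded atom {bg.atom(parent)!r}")
    return out


def place_polar_hydrogens(g: BondGraph) -> BondGraph:
    """Add riding polar hydrogens (on N, O, S donors only) to the graph.

    Hydrogens are placed at idealized geometry (1.0 A N-H, 0.96 A O-H,
    1.34 A S-H; sp2 in-plane, sp3 tetrahedral with rotatable hydroxyls
    anti to the heaviest substituent of the parent's neighbor) and inherit
    the parent's occupancy and ADP.  Apolar C-H hydrogens are never added
    with coordinates.  Returns the same graph, mutated.
    """
    for parent in list(g.nodes()):
        el = g.element(parent)
        if el not in ("N", "O", "S") or g.g.nodes[parent]["n_polar_h"] == 0:
            continue
        pa = g.atom(parent)
        if pa is None:
            continue
        positions = _h_positions(g, parent)
        for m, pos in enumerate(positions):
            h_atom = Atom(
                serial=-1, name=f"H{pa.name}"[:4] if m == 0 else f"H{pa.name}{m}"[:4],
                element="H", coords=pos, occupancy=pa.occupancy, adp=pa.adp,
                altloc="", residue_name=pa.residue_name, residue_seq=pa.residue_seq,
                icode=pa.icode, chain_id=pa.chain_id, is_polymer=pa.is_polymer,
                is_water=False,
            )
            h = g.add_atom(h_atom, "H", hyb=3, ff_type="HD", parent=parent)
            g.g.nodes[h]["polar"] = True
            g.add_bond(parent, h, 1.0)
        g.g.nodes[parent]["n_polar_h"] = 0
    return g


def _add_virtual_apolar_h(g: BondGraph) -> list[int]:
    """Graph-only C-H hydrogens for the charge iteration (no coordinates)."""
    added = []
    for parent in list(g.nodes()):
        n_h = g.g.nodes[parent].get("n_apolar_h", 0)
        for _ in range(int(n_h)):
            h = g.add_atom(None, "H", hyb=3, ff_type="H", parent=parent)
            g.g.nodes[h]["polar"] = False
            g.add_bond(parent, h, 1.0)
            added.append(h)
        g.g.nodes[parent]["n_apolar_h"] = 0
    return added


# ---------------------------------------------------------------------------
# PEOE charges
# ---------------------------------------------------------------------------

def compute_peoe_charges(g: BondGraph, n_iter: int = 8) -> dict[int, float]:
    """Gasteiger-Marsili partial equalization of orbital electronegativities.

    Starting from the formal-charge seeds, each iteration k moves charge
    along every bond from the less to the more electronegative partner,
    proportional to the electronegativity difference (chi = a + b*q + c*q^2)
    and damped by (1/2)^k; the normalizing denominator is the cation
    electronegativity a+b+c of the donating atom (20.02 for hydrogen).
    Updates are synchronous over all bonds, so the result is independent of
    atom ordering.  Charge is conserved per connected component by
    construction.

    Raises ``ValueError`` for an element with no electronegativity
    parameters.
    """
    nodes = g.nodes()
    params: dict[int, tuple[float, float, float]] = {}
    denom: dict[int, float] = {}
    for i in nodes:
        el, hyb = g.element(i), g.g.nodes[i]["hyb"]
        key = (el, hyb) if (el, hyb) in _PEOE_PARAMS else (el, 3)
        if key not in _PEOE_PARAMS:
            raise ValueError(f"element {el!r} unsupported by the PEOE charge model")
        params[i] = _PEOE_PARAMS[key]
        denom[i] = _H_CATION_CHI if el == "H" else sum(_PEOE_PARAMS[key])

    q = {i: float(g.g.nodes[i]["charge"]) for i in nodes}
    edges = list(g.g.edges())
    for k in range(1, n_iter + 1):
        damp = 0.5 ** k
        chi = {i: params[i][0] + params[i][1] * q[i] + params[i][2] * q[i] * q[i]
               for i in nodes}
        delta = {i: 0.0 for i in nodes}
        for i, j in edges:
            if chi[j] > chi[i]:
                dq = (chi[j] - chi[i]) / denom[i] * damp
                delta[i] += dq
                delta[j] -= dq
            elif chi[i] > chi[j]:
                dq = (chi[i] - chi[j]) / denom[j] * damp
                delta[j] += dq
                delta[i] -= dq
        for i in nodes:
            q[i] += delta[i]
    for i in nodes:
        g.g.nodes[i]["partial_charge"] = q[i]
    return q


def _merge_apolar_h(g: BondGraph, virtual_h: list[int],
                    charges: dict[int, float]) -> None:
    """United-atom convention: fold C-H hydrogen charges into the carbon."""
    for h in virtual_h:
        parent = g.g.nodes[h]["parent"]
        charges[parent] += charges.pop(h)
        g.g.nodes[parent]["partial_charge"] = charges[parent]
        g.g.remove_node(h)


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

def _type_one(g: BondGraph, i: int) -> str:
    node = g.g.nodes[i]
    if node.get("ff_type"):
        return node["ff_type"]
    el = node["element"]
    if el == "H":
        return "HD" if node.get("polar", True) else "H"
    if el == "C":
        return "A" if node["aromatic"] else "C"
    if el == "N":
        n_h = sum(1 for j in g.neighbors(i) if g.element(j) == "H") \
            + node.get("n_polar_h", 0)
        heavy_deg = sum(1 for j in g.neighbors(i) if g.element(j) != "H")
        # lone-pair-bearing N with no proton accepts hydrogen bonds
        if n_h == 0 and heavy_deg + n_h <= (3 if node["hyb"] == 3 else 2):
            return "NA"
        return "N"
    if el == "O":
        return "OA"
    if el in ("S", "SE"):
        return "SA" if g.order_sum(i) <= 2.01 else "S"
    if el in ("F", "CL", "BR", "I", "P"):
        return el if el != "P" else "P"
    if el in ("MG", "ZN", "MN", "FE", "CA"):
        return el
    raise ValueError(f"cannot assign a force-field type to element {el!r}")


def assign_atom_types(g: BondGraph) -> list[TypedAtom]:
    """Map every coordinate-bearing atom in the graph to a typed atom.

    Requires ``compute_peoe_charges`` to have run.  Virtual hydrogens (no
    coordinates) are excluded — they exist only for the charge model.
    """
    out: list[TypedAtom] = []
    for i in g.nodes():
        atom = g.atom(i)
        if atom is None:
            continue
        ff_type = _type_one(g, i)
        g.g.nodes[i]["ff_type"] = ff_type
        charge = g.g.nodes[i].get("partial_charge", g.g.nodes[i]["charge"])
        is_h = g.element(i) == "H"
        parent_coords = None
        if is_h:
            parent = g.g.nodes[i].get("parent")
            if parent is not None and g.atom(parent) is not None:
                parent_coords = g.atom(parent).coords
        out.append(TypedAtom(
            atom=atom, ff_type=ff_type, partial_charge=float(charge),
            is_polar_h=is_h and ff_type == "HD",
            is_donor_h=is_h and ff_type == "HD",
            is_acceptor=ff_type in ("OA", "NA", "SA", "OS", "NS"),
            parent_coords=parent_coords,
        ))
    return out


# ---------------------------------------------------------------------------
# One-call preparation
# ---------------------------------------------------------------------------

def prepare_protein(s: Structure, n_iter: int = 8) -> list[TypedAtom]:
    """Template connectivity -> polar H -> PEOE -> typing, for the protein."""
    bg = protein_connectivity(s)
    place_polar_hydrogens(bg)
    virtual = _add_virtual_apolar_h(bg)
    charges = compute_peoe_charges(bg, n_iter=n_iter)
    _merge_apolar_h(bg, virtual, charges)
    return assign_atom_types(bg)


def prepare_ligand(lig: LigandInstance, template_dir: Optional[str] = None,
                   n_iter: int = 8) -> list[TypedAtom]:
    """Perceived connectivity -> polar H -> PEOE -> typing, for the ligand."""
    bg = infer_ligand_bonds(lig, template_dir=template_dir)
    place_polar_hydrogens(bg)
    virtual = _add_virtual_apolar_h(bg)
    charges = compute_peoe_charges(bg, n_iter=n_iter)
    _merge_apolar_h(bg, virtual, charges)
    return assign_atom_types(bg)
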