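"""Synthetic protein-pocket/ligand mini-complexes with known character.

Each fixture is a legal minimal PDB-writable structure pairing a tiny
protein scaffold (a Gly-Gly dipeptide or a single lysine) with a 10-12
heavy-atom ligand placed at controlled geometry:

* ``hbond_pair``      backbone amide N-H donating to a ligand carbonyl;
* ``salt_bridge``     lysine ammonium against a ligand carboxylate;
* ``clash``           a ligand carbon far inside van der Waals contact;
* ``inert_surface``   an alkane ligand drifting >= 6 A from the protein;
* ``peg_like``        a triethylene-glycol molecule grazing the surface;
* ``covalent_suspect`` a ligand carbon at covalent-bond distance (~1.3 A).

Geometry is deterministic for a fixed spec; the seed drives only the
optional coordinate jitter.  These scaffolds emulate the archetypes seen in
deposited complexes (specific polar binding, additive/cryoprotectant surface
contacts, modelling errors producing clashes, unannotated covalent bonds) so
every classification branch is exercisable without downloads — they are not
realistic full-size proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure import Atom, Structure

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("hbond_pair", "salt_bridge", "clash", "inert_surface",
                 "peg_like", "covalent_suspect")

_DEFAULT_DISTANCE = {
    "hbond_pair": 2.9,      # donor N ... acceptor O
    "salt_bridge": 2.8,     # ammonium N ... carboxylate O
    "clash": 1.2,           # protein N ... ligand C
    "inert_surface": 6.5,   # closest approach
    "peg_like": 5.0,        # closest approach
    "covalent_suspect": 1.3,
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic complex.

    ``distance`` is the kind's key separation in Angstrom (defaults above);
    ``jitter`` adds Gaussian coordinate noise of that sigma, reproducible
    from ``seed``.
    """

    kind: str
    distance: Optional[float] = None
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")
        if self.distance is None:
            self.distance = _DEFAULT_DISTANCE[self.kind]
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b (Rodrigues)."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = _unit(np.cross(a, p))
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _zigzag(start: np.ndarray, u: np.ndarray, v: np.ndarray, n: int,
            bond: float = 1.53, angle_deg: float = 112.0) -> list[np.ndarray]:
    """n points in a planar zig-zag chain starting at ``start`` along u."""
    half = math.radians(angle_deg / 2.0)
    advance = bond * math.sin(half)
    offset = bond * math.cos(half) / 2.0
    pts = []
    for i in range(n):
        pts.append(start + (i * advance) * u + ((-1) ** i * offset) * v)
    shift = pts[0] - start  # anchor the first atom exactly at `start`
    return [p - shift for p in pts]


def _mkatom(serial: int, name: str, element: str, pos: np.ndarray, resname: str,
            seq: int, chain: str, polymer: bool, b: float = 20.0) -> Atom:
    return Atom(serial=serial, name=name, element=element,
                coords=np.asarray(pos, float), occupancy=1.0, adp=b, altloc="",
                residue_name=resname, residue_seq=seq, icode="",
                chain_id=chain, is_polymer=polymer, is_water=False)


def _gly_gly_scaffold() -> tuple[list[tuple[str, str, str, int, np.ndarray]], np.ndarray, np.ndarray]:
    """Extended Gly-Gly dipeptide, oriented so the second amide N sits at the
    origin with its riding N-H pointing along +x.

    Returns (atom records, origin N2 position, H direction) after the
    orienting transform has been applied; records are
    (name, element, resname, seq, coords).
    """
    # build in a local frame with idealized bonds/angles, roughly planar
    N1 = np.array([0.0, 0.0, 0.0])
    CA1 = np.array([1.458, 0.0, 0.0])
    # sp2 carbonyl carbon
    C1 = CA1 + 1.525 * np.array([math.cos(math.radians(69.0)),
                                 math.sin(math.radians(69.0)), 0.0])
    O1 = C1 + 1.231 * np.array([math.cos(math.radians(69.0 + 121.0)),
                                math.sin(math.radians(69.0 + 121.0)), 0.0])
    N2 = C1 + 1.329 * np.array([math.cos(math.radians(69.0 - 116.0)),
                                math.sin(math.radians(69.0 - 116.0)), 0.0])
    CA2 = N2 + 1.458 * np.array([math.cos(math.radians(69.0 - 116.0 + 59.0)),
                                 math.sin(math.radians(69.0 - 116.0 + 59.0)), 0.0])
    C2 = CA2 + 1.525 * np.array([math.cos(math.radians(10.0)),
                                 math.sin(math.radians(10.0)), 0.0])
    O2 = C2 + 1.231 * np.array([math.cos(math.radians(10.0 + 119.0)),
                                math.sin(math.radians(10.0 + 119.0)), 0.0])
    OXT = C2 + 1.231 * np.array([math.cos(math.radians(10.0 - 119.0)),
                                 math.sin(math.radians(10.0 - 119.0)), 0.0])

    hdir = -_unit(_unit(C1 - N2) + _unit(CA2 - N2))
    R = _rotation_between(hdir, np.array([1.0, 0.0, 0.0]))
    records = []
    for name, el, seq, pos in [
        ("N", "N", 1, N1), ("CA", "C", 1, CA1), ("C", "C", 1, C1),
        ("O", "O", 1, O1),
        ("N", "N", 2, N2), ("CA", "C", 2, CA2), ("C", "C", 2, C2),
        ("O", "O", 2, O2), ("OXT", "O", 2, OXT),
    ]:
        records.append((name, el, "GLY", seq, R @ (pos - N2)))
    return records, np.zeros(3), np.array([1.0, 0.0, 0.0])


def _gln_scaffold() -> tuple[list[tuple[str, str, str, int, np.ndarray]], np.ndarray]:
    """Single glutamine oriented so the side-chain amide NE2 sits at the
    origin with one riding N-H pointing along +x.

    Returns (records, donor H direction == +x)."""
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    CD = np.zeros(3)
    NE2 = CD + 1.33 * x
    OE1 = CD + 1.23 * (-0.5 * x + math.sqrt(3) / 2 * y)
    cg_dir = _unit(-0.5 * x - math.sqrt(3) / 2 * y)
    CG = CD + 1.52 * cg_dir
    CB = CG + 1.53 * _unit(cg_dir - 0.9 * y)
    CA = CB + 1.53 * _unit(cg_dir + 0.9 * y)
    N = CA + 1.46 * _unit(np.array([-1.0, -0.4, 0.6]))
    C = CA + 1.53 * _unit(np.array([-0.8, 0.9, -0.7]))
    O = C + 1.23 * _unit(np.array([-1.0, 0.1, 0.9]))
    OXT = C + 1.23 * _unit(np.array([0.2, 1.2, -1.0]))
    # riding H on NE2 (sp2, one heavy neighbor): in the amide plane at 120 deg
    # from the N->CD direction, anti to the heavier OE1 side
    hdir = 0.5 * x - math.sqrt(3) / 2 * y
    R = _rotation_between(hdir, x)
    records = []
    for name, el, pos in [("N", "N", N), ("CA", "C", CA), ("C", "C", C),
                          ("O", "O", O), ("OXT", "O", OXT), ("CB", "C", CB),
                          ("CG", "C", CG), ("CD", "C", CD), ("OE1", "O", OE1),
                          ("NE2", "N", NE2)]:
        records.append((name, el, "GLN", 1, R @ (pos - NE2)))
    return records, x


def _lys_scaffold() -> list[tuple[str, str, str, int, np.ndarray]]:
    """Single lysine oriented so NZ sits at the origin with the CE->NZ axis
    along +x (the ammonium hydrogens fan around +x)."""
    y = np.array([0.0, 1.0, 0.0])
    x = np.array([1.0, 0.0, 0.0])
    chain = _zigzag(np.zeros(3), x, y, 6, bond=1.51)  # CA CB CG CD CE NZ
    CA, CB, CG, CD, CE, NZ = chain
    N = CA + 1.458 * _unit(np.array([-0.6, -1.2, 0.3]))
    C = CA + 1.525 * _unit(np.array([-0.5, 1.3, -0.4]))
    O = C + 1.231 * _unit(np.array([-1.0, 0.3, 0.8]))
    OXT = C + 1.231 * _unit(np.array([0.3, 1.0, -1.0]))
    shift = NZ.copy()
    R = _rotation_between(_unit(NZ - CE), x)
    out = []
    for name, el, pos in [("N", "N", N), ("CA", "C", CA), ("C", "C", C),
                          ("O", "O", O), ("OXT", "O", OXT), ("CB", "C", CB),
                          ("CG", "C", CG), ("CD", "C", CD), ("CE", "C", CE),
                          ("NZ", "N", NZ)]:
        out.append((name, el, "LYS", 1, R @ (pos - shift)))
    return out


def _alkane_ligand(start: np.ndarray, u: np.ndarray, v: np.ndarray,
                   n: int = 10) -> list[tuple[str, str, np.ndarray]]:
    pts = _zigzag(start, u, v, n)
    return [(f"C{i+1}", "C", p) for i, p in enumerate(pts)]


def _carboxylate_ligand(n_pos: np.ndarray, u: np.ndarray, v: np.ndarray,
                        d_no: float) -> list[tuple[str, str, np.ndarray]]:
    """Alkyl carboxylate with both oxygens at ``d_no`` from ``n_pos``."""
    u = _unit(u)
    half_oco = math.radians(123.0 / 2.0)
    along = 1.25 * math.cos(half_oco)   # O projection onto the C->N axis
    perp = 1.25 * math.sin(half_oco)
    if d_no < perp + 0.1:
        raise ValueError("salt-bridge distance too short for the geometry")
    d_nc = along + math.sqrt(max(d_no**2 - perp**2, 1e-6))
    c1 = n_pos + d_nc * u
    o1 = c1 - along * u + perp * v
    o2 = c1 - along * u - perp * v
    tail = _zigzag(c1 + 1.52 * u, u, v, 7)
    atoms = [("C1", "C", c1), ("O1", "O", o1), ("O2", "O", o2)]
    atoms += [(f"C{i+2}", "C", p) for i, p in enumerate(tail)]
    return atoms


def _diketone_ligand(d: float, stack: float = 4.0) -> list[tuple[str, str, np.ndarray]]:
    """Diketone whose two carbonyl oxygens sit at (d,0,0) and (d,0,stack),
    bridged by a three-carbon zig-zag, with a short apolar tail (10 heavy
    atoms in total)."""
    x = np.array([1.0, 0.0, 0.0])
    o1 = d * x
    o2 = o1 + np.array([0.0, 0.0, stack])
    c1 = o1 + 1.23 * x
    c5 = o2 + 1.23 * x
    dx = math.sqrt(max(1.53**2 - (stack / 4.0) ** 2, 0.25))
    c2 = c1 + np.array([dx, 0.0, stack / 4.0])
    c3 = c1 + np.array([0.0, 0.0, stack / 2.0])
    c4 = c1 + np.array([dx, 0.0, 3.0 * stack / 4.0])
    tail_dir = _unit(np.array([1.0, -0.45, 0.0]))
    perp = np.array([0.0, 0.0, 1.0])
    t1 = c3 + 1.53 * tail_dir
    tail = _zigzag(t1, tail_dir, perp, 3)
    atoms = [("O1", "O", o1), ("C1", "C", c1), ("C2", "C", c2),
             ("C3", "C", c3), ("C4", "C", c4), ("C5", "C", c5),
             ("O2", "O", o2)]
    atoms += [(f"C{i+6}", "C", p) for i, p in enumerate(tail)]
    return atoms


def _peg_ligand(start: np.ndarray, u: np.ndarray,
                v: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Triethylene glycol: O-C-C-O-C-C-O-C-C-O zig-zag (10 heavy atoms)."""
    pts = _zigzag(start, u, v, 10, bond=1.44, angle_deg=111.0)
    pattern = ["O", "C", "C", "O", "C", "C", "O", "C", "C", "O"]
    names = {"O": 0, "C": 0}
    out = []
    for el, p in zip(pattern, pts):
        names[el] += 1
        out.append((f"{el}{names[el]}", el, p))
    return out


def make_fixture(spec: FixtureSpec) -> Structure:
    """Build the synthetic complex described by ``spec``.

    The protein scaffold sits with its interaction vector along +x and the
    ligand is placed on the +x side at the spec's key distance.  The result
    round-trips through the PDB writer/parser.
    """
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    d = float(spec.distance)

    if spec.kind == "salt_bridge":
        protein = _lys_scaffold()
        ligand = _carboxylate_ligand(np.zeros(3), x, y, d)
        het = "LGA"
    elif spec.kind == "hbond_pair":
        # two stacked glutamine side-chain amides donate parallel H-bonds
        # into the two carbonyls of a bridging diketone ligand — the
        # archetype of a specifically bound polar ligand
        gln, hdir = _gln_scaffold()
        protein = list(gln)
        for name, el, resname, _seq, pos in gln:
            protein.append((name, el, resname, 2, pos + 4.0 * z))
        ligand = _diketone_ligand(d, stack=4.0)
        het = "LGK"
    elif spec.kind in ("clash", "covalent_suspect"):
        protein, _, hdir = _gly_gly_scaffold()
        # approach 25 degrees off the amide-H axis so the offending carbon
        # hits the backbone nitrogen, not the riding hydrogen
        th = math.radians(25.0)
        approach = math.cos(th) * hdir + math.sin(th) * y
        ligand = _alkane_ligand(d * approach, approach, z)
        het = "LGC" if spec.kind == "clash" else "LGV"
    elif spec.kind == "inert_surface":
        protein, _, hdir = _gly_gly_scaffold()
        # run the chain perpendicular to the interaction axis at range d
        start = d * hdir - 5.0 * y
        ligand = _alkane_ligand(start, y, z)
        het = "LGI"
    elif spec.kind == "peg_like":
        protein, _, hdir = _gly_gly_scaffold()
        start = d * hdir - 5.5 * y
        ligand = _peg_ligand(start, y, z)
        het = "PGE"
    else:  # pragma: no cover - guarded by FixtureSpec
        raise ValueError(spec.kind)

    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    serial = 0
    for name, el, resname, seq, pos in protein:
        serial += 1
        atoms.append(_mkatom(serial, name, el, pos, resname, seq, "A", True))
    for name, el, pos in ligand:
        serial += 1
        atoms.append(_mkatom(serial, name, el, pos, het, 90, "A", False, b=30.0))
    if spec.jitter > 0:
        for a in atoms:
            a.coords = a.coords + rng.normal(0.0, spec.jitter, size=3)
    return Structure(atoms=atoms, entry_id=f"FX{spec.kind[:6].upper()}")
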