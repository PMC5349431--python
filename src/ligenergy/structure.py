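"""Reading crystallographic models and selecting/filtering the ligand of interest.

PDB and mmCIF files are parsed with gemmi; the atoms are flattened into a
simple ordered :class:`Structure` of :class:`Atom` records carrying exactly
what scoring needs (coordinates, occupancy, ADP, element, residue identity).
Ligand selection follows the survey convention: the largest noncovalently
bound non-water, non-polymer residue with 10-50 heavy atoms, taken from the
first protein chain when several copies exist.  Entry-level quality filters
(full occupancy, mean ADP, RSCC) decide whether a complex enters a survey.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "LigandInstance",
    "QualityStats",
    "FilterVerdict",
    "parse_structure",
    "write_pdb",
    "select_primary_ligand",
    "find_ligand",
    "detect_covalent_links",
    "ligand_quality_stats",
    "apply_entry_filters",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}

# Standard amino acids (incl. MSE as a polymer residue).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}

NUCLEOTIDES = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU", "DI"}


@dataclass
class Atom:
    """One atom of the deposited model.

    ``adp`` is the isotropic B-factor in Angstrom^2; ``altloc`` is empty for
    single-conformer atoms.  ``is_polymer`` marks protein/nucleic-acid chain
    atoms, ``is_water`` solvent.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float
    adp: float
    altloc: str
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str
    is_polymer: bool
    is_water: bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for {self.name}")
        if self.adp < 0.0:
            raise ValueError(f"negative ADP for {self.name}")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H" and self.element != "D"

    def residue_key(self) -> tuple[str, str, int, str]:
        return (self.chain_id, self.residue_name, self.residue_seq, self.icode)

    def __repr__(self) -> str:  # compact, for reports
        return (f"{self.chain_id}/{self.residue_name}{self.residue_seq}"
                f"{self.icode.strip()}/{self.name}")


@dataclass
class Structure:
    """Flattened atomic model plus the covalent LINK/struct_conn annotations."""

    atoms: list[Atom]
    entry_id: str = ""
    annotated_links: list[tuple[Atom, Atom]] = field(default_factory=list)

    def polymer_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_polymer]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_polymer and a.residue_name in AMINO_ACIDS]

    def first_protein_chain(self) -> Optional[str]:
        """First chain in file order containing standard amino-acid residues."""
        for a in self.atoms:
            if a.residue_name in AMINO_ACIDS:
                return a.chain_id
        return None

    def ligand_residues(self) -> list[list[Atom]]:
        """Non-polymer, non-water residues grouped in file order."""
        groups: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            if a.is_polymer or a.is_water:
                continue
            groups.setdefault(a.residue_key(), []).append(a)
        return list(groups.values())


@dataclass
class LigandInstance:
    """One concrete copy of a ligand: the heavy atoms of a single residue."""

    het_code: str
    chain_id: str
    residue_seq: int
    icode: str
    heavy_atoms: list[Atom]

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_atoms)

    def __post_init__(self) -> None:
        keys = {a.residue_key() for a in self.heavy_atoms}
        if len(keys) > 1:
            raise ValueError("ligand atoms span several residues")
        if any(a.is_water for a in self.heavy_atoms):
            raise ValueError("water cannot be a ligand instance")


@dataclass
class QualityStats:
    """Per-ligand quality summary used by the entry filters."""

    mean_adp: float
    min_occupancy: float
    n_heavy: int
    rscc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mean_adp < 0:
            raise ValueError("mean ADP cannot be negative")
        if self.rscc is not None and not (-1.0 <= self.rscc <= 1.0):
            raise ValueError("RSCC outside [-1, 1]")


@dataclass
class FilterVerdict:
    accepted: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted flag inconsistent with reasons")


def _atom_from_gemmi(serial: int, chain: gemmi.Chain, res: gemmi.Residue,
                     at: gemmi.Atom, is_polymer: bool) -> Atom:
    return Atom(
        serial=serial,
        name=at.name,
        element=at.element.name.upper() if at.element.name else "X",
        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
        occupancy=min(max(at.occ, 0.0), 1.0),
        adp=max(at.b_iso, 0.0),
        altloc=at.altloc if at.altloc != "\x00" else "",
        residue_name=res.name,
        residue_seq=res.seqid.num,
        icode=res.seqid.icode.strip(),
        chain_id=chain.name,
        is_polymer=is_polymer,
        is_water=res.name in WATER_NAMES,
    )


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per (residue, atom name): highest occupancy, ties
    broken by altloc 'A' first, then file order."""
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for idx, a in enumerate(atoms):
        key = a.residue_key() + (a.name,)
        rank = (-a.occupancy, a.altloc != "A", idx)
        if key not in best:
            best[key] = (rank, a)
            order.append(key)
        elif rank < best[key][0]:
            best[key] = (rank, a)
    return [best[k][1] for k in order]


def parse_structure(path: str, dialect: str = "auto",
                    keep_altlocs: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``dialect`` is one of ``pdb``, ``mmcif`` or ``auto`` (sniff from the file
    name/content).  By default alternate locations are collapsed to the
    highest-occupancy conformer; pass ``keep_altlocs=True`` to retain all.
    Covalent link annotations (LINK records / ``struct_conn``) are resolved to
    atom pairs where possible.

    Raises ``ValueError`` for unparseable or empty files.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(path)
        elif dialect == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(path).sole_block())
        elif dialect == "auto":
            st = gemmi.read_structure(path)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path!r}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path!r} contains no model")
    model = st[0]

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        polymer_names = {r.name for r in chain.get_polymer()}
        for res in chain:
            is_poly = (res.name in polymer_names and res.name not in WATER_NAMES) \
                or res.name in AMINO_ACIDS or res.name in NUCLEOTIDES
            for at in res:
                serial += 1
                atoms.append(_atom_from_gemmi(serial, chain, res, at, is_poly))
    if not atoms:
        raise ValueError(f"{path!r} contains no atoms")
    if not keep_altlocs:
        atoms = _dedupe_altlocs(atoms)

    index = {(a.chain_id, a.residue_seq, a.icode, a.name): a for a in atoms}
    links: list[tuple[Atom, Atom]] = []
    for con in st.connections:
        if con.type != gemmi.ConnectionType.Covale and con.type != gemmi.ConnectionType.Disulf:
            # LINK records come through as Covale/Unknown depending on dialect
            if con.type != gemmi.ConnectionType.Unknown:
                continue
        pair = []
        for cra_id in (con.partner1, con.partner2):
            key = (cra_id.chain_name, cra_id.res_id.seqid.num,
                   cra_id.res_id.seqid.icode.strip(), cra_id.atom_name)
            pair.append(index.get(key))
        if pair[0] is not None and pair[1] is not None:
            links.append((pair[0], pair[1]))

    entry = ""
    try:
        entry = st.info["_entry.id"].strip()
    except (KeyError, AttributeError):
        pass
    if not entry:
        entry = st.name.strip() or os.path.splitext(os.path.basename(path))[0]
    return Structure(atoms=atoms, entry_id=entry, annotated_links=links)


def write_pdb(s: Structure, path: str) -> None:
    """Write the structure back out as a minimal, legal PDB file."""
    with open(path, "w") as fh:
        if s.entry_id:
            fh.write(f"HEADER    COMPLEX                                 01-JAN-00   {s.entry_id[:4].upper():<4}\n")
        for a in s.atoms:
            record = "ATOM  " if a.is_polymer else "HETATM"
            x, y, z = a.coords
            name = a.name if len(a.name) == 4 else f" {a.name:<3}"
            fh.write(
                f"{record}{a.serial:>5} {name:<4}{a.altloc or ' ':1}{a.residue_name:>3} "
                f"{a.chain_id[:1]:1}{a.residue_seq:>4}{a.icode or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.adp:6.2f}"
                f"          {a.element:>2}\n"
            )
        fh.write("END\n")


def detect_covalent_links(s: Structure, lig: LigandInstance,
                          max_bond: float = 1.7) -> list[tuple[Atom, Atom, float]]:
    """Find protein-ligand atom pairs that look covalently bonded.

    Returns every protein-heavy-atom / ligand-heavy-atom pair closer than
    ``max_bond`` Angstrom, plus any pair named in the file's LINK/struct_conn
    annotations regardless of distance.  Used both to exclude covalent
    ligands from selection and to warn during scoring: deposited files do not
    always annotate covalency, so the distance heuristic is essential.
    """
    lig_ids = {id(a) for a in lig.heavy_atoms}
    out: list[tuple[Atom, Atom, float]] = []
    seen: set[tuple[int, int]] = set()

    prot = [a for a in s.polymer_atoms() if a.is_heavy]
    if prot and lig.heavy_atoms:
        pcoords = np.array([a.coords for a in prot])
        for la in lig.heavy_atoms:
            d = np.linalg.norm(pcoords - la.coords, axis=1)
            for j in np.nonzero(d < max_bond)[0]:
                pa = prot[int(j)]
                key = (id(pa), id(la))
                if key not in seen:
                    seen.add(key)
                    out.append((pa, la, float(d[j])))

    for a1, a2 in s.annotated_links:
        pa, la = None, None
        if id(a1) in lig_ids and a2.is_polymer:
            pa, la = a2, a1
        elif id(a2) in lig_ids and a1.is_polymer:
            pa, la = a1, a2
        if pa is not None and (id(pa), id(la)) not in seen:
            seen.add((id(pa), id(la)))
            out.append((pa, la, float(np.linalg.norm(pa.coords - la.coords))))
    return out


def _is_monoatomic_ion(atoms: Sequence[Atom]) -> bool:
    return len([a for a in atoms if a.is_heavy]) <= 1


def _as_ligand(atoms: Sequence[Atom]) -> LigandInstance:
    heavy = [a for a in atoms if a.is_heavy]
    first = atoms[0]
    return LigandInstance(
        het_code=first.residue_name, chain_id=first.chain_id,
        residue_seq=first.residue_seq, icode=first.icode, heavy_atoms=heavy,
    )


def select_primary_ligand(s: Structure, min_heavy: int = 10, max_heavy: int = 50,
                          max_bond: float = 1.7) -> Optional[LigandInstance]:
    """Pick the ligand of interest under the survey selection rule.

    The largest noncovalently bound non-water, non-polymer residue whose
    heavy-atom count lies in ``[min_heavy, max_heavy]``.  Monoatomic ions and
    waters are never candidates; covalency is decided by annotations plus the
    ``max_bond`` distance heuristic.  Among several copies of the winning het
    code, the copy on (or nearest to) the first protein chain is returned;
    remaining ties go to file order.  Returns ``None`` when nothing qualifies.
    """
    candidates: list[LigandInstance] = []
    for group in s.ligand_residues():
        if _is_monoatomic_ion(group):
            continue
        lig = _as_ligand(group)
        if not (min_heavy <= lig.n_heavy <= max_heavy):
            continue
        if detect_covalent_links(s, lig, max_bond=max_bond):
            continue
        candidates.append(lig)
    if not candidates:
        return None

    best_n = max(c.n_heavy for c in candidates)
    finalists = [c for c in candidates if c.n_heavy == best_n]
    if len(finalists) == 1:
        return finalists[0]
    first_chain = s.first_protein_chain()
    if first_chain is not None:
        on_first = [c for c in finalists if c.chain_id == first_chain]
        if on_first:
            return on_first[0]
        # het codes often sit on their own chain label; fall back to proximity
        prot = [a for a in s.protein_atoms() if a.chain_id == first_chain]
        if prot:
            pc = np.array([a.coords for a in prot])
            def mindist(c: LigandInstance) -> float:
                lc = np.array([a.coords for a in c.heavy_atoms])
                return float(np.min(np.linalg.norm(
                    pc[:, None, :] - lc[None, :, :], axis=2)))
            return min(finalists, key=mindist)
    return finalists[0]


def find_ligand(s: Structure, het_code: str, chain_id: Optional[str] = None,
                residue_seq: Optional[int] = None) -> LigandInstance:
    """Look up a specific ligand copy by het code (and optionally chain/seq).

    Unlike :func:`select_primary_ligand` this applies no size or covalency
    rules — it is the escape hatch for scoring flagged or covalently bound
    ligands explicitly.
    """
    for group in s.ligand_residues():
        a = group[0]
        if a.residue_name != het_code:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residue_seq is not None and a.residue_seq != residue_seq:
            continue
        return _as_ligand(group)
    raise KeyError(f"ligand {het_code}:{chain_id}:{residue_seq} not found in "
                   f"entry {s.entry_id!r}")


def ligand_quality_stats(lig: LigandInstance,
                         rscc: Optional[float] = None) -> QualityStats:
    """Mean ADP and minimum occupancy over the ligand heavy atoms."""
    if lig.n_heavy == 0:
        raise ValueError("empty ligand")
    return QualityStats(
        mean_adp=float(np.mean([a.adp for a in lig.heavy_atoms])),
        min_occupancy=float(min(a.occupancy for a in lig.heavy_atoms)),
        n_heavy=lig.n_heavy,
        rscc=rscc,
    )


def apply_entry_filters(q: QualityStats, adp_max: float = 80.0,
                        rscc_min: float = 0.917) -> FilterVerdict:
    """Survey entry filters: full occupancy, mean ADP below ``adp_max``
    Angstrom^2, and (when an RSCC is supplied) RSCC above ``rscc_min``."""
    reasons: list[str] = []
    if q.min_occupancy < 1.0:
        reasons.append("occupancy")
    if not (q.mean_adp < adp_max):
        reasons.append("ADP")
    if q.rscc is not None and not (q.rscc > rscc_min):
        reasons.append("RSCC")
    return FilterVerdict(accepted=not reasons, reasons=reasons)
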