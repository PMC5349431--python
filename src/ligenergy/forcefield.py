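"""Semi-empirical pairwise force field for protein-ligand bound-state energies.

The energy of one protein-ligand atom pair is the sum of four terms in the
AutoDock-4 style:

* a 6-12 Lennard-Jones dispersion/repulsion term, ``W_vdw*(A/r^12 - B/r^6)``,
  with A and B derived from AMBER-style equilibrium radii and well depths;
* a directional 10-12 hydrogen-bond term, ``E(t)*W_hbond*(C/r^12 - D/r^10)``,
  used *in place of* the 6-12 term for polar-H/acceptor pairs;
* a Coulomb electrostatic term with the sigmoidal Mehler-Solmajer
  distance-dependent dielectric, ``W_elec*332.06*q_i*q_j/(eps(r)*r)``;
* a Gaussian-damped pairwise desolvation term,
  ``W_sol*(S_i*V_j + S_j*V_i)*exp(-r^2/(2*sigma^2))``.

Only the bound-state energy is computed; no unbound reference state and no
torsional entropy, so the result is not a free energy of binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, TextIO

if TYPE_CHECKING:  # pragma: no cover
    from .chem import TypedAtom

__all__ = [
    "AtomTypeParams",
    "ForceFieldParams",
    "PairEnergy",
    "load_forcefield",
    "vdw_term",
    "hbond_term",
    "dielectric",
    "elec_term",
    "desolvation_term",
]

# Coulomb constant converting e^2/Angstrom to kcal/mol.
COULOMB_CONSTANT = 332.06

# Bulk water relative permittivity used as the large-r dielectric asymptote.
EPS_BULK_WATER = 78.4


@dataclass(frozen=True)
class AtomTypeParams:
    """Per-type nonbonded parameters.

    ``r_eq_half`` is half the homonuclear equilibrium separation Rii (Angstrom),
    ``eps`` the 6-12 well depth (kcal/mol). ``hbond_r_eq``/``hbond_eps`` place
    the 10-12 well for types that can accept a hydrogen bond (zero otherwise).
    ``volume`` (Angstrom^3) and ``solvation`` parameterize the desolvation term.
    """

    r_eq_half: float
    eps: float
    volume: float
    solvation: float
    hbond_r_eq: float = 0.0
    hbond_eps: float = 0.0

    @property
    def is_hbond_acceptor_type(self) -> bool:
        return self.hbond_eps > 0.0


# Published AutoDock 4 parameter set (AMBER-derived Rii/eps, 10-12 wells,
# atomic volumes and solvation parameters).  Rii is stored halved so that
# r_eq(i,j) = r_eq_half(i) + r_eq_half(j).
_AD4_TABLE: dict[str, AtomTypeParams] = {
    #        Rii/2   eps    vol      solpar   Rij_hb eps_hb
    "H":  AtomTypeParams(1.00, 0.020, 0.0000, 0.00051),
    "HD": AtomTypeParams(1.00, 0.020, 0.0000, 0.00051),
    "HS": AtomTypeParams(1.00, 0.020, 0.0000, 0.00051),
    "C":  AtomTypeParams(2.00, 0.150, 33.5103, -0.00143),
    "A":  AtomTypeParams(2.00, 0.150, 33.5103, -0.00052),
    "N":  AtomTypeParams(1.75, 0.160, 22.4493, -0.00162),
    "NA": AtomTypeParams(1.75, 0.160, 22.4493, -0.00162, 1.9, 5.0),
    "NS": AtomTypeParams(1.75, 0.160, 22.4493, -0.00162, 1.9, 5.0),
    "OA": AtomTypeParams(1.60, 0.200, 17.1573, -0.00251, 1.9, 5.0),
    "OS": AtomTypeParams(1.60, 0.200, 17.1573, -0.00251, 1.9, 5.0),
    "F":  AtomTypeParams(1.545, 0.080, 15.4480, -0.00110),
    "MG": AtomTypeParams(0.65, 0.875, 1.5600, -0.00110),
    "P":  AtomTypeParams(2.10, 0.200, 38.7924, -0.00110),
    "SA": AtomTypeParams(2.00, 0.200, 33.5103, -0.00214, 2.5, 1.0),
    "S":  AtomTypeParams(2.00, 0.200, 33.5103, -0.00214),
    "CL": AtomTypeParams(2.045, 0.276, 35.8235, -0.00110),
    "CA": AtomTypeParams(0.99, 0.550, 2.7700, -0.00110),
    "MN": AtomTypeParams(0.65, 0.875, 2.1400, -0.00110),
    "FE": AtomTypeParams(0.65, 0.010, 1.8400, -0.00110),
    "ZN": AtomTypeParams(0.74, 0.550, 1.7000, -0.00110),
    "BR": AtomTypeParams(2.165, 0.389, 42.5661, -0.00110),
    "I":  AtomTypeParams(2.36, 0.550, 55.0585, -0.00110),
}

# Published AutoDock 4 free-energy weights for the four bound-state terms.
_AD4_WEIGHTS = {
    "weight_vdw": 0.1662,
    "weight_hbond": 0.1209,
    "weight_elec": 0.1406,
    "weight_sol": 0.1322,
}


@dataclass
class ForceFieldParams:
    """Complete parameter set: per-type tables, term weights and global knobs.

    ``desolv_sigma`` is the Gaussian width of the desolvation term (Angstrom),
    ``cutoff`` the hard nonbonded truncation radius, and ``clash_scale`` the
    fraction of the pair equilibrium distance below which a contact is
    reported as a steric clash.
    """

    types: dict[str, AtomTypeParams] = field(default_factory=lambda: dict(_AD4_TABLE))
    w_vdw: float = _AD4_WEIGHTS["weight_vdw"]
    w_hbond: float = _AD4_WEIGHTS["weight_hbond"]
    w_elec: float = _AD4_WEIGHTS["weight_elec"]
    w_sol: float = _AD4_WEIGHTS["weight_sol"]
    desolv_sigma: float = 3.5
    cutoff: float = 8.0
    clash_scale: float = 0.6
    # Per-pair energy clamp (kcal/mol) limiting the 12-power blow-up at
    # very short contacts, as the source force field's grids do.
    clamp: float = 1.0e5
    # Mehler-Solmajer sigmoidal dielectric constants.
    diel_A: float = -8.5525
    diel_lambda: float = 0.003627
    diel_k: float = 7.7839

    def type_params(self, ff_type: str) -> AtomTypeParams:
        try:
            return self.types[ff_type]
        except KeyError:
            raise KeyError(f"no force-field parameters for atom type {ff_type!r}") from None

    def r_eq(self, type_i: str, type_j: str) -> float:
        """Pair equilibrium separation from the arithmetic combining rule."""
        return self.type_params(type_i).r_eq_half + self.type_params(type_j).r_eq_half

    def eps_pair(self, type_i: str, type_j: str) -> float:
        """Pair well depth from the geometric combining rule."""
        return math.sqrt(self.type_params(type_i).eps * self.type_params(type_j).eps)

    def lj_AB(self, type_i: str, type_j: str) -> tuple[float, float]:
        """6-12 coefficients A, B with the minimum -eps_ij at r_eq(i,j)."""
        r0 = self.r_eq(type_i, type_j)
        e0 = self.eps_pair(type_i, type_j)
        return e0 * r0**12, 2.0 * e0 * r0**6

    def hbond_pair(self, type_i: str, type_j: str) -> tuple[float, float]:
        """10-12 well (r_eq, depth) for a donor-H/acceptor type pair.

        The well is carried by the acceptor type; the donor hydrogen
        contributes no radius of its own.
        """
        for t in (type_i, type_j):
            p = self.type_params(t)
            if p.is_hbond_acceptor_type:
                return p.hbond_r_eq, p.hbond_eps
        raise ValueError(f"neither {type_i!r} nor {type_j!r} carries a 10-12 well")

    def hbond_CD(self, type_i: str, type_j: str) -> tuple[float, float]:
        """10-12 coefficients C, D with the minimum -eps_hb at hbond_r_eq."""
        r0, e0 = self.hbond_pair(type_i, type_j)
        return 5.0 * e0 * r0**12, 6.0 * e0 * r0**10


def load_forcefield(override: Optional[str | TextIO] = None) -> ForceFieldParams:
    """Build the parameter set, optionally applying a plain-text override file.

    The override format is whitespace-delimited lines, either

        <type> <Rii> <eps> <Rii_hb> <eps_hb> <vol> <solpar>

    or ``weight_vdw|weight_hbond|weight_elec|weight_sol <value>`` or any of
    ``desolv_sigma|cutoff|clash_scale <value>``.  ``#`` starts a comment.

    Raises ``ValueError`` on an unknown key.
    """
    p = ForceFieldParams()
    if override is None:
        return p
    if isinstance(override, str):
        with open(override) as fh:
            lines = fh.readlines()
    else:
        lines = override.readlines()
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        key = fields[0]
        if key.startswith("weight_"):
            attr = {"weight_vdw": "w_vdw", "weight_hbond": "w_hbond",
                    "weight_elec": "w_elec", "weight_sol": "w_sol"}.get(key)
            if attr is None:
                raise ValueError(f"unknown weight key {key!r} in override")
            setattr(p, attr, float(fields[1]))
        elif key in ("desolv_sigma", "cutoff", "clash_scale", "clamp"):
            setattr(p, key, float(fields[1]))
        else:
            t = key.upper()
            if len(fields) != 7:
                raise ValueError(f"atom-type line needs 7 fields: {line!r}")
            if t not in p.types:
                raise ValueError(f"unknown type key {key!r} in override")
            rii, eps, rii_hb, eps_hb, vol, sol = map(float, fields[1:])
            p.types[t] = AtomTypeParams(rii / 2.0, eps, vol, sol, rii_hb, eps_hb)
    return p


def dielectric(r: float, p: ForceFieldParams) -> float:
    """Mehler-Solmajer sigmoidal distance-dependent dielectric.

    eps(r) = A + B / (1 + k*exp(-lambda*B*r)) with B = 78.4 - A.  Rises
    monotonically from ~1.3 near contact to bulk-water permittivity.
    """
    B = EPS_BULK_WATER - p.diel_A
    return p.diel_A + B / (1.0 + p.diel_k * math.exp(-p.diel_lambda * B * r))


def vdw_term(i: "TypedAtom", j: "TypedAtom", r: float, p: ForceFieldParams) -> float:
    """6-12 dispersion/repulsion energy (kcal/mol); zero beyond the cutoff."""
    if r <= 0.0:
        raise ValueError("coincident atoms: r must be positive")
    if r >= p.cutoff:
        return 0.0
    A, B = p.lj_AB(i.ff_type, j.ff_type)
    return min(p.w_vdw * (A / r**12 - B / r**6), p.clamp)


def hbond_term(donor_h: "TypedAtom", acceptor: "TypedAtom", r: float,
               t_dev: float, p: ForceFieldParams) -> float:
    """Directional 10-12 hydrogen-bond energy (kcal/mol).

    ``r`` is the polar-H to acceptor-heavy-atom distance and ``t_dev`` the
    deviation (degrees) of the donor-H...acceptor axis from ideal linear
    geometry; the angular factor is cos^2(t_dev), zero at or beyond 90 deg.
    """
    if not donor_h.is_donor_h:
        raise ValueError(f"{donor_h} is not a polar donor hydrogen")
    if not acceptor.is_acceptor:
        raise ValueError(f"{acceptor} is not a hydrogen-bond acceptor")
    if r <= 0.0:
        raise ValueError("coincident atoms: r must be positive")
    if r >= p.cutoff or t_dev >= 90.0:
        return 0.0
    C, D = p.hbond_CD(donor_h.ff_type, acceptor.ff_type)
    directional = math.cos(math.radians(t_dev)) ** 2
    return min(directional * p.w_hbond * (C / r**12 - D / r**10), p.clamp)


def elec_term(i: "TypedAtom", j: "TypedAtom", r: float, p: ForceFieldParams) -> float:
    """Screened Coulomb electrostatic energy (kcal/mol)."""
    if r <= 0.0:
        raise ValueError("coincident atoms: r must be positive")
    if r >= p.cutoff:
        return 0.0
    return p.w_elec * COULOMB_CONSTANT * i.partial_charge * j.partial_charge / (dielectric(r, p) * r)


def desolvation_term(i: "TypedAtom", j: "TypedAtom", r: float, p: ForceFieldParams) -> float:
    """Gaussian-damped pairwise desolvation energy (kcal/mol).

    Symmetric volume/solvation cross term (S_i*V_j + S_j*V_i) damped by a
    Gaussian of width ``desolv_sigma``; symmetric in i and j by construction.
    """
    if r >= p.cutoff:
        return 0.0
    pi, pj = p.type_params(i.ff_type), p.type_params(j.ff_type)
    gauss = math.exp(-(r * r) / (2.0 * p.desolv_sigma**2))
    return p.w_sol * (pi.solvation * pj.volume + pj.solvation * pi.volume) * gauss
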