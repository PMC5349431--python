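# Methods

## Scope and model

`ligenergy` estimates the interaction energy of a protein–ligand complex *in
the modelled bound state*. There is no unbound reference state, no torsional
entropy and no conformational sampling: the question answered is whether the
deposited or proposed pose is energetically sensible, not how tightly the
ligand binds. The estimate is a pairwise sum over protein–ligand atom pairs
of four AutoDock-4-style terms (6–12 van der Waals, directional 10–12
hydrogen bond, screened Coulomb, Gaussian desolvation), evaluated on
Gasteiger–Marsili (PEOE) charges and explicit riding polar hydrogens.

Normalizing the total by the number of non-hydrogen ligand atoms gives a
size-independent per-atom energy Ê. The validation categories are fixed at
Ê > 0 (clash), 0 ≥ Ê > −0.1 (weak/nonspecific) and Ê ≤ −0.1 kcal/mol/atom
(unproblematic), with the boundary values 0 and −0.1 belonging to the weak
and unproblematic classes respectively.

## Parameters

* **Per-type tables** (Rii, well depth, 10–12 wells, atomic volume,
  solvation parameter) are the published AutoDock 4 values; the pair rules
  are arithmetic (radii) and geometric (well depths). The 10–12 well of a
  donor-H/acceptor pair is carried entirely by the acceptor type (OA/NA:
  1.9 Å, 5.0 kcal/mol; SA: 2.5 Å, 1.0 kcal/mol), consistent with explicit
  polar-hydrogen preparation: the H–acceptor distance carries the well.
* **Term weights** W_vdw = 0.1662, W_hbond = 0.1209, W_elec = 0.1406,
  W_sol = 0.1322 (the published bound-state coefficients).
* **Electrostatics** use the Mehler–Solmajer sigmoidal dielectric
  ε(r) = A + B/(1 + k·e^(−λBr)) with A = −8.5525, λ = 0.003627, k = 7.7839,
  B = 78.4 − A, and the conversion constant 332.06 (kcal·Å/mol/e²).
* **Desolvation** is the symmetric volume/solvation cross term damped by a
  Gaussian of width σ = 3.5 Å. The |q|-dependent part of the source field's
  desolvation is deliberately folded into the per-type solvation parameters
  only; charges enter the model solely through the Coulomb term.
* **Cutoff** 8.0 Å with hard truncation and no smoothing, keeping the
  analytic term tests exact. Configurable, as are all of the above, through
  a plain-text override file.
* **Clamp**: each 12-power term is capped at 10⁵ kcal/mol per pair, the
  grid-map convention of the source force field. Without a cap, a 1.0 Å
  contact alone produces arbitrarily large numbers dominated by coordinate
  noise; with it, severe clashes still score in the 10³–10⁴ kcal/mol/atom
  range that makes them unmistakable.
* **Clash flag**: a pair closer than 0.6 × its equilibrium separation. The
  fraction is a package choice (the category threshold Ê > 0 is what defines
  a clashing *complex*; the per-pair flag only localizes the problem).

## Preparation protocol

**Ligand connectivity** is perceived from geometry: heavy atoms are bonded
below the covalent-radius sum + 0.45 Å; planar 5/6-membered C/N/O/S rings
are marked aromatic; bond orders and pH-7 formal charges come from
valence-satisfaction heuristics (carbonyl by C–O distance; carboxylates get
order 1.5 and −½ per oxygen; phosphates/sulfates distribute the remaining
valence and the deprotonated group charge uniformly over their terminal
oxygens). When a chemical-component-dictionary-style template for the het
code is available (bundled, or via a template directory) its bond orders and
formal charges take precedence over the heuristics.

**Protein connectivity** comes from residue templates for the 20 standard
amino acids (+ MSE): intra-residue bonds, hybridization, force-field types
and pH-7 charges (Asp/Glu −½ per carboxylate oxygen, Lys +1, Arg +⅓ per
guanidinium nitrogen, His neutral with H on NE2, protonated amino termini,
−½ per terminal carboxylate oxygen when OXT is present). Fractional seeds on
resonance-equivalent atoms keep the charge distribution symmetric. Peptide
bonds are added below 1.8 Å (chain breaks simply omit the edge), disulfides
below 2.3 Å (suppressing the thiol hydrogen). Nonstandard residues fall back
to distance-based perception. Waters and monoatomic ions are excluded
throughout — through-water and through-ion interactions are out of scope.

**Hydrogens.** Only polar hydrogens (on N, O, S) receive coordinates, at
idealized riding geometry: 1.0 Å N–H, 0.96 Å O–H, 1.34 Å S–H; sp2 donors
in-plane, sp3 donors tetrahedral, rotatable hydroxyls placed anti to the
heaviest substituent of the parent's neighbor. Apolar C–H hydrogens never
receive coordinates, but they do participate in the charge computation as
topology-only nodes, after which their charges are merged into the parent
carbon (united-atom convention). PEOE is a pure topology method, so these
virtual hydrogens need no geometry.

**Charges.** PEOE runs 8 synchronous iterations with damping (1/2)^k and the
published electronegativity coefficients χ = a + bq + cq², seeded with the
formal charges; the damping denominator is the cation electronegativity
a+b+c of the donating atom (20.02 for hydrogen). Synchronous updates make
the result independent of atom order; charge is conserved per connected
component by construction. Eight iterations agree with a 12-iteration
reference implementation to < 0.01 e on small molecules. The protein is
equilibrated per chain over the full covalent graph, not per residue — a
choice the method's description leaves open; per-chain equilibration treats
protein and ligand identically.

**Typing** maps each atom to one AD4-style type: aromatic vs aliphatic
carbon (A/C); nitrogen with no bound hydrogen and a free lone pair as
acceptor NA, otherwise N; all oxygens OA; sulfur SA unless oxidized;
polar hydrogens HD. Donor/acceptor flags follow the type.

**Hydrogen-bond geometry.** The 10–12 term applies to donor-H/acceptor pairs
*in place of* the 6–12 term (never both), at the H–acceptor distance, scaled
by E(t) = cos²(t) where t is the deviation of the donor–H···acceptor axis
from linearity, zero at or beyond 90°. The cos² form is a deliberate
simplification of the hybridization-dependent directionality functions in
the literature; it preserves the essential behavior (full strength when
linear, extinction at right angles) with one analytic expression.

## Entry selection and filters

For survey-style use the package selects, per entry, the largest
noncovalently bound non-water ligand with 10–50 heavy atoms, preferring the
copy on (or nearest to) the first protein chain; covalency is decided by
LINK/struct_conn annotations *or* any protein–ligand heavy-atom pair below
1.7 Å, since deposited files do not reliably annotate covalent bonds.
Alternate locations collapse to the highest-occupancy conformer (ties:
altloc A, then file order). Quality filters accept an entry when the ligand
is fully occupied, its mean ADP is below 80 Å² and — when an RSCC is
supplied (always an external scalar; the package reads no maps) — the RSCC
exceeds 0.917. Explicitly requested ligands bypass selection, so flagged or
covalent ligands can still be scored; pairs below 1.7 Å are scored normally
(they produce the large positive energies that make clashes visible) and
additionally reported as covalent suspects.

Only the asymmetric unit is scored; crystallographic symmetry mates are not
expanded. For ligands bound at crystal contacts this can understate the
interaction, which is a documented limitation rather than an option.

## Candidate ranking

The combined score for ligand guessing is the mean of two within-list ranks:
RSCC descending and Ê ascending, ties sharing the mean rank; final ties
break by better Ê, then lexicographic id. Rank averaging is scale-free — any
order-preserving transformation of either metric leaves the result
unchanged — which is the point of a nonparametric combination of two metrics
with incomparable units. A min–max-rescaled alternative is available behind
a flag for sensitivity checks but is not scale-free and not the default.

## Synthetic fixtures

The generator builds six archetype mini-complexes, each a legal PDB file
(so the full I/O path is exercised) pairing a small scaffold (glutamine,
lysine, or a Gly-Gly dipeptide) with a 10-heavy-atom ligand:
double hydrogen-bond binder (stacked glutamine amides donating into a
bridging diketone), lysine/carboxylate salt bridge, steric clash (carbon at
1.2 Å), inert alkane at 6.5 Å, PEG-like glycol grazing at 5 Å, and a
covalent suspect at 1.3 Å. Key separations are parameters; geometry is
deterministic, with optional seeded Gaussian coordinate jitter (0.05 Å in
the robustness checks, the order of a good crystal structure's coordinate
precision). These fixtures emulate the interaction *archetypes* of deposited
complexes — specific polar binding, additive surface contacts, modelling
errors — but not their scale or chemistry: passing the category tests shows
the scoring pipeline orders and classifies interaction types correctly, not
that it reproduces absolute energies of real full-size complexes. That is
what the worked-example checks on deposited entries are for; they require
access to the PDB archive and run with the rest of the suite when the
network allows.

## Numerical choices and degenerate inputs

Exact coincidence of two atoms raises an error (the model is undefined at
r = 0); contacts below the clamp threshold are finite by the per-pair cap.
An empty pair list (ligand out of range) yields exactly E = 0 and the weak
category — the signature of a non-interacting ligand. Ligands must have at
least one heavy atom; the normalization denominator counts heavy atoms only,
though polar hydrogens contribute energy. The neighbor search uses a k-d
tree and is verified to match the brute-force double loop to 1e-9.

## Known limitations

No tautomer/protomer enumeration, pKa prediction, or Asn/Gln/His flips; no
through-water or through-ion interactions; no symmetry expansion; no
intra-ligand strain; RSCC is always an input, never computed. Bond-order
perception on poor-geometry ligands falls back to best-effort heuristics
with a warning. Coordinate error is not propagated into the energy, although
the steep short-range terms make the result sensitive to it; treating that
properly would require error-weighted energies.
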