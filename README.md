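# ligenergy

**Per-atom-normalized protein–ligand bound-state interaction energy for
validating and re-ranking crystallographic ligands.**

Crystallographic model building maximizes the fit of a ligand to its electron
density; whether the resulting binding mode is *energetically feasible* is
usually never checked. `ligenergy` computes a fast, semi-empirical estimate of
the interaction energy of the protein–ligand complex in its modelled bound
state, directly from a deposited or candidate PDB/mmCIF file. It is aimed at
crystallographers and structural bioinformaticians who want to

* flag deposited or freshly built ligands that clash with the protein or bind
  only nonspecifically at the surface, and
* choose among candidate ligand identities for one density cluster by
  combining the energy with a real-space density-fit term (RSCC).

## The score

The bound-state energy is an AutoDock-4-style pairwise sum over all
protein–ligand atom pairs *i, j* within an 8 Å cutoff:

```
E = W_vdw  Σ (A_ij/r_ij^12 − B_ij/r_ij^6)                 6–12 dispersion/repulsion
  + W_hb   Σ E(t) (C_ij/r_ij^12 − D_ij/r_ij^10)           directional 10–12 H-bond
  + W_elec Σ 332.06 q_i q_j / (ε(r_ij) r_ij)              Coulomb, Mehler–Solmajer ε(r)
  + W_sol  Σ (S_i V_j + S_j V_i) exp(−r_ij²/2σ²)          Gaussian desolvation
```

with AMBER-derived A/B parameters, published AutoDock 4 well depths, volumes,
solvation parameters and term weights, Gasteiger–Marsili (PEOE) partial
charges *q*, and explicit polar hydrogens placed at idealized riding
positions (apolar hydrogens are merged into their parent carbons). This is
the energy of the bound state only — not a free energy of binding.

Dividing by the number of non-hydrogen ligand atoms gives the **normalized
energy** `Ê = E / N_heavy` (kcal/mol per atom), a size-independent metric
analogous to ligand efficiency, with a three-way validation reading:

| normalized energy  | category           | meaning                                  |
|--------------------|--------------------|------------------------------------------|
| `Ê > 0`            | `clash_positive`   | interatomic clashes in the interface     |
| `0 ≥ Ê > −0.1`     | `weak_nonspecific` | weak/surface binding (buffers, PEGs, …)  |
| `Ê ≤ −0.1`         | `unproblematic`    | no problems in the protein–ligand interface |

For ligand *guessing*, each candidate's RSCC (supplied by the caller; this
package never touches density maps) and Ê are converted to within-list ranks
and averaged — a nonparametric combination that is invariant to the very
different scales of the two metrics. A high-RSCC candidate that clashes is
thereby demoted below a slightly worse-fitting but energetically sound one.

## Worked example

Generate a synthetic lysine/carboxylate salt-bridge complex and score it:

```sh
$ ligenergy fixtures --kind salt_bridge --out sb.pdb
$ ligenergy score sb.pdb --ligand LGA --rscc 0.95
entry FXSA ligand LGA:A:90: E = -1.49 kcal/mol over 40 pairs, normalized = -0.149 kcal/mol/atom (10 heavy atoms) -> unproblematic
most favourable contacts (top 10):
  hbond   A/LYS1/HNZ -- A/LGA90/O1  2.25 A  e_total -0.460
  hbond   A/LYS1/HNZ2 -- A/LGA90/O2  2.47 A  e_total -0.346
  ...
entry filters: accepted
```

The total bound-state energy is −1.49 kcal/mol over 40 atom pairs; divided by
the 10 ligand heavy atoms this gives Ê = −0.149 kcal/mol per atom, below the
−0.1 threshold, so the complex is classified `unproblematic`. The contact
list shows the interaction is carried by the ammonium–carboxylate hydrogen
bonds, and with the supplied RSCC of 0.95 the entry passes the
full-occupancy / mean-ADP < 80 Å² / RSCC > 0.917 quality filters.

Scoring a deposited entry works the same way on any local file:

```sh
ligenergy score 4ww7.pdb --ligand AMP --json report.json --report pairs.tsv
```

Candidate re-ranking takes a TSV manifest of `ligand_id`, `rscc` and either a
precomputed `e_normalized` column or per-candidate structure files:

```sh
ligenergy rank candidates.tsv --out ranked.tsv
```

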