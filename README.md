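# cugraft

Restrained grafting and geometric validation of copper sites in protein
models.

Homology models of copper enzymes — the membrane-bound ammonia and methane
monooxygenases (AMO/pMMO) and the CuA-carrying PmoD/AmoD-family proteins are
the motivating cases — are built without their metals and need the Cu ions
placed afterwards, guided by coordination geometry taken from better-studied
structures. `cugraft` implements that metal-placement stage and everything
needed to check its result:

* a **Gaussian restraint library** for three copper coordination motifs, with
  every term written as *mean ± 1σ*:
  - **CuB** — mononuclear Cu(II) bound to an N-terminal amino group
    (Cu–N 2.2 ± 0.1 Å) and three His imidazoles (Cu–Nδ 1.8 ± 0.1,
    Cu–Nε 2.1/1.9 ± 0.1 Å);
  - **CuC** — mononuclear Cu(II) with Asp Oδ1 (2.0 ± 0.1 Å), two His Nε
    (1.9 ± 0.1 Å) and a water (1.9 ± 0.1 Å) in a distorted tetrahedron;
  - **CuA2** — a dinuclear CuA-like Cu₂S₂(Cys)₂ core at a homodimer
    interface: 4 × Cu–Sγ 2.30 ± 0.10 Å, Cu–Sδ(Met) 2.50 ± 0.10 Å,
    Cu–Nδ(His) 2.10 ± 0.10 Å per copper, Cu1–Cu2 2.50 ± 0.10 Å, His-ring
    planarity torsions (180 ± 10°) and two rhombus-planarity torsions
    (0 ± 10°).
* **site grafting**: multi-start local minimization of
  E = Σᵢ (Δᵢ/σᵢ)²/2 + clash over the metal positions, the CuC water, and the
  ligand side-chain χ torsions (backbone fixed), with Cu(II) soft-sphere
  parameters derived from Zn(II) by the ionic-radius scale factor 1.01;
* **C3 symmetrization** of homotrimeric assemblies (exact rotational
  averaging about the best C3 axis);
* **geometry validation**: RMSD of the four donor atoms from an ideal
  tetrahedral or square-planar polyhedron (Kabsch superposition minimised
  over all 24 donor-to-vertex assignments), and dinuclear descriptors —
  Cu–Cu separation, Cu₂S₂ planarity, and the fold angle between the two CuS₂
  planes (180° = planar);
* **interface analysis**: Shrake–Rupley SASA, buried surface area
  BSA = SASA(A)+SASA(B)−SASA(AB), hydrogen bonds (heavy-atom criterion,
  3.5 Å / ≥ 90°) and van der Waals contacts;
* **template coverage**: alignment-driven bookkeeping of which target
  residues have support from a resolved template position, plus
  ligand-conservation checks (e.g. a His→Gln substitution disqualifying a
  candidate site);
* a **synthetic-data generator** that builds scaffolds whose donor atoms sit
  exactly at the restraint means around planted Cu positions (withheld from
  the structure, recorded as ground truth), so every stage can be verified
  quantitatively.

No deposited coordinates exist for the modelled enzymes, so the package's
tests and acceptance computations run end-to-end on these synthetic
scaffolds; on real models the same commands apply unchanged.

## Worked example

Generate a CuA-like dimer scaffold with 0.2 Å donor noise, graft the two
coppers, and validate the site geometry:

```sh
cugraft synth --name CuA2 --noise 0.2 --seed 7 --out scaffold.pdb --truth truth.json
cugraft graft --scaffold scaffold.pdb --site CuA2 --seed 7 --n-starts 4 \
        --out grafted.pdb --report graft.json
cugraft geomcheck grafted.pdb --site CuA2 --json geom.json
cugraft interface grafted.pdb --chains A,B --json iface.json
```

prints

```
wrote scaffold.pdb (48 atoms)
final energy 3.96  converged=True
CU1: rmsd to tetrahedral = 0.269 Å
CU2: rmsd to tetrahedral = 0.248 Å
buried area 316.4 Å², 8 contacts
```

and `geom.json` reports `cu_cu = 2.48 Å`, `plane_fold_angle = 173.3°`,
`rhombus_max_dev = 0.04 Å`: the grafted site is a near-planar Cu₂S₂ rhombus
with the Cu–Cu separation at its restrained value and each copper in a
mildly distorted tetrahedron — the geometry the restraint set encodes. The
final energy of ~4 is the irreducible strain left by the 0.2 Å donor noise
(each (Δ/σ)² term contributes ½ per σ of residual deviation); on a
noise-free scaffold it drops below 10⁻³ and the planted Cu positions are
recovered to better than 0.01 Å.

The full pipeline (synth → graft → geomcheck → interface → coverage) with a
persisted config and manifest:

```sh
cugraft run --site CuA2 --noise 0.2 --seed 7 --out-dir demo_run
```

## Selection mini-grammar

`select_atoms(structure, "chain A res 38 atom ND1")` — any of `chain`,
`res` (author numbering), `resname`, `atom`, each optional; matches are
returned in structure order and an empty result is not an error.

## Restraint TSV

`cugraft restraints export --site CuA2 --format tsv --out cua2.tsv` writes
columns `kind` (distance/angle/dihedral), `atoms` (pipe-joined `role:atom`
selectors, metals as `CU1:CU`/`CU2:CU`), `mean`, `sd` (Å or degrees).
`load_restraints_tsv` reads the same format back losslessly.

## Limitations

* PDB input only (fixed-column v3.3); mmCIF is not supported.
* Assemblies must be provided as explicit chains — no BIOMT expansion.
* Grafting moves metals, the CuC water and ligand χ torsions only; it is a
  site-placement stage, not a comparative-modelling engine (no loop
  rebuilding, no model ensembles, no statistical-potential scoring).

See `docs/methods.md` for the model, its assumptions, parameter defaults and
numerical choices.
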