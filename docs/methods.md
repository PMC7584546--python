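# Methods

## The restraint model

Each geometric feature of a copper site — a metal–donor distance, a
metal–donor–antecedent angle, or a torsion — is restrained by the negative
log of a Gaussian up to a constant,

    E(x) = (x − μ)² / (2σ²),

dimensionless, with μ and σ taken from the bundled site templates (all terms
are stated as *mean ± 1σ*; distances in Å, angles and torsions in degrees).
Torsion deviations are wrapped to (−180°, 180°] before squaring, so the
energy is invariant under full turns. All restraint classes carry unit
relative weight; the σ values themselves set the stiffness hierarchy
(distances 0.1 Å, angles 5–10°, torsions 10°).

The library encodes three motifs over *roles* (`his38`, `cys58A`, `water`,
…) rather than concrete residues; a role is bound to a residue only at graft
or validation time, so the same template applies to any scaffold and the
role labels can be remapped freely.

* **CuB** (4 distances, 7 angles, 6 torsions): N-terminal amino N at
  2.2 ± 0.1 Å with a Cu–N–Cα angle of 109 ± 5°; His Nδ at 1.8 ± 0.1 Å and
  two His Nε at 2.1/1.9 ± 0.1 Å, each His carrying two 120 ± 10° angles to
  its ring neighbours and two 180 ± 10° ring-planarity torsions that keep
  the metal in the imidazole plane.
* **CuC** (4 distances, 5 angles, 4 torsions): Asp Oδ1 at 2.0 ± 0.1 Å with
  Cu–Oδ1–Cγ 109 ± 5°, two His Nε at 1.9 ± 0.1 Å with the His family above,
  and a water O at 1.9 ± 0.1 Å. The water is an explicit single-atom entity.
* **CuA2** (9 distances, 12 angles, 6 torsions): the dinuclear
  Cu₂S₂(Cys)₂ core — four Cu–Sγ bonds at 2.30 ± 0.10 Å, a direct Cu1–Cu2
  term at 2.50 ± 0.10 Å and two rhombus torsions
  Cu1–SγA–Cu2–SγB / Cu2–SγB–Cu1–SγA at 0 ± 10° — plus one Met Sδ
  (2.50 ± 0.10 Å, two 109 ± 5° angles) and one His Nδ (2.10 ± 0.10 Å, His
  family) per copper. Cu–S–C angles are 109 ± 5° throughout.

Copper is treated as Cu(II) everywhere; the oxidation state affects labels
only, not the restraint arithmetic. Soft-sphere Cu(II) radii derive from the
Zn(II) Lennard-Jones parameters (Rmin/2 = 1.09 Å) by the ionic-radius scale
factor 1.01, well depth unchanged.

## Grafting

`graft_site` minimises Σ restraint energies + a soft-sphere clash penalty
over a deliberately small set of degrees of freedom: the metal coordinates
(3 per Cu), the water oxygen for CuC, and the side-chain χ torsions of the
ligand residues. The backbone never moves — grafting is a site-placement
stage applied to an otherwise finished model, not a remodelling step.

Numerical scheme: multi-start L-BFGS-B over a smooth objective. The first
start places each metal by a distance-terms-only pre-solve (trilateration
from the scaffold's donor atoms, χ = 0); subsequent starts add seeded
Gaussian jitter (1 Å positions, 5° torsions). The best local minimum wins;
ties below 10⁻⁹ resolve to the earliest start so that degenerate landscapes
(exact noise-free scaffolds admit symmetry-related zero-energy solutions)
reproducibly return the least-perturbed one. Default `n_starts` is 8 and the
RNG seed is mandatory in the CLI. Accepted-trajectory energies are recorded
and are non-increasing (L-BFGS-B line search guarantees descent per iterate).

Two regularisation choices matter:

* **Clash exclusions.** The clash term k·(d_contact − d)² (k = 10, slack
  0 Å, both configurable) guards the placed entities against the scaffold.
  Pairs inside the coordination sphere are excluded using the standard
  non-bonded convention with each metal–donor contact treated as a bond:
  atoms up to 1-4 (two covalent bonds from a donor atom) do not clash with
  the metal or water. This is not optional: restrained bond lengths
  (1.8–2.5 Å) and the ring atoms they position lie well inside generic vdW
  contact distances, so without the exclusion a perfectly restrained site
  would score a spurious clash.
* **χ tether.** Side-chain torsions are softly tethered to the input
  conformation, E += (χ/σ_χ)²/2 with σ_χ = 3° by default. Without it the
  problem is underdetermined: rings can rotate to re-satisfy every distance
  and angle at a displaced metal, so the metal position is not identifiable
  from the restraints alone. The default makes a χ move that displaces a
  donor by δ cost the same as a δ-sized distance-restraint violation
  (σ_χ ≈ σ_dist / lever arm ≈ 0.1 Å / 2 Å). Setting `chi_tether_sd = 0`
  recovers the untethered objective.

`symmetrize_c3` enforces exact three-fold rotational symmetry: the axis runs
through the mean of the three group centroids normal to their plane, the
three symmetry-mapped copies are averaged, and the average is written back
under 0/120/240° rotations. Only the rotational component is enforced — a
mirror element is not meaningful for chiral protein coordinates.

## Geometry validation

**RMSD to the ideal polyhedron.** The published "rmsd from the ideal
coordination geometry" convention is underdetermined, so the package fixes
the one label-free convention that returns exactly 0 for a perfect
polyhedron: translate the metal to the origin, scale the ideal unit vertices
(tetrahedron: four ⟨111⟩ directions; square planar: four coplanar vertices
at 90°) to the mean observed metal–donor distance, and minimise the
four-donor RMSD over all rotations (Kabsch) *and* all 24 donor-to-vertex
assignments. The metal is pinned at the origin and not counted in the RMSD
denominator (it would contribute zero residual and only dilute the value).
Tests bound the result by a brute-force SO(3) Euler-grid scan; the grid step
(6–10°) keeps the scan tractable and only weakens, never helps, the bound,
since Kabsch is exactly optimal per assignment.

**Dinuclear descriptors.** Cu–Cu separation; maximum (and rms) deviation of
the four Cu₂S₂ atoms from their least-squares plane ("deviation from the
plane" is read as the maximum, with the rms also reported); and the fold
angle between the (Cu1,S1,S2) and (Cu2,S1,S2) planes along the S–S hinge,
mapped so that a planar rhombus gives 180° (matching the convention in which
a near-planar site reads ~170°). Coincident metals degenerate to fold 0°;
coincident thiolates or a metal on the hinge raise a degeneracy error.

**Backbone φ/ψ** are computed as a coarse model check (termini and residues
flanking chain breaks — C–N > 2 Å — omitted); no full stereochemical
validation suite is attempted.

## Interface analysis

SASA is Shrake–Rupley with a Fibonacci-lattice point set (default 960
points, probe 1.4 Å), deterministic for a fixed point count, over a bundled
Bondi-style radius table (C 1.70, N 1.55, O 1.52, S 1.80, Cu 1.40 Å, …).
Buried surface area is the total over both sides,
BSA = SASA(A) + SASA(B) − SASA(A∪B) — reported as such because the
"per-side vs total" convention differs between studies. Contacts use
heavy-atom criteria (homology models carry no hydrogens): H-bond iff both
atoms are N/O, distance ≤ 3.5 Å and some antecedent–donor–acceptor angle
≥ 90° (both atoms are tried as donor; the best qualifying angle is
reported); vdW contact iff distance ≤ r(a) + r(b) + 0.5 Å. Per residue pair
and kind only the closest atom pair is kept. Spatial indexing (k-d tree) is
an implementation detail; tests verify equality with an O(n²) rescan.

## Template coverage

Intervals are 1-based inclusive throughout, matching the conventional
"1–6, 192–212 / 247" bookkeeping. A target position is covered iff some
alignment pairs it with a template position that is aligned (non-gap) and
outside that template's unresolved intervals. Sequence identity is identical
columns over aligned non-gap columns; published identity percentages from
profile searches use other conventions and are not comparable. A packaged
JSON fixture carries the unresolved-interval bookkeeping for the candidate
template structures of each modelling target (intervals and lengths only —
no sequences are bundled, so it supports interval arithmetic examples, not
re-derivation of published counts).

## Synthetic scaffolds

The generator builds each site's ligand residues from idealized
internal-coordinate templates placed so that *every* template restraint is
satisfied exactly at construction: imidazole rings are laid out in a plane
containing the metal with a 120° interior angle at the coordinating N (real
imidazoles have ~108°; the idealization is what makes both 120° metal
angles and the 180° planarity torsions exactly satisfiable), bridging
thiolate Cβ sits on the intersection of the two 109° cones about the Sγ→Cu
axes, and Met Cβ/Cε sit on the 109° cone about Sδ→Cu. Backbone atoms beyond
the restrained ones are attached at standard bond lengths in deterministic
directions. The metals (and their positions) are recorded in the ground
truth but withheld from the structure. The CuB donor directions are square
planar and the CuC/CuA2 directions tetrahedral; donor–donor angles are not
restrained, so this choice fixes the scaffold, not the objective.

Noise: `bond_noise_sd` is the standard deviation of the **total 3D
displacement** applied to each donor atom (per-coordinate sd is
`bond_noise_sd/√3`); by default only donor atoms are perturbed
(`whole_residue_noise` jitters everything). The whole assembly then gets a
seeded random rigid transform, drawn before the noise so that scaffolds
sharing a seed share a frame. Ground-truth restraint values are re-measured
from the emitted coordinates, never assumed.

What the generator does *not* emulate: real rotamer distributions, backbone
strain, neighbouring-residue packing, crystallographic disorder, or any
sequence context. Passing tests therefore demonstrate the correctness of
the restraint arithmetic, the optimizer, and the metrics — not that grafting
into a real homology model will reach any particular accuracy.

## Problem sizes and defaults

The test-suite and acceptance computations use desk-scale problems chosen as
representative rather than exhaustive: 20 seeded replicates per site for
noisy recovery (donor displacement sd 0.2 Å, the scale of good side-chain
placement in a homology model), 50 random donor constellations for the
geometry-oracle bound, 100 random alignments for coverage, 960 SASA points
(2000 where a closed form is compared at the few-percent level), and
6–12-residue poly-Ala helices for interface fixtures. The demo pipeline
(CuA2, noise 0.2, 4 starts) completes in a few seconds.

## Known limitations

* The grafting objective is local; pathological scaffolds (donors far from
  any consistent site) return `converged=False` with the best minimum found
  rather than a guaranteed global optimum.
* The χ tether trades flexibility for identifiability; scaffolds whose
  side chains need large rearrangements to bind the metal will retain
  restraint strain rather than rotate freely.
* H-bond detection without hydrogens cannot distinguish donor from acceptor;
  both interpretations are tried.
* The square↔tetrahedron RMSD gives a single scalar; it does not decompose
  distortions into angular vs radial components.
* mmCIF, altloc-aware writing, and BIOMT assembly expansion are out of
  scope.
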