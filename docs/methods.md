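# Methods

`glycofp` characterises how a protein receptor binds a
glycosaminoglycan ligand — the motivating system is human serum albumin
(HSA) with hyaluronate (HA) — by scanning trajectory frames for five
interaction types and aggregating them into interaction fingerprints,
alongside a per-frame binding-energy decomposition. This note records
the models, the tunable parameters, the numerical choices, and what the
synthetic fixtures do and do not demonstrate.

## Interaction models

### Hydrogen bonds

A donor–H···acceptor geometry is scored in kJ/mol as

    E_HB = 25 · (2.6 − max(d_HA, 2.1)) / 0.5 · s_DHA · s_HAX

with `d_HA` the hydrogen–acceptor distance in Å. The energy plateaus at
25 kJ/mol for `d_HA ≤ 2.1` and floors at 0 for `d_HA ≥ 2.6`. The two
angular factors are piecewise-linear ramps in [0, 1]:

    s(α) = 0               α ≤ θ1
           (α−θ1)/(θ2−θ1)  θ1 < α ≤ θ2
           1               α > θ2

with `(θ1, θ2) = (85°, 95°)` when the third atom of the angle is a
heavy atom and `(75°, 85°)` when it is a hydrogen. `s_DHA` is measured
at the hydrogen vertex (the D–H···A angle) and always uses the hydrogen
table; `s_HAX` is evaluated for every covalent neighbour X of the
acceptor (heavy or hydrogen table according to X's element) and
combined with the permissive maximum (configurable to minimum). An
acceptor with no covalent neighbour gets `s_HAX = 1`. A pair counts as
a hydrogen bond when `E_HB > 6.25 kJ/mol`, strictly: a geometry that
evaluates to exactly 6.25 is not a contact.

The ramp orientation deserves a remark. The source convention for this
score is sometimes quoted with the ramp written as `(θ2−α)/(θ2−θ1)`,
which is discontinuous against its own stated limits (0 below θ1, 1
above θ2) and would make bent bonds score higher than straight ones.
We use the increasing orientation, which is continuous at θ2 and
physically sensible; the decreasing form is available behind the
`decreasing_ramp` flag for comparison work.

Detection enumerates donor hydrogens of one group against N/O acceptors
of the other, in both directions, keeping every qualifying pair (no
best-per-hydrogen pruning). A k-d-tree prefilter at 2.475 Å is applied
to the H···A distance; it is lossless because
`25·(2.6−d)/0.5 > 6.25 ⟺ d < 2.475` and the angular factors can only
lower the energy.

### Water bridges

A water molecule bridges the receptor and the ligand when it donates
both hydrogens simultaneously: one hydrogen within 3.0 Å of a receptor
N/O atom and the other within 3.0 Å of a ligand N/O atom. This is a
pure distance rule — no angular term — and water acts only as a double
donor; water-accepting bridges are not counted. Both assignments of the
two hydrogens are tried and a (water, receptor atom, ligand atom)
triple counts once per frame regardless of which hydrogen serves which
side; the recorded leg distances belong to the assignment with the
smaller distance sum.

### Ionic contacts and cation bridges

Formal-charge centres at pH 7.4: LYS → NZ (+1); ARG → CZ (+1);
ASP/GLU → midpoint of the two carboxylate oxygens (−1); the
glucuronate carboxylate of the ligand → its oxygen midpoint (−1);
monatomic ions → their atom with nominal charge (+1 Na, +2 Mg/Ca,
−1 Cl). Histidine (pKa ≈ 6) is neutral by default and becomes an
ND1/NE2-midpoint (+1) centre when `his_protonated` is set. The
carboxylate midpoint (rather than the carbon) represents the
delocalised charge and is tie-free.

Two opposite-sign centres form an ionic contact when the raw
centre-centre distance minus the hydrogen-bond radius of each centre
falls in [0, 1.5] Å, both bounds inclusive. The radii are a package
convention exposed in config (N 1.75, O 1.70, C 1.80, Na 1.00,
Mg 0.85, Ca 1.10 Å); midpoint pseudo-centres use the element of their
defining atoms. Receptor–ligand, ion–receptor and ion–ligand pairings
are all reported with labels. ARG and protonated HIS centres are
scanned like any other; whether they ever form contacts is a property
of the coordinates, not a rule of the detector.

A cation bridge is a cation in simultaneous ionic contact with at
least one receptor anionic centre and one ligand anionic centre; every
centre pair is enumerated, so one cation touching two glutamates and
one ligand carboxylate yields two bridges. The default species filter
is {Ca, Mg} (the divalent bridge-formers); Na is included on request.

### Hydrophobic contacts

Carbons qualify in three classes: `CH3` (three attached hydrogens),
`CH2/CH` (two hydrogens, or one hydrogen plus three carbons), and
`aromatic-CH` (template ring carbon of PHE/TYR/TRP/HIS carrying a
hydrogen). Alpha carbons of amino acids are excluded — they are
polarised by the backbone — except glycine's CA, which carries two
hydrogens and qualifies. A contact is a receptor carbon and a ligand
carbon, both qualifying, within a cutoff. The cutoff is not part of
the published criterion; the package default is 4.5 Å between the
carbon centres, a common heavy-atom hydrophobic-contact distance, and
it is exposed in config and echoed in outputs.

### Covalent perception

Attachment (donor hydrogens, acceptor neighbours X, hydrogen counts
for carbon classes) is perceived geometrically within each residue:
a hydrogen within 1.2 Å of a heavy atom is bonded to it; heavy atoms
within 1.85 Å are bonded. Perception always uses the base-frame
coordinates, so topology is constant along a trajectory and coordinate
jitter cannot flip bond assignments. This is exact on the idealised
fixture templates and robust on ordinary PDB geometry; it does not
attempt bond orders or exotic chemistry, and inter-residue covalent
links (e.g. the glycosidic bond) are not perceived — acceptable
because all perception consumers are intra-residue questions.

## Binding energy

Per frame,

    E_bind = E_pot1 + E_pot2 + E_sol1 + E_sol2 − (E_pot_comp + E_sol_comp)

with 1/2 the receptor/ligand evaluated in isolation and "comp" their
union. Positive E_bind means affinity: attraction appears only in the
complex terms, lowering `E_pot_comp` below `E_pot1 + E_pot2`. The
evaluator is a pluggable backend contract (deterministic in the
coordinates; potential additive over non-interacting subsets), because
the energies of a real study come from the simulation force field, not
from this package. The shipped reference backend is deliberately
simple: 12-6 Lennard-Jones (Lorentz–Berthelot combining, generic
per-element parameters) plus Coulomb over formal charges with a
distance-dependent dielectric D(r) = 4r, summed over inter-residue
atom pairs (intra-residue terms cancel exactly in the E_bind
difference), and a solvation term equal to 0.02 kJ·mol⁻¹·Å⁻² times the
Shrake–Rupley solvent-accessible surface area (probe 1.4 Å, 960 sphere
points). It honours the algebra, the limits (E_bind → 0 at infinite
separation; exact −ε at the van der Waals minimum; isolated-sphere
SASA closed form) and sign conventions; it is not a force field and
its kJ/mol values are not comparable to published MD averages.

Trace statistics use a window that excludes the leading fraction of
frames as equilibration — default 40%, mirroring the common practice
of discarding the first 40 ns of a 100 ns run. The boundary is closed
on the left: a frame at exactly `t0 + 0.4·(t_end−t0)` is included.
The spread is the population standard deviation of the per-frame
series, no block averaging. Complex ranking sorts by descending
windowed mean with ties kept in input order.

## Fingerprints

Window-restricted per-frame counts are reported as both means and
totals (the published convention for such counts is ambiguous between
the two, so both are emitted). The amino-acid × oxygen-class matrices
for direct hydrogen bonds and water bridges attribute each contact to
the receptor residue type and the ligand atom's oxygen class; grand
totals always reconcile with the raw contact lists. Receptor subdomain
labels follow the albumin convention IA 5–107, IB 108–197, IIA
198–296, IIB 297–382, IIIA 383–494, IIIB 495–569 (residues 1–4 and
570–585 map to "other"), joined in canonical order, e.g.
`IA-IB-IIIA-IIIB`.

The oxygen classes O1–O10 and N label the hyaluronate disaccharide's
N/O atoms (GCU = D-glucuronate, NAG = N-acetyl-D-glucosamine). The
exact published numbering of the individual atoms is not recoverable
from text sources, so the shipped map is a documented package
convention — chosen so the hydroxyl-bearing classes are O1, O2, O8 and
O10, the carboxylate is O5, the ring oxygens share O4, the glycosidic
bridge is O7 and the acetamido nitrogen is N — and every fingerprint
output carries the map version (`glycofp-default-1`). Users can
override any assignment in config; strict mode errors on unmapped
ligand N/O atoms, lenient mode labels them `?`.

## Synthetic fixtures

The generator plants each interaction in isolation: small receptor and
ligand fragments (serine hydroxyl, asparagine carbonyl, lysine
ammonium, glutamate and glucuronate carboxylates, alanine and
N-acetyl methyls, ideal water with O–H 0.957 Å and H–O–H 104.5°) at
mid-criterion geometry — H···A 2.2 Å collinear (20 kJ/mol, threshold
crossing at 2.475 Å), water legs 2.8 Å (threshold 3.0), adjusted ionic
distance 0.75 Å (range ends 1.5), methyl pair 4.0 Å (cutoff 4.5) —
each in its own cell of a 14 Å grid under a seeded random rotation, so
ground truth holds by construction and events cannot interact. Decoys
are built just outside each criterion (2.7 Å, 3.3 Å, 1.7 Å, 4.9 Å).
The toy disaccharide is an idealised planar-hexagon GCU–NAG with
correct covalent distances, full oxygen-class coverage and a −1
carboxylate.

Pseudo-trajectories add independent isotropic Gaussian jitter per
frame; with the jitter standard deviation at or below a quarter of the
smallest criterion margin (≈0.05 Å for the defaults) the planted
counts survive in at least 95% of frames, which is itself a tested
property. None of this emulates real molecular motion: there are no
correlated fluctuations, no competing near-miss geometries from a
crowded binding site, no force-field physics. Passing these tests
demonstrates that the detectors implement their criteria exactly and
deterministically — not that the criteria themselves would reproduce
any particular published count on real trajectories, which depends on
the upstream simulation.

## Problem sizes and numerics

The test suite and the acceptance script run on desk-scale inputs:
planted complexes up to ~30 motifs (~500 atoms), trajectories of
5–100 frames, and a 10,000-site randomized sweep of the hydrogen-bond
criterion boundary (sites isolated on a 15 Å grid). Boundary locations
are found by bisection to 1e-6 Å. Detector outputs are ordered
deterministically (by atom serial); all randomness flows through
`numpy.random.default_rng` seeds. Degenerate inputs are typed errors:
hydrogen-free systems for H-dependent detectors, neutral residues for
charge centres, empty analysis windows, mismatched frame sizes.

## Known limitations

- The reference energy backend is a teaching-grade potential; use the
  backend contract to plug in real force-field evaluations.
- Covalent perception is geometric and intra-residue; unusual bond
  lengths (< 1.2 Å to H, > 1.85 Å heavy-heavy) would mis-perceive.
- Aromatic rings are template-based (PHE/TYR/TRP/HIS); non-standard
  aromatic residues are not recognised.
- The oxygen-class map is a convention; cross-study comparisons of
  class-resolved matrices require the same map version.
- Only inter-group (receptor–ligand) contacts are exposed at the CLI;
  the engines accept arbitrary disjoint groups.
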