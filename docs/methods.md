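# Methods

This note documents the models, conventions and numerical choices behind
`trimergeo`, and what its synthetic validation does and does not
demonstrate about real structures.

## Structure model and I/O

Structures are held in a small chain → residue → atom hierarchy with
orthogonal Å coordinates, author residue numbering (insertion codes kept,
gaps never re-indexed) and optional crystal metadata. Parsing of PDB and
mmCIF is delegated to gemmi; on read, one conformer per atom is kept
(highest occupancy, ties broken by file order), so all downstream geometry
is deterministic. Space-group operators are converted from fractional to
orthogonal form with the cell orthogonalisation matrix; only proper
rotations are retained (protein crystals belong to Sohncke groups).
Hydrogens and waters survive reading but are excluded from every geometry
operation — water-mediated interactions are deliberately out of scope.

Two writers exist: fixed-column PDB (byte-deterministic, coordinates at
the format's 3-decimal precision) and a JSON dump that round-trips a model
field-for-field and is used for fixtures and reports.

Masses are average (not monoisotopic) residue masses plus one water per
chain, matching how theoretical masses are quoted against SEC-MALS
measurements; `X` residues are excluded with a warning.

## Synthetic assemblies (the test-bed)

The generator emulates the quaternary architecture under study: protomers
of two globular domains joined by an extended linker, arranged with exact
Cn symmetry. Each domain is a cloud of 5-atom pseudo-residues (N, CA, C,
O, CB at fixed local offsets) whose CA positions are drawn uniformly
inside a sphere and then rigidly recentred so the arithmetic mean of all
domain atoms equals the blueprint centroid *exactly* — centroid recovery
is therefore exact by construction at zero noise. Linker residues
interpolate linearly between the edge CAs of consecutive domains.

Default study conditions: a flat C3 triangle with D1 centroids
30 Å apart (radius 30/√3 from the axis), the same-protomer D1:D2 distance
52 Å and the cross-protomer D1:D2′ distance 23.8 Å — the solved centroid
placement is D1 = (17.320508, 0, 0), D2 = (−32.460236, 15.029222, 0) with
the axis along z. Domain sizes (40 and 36 residues, radii 11 and 10 Å,
numbering 92– and 228–, 12-residue linker) keep runtimes in seconds while
preserving the two-domain numbering idiom.

Randomness: a single integer seed; CA directions then radial factors are
drawn domain by domain in blueprint order, and post-replication Gaussian
coordinate noise uses an independent stream derived from the same seed.
Noise is applied *after* replication so both the exact-symmetry and the
broken-symmetry regimes are reachable. Engineered cysteine pairs are
placed analytically so that, at zero noise, the Sγ atoms across each
D1:D2′ interface sit at exactly 2.05 Å (ideal disulfide) and the Cβ atoms
at 4.2 Å; a single engineered cysteine gets an Sγ with no partner — the
single-mutant control.

What the generator does **not** emulate: real stereochemistry, packing,
secondary structure, sequence composition or crystallographic disorder.
Passing tests demonstrate the correctness of the geometric machinery
(centroids, classes, superposition, areas, scans) — not that any
particular real protein forms a trimer.

## Distance classes

Cyclic chain order is determined from the rotations that best superpose
the first chain onto each of the others (Kabsch on CA pairs matched by
residue number), never from alphabetical order. A chain set is rejected
unless every rotation shares the cyclic axis (|cos| ≥ 0.9) and its angle
is within ~11° of a multiple of 360/n. The prime orientation is
canonicalised so that the singly-primed cross-domain class (D1:D2′) is the
*closer* of the two cross classes — i.e. the prime neighbour is the
interacting one — which also makes class summaries invariant under cyclic
relabelling of chains. Class RMSD is the population standard deviation of
the member distances.

Centroids default to all heavy atoms (`all_heavy`); `ca_only` is offered
because published centre-to-centre values may derive from reduced atom
sets, and the two modes differ by well under the 0.5 Å tolerance used for
literature comparisons.

## Superposition, TM-score, alignment

Kabsch uses the SVD formulation with the determinant correction that
excludes reflections; fewer than three pairs or collinear geometry raise
an error. TM-scores are normalised by the shorter structure's length by
default, with d₀ floored at 0.5 for L ≤ 21, and are maximised by the
standard iterative subset refinement (contiguous seed windows of halving
length, Kabsch on the subset, re-inclusion of pairs below a growing
cutoff until the subset is stable).

The aligner is a reimplementation of the *role* of structure-only
alignment tools, not of any specific program: gapless-threading seeds at
strided offsets plus 15-residue fragment-pair seeds, each refined for up
to 30 iterations by alternating Kabsch with Needleman–Wunsch re-pairing
(match `1/(1+(d/d₀)²)`, linear gap penalty 0.6, free end gaps; the DP
kernel is numba-compiled). Alignment-derived statistics on real
structures (paired-residue counts, RMSD over pairs, percent identity)
therefore carry reimplementation tolerances of roughly ±0.3 Å, ±10
residues and ±3 identity points; trimer-level whole-assembly RMSD figures
are treated as qualitative. Model-level comparisons build equivalent
sub-models (single domains, same-protomer D1:D2 concatenations, or
D1:D2′ concatenations with the interacting neighbour) and average the
TM-score over all pairings of equivalent models.

## Interfaces

Contacts: any heavy-atom pair within 4.0 Å defines a residue contact; the
k-d-tree search is exactly equivalent to the all-pairs scan (tested).
Hydrogen bonds use a distance-only criterion (donor/acceptor N/O/S heavy
atoms within 3.5 Å from per-residue templates) because deposited models
carry no hydrogens and no angle definition is available; the sidechain
flag marks bonds where either partner is not a backbone N/O.

SASA is Shrake–Rupley with probe 1.4 Å, vdW radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å (fallback 1.80 Å, logged) and a deterministic
golden-spiral point sphere, 960 points by default. Resolution governs
per-atom accuracy: at 960 points partially occluded atoms are accurate to
a few percent, at 4000 points to well under 2 % of a 10⁵-point reference
— the oracle-agreement test runs at 4000 points for that reason, while
the isolated-sphere identity holds at 960. Buried area of a pair is
computed on the isolated pair (SASA(a) + SASA(b) − SASA(a∪b)), split into
per-side losses, and half the total is reported as "interface area" for
comparability with PISA-style published values; published values carry an
additional ±10 % allowance since the exact radii/probe parameterisation
behind them is not stated.

## Cross-links

The Cβ–Cβ window default 3.5–5.5 Å brackets the 3.8–4.5 Å separation of
native disulfides with slack for sidechain flexibility; it is the key
free parameter and is CLI-exposed. Ranking is purely geometric
(|d − 4.2 Å|, deterministic tie-break by chain and residue number) — no
rotamer or energy model. Validation reports Sγ–Sγ pairs within 2.3 Å.
The design-to-validation consistency report matches designs to bonds by
residue-number pair on any chains, since a cyclic assembly realises each
design n times (orbit completeness is checked).

## Pipeline

A run is a single YAML/JSON config (CLI flags override file values).
Stages run in fixed order — load/assemble, distance classes, model
comparisons, interfaces, cross-links — any failure aborts with a
stage-labelled error, outputs are written atomically, and identical
config and inputs give a byte-identical report apart from the provenance
timestamp. The report schema is published as
`schema/analysis_report.schema.json`, generated from the pydantic models
that build the report.

For a deposited one-monomer asymmetric unit, the crystallographic trimer
can be generated either from the stored symmetry operators
(`crystal_symmetry` mode, choosing the threefold with the lattice shift
that keeps copies adjacent) or from an explicit user axis
(`explicit_axis`); the two paths must agree and are compared in the
deposited-structure tests.

## Known limitations

- The aligner is pairwise only; no multiple-structure alignment mode.
- No thermodynamic interface scoring (ΔG, complexation significance) and
  no water-mediated bridge detection.
- Cross-link design does not model mutant sidechains; candidate ranking
  is containment-oriented (chosen pairs should appear among candidates),
  not a prediction of rank order.
- Tests against deposited entries (7pkw, 8s7l, 3ub1) require those files
  to be fetched once with `scripts/fetch_pdb.py`; they cannot be bundled.
- Acceptance-script problem sizes (40/36-residue domains, 20 noise seeds,
  960–4000 sphere points) are the package's chosen defaults for fast,
  deterministic validation.
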