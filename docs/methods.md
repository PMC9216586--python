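# Methods

## Geometric core

All construction goes through one primitive: placing an atom D from three
reference atoms A, B, C given the bond |CD|, the angle B–C–D and the
dihedral A–B–C–D (sequential internal-coordinate frame placement, the
NeRF scheme). This realises torsions exactly, so the package's invariant
`measure(build(torsions)) == torsions` holds to 1e-6° and identical inputs
give bit-identical coordinates.

Signed dihedrals follow the IUPAC convention: positive when, looking along
the central bond, the far bond is rotated clockwise from the near bond.
The proper dihedral is symmetric under reversing the four points and
negated by mirror reflection; both properties are tested against an
independent projection-based formula.

Ideal stereochemical constants (Engh–Huber-like) live in one configuration
object (`IdealGeometry`): N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, Cα–Cβ
1.521 Å, Cβ–Sγ 1.808 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°,
Cα–Cβ–Sγ 114.0°; ideal S–S 2.04 Å and |χss| 90°. Missing Cβ atoms
(glycine, backbone-only models) are rebuilt at the ideal tetrahedral
position: 1.521 Å from Cα, equal angles (110.5°) to N and C, on the
L-amino-acid side of the backbone plane. ω is fixed at 180° everywhere,
including proline; cis peptides are not sampled.

## Site scanning and grading

Candidate pairs satisfy d(Cα,Cα) ≤ 6.5 Å **and** d(Cβ,Cβ) ≤ 4.5 Å.
Intra-chain pairs additionally need a sequence separation of ≥ 3 residues
(a bridge between near neighbours is sterically implausible); inter-chain
pairs are exempt. Native cystine pairs are reported from their deposited
rotamers rather than re-fixed, under a separate `native` provenance.

Sulphur fixation is an exhaustive grid over (χ1_i, χ1_j) at 5° steps
(72 × 72 placements, vectorised). The selected point minimises
|d_SS − 2.04 Å|; ties break deterministically by gauche⁻ preference
(smaller Σ|χ1 + 60°|), then by |χss| closest to 90°. Grading windows:

* **A** — d_SS ∈ [1.84, 2.24] Å and |χss| ∈ [60°, 120°];
* **B** — selected d_SS inside the covalent window [1.6, 2.6] Å but
  outside the A windows;
* **C** — even the maximal achievable d_SS over the whole grid is below
  1.6 Å (site spatially too close);
* **D** — even the minimal achievable d_SS exceeds 2.6 Å (sulphur cannot
  be fixed at covalent range despite compatible Cα/Cβ distances).

In the (rare) case where the grid straddles the covalent window without
the selected point landing inside it, the side nearer the selected point
decides C vs D, keeping the partition total and deterministic. The grading
source text describes three grades and names the fourth only in passing;
the four-way partition above is the consistent reading and every window is
configurable in `ModipConfig`. The 5° step was chosen as the coarsest grid
whose selected d_SS tracks a 1° brute-force grid within 0.05 Å (verified
on randomised cystine fixtures); grading is invariant under rigid motion
of the input by construction, and tested.

## Conformation generation

Each trial draws one (φ, ψ) per residue from Ramachandran-allowed boxes;
the sampling regions are deliberately simple axis-aligned cores, declared
in `DEFAULT_REGIONS` and overridable:

| class | boxes (φ range / ψ range, weight) |
|---|---|
| general (incl. Cys, sampled as Ala) | αR −90..−40 / −70..−20 (0.5); β −160..−80 / 100..170 (0.5) |
| glycine | the two above (0.3 each) + αL 40..90 / 20..70 (0.2) + mirror-extended 80..160 / −170..−100 (0.2) |
| proline | φ −78..−48 with ψ −55..−15 (0.4) or ψ 130..170 (0.6) |
| helix clue | −67..−47 / −57..−37 |
| strand clue | −140..−100 / 110..150 |

Secondary-structure clues override the residue class over their 1-based
inclusive range. Exactly three RNG draws are consumed per residue from one
global generator in trial order, which gives two properties for free:
bit-reproducibility from the seed, and accepted-count monotonicity in the
number of trials (a longer run extends, never perturbs, a shorter one).

A trial passes when (i) no Cα pair separated by ≥ 3 residues in sequence
is closer than 3.5 Å (self-collision filter), and (ii) every requested
cysteine pair passes the Cα/Cβ cutoffs and grades within the accepted set
{A, B, C} — grade D (sulphur unfixable) always rejects, while C is
accepted by default because published models of this kind include grade-C
bridges. Accepted models are kept in trial order up to `max_models`;
near-duplicate models are not collapsed and no ranking is applied —
choosing the best model is deliberately the user's task.

Acceptance is rare by nature: an 11-residue chain carrying the interlocked
(2,10)/(4,11) connectivity passes at roughly 1 in 20 000–50 000 trials, so
the standard run length is 200 000 trials (a few minutes on one CPU); the
test suite uses 50 000-trial runs plus a frozen seed whose first accepted
trial arrives within 300 trials for the fast unit checks.

## Loop database and pattern search

One `LoopRecord` is indexed per bridge — the inclusive residue span
between its cysteines ("loop size" counts both endpoints). Native bridges
(SSBOND records plus any Cys pair with Sγ–Sγ ≤ 2.5 Å, deduplicated) are
always indexed; modelled bridges pass a grade filter. Only intra-chain
segments are indexed as loops; inter-chain bridges are detected and
reported but not searchable, since a "loop" presumes one chain.

A query pattern is parsed from text (`C4-C19, C9-C21, C14-C26`;
case/space tolerant, `Cys` accepted) into ordered positions, pairing and
canonical offsets (positions minus the first). A chain window matches when
every query pair has a recorded bridge at exactly its offsets from the
window origin; an optional ±k per-endpoint tolerance relaxes this, but
exact matching is the default because it is reproducible. Sequence
similarity is ungapped positional identity over the matched window against
the query aligned at its first cysteine — the simplest auditable
definition. Hits rank by (worst bridge grade class with native < A < B <
C < D, identity descending, source id, window), making results invariant
to database insertion order. If a supplied query sequence disagrees with
the pattern's cysteine positions the pattern wins, with a warning — the
pattern string is authoritative.

Topology classification reduces to pairwise interval relations of the
loops: disjoint → independent, containment → nested, interleaving →
interlocked; the overall label is the uniform relation or `mixed`, and a
single bridge is `independent`. An independent set-intersection oracle
reproduces the classification exhaustively for two-bridge patterns over
positions ≤ 30 and on 20 000 seeded random three- and four-bridge
patterns (the full four-bridge enumeration over 30 positions is ~6 × 10⁸
patterns and adds nothing: the classifier only ever sees pairwise
relations, which the two-bridge enumeration covers exhaustively).

## Synthetic data

The fixture generator produces everything the tests and the acceptance
script consume; no structure is downloaded or bundled.

* **Ideal helix / extended chain / compact coil** — poly-alanine chains
  built from fixed or seeded torsions, in seeded random rigid poses. The
  compact coil (random allowed torsions) is the scan-scale fixture: an
  ideal α-helix offers *no* candidate pairs (helix Cβs point outward:
  Cβ–Cβ is 5.8 Å at i,i+3 and 6.6 Å at i,i+4), which is itself a tested
  property.
* **Bridged-pair fixture** — a peptide whose planted cystine has exact
  target geometry (default d_SS 2.04 Å, χss 90°, χ1 −60°). It is built
  side-chain-first: the Sγ–Sγ′ core is laid down in internal coordinates,
  Cβ, Cα, N and C grow outward from it (the N/C placement offset is
  measured from an ideal residue so the result is congruent with the Cβ
  reconstructor), and extended filler residues complete two segments.
  The two segments share a chain but are not peptide-bonded across the
  split — the fixture exists for pairwise bridge geometry, not chain
  continuity.
* **Toy database** — seven seeded structures planting three canonical
  connectivity architectures (interlocked (2,10)/(4,11) twice, once at an
  interior offset; nested (11,32)/(15,28); the three-bridge offsets
  [0, 5, 10, 15, 17, 22]) next to three spacing-perturbed decoys, with a
  ground-truth table of every window a search must find. Cysteines carry
  gauche⁻ Sγ atoms; bridges are declared, so search correctness is
  decoupled from the (arbitrary) bridge geometry of these chains.

What the synthetic data does not emulate: crystallographic noise,
alternative conformations beyond the altloc-selection path, non-standard
residues, multi-chain assemblies, or realistic side chains beyond Cβ/Sγ.
Passing tests therefore demonstrate algorithmic correctness under ideal
and randomised-ideal geometry, not robustness to experimental artefacts.

## Numerical and design notes

* PDB parsing is delegated to gemmi (model selection, altloc resolution to
  the highest-occupancy conformer with ties to 'A', SSBOND records);
  writing uses a minimal fixed-format emitter, 3-decimal coordinates.
  Multi-model (NMR) files default to the first model.
* Degenerate geometry (coincident points, collinear frames) raises
  `ValueError` rather than returning NaN.
* Torsions are degrees in (−180, 180]; 1-based positions in all
  user-facing pattern I/O, 0-based indices internally.
* The candidate scan excludes intra-chain pairs closer than 3 residues in
  sequence; the value is configurable and inter-chain pairs are exempt.
* Grade windows, cutoffs, grid step and clash threshold are all plain
  dataclass fields; nothing is hard-coded inside algorithms.

## Known limitations

Side chains beyond Cβ/Sγ are never built; backbone relaxation after
mutation, energy-based scoring, head-to-tail cyclisation and model ranking
are out of scope. Loop records assume intra-chain bridges. The sampling
boxes are rectangular simplifications of Ramachandran space — adequate for
generating allowed conformations, not a density model of real torsion
statistics.
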