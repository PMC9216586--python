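# ssforge

Stereochemical toolkit for disulphide-bridge engineering in proteins and
disulphide-rich peptides. Three engines share one geometric core:

* **modip** — scans a structure for residue pairs that could accommodate an
  engineered disulphide bridge without strain, fixes the two Sγ atoms by an
  exhaustive χ1 rotamer grid search, and grades every site **A** (ideal
  stereochemistry), **B** (covalently feasible but distorted), **C**
  (spatially too close) or **D** (Cα/Cβ distances compatible but the sulphur
  cannot be fixed geometrically).
* **ranmod** — generates random Ramachandran-allowed backbone conformations
  of a peptide (glycine, proline and user-declared helix/strand ranges get
  their own torsion boxes; everything else is sampled as alanine) and keeps
  conformations whose requested cysteine pairing can form bridges of
  acceptable grade. Models are reported in trial order, never ranked.
* **loopdb** — indexes disulphide-bonded segments ("loops": the residue span
  between bonded cysteines, inclusive) and searches them by multi-disulphide
  connectivity patterns such as `C4-C19, C9-C21, C14-C26`, classifying the
  loop topology (nested / interlocked / independent / mixed) and ranking
  hits by bridge grade and ungapped sequence identity.

## The model in brief

A candidate site is any residue pair with d(Cα,Cα) ≤ 6.5 Å and
d(Cβ,Cβ) ≤ 4.5 Å (Cβ rebuilt at the ideal tetrahedral position where
missing, so glycines and backbone-only models are scannable). For each
side, Sγ is placed at the ideal cysteine geometry (Cβ–Sγ 1.808 Å,
Cα–Cβ–Sγ 114°) for every χ1 on a 5° grid; the pair of rotamers minimising
|d(Sγ,Sγ′) − 2.04 Å| defines the modelled bridge, whose χss dihedral
(Cβ–Sγ–Sγ′–Cβ′, ideally ±90°) and S–S distance decide the grade. Backbone
conformations are realised from (φ, ψ, ω) by exact internal-coordinate
chain extension, so measured torsions reproduce sampled ones to 1e-6°.

## Worked example

Generate the bundled synthetic structures, index them, and search for the
interlocked two-bridge conotoxin-style pattern:

```
$ ssforge fixtures --kind toy-db --seed 7 --out toydb
wrote 7 structures + ground_truth.tsv to toydb/
$ ssforge build-db --pdb-dir toydb --no-modelled --out DB
indexed 16 loop records from 7 structures into DB/
$ ssforge search --db DB --ss "C2-C10, C4-C11"
pattern 'C2-C10, C4-C11' topology=interlocked -> 2 hit(s)
  TOY1	A	1	CPCQWNSTCC	native,native
  TOY4	A	7	CSCVMFPNCC	native,native
```

The two hits are exactly the two planted copies of the pattern (one at the
chain origin, one embedded at an interior offset); the perturbed decoy
spacings planted alongside are never reported. Topology `interlocked`
means the two loops interleave (2 < 4 < 10 < 11) — the cystine-knot
relation — whereas `C11-C32, C15-C28` would be reported `nested` (the
smaller loop lies inside the bigger one).

Model an 11-residue two-bridge peptide from sequence alone:

```
$ printf ">pep\nACACAAAAACC\n" > pep.fasta
$ ssforge ranmod --fasta pep.fasta --ss "C2-C10, C4-C11" --trials 200000 --seed 1 --out-dir rm
8 passing conformations out of 200000 trials; kept 8 models in rm/
```

(The accepted count is a property of the seed: valid interlocked-loop
conformations occur at a rate of a few per hundred thousand trials.)

Each written model is a PDB file whose declared bridges all grade within
the accepted set {A, B, C}; `rm/ranmod_summary.json` records the seed,
per-stage rejection counts and configuration needed to reproduce the run
bit-identically.

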