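"""Deterministic synthetic structures with known disulphide geometry.

Everything here is generated from a seed at run time: ideal helices,
two-segment peptides carrying a planted cystine with exact target S-S
distance and χss, and a toy multi-structure database with planted
connectivity patterns plus perturbed decoys.  The bridged fixture is built
side-chain-first — the cystine core is laid down in internal coordinates
and the two backbone segments are grown outward from it — because posing
two independent backbones to hit an exact d_SS/χss target is
ill-conditioned.

The planted connectivity patterns mirror three canonical disulphide-rich
peptide architectures: a two-bridge interlocked (cystine-knot-like)
arrangement, a loop-within-loop nested arrangement, and a three-bridge
system with offsets [0, 5, 10, 15, 17, 22].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .geometry import (IDEAL, IdealGeometry, TorsionSet, build_backbone,
                       dihedral, place_atom, reconstruct_cbeta)
from .structure_io import AtomRecord, ProteinStructure, Residue, structure_from_backbone

__all__ = [
    "FixtureSpec",
    "make_ideal_helix",
    "make_extended_chain",
    "make_disulphide_fixture",
    "make_toy_database",
    "random_rigid_transform",
    "CASE_PATTERNS",
]

# canonical planted connectivity patterns (1-based positions within the chain)
CASE_PATTERNS: dict[str, str] = {
    "interlocked-2b": "C2-C10, C4-C11",
    "nested-2b": "C11-C32, C15-C28",
    "three-bridge": "C4-C19, C9-C21, C14-C26",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic bridged-pair fixture."""

    kind: str = "bridged-pair"
    length: int = 12
    positions: tuple[int, int] = (3, 9)   # 1-based planted Cys positions
    d_ss: float = 2.04
    chiss: float = 90.0
    chi1: tuple[float, float] = (-60.0, -60.0)
    chi2: tuple[float, float] = (-85.0, -85.0)
    theta: float = 103.0                  # CB-SG-SG' angle
    seed: int = 0


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation in [-20, 20]³ Å."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20.0, 20.0, size=3)
    return q, t


def _apply_transform(st: ProteinStructure, rot: np.ndarray, trans: np.ndarray) -> None:
    for res in st.residues():
        for atom in res.atoms.values():
            atom.position = rot @ atom.position + trans


def make_ideal_helix(n: int, seed: int = 0,
                     geom: IdealGeometry = IDEAL) -> ProteinStructure:
    """Poly-alanine α-helix (φ=-57°, ψ=-47°, ω=180°) in a seeded rigid pose."""
    if n < 4:
        raise ValueError("helix fixture needs n >= 4 residues")
    torsions = [TorsionSet(phi=None if i == 0 else -57.0,
                           psi=None if i == n - 1 else -47.0,
                           omega=None if i == 0 else 180.0)
                for i in range(n)]
    coords = build_backbone("A" * n, torsions, geom)
    st = structure_from_backbone("A" * n, coords, structure_id=f"HELIX{n}")
    rot, trans = random_rigid_transform(np.random.default_rng(seed))
    _apply_transform(st, rot, trans)
    return st


def make_compact_coil(n: int, seed: int = 0,
                      geom: IdealGeometry = IDEAL) -> ProteinStructure:
    """Poly-alanine chain with seeded random allowed torsions.

    Mixed helical/extended draws fold the chain back on itself, so unlike
    the ideal helix the coil offers many residue pairs within disulphide
    engineering range; useful for exercising the candidate scan at scale.
    """
    from .ranmod import sample_torsions

    if n < 4:
        raise ValueError("coil fixture needs n >= 4 residues")
    rng = np.random.default_rng(seed)
    torsions, _ = sample_torsions("A" * n, rng=rng)
    coords = build_backbone("A" * n, torsions, geom)
    return structure_from_backbone("A" * n, coords, structure_id=f"COIL{n}")


def make_extended_chain(sequence: str, seed: int = 0,
                        geom: IdealGeometry = IDEAL) -> ProteinStructure:
    """β-extended chain (φ=-120°, ψ=+130°) for the given sequence."""
    n = len(sequence)
    torsions = [TorsionSet(phi=None if i == 0 else -120.0,
                           psi=None if i == n - 1 else 130.0,
                           omega=None if i == 0 else 180.0)
                for i in range(n)]
    coords = build_backbone(sequence, torsions, geom)
    st = structure_from_backbone(sequence, coords, structure_id="EXT")
    rot, trans = random_rigid_transform(np.random.default_rng(seed))
    _apply_transform(st, rot, trans)
    return st


@lru_cache(maxsize=4)
def _c_from_n_offset(geom: IdealGeometry = IDEAL) -> float:
    """Torsion offset between backbone C and N about the Cβ-Cα axis.

    Measured once on an ideal residue (with its reconstructed Cβ) so that
    side-chain-first construction reproduces exactly the chirality and
    angles of reconstruct_cbeta.
    """
    ts = [TorsionSet(phi=None, psi=120.0), TorsionSet(phi=-120.0, psi=None)]
    res = build_backbone("AA", ts, geom)[0]
    probe = res["CA"] + np.cross(res["CB"] - res["CA"], res["N"] - res["CA"])
    t_n = dihedral(probe, res["CB"], res["CA"], res["N"])
    t_c = dihedral(probe, res["CB"], res["CA"], res["C"])
    d = t_c - t_n
    return d + 360.0 if d <= -180.0 else d - 360.0 if d > 180.0 else d


def _cys_from_cystine(sg_self: np.ndarray, sg_other: np.ndarray,
                      cb: np.ndarray, chi1: float, chi2: float,
                      geom: IdealGeometry) -> dict[str, np.ndarray]:
    """Grow one cysteine residue (CA, N, C, O) outward from its Sγ-Cβ stub."""
    ca = place_atom(sg_other, sg_self, cb, geom.ca_cb, geom.ca_cb_sg, chi2)
    n = place_atom(sg_self, cb, ca, geom.n_ca, geom.ca_cb_angle, chi1)
    c = place_atom(sg_self, cb, ca, geom.ca_c, geom.ca_cb_angle,
                   chi1 + _c_from_n_offset(geom))
    o = place_atom(n, ca, c, geom.c_o, geom.ca_c_o, 135.0)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb, "SG": sg_self}


_EXT_PHI, _EXT_PSI = -120.0, 130.0


def _extend_forward(res: dict, count: int, geom: IdealGeometry) -> list[dict]:
    out = []
    n, ca, c = res["N"], res["CA"], res["C"]
    for _ in range(count):
        n2 = place_atom(n, ca, c, geom.c_n, geom.ca_c_n, _EXT_PSI)
        ca2 = place_atom(ca, c, n2, geom.n_ca, geom.c_n_ca, 180.0)
        c2 = place_atom(c, n2, ca2, geom.ca_c, geom.n_ca_c, _EXT_PHI)
        o2 = place_atom(n2, ca2, c2, geom.c_o, geom.ca_c_o, _EXT_PSI + 180.0)
        cb2 = reconstruct_cbeta(n2, ca2, c2, geom)
        out.append({"N": n2, "CA": ca2, "C": c2, "O": o2, "CB": cb2})
        n, ca, c = n2, ca2, c2
    return out


def _extend_backward(res: dict, count: int, geom: IdealGeometry) -> list[dict]:
    out = []
    n, ca, c = res["N"], res["CA"], res["C"]
    for _ in range(count):
        c0 = place_atom(c, ca, n, geom.c_n, geom.c_n_ca, _EXT_PHI)
        ca0 = place_atom(ca, n, c0, geom.ca_c, geom.ca_c_n, 180.0)
        n0 = place_atom(n, c0, ca0, geom.n_ca, geom.n_ca_c, _EXT_PSI)
        o0 = place_atom(n0, ca0, c0, geom.c_o, geom.ca_c_o, _EXT_PSI + 180.0)
        cb0 = reconstruct_cbeta(n0, ca0, c0, geom)
        out.insert(0, {"N": n0, "CA": ca0, "C": c0, "O": o0, "CB": cb0})
        n, ca, c = n0, ca0, c0
    return out


def make_disulphide_fixture(spec: FixtureSpec = FixtureSpec(),
                            geom: IdealGeometry = IDEAL) -> ProteinStructure:
    """Two-segment peptide whose planted Cys pair has exact bridge geometry.

    The cystine core (Sγ-Sγ' at ``spec.d_ss``, χss at ``spec.chiss``, χ1/χ2
    as requested) is placed first; both backbone segments are grown outward
    from it with extended filler torsions, so the measured d_SS matches the
    target to ~1e-6 Å and χss to ~1e-6°.  The two segments share one chain
    but are not peptide-bonded across the split — the fixture exists for
    pairwise bridge geometry, not for chain continuity.  The bridge is
    declared as an SSBOND-equivalent native pair.
    """
    p1, p2 = spec.positions
    if not (1 <= p1 < p2 <= spec.length):
        raise ValueError(f"planted positions {spec.positions} outside 1..{spec.length}")
    if not 1.0 <= spec.d_ss <= 4.0:
        raise ValueError(f"target d_ss {spec.d_ss} Å is not a reachable bridge")
    if not -180.0 < spec.chiss <= 180.0:
        raise ValueError("chiss must lie in (-180, 180]")

    sg_i = np.zeros(3)
    sg_j = np.array([spec.d_ss, 0.0, 0.0])
    th = np.radians(spec.theta)
    cb_i = sg_i + geom.cb_sg * np.array([np.cos(th), np.sin(th), 0.0])
    cb_j = place_atom(cb_i, sg_i, sg_j, geom.cb_sg, spec.theta, spec.chiss)

    cys_i = _cys_from_cystine(sg_i, sg_j, cb_i, spec.chi1[0], spec.chi2[0], geom)
    cys_j = _cys_from_cystine(sg_j, sg_i, cb_j, spec.chi1[1], spec.chi2[1], geom)

    split = (p1 + p2) // 2            # chain break between the two segments
    seg1 = (_extend_backward(cys_i, p1 - 1, geom) + [cys_i]
            + _extend_forward(cys_i, split - p1, geom))
    seg2 = (_extend_backward(cys_j, p2 - split - 1, geom) + [cys_j]
            + _extend_forward(cys_j, spec.length - p2, geom))
    coords = seg1 + seg2
    sequence = "".join("C" if k in (p1 - 1, p2 - 1) else "A"
                       for k in range(spec.length))
    st = structure_from_backbone(sequence, coords,
                                 structure_id=f"BRIDGE_{p1}_{p2}")
    st.add_native_pair(("A", p1 - 1), ("A", p2 - 1))
    rot, trans = random_rigid_transform(np.random.default_rng(spec.seed))
    _apply_transform(st, rot, trans)
    return st


# ------------------------------------------------------------- toy database

_AA_NO_CYS = "ADEFGHIKLMNPQRSTVWY"

_TOY_PLAN = [
    # (id, length, bridges 1-based, planted pattern name or None for decoys)
    ("TOY1", 12, [(2, 10), (4, 11)], "interlocked-2b"),
    ("TOY2", 35, [(11, 32), (15, 28)], "nested-2b"),
    ("TOY3", 30, [(4, 19), (9, 21), (14, 26)], "three-bridge"),
    ("TOY4", 24, [(8, 16), (10, 17)], "interlocked-2b"),   # embedded at offset
    ("TOY5", 14, [(2, 10), (5, 11)], None),                # perturbed interlock
    ("TOY6", 35, [(11, 31), (15, 28)], None),              # perturbed nest
    ("TOY7", 30, [(4, 18), (9, 21), (14, 26)], None),      # perturbed 3-bridge
]


def _toy_structure(name: str, length: int, bridges, rng: np.random.Generator,
                   geom: IdealGeometry = IDEAL) -> ProteinStructure:
    cys_pos = sorted({p for pair in bridges for p in pair})
    seq = "".join("C" if (k + 1) in cys_pos else
                  _AA_NO_CYS[rng.integers(len(_AA_NO_CYS))]
                  for k in range(length))
    # near-extended backbone with seeded torsion jitter
    torsions = [TorsionSet(
        phi=None if i == 0 else float(-120.0 + rng.uniform(-15, 15)),
        psi=None if i == length - 1 else float(130.0 + rng.uniform(-15, 15)),
        omega=None if i == 0 else 180.0) for i in range(length)]
    coords = build_backbone(seq, torsions, geom)
    st = structure_from_backbone(seq, coords, structure_id=name)
    for a, b in bridges:
        st.add_native_pair(("A", a - 1), ("A", b - 1))
        for pos in (a, b):   # gauche- SG so native geometry is measurable
            res = st.residue("A", pos - 1)
            if "SG" not in res.atoms:
                from .geometry import place_sgamma
                res.atoms["SG"] = AtomRecord("SG", place_sgamma(
                    res.coord("N"), res.coord("CA"), res.coord("CB"), -60.0, geom))
    rot, trans = random_rigid_transform(rng)
    _apply_transform(st, rot, trans)
    return st


def make_toy_database(seed: int = 0
                      ) -> tuple[list[ProteinStructure], pd.DataFrame]:
    """Toy structures with planted connectivity patterns plus decoys.

    Returns the structures and a ground-truth table listing every window
    that a search for each planted pattern must find (pattern name and
    string, source id, chain, 0-based window start).  Bit-reproducible
    from the seed.
    """
    rng = np.random.default_rng(seed)
    structures = []
    truth_rows = []
    for name, length, bridges, pattern_name in _TOY_PLAN:
        structures.append(_toy_structure(name, length, bridges, rng))
        if pattern_name is not None:
            first = min(p for pair in bridges for p in pair)
            truth_rows.append({
                "pattern_name": pattern_name,
                "pattern": CASE_PATTERNS[pattern_name],
                "source_id": name,
                "chain": "A",
                "window_start": first - 1,
            })
    truth = pd.DataFrame(truth_rows, columns=[
        "pattern_name", "pattern", "source_id", "chain", "window_start"])
    return structures, truth
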