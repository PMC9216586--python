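"""Vector geometry for peptide backbones and disulphide bridges.

Distances, bond angles, signed dihedrals (IUPAC convention), ideal-geometry
Cβ reconstruction, Sγ placement from χ1, and exact torsion-to-Cartesian
backbone construction by sequential internal-coordinate (NeRF-style) frame
placement.

All angles are degrees in (-180, 180]; all lengths are Ångström.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "IdealGeometry",
    "TorsionSet",
    "IDEAL",
    "dihedral",
    "bond_angle",
    "place_atom",
    "reconstruct_cbeta",
    "place_sgamma",
    "place_sgamma_many",
    "build_backbone",
    "measure_torsions",
]


@dataclass(frozen=True)
class IdealGeometry:
    """Standard peptide stereochemical constants (Engh–Huber-like).

    Every constant is configurable; these defaults are ordinary textbook
    peptide geometry, not fitted values.
    """

    n_ca: float = 1.458       # N-Cα bond, Å
    ca_c: float = 1.525       # Cα-C bond, Å
    c_n: float = 1.329        # C-N peptide bond, Å
    ca_cb: float = 1.521      # Cα-Cβ bond, Å
    cb_sg: float = 1.808      # Cβ-Sγ bond, Å
    c_o: float = 1.231        # C=O bond, Å
    n_ca_c: float = 111.2     # backbone angle, deg
    ca_c_n: float = 116.2
    c_n_ca: float = 121.7
    ca_c_o: float = 120.8
    ca_cb_angle: float = 110.5   # equal canonical angle of Cβ to N and C
    ca_cb_sg: float = 114.0      # Cα-Cβ-Sγ angle, deg
    ss_ideal: float = 2.04       # ideal S-S bond, Å
    chiss_ideal: float = 90.0    # ideal |χss|, deg

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "ca_cb", "cb_sg", "c_o", "ss_ideal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("n_ca_c", "ca_c_n", "c_n_ca", "ca_c_o", "ca_cb_angle", "ca_cb_sg"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"angle {name} must lie in (0, 180)")


IDEAL = IdealGeometry()


@dataclass
class TorsionSet:
    """Backbone torsions of one residue.

    ``phi`` is C(i-1)-N-Cα-C, ``psi`` is N-Cα-C-N(i+1), ``omega`` is the
    peptide torsion Cα(i-1)-C(i-1)-N-Cα preceding the residue.  ``phi`` of
    the first residue and ``psi`` of the last are undefined (None).
    """

    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float] = 180.0
    chi1: Optional[float] = None

    def __post_init__(self) -> None:
        for a in (self.phi, self.psi, self.omega, self.chi1):
            if a is not None and not -180.0 < a <= 180.0 + 1e-9:
                raise ValueError(f"torsion {a} outside (-180, 180]")


def _wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = math.fmod(deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral p1-p2-p3-p4 in degrees, range (-180, 180].

    Positive when, looking along p2->p3, the far bond p3->p4 is rotated
    clockwise from the near bond p2->p1.  Invariant under reversing the
    point order; negated by mirror reflection of the points.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    p4 = np.asarray(p4, dtype=float)
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-9:
        raise ValueError("degenerate dihedral axis: p2 and p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate dihedral: collinear points")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return _wrap_angle(math.degrees(math.atan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 at vertex p2, degrees in [0, 180]."""
    u = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("degenerate bond angle: coincident points")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _place(ax, ay, az, bx, by, bz, cx, cy, cz, bond, angle_deg, tors_deg):
    """Scalar NeRF placement: position D given A,B,C with |CD|=bond,
    angle(B,C,D)=angle_deg, dihedral(A,B,C,D)=tors_deg.  Pure-float path
    kept branch-free for the per-residue chain-building loop."""
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    th = math.radians(angle_deg)
    chi = math.radians(tors_deg)
    dx = -bond * math.cos(th)
    dpl = bond * math.sin(th)
    dy = dpl * math.cos(chi)
    dz = -dpl * math.sin(chi)
    return (
        cx + dx * bcx + dy * mx + dz * nx,
        cy + dx * bcy + dy * my + dz * ny,
        cz + dx * bcz + dy * mz + dz * nz,
    )


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A, B, C by internal coordinates.

    ``|C-D| == bond``, ``angle(B,C,D) == angle_deg`` and
    ``dihedral(A,B,C,D) == torsion_deg`` exactly (to floating point).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.linalg.norm(c - b) < 1e-9:
        raise ValueError("degenerate frame: B and C coincide")
    if np.linalg.norm(np.cross(b - a, c - b)) < 1e-12:
        raise ValueError("degenerate frame: A, B, C collinear")
    return np.array(
        _place(a[0], a[1], a[2], b[0], b[1], b[2], c[0], c[1], c[2],
               bond, angle_deg, torsion_deg)
    )


def reconstruct_cbeta(n, ca, c, geom: IdealGeometry = IDEAL) -> np.ndarray:
    """Rebuild an ideal tetrahedral Cβ from backbone N, Cα, C.

    The Cβ sits at ``geom.ca_cb`` from Cα, makes equal angles
    (``geom.ca_cb_angle``) to N and C, and lies on the L-amino-acid side
    of the N-Cα-C plane.  Mirroring the inputs mirrors the output.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    u = n - ca
    v = c - ca
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("degenerate frame: coincident backbone atoms")
    u /= nu
    v /= nv
    e3 = np.cross(u, v)
    ne3 = np.linalg.norm(e3)
    if ne3 < 1e-9:
        raise ValueError("collinear N, CA, C: cannot reconstruct CB")
    e3 /= ne3
    bis = u + v
    e1 = bis / np.linalg.norm(bis)
    half = 0.5 * bond_angle(n, ca, c)
    # equal angles theta to both u and v fix the (negative) component along e1
    alpha = math.cos(math.radians(geom.ca_cb_angle)) / math.cos(math.radians(half))
    alpha = max(-1.0, min(1.0, alpha))
    st = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    # L-configuration: CB on the +cross(u, v) side of the backbone plane
    direction = alpha * e1 + st * e3
    return ca + geom.ca_cb * direction


def place_sgamma(n, ca, cb, chi1: float, geom: IdealGeometry = IDEAL) -> np.ndarray:
    """Place Sγ on a cysteine given its χ1 (dihedral N-Cα-Cβ-Sγ)."""
    return place_atom(n, ca, cb, geom.cb_sg, geom.ca_cb_sg, chi1)


def place_sgamma_many(n, ca, cb, chi1_deg: np.ndarray,
                      geom: IdealGeometry = IDEAL) -> np.ndarray:
    """Vectorised Sγ placement over an array of χ1 values -> (k, 3) array."""
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    cb = np.asarray(cb, dtype=float)
    bc = cb - ca
    bc = bc / np.linalg.norm(bc)
    ab = ca - n
    nrm = np.cross(ab, bc)
    nrm = nrm / np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    th = math.radians(geom.ca_cb_sg)
    chi = np.radians(np.asarray(chi1_deg, dtype=float))
    dx = -geom.cb_sg * math.cos(th)
    dpl = geom.cb_sg * math.sin(th)
    return (cb
            + dx * bc
            + np.outer(dpl * np.cos(chi), m)
            - np.outer(dpl * np.sin(chi), nrm))


_GLY = "G"


def build_backbone(sequence: str, torsions: Sequence[TorsionSet],
                   geom: IdealGeometry = IDEAL) -> list[dict[str, np.ndarray]]:
    """Realise per-residue (φ, ψ, ω) torsions as backbone coordinates.

    Returns one dict per residue with keys N, CA, C, O and (except Gly) CB.
    The chain is grown by sequential frame placement so that the measured
    torsions of the built chain reproduce the inputs exactly.  Deterministic:
    identical inputs give bit-identical coordinates.
    """
    if len(sequence) != len(torsions):
        raise ValueError(
            f"sequence length {len(sequence)} != torsion count {len(torsions)}")
    if not sequence:
        return []
    g = geom
    coords: list[dict[str, np.ndarray]] = []

    # first residue: N at origin, CA on +x, C in the xy-plane
    n0 = (0.0, 0.0, 0.0)
    ca0 = (g.n_ca, 0.0, 0.0)
    th = math.radians(g.n_ca_c)
    c0 = (g.n_ca - g.ca_c * math.cos(th), g.ca_c * math.sin(th), 0.0)
    prev_n, prev_ca, prev_c = n0, ca0, c0
    raw: list[tuple] = [(n0, ca0, c0)]

    for i in range(1, len(sequence)):
        t = torsions[i]
        psi_prev = torsions[i - 1].psi
        if psi_prev is None:
            raise ValueError(f"residue {i - 1}: psi required to extend the chain")
        if t.phi is None:
            raise ValueError(f"residue {i}: phi required")
        omega = 180.0 if t.omega is None else t.omega
        n = _place(*prev_n, *prev_ca, *prev_c, g.c_n, g.ca_c_n, psi_prev)
        ca = _place(*prev_ca, *prev_c, *n, g.n_ca, g.c_n_ca, omega)
        c = _place(*prev_c, *n, *ca, g.ca_c, g.n_ca_c, t.phi)
        raw.append((n, ca, c))
        prev_n, prev_ca, prev_c = n, ca, c

    for i, (n, ca, c) in enumerate(raw):
        res: dict[str, np.ndarray] = {
            "N": np.array(n), "CA": np.array(ca), "C": np.array(c)}
        # carbonyl O anti to the next amide N (dihedral N-CA-C-O = psi + 180)
        psi = torsions[i].psi
        o_tors = _wrap_angle((psi if psi is not None else 180.0) + 180.0)
        res["O"] = np.array(_place(*n, *ca, *c, g.c_o, g.ca_c_o, o_tors))
        if sequence[i].upper() != _GLY:
            res["CB"] = reconstruct_cbeta(res["N"], res["CA"], res["C"], geom)
        coords.append(res)
    return coords


def measure_torsions(coords: Sequence[dict]) -> list[TorsionSet]:
    """Measure (φ, ψ, ω) from built or parsed backbone coordinates.

    Inverse of :func:`build_backbone` up to the undefined terminal angles.
    """
    out: list[TorsionSet] = []
    n = len(coords)
    for i, res in enumerate(coords):
        phi = psi = omega = None
        if i > 0:
            prev = coords[i - 1]
            phi = dihedral(prev["C"], res["N"], res["CA"], res["C"])
            omega = dihedral(prev["CA"], prev["C"], res["N"], res["CA"])
        if i < n - 1:
            nxt = coords[i + 1]
            psi = dihedral(res["N"], res["CA"], res["C"], nxt["N"])
        out.append(TorsionSet(phi=phi, psi=psi, omega=omega))
    return out
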