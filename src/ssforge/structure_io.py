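"""PDB structure input/output and native-disulphide detection.

Parsing is delegated to gemmi (models, altlocs, SSBOND/struct_conn records);
this module maps the parsed structure onto a light residue/atom model that
the rest of the package computes on, and provides a minimal fixed-format
PDB writer so SSBOND emission and coordinate precision stay explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import gemmi
import numpy as np

from .geometry import IDEAL, IdealGeometry, reconstruct_cbeta

__all__ = [
    "AtomRecord",
    "Residue",
    "ProteinStructure",
    "read_structure",
    "native_disulphides",
    "write_model",
    "extract_segment",
    "structure_from_backbone",
    "read_fasta",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: default Sγ-Sγ distance below which two cysteines are called bonded
SG_CUTOFF = 2.5


@dataclass
class AtomRecord:
    """One atom: uppercase label, position (Å), altloc and occupancy."""

    name: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.name = self.name.upper()
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    author_number: int
    insertion_code: str
    seq_index: int          # 0-based index along the chain, insertion-safe
    aa: str                 # one-letter code
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    cb_source: Optional[str] = None   # "observed" | "reconstructed" | None

    def has_backbone(self) -> bool:
        return all(k in self.atoms for k in ("N", "CA", "C"))

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].position

    def get_cbeta(self, geom: IdealGeometry = IDEAL) -> np.ndarray:
        """Observed Cβ, or an ideal reconstruction from N/Cα/C (cached).

        Glycine and missing-Cβ residues are handled identically: any
        residue may be proposed as a cysteine mutation target, so a
        tetrahedral Cβ is rebuilt where none is deposited.
        """
        if "CB" in self.atoms:
            if self.cb_source is None:
                self.cb_source = "observed"
            return self.atoms["CB"].position
        if not self.has_backbone():
            raise ValueError(
                f"residue {self.chain_id}{self.author_number}: "
                "backbone incomplete, cannot reconstruct CB")
        cb = reconstruct_cbeta(self.coord("N"), self.coord("CA"),
                               self.coord("C"), geom)
        self.atoms["CB"] = AtomRecord("CB", cb)
        self.cb_source = "reconstructed"
        return cb

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.author_number}{self.insertion_code}".strip()


PairKey = tuple[str, int]  # (chain_id, seq_index)


@dataclass
class ProteinStructure:
    """Chains of residues plus declared native disulphide pairs.

    ``native_disulphides`` holds ``((chain, seq_index), (chain, seq_index))``
    pairs, each ordered by (chain, seq_index) and joining two cysteines.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    native_disulphides: list[tuple[PairKey, PairKey]] = field(default_factory=list)
    source: str = ""

    def residue(self, chain_id: str, seq_index: int) -> Residue:
        return self.chains[chain_id][seq_index]

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def add_native_pair(self, a: PairKey, b: PairKey) -> None:
        pair = tuple(sorted((a, b)))
        if pair[0] == pair[1]:
            raise ValueError("native disulphide cannot pair a residue with itself")
        if pair not in self.native_disulphides:
            self.native_disulphides.append(pair)  # type: ignore[arg-type]


def _pick_altloc(atoms: list) -> "gemmi.Atom":
    # highest occupancy wins; ties resolved to the lexically first altloc ('A')
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def read_structure(pdb_text: str, model_policy: Union[str, int] = "first") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Parameters
    ----------
    pdb_text:
        PDB-format text with at least one ATOM record.
    model_policy:
        ``"first"`` keeps MODEL 1 of a multi-model (NMR) file; an integer
        selects that 0-based model index.

    Hetero and non-standard residues are skipped with a warning; residues
    missing backbone atoms are kept but flagged (``has_backbone()``).
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no ATOM records found in PDB text")
    idx = 0 if model_policy == "first" else int(model_policy)
    if idx >= len(st):
        raise ValueError(f"model index {idx} out of range ({len(st)} models)")
    model = st[idx]

    out = ProteinStructure(id=st.name or "structure")
    n_atoms = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            one = THREE_TO_ONE.get(res.name.upper())
            if one is None:
                if res.name.upper() not in ("HOH", "WAT"):
                    warnings.warn(
                        f"skipping non-standard residue {res.name} "
                        f"{chain.name}{res.seqid.num}")
                continue
            r = Residue(
                chain_id=chain.name,
                author_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                seq_index=len(residues),
                aa=one,
            )
            by_name: dict[str, list] = {}
            for atom in res:
                by_name.setdefault(atom.name.upper(), []).append(atom)
            for name, alts in by_name.items():
                a = _pick_altloc(alts)
                r.atoms[name] = AtomRecord(
                    name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                    altloc=(a.altloc or "").strip(), occupancy=a.occ)
                n_atoms += 1
            if "CB" in r.atoms:
                r.cb_source = "observed"
            if not r.has_backbone():
                warnings.warn(
                    f"residue {r.chain_id}{r.author_number} missing backbone atoms")
            residues.append(r)
        if residues:
            out.chains[chain.name] = residues
    if n_atoms == 0:
        raise ValueError("no ATOM records found in PDB text")

    by_author: dict[tuple[str, int, str], Residue] = {
        (r.chain_id, r.author_number, r.insertion_code): r
        for r in out.residues()}
    for conn in st.connections:
        if conn.type != gemmi.ConnectionType.Disulf:
            continue
        key1 = (conn.partner1.chain_name, conn.partner1.res_id.seqid.num,
                (conn.partner1.res_id.seqid.icode or "").strip())
        key2 = (conn.partner2.chain_name, conn.partner2.res_id.seqid.num,
                (conn.partner2.res_id.seqid.icode or "").strip())
        r1, r2 = by_author.get(key1), by_author.get(key2)
        if r1 is None or r2 is None or r1.aa != "C" or r2.aa != "C":
            warnings.warn(f"SSBOND names a non-Cys or absent residue: {key1}-{key2}")
            continue
        out.add_native_pair((r1.chain_id, r1.seq_index), (r2.chain_id, r2.seq_index))
    return out


def native_disulphides(structure: ProteinStructure,
                       sg_cutoff: float = SG_CUTOFF) -> list[tuple[Residue, Residue]]:
    """Native disulphide pairs: SSBOND declarations plus geometric detection.

    Returns the deduplicated union of declared SSBOND pairs and Cys pairs
    whose Sγ-Sγ distance is ≤ ``sg_cutoff`` (default 2.5 Å: covalent S-S
    ≈ 2.04 Å plus coordinate-error margin).  Each pair is ordered by
    (chain, seq_index); the result is symmetric in pair order.
    """
    keys: set = set(tuple(sorted(p)) for p in structure.native_disulphides)
    cys = [r for r in structure.residues() if r.aa == "C" and "SG" in r.atoms]
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i].coord("SG") - cys[j].coord("SG")))
            if d <= sg_cutoff:
                keys.add(tuple(sorted(((cys[i].chain_id, cys[i].seq_index),
                                       (cys[j].chain_id, cys[j].seq_index)))))
    out = []
    for a, b in sorted(keys):
        ra, rb = structure.residue(*a), structure.residue(*b)
        if ra.aa == "C" and rb.aa == "C":
            out.append((ra, rb))
    return out


_ATOM_ORDER = ("N", "CA", "C", "O", "CB", "SG")


def _format_atom(serial: int, res: Residue, atom: AtomRecord) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    elem = atom.name[0]
    x, y, z = atom.position
    return (f"ATOM  {serial:5d} {name:<4s}{'':1s}{ONE_TO_THREE[res.aa]:>3s} "
            f"{res.chain_id[:1]:1s}{res.author_number:4d}{res.insertion_code or '':1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {elem:>2s}")


def write_model(structure_or_conformation, include_sg: bool = True) -> str:
    """Serialise a structure (or anything with ``to_structure()``) to PDB text.

    Emits SSBOND records for declared native disulphides, then ATOM records
    with 1-based serials, preserving chain ids and author numbering, one TER
    per chain.  Coordinates at PDB fixed precision (3 decimals).
    """
    obj = structure_or_conformation
    if not isinstance(obj, ProteinStructure):
        obj = obj.to_structure()
    lines: list[str] = []
    for k, (a, b) in enumerate(obj.native_disulphides, start=1):
        ra, rb = obj.residue(*a), obj.residue(*b)
        lines.append(
            f"SSBOND {k:3d} CYS {ra.chain_id[:1]:1s} {ra.author_number:4d}"
            f"{ra.insertion_code or ' ':1s}   CYS {rb.chain_id[:1]:1s} "
            f"{rb.author_number:4d}{rb.insertion_code or ' ':1s}")
    serial = 0
    for chain_id, residues in obj.chains.items():
        for res in residues:
            for name in _ATOM_ORDER:
                if name == "SG" and not include_sg:
                    continue
                if name in res.atoms:
                    serial += 1
                    lines.append(_format_atom(serial, res, res.atoms[name]))
            for name, atom in res.atoms.items():
                if name not in _ATOM_ORDER:
                    serial += 1
                    lines.append(_format_atom(serial, res, atom))
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_segment(structure: ProteinStructure, chain: str,
                    start_index: int, end_index: int) -> ProteinStructure:
    """Contiguous residue slice [start_index, end_index] (0-based, inclusive).

    Native disulphides fully inside the slice are retained; bridges cut in
    half are dropped with a warning.
    """
    import copy

    residues = structure.chains[chain]
    if not (0 <= start_index <= end_index < len(residues)):
        raise IndexError(
            f"segment [{start_index}, {end_index}] out of range for chain "
            f"{chain} of length {len(residues)}")
    seg = ProteinStructure(
        id=f"{structure.id}_{chain}_{start_index}_{end_index}",
        source=structure.source)
    new_res = []
    for k, r in enumerate(residues[start_index:end_index + 1]):
        r2 = copy.deepcopy(r)
        r2.seq_index = k
        new_res.append(r2)
    seg.chains[chain] = new_res

    def inside(key: PairKey) -> bool:
        return key[0] == chain and start_index <= key[1] <= end_index

    for a, b in structure.native_disulphides:
        if inside(a) and inside(b):
            seg.add_native_pair((chain, a[1] - start_index),
                                (chain, b[1] - start_index))
        elif inside(a) or inside(b):
            warnings.warn(
                f"segment [{start_index}, {end_index}] cuts disulphide "
                f"{a}-{b}; bridge dropped")
    return seg


def structure_from_backbone(sequence: str, coords: list[dict[str, np.ndarray]],
                            structure_id: str = "model", chain_id: str = "A",
                            first_author_number: int = 1) -> ProteinStructure:
    """Wrap ``build_backbone`` output as a single-chain ProteinStructure."""
    if len(sequence) != len(coords):
        raise ValueError("sequence/coordinate length mismatch")
    st = ProteinStructure(id=structure_id)
    residues = []
    for i, (aa, res) in enumerate(zip(sequence.upper(), coords)):
        r = Residue(chain_id=chain_id, author_number=first_author_number + i,
                    insertion_code="", seq_index=i, aa=aa)
        for name, pos in res.items():
            r.atoms[name] = AtomRecord(name, np.asarray(pos, dtype=float))
        if "CB" in r.atoms:
            r.cb_source = "observed"
        residues.append(r)
    st.chains[chain_id] = residues
    return st


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text (or a bare one-letter sequence) into (id, seq) pairs."""
    text = text.strip()
    if not text:
        return []
    if not text.startswith(">"):
        return [("seq", "".join(text.split()).upper())]
    entries: list[tuple[str, str]] = []
    header, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks).upper()))
            header = line[1:].split()[0] if line[1:].split() else "seq"
            chunks = []
        else:
            chunks.append(line.strip())
    if header is not None:
        entries.append((header, "".join(chunks).upper()))
    return entries
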