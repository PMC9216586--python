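"""Random allowed-backbone conformation generation under disulphide constraints.

A trial draws one random (φ, ψ) per residue from Ramachandran-allowed
region boxes (glycine, proline and secondary-structure clue residues get
their own boxes; every other residue — including cysteine — is sampled as
alanine), realises the torsions as coordinates, rejects self-colliding
chains, and keeps the conformation only if every requested cysteine pair
can accommodate a disulphide bridge of acceptable grade.  Models are
reported in trial order and never ranked; picking the "best" one is the
user's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import TorsionSet, build_backbone
from .modip import (CandidatePair, DisulphideModel, ModipConfig,
                    fix_sulphurs_frames, grade)
from .structure_io import ProteinStructure, structure_from_backbone

__all__ = [
    "TorsionRegion",
    "SecondaryStructureClue",
    "RanmodConfig",
    "ModelResult",
    "Conformation",
    "RanmodRun",
    "sample_torsions",
    "clash_filter",
    "evaluate_connectivity",
    "run_ranmod",
    "DEFAULT_REGIONS",
]


@dataclass(frozen=True)
class TorsionRegion:
    """One allowed (φ, ψ) box with its sampling weight within a residue class."""

    name: str
    phi_range: tuple[float, float]
    psi_range: tuple[float, float]
    weight: float

    def contains(self, phi: float, psi: float, tol: float = 1e-9) -> bool:
        return (self.phi_range[0] - tol <= phi <= self.phi_range[1] + tol
                and self.psi_range[0] - tol <= psi <= self.psi_range[1] + tol)


# Allowed-region boxes per residue class.  Standard Ramachandran cores;
# weights within each class sum to 1.  All overridable via sample_torsions.
DEFAULT_REGIONS: dict[str, tuple[TorsionRegion, ...]] = {
    "general": (
        TorsionRegion("alphaR", (-90.0, -40.0), (-70.0, -20.0), 0.5),
        TorsionRegion("beta", (-160.0, -80.0), (100.0, 170.0), 0.5),
    ),
    "gly": (
        TorsionRegion("alphaR", (-90.0, -40.0), (-70.0, -20.0), 0.3),
        TorsionRegion("beta", (-160.0, -80.0), (100.0, 170.0), 0.3),
        TorsionRegion("alphaL", (40.0, 90.0), (20.0, 70.0), 0.2),
        TorsionRegion("gly-extra", (80.0, 160.0), (-170.0, -100.0), 0.2),
    ),
    "pro": (
        TorsionRegion("pro-alphaR", (-78.0, -48.0), (-55.0, -15.0), 0.4),
        TorsionRegion("pro-ppII", (-78.0, -48.0), (130.0, 170.0), 0.6),
    ),
    "helix-clue": (
        TorsionRegion("helix-clue", (-67.0, -47.0), (-57.0, -37.0), 1.0),
    ),
    "strand-clue": (
        TorsionRegion("strand-clue", (-140.0, -100.0), (110.0, 150.0), 1.0),
    ),
}


@dataclass(frozen=True)
class SecondaryStructureClue:
    """Residue range (1-based, inclusive) constrained to helix or strand boxes."""

    start: int
    end: int
    kind: str  # "helix" | "strand"

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"unknown clue kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid clue range {self.start}-{self.end}")


@dataclass(frozen=True)
class RanmodConfig:
    n_trials: int = 200_000
    seed: int = 0
    accept_grades: frozenset = frozenset({"A", "B", "C"})
    clash_min_ca: float = 3.5
    max_models: int = 10
    modip: ModipConfig = field(default_factory=ModipConfig)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if "D" in self.accept_grades:
            raise ValueError("grade D (sulphur unfixable) cannot be accepted")


@dataclass
class Conformation:
    sequence: str
    torsions: list[TorsionSet]
    regions: list[str]                 # region each residue was drawn from
    coords: list[dict[str, np.ndarray]]
    seed: int = 0
    trial_index: int = 0

    def to_structure(self, structure_id: Optional[str] = None) -> ProteinStructure:
        return structure_from_backbone(
            self.sequence, self.coords,
            structure_id or f"ranmod_trial{self.trial_index}")


@dataclass
class ModelResult:
    conformation: Conformation
    bridge_models: list[DisulphideModel]
    trial_index: int
    seed: int


@dataclass
class RanmodRun:
    models: list[ModelResult]
    summary: dict


def _residue_classes(sequence: str,
                     clues: Sequence[SecondaryStructureClue]) -> list[str]:
    classes = []
    for aa in sequence.upper():
        if aa == "G":
            classes.append("gly")
        elif aa == "P":
            classes.append("pro")
        else:
            classes.append("general")   # Cys and all others sampled as Ala
    for clue in clues:
        if clue.end > len(sequence):
            raise ValueError(
                f"clue {clue.start}-{clue.end} outside sequence of "
                f"length {len(sequence)}")
        for pos in range(clue.start - 1, clue.end):
            classes[pos] = f"{clue.kind}-clue"
    return classes


def sample_torsions(sequence: str,
                    clues: Sequence[SecondaryStructureClue] = (),
                    rng: Optional[np.random.Generator] = None,
                    regions: Optional[dict] = None,
                    ) -> tuple[list[TorsionSet], list[str]]:
    """Draw one random allowed (φ, ψ) per residue; ω fixed trans (180°).

    Region choice per residue: clue box if the residue is covered by a
    clue, otherwise a box of its residue class chosen by weight, then a
    uniform draw within the box.  Returns the torsions and the name of the
    region each was drawn from.  Exactly three RNG draws per residue, so a
    seeded generator reproduces the sequence of trials bit-identically.
    """
    if not sequence:
        raise ValueError("empty sequence")
    rng = rng or np.random.default_rng()
    regions = regions or DEFAULT_REGIONS
    classes = _residue_classes(sequence, clues)
    u = rng.random((len(sequence), 3))
    torsions: list[TorsionSet] = []
    names: list[str] = []
    for i, cls in enumerate(classes):
        boxes = regions[cls]
        cum, pick = 0.0, boxes[-1]
        for box in boxes:
            cum += box.weight
            if u[i, 0] < cum:
                pick = box
                break
        phi = pick.phi_range[0] + u[i, 1] * (pick.phi_range[1] - pick.phi_range[0])
        psi = pick.psi_range[0] + u[i, 2] * (pick.psi_range[1] - pick.psi_range[0])
        torsions.append(TorsionSet(phi=phi, psi=psi, omega=180.0))
        names.append(pick.name)
    return torsions, names


def clash_filter(coords: Sequence[dict], clash_min_ca: float = 3.5) -> bool:
    """True iff no Cα pair separated by ≥3 in sequence is closer than the cutoff."""
    if clash_min_ca <= 0:
        return True
    ca = np.array([c["CA"] for c in coords])
    n = len(ca)
    if n < 4:
        return True
    d = cdist(ca, ca)
    mask = np.triu(np.ones((n, n), dtype=bool), k=3)
    return bool(d[mask].min() >= clash_min_ca)


def _check_pairing(sequence: str, pairing: Sequence[tuple[int, int]]) -> None:
    seq = sequence.upper()
    if pairing and "C" not in seq:
        raise ValueError("pairing given but sequence contains no cysteine")
    for i, j in pairing:
        if not i < j:
            raise ValueError(f"pair ({i},{j}) must have i < j")
        for pos in (i, j):
            if not 1 <= pos <= len(seq):
                raise ValueError(f"pair position {pos} outside sequence")
            if seq[pos - 1] != "C":
                raise ValueError(
                    f"position {pos} is {seq[pos - 1]}, not cysteine")


def _grade_pairing(coords: Sequence[dict], pairing: Sequence[tuple[int, int]],
                   modip_cfg: ModipConfig):
    """Distance-check then grade every queried pair on raw coordinates.

    Returns (params_or_None per pair, grades per pair); a ``None`` entry
    means the Cα/Cβ cutoffs already ruled the pair out.
    """
    out_params, grades = [], []
    for i, j in pairing:
        ri, rj = coords[i - 1], coords[j - 1]
        d_ca = float(np.linalg.norm(ri["CA"] - rj["CA"]))
        d_cb = float(np.linalg.norm(ri["CB"] - rj["CB"]))
        if d_ca > modip_cfg.ca_max or d_cb > modip_cfg.cb_max:
            out_params.append(None)
            grades.append(None)
            continue
        params = fix_sulphurs_frames(ri["N"], ri["CA"], ri["CB"],
                                     rj["N"], rj["CA"], rj["CB"], modip_cfg)
        params["d_ca"], params["d_cb"] = d_ca, d_cb
        probe = DisulphideModel(pair=None, **{k: v for k, v in params.items()
                                              if k not in ("d_ca", "d_cb")})
        g = grade(probe, modip_cfg)
        out_params.append(params)
        grades.append(g)
    return out_params, grades


def evaluate_connectivity(conformation: Conformation,
                          pairing: Sequence[tuple[int, int]],
                          config: RanmodConfig = RanmodConfig(),
                          ) -> list[Optional[DisulphideModel]]:
    """Grade every queried cysteine pair on a built conformation.

    Positions are 1-based and must be cysteines in the sequence.  Each
    returned entry is a graded :class:`DisulphideModel`, or ``None`` when
    the pair already fails the Cα/Cβ distance cutoffs (not gradeable).
    The conformation passes iff no entry is ``None`` and every grade is in
    ``config.accept_grades``; an empty pairing passes vacuously.
    """
    _check_pairing(conformation.sequence, pairing)
    params_list, grades = _grade_pairing(conformation.coords, pairing,
                                         config.modip)
    st = conformation.to_structure()
    out: list[Optional[DisulphideModel]] = []
    for (i, j), params, g in zip(pairing, params_list, grades):
        if params is None:
            out.append(None)
            continue
        chain = next(iter(st.chains))
        pair = CandidatePair(st.residue(chain, i - 1), st.residue(chain, j - 1),
                             params.pop("d_ca"), params.pop("d_cb"))
        model = DisulphideModel(pair=pair, grade=g, **params)
        out.append(model)
    return out


def connectivity_passes(models: Sequence[Optional[DisulphideModel]],
                        accept_grades=frozenset({"A", "B", "C"})) -> bool:
    return all(m is not None and m.grade in accept_grades for m in models)


def run_ranmod(sequence: str,
               pairing: Sequence[tuple[int, int]],
               clues: Sequence[SecondaryStructureClue] = (),
               config: RanmodConfig = RanmodConfig()) -> RanmodRun:
    """Sample ``config.n_trials`` random conformations and keep the valid ones.

    Pipeline per trial: draw torsions → build backbone → Cα clash filter →
    per-pair distance check, sulphur fixation and grading.  A trial is
    accepted when every queried pair is graded within ``accept_grades``.
    Up to ``max_models`` accepted conformations are retained, in trial
    order (no ranking).  One global RNG stream seeded from ``config.seed``
    is consumed in trial order, so the run is bit-reproducible and the
    accepted count is non-decreasing in ``n_trials``.
    """
    sequence = sequence.upper()
    _check_pairing(sequence, pairing)
    classes = _residue_classes(sequence, clues)  # validates clue ranges
    del classes
    rng = np.random.default_rng(config.seed)
    modip_cfg = config.modip
    n_pass = 0
    rejected = {"clash": 0, "distance": 0, "grade": 0}
    models: list[ModelResult] = []
    for trial in range(config.n_trials):
        torsions, names = sample_torsions(sequence, clues, rng)
        coords = build_backbone(sequence, torsions)
        if not clash_filter(coords, config.clash_min_ca):
            rejected["clash"] += 1
            continue
        params_list, grades = _grade_pairing(coords, pairing, modip_cfg)
        if any(p is None for p in params_list):
            rejected["distance"] += 1
            continue
        if not all(g in config.accept_grades for g in grades):
            rejected["grade"] += 1
            continue
        n_pass += 1
        if len(models) < config.max_models:
            conf = Conformation(sequence, torsions, names, coords,
                                seed=config.seed, trial_index=trial)
            bridge_models = evaluate_connectivity(conf, pairing, config)
            models.append(ModelResult(conf, bridge_models, trial, config.seed))
    summary = {
        "sequence": sequence,
        "pairing": [list(p) for p in pairing],
        "clues": [[c.start, c.end, c.kind] for c in clues],
        "seed": config.seed,
        "n_trials": config.n_trials,
        "accept_grades": sorted(config.accept_grades),
        "clash_min_ca": config.clash_min_ca,
        "n_pass": n_pass,
        "n_models_kept": len(models),
        "rejected": rejected,
    }
    return RanmodRun(models=models, summary=summary)
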