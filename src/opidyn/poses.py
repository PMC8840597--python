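"""Docking-pose rescoring against a reference interaction fingerprint.

Externally generated poses (single-frame systems) are evaluated against the
interaction pattern of a reference agonist–receptor complex: each fingerprint
entry (PI, HY, HBA/HBD, or a water bridge) either matches or not, and the
pose score is the unweighted count of matched entries.  A hard distance
constraint between the morphinan amine nitrogen and the side-chain
carboxylate carbon (γC) of D3.32 — 5.5 Å by default — filters out poses that
cannot form the canonical opioid salt bridge.  Ranking is by descending
score, ties broken by ascending constraint distance (the closer amine–D3.32
contact wins), then by pose id for stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynophore import InteractionDefinition
from .errors import ConfigurationError
from .interactions import GeometricCriteria
from .structure import MolecularSystem

DEFAULT_MAX_CONSTRAINT = 5.5  # Å, amine N — D3.32 γC

#: default ligand selection per fingerprint entry type
_DEFAULT_LIGAND_SIDE = {
    "PI": "ligand:morphinan_amine",
    "HY": "ligand:scaffold",
    "HBA": "ligand:phenol",
    "HBD": "ligand:phenol",
    "WATER_MEDIATED": "ligand:phenol",
}

_KIND_FOR_ITYPE = {
    "PI": "ionic",
    "HY": "hydrophobic",
    "HBA": "hbond",
    "HBD": "hbond",
    "WATER_MEDIATED": "water_mediated",
}


@dataclass(frozen=True)
class FingerprintEntry:
    """One expected interaction: type, receptor partner, optional ligand side."""

    itype: str                       # PI | HY | HBA | HBD | WATER_MEDIATED
    partner: str                     # selection spec, e.g. "res:149", "sidechain:153"
    ligand: str | None = None        # selection spec; None -> default for itype

    def definition(self, key: str) -> InteractionDefinition:
        if self.itype not in _KIND_FOR_ITYPE:
            raise ConfigurationError(f"unknown fingerprint entry type {self.itype!r}")
        ligand = self.ligand or _DEFAULT_LIGAND_SIDE[self.itype]
        return InteractionDefinition(key=key, kind=_KIND_FOR_ITYPE[self.itype],
                                     a=ligand, b=self.partner)


@dataclass
class ReferenceFingerprint:
    """Expected interaction pattern of the reference complex for one receptor."""

    receptor_id: str
    entries: list[FingerprintEntry]
    d332_res: int                    # author number of D3.32
    amine_atom: str = "N1"           # ligand amine nitrogen atom name

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference fingerprint must be non-empty")


@dataclass
class PoseEvaluation:
    """Match result for one pose against the reference fingerprint."""

    pose_id: str
    score: int
    constraint_distance: float
    constraint_pass: bool
    matched_entries: list[str] = field(default_factory=list)
    rank: int | None = None


def constraint_distance(pose: MolecularSystem, reference: ReferenceFingerprint) -> float:
    """Amine N ↔ D3.32 γC distance (Å) in a single-frame pose."""
    lig = pose.atoms[(pose.atoms.role == "ligand")
                     & (pose.atoms.name == reference.amine_atom)]
    if lig.empty:
        raise ConfigurationError(
            f"ligand amine atom {reference.amine_atom!r} not found"
        )
    try:
        cg = pose.residue_atoms(reference.d332_res, names=("CG",))
    except Exception as exc:
        raise ConfigurationError(
            f"D3.32 residue {reference.d332_res} unresolvable: {exc}"
        ) from exc
    frame = pose.frame(0)
    return float(np.linalg.norm(frame[lig.index[0]] - frame[cg[0]]))


def evaluate_pose(
    pose: MolecularSystem,
    reference: ReferenceFingerprint,
    criteria: GeometricCriteria,
    max_constraint: float = DEFAULT_MAX_CONSTRAINT,
    pose_id: str = "pose",
) -> PoseEvaluation:
    """Score one pose: count matched fingerprint entries, measure the constraint."""
    matched = []
    for entry in reference.entries:
        definition = entry.definition(key=f"{entry.itype}:{entry.partner}")
        if definition.detect(pose, 0, criteria) is not None:
            matched.append(definition.key)
    d = constraint_distance(pose, reference)
    return PoseEvaluation(
        pose_id=pose_id,
        score=len(matched),
        constraint_distance=d,
        constraint_pass=d <= max_constraint,
        matched_entries=matched,
    )


def filter_constraint(
    evaluations: list[PoseEvaluation],
    max_constraint: float = DEFAULT_MAX_CONSTRAINT,
) -> list[PoseEvaluation]:
    """Keep poses whose amine–D3.32 distance is within the constraint (inclusive)."""
    return [e for e in evaluations if e.constraint_distance <= max_constraint]


def rank_poses(evaluations: list[PoseEvaluation]) -> list[PoseEvaluation]:
    """Order by descending score; ties by ascending constraint distance, then id."""
    if not evaluations:
        raise ValueError("cannot rank an empty evaluation list")
    ordered = sorted(
        evaluations,
        key=lambda e: (-e.score, e.constraint_distance, e.pose_id),
    )
    for i, e in enumerate(ordered):
        e.rank = i + 1
    return ordered
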