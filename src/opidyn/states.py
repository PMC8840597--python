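"""TM6-deflection activation-state analysis.

Receptor activation in class-A GPCRs is accompanied by an outward movement
of the intracellular end of TM6.  As a surrogate for that movement we
measure the distance between the Cα atoms of residue 6.31 (bottom of TM6)
and residue 4.40 (bottom of TM4).  Framed against the analogous distances
measured in active- and inactive-state crystal structures (user-supplied;
the package never downloads them), each trajectory frame is classified as

* ``active_like``   — deflection ≥ active reference − tolerance,
* ``inactive_like`` — deflection ≤ inactive reference + tolerance,
* ``intermediate``  — strictly between.

A persistent TM5–TM6 salt bridge (K5.39–E6.58) tethers TM6 and biases the
receptor toward sub-active deflection; its occupancy is reported with the
same frame-counting rule as the dynophore statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dynophore import InteractionDefinition, pair_occupancy
from .errors import TopologyError
from .interactions import GeometricCriteria
from .structure import MolecularSystem

logger = logging.getLogger(__name__)

LABELS = ("active_like", "intermediate", "inactive_like")


@dataclass
class StateReference:
    """Crystal-anchored deflection references for one receptor."""

    receptor_id: str
    residue_631: int            # author number of the 6.31 anchor
    residue_440: int            # author number of the 4.40 anchor
    active_ref_dist: float      # Å, active-state crystal deflection
    inactive_ref_dist: float    # Å, inactive-state crystal deflection
    tolerance: float = 0.0      # Å band added to each reference
    measure_atom: str = "CA"    # "CA" (default) or "C" for the carbonyl carbon

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.active_ref_dist == self.inactive_ref_dist:
            raise ValueError("active and inactive references must differ")
        if self.residue_631 == self.residue_440:
            raise ValueError("the two anchors must be distinct residues")
        if self.active_ref_dist < self.inactive_ref_dist:
            logger.warning(
                "active reference (%.2f) below inactive reference (%.2f); "
                "swapping — outward TM6 movement increases the deflection",
                self.active_ref_dist, self.inactive_ref_dist,
            )
            self.active_ref_dist, self.inactive_ref_dist = (
                self.inactive_ref_dist, self.active_ref_dist)


@dataclass
class StateProfile:
    """Per-frame state labels and their pooled fractions (%)."""

    labels: list[str]
    fractions: dict[str, float]

    @property
    def n_frames(self) -> int:
        return len(self.labels)


def tm6_deflection(system: MolecularSystem, frame_index: int,
                   reference: StateReference) -> float:
    """Cα(6.31)–Cα(4.40) distance (Å) in one frame.

    With ``measure_atom="C"`` the backbone carbonyl carbons are used instead.
    """
    name = reference.measure_atom
    try:
        i631 = system.residue_atoms(reference.residue_631, names=(name,))
        i440 = system.residue_atoms(reference.residue_440, names=(name,))
    except TopologyError as exc:
        raise TopologyError(f"deflection anchors missing atom {name}: {exc}") from exc
    frame = system.frame(frame_index)
    return float(np.linalg.norm(frame[i631[0]] - frame[i440[0]]))


def classify_frame(deflection: float, reference: StateReference) -> str:
    """Label one deflection value against the crystal references."""
    if not math.isfinite(deflection):
        raise ValueError("deflection must be finite")
    if deflection >= reference.active_ref_dist - reference.tolerance:
        return "active_like"
    if deflection <= reference.inactive_ref_dist + reference.tolerance:
        return "inactive_like"
    return "intermediate"


def state_fractions(replicate_systems: list[MolecularSystem],
                    reference: StateReference) -> StateProfile:
    """Classify every frame of every replicate (pooled) and report fractions."""
    if not replicate_systems:
        raise ValueError("need at least one replicate")
    labels: list[str] = []
    for system in replicate_systems:
        for f in range(system.n_frames):
            labels.append(classify_frame(tm6_deflection(system, f, reference),
                                         reference))
    n = len(labels)
    fractions = {lab: 100.0 * labels.count(lab) / n for lab in LABELS}
    return StateProfile(labels=labels, fractions=fractions)


def deflection_series(system: MolecularSystem,
                      reference: StateReference) -> np.ndarray:
    """Per-frame deflection values for one trajectory."""
    return np.array([tm6_deflection(system, f, reference)
                     for f in range(system.n_frames)])


def tm5_tm6_bridge_occupancy(
    system: MolecularSystem,
    k539_res: int,
    e658_res: int,
    criteria: GeometricCriteria,
) -> float:
    """Occupancy (%) of the K5.39–E6.58 ionic bridge over one trajectory."""
    definition = InteractionDefinition(
        key="tm5_tm6_bridge", kind="ionic",
        a=f"res:{k539_res}", b=f"res:{e658_res}",
    )
    return pair_occupancy(system, definition, criteria)
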