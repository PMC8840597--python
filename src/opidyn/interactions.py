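"""Per-frame geometric interaction detectors.

Each detector takes one coordinate frame (``(n_atoms, 3)`` in Å), index
arrays for the partner groups, and a :class:`GeometricCriteria`, and returns
an :class:`InteractionEvent` when the geometry satisfies the criterion
(``None`` otherwise).  All distance boundaries are inclusive.

The criteria are explicit, configurable stand-ins for pharmacophore-toolkit
conventions: ionic contacts by minimum heavy-atom distance between the
charged groups; hydrogen bonds by donor–acceptor heavy-atom distance plus an
angle (measured at the donor hydrogen when present, or at the donor heavy
atom against its bonded root as a surrogate — trajectories often lack
hydrogens); hydrophobic contacts by minimum apolar–apolar (C/S) distance;
cation–π by cation–ring-centroid distance and offset from the ring normal;
clashes by van der Waals overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


class InteractionType(str, Enum):
    PI = "PI"                           # positive ionizable
    NI = "NI"                           # negative ionizable
    HBD = "HBD"                         # hydrogen-bond donor (ligand side)
    HBA = "HBA"                         # hydrogen-bond acceptor (ligand side)
    HY = "HY"                           # hydrophobic
    CATPI = "CATPI"                     # cation–π
    WATER_MEDIATED = "WATER_MEDIATED"   # single-water bridge
    CLASH = "CLASH"                     # steric overlap


#: Bondi-style van der Waals radii, Å
DEFAULT_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75,
}


@dataclass
class GeometricCriteria:
    """Distance/angle cutoffs for every detector; all in Å and degrees."""

    ionic_max_dist: float = 4.5
    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 130.0
    hydrophobic_max_dist: float = 4.5
    cationpi_max_dist: float = 6.0
    cationpi_max_offset_angle: float = 30.0
    clash_overlap: float = 0.4
    ring_planarity_tol: float = 0.3
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def __post_init__(self) -> None:
        for name in ("ionic_max_dist", "hbond_max_dist", "hydrophobic_max_dist",
                     "cationpi_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hbond_min_angle", "cationpi_max_offset_angle"):
            v = getattr(self, name)
            if not 0 < v <= 180:
                raise ValueError(f"{name} must lie in (0, 180]")
        if self.clash_overlap < 0:
            raise ValueError("clash_overlap must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "GeometricCriteria":
        return cls(**d)


@dataclass(frozen=True)
class InteractionEvent:
    """One detected contact in one frame."""

    frame_index: int
    itype: InteractionType
    ligand_group: str
    partner: str
    distance: float
    angle: float | None = None
    water_id: int | None = None

    def as_row(self) -> dict:
        return dict(frame=self.frame_index, itype=self.itype.value,
                    ligand_group=self.ligand_group, partner=self.partner,
                    distance=self.distance, angle=self.angle,
                    water_id=self.water_id)


def _check_group(idx: np.ndarray, what: str) -> np.ndarray:
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValueError(f"{what} group is empty")
    return idx


def min_distance(frame: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """Minimum pairwise distance between two atom-index groups."""
    return float(cdist(frame[idx_a], frame[idx_b]).min())


def _angle_deg(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - apex, b - apex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_ionic(
    frame: np.ndarray,
    cation_idx: np.ndarray,
    anion_idx: np.ndarray,
    criteria: GeometricCriteria,
    frame_index: int = 0,
    ligand_group: str = "",
    partner: str = "",
    itype: InteractionType = InteractionType.PI,
) -> InteractionEvent | None:
    """Salt bridge: minimum heavy-atom distance between the charged groups."""
    cation_idx = _check_group(cation_idx, "cation")
    anion_idx = _check_group(anion_idx, "anion")
    d = min_distance(frame, cation_idx, anion_idx)
    if d <= criteria.ionic_max_dist:
        return InteractionEvent(frame_index, itype, ligand_group, partner, d)
    return None


def detect_hbond(
    frame: np.ndarray,
    donor_idx: np.ndarray,
    acceptor_idx: np.ndarray,
    criteria: GeometricCriteria,
    donor_root_idx: np.ndarray | None = None,
    hydrogen_idx: np.ndarray | None = None,
    strict: bool = False,
    frame_index: int = 0,
    ligand_group: str = "",
    partner: str = "",
    itype: InteractionType = InteractionType.HBD,
) -> InteractionEvent | None:
    """Hydrogen bond between donor and acceptor heavy-atom groups.

    The closest donor/acceptor heavy-atom pair must lie within
    ``hbond_max_dist``.  The angle criterion uses, in order of preference:
    the best D–H–A angle over ``hydrogen_idx``; the root–D–A surrogate angle
    over ``donor_root_idx``; or no angle at all (distance-only) when neither
    is supplied.  ``strict=True`` demands explicit hydrogens.
    """
    donor_idx = _check_group(donor_idx, "donor")
    acceptor_idx = _check_group(acceptor_idx, "acceptor")
    if strict and hydrogen_idx is None:
        raise ValueError("strict hydrogen-bond mode requires hydrogen_idx")
    dm = cdist(frame[donor_idx], frame[acceptor_idx])
    i, j = np.unravel_index(np.argmin(dm), dm.shape)
    d = float(dm[i, j])
    if d > criteria.hbond_max_dist:
        return None
    donor_pos, acceptor_pos = frame[donor_idx[i]], frame[acceptor_idx[j]]
    angle: float | None = None
    if hydrogen_idx is not None and len(hydrogen_idx) > 0:
        angle = max(_angle_deg(donor_pos, frame[h], acceptor_pos)
                    for h in np.asarray(hydrogen_idx, dtype=int))
    elif donor_root_idx is not None and len(donor_root_idx) > 0:
        angle = max(_angle_deg(frame[r], donor_pos, acceptor_pos)
                    for r in np.asarray(donor_root_idx, dtype=int))
    if angle is not None and angle < criteria.hbond_min_angle:
        return None
    return InteractionEvent(frame_index, itype, ligand_group, partner, d, angle=angle)


def detect_water_mediated(
    frame: np.ndarray,
    ligand_idx: np.ndarray,
    receptor_idx: np.ndarray,
    waters: dict[int, np.ndarray],
    criteria: GeometricCriteria,
    frame_index: int = 0,
    ligand_group: str = "",
    partner: str = "",
) -> InteractionEvent | None:
    """Single-water bridge: the SAME water hydrogen-bonds both partners.

    Both legs use the distance-only hydrogen-bond criterion (water hydrogens
    are rarely resolved).  The event records the bridging water id and the
    longer of the two leg distances.
    """
    ligand_idx = _check_group(ligand_idx, "ligand")
    receptor_idx = _check_group(receptor_idx, "receptor")
    best: tuple[float, int] | None = None
    for water_id, w_idx in waters.items():
        if len(w_idx) == 0:
            continue
        d_lig = min_distance(frame, ligand_idx, w_idx)
        d_rec = min_distance(frame, receptor_idx, w_idx)
        worst_leg = max(d_lig, d_rec)
        if worst_leg <= criteria.hbond_max_dist:
            if best is None or worst_leg < best[0]:
                best = (worst_leg, water_id)
    if best is None:
        return None
    return InteractionEvent(frame_index, InteractionType.WATER_MEDIATED,
                            ligand_group, partner, best[0], water_id=best[1])


APOLAR_ELEMENTS = {"C", "S"}


def detect_hydrophobic(
    frame: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    criteria: GeometricCriteria,
    elements: np.ndarray | None = None,
    frame_index: int = 0,
    ligand_group: str = "",
    partner: str = "",
) -> InteractionEvent | None:
    """Hydrophobic contact between the apolar (C/S) atoms of two groups.

    When ``elements`` (per-atom element symbols for the whole frame) is
    given, polar atoms are filtered out first; a side left with no apolar
    atom yields no event and a logged warning.
    """
    idx_a = _check_group(idx_a, "group_a")
    idx_b = _check_group(idx_b, "group_b")
    if elements is not None:
        elements = np.asarray(elements)
        idx_a = idx_a[np.isin(elements[idx_a], list(APOLAR_ELEMENTS))]
        idx_b = idx_b[np.isin(elements[idx_b], list(APOLAR_ELEMENTS))]
        if idx_a.size == 0 or idx_b.size == 0:
            logger.warning("hydrophobic detector: a group has no apolar atoms")
            return None
    d = min_distance(frame, idx_a, idx_b)
    if d <= criteria.hydrophobic_max_dist:
        return InteractionEvent(frame_index, InteractionType.HY,
                                ligand_group, partner, d)
    return None


def ring_geometry(frame: np.ndarray, ring_idx: np.ndarray,
                  planarity_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring; rejects non-planar atom sets."""
    ring_idx = np.asarray(ring_idx, dtype=int)
    if ring_idx.size < 5:
        raise ValueError("a ring needs at least 5 atoms")
    pts = frame[ring_idx]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # smallest singular vector = plane normal; smallest singular value / sqrt(n)
    # = RMS out-of-plane deviation
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rms_dev = s[-1] / np.sqrt(len(pts))
    if rms_dev > planarity_tol:
        raise ValueError(
            f"ring atoms deviate from a plane (RMS {rms_dev:.2f} Å "
            f"> tolerance {planarity_tol} Å)"
        )
    return centroid, vt[-1]


def detect_cation_pi(
    frame: np.ndarray,
    cation_idx: np.ndarray,
    ring_idx: np.ndarray,
    criteria: GeometricCriteria,
    frame_index: int = 0,
    ligand_group: str = "",
    partner: str = "",
) -> InteractionEvent | None:
    """Cation–π: cation within distance of the ring centroid and near its normal."""
    cation_idx = _check_group(cation_idx, "cation")
    centroid, normal = ring_geometry(frame, ring_idx, criteria.ring_planarity_tol)
    best: tuple[float, float] | None = None
    for c in cation_idx:
        v = frame[c] - centroid
        d = float(np.linalg.norm(v))
        if d == 0.0:
            continue
        cosang = abs(np.dot(v / d, normal))
        offset = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if d <= criteria.cationpi_max_dist and offset <= criteria.cationpi_max_offset_angle:
            if best is None or d < best[0]:
                best = (d, offset)
    if best is None:
        return None
    return InteractionEvent(frame_index, InteractionType.CATPI,
                            ligand_group, partner, best[0], angle=best[1])


def detect_clash(
    frame: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    elements: np.ndarray,
    criteria: GeometricCriteria,
    frame_index: int = 0,
    ligand_group: str = "",
    partner: str = "",
) -> list[InteractionEvent]:
    """All atom pairs whose van der Waals overlap reaches ``clash_overlap``."""
    idx_a = _check_group(idx_a, "group_a")
    idx_b = _check_group(idx_b, "group_b")
    elements = np.asarray(elements)
    try:
        ra = np.array([criteria.vdw_radii[str(e).upper()] for e in elements[idx_a]])
        rb = np.array([criteria.vdw_radii[str(e).upper()] for e in elements[idx_b]])
    except KeyError as exc:
        raise ConfigurationError(f"no van der Waals radius for element {exc}") from exc
    dm = cdist(frame[idx_a], frame[idx_b])
    overlap = ra[:, None] + rb[None, :] - dm
    events = []
    for i, j in zip(*np.nonzero(overlap >= criteria.clash_overlap)):
        events.append(
            InteractionEvent(frame_index, InteractionType.CLASH, ligand_group,
                             partner, float(dm[i, j]))
        )
    return events
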