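"""Topology model for a 7TM receptor–ligand system.

A :class:`MolecularSystem` couples a flat atom table (names, elements,
residue assignment, protein/ligand/water role) with a stack of coordinate
frames in Å.  Residues are identified by author numbering, exactly as read
from the PDB file; Ballesteros–Weinstein (BW) labels are assigned on top of
that via an :class:`AnchorTable` holding the x.50 anchor residue and the
helix boundaries for each of the seven transmembrane helices.

The BW convention: within helix ``t`` whose most conserved residue (the
anchor) is author residue ``a``, residue ``r`` receives position
``50 - (a - r)``, i.e. a constant offset.  Residues outside every helix
range receive a region tag (N-term, ECL1..3, ICL1..3, C-term) from the
anchor table's region list, or ``"unassigned"`` with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TopologyError

logger = logging.getLogger(__name__)

#: side-chain atoms carrying the formal charge, per residue type
CHARGED_SIDECHAIN_ATOMS = {
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE", "CZ"),
    "HIS": ("ND1", "NE2"),
}

REGION_TAGS = frozenset(
    {"N-term", "ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3", "C-term"}
)


@dataclass(frozen=True)
class ResidueRef:
    """One receptor residue in author numbering, optionally BW-labelled."""

    chain_id: str
    res_number: int
    res_name: str
    bw_label: str | None = None

    def __post_init__(self) -> None:
        if self.bw_label is not None and self.bw_label not in REGION_TAGS \
                and self.bw_label != "unassigned":
            tm, _, pos = self.bw_label.partition(".")
            if not (tm.isdigit() and pos.isdigit()
                    and 1 <= int(tm) <= 7 and 1 <= int(pos) <= 99):
                raise ValueError(f"malformed BW label {self.bw_label!r}")

    def __str__(self) -> str:  # e.g. K227^5.39
        sup = f"^{self.bw_label}" if self.bw_label else ""
        return f"{self.res_name}{self.res_number}{sup}"


@dataclass
class AnchorTable:
    """x.50 anchors, TM boundary ranges and loop regions for one receptor.

    ``anchors`` maps helix index (1..7) to the author residue number of the
    x.50 residue; ``tm_ranges`` maps helix index to the inclusive
    (first, last) author-number span of that helix; ``regions`` is a list of
    ``(first, last, tag)`` spans for everything outside the helices.
    """

    receptor_id: str
    anchors: dict[int, int]
    tm_ranges: dict[int, tuple[int, int]]
    regions: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sorted(self.anchors) != list(range(1, 8)):
            raise ValueError("anchor table must define exactly helices 1..7")
        if sorted(self.tm_ranges) != list(range(1, 8)):
            raise ValueError("anchor table must define ranges for helices 1..7")
        prev_end = -(10 ** 9)
        for tm in range(1, 8):
            lo, hi = self.tm_ranges[tm]
            if lo > hi:
                raise ValueError(f"TM{tm} range ({lo},{hi}) is inverted")
            if lo <= prev_end:
                raise ValueError("TM ranges must be ordered and non-overlapping")
            prev_end = hi
            a = self.anchors[tm]
            if not lo <= a <= hi:
                raise ValueError(f"anchor {a} for TM{tm} lies outside ({lo},{hi})")

    def bw_for(self, res_number: int) -> str | None:
        """BW label or region tag for an author residue number, or None."""
        for tm in range(1, 8):
            lo, hi = self.tm_ranges[tm]
            if lo <= res_number <= hi:
                pos = 50 - (self.anchors[tm] - res_number)
                if not 1 <= pos <= 99:
                    raise ValueError(
                        f"residue {res_number} maps outside BW positions 1..99"
                    )
                return f"{tm}.{pos}"
        for lo, hi, tag in self.regions:
            if lo <= res_number <= hi:
                return tag
        return None

    def res_number_for(self, bw_label: str) -> int:
        """Inverse lookup: author residue number of a TM BW label."""
        tm_s, _, pos_s = bw_label.partition(".")
        tm, pos = int(tm_s), int(pos_s)
        r = self.anchors[tm] - (50 - pos)
        lo, hi = self.tm_ranges[tm]
        if not lo <= r <= hi:
            raise ValueError(f"BW label {bw_label} falls outside TM{tm} range")
        return r


class MolecularSystem:
    """Atom table + per-frame coordinates for one receptor–ligand system.

    Parameters
    ----------
    atoms : pandas.DataFrame
        Columns ``name, element, chain_id, res_number, res_name, role``
        with ``role`` one of ``protein | ligand | water``.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    ligand_groups : mapping of feature-group name -> atom-name list
        Resolved against the ligand atoms; the four canonical groups for a
        zwitterionic morphinan ligand are ``morphinan_amine``,
        ``secondary_amine``, ``carboxylate`` and ``phenol``.
    frame_interval_ps : float
        Recording interval between frames, picoseconds.
    """

    REQUIRED_GROUPS = ("morphinan_amine", "secondary_amine", "carboxylate", "phenol")

    def __init__(
        self,
        atoms: pd.DataFrame,
        coords: np.ndarray,
        ligand_groups: dict[str, list[str]],
        frame_interval_ps: float = 100.0,
        bw_map: dict[int, str] | None = None,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != len(atoms):
            raise ValueError(
                f"coordinate frames carry {coords.shape[1]} atoms, "
                f"topology has {len(atoms)}"
            )
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        if frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be > 0")
        self.atoms = atoms.reset_index(drop=True)
        self.coords = coords
        self.frame_interval_ps = float(frame_interval_ps)
        self.bw_map = dict(bw_map or {})
        missing = [g for g in self.REQUIRED_GROUPS if g not in ligand_groups]
        if missing:
            raise ConfigurationError(
                f"ligand_spec must define the canonical feature groups; "
                f"missing: {missing}"
            )
        self.ligand_groups: dict[str, np.ndarray] = {}
        lig = self.atoms[self.atoms.role == "ligand"]
        for group, names in ligand_groups.items():
            idx = lig.index[lig.name.isin(names)].to_numpy()
            if len(idx) == 0:
                raise ConfigurationError(
                    f"ligand feature group {group!r} resolves to no atoms "
                    f"(wanted names {list(names)})"
                )
            self.ligand_groups[group] = idx

    # ------------------------------------------------------------------ basics
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def water_ids(self) -> list[int]:
        """Residue numbers of water molecules."""
        w = self.atoms[self.atoms.role == "water"]
        return sorted(w.res_number.unique().tolist())

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    # -------------------------------------------------------------- selections
    def residue_atoms(self, res_number: int, names: tuple[str, ...] | None = None,
                      chain_id: str | None = None) -> np.ndarray:
        """Atom indices of a protein residue, optionally restricted to names."""
        m = (self.atoms.res_number == res_number) & (self.atoms.role == "protein")
        if chain_id is not None:
            m &= self.atoms.chain_id == chain_id
        if names is not None:
            m &= self.atoms.name.isin(names)
        idx = self.atoms.index[m].to_numpy()
        if len(idx) == 0:
            raise TopologyError(
                f"no atoms for residue {res_number}"
                + (f" names {names}" if names else "")
            )
        return idx

    def residue_ref(self, res_number: int) -> ResidueRef:
        m = (self.atoms.res_number == res_number) & (self.atoms.role == "protein")
        rows = self.atoms[m]
        if rows.empty:
            raise TopologyError(f"residue {res_number} not in topology")
        row = rows.iloc[0]
        return ResidueRef(row.chain_id, int(res_number), row.res_name,
                          self.bw_map.get(int(res_number)))

    def charged_group(self, res_number: int) -> np.ndarray:
        """Indices of the formally charged side-chain atoms of a residue."""
        ref = self.residue_ref(res_number)
        names = CHARGED_SIDECHAIN_ATOMS.get(ref.res_name)
        if names is None:
            raise TopologyError(
                f"residue {ref} ({ref.res_name}) has no charged side chain"
            )
        return self.residue_atoms(res_number, names=names)

    def water_oxygens(self) -> dict[int, np.ndarray]:
        """water residue number -> indices of its O atoms."""
        w = self.atoms[(self.atoms.role == "water") & (self.atoms.element == "O")]
        return {int(r): w.index[w.res_number == r].to_numpy()
                for r in w.res_number.unique()}

    def resolve_bw(self, bw_label: str) -> int:
        """Author residue number carrying a BW label (after assign_bw_numbers)."""
        for res, lab in self.bw_map.items():
            if lab == bw_label:
                return res
        raise TopologyError(f"no residue labelled {bw_label!r}")

    def with_frames(self, coords: np.ndarray) -> "MolecularSystem":
        """Same topology, new coordinate stack."""
        out = MolecularSystem.__new__(MolecularSystem)
        out.atoms = self.atoms
        out.frame_interval_ps = self.frame_interval_ps
        out.bw_map = dict(self.bw_map)
        out.ligand_groups = {k: v.copy() for k, v in self.ligand_groups.items()}
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1] != self.n_atoms:
            raise ValueError("atom count mismatch")
        out.coords = coords
        return out

    def same_topology(self, other: "MolecularSystem") -> bool:
        cols = ["name", "element", "chain_id", "res_number", "res_name", "role"]
        return self.atoms[cols].equals(other.atoms[cols])


def assign_bw_numbers(system: MolecularSystem, anchors: AnchorTable) -> MolecularSystem:
    """Fill the system's BW map from an anchor table.

    Residues inside a TM range get ``t.pp`` labels by constant offset from
    the x.50 anchor; residues covered by a region span get the region tag;
    anything else is labelled ``"unassigned"`` with a logged warning.
    """
    bw_map: dict[int, str] = {}
    prot = system.atoms[system.atoms.role == "protein"]
    for res_number in prot.res_number.unique():
        label = anchors.bw_for(int(res_number))
        if label is None:
            logger.warning("residue %s outside all TM ranges and regions; "
                           "labelled 'unassigned'", res_number)
            label = "unassigned"
        bw_map[int(res_number)] = label
    out = system.with_frames(system.coords)
    out.bw_map = bw_map
    return out
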