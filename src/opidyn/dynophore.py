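"""Dynamic-pharmacophore occurrence statistics over trajectories.

A monitored interaction is one (detector, ligand feature group, receptor
partner) triple.  Per frame, the configured detector either fires or not; a
frame counts as positive when at least one event of the row's kind occurs
(no multiplicity weighting).  The occurrence frequency of a row is the
percentage of positive frames, reported per replicate together with the
unweighted arithmetic mean over replicates — the layout of a dynophore
frequency table.  Distance profiles report the per-frame distance between
one ligand atom and one receptor atom with a quartile summary.

Partner selections use a small spec mini-language so YAML configs stay flat:

=================  ====================================================
``ligand:NAME``    ligand feature group NAME (all its atoms)
``res:N``          charged side-chain group of protein residue N
``bw:T.PP``        same, residue found via its Ballesteros–Weinstein label
``atom:N:NAME``    single atom NAME of protein residue N
``latom:NAME``     single ligand atom NAME
``ring:N``         aromatic ring atoms of protein residue N
``sidechain:N``    all side-chain heavy atoms of residue N
=================  ====================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .interactions import (
    GeometricCriteria,
    InteractionEvent,
    InteractionType,
    detect_cation_pi,
    detect_hbond,
    detect_hydrophobic,
    detect_ionic,
    detect_water_mediated,
)
from .structure import MolecularSystem

RING_ATOM_NAMES = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "NE1",
                   "CE3", "CZ2", "CZ3", "CH2")
BACKBONE_NAMES = ("N", "CA", "C", "O")

KINDS = ("ionic", "hbond", "hydrophobic", "cation_pi", "water_mediated")

_KIND_ITYPE = {
    "ionic": InteractionType.PI,
    "hbond": InteractionType.HBD,
    "hydrophobic": InteractionType.HY,
    "cation_pi": InteractionType.CATPI,
    "water_mediated": InteractionType.WATER_MEDIATED,
}


def resolve_selection(system: MolecularSystem, spec: str) -> np.ndarray:
    """Resolve a selection spec string to atom indices."""
    head, _, rest = spec.partition(":")
    try:
        if head == "ligand":
            if rest not in system.ligand_groups:
                raise ConfigurationError(f"unknown ligand feature group {rest!r}")
            return system.ligand_groups[rest]
        if head == "latom":
            lig = system.atoms[(system.atoms.role == "ligand")
                               & (system.atoms.name == rest)]
            if lig.empty:
                raise ConfigurationError(f"no ligand atom named {rest!r}")
            return lig.index.to_numpy()
        if head == "res":
            return system.charged_group(int(rest))
        if head == "bw":
            return system.charged_group(system.resolve_bw(rest))
        if head == "atom":
            res_s, _, name = rest.partition(":")
            return system.residue_atoms(int(res_s), names=(name,))
        if head == "ring":
            return system.residue_atoms(int(rest), names=RING_ATOM_NAMES)
        if head == "sidechain":
            idx = system.residue_atoms(int(rest))
            sub = system.atoms.loc[idx]
            keep = idx[~sub.name.isin(BACKBONE_NAMES).to_numpy()
                       & (sub.element != "H").to_numpy()]
            if keep.size == 0:
                raise ConfigurationError(f"residue {rest} has no side-chain atoms")
            return keep
    except (ValueError, KeyError) as exc:
        raise ConfigurationError(f"bad selection spec {spec!r}: {exc}") from exc
    raise ConfigurationError(f"unknown selection spec {spec!r}")


def _partner_label(system: MolecularSystem, spec: str) -> str:
    head, _, rest = spec.partition(":")
    try:
        if head in ("res", "ring", "sidechain"):
            return str(system.residue_ref(int(rest)))
        if head == "bw":
            return str(system.residue_ref(system.resolve_bw(rest)))
        if head == "atom":
            res_s, _, name = rest.partition(":")
            return f"{system.residue_ref(int(res_s))}:{name}"
    except Exception:
        pass
    return spec


@dataclass(frozen=True)
class InteractionDefinition:
    """One monitored row: detector kind plus the two partner selections.

    ``a`` is conventionally the ligand side (``ligand:...``) but may be any
    selection, so receptor–receptor pairs (e.g. the TM5–TM6 salt bridge) are
    expressed the same way.
    """

    key: str
    kind: str
    a: str
    b: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(
                f"unknown detector kind {self.kind!r} (expected one of {KINDS})"
            )

    def compile(self, system: MolecularSystem, criteria: GeometricCriteria):
        """Resolve selections once; return ``f(frame_index) -> event | None``."""
        idx_a = resolve_selection(system, self.a)
        idx_b = resolve_selection(system, self.b)
        label_a = self.a.removeprefix("ligand:")
        label_b = _partner_label(system, self.b)
        kw = dict(ligand_group=label_a, partner=label_b)
        if self.kind == "ionic":
            return lambda f: detect_ionic(system.frame(f), idx_a, idx_b,
                                          criteria, frame_index=f, **kw)
        if self.kind == "hbond":
            return lambda f: detect_hbond(system.frame(f), idx_a, idx_b,
                                          criteria, frame_index=f, **kw)
        if self.kind == "hydrophobic":
            elements = system.atoms.element.to_numpy()
            return lambda f: detect_hydrophobic(
                system.frame(f), idx_a, idx_b, criteria, elements=elements,
                frame_index=f, **kw)
        if self.kind == "cation_pi":
            return lambda f: detect_cation_pi(system.frame(f), idx_a, idx_b,
                                              criteria, frame_index=f, **kw)
        if self.kind == "water_mediated":
            waters = system.water_oxygens()
            return lambda f: detect_water_mediated(
                system.frame(f), idx_a, idx_b, waters, criteria,
                frame_index=f, **kw)
        raise AssertionError(self.kind)

    def detect(self, system: MolecularSystem, frame_index: int,
               criteria: GeometricCriteria) -> InteractionEvent | None:
        return self.compile(system, criteria)(frame_index)


def frame_fingerprint(
    system: MolecularSystem,
    frame_index: int,
    definitions: list[InteractionDefinition],
    criteria: GeometricCriteria,
) -> list[InteractionEvent]:
    """Positive events for one frame, in definition order."""
    events = []
    for definition in definitions:
        ev = definition.detect(system, frame_index, criteria)
        if ev is not None:
            events.append(ev)
    return events


@dataclass
class OccurrenceTable:
    """Occurrence frequencies (%) per replicate, with their mean."""

    table: pd.DataFrame          # index: definition key; columns: rep_i..., mean
    n_replicates: int
    n_frames: list[int]          # per replicate

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "interaction"
        out.round(1).to_csv(path)


def _positive_mask(system: MolecularSystem, definition: InteractionDefinition,
                   criteria: GeometricCriteria) -> np.ndarray:
    detect = definition.compile(system, criteria)
    return np.array([detect(f) is not None for f in range(system.n_frames)],
                    dtype=bool)


def occurrence_frequencies(
    replicate_systems: list[MolecularSystem],
    definitions: list[InteractionDefinition],
    criteria: GeometricCriteria,
    pooled: bool = False,
) -> OccurrenceTable:
    """Occurrence-frequency table over replicate trajectories.

    Per replicate, the frequency of a row is ``100 × positive frames /
    n_frames``.  The ``mean`` column is the unweighted arithmetic mean over
    replicates; with ``pooled=True`` it is instead computed over all frames
    pooled (identical when replicate lengths match).
    """
    if not replicate_systems:
        raise ValueError("need at least one replicate")
    first = replicate_systems[0]
    for other in replicate_systems[1:]:
        if not first.same_topology(other):
            raise ValueError("replicates do not share a topology")
    data: dict[str, list[float]] = {}
    pooled_hits: dict[str, int] = {}
    for definition in definitions:
        freqs = []
        hits = 0
        for system in replicate_systems:
            mask = _positive_mask(system, definition, criteria)
            freqs.append(100.0 * mask.sum() / system.n_frames)
            hits += int(mask.sum())
        data[definition.key] = freqs
        pooled_hits[definition.key] = hits
    n_frames = [s.n_frames for s in replicate_systems]
    table = pd.DataFrame.from_dict(
        data, orient="index",
        columns=[f"rep_{i + 1}" for i in range(len(replicate_systems))],
    )
    if pooled:
        total = sum(n_frames)
        table["mean"] = [100.0 * pooled_hits[k] / total for k in table.index]
    else:
        table["mean"] = table.mean(axis=1)
    return OccurrenceTable(table, len(replicate_systems), n_frames)


def pair_occupancy(
    system: MolecularSystem,
    definition: InteractionDefinition,
    criteria: GeometricCriteria,
) -> float:
    """Single-trajectory occurrence frequency (%) of one monitored pair."""
    mask = _positive_mask(system, definition, criteria)
    return 100.0 * mask.sum() / system.n_frames


@dataclass
class DistanceSeries:
    """Per-frame distance between two atoms with a quartile summary."""

    pair: str
    distances: np.ndarray

    def summary(self) -> dict[str, float]:
        q = np.quantile(self.distances, [0.0, 0.25, 0.5, 0.75, 1.0])
        return dict(min=float(q[0]), q1=float(q[1]), median=float(q[2]),
                    q3=float(q[3]), max=float(q[4]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.distances)),
                             "distance": self.distances})


def distance_profile(system: MolecularSystem, atom_a: str, atom_b: str) -> DistanceSeries:
    """Distance between two single atoms over all frames (specs as above).

    Multi-atom selections are rejected: the profile is an atom-pair
    measurement (e.g. carboxylate C ↔ lysine Nz).
    """
    idx_a = resolve_selection(system, atom_a)
    idx_b = resolve_selection(system, atom_b)
    if len(idx_a) != 1 or len(idx_b) != 1:
        raise ValueError("distance_profile needs single-atom selections")
    diff = system.coords[:, idx_a[0], :] - system.coords[:, idx_b[0], :]
    return DistanceSeries(pair=f"{atom_a} <-> {atom_b}",
                          distances=np.linalg.norm(diff, axis=1))
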