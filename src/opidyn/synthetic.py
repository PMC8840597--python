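"""Synthetic receptor–ligand systems with known ground truth.

The generator builds a toy 7-helix scaffold — a Cα trace of seven straight
helices on a circle — carrying properly named key residues (D3.32, Y3.33,
K5.39, the variable 6.58 position as K/W/E, the 6.31 and 4.40 deflection
anchors, an N-terminal aspartate and ECL2/ECL3 charged residues), a
four-feature zwitterionic morphinan-like ligand (protonated ring amine,
secondary amine, carboxylate, phenol) and optional water sites.  It then
renders trajectories in which every monitored contact follows a scheduled
per-frame occupancy and every frame's TM6 deflection follows a scheduled
activation-state fraction, so the downstream statistics have exact expected
values.

Mechanics: the ligand stays fixed; each scheduled interaction moves its
receptor side-chain tip along its own axis (the direction from the ligand
group outward through the residue's home position), placing the key charged
atom exactly ``bound_dist`` (mask true) or ``unbound_dist`` (mask false)
from the nearest ligand-group atom, plus Gaussian noise.  Because the axes
point outward from the ligand group and secondary group atoms are offset
perpendicular to the axis, the minimum inter-group distance equals the
scheduled distance exactly at zero noise.  Receptor–receptor pairs (the
TM5–TM6 salt bridge) are placed after the ligand-partnered pairs, relative
to the partner's current position.  Physical realism (force fields,
membrane, solvent) is explicitly out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as opio
from .interactions import GeometricCriteria
from .structure import AnchorTable, MolecularSystem

# ----------------------------------------------------------------- geometry
_R_HELIX = 11.0          # Å, helix circle radius
_RISE = 1.4              # Å per residue along z
_ANCHOR_POS = 30         # author offset of the x.50 anchor within each helix

#: author residue numbers of the named template residues
TEMPLATE_RESIDUES = {
    "D3.32": 312, "Y3.33": 313, "K5.39": 519, "6.58": 638,
    "6.31": 611, "4.40": 420,
    "D_nterm": 56, "K_ecl2": 444, "E_ecl2": 449, "R_ecl3": 645,
}

LIGAND_SPEC = {
    "morphinan_amine": ["N1"],
    "secondary_amine": ["N2"],
    "carboxylate": ["C10", "O1", "O2"],
    "phenol": ["O3"],
    "scaffold": ["C1", "C2", "C3", "C4", "C5"],
    "phenol_ring": ["C11", "C12", "C13", "C14", "C15", "C16"],
}

_CUTOFF_FIELD = {
    "ionic": "ionic_max_dist",
    "hbond": "hbond_max_dist",
    "hydrophobic": "hydrophobic_max_dist",
    "water_mediated": "hbond_max_dist",
}


def template_anchor_table(receptor_id: str = "TOY") -> AnchorTable:
    """Anchor table matching the toy scaffold's numbering."""
    return AnchorTable(
        receptor_id=receptor_id,
        anchors={t: t * 100 + _ANCHOR_POS for t in range(1, 8)},
        tm_ranges={t: (t * 100 + 1, t * 100 + 40) for t in range(1, 8)},
        regions=[
            (1, 100, "N-term"), (141, 200, "ICL1"), (241, 300, "ECL1"),
            (341, 400, "ICL2"), (441, 500, "ECL2"), (541, 600, "ICL3"),
            (641, 700, "ECL3"), (741, 900, "C-term"),
        ],
    )


@dataclass(frozen=True)
class ScheduledInteraction:
    """One contact with a scheduled per-frame occupancy.

    ``ligand_group`` names the ligand side; for receptor–receptor pairs it
    is ``None`` and ``partner_b`` names the second residue (both from
    :data:`TEMPLATE_RESIDUES` keys).  ``kind`` picks the detector whose
    cutoff the separation invariant is checked against.
    """

    key: str
    partner: str                      # TEMPLATE_RESIDUES key, e.g. "K5.39"
    p: float
    ligand_group: str | None = "carboxylate"
    partner_b: str | None = None      # second residue for receptor-receptor rows
    kind: str = "ionic"
    mode: str = "exact"               # exact | bernoulli
    bound_dist: float = 3.0
    unbound_dist: float = 8.0


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic receptor system."""

    receptor_id: str = "TOY"
    residue_658: str = "K"            # K | W | E at position 6.58
    n_frames: int = 1000
    n_replicates: int = 5
    seed: int = 42
    interactions: list[ScheduledInteraction] = field(default_factory=list)
    state_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)  # act, int, inact
    state_mode: str = "exact"
    active_ref_dist: float = 12.0
    inactive_ref_dist: float = 8.0
    deflection_targets: dict[str, float] | None = None  # per state label
    noise_sd: float = 0.05
    include_waters: bool = True
    clash_fixture: bool = False
    frame_interval_ps: float = 100.0

    def targets(self) -> dict[str, float]:
        if self.deflection_targets is not None:
            return dict(self.deflection_targets)
        mid = 0.5 * (self.active_ref_dist + self.inactive_ref_dist)
        return {
            "active_like": self.active_ref_dist + 0.5,
            "intermediate": mid,
            "inactive_like": self.inactive_ref_dist - 0.5,
        }

    def validate(self, criteria: GeometricCriteria | None = None) -> None:
        """Raise ValueError listing every violated invariant."""
        criteria = criteria or GeometricCriteria()
        problems: list[str] = []
        if self.n_frames < 1 or self.n_replicates < 1:
            problems.append("n_frames and n_replicates must be >= 1")
        if self.residue_658 not in ("K", "W", "E"):
            problems.append(f"residue_658 must be K, W or E, got {self.residue_658!r}")
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            problems.append(
                f"state fractions {self.state_fractions} do not sum to 1"
            )
        if any(f < 0 for f in self.state_fractions):
            problems.append("state fractions must be non-negative")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        seen = set()
        for si in self.interactions:
            if si.key in seen:
                problems.append(f"duplicate interaction key {si.key!r}")
            seen.add(si.key)
            if not 0.0 <= si.p <= 1.0:
                problems.append(f"{si.key}: occupancy p={si.p} outside [0,1]")
            if si.mode not in ("exact", "bernoulli"):
                problems.append(f"{si.key}: unknown mode {si.mode!r}")
            if si.partner not in TEMPLATE_RESIDUES:
                problems.append(f"{si.key}: unknown partner {si.partner!r}")
            if si.partner_b is not None and si.partner_b not in TEMPLATE_RESIDUES:
                problems.append(f"{si.key}: unknown partner_b {si.partner_b!r}")
            cutoff_field = _CUTOFF_FIELD.get(si.kind)
            if cutoff_field is None:
                problems.append(f"{si.key}: unschedulable kind {si.kind!r}")
                continue
            cutoff = getattr(criteria, cutoff_field)
            if si.kind == "water_mediated":
                # the scheduled quantity is each 2.8 Å bridge leg
                if not (_BRIDGE_LEG + 3 * self.noise_sd < cutoff):
                    problems.append(f"{si.key}: water legs overlap the cutoff")
                continue
            if not (si.bound_dist + 3 * self.noise_sd < cutoff
                    < si.unbound_dist - 3 * self.noise_sd):
                problems.append(
                    f"{si.key}: need bound+3sd < cutoff < unbound-3sd "
                    f"(got {si.bound_dist}+3·{self.noise_sd} vs {cutoff} vs "
                    f"{si.unbound_dist}-3·{self.noise_sd})"
                )
        t = self.targets()
        if not (t["active_like"] - 3 * self.noise_sd >= self.active_ref_dist):
            problems.append("active deflection target too close to the reference")
        if not (t["inactive_like"] + 3 * self.noise_sd <= self.inactive_ref_dist):
            problems.append("inactive deflection target too close to the reference")
        if not (self.inactive_ref_dist + 3 * self.noise_sd
                < t["intermediate"] < self.active_ref_dist - 3 * self.noise_sd):
            problems.append("intermediate deflection target outside the band")
        if problems:
            raise ValueError("invalid synthetic spec:\n  " + "\n  ".join(problems))


_BRIDGE_LEG = 2.8  # Å, each leg of a scheduled water bridge


def _hexagon(center: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        a = math.pi * k / 3
        pts.append(center + radius * np.array([math.cos(a), math.sin(a), 0.0]))
    return pts


def _helix_dir(t: int) -> np.ndarray:
    a = 2 * math.pi * (t - 1) / 7
    return np.array([math.cos(a), math.sin(a), 0.0])


def generate_template(spec: SyntheticSpec) -> MolecularSystem:
    """Single-frame toy system with every named residue resolvable."""
    spec.validate()
    rows: list[dict] = []
    xyz: list[np.ndarray] = []

    def add(name, element, chain, resnum, resname, role, pos):
        rows.append(dict(name=name, element=element, chain_id=chain,
                         res_number=resnum, res_name=resname, role=role))
        xyz.append(np.asarray(pos, dtype=float))

    named = TEMPLATE_RESIDUES
    resnames = {
        named["D3.32"]: "ASP", named["Y3.33"]: "TYR", named["K5.39"]: "LYS",
        named["6.58"]: {"K": "LYS", "W": "TRP", "E": "GLU"}[spec.residue_658],
        named["6.31"]: "ARG", named["4.40"]: "ARG",
        named["D_nterm"]: "ASP", named["K_ecl2"]: "LYS",
        named["E_ecl2"]: "GLU", named["R_ecl3"]: "ARG",
    }

    # --- helix Cα trace -----------------------------------------------------
    for t in range(1, 8):
        u = _helix_dir(t)
        for i in range(1, 41):                    # BW positions 21..60
            resnum = t * 100 + i
            pos_bw = i + 20
            ca = _R_HELIX * u + np.array([0.0, 0.0, _RISE * (pos_bw - 40)])
            add("CA", "C", "A", resnum, resnames.get(resnum, "GLY"), "protein", ca)

    # hand-placed loop residues (Cα near the extracellular rim)
    for key, t_near, z in (("D_nterm", 1, 16.0), ("K_ecl2", 2, 14.0),
                           ("E_ecl2", 7, 14.5), ("R_ecl3", 4, 15.0)):
        r = named[key]
        ca = 10.0 * _helix_dir(t_near) + np.array([0.0, 0.0, z])
        add("CA", "C", "A", r, resnames[r], "protein", ca)

    # backbone carbonyl C for the deflection anchors (carbonyl-switch support);
    # both carry the same offset from their Cα so either metric gives the
    # same anchor–anchor distance
    for key in ("4.40", "6.31"):
        r = named[key]
        t, i = r // 100, r % 100
        ca = _R_HELIX * _helix_dir(t) + np.array([0.0, 0.0, _RISE * (i - 20)])
        add("C", "C", "A", r, resnames[r], "protein", ca + np.array([0.8, 0.0, 0.0]))

    # --- ligand -------------------------------------------------------------
    n1 = np.array([0.0, 0.0, 0.0])
    add("N1", "N", "L", 900, "LIG", "ligand", n1)
    scaffold = [np.array([1.4, 0.0, 0.0]), np.array([2.1, 1.2, 0.0]),
                np.array([1.4, 2.4, 0.0]), np.array([0.0, 2.4, 0.0]),
                np.array([-0.7, 1.2, 0.0])]
    for i, p in enumerate(scaffold, start=1):
        add(f"C{i}", "C", "L", 900, "LIG", "ligand", p)
    n2 = np.array([0.0, -1.4, 1.0])
    add("N2", "N", "L", 900, "LIG", "ligand", n2)
    c10 = np.array([0.5, -2.6, 1.8])
    add("C10", "C", "L", 900, "LIG", "ligand", c10)
    add("O1", "O", "L", 900, "LIG", "ligand", c10 + np.array([1.2, -0.3, 0.0]))
    add("O2", "O", "L", 900, "LIG", "ligand", c10 + np.array([-0.9, -0.8, 0.4]))
    ring_c = np.array([3.5, 0.7, 0.3])
    for i, p in enumerate(_hexagon(ring_c), start=11):
        add(f"C{i}", "C", "L", 900, "LIG", "ligand", p)
    o3 = np.array([4.9, 0.7, 0.5])                 # phenolic hydroxyl oxygen
    add("O3", "O", "L", 900, "LIG", "ligand", o3)

    # --- named side chains --------------------------------------------------
    def perp(u: np.ndarray) -> np.ndarray:
        w = np.cross(u, np.array([0.0, 0.0, 1.0]))
        n = np.linalg.norm(w)
        if n < 1e-8:
            w = np.cross(u, np.array([1.0, 0.0, 0.0]))
            n = np.linalg.norm(w)
        return w / n

    u3 = _helix_dir(3)
    od1 = n1 + 7.5 * u3                            # D3.32 home: unbound from N1
    add("CB", "C", "A", named["D3.32"], "ASP", "protein", od1 + 1.5 * perp(u3))
    add("CG", "C", "A", named["D3.32"], "ASP", "protein", od1 + 0.7 * perp(u3))
    add("OD1", "O", "A", named["D3.32"], "ASP", "protein", od1)
    add("OD2", "O", "A", named["D3.32"], "ASP", "protein", od1 + 1.4 * perp(u3))

    # Y3.33 ring: blocks the pocket when the clash fixture is on
    y_center = scaffold[1] if spec.clash_fixture else n1 + 8.5 * (
        0.96 * u3 + 0.28 * perp(u3))
    ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    for nm, p in zip(ring_names, _hexagon(y_center)):
        add(nm, "C", "A", named["Y3.33"], "TYR", "protein", p)
    add("OH", "O", "A", named["Y3.33"], "TYR", "protein",
        y_center + np.array([2.8, 0.0, 0.0]))

    carb = np.mean([c10, c10 + np.array([1.2, -0.3, 0.0]),
                    c10 + np.array([-0.9, -0.8, 0.4])], axis=0)
    u5 = _helix_dir(5)
    nz539 = carb + 8.0 * u5                        # K5.39 home
    add("NZ", "N", "A", named["K5.39"], "LYS", "protein", nz539)
    # K5.39 backbone carbonyl O: 5 Å outward beyond the phenol hydroxyl, so a
    # single water can bridge both with 2.8 Å legs
    u_o3 = (o3 - n1) / np.linalg.norm(o3 - n1)
    ko = o3 + 5.0 * u_o3
    add("O", "O", "A", named["K5.39"], "LYS", "protein", ko)

    u6 = _helix_dir(6)
    home658 = carb + 8.5 * u6
    if spec.residue_658 == "K":
        add("NZ", "N", "A", named["6.58"], "LYS", "protein", home658)
    elif spec.residue_658 == "E":
        add("CD", "C", "A", named["6.58"], "GLU", "protein",
            home658 + 0.7 * perp(u6))
        add("OE1", "O", "A", named["6.58"], "GLU", "protein", home658)
        add("OE2", "O", "A", named["6.58"], "GLU", "protein",
            home658 + 1.4 * perp(u6))
    else:                                          # W: indole six-ring subset
        for nm, p in zip(("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
                         _hexagon(home658)):
            add(nm, "C", "A", named["6.58"], "TRP", "protein", p)
        add("NE1", "N", "A", named["6.58"], "TRP", "protein",
            home658 + np.array([2.1, 0.8, 0.0]))

    ud = np.array([-0.2, -0.9, 0.4]); ud = ud / np.linalg.norm(ud)
    d56 = n2 + 8.0 * ud                            # N-terminal aspartate home
    add("CG", "C", "A", named["D_nterm"], "ASP", "protein", d56 + 0.7 * perp(ud))
    add("OD1", "O", "A", named["D_nterm"], "ASP", "protein", d56)
    add("OD2", "O", "A", named["D_nterm"], "ASP", "protein", d56 + 1.4 * perp(ud))

    u2 = _helix_dir(2)
    add("NZ", "N", "A", named["K_ecl2"], "LYS", "protein", carb + 9.0 * u2)
    u7 = _helix_dir(7)
    e449 = n2 + 9.0 * u7
    add("CD", "C", "A", named["E_ecl2"], "GLU", "protein", e449 + 0.7 * perp(u7))
    add("OE1", "O", "A", named["E_ecl2"], "GLU", "protein", e449)
    add("OE2", "O", "A", named["E_ecl2"], "GLU", "protein", e449 + 1.4 * perp(u7))
    u1 = _helix_dir(1)
    r645 = carb + 9.0 * u1
    add("CZ", "C", "A", named["R_ecl3"], "ARG", "protein", r645 + 0.7 * perp(u1))
    add("NH1", "N", "A", named["R_ecl3"], "ARG", "protein", r645)
    add("NH2", "N", "A", named["R_ecl3"], "ARG", "protein", r645 + 1.4 * perp(u1))

    # --- waters -------------------------------------------------------------
    if spec.include_waters:
        add("O", "O", "W", 1, "HOH", "water", _bridge_point(o3, ko))
        add("O", "O", "W", 2, "HOH", "water", np.array([-8.0, -8.0, 6.0]))

    atoms = pd.DataFrame(rows)
    coords = np.asarray(xyz)[None]
    # canonical order (chain, residue, insertion order) so that PDB output,
    # CSV frames and the in-memory table all agree atom-for-atom
    order = atoms.sort_values(["chain_id", "res_number"],
                              kind="stable").index.to_numpy()
    atoms = atoms.loc[order].reset_index(drop=True)
    coords = coords[:, order]
    system = MolecularSystem(atoms, coords, LIGAND_SPEC,
                             frame_interval_ps=spec.frame_interval_ps)
    return system


def _bridge_point(a: np.ndarray, b: np.ndarray, leg: float = _BRIDGE_LEG) -> np.ndarray:
    """A point at distance ``leg`` from both a and b (two-sphere intersection)."""
    mid = 0.5 * (a + b)
    half = 0.5 * np.linalg.norm(b - a)
    if leg < half:
        raise ValueError("bridge legs too short for the partner separation")
    h = math.sqrt(leg ** 2 - half ** 2)
    axis = (b - a) / np.linalg.norm(b - a)
    w = np.cross(axis, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(w) < 1e-8:
        w = np.cross(axis, np.array([1.0, 0.0, 0.0]))
    w = w / np.linalg.norm(w)
    return mid + h * w


def schedule_occupancy(n_frames: int, p: float, mode: str,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Boolean occupancy mask.

    ``exact``: exactly round-half-up(p·n) true entries, positions shuffled by
    the seeded RNG.  ``bernoulli``: i.i.d. true with probability p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"occupancy p={p} outside [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if mode == "exact":
        k = math.floor(p * n_frames + 0.5)
        mask = np.zeros(n_frames, dtype=bool)
        mask[:k] = True
        return rng.permutation(mask)
    if mode == "bernoulli":
        return rng.random(n_frames) < p
    raise ValueError(f"unknown mode {mode!r}")


def schedule_states(n_frames: int, fractions: tuple[float, float, float],
                    mode: str, rng: np.random.Generator) -> np.ndarray:
    """Per-frame state labels; exact mode hits round-half-up counts."""
    labels = np.array(["active_like", "intermediate", "inactive_like"])
    f_act, f_int, _ = fractions
    if mode == "exact":
        k_act = math.floor(f_act * n_frames + 0.5)
        k_int = math.floor(f_int * n_frames + 0.5)
        k_act = min(k_act, n_frames)
        k_int = min(k_int, n_frames - k_act)
        out = np.concatenate([
            np.repeat(labels[0], k_act),
            np.repeat(labels[1], k_int),
            np.repeat(labels[2], n_frames - k_act - k_int),
        ])
        return rng.permutation(out)
    if mode == "bernoulli":
        return rng.choice(labels, size=n_frames, p=list(fractions))
    raise ValueError(f"unknown state mode {mode!r}")


# ------------------------------------------------------------------ rendering
def _group_anchor(frame: np.ndarray, idx: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Group atom with the largest projection on the axis (nearest along it)."""
    pts = frame[idx]
    return pts[np.argmax(pts @ axis)]


def _moving_atoms(system: MolecularSystem, res_key: str) -> np.ndarray:
    """Charged/side-chain atoms of a named residue that the renderer moves."""
    res = TEMPLATE_RESIDUES[res_key]
    return system.charged_group(res)


def _interaction_frame_geometry(
    system: MolecularSystem,
    si: ScheduledInteraction,
    base_frame: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Static-side anchor, axis, moving indices and their template offsets."""
    move_idx = _moving_atoms(system, si.partner_b or si.partner)
    if si.partner_b is None:
        if si.kind == "water_mediated":
            raise AssertionError("water rows handled separately")
        static_idx = system.ligand_groups[si.ligand_group]
    else:
        static_idx = _moving_atoms(system, si.partner)
    home_key = base_frame[move_idx[0]]
    centroid = base_frame[static_idx].mean(axis=0)
    axis = home_key - centroid
    axis = axis / np.linalg.norm(axis)
    anchor = _group_anchor(base_frame, static_idx, axis)
    # internal offsets of the moving group, orthogonalised against the axis
    # so every secondary atom lies at >= the key atom's distance and the
    # minimum inter-group distance equals the scheduled distance exactly
    offsets = base_frame[move_idx] - home_key
    offsets = offsets - (offsets @ axis)[:, None] * axis
    return anchor, axis, move_idx, offsets


def render_trajectory(
    template: MolecularSystem,
    spec: SyntheticSpec,
    criteria: GeometricCriteria | None = None,
    out_dir: str | Path | None = None,
    write_binary: bool = False,
) -> tuple[list[MolecularSystem], dict]:
    """Render replicate trajectories following the spec's schedules.

    Returns the replicate systems and the ground-truth dict (persisted as
    ``ground_truth.json`` when ``out_dir`` is given, together with
    ``template.pdb`` and per-replicate CSV frames, plus DCD if requested).
    """
    criteria = criteria or GeometricCriteria()
    spec.validate(criteria)
    base = template.frame(0)
    named = TEMPLATE_RESIDUES
    targets = spec.targets()

    ca440_idx = template.residue_atoms(named["4.40"], names=("CA",))[0]
    ca631_idx = template.residue_atoms(named["6.31"], names=("CA",))[0]
    c631_idx = template.residue_atoms(named["6.31"], names=("C",))[0]
    ca440 = base[ca440_idx]
    tm6_axis = base[ca631_idx] - ca440
    tm6_axis = tm6_axis / np.linalg.norm(tm6_axis)
    c_offset = base[c631_idx] - base[ca631_idx]

    water_rows = [si for si in spec.interactions if si.kind == "water_mediated"]
    pair_rows = [si for si in spec.interactions if si.kind != "water_mediated"]
    ligand_rows = [si for si in pair_rows if si.partner_b is None]
    bridge_rows = [si for si in pair_rows if si.partner_b is not None]

    if water_rows and not spec.include_waters:
        raise ValueError("water-mediated schedule requires include_waters")

    o3 = base[template.ligand_groups["phenol"][0]]
    ko = base[template.residue_atoms(named["K5.39"], names=("O",))[0]]
    bridge_pt = _bridge_point(o3, ko)
    far_pt = bridge_pt + np.array([0.0, 0.0, 12.0])

    replicates: list[MolecularSystem] = []
    truth: dict = {
        "spec": {
            **{k: v for k, v in asdict(spec).items() if k != "interactions"},
            "interactions": [asdict(si) for si in spec.interactions],
        },
        "replicates": [],
    }

    for r in range(spec.n_replicates):
        rep_seed = spec.seed + r
        rng = np.random.default_rng(rep_seed)
        masks = {si.key: schedule_occupancy(spec.n_frames, si.p, si.mode, rng)
                 for si in spec.interactions}
        state_labels = schedule_states(spec.n_frames, spec.state_fractions,
                                       spec.state_mode, rng)
        coords = np.repeat(base[None], spec.n_frames, axis=0)

        geoms = {si.key: _interaction_frame_geometry(template, si, base)
                 for si in ligand_rows}
        bridge_geoms = {si.key: _interaction_frame_geometry(template, si, base)
                        for si in bridge_rows}
        bridge_static = {si.key: _moving_atoms(template, si.partner)
                         for si in bridge_rows}
        water_idx = template.water_oxygens()[1] if water_rows else None

        for f in range(spec.n_frames):
            frame = coords[f]
            for si in ligand_rows:
                anchor, axis, move_idx, offsets = geoms[si.key]
                d = si.bound_dist if masks[si.key][f] else si.unbound_dist
                if spec.noise_sd > 0:
                    d += rng.normal(0.0, spec.noise_sd)
                frame[move_idx] = anchor + d * axis + offsets
            for si in bridge_rows:
                _, axis, move_idx, offsets = bridge_geoms[si.key]
                anchor = _group_anchor(frame, bridge_static[si.key], axis)
                d = si.bound_dist if masks[si.key][f] else si.unbound_dist
                if spec.noise_sd > 0:
                    d += rng.normal(0.0, spec.noise_sd)
                frame[move_idx] = anchor + d * axis + offsets
            for si in water_rows:
                pos = bridge_pt if masks[si.key][f] else far_pt
                if spec.noise_sd > 0:
                    pos = pos + rng.normal(0.0, spec.noise_sd, size=3)
                frame[water_idx] = pos
            d_state = targets[state_labels[f]]
            if spec.noise_sd > 0:
                d_state += rng.normal(0.0, spec.noise_sd)
            ca631_new = ca440 + d_state * tm6_axis
            frame[ca631_idx] = ca631_new
            frame[c631_idx] = ca631_new + c_offset

        replicates.append(template.with_frames(coords))
        truth["replicates"].append({
            "seed": rep_seed,
            "masks": {k: m.astype(int).tolist() for k, m in masks.items()},
            "state_labels": state_labels.tolist(),
            "state_counts": {lab: int((state_labels == lab).sum())
                             for lab in ("active_like", "intermediate",
                                         "inactive_like")},
        })

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        opio.write_pdb(template, out_dir / "template.pdb")
        for r, rep in enumerate(replicates):
            opio.write_csv_frames(rep.coords, out_dir / f"rep_{r + 1}.csv")
            if write_binary:
                opio.write_binary_frames(rep, out_dir / "template.pdb",
                                         out_dir / f"rep_{r + 1}.dcd")
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return replicates, truth


def render_pose(template: MolecularSystem,
                distances: dict[str, tuple[ScheduledInteraction, float]]
                ) -> MolecularSystem:
    """Single-frame pose with chosen contacts placed at explicit distances.

    ``distances`` maps a label to an interaction description plus the exact
    distance (Å) at which to place that receptor group from its ligand
    partner.  Used to construct docking-pose fixtures with known scores and
    constraint distances; no separation invariant applies.
    """
    base = template.frame(0).copy()
    for si, d in distances.values():
        anchor, axis, move_idx, offsets = _interaction_frame_geometry(
            template, si, template.frame(0))
        base[move_idx] = anchor + d * axis + offsets
    return template.with_frames(base[None])


def definitions_for_spec(spec: SyntheticSpec):
    """Monitored-interaction definitions matching a spec's scheduled rows."""
    from .dynophore import InteractionDefinition

    defs = []
    for si in spec.interactions:
        b = f"res:{TEMPLATE_RESIDUES[si.partner_b or si.partner]}"
        if si.partner_b is None:
            if si.kind == "water_mediated":
                a = "ligand:phenol"
                b = f"atom:{TEMPLATE_RESIDUES[si.partner]}:O"
            else:
                a = f"ligand:{si.ligand_group}"
        else:
            a = f"res:{TEMPLATE_RESIDUES[si.partner]}"
        defs.append(InteractionDefinition(key=si.key, kind=si.kind, a=a, b=b))
    return defs


def state_reference_for_spec(spec: SyntheticSpec):
    """Deflection references matching a spec's scheduled state fractions."""
    from .states import StateReference

    return StateReference(
        receptor_id=spec.receptor_id,
        residue_631=TEMPLATE_RESIDUES["6.31"],
        residue_440=TEMPLATE_RESIDUES["4.40"],
        active_ref_dist=spec.active_ref_dist,
        inactive_ref_dist=spec.inactive_ref_dist,
    )


# ------------------------------------------------- per-receptor study conditions
def _common_rows(extra: list[ScheduledInteraction]) -> list[ScheduledInteraction]:
    amine = ScheduledInteraction(
        key="amine_D3.32", partner="D3.32", p=1.0,
        ligand_group="morphinan_amine")
    return [amine, *extra]


def mor_spec(**overrides) -> SyntheticSpec:
    """MOR-like conditions: four ionic contacts and a 44.6% intermediate state."""
    rows = _common_rows([
        ScheduledInteraction(key="secondary_amine_D56", partner="D_nterm",
                             p=0.737, ligand_group="secondary_amine"),
        ScheduledInteraction(key="carboxylate_K5.39", partner="K5.39", p=0.813),
        ScheduledInteraction(key="carboxylate_K6.58", partner="6.58", p=0.750),
    ])
    kw = dict(receptor_id="MOR", residue_658="K", interactions=rows,
              state_fractions=(0.554, 0.446, 0.0))
    kw.update(overrides)
    return SyntheticSpec(**kw)


def dor_spec(**overrides) -> SyntheticSpec:
    """DOR-like conditions: W6.58, three ionic contacts, 5.3% intermediate."""
    rows = _common_rows([
        ScheduledInteraction(key="carboxylate_K5.39", partner="K5.39", p=0.650),
        ScheduledInteraction(key="carboxylate_R_ECL3", partner="R_ecl3", p=0.092),
    ])
    kw = dict(receptor_id="DOR", residue_658="W", interactions=rows,
              state_fractions=(0.947, 0.053, 0.0))
    kw.update(overrides)
    return SyntheticSpec(**kw)


def kor_spec(**overrides) -> SyntheticSpec:
    """KOR-like conditions: E6.58, four ionic contacts, the 45.6% TM5–TM6
    bridge and a 51.9% intermediate state."""
    rows = _common_rows([
        ScheduledInteraction(key="secondary_amine_E_ECL2", partner="E_ecl2",
                             p=0.125, ligand_group="secondary_amine"),
        ScheduledInteraction(key="carboxylate_K5.39", partner="K5.39", p=0.633),
        ScheduledInteraction(key="carboxylate_K_ECL2", partner="K_ecl2", p=0.157),
        ScheduledInteraction(key="bridge_K5.39_E6.58", partner="K5.39",
                             partner_b="6.58", p=0.456, ligand_group=None),
    ])
    kw = dict(receptor_id="KOR", residue_658="E", interactions=rows,
              state_fractions=(0.481, 0.519, 0.0))
    kw.update(overrides)
    return SyntheticSpec(**kw)
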