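"""YAML loaders for anchor tables, criteria, specs, fingerprints and runs."""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .interactions import GeometricCriteria
from .poses import FingerprintEntry, ReferenceFingerprint
from .states import StateReference
from .structure import AnchorTable
from .synthetic import ScheduledInteraction, SyntheticSpec


def _load(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    return data


def config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_anchor_table(path) -> AnchorTable:
    d = _load(path)
    try:
        return AnchorTable(
            receptor_id=d["receptor"],
            anchors={int(k): int(v) for k, v in d["anchors"].items()},
            tm_ranges={int(k): (int(v[0]), int(v[1]))
                       for k, v in d["tm_ranges"].items()},
            regions=[(int(r["first"]), int(r["last"]), str(r["tag"]))
                     for r in d.get("regions", [])],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: bad anchor table: {exc}") from exc


def load_criteria(path_or_dict) -> GeometricCriteria:
    d = path_or_dict if isinstance(path_or_dict, dict) else _load(path_or_dict)
    d = d.get("criteria", d)
    try:
        return GeometricCriteria.from_dict(d)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"bad criteria: {exc}") from exc


def load_synthetic_spec(path) -> SyntheticSpec:
    d = _load(path)
    try:
        rows = [ScheduledInteraction(**row) for row in d.pop("interactions", [])]
        if "state_fractions" in d:
            d["state_fractions"] = tuple(d["state_fractions"])
        spec = SyntheticSpec(interactions=rows, **d)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: bad synthetic spec: {exc}") from exc
    spec.validate()
    return spec


def load_fingerprint(path) -> ReferenceFingerprint:
    d = _load(path)
    try:
        entries = [FingerprintEntry(itype=e["itype"], partner=e["partner"],
                                    ligand=e.get("ligand"))
                   for e in d["entries"]]
        return ReferenceFingerprint(
            receptor_id=d["receptor"], entries=entries,
            d332_res=int(d["d332_res"]),
            amine_atom=d.get("amine_atom", "N1"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: bad fingerprint: {exc}") from exc


def load_state_reference(path_or_dict) -> StateReference:
    d = path_or_dict if isinstance(path_or_dict, dict) \
        else _load(path_or_dict)
    try:
        return StateReference(
            receptor_id=d["receptor"],
            residue_631=int(d["residue_631"]),
            residue_440=int(d["residue_440"]),
            active_ref_dist=float(d["active_ref_dist"]),
            inactive_ref_dist=float(d["inactive_ref_dist"]),
            tolerance=float(d.get("tolerance", 0.0)),
            measure_atom=d.get("measure_atom", "CA"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"bad state reference: {exc}") from exc
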