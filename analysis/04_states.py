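#!/usr/bin/env python
"""TM6-deflection state classification and TM5-TM6 bridge occupancy.

Classifies every frame of each receptor's first replicate against toy
active/inactive reference deflections (12.0 / 8.0 A between the 6.31 and
4.40 Calpha anchors) and reports the activation-state fractions.  For the
KOR-like system it additionally measures the K5.39-E6.58 salt-bridge
occupancy — the interaction held responsible for trapping the receptor in
the intermediate state and hence for partial agonism.
"""

import json
from pathlib import Path

from opidyn import synthetic as syn
from opidyn.interactions import GeometricCriteria
from opidyn.io import load_structure
from opidyn.states import state_fractions, tm5_tm6_bridge_occupancy
from opidyn.synthetic import state_reference_for_spec

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    criteria = GeometricCriteria()
    report = {}
    for factory in (syn.mor_spec, syn.dor_spec, syn.kor_spec):
        spec = factory()
        sim = BASE.parent / "scratch" / "sim" / spec.receptor_id
        system = load_structure(sim / "template.pdb", syn.LIGAND_SPEC,
                                traj_path=sim / "rep_1.csv")
        profile = state_fractions([system], state_reference_for_spec(spec))
        entry = {"state_fractions_percent": profile.fractions}
        if spec.receptor_id == "KOR":
            entry["tm5_tm6_bridge_percent"] = tm5_tm6_bridge_occupancy(
                system, syn.TEMPLATE_RESIDUES["K5.39"],
                syn.TEMPLATE_RESIDUES["6.58"], criteria)
        report[spec.receptor_id] = entry
        frac = profile.fractions
        print(f"{spec.receptor_id}: active {frac['active_like']:.1f}%  "
              f"intermediate {frac['intermediate']:.1f}%  "
              f"inactive {frac['inactive_like']:.1f}%"
              + (f"  | TM5-TM6 bridge {entry['tm5_tm6_bridge_percent']:.1f}%"
                 if "tm5_tm6_bridge_percent" in entry else ""))
    out = BASE / "state_report.json"
    out.write_text(json.dumps(report, indent=1))
    print(f"state report -> {out}")


if __name__ == "__main__":
    main()
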