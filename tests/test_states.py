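"""TM6 deflection, state classification, fractions and the TM5-TM6 bridge."""

import numpy as np
import pytest

from opidyn import synthetic as syn
from opidyn.states import (
    StateReference,
    classify_frame,
    state_fractions,
    tm5_tm6_bridge_occupancy,
    tm6_deflection,
)
from opidyn.synthetic import state_reference_for_spec

R631 = syn.TEMPLATE_RESIDUES["6.31"]
R440 = syn.TEMPLATE_RESIDUES["4.40"]
K539 = syn.TEMPLATE_RESIDUES["K5.39"]
E658 = syn.TEMPLATE_RESIDUES["6.58"]


def reference(**kw):
    args = dict(receptor_id="toy", residue_631=R631, residue_440=R440,
                active_ref_dist=12.0, inactive_ref_dist=8.0)
    args.update(kw)
    return StateReference(**args)


class TestDeflection:
    def test_matches_hand_computed_norm(self, small_mor):
        _, _, replicates, _ = small_mor
        rep = replicates[0]
        ref = reference()
        i = rep.residue_atoms(R631, names=("CA",))[0]
        j = rep.residue_atoms(R440, names=("CA",))[0]
        for f in (0, 7, 42):
            p, q = rep.frame(f)[i], rep.frame(f)[j]
            by_hand = ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
                       + (p[2] - q[2]) ** 2) ** 0.5
            assert tm6_deflection(rep, f, ref) == pytest.approx(by_hand)

    def test_carbonyl_switch_gives_same_distance(self, small_mor):
        # both anchors carry the same Calpha->C offset in the toy scaffold
        _, _, replicates, _ = small_mor
        ref_ca, ref_c = reference(), reference(measure_atom="C")
        assert tm6_deflection(replicates[0], 3, ref_ca) == \
            pytest.approx(tm6_deflection(replicates[0], 3, ref_c))


class TestClassify:
    @pytest.mark.parametrize("d,label", [
        (12.0, "active_like"),       # boundary belongs to the end state
        (13.5, "active_like"),
        (10.0, "intermediate"),
        (8.0, "inactive_like"),
        (7.5, "inactive_like"),
    ])
    def test_banding(self, d, label):
        assert classify_frame(d, reference()) == label

    def test_tolerance_widens_end_states(self):
        ref = reference(tolerance=0.5)
        assert classify_frame(11.6, ref) == "active_like"
        assert classify_frame(8.4, ref) == "inactive_like"
        assert classify_frame(10.0, ref) == "intermediate"

    def test_monotone_in_deflection(self):
        ref = reference()
        order = {"inactive_like": 0, "intermediate": 1, "active_like": 2}
        labels = [order[classify_frame(d, ref)] for d in np.linspace(5, 15, 101)]
        assert labels == sorted(labels)

    def test_swapped_references_auto_corrected(self, caplog):
        ref = StateReference("toy", R631, R440,
                             active_ref_dist=8.0, inactive_ref_dist=12.0)
        assert ref.active_ref_dist == 12.0
        assert classify_frame(12.5, ref) == "active_like"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_frame(float("nan"), reference())


class TestStateFractions:
    def test_all_active_frames(self, template):
        spec = syn.mor_spec(n_replicates=1, n_frames=50,
                            state_fractions=(1.0, 0.0, 0.0))
        replicates, _ = syn.render_trajectory(syn.generate_template(spec), spec)
        profile = state_fractions(replicates, state_reference_for_spec(spec))
        assert profile.fractions["active_like"] == 100.0

    def test_recovers_scheduled_fractions_exactly(self):
        spec = syn.kor_spec(n_replicates=1, n_frames=1000)
        replicates, truth = syn.render_trajectory(
            syn.generate_template(spec), spec)
        profile = state_fractions(replicates, state_reference_for_spec(spec))
        counts = truth["replicates"][0]["state_counts"]
        for label in ("active_like", "intermediate", "inactive_like"):
            assert profile.fractions[label] == \
                pytest.approx(100.0 * counts[label] / 1000)
        assert profile.fractions["intermediate"] == 51.9

    def test_fractions_sum_to_100(self, small_mor):
        spec, _, replicates, _ = small_mor
        profile = state_fractions(replicates, state_reference_for_spec(spec))
        assert sum(profile.fractions.values()) == pytest.approx(100.0)

    def test_invariant_under_replicate_order_and_permutation(self, small_mor, rng):
        spec, _, replicates, _ = small_mor
        ref = state_reference_for_spec(spec)
        a = state_fractions(replicates, ref).fractions
        b = state_fractions(replicates[::-1], ref).fractions
        shuffled = [r.with_frames(r.coords[rng.permutation(r.n_frames)])
                    for r in replicates]
        c = state_fractions(shuffled, ref).fractions
        assert a == b == c


class TestBridge:
    def test_scheduled_bridge_occupancy_recovered(self, criteria):
        spec = syn.kor_spec(n_replicates=1, n_frames=1000)
        replicates, _ = syn.render_trajectory(syn.generate_template(spec), spec)
        occ = tm5_tm6_bridge_occupancy(replicates[0], K539, E658, criteria)
        assert occ == 45.6

    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 100.0)])
    def test_degenerate_occupancies(self, criteria, p, expected):
        spec = syn.kor_spec(n_replicates=1, n_frames=100)
        rows = [si for si in spec.interactions if si.partner_b is None]
        rows.append(syn.ScheduledInteraction(
            key="bridge_K5.39_E6.58", partner="K5.39", partner_b="6.58",
            p=p, ligand_group=None))
        spec.interactions = rows
        replicates, _ = syn.render_trajectory(syn.generate_template(spec), spec)
        assert tm5_tm6_bridge_occupancy(replicates[0], K539, E658,
                                        criteria) == expected

    def test_bridge_coupled_to_subactive_deflection_raises_intermediate(
            self, criteria):
        """Coupling bridged frames to sub-active TM6 deflection: higher
        scheduled bridge occupancy yields a higher intermediate fraction."""
        intermediates = []
        for p in (0.2, 0.6):
            spec = syn.kor_spec(n_replicates=1, n_frames=500,
                                state_fractions=(1.0 - p, p, 0.0))
            for i, si in enumerate(spec.interactions):
                if si.partner_b is not None:
                    spec.interactions[i] = syn.ScheduledInteraction(
                        key=si.key, partner=si.partner, partner_b=si.partner_b,
                        p=p, ligand_group=None)
            replicates, _ = syn.render_trajectory(
                syn.generate_template(spec), spec)
            occ = tm5_tm6_bridge_occupancy(replicates[0], K539, E658, criteria)
            frac = state_fractions(replicates,
                                   state_reference_for_spec(spec)).fractions
            assert occ == pytest.approx(100.0 * p)
            intermediates.append(frac["intermediate"])
        assert intermediates[1] > intermediates[0]
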