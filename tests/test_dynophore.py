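"""Occurrence statistics, pair occupancy and distance profiles."""

import numpy as np
import pandas as pd
import pytest

from opidyn import synthetic as syn
from opidyn.dynophore import (
    InteractionDefinition,
    distance_profile,
    frame_fingerprint,
    occurrence_frequencies,
    pair_occupancy,
)
from opidyn.errors import ConfigurationError
from opidyn.synthetic import definitions_for_spec

from .oracles import quantiles_by_sorting

D332 = syn.TEMPLATE_RESIDUES["D3.32"]
K539 = syn.TEMPLATE_RESIDUES["K5.39"]

AMINE_DEF = InteractionDefinition(key="amine", kind="ionic",
                                  a="ligand:morphinan_amine", b=f"res:{D332}")


class TestFrameFingerprint:
    def test_bound_frame_contains_pi_to_d332(self, small_mor, criteria):
        spec, _, replicates, truth = small_mor
        mask = truth["replicates"][0]["masks"]["amine_D3.32"]
        f = mask.index(1)
        events = frame_fingerprint(replicates[0], f, [AMINE_DEF], criteria)
        assert len(events) == 1
        assert events[0].partner.startswith("ASP")

    def test_unbound_frame_is_empty_for_that_pair(self, small_mor, criteria):
        spec, _, replicates, truth = small_mor
        mask = truth["replicates"][0]["masks"]["carboxylate_K5.39"]
        f = mask.index(0)
        definition = InteractionDefinition(key="c", kind="ionic",
                                           a="ligand:carboxylate", b=f"res:{K539}")
        assert frame_fingerprint(replicates[0], f, [definition], criteria) == []

    def test_repeated_call_identical(self, small_mor, criteria):
        _, _, replicates, _ = small_mor
        a = frame_fingerprint(replicates[0], 5, [AMINE_DEF], criteria)
        b = frame_fingerprint(replicates[0], 5, [AMINE_DEF], criteria)
        assert a == b

    def test_unknown_group_is_config_error(self, small_mor, criteria):
        _, _, replicates, _ = small_mor
        bad = InteractionDefinition(key="x", kind="ionic",
                                    a="ligand:nope", b=f"res:{D332}")
        with pytest.raises(ConfigurationError):
            frame_fingerprint(replicates[0], 0, [bad], criteria)


class TestOccurrenceFrequencies:
    def test_always_bound_pair_is_100_percent(self, small_mor, criteria):
        _, _, replicates, _ = small_mor
        table = occurrence_frequencies(replicates, [AMINE_DEF], criteria)
        assert table.mean["amine"] == 100.0

    def test_recovers_scheduled_frequencies_exactly(self, small_mor, criteria):
        spec, _, replicates, truth = small_mor
        table = occurrence_frequencies(replicates, definitions_for_spec(spec),
                                       criteria)
        for si in spec.interactions:
            scheduled = [100.0 * sum(rep["masks"][si.key]) / spec.n_frames
                         for rep in truth["replicates"]]
            for r, val in enumerate(scheduled):
                assert table.table.loc[si.key, f"rep_{r + 1}"] == val
            assert table.mean[si.key] == pytest.approx(np.mean(scheduled))

    def test_mean_is_arithmetic_mean(self):
        # two replicates at 60% and 80% -> mean 70%
        table = pd.DataFrame({"rep_1": [60.0], "rep_2": [80.0]}, index=["k"])
        table["mean"] = table.mean(axis=1)
        assert table["mean"].iloc[0] == 70.0

    def test_occupancy_matches_per_frame_recount(self, small_mor, criteria):
        """pair_occupancy equals an independent frame-by-frame fingerprint
        recount, and event and no-event frames partition the trajectory."""
        spec, _, replicates, _ = small_mor
        definition = definitions_for_spec(spec)[2]
        rep = replicates[0]
        freq = pair_occupancy(rep, definition, criteria)
        hits = sum(
            bool(frame_fingerprint(rep, f, [definition], criteria))
            for f in range(rep.n_frames)
        )
        misses = rep.n_frames - hits
        assert freq == 100.0 * hits / rep.n_frames
        assert freq + 100.0 * misses / rep.n_frames == 100.0

    def test_single_replicate_equals_pair_occupancy(self, small_mor, criteria):
        spec, _, replicates, _ = small_mor
        definition = definitions_for_spec(spec)[1]
        table = occurrence_frequencies(replicates[:1], [definition], criteria)
        assert table.mean[definition.key] == \
            pair_occupancy(replicates[0], definition, criteria)

    def test_invariant_under_frame_reordering(self, small_mor, criteria, rng):
        spec, _, replicates, _ = small_mor
        definition = definitions_for_spec(spec)[1]
        rep = replicates[0]
        shuffled = rep.with_frames(rep.coords[rng.permutation(rep.n_frames)])
        assert pair_occupancy(rep, definition, criteria) == \
            pair_occupancy(shuffled, definition, criteria)

    def test_topology_mismatch_rejected(self, small_mor, criteria):
        _, _, replicates, _ = small_mor
        other = syn.generate_template(syn.kor_spec())  # GLU at 6.58, different atoms
        with pytest.raises(ValueError):
            occurrence_frequencies([replicates[0], other], [AMINE_DEF], criteria)

    def test_bernoulli_mode_matches_persisted_mask(self, criteria):
        spec = syn.mor_spec(n_replicates=1, n_frames=300)
        spec.interactions[2] = syn.ScheduledInteraction(
            key="carboxylate_K5.39", partner="K5.39", p=0.5, mode="bernoulli")
        template = syn.generate_template(spec)
        replicates, truth = syn.render_trajectory(template, spec)
        definition = definitions_for_spec(spec)[2]
        recounted = pair_occupancy(replicates[0], definition, criteria)
        mask = truth["replicates"][0]["masks"]["carboxylate_K5.39"]
        assert recounted == 100.0 * sum(mask) / len(mask)


class TestDistanceProfile:
    def test_constant_trajectory_all_quantiles_equal(self, small_mor):
        _, template, _, _ = small_mor
        coords = np.repeat(template.frame(0)[None], 5, axis=0)
        system = template.with_frames(coords)
        series = distance_profile(system, "latom:N1", f"atom:{D332}:CG")
        s = series.summary()
        assert s["min"] == s["median"] == s["max"]

    def test_median_of_1234_is_2_5(self):
        assert float(np.quantile([1, 2, 3, 4], 0.5)) == 2.5

    def test_quantiles_match_sort_oracle(self, small_mor):
        spec, _, replicates, _ = small_mor
        series = distance_profile(replicates[0], "latom:C10", f"atom:{K539}:NZ")
        got = series.summary()
        expect = quantiles_by_sorting(series.distances.tolist(),
                                      [0.0, 0.25, 0.5, 0.75, 1.0])
        for key, val in zip(("min", "q1", "median", "q3", "max"), expect):
            assert got[key] == pytest.approx(val, abs=1e-12)

    def test_summary_quantiles_non_decreasing(self, small_mor):
        _, _, replicates, _ = small_mor
        s = distance_profile(replicates[0], "latom:C10",
                             f"atom:{K539}:NZ").summary()
        assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]

    def test_unknown_atom_rejected(self, small_mor):
        _, _, replicates, _ = small_mor
        with pytest.raises(Exception):
            distance_profile(replicates[0], "latom:QQ", f"atom:{K539}:NZ")

    def test_multi_atom_selection_rejected(self, small_mor):
        _, _, replicates, _ = small_mor
        with pytest.raises(ValueError):
            distance_profile(replicates[0], "ligand:carboxylate",
                             f"atom:{K539}:NZ")
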