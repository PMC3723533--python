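"""Phase orientation, inversion parsimony and co-conversion tract inference."""

import numpy as np
import pytest

from palinconv.caller import enumerate_events
from palinconv.model import Psv
from palinconv.phase import (
    DISTAL,
    PROXIMAL,
    Orientation,
    borrow_phase,
    min_coconversion_tracts,
    min_inversions,
    phase_orientation,
    tract_stats,
    CoConversionTract,
    TractSet,
)

from _oracles import min_flips_bruteforce
from conftest import HET, HOM_ANC, HOM_DER, build_tree, matrix_from, random_instance

REF = {"PSV1": ("G", "A"), "PSV2": ("C", "T"), "PSV3": ("A", "G")}


class TestPhaseOrientation:
    def test_matching_arm_assignments_are_same(self):
        sample = {"PSV1": ("G", "A"), "PSV2": ("C", "T")}
        assert phase_orientation(sample, REF) is Orientation.SAME

    def test_swapped_arm_assignments_are_inverted(self):
        sample = {"PSV1": ("A", "G"), "PSV2": ("T", "C")}
        assert phase_orientation(sample, REF) is Orientation.INVERTED

    def test_all_homozygous_is_uninformative(self):
        sample = {"PSV1": ("G", "G"), "PSV2": ("T", "T")}
        assert phase_orientation(sample, REF) is Orientation.UNINFORMATIVE

    def test_mixed_pattern_is_flagged_mosaic(self):
        sample = {"PSV1": ("G", "A"), "PSV2": ("T", "C")}
        assert phase_orientation(sample, REF) is Orientation.MOSAIC

    def test_missing_reference_is_configuration_error(self):
        from palinconv.phase import ConfigurationError

        with pytest.raises(ConfigurationError):
            phase_orientation({"PSV1": ("G", "A")}, {})


class TestMinInversions:
    def test_inverted_haplogroup_called_at_its_stem(self, fig_tree):
        orientations = {"sA": Orientation.INVERTED, "sB": Orientation.SAME,
                        "sC": Orientation.SAME, "sOut": Orientation.SAME}
        calls = min_inversions(fig_tree, orientations)
        assert len(calls) == 1
        assert calls[0].child == "sA" or calls[0].child == "A"

    def test_all_same_yields_no_calls(self, fig_tree):
        orientations = {s: Orientation.SAME for s in fig_tree.samples}
        assert min_inversions(fig_tree, orientations) == []

    def test_concordant_haplogroup_counts_one_event(self):
        tree = build_tree("((A,B)AB,C)ROOT;",
                          {"a1": "A", "a2": "A", "a3": "A", "c1": "C"})
        orientations = {"a1": Orientation.INVERTED, "a2": Orientation.INVERTED,
                        "a3": Orientation.INVERTED, "c1": Orientation.SAME}
        calls = min_inversions(tree, orientations)
        assert len(calls) == 1

    def test_parsimony_matches_bruteforce_on_random_trees(self):
        rng = np.random.default_rng(3)
        labels = [Orientation.SAME, Orientation.INVERTED, Orientation.UNINFORMATIVE]
        for _ in range(150):
            tree, _ = random_instance(rng)
            orientations = {
                s: labels[int(rng.integers(3))] for s in tree.sample_map
            }
            expected = min_flips_bruteforce(tree, orientations)
            assert len(min_inversions(tree, orientations)) == expected

    def test_planted_disjoint_flips_recovered(self):
        from palinconv.simulate import SimParams, simulate_conversion_history, simulate_phylogeny

        params = SimParams(seed=9, n_haplogroups=15, samples_per_haplogroup=2,
                           total_generations=100_000, conversion_rate=0.0,
                           inversion_rate=3e-5, psv_origin="root")
        rng = np.random.default_rng(9)
        tree, sg = simulate_phylogeny(params, rng)
        _, phase_df, ref, truth = simulate_conversion_history(tree, sg, params, rng)
        by_sample = {}
        for row in phase_df.itertuples():
            by_sample.setdefault(row.sample_id, {})[row.psv_id] = (
                row.proximal_allele, row.distal_allele
            )
        orientations = {s: phase_orientation(r, ref) for s, r in by_sample.items()}
        called = len(min_inversions(tree, orientations))
        assert 0 < called <= len(truth.inversion_events)


PSVS = [Psv("PSV1", 1000, "G", "A"), Psv("PSV2", 1081, "C", "T"),
        Psv("PSV3", 2650, "A", "G"), Psv("PSV4", 4120, "G", "T"),
        Psv("PSV5", 5136, "C", "G"), Psv("PSV6", 7410, "C", "A"),
        Psv("PSV7", 10023, "A", "G")]
#: reference phase: derived allele on the distal arm at every PSV
REF7 = {p.id: (p.allele_ancestral, p.allele_derived) for p in PSVS}


def _tract_inputs(sample_states):
    """One haplogroup with a HET founder at all 7 PSVs; one converted sample."""
    tree = build_tree("((A,B)AB,C)ROOT;",
                      {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
    columns = {}
    for psv in PSVS:
        col = {"a2": HET, "b1": HET, "c1": HET}
        col["a1"] = sample_states.get(psv.id, HET)
        columns[psv.id] = col
    matrix = matrix_from(columns, tree.samples)
    calls = enumerate_events(tree, matrix, PSVS)
    return tree, matrix, calls


class TestCoConversionTracts:
    def test_seven_psv_run_matching_one_arm_is_one_tract(self):
        # all seven PSVs fixed for the proximal (ancestral) reference arm
        tree, matrix, calls = _tract_inputs({p.id: HOM_ANC for p in PSVS})
        tracts = min_coconversion_tracts(tree, matrix, calls, PSVS, REF7)
        multi = [t for t in tracts.tracts if t.size >= 2]
        assert len(multi) == 1
        assert multi[0].size == 7
        assert multi[0].min_length_bp == 9023
        assert multi[0].donor_arm == PROXIMAL

    def test_adjacent_opposite_conversions_are_split(self):
        # PSV1 fixed ancestral (proximal arm), PSV2 fixed derived (distal arm):
        # no single donor arm explains both
        tree, matrix, calls = _tract_inputs({"PSV1": HOM_ANC, "PSV2": HOM_DER})
        tracts = min_coconversion_tracts(tree, matrix, calls, PSVS, REF7)
        assert all(t.size == 1 for t in tracts.tracts)
        assert len(tracts.tracts) == 2
        assert {t.donor_arm for t in tracts.tracts} == {PROXIMAL, DISTAL}

    def test_single_converted_psv_is_singleton_with_zero_length(self):
        tree, matrix, calls = _tract_inputs({"PSV4": HOM_DER})
        tracts = min_coconversion_tracts(tree, matrix, calls, PSVS, REF7)
        assert len(tracts.tracts) == 1
        assert tracts.tracts[0].size == 1
        assert tracts.tracts[0].min_length_bp == 0

    def test_het_psv_breaks_a_run(self):
        # PSV1,2 converted; PSV3 heterozygous; PSV4 converted -> two tracts
        tree, matrix, calls = _tract_inputs(
            {"PSV1": HOM_ANC, "PSV2": HOM_ANC, "PSV3": HET, "PSV4": HOM_ANC}
        )
        tracts = min_coconversion_tracts(tree, matrix, calls, PSVS, REF7)
        sizes = sorted(t.size for t in tracts.tracts)
        assert sizes == [1, 2]

    def test_identical_tracts_within_haplogroup_counted_once(self):
        tree = build_tree("((A,B)AB,C)ROOT;",
                          {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        columns = {
            p.id: {"a1": HOM_ANC, "a2": HOM_ANC, "b1": HET, "c1": HET}
            for p in PSVS[:2]
        }
        columns.update({p.id: {s: HET for s in tree.samples} for p in PSVS[2:]})
        matrix = matrix_from(columns, tree.samples)
        calls = enumerate_events(tree, matrix, PSVS)
        tracts = min_coconversion_tracts(tree, matrix, calls, PSVS, REF7)
        assert len([t for t in tracts.tracts if t.size == 2]) == 1

    def test_collapsing_never_increases_event_count(self):
        tree, matrix, calls = _tract_inputs({p.id: HOM_ANC for p in PSVS})
        tracts = min_coconversion_tracts(tree, matrix, calls, PSVS, REF7)
        n_after = len(tracts.tracts)
        assert n_after <= tracts.total_conversions


class TestTractStats:
    def test_mean_of_minimum_lengths(self):
        ts = TractSet(
            tracts=[
                CoConversionTract("A", ("PSV1", "PSV2"), ("G", "C"), PROXIMAL, 81),
                CoConversionTract("B", ("PSV3", "PSV5"), ("A", "C"), PROXIMAL, 4055),
            ],
            total_conversions=4,
        )
        s = tract_stats(ts)
        assert s["mean_min_length_bp"] == pytest.approx(2068)
        assert s["max_min_length_bp"] == 4055

    def test_single_tract_mean_equals_max(self):
        ts = TractSet(
            tracts=[CoConversionTract("A", ("PSV1", "PSV7"), ("G", "A"), None, 9023)],
            total_conversions=2,
        )
        s = tract_stats(ts)
        assert s["mean_min_length_bp"] == s["max_min_length_bp"] == 9023

    def test_fraction_of_events_explained(self):
        # 18 tracts jointly covering 49 of 107 individual conversions
        tracts = []
        sizes = [3] * 13 + [2] * 5  # sums to 49
        for i, size in enumerate(sizes):
            ids = tuple(f"PSV{j}" for j in range(size))
            tracts.append(CoConversionTract(f"H{i}", ids, ("G",) * size, PROXIMAL, 100))
        ts = TractSet(tracts=tracts, total_conversions=107)
        s = tract_stats(ts)
        assert s["n_tracts_multi"] == 18
        assert s["explained_conversions"] == 49
        assert s["fraction_explained"] == pytest.approx(0.458, abs=0.001)

    def test_empty_set_is_empty_summary(self):
        s = tract_stats(TractSet(tracts=[], total_conversions=0))
        assert s["mean_min_length_bp"] is None
        assert s["fraction_explained"] is None


class TestBorrowPhase:
    def test_concordant_haplogroup_lends_phase(self):
        tree = build_tree("((A,B)AB,C)ROOT;", {"a1": "A", "a2": "A", "c1": "C"})
        extended = borrow_phase(tree, {"a1": Orientation.INVERTED})
        assert extended["a2"] is Orientation.INVERTED
        assert "c1" not in extended

    def test_discordant_haplogroup_lends_nothing(self):
        tree = build_tree("((A,B)AB,C)ROOT;",
                          {"a1": "A", "a2": "A", "a3": "A"})
        extended = borrow_phase(
            tree, {"a1": Orientation.INVERTED, "a2": Orientation.SAME}
        )
        assert "a3" not in extended
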