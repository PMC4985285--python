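import math

import numpy as np
import pytest

from sdabkit.alphabet import reverse_complement, translate
from sdabkit.diversity import CdrDesign, LibraryDesign, PositionProfile
from sdabkit.scaffold import humanized_scaffold
from sdabkit.simulate import (
    DefectConfig,
    PlatformProfile,
    apply_defects,
    emit_reads,
    generate_cytometry_events,
    generate_library,
    inject_defect,
    make_sanger_fixture,
    simulate_panning_pool,
)


def point_mass_design():
    pm = PositionProfile({"A": 1.0})
    return LibraryDesign.from_cdr_designs(
        humanized_scaffold(),
        CdrDesign("CDR1", (pm,) * 7),
        CdrDesign("CDR2", (pm,) * 7),
        CdrDesign("CDR3", (pm,) * 9, {9: 1.0}),
    )


class TestGenerateLibrary:
    def test_cdr12_lengths_fixed_at_seven(self, library_1k):
        assert all(len(c.cdr_seqs["CDR1"]) == 7 for c in library_1k)
        assert all(len(c.cdr_seqs["CDR2"]) == 7 for c in library_1k)

    def test_ok_clones_translate_cleanly(self, library_1k):
        for clone in library_1k[:100]:
            assert translate(clone.dna) == clone.protein
            assert "*" not in clone.protein

    def test_point_mass_design_gives_identical_clones(self):
        clones = generate_library(point_mass_design(), 20, seed=3)
        assert len({c.dna for c in clones}) == 1
        assert clones[0].cdr_seqs["CDR3"] == "A" * 9

    def test_reproducible_under_fixed_seed(self, design):
        a = generate_library(design, 50, seed=11)
        b = generate_library(design, 50, seed=11)
        assert [c.dna for c in a] == [c.dna for c in b]

    def test_per_position_frequencies_within_3_sigma(self, design):
        # binomial sampling bands around the design profile
        m = 20_000
        clones = generate_library(design, m, seed=5)
        for position in (0, 3, 6):
            profile = design.cdr1.profiles[position]
            observed = np.array([c.cdr_seqs["CDR1"][position] for c in clones])
            for aa in profile.support():
                p = profile[aa]
                sigma = math.sqrt(p * (1 - p) / m)
                freq = float(np.mean(observed == aa))
                assert abs(freq - p) <= 3 * sigma + 1e-9


class TestInjectDefect:
    @pytest.fixture()
    def clone(self, library_1k):
        return library_1k[0]

    def test_frameshift_deletes_exactly_one_base(self, clone):
        mutated = inject_defect(clone, "frameshift", seed=1)
        assert len(mutated.dna) == len(clone.dna) - 1
        assert mutated.truth_defect == "frameshift"

    def test_ok_class_is_identity(self, clone):
        assert inject_defect(clone, "ok", seed=1) is clone

    def test_in_frame_stop_visible_by_translate_and_scan(self, clone):
        mutated = inject_defect(clone, "in_frame_stop", seed=2)
        protein = translate(mutated.dna)
        fr4_len = clone.region_map["FR4"].length
        assert "*" in protein[:-fr4_len]  # stop appears before FR4 ends
        assert len(mutated.dna) == len(clone.dna)

    def test_missing_region_excises_cdr1_or_through_cdr2(self, clone):
        seen = set()
        for seed in range(12):
            mutated = inject_defect(clone, "missing_region", seed=seed)
            seen.add(len(clone.dna) - len(mutated.dna))
        # CDR1 alone is 21 nt; CDR1-FR2-CDR2 is 21+60+21 nt
        assert seen <= {21, 102}
        assert seen == {21, 102}

    def test_empty_replaces_insert_with_stuffer(self, clone):
        mutated = inject_defect(clone, "empty", seed=1)
        assert mutated.dna != clone.dna
        assert mutated.region_map is None
        # re-emptying an empty clone is a flagged no-op
        assert inject_defect(mutated, "empty", seed=2) is mutated

    def test_unknown_class_rejected(self, clone):
        with pytest.raises(ValueError):
            inject_defect(clone, "bogus", seed=1)


class TestSangerFixture:
    def test_exactly_315_records_13_defective(self, sanger):
        clones, truth = sanger
        assert len(clones) == 315
        assert (truth["truth_defect"] != "ok").sum() == 13

    def test_default_class_split(self, sanger):
        _, truth = sanger
        counts = truth["truth_defect"].value_counts()
        assert counts["in_frame_stop"] == 4
        assert counts["frameshift"] == 4
        assert counts["missing_region"] == 3
        assert counts["empty"] == 2

    def test_byte_identical_under_pinned_seed(self, sanger):
        clones_again, truth_again = make_sanger_fixture()
        assert [c.dna for c in clones_again] == [c.dna for c in sanger[0]]
        assert truth_again.equals(sanger[1])

    def test_zero_defect_config(self):
        clones, truth = make_sanger_fixture(
            config=DefectConfig(counts={"frameshift": 0})
        )
        assert (truth["truth_defect"] == "ok").all()

    def test_apply_defects_bounds(self, library_1k):
        with pytest.raises(ValueError):
            apply_defects(library_1k[:5], DefectConfig(), seed=0)


class TestEmitReads:
    def test_zero_noise_reads_equal_clone_dna(self, library_1k):
        reads = emit_reads(library_1k[:20], seed=0)
        for read, clone in zip(reads.reads, library_1k):
            assert read.sequence == clone.dna
            assert not read.flipped

    def test_flip_probability_one_is_an_involution(self, library_1k):
        clones = library_1k[:20]
        reads = emit_reads(clones, PlatformProfile(flip_probability=1.0), seed=0)
        assert all(r.flipped for r in reads.reads)
        for read, clone in zip(reads.reads, clones):
            assert reverse_complement(read.sequence) == clone.dna

    def test_substitution_rate_within_3_sigma(self, library_10k):
        rate = 0.01
        clones = library_10k
        reads = emit_reads(clones, PlatformProfile(substitution_rate=rate), seed=4)
        mismatches = bases = 0
        for read, clone in zip(reads.reads, clones):
            bases += len(clone.dna)
            mismatches += sum(a != b for a, b in zip(read.sequence, clone.dna))
        observed = mismatches / bases
        sigma = math.sqrt(rate * (1 - rate) / bases)
        assert abs(observed - rate) <= 3 * sigma

    def test_quality_string_matches_length(self, library_1k):
        reads = emit_reads(library_1k[:5], seed=0, with_quality=True)
        for read in reads.reads:
            assert len(read.quality) == len(read.sequence)


class TestCytometryEvents:
    def test_zero_transfected_fraction_single_population(self):
        table = generate_cytometry_events(1000, 0.0, (30.0, 100.0), seed=1)
        assert not table["transfected"].any()

    def test_deterministic_under_seed(self):
        a = generate_cytometry_events(500, 0.4, (30.0, 100.0), seed=9)
        b = generate_cytometry_events(500, 0.4, (30.0, 100.0), seed=9)
        assert a.equals(b)

    def test_channels_positive(self):
        table = generate_cytometry_events(2000, 0.5, (30.0, 100.0), seed=2)
        assert (table[["gfp", "mcherry"]] > 0).all().all()


class TestPanningPool:
    def test_equal_factors_leave_frequencies_unchanged(self):
        pools = simulate_panning_pool(
            {"a": 0.2, "b": 0.3, "c": 0.5}, {"a": 2.0, "b": 2.0, "c": 2.0}, 4
        )
        for _, row in pools.iterrows():
            assert row.to_dict() == pytest.approx({"a": 0.2, "b": 0.3, "c": 0.5})

    def test_enriched_clone_crosses_half_at_predicted_round(self):
        # f_r = f0*g^r / (f0*g^r + (1-f0)); crossing when f0*g^r > 1-f0
        f0, g = 0.01, 10.0
        predicted = math.ceil(math.log((1 - f0) / f0) / math.log(g))
        others = {f"c{i}": (1 - f0) / 99 for i in range(99)}
        pools = simulate_panning_pool(
            {"hit": f0, **others}, {"hit": g}, rounds=predicted
        )
        assert pools["hit"].iloc[predicted] > 0.5
        assert pools["hit"].iloc[predicted - 1] <= 0.5

    def test_rows_normalized(self):
        pools = simulate_panning_pool({"a": 1.0, "b": 3.0}, {"a": 5.0}, 6)
        assert np.allclose(pools.sum(axis=1), 1.0)
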