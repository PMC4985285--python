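import itertools
import math
from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from sdabkit.alphabet import AMINO_ACIDS, CODON_TO_AA, STOP_CODONS
from sdabkit.diversity import (
    CdrDesign,
    LibraryDesign,
    PositionProfile,
    ProfileError,
    codon_mix_for_profile,
    collision_probability,
    compare_profiles,
    constrain_profile,
    default_library_design,
    default_position_profile,
    nnk_codon_profile,
    profile_from_repertoire,
    profiles_from_frame,
    profiles_to_frame,
    sequence_space_size,
)

# hypothesis strategy: random valid profiles over a random residue subset
@st.composite
def profiles(draw, min_support=1, alphabet=AMINO_ACIDS):
    support = draw(st.lists(st.sampled_from(alphabet), min_size=min_support,
                            max_size=len(alphabet), unique=True))
    weights = draw(st.lists(st.floats(0.01, 1.0), min_size=len(support),
                            max_size=len(support)))
    total = sum(weights)
    return PositionProfile({aa: w / total for aa, w in zip(support, weights)})


class TestPositionProfile:
    def test_mass_must_sum_to_one(self):
        with pytest.raises(ProfileError):
            PositionProfile({"A": 0.6, "G": 0.5})

    def test_zero_mass_residues_dropped_from_support(self):
        profile = PositionProfile({"A": 1.0, "G": 0.0})
        assert profile.support() == ("A",)

    def test_tsv_round_trip(self):
        original = [PositionProfile({"A": 0.25, "Y": 0.75}),
                    PositionProfile({"G": 1.0})]
        recovered = profiles_from_frame(profiles_to_frame(original))
        for a, b in zip(original, recovered):
            assert a.probs == pytest.approx(b.probs)


class TestProfileFromRepertoire:
    def test_direct_counting(self):
        p1, p2 = profile_from_repertoire(["AY", "AY", "GY"])
        assert p1.probs == pytest.approx({"A": 2 / 3, "G": 1 / 3})
        assert p2.probs == pytest.approx({"Y": 1.0})

    def test_single_sequence_gives_point_masses(self):
        for profile, aa in zip(profile_from_repertoire(["QVQ"]), "QVQ"):
            assert profile.probs == {aa: 1.0}

    def test_matches_exhaustive_counts_on_random_alignment(self):
        rng = np.random.default_rng(42)
        alignment = ["".join(rng.choice(list(AMINO_ACIDS), 7)) for _ in range(50)]
        for i, profile in enumerate(profile_from_repertoire(alignment)):
            counts = Counter(s[i] for s in alignment)
            expected = {aa: c / 50 for aa, c in counts.items()}
            assert profile.probs == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ProfileError):
            profile_from_repertoire([])
        with pytest.raises(ProfileError):
            profile_from_repertoire(["AA", "A"])


class TestConstrainProfile:
    def test_forced_cap_example(self):
        result = constrain_profile(
            PositionProfile({"F": 0.5, "A": 0.5}),
            banned=frozenset(), hydrophobic_set=frozenset("F"), cap=0.1,
        )
        assert result.probs == pytest.approx({"F": 0.1, "A": 0.9})

    def test_banning_cys_on_cys_free_profile_is_identity(self):
        profile = PositionProfile({"A": 0.4, "G": 0.6})
        result = constrain_profile(profile, banned=frozenset("C"), cap=1.0)
        assert result.probs == pytest.approx(profile.probs)

    def test_all_mass_banned_is_an_error(self):
        with pytest.raises(ProfileError):
            constrain_profile(PositionProfile({"C": 1.0}), banned=frozenset("C"))

    @given(profiles(min_support=3))
    @settings(max_examples=60, deadline=None)
    def test_cap_and_normalization_properties(self, profile):
        assume(set(profile.support()) - set("CFILMVW"))  # cap must be feasible
        result = constrain_profile(profile, banned=frozenset("C"), cap=0.15)
        assert math.fsum(result.probs.values()) == pytest.approx(1.0, abs=1e-12)
        assert result.mass("FILMVW") <= 0.15 + 1e-12
        assert result["C"] == 0.0


class TestCodonMix:
    def test_point_mass_with_explicit_codon(self):
        mix = codon_mix_for_profile(PositionProfile({"A": 1.0}), {"A": "GCT"})
        assert mix.fractions == {"GCT": 1.0}

    def test_missing_codon_assignment(self):
        with pytest.raises(ProfileError):
            codon_mix_for_profile(PositionProfile({"A": 1.0}), {"G": "GGT"})

    @given(profiles())
    @settings(max_examples=60, deadline=None)
    def test_translation_exactness_and_no_stops(self, profile):
        mix = codon_mix_for_profile(profile)
        translated = mix.translated_profile()
        for aa in AMINO_ACIDS:
            assert abs(translated[aa] - profile[aa]) <= 1e-12
        assert not set(mix.fractions) & STOP_CODONS

    @given(profiles(alphabet=AMINO_ACIDS.replace("C", "")))
    @settings(max_examples=30, deadline=None)
    def test_no_cys_codon_when_cys_banned(self, profile):
        mix = codon_mix_for_profile(profile)
        assert all(CODON_TO_AA[c] != "C" for c in mix.fractions)

    def test_nnk_comparison_mode_has_stop_and_cys_mass(self):
        nnk = nnk_codon_profile()
        assert nnk["*"] == pytest.approx(1 / 32)
        assert nnk["C"] > 0


class TestSequenceSpaceSize:
    @staticmethod
    def _design(cdr3_profiles, weights, point="A"):
        from sdabkit.scaffold import humanized_scaffold
        pm = PositionProfile({point: 1.0})
        return LibraryDesign.from_cdr_designs(
            humanized_scaffold(),
            CdrDesign("CDR1", (pm,) * 7),
            CdrDesign("CDR2", (pm,) * 7),
            CdrDesign("CDR3", tuple(cdr3_profiles), weights),
        )

    def test_cdr3_only_19_support_length_9(self):
        support19 = PositionProfile.uniform(AMINO_ACIDS.replace("C", ""))
        design = self._design((support19,) * 9, {9: 1.0})
        assert sequence_space_size(design) == 19 ** 9

    def test_all_point_mass_is_one(self):
        design = self._design((PositionProfile({"G": 1.0}),) * 9, {9: 1.0})
        assert sequence_space_size(design) == 1

    def test_matches_exhaustive_enumeration_on_toy_design(self):
        p = PositionProfile({"A": 0.5, "G": 0.3, "S": 0.2})
        design = self._design((p, p), {1: 0.5, 2: 0.5})
        enumerated = set()
        for length in (1, 2):
            for combo in itertools.product("AGS", repeat=length):
                enumerated.add("".join(combo))
        assert sequence_space_size(design) == len(enumerated) == 12

    def test_default_design_exact_integer(self, design):
        size = sequence_space_size(design)
        # 19-residue support at every CDR position, lengths 9/12/15/18
        assert size == 19 ** 14 * sum(19 ** L for L in (9, 12, 15, 18))


class TestCollisionProbability:
    def test_trivial_cases(self):
        assert collision_probability(1, 10 ** 9) == 0.0
        assert collision_probability(0, 5) == 0.0
        assert collision_probability(3, 2) == 1.0

    def test_matches_extended_precision_oracle(self):
        n, N = 315, 3_000_000_000
        no_collision = Fraction(1)
        for i in range(1, n):
            no_collision *= Fraction(N - i, N)
        oracle = float(1 - no_collision)
        value = collision_probability(n, N)
        assert value == pytest.approx(oracle, rel=1e-12)
        assert value == pytest.approx(1.6484864699183845e-05, rel=1e-12)

    def test_approximation_close_to_exact(self):
        exact = collision_probability(315, 3_000_000_000)
        approx = collision_probability(315, 3_000_000_000, method="approx")
        assert approx == pytest.approx(exact, rel=1e-4)

    @given(st.integers(2, 500), st.integers(500, 10 ** 6))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_n_and_N(self, n, N):
        p = collision_probability(n, N)
        assert collision_probability(n + 1, N) >= p
        assert collision_probability(n, 2 * N) <= p
        assert 0.0 <= p <= 1.0


class TestCompareProfiles:
    def test_identical_lists_distance_zero(self):
        p = [default_position_profile()] * 3
        report = compare_profiles(p, p)
        assert (report["tv"] == 0.0).all()

    def test_disjoint_point_masses_distance_one(self):
        a = [PositionProfile({"A": 1.0})]
        b = [PositionProfile({"Y": 1.0})]
        assert compare_profiles(a, b)["tv"].iloc[0] == pytest.approx(1.0)

    @given(profiles(), profiles())
    @settings(max_examples=60, deadline=None)
    def test_tv_equals_direct_sum_and_symmetry(self, p, q):
        forward = compare_profiles([p], [q])["tv"].iloc[0]
        backward = compare_profiles([q], [p])["tv"].iloc[0]
        direct = 0.5 * sum(abs(p[aa] - q[aa]) for aa in AMINO_ACIDS)
        assert forward == pytest.approx(direct, abs=1e-12)
        assert forward == pytest.approx(backward, abs=1e-15)
        assert 0.0 <= forward <= 1.0


class TestDefaultDesign:
    def test_profiles_cys_free_and_capped(self, design):
        for cdr in (design.cdr1, design.cdr2, design.cdr3):
            for profile in cdr.profiles:
                assert profile["C"] == 0.0
                assert profile.mass("FILMVW") <= 0.15 + 1e-12
                assert math.fsum(profile.probs.values()) == pytest.approx(1.0)

    def test_cdr3_length_mixture_uniform(self, design):
        assert design.cdr3.length_weights == {9: 0.25, 12: 0.25, 15: 0.25, 18: 0.25}

    def test_template_count_exceeds_library_size(self, design):
        assert design.template_molecules >= design.library_size == 3_000_000_000
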