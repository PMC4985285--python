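"""Single-domain antibody scaffold model.

A scaffold is the constant part of a single-domain antibody: four framework
segments (FR1..FR4) flanking three CDR slots.  Positions are scaffold-local,
1-based and sequential on the *reference map* (the map whose CDR3 slot has
the reference length); an alias map can be supplied by users who prefer a
published numbering scheme.

The module provides region segmentation, per-column consensus derivation,
rule-based framework humanization (which must never touch the solubility
hallmark positions), and CDR grafting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .alphabet import AMINO_ACIDS, reverse_translate

REGION_ORDER: tuple[str, ...] = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
FRAMEWORK_REGIONS: tuple[str, ...] = ("FR1", "FR2", "FR3", "FR4")
CDR_REGIONS: tuple[str, ...] = ("CDR1", "CDR2", "CDR3")

#: Fixed CDR1/CDR2 design length and the allowed CDR3 design lengths.
CDR12_LENGTH: int = 7
CDR3_LENGTHS: tuple[int, ...] = (9, 12, 15, 18)
REFERENCE_CDR3_LENGTH: int = 12


class SegmentationError(ValueError):
    """Sequence length does not match the region map span."""


class HumanizationError(ValueError):
    """A humanization rule targets a protected or out-of-framework position."""


class GraftError(ValueError):
    """A CDR of disallowed length was grafted without an override."""


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.name not in REGION_ORDER:
            raise ValueError(f"unknown region name {self.name!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad span {self.start}..{self.end} for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def slice(self) -> slice:
        """0-based half-open slice for internal indexing."""
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class RegionMap:
    """Ordered, contiguous FR/CDR segmentation of a scaffold sequence."""

    regions: tuple[Region, ...]
    numbering_scheme: str = "scaffold-local sequential (1-based)"

    def __post_init__(self) -> None:
        names = tuple(r.name for r in self.regions)
        if names != REGION_ORDER:
            raise ValueError(f"regions must be exactly {REGION_ORDER}, got {names}")
        expected = 1
        for region in self.regions:
            if region.start != expected:
                raise ValueError(
                    f"{region.name} starts at {region.start}, expected {expected} "
                    "(regions must be contiguous and non-overlapping)"
                )
            expected = region.end + 1

    @property
    def span(self) -> int:
        return self.regions[-1].end

    def __getitem__(self, name: str) -> Region:
        for region in self.regions:
            if region.name == name:
                return region
        raise KeyError(name)

    def region_of(self, position: int) -> tuple[str, int]:
        """Map a 1-based scaffold position to ``(region_name, 0-based offset)``."""
        for region in self.regions:
            if region.start <= position <= region.end:
                return region.name, position - region.start
        raise ValueError(f"position {position} outside map span 1..{self.span}")


def build_region_map(
    fr_lengths: tuple[int, int, int, int],
    cdr3_length: int = REFERENCE_CDR3_LENGTH,
    cdr12_length: int = CDR12_LENGTH,
) -> RegionMap:
    """Assemble a contiguous region map from segment lengths."""
    lengths = {
        "FR1": fr_lengths[0], "CDR1": cdr12_length, "FR2": fr_lengths[1],
        "CDR2": cdr12_length, "FR3": fr_lengths[2], "CDR3": cdr3_length,
        "FR4": fr_lengths[3],
    }
    regions = []
    start = 1
    for name in REGION_ORDER:
        end = start + lengths[name] - 1
        regions.append(Region(name, start, end))
        start = end + 1
    return RegionMap(tuple(regions))


@dataclass(frozen=True)
class ScaffoldModel:
    """Framework residues plus region geometry and hallmark constraints.

    ``hallmarks`` maps reference-map positions to their required residues.
    Internally hallmarks are tracked by (region, offset) so the constraint
    survives CDR3 length changes that shift downstream numbering.
    """

    name: str
    frameworks: dict[str, str]
    region_map: RegionMap
    hallmarks: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fr in FRAMEWORK_REGIONS:
            if fr not in self.frameworks:
                raise ValueError(f"missing framework segment {fr}")
            if len(self.frameworks[fr]) != self.region_map[fr].length:
                raise ValueError(
                    f"{fr} has {len(self.frameworks[fr])} residues but the map "
                    f"allots {self.region_map[fr].length}"
                )
        for pos, residue in self.hallmarks.items():
            region, offset = self.region_map.region_of(pos)
            if region not in FRAMEWORK_REGIONS:
                raise ValueError(f"hallmark {pos} falls in {region}, not a framework")
            actual = self.frameworks[region][offset]
            if actual != residue:
                raise ValueError(
                    f"hallmark {pos} requires {residue} but scaffold has {actual}"
                )

    def framework_residue(self, position: int) -> str:
        region, offset = self.region_map.region_of(position)
        if region not in FRAMEWORK_REGIONS:
            raise ValueError(f"position {position} is in {region}, not a framework")
        return self.frameworks[region][offset]

    def framework_dna(self) -> dict[str, str]:
        """Preferred-codon DNA for each framework segment."""
        return {fr: reverse_translate(seq) for fr, seq in self.frameworks.items()}

    def map_for_cdr3(self, cdr3_length: int) -> RegionMap:
        """Region map with the CDR3 slot resized to ``cdr3_length``."""
        fr_lengths = tuple(self.region_map[fr].length for fr in FRAMEWORK_REGIONS)
        return build_region_map(fr_lengths, cdr3_length,
                                self.region_map["CDR1"].length)


@dataclass(frozen=True)
class HumanizationRuleSet:
    """Point substitutions toward a human framework, plus protected positions.

    Substitution positions and protected positions must be disjoint; hallmark
    positions are implicitly protected on application.
    """

    substitutions: tuple[tuple[int, str], ...]
    protected: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        positions = [pos for pos, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate substitution positions")
        overlap = set(positions) & self.protected
        if overlap:
            raise ValueError(f"substitutions target protected positions {sorted(overlap)}")


def segment_sequence(protein: str, region_map: RegionMap) -> dict[str, str]:
    """Split a full-length protein into its 7 region substrings.

    Raises :class:`SegmentationError` when the sequence length does not equal
    the map span.  The concatenation of the returned values always reproduces
    the input.
    """
    if len(protein) != region_map.span:
        raise SegmentationError(
            f"sequence length {len(protein)} != map span {region_map.span}"
        )
    return {r.name: protein[r.slice] for r in region_map.regions}


def derive_consensus(sequences: list[str]) -> tuple[str, list[dict[str, float]]]:
    """Per-column modal consensus of an aligned set of protein sequences.

    Returns the consensus string and a per-column residue frequency table
    (relative frequencies, summing to 1 per column).  Ties are broken
    alphabetically by one-letter code, deterministically.
    """
    if not sequences:
        raise ValueError("cannot derive a consensus from an empty alignment")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("aligned sequences must all have equal length")
    consensus = []
    columns: list[dict[str, float]] = []
    n = len(sequences)
    for i in range(length):
        counts = Counter(s[i] for s in sequences)
        # max count, alphabetical tie-break
        best = min(sorted(counts), key=lambda aa: (-counts[aa], aa))
        consensus.append(best)
        columns.append({aa: c / n for aa, c in sorted(counts.items())})
    return "".join(consensus), columns


def humanize(scaffold: ScaffoldModel, rules: HumanizationRuleSet) -> ScaffoldModel:
    """Apply framework substitutions; hallmark positions are inviolable.

    The output differs from the input at exactly the rule positions whose
    target residue differs from the current one (re-applying the same rules
    is therefore idempotent).
    """
    protected = set(rules.protected) | set(scaffold.hallmarks)
    frameworks = {fr: list(seq) for fr, seq in scaffold.frameworks.items()}
    for pos, target in rules.substitutions:
        if target not in AMINO_ACIDS:
            raise HumanizationError(f"invalid target residue {target!r} at {pos}")
        if pos in protected:
            raise HumanizationError(f"rule targets protected/hallmark position {pos}")
        region, offset = scaffold.region_map.region_of(pos)
        if region not in FRAMEWORK_REGIONS:
            raise HumanizationError(f"rule position {pos} is in {region}, not a framework")
        frameworks[region][offset] = target
    result = replace(
        scaffold,
        frameworks={fr: "".join(seq) for fr, seq in frameworks.items()},
    )
    for pos, residue in scaffold.hallmarks.items():  # paranoid post-condition
        assert result.framework_residue(pos) == residue
    return result


def graft_cdrs(
    scaffold: ScaffoldModel,
    cdr1: str,
    cdr2: str,
    cdr3: str,
    allow_nonstandard_lengths: bool = False,
) -> str:
    """Insert three CDR loops into the scaffold and return the full protein.

    CDR1/CDR2 must have the fixed design length and CDR3 one of the design
    lengths unless ``allow_nonstandard_lengths`` is set (CDR1/CDR2 overrides
    still require the map's slot length to be respected for CDR1/CDR2, so
    only CDR3 is free-length under override).
    """
    want12 = scaffold.region_map["CDR1"].length
    if len(cdr1) != want12 or len(cdr2) != want12:
        raise GraftError(
            f"CDR1/CDR2 must be length {want12}, got {len(cdr1)}/{len(cdr2)}"
        )
    if len(cdr3) not in CDR3_LENGTHS and not allow_nonstandard_lengths:
        raise GraftError(
            f"CDR3 length {len(cdr3)} not in design lengths {CDR3_LENGTHS}; "
            "pass allow_nonstandard_lengths=True to override"
        )
    f = scaffold.frameworks
    return f["FR1"] + cdr1 + f["FR2"] + cdr2 + f["FR3"] + cdr3 + f["FR4"]


# ---------------------------------------------------------------------------
# Packaged baseline scaffold fixture
# ---------------------------------------------------------------------------
# Synthetic but realistically proportioned camelid-style single-domain
# framework: 118 residues on the reference map (CDR3 = 12).  Hallmarks are
# the framework-2 solubility tetrad at 42/49/50/52 and the Gln at 103.

_BASELINE_FR1 = "QVQLQESGGGLVQAGGSLRLSCAASG"            # 1..26
_BASELINE_FR2 = "WVRQAPGKFLEWVSAERTGS"                  # 34..53 (F42 E49 R50 G52)
_BASELINE_FR3 = "RFTISRDNAKNTVYLQMNSLRAEDTAVYYC"        # 61..90
_BASELINE_FR4 = "QWGQGTQVTVSSGSEL"                      # 103..118 (Q103)

DEFAULT_HALLMARKS: dict[int, str] = {42: "F", 49: "E", 50: "R", 52: "G", 103: "Q"}

#: Divergent camelid residues deliberately retained during humanization.
DEFAULT_RETAINED_POSITIONS: frozenset[int] = frozenset({37, 44, 47, 84, 87})


def baseline_scaffold() -> ScaffoldModel:
    """The packaged pre-humanization consensus scaffold fixture."""
    region_map = build_region_map((26, 20, 30, 16))
    return ScaffoldModel(
        name="baseline-sdab",
        frameworks={
            "FR1": _BASELINE_FR1, "FR2": _BASELINE_FR2,
            "FR3": _BASELINE_FR3, "FR4": _BASELINE_FR4,
        },
        region_map=region_map,
        hallmarks=dict(DEFAULT_HALLMARKS),
    )


def default_humanization_rules() -> HumanizationRuleSet:
    """The packaged 7-substitution rule set (framework positions only).

    Exactly seven framework residues are moved toward the human VH3
    consensus while the framework-2 hallmarks, Q103 and five divergent
    residues are kept untouched.
    """
    return HumanizationRuleSet(
        substitutions=(
            (5, "V"),    # FR1
            (14, "P"),   # FR1
            (23, "K"),   # FR1
            (64, "V"),   # FR3
            (75, "A"),   # FR3
            (83, "K"),   # FR3
            (108, "L"),  # FR4
        ),
        protected=DEFAULT_RETAINED_POSITIONS,
    )


def humanized_scaffold() -> ScaffoldModel:
    """Baseline scaffold with the default humanization rules applied."""
    model = humanize(baseline_scaffold(), default_humanization_rules())
    return replace(model, name="humanized-sdab")
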