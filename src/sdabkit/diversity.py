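"""Rational CDR diversity design.

Per-position categorical amino-acid profiles (with residue bans and a cap on
aggregate hydrophobic mass), a CDR3 length mixture, and whole-codon
(trinucleotide) mixes that realize each profile *exactly* at the DNA level —
no stop codons, no banned residues, in contrast to NNN/NNK degenerate
randomization which cannot exclude either.

Also provides the design-side counting statistics: exact sequence-space
size and the birthday-collision probability used to interpret "no redundant
clone" observations in a finite sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .alphabet import (
    AMINO_ACIDS,
    CODON_TO_AA,
    HYDROPHOBIC_RESIDUES,
    PREFERRED_CODON,
    STOP_CODONS,
)
from .scaffold import CDR3_LENGTHS, CDR12_LENGTH, ScaffoldModel, humanized_scaffold

_NORM_TOL = 1e-9

DEFAULT_HYDROPHOBIC_CAP = 0.15
DEFAULT_BANNED = frozenset("C")


class ProfileError(ValueError):
    """Invalid positional profile (bad mass, empty support, ...)."""


@dataclass(frozen=True)
class PositionProfile:
    """Categorical distribution over the 20 canonical residues at one position."""

    probs: dict[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for aa, p in self.probs.items():
            if aa not in AMINO_ACIDS:
                raise ProfileError(f"unknown residue {aa!r}")
            if p < 0:
                raise ProfileError(f"negative probability for {aa}")
            if p > 0:
                clean[aa] = float(p)
        if not clean:
            raise ProfileError("profile has empty support")
        total = math.fsum(clean.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise ProfileError(f"profile mass {total} != 1")
        object.__setattr__(self, "probs", clean)

    @classmethod
    def point_mass(cls, residue: str) -> "PositionProfile":
        return cls({residue: 1.0})

    @classmethod
    def uniform(cls, residues: str = AMINO_ACIDS) -> "PositionProfile":
        return cls({aa: 1.0 / len(residues) for aa in residues})

    def support(self) -> tuple[str, ...]:
        return tuple(sorted(self.probs))

    def mass(self, residues) -> float:
        return math.fsum(self.probs.get(aa, 0.0) for aa in residues)

    def __getitem__(self, residue: str) -> float:
        return self.probs.get(residue, 0.0)


@dataclass(frozen=True)
class CodonMix:
    """Trinucleotide fractions realizing one positional residue profile."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for codon, frac in self.fractions.items():
            if codon in STOP_CODONS:
                raise ProfileError(f"stop codon {codon} in mix")
            if codon not in CODON_TO_AA:
                raise ProfileError(f"invalid codon {codon!r}")
            if frac < 0:
                raise ProfileError(f"negative fraction for {codon}")
        total = math.fsum(self.fractions.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise ProfileError(f"codon mix mass {total} != 1")

    def translated_profile(self) -> PositionProfile:
        probs: dict[str, float] = {}
        for codon, frac in self.fractions.items():
            aa = CODON_TO_AA[codon]
            probs[aa] = probs.get(aa, 0.0) + frac
        return PositionProfile(probs)


@dataclass(frozen=True)
class CdrDesign:
    """Positional profiles for one CDR; CDR3 additionally carries a length mix.

    For a variable-length CDR3 the profile list covers the longest design
    length and a sampled loop of length ``L`` uses the first ``L`` profiles.
    """

    region_name: str
    profiles: tuple[PositionProfile, ...]
    length_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.region_name in ("CDR1", "CDR2"):
            if len(self.profiles) != CDR12_LENGTH:
                raise ProfileError(
                    f"{self.region_name} needs exactly {CDR12_LENGTH} profiles"
                )
            if self.length_weights is not None:
                raise ProfileError("fixed-length CDRs take no length mixture")
        elif self.region_name == "CDR3":
            if self.length_weights is None:
                raise ProfileError("CDR3 requires a length mixture")
            if abs(math.fsum(self.length_weights.values()) - 1.0) > _NORM_TOL:
                raise ProfileError("CDR3 length weights must sum to 1")
            if len(self.profiles) < max(self.length_weights):
                raise ProfileError("not enough CDR3 profiles for the longest length")
        else:
            raise ProfileError(f"unknown CDR {self.region_name!r}")

    def lengths(self) -> tuple[int, ...]:
        if self.length_weights is None:
            return (len(self.profiles),)
        return tuple(sorted(L for L, w in self.length_weights.items() if w > 0))

    def profiles_for_length(self, length: int) -> tuple[PositionProfile, ...]:
        return self.profiles[:length]


@dataclass(frozen=True)
class LibraryDesign:
    """Complete library recipe: scaffold + CDR designs + codon realization."""

    scaffold: ScaffoldModel
    cdr1: CdrDesign
    cdr2: CdrDesign
    cdr3: CdrDesign
    codon_mixes: dict[str, tuple[CodonMix, ...]] = field(default_factory=dict)
    library_size: int = 3_000_000_000
    template_molecules: int = 200_000_000_000

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.template_molecules < self.library_size:
            raise ValueError("template_molecules must be >= library_size")

    def cdr(self, region: str) -> CdrDesign:
        return {"CDR1": self.cdr1, "CDR2": self.cdr2, "CDR3": self.cdr3}[region]

    @classmethod
    def from_cdr_designs(
        cls,
        scaffold: ScaffoldModel,
        cdr1: CdrDesign,
        cdr2: CdrDesign,
        cdr3: CdrDesign,
        codon_choice: dict[str, str] | None = None,
        **kwargs,
    ) -> "LibraryDesign":
        """Build a design with codon mixes derived from the profiles."""
        mixes = {
            region.region_name: tuple(
                codon_mix_for_profile(p, codon_choice) for p in region.profiles
            )
            for region in (cdr1, cdr2, cdr3)
        }
        return cls(scaffold, cdr1, cdr2, cdr3, mixes, **kwargs)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def profile_from_repertoire(aligned_cdrs: list[str],
                            pseudocount: float = 0.0) -> list[PositionProfile]:
    """Per-column relative residue frequencies of an equal-length alignment."""
    if not aligned_cdrs:
        raise ProfileError("empty repertoire")
    length = len(aligned_cdrs[0])
    if any(len(s) != length for s in aligned_cdrs):
        raise ProfileError("repertoire sequences must have equal length")
    profiles = []
    for i in range(length):
        counts = {aa: pseudocount for aa in AMINO_ACIDS} if pseudocount else {}
        for seq in aligned_cdrs:
            counts[seq[i]] = counts.get(seq[i], 0.0) + 1.0
        total = math.fsum(counts.values())
        profiles.append(PositionProfile({aa: c / total for aa, c in counts.items()}))
    return profiles


def constrain_profile(
    profile: PositionProfile,
    banned: frozenset[str] = DEFAULT_BANNED,
    hydrophobic_set: frozenset[str] = HYDROPHOBIC_RESIDUES,
    cap: float = DEFAULT_HYDROPHOBIC_CAP,
) -> PositionProfile:
    """Zero banned residues and cap total hydrophobic mass at ``cap``.

    The hydrophobic residues are scaled down proportionally and the
    remaining mass is redistributed proportionally over the rest, so the
    result sums to 1 with hydrophobic mass exactly ``min(cap, current)``.
    """
    if not 0.0 <= cap <= 1.0:
        raise ProfileError("cap must be in [0, 1]")
    kept = {aa: p for aa, p in profile.probs.items() if aa not in banned}
    if not kept:
        raise ProfileError("all profile mass is banned")
    total = math.fsum(kept.values())
    kept = {aa: p / total for aa, p in kept.items()}
    hydro = math.fsum(p for aa, p in kept.items() if aa in hydrophobic_set)
    if hydro > cap:
        if hydro >= 1.0 - _NORM_TOL:
            raise ProfileError("profile is entirely hydrophobic; cannot cap")
        down = cap / hydro
        up = (1.0 - cap) / (1.0 - hydro)
        kept = {
            aa: p * (down if aa in hydrophobic_set else up)
            for aa, p in kept.items()
        }
    return PositionProfile(kept)


def codon_mix_for_profile(
    profile: PositionProfile,
    codon_choice: dict[str, str] | None = None,
) -> CodonMix:
    """Realize a residue profile as a trinucleotide mix, exactly.

    With one codon per residue (the default table) the translated mix equals
    the profile identically — the guarantee that whole-codon synthesis gives
    and degenerate codons cannot.
    """
    table = codon_choice or PREFERRED_CODON
    fractions: dict[str, float] = {}
    for aa, p in profile.probs.items():
        if aa not in table:
            raise ProfileError(f"no codon assigned for residue {aa}")
        codon = table[aa]
        if CODON_TO_AA.get(codon) != aa:
            raise ProfileError(f"codon {codon} does not encode {aa}")
        fractions[codon] = fractions.get(codon, 0.0) + p
    return CodonMix(fractions)


def nnk_codon_profile() -> dict[str, float]:
    """Amino-acid (+stop) distribution of the degenerate NNK codon scheme.

    Provided for comparison only: unlike trinucleotide mixes it places mass
    on a stop codon (TAG) and on cysteine, which is exactly why it is not
    used for the synthesis route.
    """
    out: dict[str, float] = {}
    for n1 in "ACGT":
        for n2 in "ACGT":
            for n3 in "GT":
                codon = n1 + n2 + n3
                aa = CODON_TO_AA.get(codon, "*")
                out[aa] = out.get(aa, 0.0) + 1.0 / 32.0
    return out


# ---------------------------------------------------------------------------
# Counting statistics
# ---------------------------------------------------------------------------

def sequence_space_size(design: LibraryDesign) -> int:
    """Exact number of distinct CDR-combination proteins the design can emit.

    Product of per-position support sizes, summed over CDR3 lengths; pure
    integer arithmetic.
    """
    def region_count(profiles) -> int:
        count = 1
        for profile in profiles:
            count *= len(profile.support())
        return count

    fixed = region_count(design.cdr1.profiles) * region_count(design.cdr2.profiles)
    total = 0
    for length in design.cdr3.lengths():
        total += region_count(design.cdr3.profiles_for_length(length))
    return fixed * total


def collision_probability(n: int, N: int, method: str = "exact") -> float:
    """Probability that any two of ``n`` uniform draws from ``N`` clones coincide.

    ``exact`` evaluates 1 - prod_{i<n}(1 - i/N) stably via log1p/expm1;
    ``approx`` is the textbook 1 - exp(-n(n-1)/(2N)).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    if n <= 1:
        return 0.0
    if method == "approx":
        return -math.expm1(-n * (n - 1) / (2.0 * N))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n > N:
        return 1.0
    log_no_collision = math.fsum(math.log1p(-i / N) for i in range(1, n))
    return -math.expm1(log_no_collision)


def compare_profiles(
    designed: list[PositionProfile],
    observed: list[PositionProfile],
) -> pd.DataFrame:
    """Per-position total-variation distance between two profile lists.

    Returns a DataFrame with one row per position (column ``tv``); the
    ``.attrs`` carry ``max_tv`` and ``mean_tv``.  Symmetric in its arguments.
    """
    if len(designed) != len(observed):
        raise ValueError("profile lists must have equal length")
    rows = []
    for i, (p, q) in enumerate(zip(designed, observed), start=1):
        tv = 0.5 * math.fsum(
            abs(p[aa] - q[aa]) for aa in AMINO_ACIDS
        )
        rows.append({"position": i, "tv": min(tv, 1.0)})  # clamp float jitter
    frame = pd.DataFrame(rows).set_index("position")
    frame.attrs["max_tv"] = float(frame["tv"].max()) if rows else 0.0
    frame.attrs["mean_tv"] = float(frame["tv"].mean()) if rows else 0.0
    return frame


# ---------------------------------------------------------------------------
# Packaged default design
# ---------------------------------------------------------------------------

#: Natural-repertoire-shaped CDR background composition (before constraints).
NATURAL_CDR_BACKGROUND: dict[str, float] = {
    "G": 0.08, "S": 0.09, "Y": 0.08, "A": 0.07, "D": 0.07, "T": 0.07,
    "R": 0.06, "N": 0.06, "E": 0.05, "K": 0.05, "P": 0.05, "Q": 0.04,
    "H": 0.03, "W": 0.02, "C": 0.02, "F": 0.04, "I": 0.03, "L": 0.04,
    "V": 0.04, "M": 0.01,
}

#: CDR3 length mixture actually observed by deep sequencing of the built
#: library; the design default below is the uniform mixture.
OBSERVED_CDR3_LENGTH_MIX: dict[int, float] = {9: 0.26, 12: 0.272, 15: 0.237, 18: 0.231}


def default_position_profile(
    banned: frozenset[str] = DEFAULT_BANNED,
    cap: float = DEFAULT_HYDROPHOBIC_CAP,
) -> PositionProfile:
    """The constrained natural-background profile used at every CDR position."""
    return constrain_profile(PositionProfile(dict(NATURAL_CDR_BACKGROUND)),
                             banned=banned, cap=cap)


def default_library_design(
    scaffold: ScaffoldModel | None = None,
    cdr3_length_weights: dict[int, float] | None = None,
) -> LibraryDesign:
    """Packaged default design: Cys-free, hydrophobicity-capped CDR profiles,
    fixed 7-residue CDR1/CDR2 and a uniform CDR3 length mixture over
    {9, 12, 15, 18}."""
    scaffold = scaffold or humanized_scaffold()
    base = default_position_profile()
    weights = cdr3_length_weights or {L: 1.0 / len(CDR3_LENGTHS) for L in CDR3_LENGTHS}
    cdr1 = CdrDesign("CDR1", (base,) * CDR12_LENGTH)
    cdr2 = CdrDesign("CDR2", (base,) * CDR12_LENGTH)
    cdr3 = CdrDesign("CDR3", (base,) * max(CDR3_LENGTHS), dict(weights))
    mixes = {
        "CDR1": tuple(codon_mix_for_profile(p) for p in cdr1.profiles),
        "CDR2": tuple(codon_mix_for_profile(p) for p in cdr2.profiles),
        "CDR3": tuple(codon_mix_for_profile(p) for p in cdr3.profiles),
    }
    return LibraryDesign(scaffold, cdr1, cdr2, cdr3, mixes)


# ---------------------------------------------------------------------------
# TSV round-trip (position x residue matrices)
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: list[PositionProfile]) -> pd.DataFrame:
    data = {aa: [p[aa] for p in profiles] for aa in AMINO_ACIDS}
    frame = pd.DataFrame(data, index=range(1, len(profiles) + 1))
    frame.index.name = "position"
    return frame


def profiles_from_frame(frame: pd.DataFrame) -> list[PositionProfile]:
    return [
        PositionProfile({aa: float(row[aa]) for aa in frame.columns if row[aa] > 0})
        for _, row in frame.iterrows()
    ]
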