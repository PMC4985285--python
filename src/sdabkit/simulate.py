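"""In-silico library generation and synthetic assay data.

Generates clone populations from a :class:`~sdabkit.diversity.LibraryDesign`
(DNA realized through the trinucleotide codon mixes), injects the four-class
defect taxonomy observed in colony-sequencing QC (in-frame stop, single-base
frameshift, excised CDR region, empty/stuffer clone), emits reads with a
configurable error model, and produces cytometry-like event tables and
panning-pool frequency trajectories so every downstream analysis stage can
be exercised without external data.

All operations are deterministic under a fixed seed: each takes either an
integer seed or a ``numpy.random.Generator`` and uses a single stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alphabet import CODON_TO_AA, STOP_CODONS, reverse_complement, translate
from .diversity import LibraryDesign, default_library_design
from .scaffold import CDR_REGIONS, RegionMap

DEFECT_CLASSES: tuple[str, ...] = (
    "ok", "in_frame_stop", "frameshift", "missing_region", "empty",
)

#: Pinned seed of the packaged colony-sequencing QC fixture.
SANGER_FIXTURE_SEED: int = 20160719
SANGER_FIXTURE_SIZE: int = 315

#: Default per-class split of the fixture's 13 defective clones (the split
#: itself is a fixture convention; only the total is meaningful).
DEFAULT_DEFECT_COUNTS: dict[str, int] = {
    "in_frame_stop": 4, "frameshift": 4, "missing_region": 3, "empty": 2,
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# Fixed vector-stuffer placeholder for "empty" clones: reproducible junk DNA
# with no framework anchors (stands in for a ccdB-style stuffer cassette).
_STUFFER: str = "".join(
    np.random.default_rng(777).choice(list("ACGT"), size=312)
)


@dataclass(frozen=True)
class CloneRecord:
    """One library member: DNA, protein, CDR annotation and truth label."""

    clone_id: str
    dna: str
    protein: str
    cdr3_length: int
    region_map: RegionMap | None
    cdr_seqs: dict[str, str] | None
    truth_defect: str = "ok"

    def __post_init__(self) -> None:
        if self.truth_defect not in DEFECT_CLASSES:
            raise ValueError(f"unknown defect class {self.truth_defect!r}")

    def region_dna_span(self, region: str) -> tuple[int, int]:
        """0-based half-open nucleotide span of a region within the clone DNA."""
        if self.region_map is None:
            raise ValueError("clone has no region map (defective record)")
        r = self.region_map[region]
        return (r.start - 1) * 3, r.end * 3


@dataclass(frozen=True)
class DefectConfig:
    """How many clones of each defect class to seed into a population."""

    counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DEFECT_COUNTS)
    )

    def __post_init__(self) -> None:
        for cls, count in self.counts.items():
            if cls not in DEFECT_CLASSES or cls == "ok":
                raise ValueError(f"invalid defect class {cls!r}")
            if count < 0:
                raise ValueError("defect counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: str | None = None
    source_id: str | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality string length must match sequence length")


@dataclass(frozen=True)
class PlatformProfile:
    """Sequencing error model: per-base substitution/indel rates, strand flips."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    flip_probability: float = 0.0
    quality_char: str = "I"

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.insertion_rate,
                     self.deletion_rate, self.flip_probability):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class ReadSet:
    reads: tuple[Read, ...]
    profile: PlatformProfile

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def generate_library(design: LibraryDesign, m: int, seed) -> list[CloneRecord]:
    """Draw ``m`` i.i.d. clones from the design via its codon mixes."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = _as_rng(seed)
    scaffold = design.scaffold
    fr_dna = scaffold.framework_dna()
    fr_prot = scaffold.frameworks

    lengths_avail = design.cdr3.lengths()
    if design.cdr3.length_weights is not None:
        weights = np.array(
            [design.cdr3.length_weights[L] for L in lengths_avail], dtype=float
        )
        weights /= weights.sum()
        cdr3_lengths = rng.choice(lengths_avail, size=m, p=weights)
    else:
        cdr3_lengths = np.full(m, lengths_avail[0])

    def draw_codons(region: str, n_positions: int) -> list[np.ndarray]:
        columns = []
        for mix in design.codon_mixes[region][:n_positions]:
            codons = sorted(mix.fractions)
            probs = np.array([mix.fractions[c] for c in codons], dtype=float)
            probs /= probs.sum()
            columns.append(rng.choice(codons, size=m, p=probs))
        return columns

    cdr1_cols = draw_codons("CDR1", len(design.cdr1.profiles))
    cdr2_cols = draw_codons("CDR2", len(design.cdr2.profiles))
    cdr3_cols = draw_codons("CDR3", max(lengths_avail))

    maps = {L: scaffold.map_for_cdr3(int(L)) for L in set(int(x) for x in cdr3_lengths)}
    clones = []
    for i in range(m):
        cdr1_dna = "".join(col[i] for col in cdr1_cols)
        cdr2_dna = "".join(col[i] for col in cdr2_cols)
        L = int(cdr3_lengths[i])
        cdr3_dna = "".join(col[i] for col in cdr3_cols[:L])
        dna = (fr_dna["FR1"] + cdr1_dna + fr_dna["FR2"] + cdr2_dna
               + fr_dna["FR3"] + cdr3_dna + fr_dna["FR4"])
        cdr_seqs = {
            "CDR1": translate(cdr1_dna),
            "CDR2": translate(cdr2_dna),
            "CDR3": translate(cdr3_dna),
        }
        protein = (fr_prot["FR1"] + cdr_seqs["CDR1"] + fr_prot["FR2"]
                   + cdr_seqs["CDR2"] + fr_prot["FR3"] + cdr_seqs["CDR3"]
                   + fr_prot["FR4"])
        clones.append(CloneRecord(
            clone_id=f"clone{i:06d}",
            dna=dna,
            protein=protein,
            cdr3_length=L,
            region_map=maps[L],
            cdr_seqs=cdr_seqs,
        ))
    return clones


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------

def inject_defect(clone: CloneRecord, defect_class: str, seed) -> CloneRecord:
    """Return a copy of ``clone`` carrying the requested defect.

    * ``in_frame_stop`` — one CDR codon replaced by a stop codon, in frame.
    * ``frameshift``    — exactly one base deleted at a uniform position.
    * ``missing_region``— the CDR1 span, or the CDR1-through-CDR2 span
      (including the intervening FR2), excised in frame; variants 50/50.
    * ``empty``         — the insert replaced by the stuffer placeholder.
    """
    if defect_class not in DEFECT_CLASSES:
        raise ValueError(f"unknown defect class {defect_class!r}")
    if defect_class == "ok":
        return clone
    if clone.truth_defect == "empty" and defect_class == "empty":
        return clone  # flagged no-op: already empty
    rng = _as_rng(seed)

    if defect_class == "empty":
        return replace(clone, dna=_STUFFER, protein=translate(_STUFFER),
                       region_map=None, cdr_seqs=None, truth_defect="empty")

    if defect_class == "frameshift":
        pos = int(rng.integers(0, len(clone.dna)))
        dna = clone.dna[:pos] + clone.dna[pos + 1:]
        return replace(clone, dna=dna, protein=translate(dna),
                       cdr_seqs=None, truth_defect="frameshift")

    if defect_class == "missing_region":
        variant = rng.choice(["cdr1", "cdr1_fr2_cdr2"])
        start, end = clone.region_dna_span("CDR1")
        if variant == "cdr1_fr2_cdr2":
            end = clone.region_dna_span("CDR2")[1]
        dna = clone.dna[:start] + clone.dna[end:]
        return replace(clone, dna=dna, protein=translate(dna),
                       region_map=None, cdr_seqs=None,
                       truth_defect="missing_region")

    # in_frame_stop: pick a random CDR codon and replace it with a stop.
    region = rng.choice(list(CDR_REGIONS))
    start, end = clone.region_dna_span(str(region))
    codon_index = int(rng.integers(0, (end - start) // 3))
    stop = rng.choice(sorted(STOP_CODONS))
    pos = start + 3 * codon_index
    dna = clone.dna[:pos] + str(stop) + clone.dna[pos + 3:]
    return replace(clone, dna=dna, protein=translate(dna),
                   cdr_seqs=None, truth_defect="in_frame_stop")


def apply_defects(clones: list[CloneRecord], config: DefectConfig,
                  seed) -> list[CloneRecord]:
    """Seed ``config`` defects into random distinct clones of a population."""
    if config.total > len(clones):
        raise ValueError("more defects requested than clones available")
    rng = _as_rng(seed)
    targets = rng.choice(len(clones), size=config.total, replace=False)
    classes = [cls for cls, n in sorted(config.counts.items()) for _ in range(n)]
    out = list(clones)
    for idx, cls in zip(targets, classes):
        out[int(idx)] = inject_defect(out[int(idx)], cls, rng)
    return out


def make_sanger_fixture(
    seed: int = SANGER_FIXTURE_SEED,
    design: LibraryDesign | None = None,
    config: DefectConfig | None = None,
) -> tuple[list[CloneRecord], pd.DataFrame]:
    """The packaged 315-clone colony-sequencing QC fixture.

    Returns the clone list plus a truth table (clone_id, truth_defect).
    Under the default pinned seed and defect configuration exactly 13 clones
    are defective, split 4/4/3/2 over the four classes.
    """
    design = design or default_library_design()
    config = config or DefectConfig()
    root = np.random.SeedSequence(seed)
    lib_rng, defect_rng = (np.random.default_rng(s) for s in root.spawn(2))
    clones = generate_library(design, SANGER_FIXTURE_SIZE, lib_rng)
    clones = apply_defects(clones, config, defect_rng)
    truth = pd.DataFrame(
        {"clone_id": [c.clone_id for c in clones],
         "truth_defect": [c.truth_defect for c in clones]}
    )
    return clones, truth


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _mutate(seq: str, profile: PlatformProfile, rng: np.random.Generator) -> str:
    if (profile.substitution_rate == 0 and profile.insertion_rate == 0
            and profile.deletion_rate == 0):
        return seq
    if profile.insertion_rate == 0 and profile.deletion_rate == 0:
        # substitution-only fast path
        hits = np.nonzero(rng.random(len(seq)) < profile.substitution_rate)[0]
        if hits.size == 0:
            return seq
        chars = list(seq)
        for pos in hits:
            others = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = others[int(rng.integers(0, 3))]
        return "".join(chars)
    out = []
    for base in seq:
        roll = rng.random()
        if roll < profile.deletion_rate:
            continue
        if roll < profile.deletion_rate + profile.insertion_rate:
            out.append(str(rng.choice(_BASES)))
        if rng.random() < profile.substitution_rate:
            others = [b for b in "ACGT" if b != base]
            out.append(str(rng.choice(others)))
        else:
            out.append(base)
    return "".join(out)


def emit_reads(
    clones: list[CloneRecord],
    profile: PlatformProfile | None = None,
    seed=0,
    with_quality: bool = False,
) -> ReadSet:
    """One read per clone under the platform error model."""
    profile = profile or PlatformProfile()
    rng = _as_rng(seed)
    reads = []
    for i, clone in enumerate(clones):
        seq = clone.dna
        flipped = bool(rng.random() < profile.flip_probability)
        if flipped:
            seq = reverse_complement(seq)
        seq = _mutate(seq, profile, rng)
        quality = profile.quality_char * len(seq) if with_quality else None
        reads.append(Read(
            read_id=f"read{i:06d}", sequence=seq, quality=quality,
            source_id=clone.clone_id, flipped=flipped,
        ))
    return ReadSet(tuple(reads), profile)


# ---------------------------------------------------------------------------
# Assay-level synthetic data
# ---------------------------------------------------------------------------

def generate_cytometry_events(
    n_events: int,
    transfected_fraction: float,
    gfp_medians: tuple[float, float],
    mcherry_separation: float = 50.0,
    seed=0,
    log_sd: float = 0.5,
    base_mcherry_median: float = 100.0,
) -> pd.DataFrame:
    """Two-channel log-normal event table with truth subpopulation labels.

    ``gfp_medians`` is (transfected, untransfected); transfected events have
    an mCherry median ``mcherry_separation`` times the untransfected one.
    """
    if not 0.0 <= transfected_fraction <= 1.0:
        raise ValueError("transfected_fraction must be in [0, 1]")
    rng = _as_rng(seed)
    transfected = rng.random(n_events) < transfected_fraction
    gfp_mu = np.where(transfected, np.log(gfp_medians[0]), np.log(gfp_medians[1]))
    mch_mu = np.where(
        transfected,
        np.log(base_mcherry_median * mcherry_separation),
        np.log(base_mcherry_median),
    )
    frame = pd.DataFrame({
        "gfp": np.exp(rng.normal(gfp_mu, log_sd)),
        "mcherry": np.exp(rng.normal(mch_mu, log_sd)),
        "transfected": transfected,
    })
    frame.attrs["suggested_mcherry_threshold"] = float(
        base_mcherry_median * np.sqrt(mcherry_separation)
    )
    return frame


def simulate_panning_pool(
    initial_frequencies: dict[str, float],
    enrichment_factors: dict[str, float],
    rounds: int,
) -> pd.DataFrame:
    """Per-round clone frequencies under multiplicative enrichment.

    Row 0 is the (normalized) input pool; each subsequent row multiplies by
    the per-clone enrichment factor and renormalizes.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    ids = sorted(initial_frequencies)
    freq = np.array([initial_frequencies[c] for c in ids], dtype=float)
    if freq.sum() <= 0:
        raise ValueError("initial frequencies must have positive mass")
    freq = freq / freq.sum()
    factors = np.array([enrichment_factors.get(c, 1.0) for c in ids], dtype=float)
    rows = [freq.copy()]
    for _ in range(rounds):
        freq = freq * factors
        freq = freq / freq.sum()
        rows.append(freq.copy())
    frame = pd.DataFrame(rows, columns=ids)
    frame.index.name = "round"
    return frame
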