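"""Sequencing-based library quality control.

Anchors reads to the scaffold framework segments by tolerant alignment
(both strands), extracts the inter-anchor CDR spans, classifies the defect
taxonomy, and aggregates diversity statistics: defect fractions, CDR3
length mixture, per-position residue profiles, design-vs-observed
total-variation distances, unique-clone collapsing and clonal dominance.

Defect classification applies a fixed precedence:
``empty`` (no anchors) -> ``frameshift`` (lengths off by a non-multiple of
three) -> ``missing_region`` (fused anchors) -> ``in_frame_stop`` -> ``ok``;
contradictory evidence yields ``unclassified``, never a silent ``ok``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from .align import Match, approx_search
from .alphabet import reverse_complement, translate
from .diversity import (
    LibraryDesign,
    PositionProfile,
    compare_profiles,
    profile_from_repertoire,
)
from .scaffold import CDR3_LENGTHS, FRAMEWORK_REGIONS, ScaffoldModel
from .simulate import CloneRecord, Read

INFERRED_CLASSES: tuple[str, ...] = (
    "ok", "in_frame_stop", "frameshift", "missing_region", "empty", "unclassified",
)

#: CDR slot between each pair of consecutive framework anchors.
_CDR_BETWEEN: dict[tuple[str, str], str] = {
    ("FR1", "FR2"): "CDR1", ("FR2", "FR3"): "CDR2", ("FR3", "FR4"): "CDR3",
}

DEFAULT_MAX_EDIT = 2


@dataclass(frozen=True)
class CloneAnnotation:
    """Scaffold anchoring of one read plus the inferred defect class."""

    read_id: str
    orientation: str                      # '+' or '-'
    sequence: str                         # read in scaffold orientation
    anchor_spans: dict[str, Match | None]
    cdr_nt: dict[str, str]
    cdr_seqs: dict[str, str] | None
    inferred_defect: str = "unclassified"

    def __post_init__(self) -> None:
        if self.inferred_defect not in INFERRED_CLASSES:
            raise ValueError(f"unknown class {self.inferred_defect!r}")

    @property
    def frame(self) -> int | None:
        hit = self.anchor_spans.get("FR1")
        return hit.start % 3 if hit else None

    def located(self) -> list[str]:
        return [fr for fr in FRAMEWORK_REGIONS if self.anchor_spans.get(fr)]


def _locate_anchors(sequence: str, anchors: dict[str, str],
                    max_edit: int) -> dict[str, Match | None]:
    """Find each framework anchor left to right; later anchors must follow
    earlier ones (searches resume at the previous anchor's end)."""
    spans: dict[str, Match | None] = {}
    offset = 0
    for name in FRAMEWORK_REGIONS:
        hit = approx_search(anchors[name], sequence[offset:], max_edit)
        if hit is None:
            spans[name] = None
        else:
            spans[name] = Match(hit.start + offset, hit.end + offset, hit.distance)
            offset = hit.end + offset
    return spans


def annotate_read(
    read: Read | str,
    scaffold: ScaffoldModel,
    max_edit: int = DEFAULT_MAX_EDIT,
) -> CloneAnnotation:
    """Anchor a read to the scaffold, trying both strands, and classify it."""
    if isinstance(read, Read):
        read_id, seq = read.read_id, read.sequence
    else:
        read_id, seq = "read", read
    anchors = scaffold.framework_dna()

    forward = _locate_anchors(seq, anchors, max_edit)
    n_fwd = sum(1 for h in forward.values() if h)
    if n_fwd == len(FRAMEWORK_REGIONS) and all(
        h.distance == 0 for h in forward.values() if h
    ):
        orientation, spans, oriented = "+", forward, seq
    else:
        rc = reverse_complement(seq)
        backward = _locate_anchors(rc, anchors, max_edit)
        n_bwd = sum(1 for h in backward.values() if h)
        dist_fwd = sum(h.distance for h in forward.values() if h)
        dist_bwd = sum(h.distance for h in backward.values() if h)
        if (n_bwd, -dist_bwd) > (n_fwd, -dist_fwd):
            orientation, spans, oriented = "-", backward, rc
        else:
            orientation, spans, oriented = "+", forward, seq

    cdr_nt: dict[str, str] = {}
    for (left, right), cdr in _CDR_BETWEEN.items():
        lhit, rhit = spans.get(left), spans.get(right)
        if lhit and rhit:
            cdr_nt[cdr] = oriented[lhit.end:rhit.start]
    cdr_seqs = None
    if len(cdr_nt) == 3 and all(len(v) % 3 == 0 for v in cdr_nt.values()):
        cdr_seqs = {cdr: translate(nt) for cdr, nt in cdr_nt.items()}

    annotation = CloneAnnotation(
        read_id=read_id, orientation=orientation, sequence=oriented,
        anchor_spans=spans, cdr_nt=cdr_nt, cdr_seqs=cdr_seqs,
    )
    return classify_defect(annotation)


def classify_defect(annotation: CloneAnnotation) -> CloneAnnotation:
    """Assign the defect class for an anchored read (fixed precedence)."""
    spans = annotation.anchor_spans
    located = annotation.located()

    def done(cls: str) -> CloneAnnotation:
        return replace(annotation, inferred_defect=cls)

    # 1. empty: no scaffold anchor at all.
    if not located:
        return done("empty")

    # 2. frameshift: overall or inter-anchor spacing off a codon boundary.
    fr1, fr4 = spans.get("FR1"), spans.get("FR4")
    if fr1 and fr4 and (fr4.end - fr1.start) % 3 != 0:
        return done("frameshift")
    for (left, right), _ in _CDR_BETWEEN.items():
        lhit, rhit = spans.get(left), spans.get(right)
        if lhit and rhit and (rhit.start - lhit.end) % 3 != 0:
            return done("frameshift")

    # 3. missing_region: fused anchors where a CDR (or CDR1-FR2-CDR2) should be.
    if len(located) == len(FRAMEWORK_REGIONS):
        if spans["FR2"].start - spans["FR1"].end == 0:
            return done("missing_region")
    elif set(FRAMEWORK_REGIONS) - set(located) == {"FR2"}:
        if fr1 and spans["FR3"] and spans["FR3"].start - fr1.end == 0:
            return done("missing_region")
        return done("unclassified")
    else:
        return done("unclassified")

    # 4. in-frame stop anywhere in the anchored ORF.
    orf = annotation.sequence[fr1.start:fr4.end]
    if "*" in translate(orf):
        return done("in_frame_stop")

    # 5. ok, provided the CDR geometry matches the design.
    want12 = 3 * 7
    cdr3_nt = len(annotation.cdr_nt.get("CDR3", ""))
    if (len(annotation.cdr_nt.get("CDR1", "")) == want12
            and len(annotation.cdr_nt.get("CDR2", "")) == want12
            and cdr3_nt % 3 == 0 and cdr3_nt // 3 in CDR3_LENGTHS):
        return done("ok")
    return done("unclassified")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Aggregate library QC statistics over a set of annotated reads."""

    total: int
    class_counts: dict[str, int]
    defect_count: int
    defect_fraction: float
    cdr3_length_counts: dict[int, int]
    cdr3_length_proportions: dict[int, float]
    observed_profiles: dict[str, list[PositionProfile]]
    design_distances: dict[str, pd.DataFrame] = field(default_factory=dict)
    unique_clone_count: int | None = None
    dominance_fraction: float | None = None
    dominant: bool | None = None
    empty_input: bool = False

    def to_dict(self) -> dict:
        out = {
            "total": self.total,
            "class_counts": self.class_counts,
            "defect_count": self.defect_count,
            "defect_fraction": self.defect_fraction,
            "cdr3_length_counts": {str(k): v for k, v in self.cdr3_length_counts.items()},
            "cdr3_length_proportions": {
                str(k): v for k, v in self.cdr3_length_proportions.items()
            },
            "unique_clone_count": self.unique_clone_count,
            "dominance_fraction": self.dominance_fraction,
            "dominant": self.dominant,
            "empty_input": self.empty_input,
        }
        out["design_distances"] = {
            region: {"mean_tv": frame.attrs["mean_tv"], "max_tv": frame.attrs["max_tv"]}
            for region, frame in self.design_distances.items()
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def qc_report(
    annotations: list[CloneAnnotation],
    design: LibraryDesign | None = None,
    dominance_threshold: float = 0.5,
) -> QCReport:
    """Build the full QC summary from annotated reads.

    Class counts partition the input exactly; diversity statistics (CDR3
    length mixture, positional profiles, uniqueness, dominance) are computed
    over the ``ok`` subset.
    """
    if not annotations:
        return QCReport(
            total=0, class_counts={c: 0 for c in INFERRED_CLASSES},
            defect_count=0, defect_fraction=0.0,
            cdr3_length_counts={}, cdr3_length_proportions={},
            observed_profiles={}, empty_input=True,
        )
    counts = Counter(a.inferred_defect for a in annotations)
    class_counts = {c: counts.get(c, 0) for c in INFERRED_CLASSES}
    total = len(annotations)
    defect_count = total - class_counts["ok"]

    ok = [a for a in annotations if a.inferred_defect == "ok" and a.cdr_seqs]
    lengths = Counter(len(a.cdr_seqs["CDR3"]) for a in ok)
    n_ok = len(ok)
    proportions = {L: c / n_ok for L, c in sorted(lengths.items())} if n_ok else {}

    observed: dict[str, list[PositionProfile]] = {}
    if ok:
        observed["CDR1"] = profile_from_repertoire([a.cdr_seqs["CDR1"] for a in ok])
        observed["CDR2"] = profile_from_repertoire([a.cdr_seqs["CDR2"] for a in ok])
        for L in sorted(lengths):
            group = [a.cdr_seqs["CDR3"] for a in ok if len(a.cdr_seqs["CDR3"]) == L]
            observed[f"CDR3_{L}"] = profile_from_repertoire(group)

    distances: dict[str, pd.DataFrame] = {}
    if design is not None and ok:
        distances["CDR1"] = compare_profiles(list(design.cdr1.profiles),
                                             observed["CDR1"])
        distances["CDR2"] = compare_profiles(list(design.cdr2.profiles),
                                             observed["CDR2"])
        for L in sorted(lengths):
            key = f"CDR3_{L}"
            distances[key] = compare_profiles(
                list(design.cdr3.profiles_for_length(L)), observed[key]
            )

    unique = dominance_frac = is_dominant = None
    if ok:
        clusters = collapse_unique(ok, level="protein")
        unique = len(clusters)
        dominance_frac, is_dominant = dominance(
            [size for _, size in clusters], threshold=dominance_threshold
        )

    return QCReport(
        total=total, class_counts=class_counts,
        defect_count=defect_count, defect_fraction=defect_count / total,
        cdr3_length_counts=dict(sorted(lengths.items())),
        cdr3_length_proportions=proportions,
        observed_profiles=observed, design_distances=distances,
        unique_clone_count=unique,
        dominance_fraction=dominance_frac, dominant=is_dominant,
    )


def _clone_key(item, level: str) -> str:
    if isinstance(item, str):
        return item
    if isinstance(item, CloneRecord):
        if level == "dna":
            return item.dna
        if level == "protein":
            return item.protein
        if item.cdr_seqs is None:
            raise ValueError(f"clone {item.clone_id} has no CDR annotation")
        return item.cdr_seqs["CDR3"]
    if isinstance(item, CloneAnnotation):
        if level == "dna":
            return item.sequence
        if level == "protein":
            fr1, fr4 = item.anchor_spans.get("FR1"), item.anchor_spans.get("FR4")
            if not (fr1 and fr4):
                raise ValueError(f"read {item.read_id} lacks terminal anchors")
            return translate(item.sequence[fr1.start:fr4.end])
        if item.cdr_seqs is None:
            raise ValueError(f"read {item.read_id} has no CDR annotation")
        return item.cdr_seqs["CDR3"]
    raise TypeError(f"cannot derive a clone key from {type(item).__name__}")


def collapse_unique(items, level: str = "protein") -> list[tuple[str, int]]:
    """Group clones by exact identity at ``level`` in {dna, protein, cdr3}.

    Returns (key, cluster_size) pairs sorted by decreasing size (ties by
    key); cluster sizes sum to the input count.
    """
    if level not in ("dna", "protein", "cdr3"):
        raise ValueError(f"unknown collapse level {level!r}")
    counts = Counter(_clone_key(item, level) for item in items)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def dominance(pool, threshold: float = 0.5) -> tuple[float, bool]:
    """Top-clone fraction of a pool and whether it exceeds ``threshold``.

    ``pool`` may be a mapping/sequence of clone weights (counts or
    frequencies) or a sequence of clone labels/records (collapsed first).
    """
    if isinstance(pool, dict):
        weights = list(pool.values())
    else:
        pool = list(pool)
        if pool and isinstance(pool[0], (int, float)):
            weights = [float(x) for x in pool]
        else:
            weights = [size for _, size in collapse_unique(pool)]
    total = sum(weights)
    if total <= 0:
        raise ValueError("pool has no mass")
    top = max(weights) / total
    return top, top > threshold


def confusion_matrix(
    truth: list[str], inferred: list[str]
) -> pd.DataFrame:
    """Truth-by-inferred class count matrix (rows: truth, columns: inferred)."""
    if len(truth) != len(inferred):
        raise ValueError("label lists must have equal length")
    frame = pd.crosstab(
        pd.Series(truth, name="truth"), pd.Series(inferred, name="inferred")
    )
    return frame.reindex(
        index=sorted(set(truth)), columns=sorted(set(inferred)), fill_value=0
    )
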