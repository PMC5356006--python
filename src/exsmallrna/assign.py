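"""Hierarchical biotype assignment of collapsed small-RNA reads.

Reads are matched against staged reference libraries the way short-read
annotation pipelines do it:

stage 1
    exact match to rRNA; matching reads are removed,
stage 2
    match to the genome and the miRNA library allowing one substitution,
    seeded on the first 19 bases; reads missing the genome become
    ``genome_unaligned``, miRNA hits become ``miRNA``,
stage 3
    simultaneous exact match to mature tRNA (+50-bp flanks), piRNA,
    YRNA, other non-coding and protein-coding libraries, each read
    allowed at most 40 annotation hits.  A read hitting exactly one
    biotype gets that biotype; two or more biotypes -> ``shared``; no
    annotation hit or >40 hits -> ``unassigned``.

Each read's count lands in exactly one category, so category totals are
conserved.  One-mismatch matching is substitutions only (no indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import CollapsedRead, PreprocessStats
from .references import ReferenceBundle, SeedIndex, index_genome, index_references

DEFAULT_SEED_LENGTH = 19
DEFAULT_MAX_ANNOTATION_HITS = 40

#: Final read categories, in reporting order.
CATEGORIES = (
    "too_short",
    "rRNA",
    "miRNA",
    "tRNA",
    "tRNA_flank",
    "piRNA",
    "YRNA",
    "other_ncRNA",
    "protein_coding",
    "shared",
    "unassigned",
    "genome_unaligned",
)

#: Categories excluded from the genome-mapped percentage denominator.
NON_GENOME_CATEGORIES = frozenset({"too_short", "rRNA", "genome_unaligned"})

QC_THRESHOLDS = {"plasma": 5.0, "urine": 0.5, "saliva": 0.5}


def hamming_distance(a: str, b: str) -> int:
    """Number of substitutions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True, order=True)
class AlignmentHit:
    record_id: str
    offset: int
    mismatches: int


def _hamming_at_most(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def _seed_neighbors(seed: str) -> list[str]:
    """All one-substitution variants of a seed (for 1-mismatch seeding)."""
    out = []
    for i, base in enumerate(seed):
        for alt in "ACGT":
            if alt != base:
                out.append(seed[:i] + alt + seed[i + 1 :])
    return out


def match_read(
    seq: str,
    index: SeedIndex,
    max_mismatch: int = 0,
    first_only: bool = False,
) -> list[AlignmentHit]:
    """All occurrences of ``seq`` in the indexed sequences with <= max_mismatch
    substitutions.

    Seeds on the first k bases of the read: an exact-seed lookup finds
    every alignment whose mismatch (if any) lies outside the seed, and
    for ``max_mismatch=1`` lookups of all one-substitution seed variants
    cover mismatches inside it, so the search is complete.  Reads
    shorter than the seed length are matched exactly by scanning.
    ``first_only`` short-circuits at the first hit (existence queries).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    k = index.k
    n = len(seq)
    hits: list[AlignmentHit] = []
    if n < k:
        # short-read rule: exact substring scan (mismatches not seedable)
        for name, ref in list(index.sequences.items()):
            start = ref.find(seq)
            while start >= 0:
                hits.append(AlignmentHit(name, start, 0))
                if first_only:
                    return hits
                start = ref.find(seq, start + 1)
        return sorted(hits)

    seen: set[tuple[str, int]] = set()
    seeds = [seq[:k]]
    if max_mismatch == 1:
        seeds.extend(_seed_neighbors(seq[:k]))
    for seed in seeds:
        for name, off in index.lookup(seed):
            if (name, off) in seen:
                continue
            ref = index.sequences[name]
            if off + n > len(ref):
                continue
            d = _hamming_at_most(seq, ref[off : off + n], max_mismatch)
            if d <= max_mismatch:
                seen.add((name, off))
                hits.append(AlignmentHit(name, off, d))
                if first_only:
                    return hits
    return sorted(hits)


def match_reads(
    collapsed: list[CollapsedRead],
    index: SeedIndex,
    max_mismatch: int = 0,
    max_hits: int | None = None,
) -> tuple[dict[str, list[AlignmentHit]], set[str]]:
    """Match every collapsed read; cap hit lists at ``max_hits``.

    Returns (hits per sequence, set of sequences whose number of distinct
    hit records exceeded the cap).
    """
    hits: dict[str, list[AlignmentHit]] = {}
    overflow: set[str] = set()
    for cr in collapsed:
        h = match_read(cr.sequence, index, max_mismatch)
        if max_hits is not None and len({x.record_id for x in h}) > max_hits:
            overflow.add(cr.sequence)
            h = h[: max_hits]
        if h:
            hits[cr.sequence] = h
    return hits, overflow


@dataclass
class AssignmentTable:
    """Per collapsed read: the resolved category plus annotation-stage hits."""

    table: pd.DataFrame  # columns: sequence, count, category, stage, n_hits, hit_ids
    annotation_hits: dict[str, list[AlignmentHit]] = field(default_factory=dict)
    mirna_hits: dict[str, list[AlignmentHit]] = field(default_factory=dict)
    n_too_short: int = 0

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        out["too_short"] = self.n_too_short
        for cat, cnt in zip(self.table["category"], self.table["count"]):
            out[cat] += int(cnt)
        return out

    def total_count(self) -> int:
        return int(self.table["count"].sum()) + self.n_too_short


def hierarchical_assign(
    collapsed: list[CollapsedRead],
    bundle: ReferenceBundle,
    seed_len: int = DEFAULT_SEED_LENGTH,
    max_annotation_hits: int = DEFAULT_MAX_ANNOTATION_HITS,
    n_too_short: int = 0,
    _indexes: dict[str, SeedIndex] | None = None,
) -> AssignmentTable:
    """Run the three matching stages and resolve one category per read."""
    for stage in (("rRNA",), ("miRNA",)):
        if not bundle.by_biotype(*stage):
            raise ValueError(f"bundle missing stage library {stage[0]}")
    if not bundle.genome:
        raise ValueError("bundle missing genome sequences")

    idx = _indexes if _indexes is not None else build_stage_indexes(bundle, seed_len)

    rows = []
    annotation_hits: dict[str, list[AlignmentHit]] = {}
    mirna_hits: dict[str, list[AlignmentHit]] = {}
    for cr in collapsed:
        seq = cr.sequence
        # stage 1: rRNA, exact
        if match_read(seq, idx["rRNA"], 0, first_only=True):
            rows.append((seq, cr.count, "rRNA", 1, 1, ""))
            continue
        # stage 2: genome + miRNA, 1 substitution, seed on first 19 nt
        if not match_read(seq, idx["genome"], 1, first_only=True):
            rows.append((seq, cr.count, "genome_unaligned", 2, 0, ""))
            continue
        mh = match_read(seq, idx["miRNA"], 1)
        if mh:
            mirna_hits[seq] = mh
            rows.append(
                (seq, cr.count, "miRNA", 2, len(mh), ",".join(h.record_id for h in mh))
            )
            continue
        # stage 3: annotation libraries, exact, <=40 annotations
        ah = match_read(seq, idx["annotation"], 0)
        record_ids = {h.record_id for h in ah}
        if not ah:
            rows.append((seq, cr.count, "unassigned", 3, 0, ""))
            continue
        if len(record_ids) > max_annotation_hits:
            rows.append((seq, cr.count, "unassigned", 3, len(record_ids), ""))
            continue
        annotation_hits[seq] = ah
        biotypes = set()
        for rid in record_ids:
            bt = bundle[rid].biotype
            biotypes.add("tRNA_flank" if bt in ("tRNA_flank5", "tRNA_flank3") else bt)
        category = biotypes.pop() if len(biotypes) == 1 else "shared"
        rows.append(
            (seq, cr.count, category, 3, len(record_ids), ",".join(sorted(record_ids)))
        )

    table = pd.DataFrame(
        rows, columns=["sequence", "count", "category", "stage", "n_hits", "hit_ids"]
    )
    return AssignmentTable(table, annotation_hits, mirna_hits, n_too_short)


def build_stage_indexes(bundle: ReferenceBundle, seed_len: int = DEFAULT_SEED_LENGTH) -> dict[str, SeedIndex]:
    """Precompute the per-stage seed indexes (reusable across samples)."""
    return {
        "rRNA": index_references(bundle, seed_len, ["rRNA"]),
        "genome": index_genome(bundle, seed_len),
        "miRNA": index_references(bundle, seed_len, ["miRNA"]),
        "annotation": index_references(
            bundle,
            seed_len,
            ["tRNA", "tRNA_flank5", "tRNA_flank3", "piRNA", "YRNA", "other_ncRNA", "protein_coding"],
        ),
    }


@dataclass
class BiotypeProfile:
    """Per-sample category counts and genome-mapped percentages."""

    sample_id: str
    counts: dict[str, int]
    denominator_genome_mapped: int
    percentages: dict[str, float] | None  # None when the denominator is zero

    @property
    def mirna_pct_of_mapped(self) -> float | None:
        if self.percentages is None:
            return None
        return self.percentages["miRNA"]


def biotype_profile(
    assignment: AssignmentTable | dict[str, int], sample_id: str = "sample"
) -> BiotypeProfile:
    """Fig-1B-style composition: percentages over genome-mapped reads.

    The denominator excludes too-short, rRNA and genome-unaligned reads.
    A zero denominator yields ``percentages=None`` (flagged missing, not 0).
    """
    counts = (
        assignment.category_counts()
        if isinstance(assignment, AssignmentTable)
        else {c: int(assignment.get(c, 0)) for c in CATEGORIES}
    )
    denom = sum(v for c, v in counts.items() if c not in NON_GENOME_CATEGORIES)
    if denom == 0:
        return BiotypeProfile(sample_id, counts, 0, None)
    pct = {
        c: 100.0 * v / denom for c, v in counts.items() if c not in NON_GENOME_CATEGORIES
    }
    return BiotypeProfile(sample_id, counts, denom, pct)


@dataclass(frozen=True)
class QCDecision:
    sample_id: str
    fluid: str
    mirna_pct_of_mapped: float | None
    threshold: float
    passed: bool


def sample_qc(profile: BiotypeProfile, fluid: str) -> QCDecision:
    """Exclude samples with too little miRNA among genome-mapped reads.

    Plasma needs >=5% miRNA of genome-mapped reads, urine and saliva
    >=0.5% (the exclusion rule is "<threshold", so the boundary passes).
    """
    if fluid not in QC_THRESHOLDS:
        raise ValueError(f"unknown fluid {fluid!r}; expected one of {sorted(QC_THRESHOLDS)}")
    thr = QC_THRESHOLDS[fluid]
    pct = profile.mirna_pct_of_mapped
    passed = pct is not None and pct >= thr
    return QCDecision(profile.sample_id, fluid, pct, thr, passed)


def mirna_counts(assignment: AssignmentTable) -> dict[str, int]:
    """Per-miRNA read counts (a read counts once per matched miRNA)."""
    counts: dict[str, int] = {}
    table = assignment.table
    for seq, cnt in zip(table["sequence"], table["count"]):
        for hit in assignment.mirna_hits.get(seq, ()):
            counts[hit.record_id] = counts.get(hit.record_id, 0) + int(cnt)
    return counts
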