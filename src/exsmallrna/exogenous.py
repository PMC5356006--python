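"""Species-level unique-signature profiling of exogenous (bacterial) reads.

A signature database is built by k-mer exclusion: for each species,
every 24-mer also present in the host genome or in any other species is
removed, and the maximal runs of bases whose overlapping k-mers are all
unique (at least k nt long) are kept as that species' genomic
signature.  Reads are then matched exactly against signature segments;
a species is called significant in a sample only with at least 100
non-overlapping covered bases, signature coverage of at least 0.5% and
at least 10 hits.  Species-level results roll up a taxonomy
(genus, family, order, class, phylum).

Exogenous RPM uses its own denominator: input reads of length >=15 nt,
not genome-mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_K = 24
TAXONOMIC_RANKS = ("species", "genus", "family", "order", "class", "phylum")

MIN_COVERED_BASES = 100
MIN_COVERAGE = 0.005
MIN_HITS = 10

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_set(sequences: Iterable[str], k: int, both_strands: bool = True) -> set[str]:
    out: set[str] = set()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            out.add(seq[i : i + k])
        if both_strands:
            rc = reverse_complement(seq)
            for i in range(len(rc) - k + 1):
                out.add(rc[i : i + k])
    return out


@dataclass(frozen=True)
class SignatureSegment:
    sequence: str
    replicon: str
    start: int  # 0-based, half-open on the source replicon
    end: int


@dataclass
class SignatureDB:
    k: int
    segments: dict[str, list[SignatureSegment]]  # species -> segments
    taxonomy: dict[str, str]  # child -> parent, species up to phylum
    ranks: dict[str, str] = field(default_factory=dict)  # node -> rank name

    def signature_bases(self, species: str) -> int:
        return sum(len(s.sequence) for s in self.segments.get(species, []))

    def species(self) -> list[str]:
        return sorted(self.segments)


def build_signature_db(
    species_fastas: Mapping[str, Mapping[str, str]],
    host: Mapping[str, str],
    k: int = DEFAULT_K,
    taxonomy: Mapping[str, str] | None = None,
    ranks: Mapping[str, str] | None = None,
) -> SignatureDB:
    """Build per-species unique signatures by k-mer exclusion.

    ``species_fastas`` maps species name -> {replicon name -> sequence}.
    A base run survives for a species only if every k-mer overlapping it
    is absent from the host genome (both strands) and from every other
    species (both strands); runs shorter than k are discarded.
    """
    if k < 12:
        raise ValueError("exclusion k-mer size must be >= 12")
    names = list(species_fastas)
    if len(names) != len(set(names)):
        raise ValueError("species sharing an id")

    host_kmers = _kmer_set(host.values(), k)
    species_kmers = {
        sp: _kmer_set(replicons.values(), k) for sp, replicons in species_fastas.items()
    }

    segments: dict[str, list[SignatureSegment]] = {}
    for sp in names:
        exclusion = set(host_kmers)
        for other, kmers in species_kmers.items():
            if other != sp:
                exclusion |= kmers
        segs: list[SignatureSegment] = []
        for replicon, seq in species_fastas[sp].items():
            n = len(seq)
            if n < k:
                continue
            good = [seq[i : i + k] not in exclusion for i in range(n - k + 1)]
            # maximal runs of positions whose every overlapping k-mer is unique
            i = 0
            while i < len(good):
                if not good[i]:
                    i += 1
                    continue
                j = i
                while j < len(good) and good[j]:
                    j += 1
                start, end = i, j - 1 + k  # covered bases [start, end)
                if end - start >= k:
                    segs.append(SignatureSegment(seq[start:end], replicon, start, end))
                i = j
        segments[sp] = segs

    tax = dict(taxonomy or {})
    return SignatureDB(k=k, segments=segments, taxonomy=tax, ranks=dict(ranks or {}))


@dataclass
class SpeciesHits:
    n_hits: int = 0
    intervals: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    # segment index -> hit intervals on that segment

    def covered_bases(self) -> int:
        total = 0
        for ivs in self.intervals.values():
            ivs = sorted(ivs)
            cur_start, cur_end = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_end:
                    cur_end = max(cur_end, e)
                else:
                    total += cur_end - cur_start
                    cur_start, cur_end = s, e
            total += cur_end - cur_start
        return total


def profile_sample(
    reads: Iterable[tuple[str, int]],
    db: SignatureDB,
    check_reverse_complement: bool = True,
) -> dict[str, SpeciesHits]:
    """Match (sequence, count) reads exactly against signature segments.

    A read hits a species when it is an exact substring of one of its
    segments (in the given orientation, or either orientation with
    ``check_reverse_complement``); every occurrence contributes a
    covered interval, and the read's count contributes to the hit total.
    """
    if not any(db.segments.values()):
        raise ValueError("signature database has no segments")
    out: dict[str, SpeciesHits] = {}
    for seq, count in reads:
        queries = [seq]
        if check_reverse_complement:
            rc = reverse_complement(seq)
            if rc != seq:
                queries.append(rc)
        for sp, segs in db.segments.items():
            hit_any = False
            for si, seg in enumerate(segs):
                for q in queries:
                    start = seg.sequence.find(q)
                    while start >= 0:
                        hit_any = True
                        out.setdefault(sp, SpeciesHits()).intervals.setdefault(
                            si, []
                        ).append((start, start + len(q)))
                        start = seg.sequence.find(q, start + 1)
            if hit_any:
                out[sp].n_hits += count
    return out


@dataclass(frozen=True)
class SignatureHitReport:
    name: str
    rank: str
    n_hits: int
    covered_nonoverlapping_bases: int
    coverage_fraction: float
    rpm: float
    significant: bool


def filter_and_rollup(
    raw_hits: Mapping[str, SpeciesHits],
    db: SignatureDB,
    input_reads_ge15: int,
    min_bases: int = MIN_COVERED_BASES,
    min_cov: float = MIN_COVERAGE,
    min_hits: int = MIN_HITS,
) -> dict[str, list[SignatureHitReport]]:
    """Apply the three significance filters and roll counts up the taxonomy.

    A species is significant with >= ``min_bases`` non-overlapping
    covered signature bases, coverage >= ``min_cov`` of its signature,
    and >= ``min_hits`` hits (all boundaries inclusive).  Counts of
    significant species are summed into their genus/family/order/class/
    phylum ancestors.  RPM is hits per million input reads >=15 nt.
    """
    if input_reads_ge15 <= 0:
        raise ValueError("input_reads_ge15 must be positive")
    species_reports: list[SignatureHitReport] = []
    rollup: dict[str, dict[str, float]] = {r: {} for r in TAXONOMIC_RANKS[1:]}
    for sp, hits in sorted(raw_hits.items()):
        sig_bases = db.signature_bases(sp)
        covered = hits.covered_bases()
        coverage = covered / sig_bases if sig_bases else 0.0
        significant = (
            covered >= min_bases and coverage >= min_cov and hits.n_hits >= min_hits
        )
        species_reports.append(
            SignatureHitReport(
                sp,
                "species",
                hits.n_hits,
                covered,
                coverage,
                rpm_exogenous(hits.n_hits, input_reads_ge15),
                significant,
            )
        )
        if not significant:
            continue
        node = sp
        for rank in TAXONOMIC_RANKS[1:]:
            if node not in db.taxonomy:
                raise ValueError(f"taxonomy missing parent of {node!r}")
            node = db.taxonomy[node]
            rollup[rank][node] = rollup[rank].get(node, 0) + hits.n_hits

    out = {"species": species_reports}
    for rank in TAXONOMIC_RANKS[1:]:
        out[rank] = [
            SignatureHitReport(
                name, rank, int(n), 0, float("nan"),
                rpm_exogenous(n, input_reads_ge15), True,
            )
            for name, n in sorted(rollup[rank].items())
        ]
    return out


def rpm_exogenous(hits: float, input_reads_ge15: int) -> float:
    """Exogenous RPM: hits per million input reads of length >=15 nt."""
    if input_reads_ge15 <= 0:
        raise ValueError("input_reads_ge15 must be positive")
    return hits * 1e6 / input_reads_ge15


def cohort_summary(
    per_sample: Mapping[str, dict[str, list[SignatureHitReport]]],
    rank: str = "species",
) -> pd.DataFrame:
    """Cohort roll-up shaped like a prevalence table.

    Columns: taxa, n_samples (samples where significant), average RPM
    over those samples; sorted by prevalence then RPM.
    """
    acc: dict[str, list[float]] = {}
    for reports in per_sample.values():
        for rep in reports.get(rank, []):
            if rep.significant:
                acc.setdefault(rep.name, []).append(rep.rpm)
    rows = [
        {"taxa": name, "n_samples": len(rpms), "average_rpm": sum(rpms) / len(rpms)}
        for name, rpms in acc.items()
    ]
    df = pd.DataFrame(rows, columns=["taxa", "n_samples", "average_rpm"])
    return df.sort_values(["n_samples", "average_rpm"], ascending=False).reset_index(drop=True)


def load_taxonomy_tsv(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a child/parent/rank TSV into (parent map, rank map)."""
    parents: dict[str, str] = {}
    ranks: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("child"):
            fh.seek(0)
        for line in fh:
            child, parent, rank = line.rstrip("\n").split("\t")
            parents[child] = parent
            ranks[child] = rank
    return parents, ranks
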