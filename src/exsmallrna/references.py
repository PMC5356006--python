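"""Biotype reference libraries: records, bundles and the exact k-mer seed index.

The assignment engine matches reads against small per-biotype sequence
libraries (rRNA, miRNA, mature tRNA with 50-bp flanks, piRNA, YRNA,
other non-coding, protein-coding fragments) plus a genome built from the
same records.  Mature tRNAs are intron-free and carry a 3' ``CCA``, the
post-transcriptionally added acceptor end every mature tRNA has; the
50-bp genomic flanks are kept as separately indexable records so flank
hits can be reported as their own category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical biotype labels for reference records.
BIOTYPES = (
    "rRNA",
    "miRNA",
    "tRNA",
    "tRNA_flank5",
    "tRNA_flank3",
    "piRNA",
    "YRNA",
    "other_ncRNA",
    "protein_coding",
)

#: Annotation-source biotype names folded into ``other_ncRNA`` on load.
_OTHER_NC_ALIASES = frozenset(
    {
        "lincRNA",
        "misc_RNA",
        "snoRNA",
        "snRNA",
        "vaultRNA",
        "VaultRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "processed_pseudogene",
        "pseudogene",
        "Mt_tRNA",
        "other_ncRNA",
    }
)

_VALID_CHARS = frozenset("ACGT")

FLANK_LENGTH = 50


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T; reject characters outside ACGTU(N)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_CHARS - {"N"}
    if bad:
        raise ValueError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference sequence with its biotype and optional grouping metadata.

    ``family`` is the tRNA isoacceptor family (amino acid + anticodon,
    e.g. ``GlyGCC``); ``parent`` groups YRNA pseudogenes under their
    source gene (e.g. ``RNY4``).
    """

    id: str
    biotype: str
    sequence: str
    family: str | None = None
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for record {self.id}")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.biotype == "tRNA" and not self.sequence.endswith("CCA"):
            raise ValueError(f"mature tRNA {self.id} does not end in CCA")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceBundle:
    """All reference records plus the genome they live in.

    ``stage_order`` fixes the hierarchical matching order: rRNA first,
    then genome+miRNA, then the simultaneous annotation stage.
    """

    records: list[ReferenceRecord]
    genome: dict[str, str] = field(default_factory=dict)
    stage_order: tuple[tuple[str, ...], ...] = (
        ("rRNA",),
        ("miRNA",),
        ("tRNA", "tRNA_flank5", "tRNA_flank3", "piRNA", "YRNA", "other_ncRNA", "protein_coding"),
    )

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup[:5]}")
        self._by_id = {r.id: r for r in self.records}

    def __getitem__(self, rid: str) -> ReferenceRecord:
        return self._by_id[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._by_id

    def by_biotype(self, *biotypes: str) -> list[ReferenceRecord]:
        want = set(biotypes)
        return [r for r in self.records if r.biotype in want]

    def biotype_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.biotype] = out.get(r.biotype, 0) + 1
        return out


def build_mature_trna(
    trna_id: str,
    exons: Sequence[str],
    flank5: str | None = None,
    flank3: str | None = None,
    family: str | None = None,
) -> list[ReferenceRecord]:
    """Assemble a mature tRNA record from its exons, plus flank records.

    Introns are represented by the exon split: the mature sequence is the
    exon concatenation with ``CCA`` appended.  When 50-nt genomic flanks
    are given they become separate ``tRNA_flank5``/``tRNA_flank3``
    records so flank-derived reads stay a distinct category.
    """
    if not exons or any(len(e) == 0 for e in exons):
        raise ValueError("exons must be non-empty sequences")
    for name, flank in (("flank5", flank5), ("flank3", flank3)):
        if flank is not None and len(flank) != FLANK_LENGTH:
            raise ValueError(f"{name} must be exactly {FLANK_LENGTH} nt, got {len(flank)}")
    mature = "".join(normalize_sequence(e) for e in exons) + "CCA"
    out = [ReferenceRecord(trna_id, "tRNA", mature, family=family)]
    if flank5 is not None:
        out.append(ReferenceRecord(f"{trna_id}_flank5", "tRNA_flank5", flank5, family=family))
    if flank3 is not None:
        out.append(ReferenceRecord(f"{trna_id}_flank3", "tRNA_flank3", flank3, family=family))
    return out


def _map_biotype(raw: str) -> str:
    if raw in BIOTYPES:
        return raw
    if raw in _OTHER_NC_ALIASES:
        return "other_ncRNA"
    raise ValueError(f"unknown biotype {raw!r}")


def load_reference_bundle(
    fasta_paths: Sequence[str | Path],
    annotation_tsv: str | Path,
    genome_fasta: str | Path | None = None,
) -> ReferenceBundle:
    """Load FASTA sequence files plus the id/biotype/family/parent table.

    The annotation TSV has a header ``id biotype family parent`` (empty
    family/parent allowed).  Sequences are U->T normalized; annotation
    biotypes outside the canonical set are folded into ``other_ncRNA``
    when they are recognized non-coding classes.
    """
    seqs: dict[str, str] = {}
    for p in fasta_paths:
        for rec in SeqIO.parse(str(p), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate record id {rec.id!r} across FASTA inputs")
            seqs[rec.id] = normalize_sequence(str(rec.seq))

    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    with open(annotation_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("id", "biotype"):
            if req not in idx:
                raise ValueError(f"annotation table missing column {req!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rid = parts[idx["id"]]
            if rid in seen:
                raise ValueError(f"duplicate annotation id {rid!r}")
            seen.add(rid)
            if rid not in seqs:
                raise ValueError(f"annotated id {rid!r} has no FASTA sequence")
            fam = parts[idx["family"]] if "family" in idx and len(parts) > idx["family"] else ""
            par = parts[idx["parent"]] if "parent" in idx and len(parts) > idx["parent"] else ""
            records.append(
                ReferenceRecord(
                    rid,
                    _map_biotype(parts[idx["biotype"]]),
                    seqs[rid],
                    family=fam or None,
                    parent=par or None,
                )
            )

    genome: dict[str, str] = {}
    if genome_fasta is not None:
        for rec in SeqIO.parse(str(genome_fasta), "fasta"):
            genome[rec.id] = normalize_sequence(str(rec.seq))

    bundle = ReferenceBundle(records, genome=genome)
    for bt, n in sorted(bundle.biotype_counts().items()):
        logger.info("loaded %d %s records", n, bt)
    return bundle


def write_reference_bundle(bundle: ReferenceBundle, out_dir: str | Path) -> None:
    """Write a bundle as references.fasta + annotation.tsv (+ genome.fasta)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in bundle.records),
        str(out / "references.fasta"),
        "fasta",
    )
    with open(out / "annotation.tsv", "w") as fh:
        fh.write("id\tbiotype\tfamily\tparent\n")
        for r in bundle.records:
            fh.write(f"{r.id}\t{r.biotype}\t{r.family or ''}\t{r.parent or ''}\n")
    if bundle.genome:
        SeqIO.write(
            (SeqRecord(Seq(s), id=name, description="") for name, s in bundle.genome.items()),
            str(out / "genome.fasta"),
            "fasta",
        )


def read_reference_bundle(in_dir: str | Path) -> ReferenceBundle:
    """Inverse of :func:`write_reference_bundle`."""
    d = Path(in_dir)
    genome = d / "genome.fasta"
    return load_reference_bundle(
        [d / "references.fasta"],
        d / "annotation.tsv",
        genome_fasta=genome if genome.exists() else None,
    )


class SeedIndex:
    """Exact k-mer index over a set of named sequences.

    Every length-k substring of every indexed sequence gets one posting
    ``(name, offset)``.  Sequences shorter than k are kept in a side
    table and matched by whole-sequence scanning (the short-record rule).
    """

    def __init__(self, sequences: Mapping[str, str], k: int):
        if k < 10:
            raise ValueError(f"seed length must be >= 10, got {k}")
        self.k = int(k)
        self.sequences: dict[str, str] = dict(sequences)
        self.postings: dict[str, list[tuple[str, int]]] = {}
        self.short_records: dict[str, str] = {}
        for name, seq in self.sequences.items():
            if len(seq) < k:
                self.short_records[name] = seq
                logger.warning("record %s shorter than seed length %d; indexed whole", name, k)
                continue
            for off in range(len(seq) - k + 1):
                self.postings.setdefault(seq[off : off + k], []).append((name, off))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer, [])

    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


def index_references(
    bundle: ReferenceBundle, k: int, biotypes: Iterable[str] | None = None
) -> SeedIndex:
    """Build a :class:`SeedIndex` over (a biotype subset of) a bundle."""
    if biotypes is None:
        records = bundle.records
    else:
        records = bundle.by_biotype(*biotypes)
    return SeedIndex({r.id: r.sequence for r in records}, k)


def index_genome(bundle: ReferenceBundle, k: int) -> SeedIndex:
    """Seed index over the bundle's genome sequences."""
    if not bundle.genome:
        raise ValueError("bundle has no genome sequences")
    return SeedIndex(bundle.genome, k)
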