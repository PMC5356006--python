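"""Synthetic reference sets, read samples and cohorts with known truth.

Everything the pipeline consumes can be generated here with a fixed
seed: per-biotype reference libraries (mature tRNAs assembled from
exons with the 3' CCA and 50-bp flanks, YRNA genes with pseudogene
copies, a planted piRNA duplicating a Gly tRNA 5' end to reproduce the
tRNA/piRNA shared-read phenomenon, a genome embedding every record
between random intergenic spacers), single samples following a
:class:`~exsmallrna.profiles.BiofluidProfile`, and multi-sample
cohorts with subject structure (lognormal inter- and intra-subject
dispersion of per-miRNA abundance).

Each emitted read is logged in a truth table (biotype, source record,
end class, intended insert length), so recovery of generator
parameters by the pipeline can be checked exactly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawRead
from .profiles import (
    BiofluidProfile,
    GENOME_CLASSES,
    MAX_INSERT,
)
from .references import FLANK_LENGTH, ReferenceBundle, ReferenceRecord

BASES = np.array(list("ACGT"))

#: tRNA isoacceptor families shipped by default (covers every family
#: named in the biofluid profiles).
TRNA_FAMILIES = (
    "GlyGCC", "ValCAC", "ValAAC", "ProCGG", "GluCTC", "GlnTTG", "ProTGG",
    "GlnCTG", "LysCTT", "GluTTC", "GlyCCC", "MetCAT", "LysTTT", "HisGTG",
    "LeuCAG", "AlaAGC", "SerGCT", "ArgTCT", "IleAAT", "ThrTGT",
)

YRNA_GENES = {"RNY1": 112, "RNY3": 101, "RNY4": 96, "RNY5": 83}

DEFAULT_N_PER_BIOTYPE = {
    "rRNA": 3,
    "miRNA": 150,
    "tRNA": 40,
    "piRNA": 20,
    "YRNA": 8,  # 4 canonical genes + pseudogene copies
    "other_ncRNA": 10,
    "protein_coding": 10,
}

DEFAULT_READ_LENGTH = 50
#: Sequence downstream of the 3' adapter (index/primer side) used to pad
#: reads out to the read length.
POST_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTGAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"
HIGH_QUALITY = 37
LOW_QUALITY = 2

#: Insert-length range for read classes without an explicit profile
#: distribution (rRNA and other annotation fragments).
GENERIC_LENGTHS = (20, 34)
TOO_SHORT_LENGTHS = (5, 14)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, positions: list[int]) -> str:
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


@dataclass
class SyntheticReferences:
    """A reference bundle plus generator-side extras."""

    bundle: ReferenceBundle
    spacers: list[str]
    seed: int

    def trna_families(self) -> dict[str, list[ReferenceRecord]]:
        fams: dict[str, list[ReferenceRecord]] = {}
        for rec in self.bundle.by_biotype("tRNA"):
            fams.setdefault(rec.family, []).append(rec)
        return fams

    def yrna_parents(self) -> dict[str, list[ReferenceRecord]]:
        out: dict[str, list[ReferenceRecord]] = {}
        for rec in self.bundle.by_biotype("YRNA"):
            out.setdefault(rec.parent or rec.id, []).append(rec)
        return out


def build_synthetic_references(
    n_per_biotype: dict[str, int] | None = None,
    seed: int = 1,
    plant_shared_pirna: bool = True,
    spacer_length: int = 300,
    fragment_simulation: bool = True,
) -> SyntheticReferences:
    """Deterministically generate a full reference bundle.

    Mature tRNAs are built from random exons (isodecoders of one family
    share their 5' half, as real families do) with CCA appended and
    50-nt flank records.  YRNA pseudogenes copy a canonical gene with a
    few internal substitutions so 5' fragments multimap within the
    parent group.  One piRNA is planted as the exact 30-nt prefix of a
    GlyGCC tRNA, reproducing the tRNA/piRNA shared-read overlap.  The
    genome embeds every record between random intergenic spacers.
    """
    n = dict(DEFAULT_N_PER_BIOTYPE)
    if n_per_biotype:
        n.update(n_per_biotype)
    missing = set(DEFAULT_N_PER_BIOTYPE) - set(n)
    if missing:
        raise ValueError(f"n_per_biotype missing biotypes: {sorted(missing)}")
    if fragment_simulation and (n["tRNA"] == 0 or n["YRNA"] == 0):
        raise ValueError("fragment simulation requires tRNA and YRNA references")

    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []

    rrna_lengths = (500, 900, 1500)
    for i in range(n["rRNA"]):
        length = rrna_lengths[i % len(rrna_lengths)]
        records.append(ReferenceRecord(f"rRNA-{i + 1}", "rRNA", _random_seq(rng, length)))

    for i in range(n["miRNA"]):
        length = int(rng.integers(20, 24))
        records.append(ReferenceRecord(f"miR-{i + 1}", "miRNA", _random_seq(rng, length)))

    # tRNAs: per-family consensus body; isodecoders mutate two bases in
    # the 3' half so the 5' ends stay identical within a family
    n_fam = len(TRNA_FAMILIES)
    consensus = {}
    for fam in TRNA_FAMILIES:
        body_len = int(rng.integers(70, 74))
        consensus[fam] = _random_seq(rng, body_len)
    for i in range(n["tRNA"]):
        fam = TRNA_FAMILIES[i % n_fam]
        body = consensus[fam]
        copy_idx = i // n_fam
        if copy_idx > 0:
            positions = sorted(
                int(p) for p in rng.choice(
                    np.arange(45, len(body)), size=2, replace=False
                )
            )
            body = _mutate(rng, body, positions)
        records.extend(
            _build_trna_records(
                f"tRNA-{fam}-{copy_idx + 1}", body, fam,
                _random_seq(rng, FLANK_LENGTH), _random_seq(rng, FLANK_LENGTH),
            )
        )

    # YRNAs: canonical genes plus pseudogenes sharing the parent 5' half
    yrna_ids = list(YRNA_GENES)
    canon_seq = {}
    for gene, length in YRNA_GENES.items():
        canon_seq[gene] = _random_seq(rng, length)
        records.append(ReferenceRecord(gene, "YRNA", canon_seq[gene], parent=gene))
    for j in range(max(0, n["YRNA"] - len(YRNA_GENES))):
        gene = yrna_ids[j % len(yrna_ids)]
        seq = canon_seq[gene]
        positions = sorted(
            int(p) for p in rng.choice(np.arange(45, len(seq) - 5), size=3, replace=False)
        )
        records.append(
            ReferenceRecord(
                f"{gene}P{j + 1}", "YRNA", _mutate(rng, seq, positions), parent=gene
            )
        )

    gly = next(r for r in records if r.biotype == "tRNA" and r.family == "GlyGCC")
    for i in range(n["piRNA"]):
        if plant_shared_pirna and i == 0:
            seq = gly.sequence[:30]  # exact tRNA 5'-end duplicate
        else:
            seq = _random_seq(rng, int(rng.integers(26, 32)))
        records.append(ReferenceRecord(f"piR-syn-{i + 1}", "piRNA", seq))

    for i in range(n["other_ncRNA"]):
        records.append(
            ReferenceRecord(
                f"ncRNA-{i + 1}", "other_ncRNA", _random_seq(rng, int(rng.integers(80, 301)))
            )
        )
    for i in range(n["protein_coding"]):
        records.append(
            ReferenceRecord(
                f"pc-{i + 1}", "protein_coding", _random_seq(rng, int(rng.integers(200, 501)))
            )
        )

    spacers = [_random_seq(rng, spacer_length) for _ in range(len(records) + 1)]
    chrom_parts = [spacers[0]]
    for rec, spacer in zip(records, spacers[1:]):
        chrom_parts.append(rec.sequence)
        chrom_parts.append(spacer)
    genome = {"chr1": "".join(chrom_parts)}

    return SyntheticReferences(
        ReferenceBundle(records, genome=genome), spacers=spacers, seed=seed
    )


def _build_trna_records(
    trna_id: str, body: str, family: str, flank5: str, flank3: str
) -> list[ReferenceRecord]:
    from .references import build_mature_trna

    return build_mature_trna(trna_id, [body], flank5=flank5, flank3=flank3, family=family)


# -------------------------------------------------------------- species

def build_synthetic_species(
    n_species: int = 5, replicon_length: int = 3000, seed: int = 7
) -> tuple[dict[str, dict[str, str]], dict[str, str], dict[str, str]]:
    """Random bacterial "species" genomes plus a toy taxonomy.

    Returns (species -> {replicon -> sequence}, child -> parent map,
    node -> rank map) with species grouped pairwise into genera and up
    through family/order/class/phylum.
    """
    rng = np.random.default_rng(seed)
    species = {
        f"species_{i + 1}": {f"species_{i + 1}_chrom": _random_seq(rng, replicon_length)}
        for i in range(n_species)
    }
    parents: dict[str, str] = {}
    ranks: dict[str, str] = {}
    for i, sp in enumerate(species):
        chain = [
            (sp, "species"),
            (f"genus_{i // 2 + 1}", "genus"),
            (f"family_{i // 4 + 1}", "family"),
            ("order_1", "order"),
            ("class_1", "class"),
            ("phylum_1", "phylum"),
        ]
        for (child, crank), (parent, prank) in zip(chain, chain[1:]):
            parents[child] = parent
            ranks[child] = crank
            ranks[parent] = prank
    return species, parents, ranks


# --------------------------------------------------------------- sample

@dataclass
class SimulatedSample:
    """Reads plus the row-per-read truth table."""

    sample_id: str
    reads: list[RawRead]
    truth: pd.DataFrame
    profile_name: str
    adapter: str

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fastq = out / f"{self.sample_id}.fastq.gz"
        with gzip.open(fastq, "wt") as fh:
            for read in self.reads:
                qual = "".join(chr(q + 33) for q in read.quality)
                fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
        truth_path = out / f"{self.sample_id}.truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return fastq, truth_path


def global_mirna_weights(n: int, decay: float = 0.8) -> np.ndarray:
    """Skewed (power-law) global miRNA abundance weights."""
    w = 1.0 / np.arange(1, n + 1) ** decay
    return w / w.sum()


def _sample_lengths(rng, dist: dict[int, float], size: int) -> np.ndarray:
    lengths = np.fromiter(dist.keys(), dtype=int)
    probs = np.fromiter(dist.values(), dtype=float)
    return lengths[rng.choice(len(lengths), size=size, p=probs / probs.sum())]


def simulate_sample(
    profile: BiofluidProfile,
    refs: SyntheticReferences,
    n_reads: int,
    seed: int,
    sample_id: str = "sample",
    read_length: int = DEFAULT_READ_LENGTH,
    mirna_weights: np.ndarray | None = None,
    species: dict[str, dict[str, str]] | None = None,
    low_quality_tail: int = 0,
) -> SimulatedSample:
    """Emit ``n_reads`` reads following a biofluid profile, with truth rows.

    Inserts are drawn per the profile (category, then biotype-specific
    source and length), the 3' adapter is appended and the read padded
    to ``read_length`` with downstream primer sequence.  Qualities are
    constant Q37 except an optional ``low_quality_tail`` of Q2 bases at
    the 3' end (to exercise quality trimming).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    profile.validate()
    rng = np.random.default_rng(seed)

    trna_fams = refs.trna_families()
    yrna_parents = refs.yrna_parents()
    if profile.biotype_proportions.get("tRNA", 0) > 0 and not trna_fams:
        raise ValueError("profile requests tRNA reads but references contain no tRNA")
    for fam in profile.family_weights:
        if fam != "other" and fam not in trna_fams:
            raise ValueError(f"profile family {fam!r} not present in references")
    other_fams = sorted(set(trna_fams) - set(profile.family_weights))

    mirnas = refs.bundle.by_biotype("miRNA")
    if mirna_weights is None:
        mirna_weights = global_mirna_weights(len(mirnas))
    pirnas = refs.bundle.by_biotype("piRNA")
    rrnas = refs.bundle.by_biotype("rRNA")
    by_class = {
        "other_ncRNA": refs.bundle.by_biotype("other_ncRNA"),
        "protein_coding": refs.bundle.by_biotype("protein_coding"),
    }
    species_names = sorted(species) if species else []

    categories = ["too_short", "rRNA", "exogenous"] + list(GENOME_CLASSES)
    genome_mass = 1.0 - (
        profile.too_short_fraction + profile.rrna_fraction + profile.exogenous_fraction
    )
    probs = np.array(
        [profile.too_short_fraction, profile.rrna_fraction, profile.exogenous_fraction]
        + [genome_mass * profile.biotype_proportions.get(c, 0.0) for c in GENOME_CLASSES]
    )
    cat_idx = rng.choice(len(categories), size=n_reads, p=probs / probs.sum())

    full_adapter = profile.adapter + POST_ADAPTER

    seqs: list[str] = []
    truth_rows = {
        "read_id": [], "category": [], "record_id": [], "group": [],
        "end_class": [], "insert_length": [],
    }

    def emit(i: int, insert: str, category: str, record_id: str, group: str, end_class: str):
        if len(insert) > read_length:
            raise ValueError(
                f"insert of length {len(insert)} exceeds read length {read_length}"
            )
        read = (insert + full_adapter)[:read_length]
        seqs.append(read)
        truth_rows["read_id"].append(f"{sample_id}:{i}")
        truth_rows["category"].append(category)
        truth_rows["record_id"].append(record_id)
        truth_rows["group"].append(group)
        truth_rows["end_class"].append(end_class)
        truth_rows["insert_length"].append(len(insert))

    fam_names = list(profile.family_weights)
    fam_probs = np.array([profile.family_weights[f] for f in fam_names])
    parent_names = list(profile.parent_weights) or sorted(yrna_parents)
    parent_probs = (
        np.array([profile.parent_weights[p] for p in parent_names])
        if profile.parent_weights
        else np.ones(len(parent_names))
    )

    for i in range(n_reads):
        category = categories[cat_idx[i]]
        if category == "too_short":
            length = int(rng.integers(TOO_SHORT_LENGTHS[0], TOO_SHORT_LENGTHS[1] + 1))
            emit(i, _random_seq(rng, length), category, "", "", "")
        elif category == "rRNA":
            rec = rrnas[rng.integers(0, len(rrnas))]
            length = int(rng.integers(GENERIC_LENGTHS[0], GENERIC_LENGTHS[1] + 1))
            start = int(rng.integers(0, len(rec.sequence) - length + 1))
            emit(i, rec.sequence[start : start + length], category, rec.id, "", "")
        elif category == "exogenous":
            if not species_names:
                # exogenous reads requested but no species genomes: random junk
                length = int(rng.integers(GENERIC_LENGTHS[0], GENERIC_LENGTHS[1] + 1))
                emit(i, _random_seq(rng, length), category, "", "", "")
            else:
                sp = species_names[rng.integers(0, len(species_names))]
                replicons = species[sp]
                rep = sorted(replicons)[rng.integers(0, len(replicons))]
                seq = replicons[rep]
                length = int(rng.integers(GENERIC_LENGTHS[0], GENERIC_LENGTHS[1] + 1))
                start = int(rng.integers(0, len(seq) - length + 1))
                emit(i, seq[start : start + length], category, rep, sp, "")
        elif category == "miRNA":
            j = int(rng.choice(len(mirnas), p=mirna_weights))
            emit(i, mirnas[j].sequence, category, mirnas[j].id, "", "")
        elif category == "piRNA":
            rec = pirnas[rng.integers(0, len(pirnas))]
            emit(i, rec.sequence, category, rec.id, "", "")
        elif category == "tRNA":
            fam = fam_names[rng.choice(len(fam_names), p=fam_probs / fam_probs.sum())]
            if fam == "other":
                fam = other_fams[rng.integers(0, len(other_fams))]
            recs = trna_fams[fam]
            rec = recs[rng.integers(0, len(recs))]
            insert, end_class = _fragment_insert(rng, rec.sequence, profile, "tRNA")
            emit(i, insert, category, rec.id, fam, end_class)
        elif category == "YRNA":
            pname = parent_names[rng.choice(len(parent_names), p=parent_probs / parent_probs.sum())]
            recs = yrna_parents[pname]
            rec = recs[rng.integers(0, len(recs))]
            insert, end_class = _fragment_insert(rng, rec.sequence, profile, "YRNA")
            emit(i, insert, category, rec.id, pname, end_class)
        elif category == "intergenic":
            spacer = refs.spacers[rng.integers(0, len(refs.spacers))]
            length = int(rng.integers(GENERIC_LENGTHS[0], GENERIC_LENGTHS[1] + 1))
            start = int(rng.integers(0, len(spacer) - length + 1))
            emit(i, spacer[start : start + length], category, "", "", "")
        else:  # other_ncRNA / protein_coding
            recs = by_class[category]
            rec = recs[rng.integers(0, len(recs))]
            length = int(rng.integers(GENERIC_LENGTHS[0], GENERIC_LENGTHS[1] + 1))
            start = int(rng.integers(0, len(rec.sequence) - length + 1))
            emit(i, rec.sequence[start : start + length], category, rec.id, "", "")

    reads = []
    for i, seq in enumerate(seqs):
        qual = [HIGH_QUALITY] * len(seq)
        if low_quality_tail:
            tail = min(low_quality_tail, len(seq))
            qual[len(seq) - tail :] = [LOW_QUALITY] * tail
        reads.append(RawRead(f"{sample_id}:{i}", seq, tuple(qual)))

    truth = pd.DataFrame(truth_rows)
    return SimulatedSample(sample_id, reads, truth, profile.name, profile.adapter)


def _fragment_insert(
    rng: np.random.Generator, parent: str, profile: BiofluidProfile, biotype: str
) -> tuple[str, str]:
    ends = profile.end_class_proportions[biotype]
    names = list(ends)
    end_class = names[rng.choice(len(names), p=np.array([ends[e] for e in names]))]
    dist = profile.length_distribution[biotype]
    length = int(_sample_lengths(rng, dist, 1)[0])
    length = min(length, len(parent) - 2, MAX_INSERT)
    if end_class == "F5":
        return parent[:length], "F5"
    if end_class == "F3":
        return parent[-length:], "F3"
    start = int(rng.integers(1, len(parent) - length))
    return parent[start : start + length], "FM"


# --------------------------------------------------------------- cohort

@dataclass
class CohortConfig:
    n_subjects: int
    samples_per_subject: int
    fluid: str
    inter_subject_sd: float
    intra_subject_sd: float
    reads_per_sample: int
    seed: int

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.samples_per_subject < 1:
            raise ValueError("samples_per_subject must be >= 1")
        if self.inter_subject_sd < 0 or self.intra_subject_sd < 0:
            raise ValueError("dispersion sds must be >= 0")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")


@dataclass
class SimulatedCohort:
    sample_sheet: pd.DataFrame  # sample_id, subject_id, fluid
    samples: list[SimulatedSample]
    mirna_ids: list[str]
    expected_weights: pd.DataFrame  # miRNA x sample expected proportions


def _cohort_weights(
    cfg: CohortConfig, n_mirna: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample expected miRNA proportions under the lognormal model.

    expected abundance = global mean x subject effect x sample effect,
    with effects lognormal(0, inter_sd) and lognormal(0, intra_sd).
    """
    base = global_mirna_weights(n_mirna)
    sheet_rows = []
    cols = {}
    for s in range(cfg.n_subjects):
        subject_id = f"subj{s + 1:02d}"
        subject_effect = np.exp(rng.normal(0.0, cfg.inter_subject_sd, size=n_mirna))
        for r in range(cfg.samples_per_subject):
            sample_id = f"{subject_id}_s{r + 1:02d}"
            sample_effect = np.exp(rng.normal(0.0, cfg.intra_subject_sd, size=n_mirna))
            w = base * subject_effect * sample_effect
            cols[sample_id] = w / w.sum()
            sheet_rows.append({"sample_id": sample_id, "subject_id": subject_id, "fluid": cfg.fluid})
    sheet = pd.DataFrame(sheet_rows)
    return sheet, pd.DataFrame(cols)


def simulate_cohort(
    cfg: CohortConfig,
    profile: BiofluidProfile,
    refs: SyntheticReferences,
    species: dict[str, dict[str, str]] | None = None,
) -> SimulatedCohort:
    """Read-level cohort: one FASTQ-able sample per subject x replicate."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mirnas = [r.id for r in refs.bundle.by_biotype("miRNA")]
    sheet, weights = _cohort_weights(cfg, len(mirnas), rng)
    weights.index = pd.Index(mirnas, name="miRNA")
    samples = []
    for row in sheet.itertuples():
        sample = simulate_sample(
            profile,
            refs,
            cfg.reads_per_sample,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=row.sample_id,
            mirna_weights=weights[row.sample_id].to_numpy(),
            species=species,
        )
        sample.truth["sample_id"] = row.sample_id
        sample.truth["subject_id"] = row.subject_id
        samples.append(sample)
    return SimulatedCohort(sheet, samples, mirnas, weights)


def simulate_cohort_counts(
    cfg: CohortConfig, n_mirna: int = 150
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-level cohort fast path for statistics at realistic depth.

    Draws the per-sample miRNA count vector directly as a multinomial
    over the same lognormal subject/sample-effect expected proportions
    the read-level simulator uses.  Returns (counts, sample sheet).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sheet, weights = _cohort_weights(cfg, n_mirna, rng)
    counts = {
        sid: rng.multinomial(cfg.reads_per_sample, weights[sid].to_numpy())
        for sid in weights.columns
    }
    matrix = pd.DataFrame(
        counts, index=pd.Index([f"miR-{i + 1}" for i in range(n_mirna)], name="miRNA")
    )
    return matrix, sheet
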