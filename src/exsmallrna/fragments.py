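"""tRNA / YRNA fragment analysis.

Reads mapping to a mature parent RNA are classified by which end of the
parent they span: fragments carrying the parent's 5' end are tRF5/YRF5,
the 3' end tRF3/YRF3, and strictly internal fragments tRFM/YRFM.  Reads
sharing an anchored end on the same parents are nested prefixes (or
suffixes) of one another; each such stack is collapsed to its longest
sequence with the read counts summed.  The same engine serves tRNA
fragments (grouped by isoacceptor family, e.g. GlyGCC) and YRNA
fragments (grouped by parent gene, e.g. RNY4).

Terminal evidence wins every tie: a read that is simultaneously a
prefix and a suffix (or internal elsewhere) is classed 5'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .assign import AssignmentTable
from .references import ReferenceBundle

END_CLASSES = ("F5", "F3", "FM")


@dataclass(frozen=True)
class ClassifiedRead:
    """One collapsed read sequence with its end class on its parent group."""

    sequence: str
    count: int
    end_class: str
    parent_group: frozenset[str]


@dataclass(frozen=True)
class FragmentRecord:
    """A collapsed fragment: longest member of a stack, counts summed."""

    collapsed_sequence: str
    parent_group: frozenset[str]
    end_class: str
    count: int

    @property
    def length(self) -> int:
        return len(self.collapsed_sequence)


def classify_fragment(
    seq: str, parents: Mapping[str, str]
) -> tuple[str, frozenset[str]]:
    """End class of ``seq`` against its matched parent mature sequences.

    F5 if the read is a prefix of any parent, else F3 if a suffix, else
    FM; the parent group is the set of parents supporting the chosen
    class.
    """
    matched = {pid: ps for pid, ps in parents.items() if seq in ps}
    if not matched:
        raise ValueError("sequence matches none of the given parents")
    f5 = frozenset(pid for pid, ps in matched.items() if ps.startswith(seq))
    if f5:
        return "F5", f5
    f3 = frozenset(pid for pid, ps in matched.items() if ps.endswith(seq))
    if f3:
        return "F3", f3
    return "FM", frozenset(matched)


def collapse_fragments(
    classified: Sequence[ClassifiedRead],
    require_shared_parents: bool = False,
) -> list[FragmentRecord]:
    """Collapse nested end-anchored stacks to their longest sequence.

    5'-anchored reads that are prefixes of a longer 5' fragment join its
    stack (symmetrically for 3' suffixes); middle fragments collapse
    only when identical.  Output counts conserve input counts exactly.

    With ``require_shared_parents`` the whole input must share at least
    one parent (the single-parent-group calling convention); mixed
    groups raise.
    """
    if require_shared_parents and classified:
        common = set(classified[0].parent_group)
        for cr in classified[1:]:
            common &= cr.parent_group
        if not common:
            raise ValueError("mixed parent groups: inputs share no common parent")

    out: list[FragmentRecord] = []
    for end_class, anchored in (("F5", str.startswith), ("F3", str.endswith)):
        members = sorted(
            (c for c in classified if c.end_class == end_class),
            key=lambda c: (-len(c.sequence), c.sequence),
        )
        stacks: list[list[ClassifiedRead]] = []
        for cr in members:
            for stack in stacks:
                rep = stack[0].sequence
                if anchored(rep, cr.sequence):
                    stack.append(cr)
                    break
            else:
                stacks.append([cr])
        for stack in stacks:
            out.append(
                FragmentRecord(
                    stack[0].sequence,
                    stack[0].parent_group,
                    end_class,
                    sum(c.count for c in stack),
                )
            )
    mid: dict[str, list[ClassifiedRead]] = {}
    for cr in classified:
        if cr.end_class == "FM":
            mid.setdefault(cr.sequence, []).append(cr)
    for seq, group in mid.items():
        out.append(
            FragmentRecord(seq, group[0].parent_group, "FM", sum(c.count for c in group))
        )
    return out


def extract_fragment_reads(
    assignment: AssignmentTable, bundle: ReferenceBundle, biotype: str
) -> list[tuple[str, int]]:
    """Collapsed reads with at least one annotation hit on ``biotype`` records.

    All reads that map to the mature parents are used, including reads
    whose resolved category is ``shared`` (e.g. the tRNA/piRNA overlap).
    """
    out = []
    for seq, cnt in zip(assignment.table["sequence"], assignment.table["count"]):
        hits = assignment.annotation_hits.get(seq)
        if hits and any(bundle[h.record_id].biotype == biotype for h in hits):
            out.append((seq, int(cnt)))
    return out


def classify_fragment_reads(
    fragment_reads: Iterable[tuple[str, int]],
    parents: Mapping[str, str],
) -> list[ClassifiedRead]:
    out = []
    for seq, cnt in fragment_reads:
        end_class, group = classify_fragment(seq, parents)
        out.append(ClassifiedRead(seq, cnt, end_class, group))
    return out


def analyze_fragments(
    assignment: AssignmentTable, bundle: ReferenceBundle, biotype: str = "tRNA"
) -> tuple[list[FragmentRecord], list[ClassifiedRead]]:
    """Full fragment pass for one biotype: select, classify, collapse."""
    parents = {r.id: r.sequence for r in bundle.by_biotype(biotype)}
    reads = extract_fragment_reads(assignment, bundle, biotype)
    classified = classify_fragment_reads(reads, parents)
    return collapse_fragments(classified), classified


def default_grouping(bundle: ReferenceBundle, biotype: str) -> Callable[[str], str]:
    """tRNAs group by isoacceptor family; YRNAs by parent gene."""
    if biotype == "tRNA":
        return lambda rid: bundle[rid].family or rid
    return lambda rid: bundle[rid].parent or rid


def fragment_table(
    records: Sequence[FragmentRecord], group_of: Callable[[str], str]
) -> pd.DataFrame:
    """Long-form fragment table: sequence, group, end_class, count, length.

    A fragment whose parents span several groups is labelled
    ``ambiguous`` rather than split across them.
    """
    rows = []
    for rec in records:
        groups = {group_of(rid) for rid in rec.parent_group}
        group = groups.pop() if len(groups) == 1 else "ambiguous"
        rows.append((rec.collapsed_sequence, group, rec.end_class, rec.count, rec.length))
    return pd.DataFrame(rows, columns=["sequence", "group", "end_class", "count", "length"])


def end_class_percentages(
    records: Sequence[FragmentRecord], size_factor: float = 1.0
) -> dict[str, float]:
    """Percent of fragment-assigned (normalized) reads per end class."""
    totals = {e: 0.0 for e in END_CLASSES}
    for rec in records:
        totals[rec.end_class] += rec.count / size_factor
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no fragment reads")
    return {e: 100.0 * v / grand for e, v in totals.items()}


def family_summary(
    records: Sequence[FragmentRecord],
    group_of: Callable[[str], str],
    size_factor: float = 1.0,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Percent of fragment-assigned normalized reads per family/parent group.

    With ``top_n``, groups past the top N collapse into ``Other``.
    Columns: group, normalized_count, percent, pct_F5, pct_F3, pct_FM.
    """
    tab = fragment_table(records, group_of)
    if tab.empty or tab["count"].sum() == 0:
        raise ValueError("no fragment reads to summarize")
    tab = tab.assign(norm=tab["count"] / size_factor)
    total = tab["norm"].sum()
    agg = (
        tab.pivot_table(index="group", columns="end_class", values="norm", aggfunc="sum")
        .reindex(columns=END_CLASSES)
        .fillna(0.0)
    )
    agg["normalized_count"] = agg[list(END_CLASSES)].sum(axis=1)
    agg = agg.sort_values("normalized_count", ascending=False)
    if top_n is not None and len(agg) > top_n:
        head, tail = agg.iloc[:top_n], agg.iloc[top_n:]
        other = tail.sum().to_frame().T
        other.index = pd.Index(["Other"], name="group")
        agg = pd.concat([head, other])
    out = pd.DataFrame(index=agg.index)
    out["normalized_count"] = agg["normalized_count"]
    out["percent"] = 100.0 * agg["normalized_count"] / total
    for e in END_CLASSES:
        with pd.option_context("mode.chained_assignment", None):
            out[f"pct_{e}"] = (
                100.0 * agg[e] / agg["normalized_count"].where(agg["normalized_count"] > 0)
            ).fillna(0.0)
    return out.reset_index()


def group_end_share(
    records: Sequence[FragmentRecord],
    group_of: Callable[[str], str],
    group: str,
    end_class: str,
    size_factor: float = 1.0,
) -> float:
    """Percent of all fragment-assigned reads in one (group, end-class) cell."""
    tab = fragment_table(records, group_of)
    total = tab["count"].sum() / size_factor
    if total == 0:
        raise ValueError("no fragment reads")
    cell = tab.loc[(tab["group"] == group) & (tab["end_class"] == end_class), "count"].sum()
    return 100.0 * (cell / size_factor) / total


def length_distribution(
    fragment_reads: Iterable[tuple[str, int]], genome_mapped_total: int
) -> pd.Series:
    """Pre-collapse read-length histogram in RPM of genome-mapped reads.

    The histogram reflects the lengths of the original reads (weighted
    by their counts), not of the collapsed fragments.
    """
    counts: dict[int, int] = {}
    for seq, cnt in fragment_reads:
        counts[len(seq)] = counts.get(len(seq), 0) + cnt
    if not counts:
        return pd.Series(dtype=float, name="rpm")
    if genome_mapped_total <= 0:
        raise ValueError("genome_mapped_total must be positive")
    ser = pd.Series(counts, name="rpm").sort_index()
    return ser * 1e6 / genome_mapped_total
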