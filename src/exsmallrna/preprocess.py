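"""Raw-read preprocessing: 3' adapter clipping, quality trimming, length
filtering and sequence collapsing.

Small-RNA libraries read through the insert into the 3' sequencing
adapter, so the adapter is clipped from the 3' end (suffix overlap
allowed, one error per 10 adapter bases), then 3' bases below Q30 are
trimmed, reads shorter than 15 nt are discarded, and identical
sequences are collapsed to one record carrying the summed read count.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

DEFAULT_MIN_LENGTH = 15
DEFAULT_QMIN = 30
MIN_ADAPTER_OVERLAP = 3


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class CollapsedRead:
    """A unique insert sequence with its summed read count."""

    sequence: str
    count: int


@dataclass
class PreprocessStats:
    n_input: int = 0
    n_too_short: int = 0
    n_kept: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_too_short": self.n_too_short,
                "n_kept": self.n_kept,
                "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
            },
            indent=2,
        )


def _adapter_errors_allowed(overlap: int, max_error_rate: float) -> int:
    return int(overlap * max_error_rate)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_adapter_start(seq: str, adapter: str, max_error_rate: float = 0.1) -> int | None:
    """Return the start of the best 3' adapter occurrence, or None.

    Considers every start position where either the full adapter or a
    3'-terminal adapter prefix (>= 3 nt overlap) aligns within the error
    budget ``floor(overlap * max_error_rate)``; among candidates the
    longest overlap wins, ties broken by fewer errors then leftmost
    position.  Equivalent to an exhaustive scan (checked against one in
    the tests) but with exact-match fast paths for the common case.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(seq), len(adapter)
    # fast path: a full exact adapter occurrence is always optimal
    # (maximal overlap, zero errors, leftmost by construction)
    pos = seq.find(adapter)
    if pos >= 0:
        return pos
    best: tuple[int, int, int] | None = None  # (-overlap, errors, start)
    for start in range(0, n - MIN_ADAPTER_OVERLAP + 1):
        overlap = min(m, n - start)
        errors = _hamming(seq[start : start + overlap], adapter[:overlap])
        if errors <= _adapter_errors_allowed(overlap, max_error_rate):
            key = (-overlap, errors, start)
            if best is None or key < best:
                best = key
    return None if best is None else best[2]


def trim_adapter(read: RawRead, adapter: str, max_error_rate: float = 0.1) -> RawRead:
    """Clip the 3' adapter; reads without a match are returned unchanged."""
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    start = find_adapter_start(read.sequence, adapter, max_error_rate)
    if start is None:
        return read
    return RawRead(read.id, read.sequence[:start], read.quality[:start])


def quality_trim_3prime(read: RawRead, qmin: int = DEFAULT_QMIN) -> RawRead:
    """Remove the longest 3' suffix whose every base is below ``qmin``."""
    end = len(read.quality)
    while end > 0 and read.quality[end - 1] < qmin:
        end -= 1
    if end == len(read.quality):
        return read
    return RawRead(read.id, read.sequence[:end], read.quality[:end])


def length_filter(
    reads: Iterable[RawRead], min_len: int = DEFAULT_MIN_LENGTH
) -> tuple[list[RawRead], PreprocessStats]:
    """Drop reads shorter than ``min_len``, accounting them as too-short."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    stats = PreprocessStats()
    kept: list[RawRead] = []
    for read in reads:
        stats.n_input += 1
        n = len(read)
        if n < min_len:
            stats.n_too_short += 1
            continue
        stats.n_kept += 1
        stats.length_histogram[n] = stats.length_histogram.get(n, 0) + 1
        kept.append(read)
    return kept, stats


def collapse_reads(reads: Iterable[RawRead | str]) -> list[CollapsedRead]:
    """Collapse identical sequences; sorted by (count desc, sequence asc)."""
    counts: Counter[str] = Counter(
        r if isinstance(r, str) else r.sequence for r in reads
    )
    return sorted(
        (CollapsedRead(seq, c) for seq, c in counts.items()),
        key=lambda cr: (-cr.count, cr.sequence),
    )


def preprocess_reads(
    reads: Iterable[RawRead],
    adapter: str,
    min_len: int = DEFAULT_MIN_LENGTH,
    qmin: int = DEFAULT_QMIN,
    max_error_rate: float = 0.1,
) -> tuple[list[CollapsedRead], PreprocessStats]:
    """Full preprocessing driver: clip adapter, quality-trim, filter, collapse.

    Adapter-search results are memoized per raw sequence: identical raw
    sequences trim identically, and library reads are highly redundant.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    cache: dict[str, int | None] = {}

    def trimmed() -> Iterator[RawRead]:
        for r in reads:
            start = cache.get(r.sequence, -2)
            if start == -2:
                start = find_adapter_start(r.sequence, adapter, max_error_rate)
                cache[r.sequence] = start
            clipped = r if start is None else RawRead(r.id, r.sequence[:start], r.quality[:start])
            yield quality_trim_3prime(clipped, qmin)

    kept, stats = length_filter(trimmed(), min_len)
    return collapse_reads(kept), stats


# ---------------------------------------------------------------- file I/O

def parse_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a (optionally gzipped) Sanger FASTQ file as RawReads."""
    p = Path(path)
    opener = gzip.open if p.suffix == ".gz" else open
    with opener(p, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield RawRead(header[1:].split()[0], seq, tuple(ord(c) - 33 for c in qual))


def write_collapsed_tsv(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for cr in collapsed:
            fh.write(f"{cr.sequence}\t{cr.count}\n")


def read_collapsed_tsv(path: str | Path) -> list[CollapsedRead]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            seq, count = line.rstrip("\n").split("\t")
            out.append(CollapsedRead(seq, int(count)))
    return out
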