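"""End-to-end per-sample driver: preprocess -> assign -> profile."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .assign import (
    AssignmentTable,
    BiotypeProfile,
    biotype_profile,
    build_stage_indexes,
    hierarchical_assign,
)
from .preprocess import CollapsedRead, PreprocessStats, RawRead, preprocess_reads
from .references import ReferenceBundle, SeedIndex


@dataclass
class SampleResult:
    sample_id: str
    collapsed: list[CollapsedRead]
    stats: PreprocessStats
    assignment: AssignmentTable
    profile: BiotypeProfile

    @property
    def genome_mapped(self) -> int:
        return self.profile.denominator_genome_mapped

    @property
    def input_reads_ge15(self) -> int:
        return self.stats.n_kept


def run_sample(
    reads: Iterable[RawRead],
    bundle: ReferenceBundle,
    adapter: str,
    sample_id: str = "sample",
    indexes: dict[str, SeedIndex] | None = None,
) -> SampleResult:
    """Preprocess raw reads and assign them hierarchically to biotypes."""
    collapsed, stats = preprocess_reads(reads, adapter)
    assignment = hierarchical_assign(
        collapsed, bundle, n_too_short=stats.n_too_short, _indexes=indexes
    )
    profile = biotype_profile(assignment, sample_id)
    return SampleResult(sample_id, collapsed, stats, assignment, profile)


__all__ = ["SampleResult", "run_sample", "build_stage_indexes"]
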