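"""End-to-end orchestration: reads -> tags -> assignments -> binding summary."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .binding_quantify import (
    BindingSummary,
    CorrelationResult,
    correlate_with_editing_extent,
    summarize_binding,
    total_shares,
)
from .editing_aware_align import (
    AlignmentParams,
    TagAssignment,
    map_library,
    project_to_transcripts,
)
from .mito_reference import PAN_EDITED, ReferencePair
from .synthetic_data import SimulatedWorld
from .tag_preprocess import PreprocessResult, preprocess


@dataclass
class LibraryResult:
    """Mapped and summarized output of one demultiplexed library."""

    library: str
    assignments: list[TagAssignment]
    summary: BindingSummary


@dataclass
class PipelineResult:
    preprocess: PreprocessResult
    libraries: dict[str, LibraryResult]


def run_pipeline(
    reads: Iterable[tuple[str, str]],
    pair: ReferencePair,
    adapter: str,
    barcode_table: Mapping[str, str],
    params: AlignmentParams = AlignmentParams(),
    min_insert_length: int = 20,
) -> PipelineResult:
    """Preprocess raw reads, map each library to the dual reference, summarize."""
    pre = preprocess(reads, adapter, barcode_table, min_insert_length=min_insert_length)
    libraries: dict[str, LibraryResult] = {}
    annotations = list(pair.annotations.values())
    for lib, tags in pre.libraries.items():
        assignments = project_to_transcripts(map_library(tags, pair, params), pair)
        libraries[lib] = LibraryResult(lib, assignments, summarize_binding(assignments, annotations))
    return PipelineResult(pre, libraries)


def pan_edited_correlation(
    summary: BindingSummary, world: SimulatedWorld
) -> CorrelationResult:
    """Pearson r between total binding share and editing extent over pan-edited RNAs."""
    counts = summary.counts
    shares = total_shares(counts)
    pan = counts.index[counts["category"] == PAN_EDITED]
    return correlate_with_editing_extent(
        {t: float(shares[t]) for t in pan}, {t: world.extents[t] for t in pan}
    )
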