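"""Binding summaries: counts, shares, densities, coverage, and the editing correlation.

All quantities are computed over uniquely mapped, sense, intra-transcript
tags only (multimapped, antisense, and intergenic tags are excluded), and for
transcripts undergoing editing the preedited and fully edited tag counts are
combined into the per-transcript total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .editing_aware_align import FLAG_OK, FULLY_EDITED, PREEDITED, TagAssignment
from .mito_reference import CATEGORIES, EDITING_CATEGORIES, TranscriptAnnotation


@dataclass
class CorrelationResult:
    """Pearson correlation between editing extent (x) and binding share (y)."""

    r: float
    n: int
    x: np.ndarray
    y: np.ndarray


def _counted(assignments: Iterable[TagAssignment]) -> list[TagAssignment]:
    return [
        a
        for a in assignments
        if a.status in (PREEDITED, FULLY_EDITED) and a.flag == FLAG_OK
    ]


def count_per_transcript(
    assignments: Iterable[TagAssignment],
    annotations: Iterable[TranscriptAnnotation],
) -> pd.DataFrame:
    """Unique-tag counts per transcript, split by reference frame.

    Returns a frame indexed by transcript_id with columns ``category``,
    ``length``, ``n_preedited``, ``n_fully_edited``, ``n_total``; every
    annotated transcript is present (zeros when unbound).
    """
    anns = list(annotations)
    counts = pd.DataFrame(
        {
            "category": [a.category for a in anns],
            "length": [a.length for a in anns],
            "n_preedited": 0,
            "n_fully_edited": 0,
        },
        index=pd.Index([a.transcript_id for a in anns], name="transcript_id"),
    )
    for a in _counted(assignments):
        col = "n_preedited" if a.status == PREEDITED else "n_fully_edited"
        counts.loc[a.transcript_id, col] += 1
    counts["n_total"] = counts["n_preedited"] + counts["n_fully_edited"]
    return counts


def category_shares(counts: pd.DataFrame) -> pd.Series:
    """Percent of uniquely mapped tags per editing category (sums to 100)."""
    per_cat = counts.groupby("category")["n_total"].sum().reindex(CATEGORIES, fill_value=0)
    grand = per_cat.sum()
    if grand == 0:
        return pd.Series(np.nan, index=per_cat.index, name="percent")
    return (100.0 * per_cat / grand).rename("percent")


def region_shares(counts: pd.DataFrame) -> dict[str, float]:
    """Percent preedited vs fully edited among editing-category tags.

    Never-edited transcripts are excluded from the denominator: they exist in
    the genome frame only, so including them would inflate the preedited side.
    """
    editing = counts[counts["category"].isin(EDITING_CATEGORIES)]
    denom = editing["n_total"].sum()
    if denom == 0:
        return {"preedited": float("nan"), "fully_edited": float("nan")}
    return {
        "preedited": 100.0 * editing["n_preedited"].sum() / denom,
        "fully_edited": 100.0 * editing["n_fully_edited"].sum() / denom,
    }


def length_normalized_density(counts: pd.DataFrame) -> pd.Series:
    """Tags per kilonucleotide of preedited transcript length."""
    return (1000.0 * counts["n_total"] / counts["length"]).rename("tags_per_knt")


def total_shares(counts: pd.DataFrame) -> pd.Series:
    """Per-transcript percent of all uniquely mapped tags (preedited + edited)."""
    grand = counts["n_total"].sum()
    if grand == 0:
        return pd.Series(np.nan, index=counts.index, name="total_share_percent")
    return (100.0 * counts["n_total"] / grand).rename("total_share_percent")


def coverage_track(
    starts: Sequence[int], lengths: Sequence[int], track_length: int
) -> np.ndarray:
    """Per-position unique-tag coverage from tag start positions and lengths.

    Position i counts tags with start <= i < start + length; intervals are
    clipped to the track. With no clipping the track sums to the total tag
    length (mass conservation).
    """
    diff = np.zeros(track_length + 1, dtype=np.int64)
    for s, L in zip(starts, lengths):
        lo = max(0, int(s))
        hi = min(track_length, int(s) + int(L))
        if hi > lo:
            diff[lo] += 1
            diff[hi] -= 1
    return np.cumsum(diff[:-1])


def coverage_tracks(
    assignments: Iterable[TagAssignment],
    annotations: Mapping[str, TranscriptAnnotation],
    edited_lengths: Mapping[str, int],
) -> dict[tuple[str, str], np.ndarray]:
    """Coverage per (transcript, frame): preedited frame and fully edited frame."""
    grouped: dict[tuple[str, str], list[TagAssignment]] = {}
    for a in _counted(assignments):
        grouped.setdefault((a.transcript_id, a.status), []).append(a)
    tracks: dict[tuple[str, str], np.ndarray] = {}
    for (tid, frame), group in grouped.items():
        length = (
            annotations[tid].length if frame == PREEDITED else edited_lengths[tid]
        )
        tracks[(tid, frame)] = coverage_track(
            [a.tx_position for a in group], [a.length for a in group], length
        )
    return tracks


def five_prime_bias(starts: Sequence[int], region_length: int) -> float:
    """Fraction of tag 5' ends falling in the 5' third of the region.

    Uniform starts give ~1/3; a 5'-restricted binder approaches 1. NaN with
    no tags.
    """
    if len(starts) == 0:
        return float("nan")
    third = region_length / 3.0
    return float(np.mean(np.asarray(starts) < third))


def correlate_with_editing_extent(
    shares: Mapping[str, float], extents: Mapping[str, int]
) -> CorrelationResult:
    """Pearson r between per-transcript editing extent and total binding share."""
    tids = sorted(set(shares) & set(extents))
    if len(tids) < 3:
        raise ValueError("need >= 3 transcripts with defined shares and extents")
    x = np.array([extents[t] for t in tids], dtype=float)
    y = np.array([shares[t] for t in tids], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance in extents or shares; correlation undefined")
        return CorrelationResult(float("nan"), len(tids), x, y)
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r, len(tids), x, y)


@dataclass
class BindingSummary:
    """All headline binding quantities of one mapped library."""

    counts: pd.DataFrame
    category_shares: pd.Series
    region_shares: dict[str, float]
    densities: pd.Series
    total_shares: pd.Series


def summarize_binding(
    assignments: Iterable[TagAssignment],
    annotations: Iterable[TranscriptAnnotation],
) -> BindingSummary:
    assignments = list(assignments)
    counts = count_per_transcript(assignments, annotations)
    return BindingSummary(
        counts=counts,
        category_shares=category_shares(counts),
        region_shares=region_shares(counts),
        densities=length_normalized_density(counts),
        total_shares=total_shares(counts),
    )


# ---------------------------------------------------------------------------
# I/O


def write_summary(path: str | Path, summary: BindingSummary) -> None:
    df = summary.counts.copy()
    df["tags_per_knt"] = summary.densities
    df["total_share_percent"] = summary.total_shares
    df.to_csv(path, sep="\t")


def write_bedgraph(path: str | Path, track: np.ndarray, chrom: str) -> None:
    """bedGraph (0-based half-open) of a coverage track, run-length encoded."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{chrom}"\n')
        if len(track) == 0:
            return
        start = 0
        current = track[0]
        for i in range(1, len(track)):
            if track[i] != current:
                fh.write(f"{chrom}\t{start}\t{i}\t{current}\n")
                start, current = i, track[i]
        fh.write(f"{chrom}\t{start}\t{len(track)}\t{current}\n")
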