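"""Editing-aware dual-reference tag classification.

Tags are mapped sequentially: first against the maxicircle genome, then —
only if they found no genome locus at all — against the catenated fully
edited transcript catalog. A tag with exactly one best-scoring locus on the
genome is classified ``preedited``; a unique best locus on the edited
reference makes it ``fully_edited``; ties at the best score make it
``multimapped`` and exclude it from binding counts; everything else is
``unmapped``. Because a tag spanning an editing site carries inserted or
deleted Us, it cannot align ungapped to the genome and is rescued only by the
edited reference — the editing state is discriminated by the dual references,
not by gapped alignment.

The aligner itself is exact ungapped seed-and-extend: every locus where the
full tag matches with at most ``max_mismatches`` substitutions and a score of
``min_score_fraction`` x tag length is reported. Seeds are disjoint exact
k-mers; with ``m`` allowed mismatches and ``m + 1`` disjoint seeds the
pigeonhole principle guarantees one seed is error-free, so no qualifying
locus is missed (the seed length shrinks automatically for short tags to
preserve this guarantee). Score = matches x match_score - mismatches x
mismatch_penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .mito_reference import ReferencePair, TranscriptAnnotation, revcomp
from .tag_preprocess import Tag

PREEDITED = "preedited"
FULLY_EDITED = "fully_edited"
UNMAPPED = "unmapped"
MULTIMAPPED = "multimapped"
STATUSES = (PREEDITED, FULLY_EDITED, UNMAPPED, MULTIMAPPED)

FLAG_OK = "ok"
FLAG_INTERGENIC = "intergenic"
FLAG_ANTISENSE = "antisense"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and seeding parameters for the ungapped aligner."""

    seed_length: int = 12
    max_mismatches: int = 2
    mismatch_penalty: float = 1.0
    match_score: float = 1.0
    min_score_fraction: float = 0.9

    def allowed_mismatches(self, tag_length: int) -> int:
        """Largest mismatch count compatible with both acceptance rules.

        score(m) = L*match - m*(match + penalty) must stay >= min_score_fraction
        * L * match, and m <= max_mismatches.
        """
        by_score = math.floor(
            tag_length * self.match_score * (1.0 - self.min_score_fraction)
            / (self.match_score + self.mismatch_penalty)
            + 1e-9
        )
        return min(self.max_mismatches, by_score)

    def score(self, tag_length: int, mismatches: int) -> float:
        return (tag_length - mismatches) * self.match_score - mismatches * self.mismatch_penalty


@dataclass(frozen=True)
class Hit:
    """One ungapped alignment locus of a full tag."""

    ref_id: str
    start: int  # 0-based start on the forward reference strand
    strand: str
    score: float
    mismatches: int


@dataclass
class TagAssignment:
    """A tag's classification, and its unique locus when mapped."""

    tag_id: str
    status: str
    length: int
    multiplicity: int = 1
    ref_id: str | None = None
    position: int | None = None
    strand: str | None = None
    score: float = float("nan")
    transcript_id: str | None = None
    tx_position: int | None = None
    flag: str | None = None


class SeedIndex:
    """Exact k-mer lookup over a set of reference sequences.

    Indexes are built lazily per seed length (short tags need shorter seeds
    to keep the pigeonhole guarantee). k-mers containing N (spacers) are
    skipped.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = dict(sequences)
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _build(self, k: int) -> dict[str, list[tuple[str, int]]]:
        index: dict[str, list[tuple[str, int]]] = {}
        for ref_id, seq in self.sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ref_id, pos))
        return index

    def lookup(self, k: int, kmer: str) -> list[tuple[str, int]]:
        if k not in self._indexes:
            self._indexes[k] = self._build(k)
        return self._indexes[k].get(kmer, ())


def align_tag(
    tag_sequence: str, index: SeedIndex, params: AlignmentParams = AlignmentParams()
) -> list[Hit]:
    """All loci where the tag aligns ungapped within the acceptance rules.

    Both strands of every reference are searched; minus-strand hits report the
    start of the reverse-complemented tag in forward reference coordinates.
    Tags shorter than the seed length are unalignable by contract.
    """
    L = len(tag_sequence)
    if L < params.seed_length:
        return []
    allowed = params.allowed_mismatches(L)
    k = min(params.seed_length, L // (allowed + 1))
    offsets = [i * k for i in range(allowed + 1)]
    hits: dict[tuple[str, int, str], Hit] = {}
    for strand, oriented in (("+", tag_sequence), ("-", revcomp(tag_sequence))):
        for off in offsets:
            for ref_id, pos in index.lookup(k, oriented[off : off + k]):
                start = pos - off
                ref = index.sequences[ref_id]
                if start < 0 or start + L > len(ref):
                    continue
                key = (ref_id, start, strand)
                if key in hits:
                    continue
                window = ref[start : start + L]
                if window == oriented:
                    mm = 0
                else:
                    mm = 0
                    for a, b in zip(oriented, window):
                        if a != b:
                            mm += 1
                            if mm > allowed:
                                break
                    if mm > allowed:
                        continue
                hits[key] = Hit(ref_id, start, strand, params.score(L, mm), mm)
    return list(hits.values())


def _classify(hits: Sequence[Hit]) -> Hit | None | str:
    """Unique best-score hit, None when empty, MULTIMAPPED on a best-score tie."""
    if not hits:
        return None
    best = max(h.score for h in hits)
    top = [h for h in hits if h.score == best]
    return top[0] if len(top) == 1 else MULTIMAPPED


GENOME_REF_ID = "maxicircle"
EDITED_REF_ID = "edited_catalog"


def map_library(
    tags: Iterable[Tag],
    pair: ReferencePair,
    params: AlignmentParams = AlignmentParams(),
) -> list[TagAssignment]:
    """Sequential two-reference mapping of a tag library.

    Stage 1 maps every tag to the maxicircle genome: a unique best locus
    fixes the tag as ``preedited`` (it is never re-mapped), a best-score tie
    discards it as ``multimapped``. Stage 2 maps the remaining hitless tags
    to the catenated fully edited reference under the same uniqueness rule.
    """
    genome_index = SeedIndex({GENOME_REF_ID: pair.genome})
    edited_index = SeedIndex({EDITED_REF_ID: pair.catenated})
    assignments: list[TagAssignment] = []
    for tag in tags:
        a = TagAssignment(tag.tag_id, UNMAPPED, len(tag.sequence), tag.multiplicity)
        for status, idx in ((PREEDITED, genome_index), (FULLY_EDITED, edited_index)):
            outcome = _classify(align_tag(tag.sequence, idx, params))
            if outcome is None:
                continue
            if outcome == MULTIMAPPED:
                a.status = MULTIMAPPED
            else:
                a.status = status
                a.ref_id = outcome.ref_id
                a.position = outcome.start
                a.strand = outcome.strand
                a.score = outcome.score
            break
        assignments.append(a)
    return assignments


def project_to_transcripts(
    assignments: Iterable[TagAssignment], pair: ReferencePair
) -> list[TagAssignment]:
    """Translate mapped loci into transcript coordinates.

    Genome hits are assigned to the annotated transcript containing their
    start (``intergenic`` otherwise) and must agree with the annotation
    strand — tags derive from mRNA, so antisense hits are flagged and
    excluded from binding counts. Edited-reference hits are translated via
    the catenated coordinate map; sense in that frame is the plus strand.
    Transcript positions are the tag's 5' offset in transcript orientation.
    """
    anns = sorted(pair.annotations.values(), key=lambda a: a.start)
    out: list[TagAssignment] = []
    for a in assignments:
        a = TagAssignment(**vars(a))
        if a.status == PREEDITED:
            ann = next(
                (x for x in anns if x.start <= a.position < x.end), None
            )
            if ann is None:
                a.flag = FLAG_INTERGENIC
            else:
                a.transcript_id = ann.transcript_id
                if a.strand != ann.strand:
                    a.flag = FLAG_ANTISENSE
                else:
                    a.flag = FLAG_OK
                    if ann.strand == "+":
                        a.tx_position = a.position - ann.start
                    else:
                        a.tx_position = ann.end - (a.position + a.length)
        elif a.status == FULLY_EDITED:
            located = pair.map_catenated(a.position)
            end_located = pair.map_catenated(a.position + a.length - 1)
            assert located is not None and end_located is not None, (
                "edited-reference hit crosses a spacer"
            )
            tid, j = located
            assert end_located[0] == tid, "edited-reference hit spans two transcripts"
            a.transcript_id = tid
            if a.strand != "+":
                a.flag = FLAG_ANTISENSE
            else:
                a.flag = FLAG_OK
                a.tx_position = j
        out.append(a)
    return out


# ---------------------------------------------------------------------------
# I/O


def assignments_to_dataframe(assignments: Iterable[TagAssignment]):
    import pandas as pd

    return pd.DataFrame([vars(a) for a in assignments])


def write_assignments(path: str | Path, assignments: Iterable[TagAssignment]) -> None:
    assignments_to_dataframe(assignments).to_csv(path, sep="\t", index=False)


def write_sam(
    path: str | Path,
    assignments: Iterable[TagAssignment],
    pair: ReferencePair,
    tags: Mapping[str, str] | None = None,
) -> None:
    """Emit mapped assignments as SAM (1-based coordinates) for browser views."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{GENOME_REF_ID}\tLN:{len(pair.genome)}\n")
        fh.write(f"@SQ\tSN:{EDITED_REF_ID}\tLN:{len(pair.catenated)}\n")
        for a in assignments:
            if a.status not in (PREEDITED, FULLY_EDITED):
                continue
            flag = 16 if a.strand == "-" else 0
            seq = (tags or {}).get(a.tag_id, "*")
            if flag == 16 and seq != "*":
                seq = revcomp(seq)
            fh.write(
                f"{a.tag_id}\t{flag}\t{a.ref_id}\t{a.position + 1}\t255\t"
                f"{a.length}M\t*\t0\t0\t{seq}\t*\n"
            )
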