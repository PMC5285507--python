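"""Maxicircle transcript models and uridine-insertion/deletion editing references.

Kinetoplastid mitochondrial (maxicircle) mRNAs fall into three categories:
pan-edited transcripts that are extensively remodelled by guide-RNA-directed
uridine (U) insertion/deletion editing, minimally edited transcripts with a
single small edited region, and never-edited transcripts. Because editing
only ever adds or removes Us, the preedited (genome-encoded) and fully edited
forms of a transcript share an identical non-U backbone.

This module models editing events on the preedited sequence, builds the pair
of references used for editing-aware tag classification — the maxicircle
genome plus a catenated catalog of fully edited transcripts — and counts the
editing extent (total Us inserted plus deleted) of each transcript.

Everything is in the DNA alphabet: reads are cDNA and references genomic, so
U is stored as T throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PAN_EDITED = "pan_edited"
MINIMALLY_EDITED = "minimally_edited"
NEVER_EDITED = "never_edited"
CATEGORIES = (PAN_EDITED, MINIMALLY_EDITED, NEVER_EDITED)
#: Categories whose transcripts have a fully edited form (and hence appear in
#: the catenated edited reference).
EDITING_CATEGORIES = (PAN_EDITED, MINIMALLY_EDITED)

INSERTION = "insertion"
DELETION = "deletion"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class EditingModelError(ValueError):
    """Raised for inconsistent annotations, events, or sequence pairs."""


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One maxicircle transcript: a genome interval plus its editing category.

    Coordinates are 0-based half-open on the maxicircle genome; ``strand`` is
    ``+`` or ``-``; ``category`` is one of :data:`CATEGORIES`.
    """

    transcript_id: str
    start: int
    end: int
    strand: str
    category: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise EditingModelError(
                f"{self.transcript_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise EditingModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.category not in CATEGORIES:
            raise EditingModelError(
                f"{self.transcript_id}: unknown category {self.category!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EditingEvent:
    """A single U-insertion or U-deletion event on a preedited transcript.

    ``anchor`` is a 0-based position in the preedited transcript sequence
    (transcript orientation); the event applies immediately 3' of that base:
    an insertion places ``n_u`` Ts after it, a deletion removes ``n_u`` Ts
    that must already follow it.
    """

    transcript_id: str
    anchor: int
    kind: str
    n_u: int

    def __post_init__(self) -> None:
        if self.kind not in (INSERTION, DELETION):
            raise EditingModelError(f"unknown event kind {self.kind!r}")
        if self.n_u < 1:
            raise EditingModelError(f"{self}: n_u must be >= 1")
        if self.anchor < 0:
            raise EditingModelError(f"{self}: negative anchor")


@dataclass(frozen=True)
class EditingExtent:
    """Total Us inserted and deleted between preedited and fully edited forms."""

    transcript_id: str
    insertions: int
    deletions: int

    @property
    def total(self) -> int:
        return self.insertions + self.deletions


def transcript_sequence(genome: str, annotation: TranscriptAnnotation) -> str:
    """Preedited transcript sequence in transcript (mRNA sense) orientation."""
    if annotation.end > len(genome):
        raise EditingModelError(
            f"{annotation.transcript_id} extends past genome end ({annotation.end} > {len(genome)})"
        )
    s = genome[annotation.start : annotation.end]
    return revcomp(s) if annotation.strand == "-" else s


def build_edited_sequence(preedited_seq: str, events: Sequence[EditingEvent]) -> str:
    """Apply U-insertion/deletion events to a preedited transcript sequence.

    Events are applied from the highest anchor to the lowest so that anchor
    coordinates (which refer to the preedited sequence) never shift. The
    output length is input length + total insertions - total deletions, and
    removing every T from input and output yields identical strings.
    """
    n = len(preedited_seq)
    anchors = [e.anchor for e in events]
    if len(set(anchors)) != len(anchors):
        raise EditingModelError("events of one transcript must have distinct anchors")
    seq = preedited_seq
    for e in sorted(events, key=lambda e: e.anchor, reverse=True):
        if e.anchor >= n:
            raise EditingModelError(f"{e}: anchor beyond sequence of length {n}")
        cut = e.anchor + 1
        if e.kind == INSERTION:
            seq = seq[:cut] + "T" * e.n_u + seq[cut:]
        else:
            run = preedited_seq[cut : cut + e.n_u]
            if len(run) < e.n_u or set(run) != {"T"}:
                raise EditingModelError(
                    f"{e}: deletion needs {e.n_u} consecutive Us after anchor {e.anchor}"
                )
            seq = seq[:cut] + seq[cut + e.n_u :]
    return seq


def _t_run_decomposition(seq: str) -> tuple[str, list[int]]:
    """Split a sequence into its non-T backbone and the T-run length in each gap.

    Returns ``(backbone, runs)`` where ``runs`` has ``len(backbone) + 1``
    entries: the number of Ts before the first backbone base, between each
    consecutive pair, and after the last.
    """
    backbone: list[str] = []
    runs = [0]
    for c in seq:
        if c == "T":
            runs[-1] += 1
        else:
            backbone.append(c)
            runs.append(0)
    return "".join(backbone), runs


def count_editing_extent(
    preedited_seq: str, edited_seq: str, transcript_id: str = ""
) -> EditingExtent:
    """Minimal U-only edit counts between a preedited/edited sequence pair.

    The two sequences must be identical after removing all Ts (the non-U
    backbone is conserved by editing). Aligning them while allowing only
    T-indels forces every backbone base to match, so the minimal alignment
    simply compares the T-run lengths gap by gap: a surplus of Ts in the
    edited sequence counts as insertions, a deficit as deletions.
    """
    pre_bb, pre_runs = _t_run_decomposition(preedited_seq)
    ed_bb, ed_runs = _t_run_decomposition(edited_seq)
    if pre_bb != ed_bb:
        raise EditingModelError(
            f"{transcript_id or 'sequence pair'}: non-U backbones differ; "
            "not an editing pair"
        )
    insertions = sum(max(0, e - p) for p, e in zip(pre_runs, ed_runs))
    deletions = sum(max(0, p - e) for p, e in zip(pre_runs, ed_runs))
    return EditingExtent(transcript_id, insertions, deletions)


@dataclass
class ReferencePair:
    """Dual reference for editing-aware tag classification.

    ``genome`` is the (circular) maxicircle sequence; ``edited_catalog`` maps
    each editing-category transcript to its fully edited sequence, catenated
    into ``catenated`` with runs of ``spacer_length`` Ns between entries so no
    tag can align across a junction. ``offsets`` locate each transcript in the
    catenated frame.
    """

    genome: str
    annotations: dict[str, TranscriptAnnotation]
    events: dict[str, tuple[EditingEvent, ...]]
    edited_catalog: dict[str, str]
    offsets: dict[str, int]
    catenated: str
    spacer_length: int = 100
    _starts: list[tuple[int, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._starts = sorted((off, tid) for tid, off in self.offsets.items())

    def map_catenated(self, position: int) -> tuple[str, int] | None:
        """Map a catenated-reference position to ``(transcript_id, position)``.

        Returns None for positions inside a spacer.
        """
        if not 0 <= position < len(self.catenated):
            raise IndexError(f"position {position} outside catenated reference")
        tid = None
        for off, t in self._starts:
            if off <= position:
                tid = t
            else:
                break
        if tid is None:
            return None
        j = position - self.offsets[tid]
        if j >= len(self.edited_catalog[tid]):
            return None  # spacer
        return tid, j

    def preedited_sequence(self, transcript_id: str) -> str:
        return transcript_sequence(self.genome, self.annotations[transcript_id])


def build_reference_pair(
    genome: str,
    annotations: Iterable[TranscriptAnnotation],
    events: Iterable[EditingEvent],
    spacer_length: int = 100,
) -> ReferencePair:
    """Build the preedited-genome / catenated-fully-edited reference pair.

    Only editing-category (pan- and minimally edited) transcripts enter the
    edited catalog; never-edited transcripts exist in the genome frame only
    and must carry no events.
    """
    ann_map = {a.transcript_id: a for a in annotations}
    for a in ann_map.values():
        if a.end > len(genome):
            raise EditingModelError(f"{a.transcript_id} outside genome bounds")
    by_tid: dict[str, list[EditingEvent]] = {}
    for e in events:
        if e.transcript_id not in ann_map:
            raise EditingModelError(f"event for unknown transcript {e.transcript_id!r}")
        if ann_map[e.transcript_id].category == NEVER_EDITED:
            raise EditingModelError(
                f"never-edited transcript {e.transcript_id} cannot carry editing events"
            )
        by_tid.setdefault(e.transcript_id, []).append(e)

    catalog: dict[str, str] = {}
    for tid, ann in ann_map.items():
        if ann.category not in EDITING_CATEGORIES:
            continue
        pre = transcript_sequence(genome, ann)
        catalog[tid] = build_edited_sequence(pre, by_tid.get(tid, []))

    offsets: dict[str, int] = {}
    parts: list[str] = []
    pos = 0
    spacer = "N" * spacer_length
    for i, (tid, seq) in enumerate(catalog.items()):
        if i:
            parts.append(spacer)
            pos += spacer_length
        offsets[tid] = pos
        parts.append(seq)
        pos += len(seq)

    return ReferencePair(
        genome=genome,
        annotations=ann_map,
        events={t: tuple(v) for t, v in by_tid.items()},
        edited_catalog=catalog,
        offsets=offsets,
        catenated="".join(parts),
        spacer_length=spacer_length,
    )


def editing_extents(pair: ReferencePair) -> dict[str, EditingExtent]:
    """Per-transcript editing extent; never-edited transcripts get (0, 0)."""
    out: dict[str, EditingExtent] = {}
    for tid, ann in pair.annotations.items():
        if tid in pair.edited_catalog:
            out[tid] = count_editing_extent(
                pair.preedited_sequence(tid), pair.edited_catalog[tid], tid
            )
        else:
            out[tid] = EditingExtent(tid, 0, 0)
    return out


# ---------------------------------------------------------------------------
# I/O helpers (plain FASTA and tab-separated tables)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path: str | Path) -> list[TranscriptAnnotation]:
    """Read a transcript table: transcript_id, start, end, strand, category."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TranscriptAnnotation(r.transcript_id, int(r.start), int(r.end), r.strand, r.category)
        for r in df.itertuples()
    ]


def write_annotations(path: str | Path, annotations: Iterable[TranscriptAnnotation]) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (a.transcript_id, a.start, a.end, a.strand, a.category)
            for a in annotations
        ],
        columns=["transcript_id", "start", "end", "strand", "category"],
    ).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[EditingEvent]:
    """Read an event table: transcript_id, anchor, kind, n_u."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        EditingEvent(r.transcript_id, int(r.anchor), r.kind, int(r.n_u))
        for r in df.itertuples()
    ]


def write_events(path: str | Path, events: Iterable[EditingEvent]) -> None:
    import pandas as pd

    pd.DataFrame(
        [(e.transcript_id, e.anchor, e.kind, e.n_u) for e in events],
        columns=["transcript_id", "anchor", "kind", "n_u"],
    ).to_csv(path, sep="\t", index=False)


def write_extent_table(path: str | Path, extents: Mapping[str, EditingExtent]) -> None:
    import pandas as pd

    pd.DataFrame(
        [(x.transcript_id, x.insertions, x.deletions, x.total) for x in extents.values()],
        columns=["transcript_id", "insertions", "deletions", "total"],
    ).to_csv(path, sep="\t", index=False)
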