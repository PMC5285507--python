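"""Raw-read preprocessing: adapter trimming, duplicate collapsing, demultiplexing.

The processing chain is trim 3' adapters -> collapse PCR duplicates ->
split libraries on 4-nt experimental barcodes, in that order. Collapsing is
by exact full-sequence identity (quality strings are ignored), so collapsing
before or after an exact-prefix demultiplex yields the same per-library
unique-tag counts; keeping the collapse first matches the published chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_BARCODE_LENGTH = 4
DEFAULT_MIN_INSERT_LENGTH = 20
DEFAULT_MIN_OVERLAP = 5
DEFAULT_MAX_ADAPTER_MISMATCHES = 1


@dataclass
class Tag:
    """One processed cross-link tag: barcode-stripped insert plus provenance."""

    tag_id: str
    sequence: str
    library: str
    multiplicity: int = 1


@dataclass
class PreprocessReport:
    """Read accounting for one preprocessing run.

    Conservation invariant: ``n_input == assigned multiplicities +
    n_short_discarded + unassigned multiplicities``.
    """

    n_input: int = 0
    n_short_discarded: int = 0
    n_unassigned_reads: int = 0
    per_library_reads: dict[str, int] = field(default_factory=dict)
    per_library_unique: dict[str, int] = field(default_factory=dict)


@dataclass
class PreprocessResult:
    libraries: dict[str, list[Tag]]
    unassigned: list[Tag]
    report: PreprocessReport


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatches: int = DEFAULT_MAX_ADAPTER_MISMATCHES,
) -> str:
    """Remove the longest read suffix matching a prefix of the 3' adapter.

    A suffix starting at cut point ``c`` matches if its overlap with the
    adapter (the first ``min(len(read) - c, len(adapter))`` characters) agrees
    up to ``max_mismatches`` and is at least ``min_overlap`` long. The longest
    matching suffix (smallest ``c``) wins; untrimmable reads pass through.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, alen = len(read), len(adapter)
    for cut in range(0, n - min_overlap + 1):
        k = min(n - cut, alen)
        mm = 0
        for i in range(k):
            if read[cut + i] != adapter[i]:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return read[:cut]
    return read


def collapse_duplicates(
    reads: Iterable[str | tuple[str, int]],
) -> list[tuple[str, int]]:
    """Collapse identical sequences into (sequence, multiplicity), order-preserving.

    Accepts plain sequences or already-collapsed (sequence, count) pairs,
    which makes the operation idempotent.
    """
    counts: dict[str, int] = {}
    for item in reads:
        if isinstance(item, str):
            seq, n = item, 1
        else:
            seq, n = item
        counts[seq] = counts.get(seq, 0) + n
    return list(counts.items())


def _validate_barcodes(
    barcode_table: Mapping[str, str] | Iterable[tuple[str, str]],
    barcode_length: int,
) -> dict[str, str]:
    pairs = (
        list(barcode_table.items())
        if isinstance(barcode_table, Mapping)
        else list(barcode_table)
    )
    table: dict[str, str] = {}
    for barcode, library in pairs:
        if len(barcode) != barcode_length:
            raise ValueError(f"barcode {barcode!r} is not {barcode_length} nt")
        if barcode in table:
            raise ValueError(f"duplicate barcode {barcode!r} in table")
        table[barcode] = library
    return table


def demultiplex(
    collapsed: Sequence[tuple[str, int]],
    barcode_table: Mapping[str, str] | Iterable[tuple[str, str]],
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
) -> tuple[dict[str, list[Tag]], list[Tag]]:
    """Assign collapsed tags to libraries by exact match of their leading barcode.

    The barcode is stripped from assigned tags; tags with an unlisted prefix
    are routed to the unassigned bin with their barcode left in place.
    """
    table = _validate_barcodes(barcode_table, barcode_length)
    libraries: dict[str, list[Tag]] = {lib: [] for lib in table.values()}
    unassigned: list[Tag] = []
    for i, (seq, mult) in enumerate(collapsed):
        library = table.get(seq[:barcode_length])
        if library is None:
            unassigned.append(Tag(f"tag{i:07d}", seq, "unassigned", mult))
        else:
            libraries[library].append(
                Tag(f"tag{i:07d}", seq[barcode_length:], library, mult)
            )
    return libraries, unassigned


def preprocess(
    reads: Iterable[tuple[str, str] | str],
    adapter: str,
    barcode_table: Mapping[str, str] | Iterable[tuple[str, str]],
    min_insert_length: int = DEFAULT_MIN_INSERT_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_adapter_mismatches: int = DEFAULT_MAX_ADAPTER_MISMATCHES,
    barcode_length: int = DEFAULT_BARCODE_LENGTH,
) -> PreprocessResult:
    """Full chain: trim -> length filter -> collapse -> demultiplex, with accounting."""
    report = PreprocessReport()
    trimmed: list[str] = []
    min_total = min_insert_length + barcode_length
    for item in reads:
        seq = item if isinstance(item, str) else item[1]
        report.n_input += 1
        t = trim_adapter(seq, adapter, min_overlap, max_adapter_mismatches)
        if len(t) < min_total:
            report.n_short_discarded += 1
        else:
            trimmed.append(t)

    collapsed = collapse_duplicates(trimmed)
    libraries, unassigned = demultiplex(collapsed, barcode_table, barcode_length)

    report.n_unassigned_reads = sum(t.multiplicity for t in unassigned)
    for lib, tags in libraries.items():
        report.per_library_reads[lib] = sum(t.multiplicity for t in tags)
        report.per_library_unique[lib] = len(tags)
    assigned = sum(report.per_library_reads.values())
    assert report.n_input == assigned + report.n_short_discarded + report.n_unassigned_reads, (
        "read conservation violated"
    )
    return PreprocessResult(libraries, unassigned, report)


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    with open(path) as fh:
        return [(title.split()[0], seq.upper()) for title, seq, _ in FastqGeneralIterator(fh)]


def write_tags_fasta(path: str | Path, tags: Iterable[Tag]) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.tag_id} library={t.library} multiplicity={t.multiplicity}\n{t.sequence}\n")


def write_report(path: str | Path, report: PreprocessReport) -> None:
    import pandas as pd

    rows = [
        ("input_reads", report.n_input),
        ("short_discarded", report.n_short_discarded),
        ("unassigned_reads", report.n_unassigned_reads),
    ]
    rows += [(f"reads_{lib}", n) for lib, n in report.per_library_reads.items()]
    rows += [(f"unique_tags_{lib}", n) for lib, n in report.per_library_unique.items()]
    pd.DataFrame(rows, columns=["stage", "count"]).to_csv(path, sep="\t", index=False)
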