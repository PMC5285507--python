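"""Synthetic maxicircle world and iCLIP-style read libraries with ground truth.

The generator emulates the study system end to end so the whole pipeline runs
without any deposited data: a circular maxicircle-like genome carrying 18
protein-coding transcripts (9 pan-edited, 3 minimally edited, 6 never-edited),
a 3'-to-5' guide-RNA-block editing cascade that yields preedited, partially
edited, and fully edited molecules, a protein-binding model in which expected
tag counts scale with editing extent (or are confined to the 5' third of a
transcript), and iCLIP-style reads of the form

    4-nt experimental barcode + insert + 3' adapter (possibly truncated)

with geometric PCR duplication, uniform substitution sequencing error, and a
near-empty random-sequence control library. Every emitted read has exactly
one ground-truth record, so classification accuracy and binding recovery can
be scored exactly.

All randomness flows from ``numpy.random.default_rng`` seeds: identical
configuration and seed give byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mito_reference import (
    DELETION,
    EDITING_CATEGORIES,
    INSERTION,
    MINIMALLY_EDITED,
    NEVER_EDITED,
    PAN_EDITED,
    EditingEvent,
    EditingModelError,
    ReferencePair,
    TranscriptAnnotation,
    build_edited_sequence,
    build_reference_pair,
    editing_extents,
    transcript_sequence,
)

BINDING_MODELS = ("extent_proportional", "five_prime_restricted", "uniform")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic maxicircle world and read libraries.

    Defaults follow the study system: a ~23 kb circular genome, the 9/3/6
    pan/minimal/never transcript partition, editing extents of 50-550 U for
    pan-edited and 4-40 U for minimally edited transcripts, ~30-50 nt tags on
    75 nt single-end reads, and a 483-read control library.
    """

    seed: int = 0
    genome_length: int = 23_000
    n_pan_edited: int = 9
    n_minimally_edited: int = 3
    n_never_edited: int = 6
    transcript_length_range: tuple[int, int] = (500, 900)
    pan_extent_range: tuple[int, int] = (50, 550)
    minimal_extent_range: tuple[int, int] = (4, 40)
    deletion_fraction: float = 0.1  # share of editing extent realized as U deletions
    grna_block_length: int = 60  # preedited nt consumed per editing block, 3'->5'
    molecules_per_transcript: int = 30
    binding_model: str = "extent_proportional"
    baseline_weight: float = 5.0  # additive binding weight so never-edited RNAs get rare tags
    tag_length_range: tuple[int, int] = (30, 50)
    read_length: int = 75
    adapter: str = "AGATCGGAAGAGCGGTTCAG"
    pcr_duplication_rate: float = 0.3
    sequencing_error_rate: float = 0.001
    control_tag_count: int = 483

    def __post_init__(self) -> None:
        if self.binding_model not in BINDING_MODELS:
            raise ValueError(f"unknown binding model {self.binding_model!r}")
        lo, hi = self.tag_length_range
        if not (20 <= lo <= hi <= 60):
            raise ValueError("tag_length_range must lie within [20, 60]")
        for name in ("deletion_fraction", "pcr_duplication_rate", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.grna_block_length < 1:
            raise ValueError("grna_block_length must be positive")

    def to_json(self, path: str | Path) -> None:
        """Snapshot the configuration for provenance."""
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class Molecule:
    """One transcript molecule at a given point of the 3'->5' editing cascade.

    ``boundary`` is the preedited-frame coordinate of the editing front:
    positions 5' of it are still preedited, positions 3' of it carry every
    editing event of the completed blocks (hence match the fully edited
    sequence). Because all applied events anchor at or 3' of the boundary,
    the molecule prefix ``sequence[:boundary]`` equals the preedited prefix.
    """

    transcript_id: str
    progress: int
    n_blocks: int
    boundary: int
    preedited_length: int
    sequence: str


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _gap_ids(seq: str) -> list[int]:
    """For each position, the index of the inter-backbone T-gap it anchors into."""
    ids = []
    g = 0
    for c in seq:
        if c != "T":
            g += 1
        ids.append(g)
    return ids


def random_editing_events(
    seq: str,
    transcript_id: str,
    target_extent: int,
    rng: np.random.Generator,
    deletion_fraction: float = 0.1,
) -> list[EditingEvent]:
    """Draw a valid editing-event set of (approximately exactly) ``target_extent`` U.

    Validity beyond the type invariants: no inter-backbone T-gap receives
    both an insertion and a deletion, and each preedited T-run hosts at most
    one deletion. Under these constraints the minimal U-only alignment cannot
    cancel events against each other, so the editing extent of the generated
    (preedited, edited) pair equals the per-kind sums of the event set.
    """
    if target_extent <= 0:
        return []
    gaps = _gap_ids(seq)
    events: list[EditingEvent] = []
    used_anchors: set[int] = set()
    del_gaps: set[int] = set()
    ins_gaps: set[int] = set()

    # Deletions first: anchored on the non-T base preceding a T-run.
    target_del = int(round(target_extent * deletion_fraction))
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "T":
            j = i
            while j < len(seq) and seq[j] == "T":
                j += 1
            if i > 0:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    order = rng.permutation(len(runs))
    deleted = 0
    for k in order:
        if deleted >= target_del:
            break
        run_start, run_len = runs[int(k)]
        anchor = run_start - 1
        if gaps[anchor] in del_gaps or anchor in used_anchors:
            continue
        n_u = int(min(run_len, target_del - deleted, 1 + rng.integers(0, 3)))
        events.append(EditingEvent(transcript_id, anchor, DELETION, n_u))
        used_anchors.add(anchor)
        del_gaps.add(gaps[anchor])
        deleted += n_u

    target_ins = target_extent - deleted
    free = [
        int(a)
        for a in rng.permutation(len(seq))
        if int(a) not in used_anchors and gaps[int(a)] not in del_gaps
    ]
    inserted = 0
    insertions: list[EditingEvent] = []
    for anchor in free:
        if inserted >= target_ins:
            break
        n_u = int(min(target_ins - inserted, 1 + rng.integers(0, 5)))
        insertions.append(EditingEvent(transcript_id, anchor, INSERTION, n_u))
        used_anchors.add(anchor)
        ins_gaps.add(gaps[anchor])
        inserted += n_u
    if inserted < target_ins:
        if not insertions:
            raise EditingModelError(
                f"{transcript_id}: could not place {target_ins} insertions on a "
                f"{len(seq)} nt transcript"
            )
        # top up the last event so the extent target is met exactly
        last = insertions[-1]
        insertions[-1] = EditingEvent(
            transcript_id, last.anchor, INSERTION, last.n_u + (target_ins - inserted)
        )
    return events + insertions


def simulate_maxicircle(
    config: SimulationConfig,
) -> tuple[str, list[TranscriptAnnotation], list[EditingEvent]]:
    """Generate a toy maxicircle genome, annotations, and editing events.

    Pan-edited transcripts receive total extents spread evenly (with jitter)
    across ``pan_extent_range`` so the binding/extent correlation is
    identifiable; minimally edited transcripts draw from
    ``minimal_extent_range``; never-edited transcripts carry no events.
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config.genome_length)

    labels = (
        [(f"PAN{i+1:02d}", PAN_EDITED) for i in range(config.n_pan_edited)]
        + [(f"MIN{i+1:02d}", MINIMALLY_EDITED) for i in range(config.n_minimally_edited)]
        + [(f"NEV{i+1:02d}", NEVER_EDITED) for i in range(config.n_never_edited)]
    )
    lo, hi = config.pan_extent_range
    pan_targets = np.linspace(lo, hi, max(config.n_pan_edited, 1)).round().astype(int)
    pan_targets = np.clip(pan_targets + rng.integers(-10, 11, size=len(pan_targets)), lo, hi)
    targets = {f"PAN{i+1:02d}": int(pan_targets[i]) for i in range(config.n_pan_edited)}
    mlo, mhi = config.minimal_extent_range
    for i in range(config.n_minimally_edited):
        targets[f"MIN{i+1:02d}"] = int(rng.integers(mlo, mhi + 1))

    order = rng.permutation(len(labels))
    annotations: list[TranscriptAnnotation] = []
    pos = int(rng.integers(50, 200))
    tlo, thi = config.transcript_length_range
    for k in order:
        tid, category = labels[int(k)]
        length = int(rng.integers(tlo, thi + 1))
        if pos + length > config.genome_length:
            raise EditingModelError(
                f"genome of {config.genome_length} nt too short for requested transcripts"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        annotations.append(TranscriptAnnotation(tid, pos, pos + length, strand, category))
        pos += length + int(rng.integers(50, 200))

    events: list[EditingEvent] = []
    for ann in annotations:
        if ann.category == NEVER_EDITED:
            continue
        pre = transcript_sequence(genome, ann)
        events.extend(
            random_editing_events(
                pre, ann.transcript_id, targets[ann.transcript_id], rng,
                deletion_fraction=config.deletion_fraction,
            )
        )
    return genome, annotations, events


def simulate_transcript_pool(
    config: SimulationConfig,
    genome: str,
    annotations: Sequence[TranscriptAnnotation],
    events: Sequence[EditingEvent],
    rng: np.random.Generator | None = None,
) -> dict[str, list[Molecule]]:
    """Draw molecules at random stages of the 3'->5' editing cascade.

    The preedited sequence is tiled into fixed-length guide-RNA blocks that
    are consumed strictly from the 3' end; a molecule with progress ``p``
    carries every event anchored in its ``p`` 3'-most blocks and nothing 5'
    of them. Progress is uniform over {0, ..., n_blocks}: progress 0 is the
    preedited molecule, full progress the fully edited one. Never-edited
    transcripts are always emitted unedited.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    by_tid: dict[str, list[EditingEvent]] = {}
    for e in events:
        by_tid.setdefault(e.transcript_id, []).append(e)

    pool: dict[str, list[Molecule]] = {}
    for ann in annotations:
        pre = transcript_sequence(genome, ann)
        n_blocks = math.ceil(len(pre) / config.grna_block_length)
        tx_events = by_tid.get(ann.transcript_id, [])
        cache: dict[int, tuple[int, str]] = {}
        mols: list[Molecule] = []
        for _ in range(config.molecules_per_transcript):
            if ann.category == NEVER_EDITED or not tx_events:
                progress = 0
            else:
                progress = int(rng.integers(0, n_blocks + 1))
            if progress not in cache:
                boundary = max(0, len(pre) - progress * config.grna_block_length)
                applied = [e for e in tx_events if e.anchor >= boundary]
                cache[progress] = (boundary, build_edited_sequence(pre, applied))
            boundary, seq = cache[progress]
            mols.append(
                Molecule(ann.transcript_id, progress, n_blocks, boundary, len(pre), seq)
            )
        pool[ann.transcript_id] = mols
    return pool


def molecule_at_progress(
    preedited_seq: str,
    events: Sequence[EditingEvent],
    progress: int,
    block_length: int,
    transcript_id: str = "",
) -> Molecule:
    """Deterministically build the molecule after ``progress`` completed blocks."""
    n_blocks = math.ceil(len(preedited_seq) / block_length)
    if not 0 <= progress <= n_blocks:
        raise ValueError(f"progress {progress} outside [0, {n_blocks}]")
    boundary = max(0, len(preedited_seq) - progress * block_length)
    applied = [e for e in events if e.anchor >= boundary]
    return Molecule(
        transcript_id, progress, n_blocks, boundary, len(preedited_seq),
        build_edited_sequence(preedited_seq, applied),
    )


def _binding_weights(
    config: SimulationConfig,
    transcript_ids: Sequence[str],
    extents: Mapping[str, int],
) -> np.ndarray:
    if config.binding_model == "uniform":
        w = np.ones(len(transcript_ids))
    else:
        w = np.array(
            [extents[t] + config.baseline_weight for t in transcript_ids], dtype=float
        )
    total = w.sum()
    if total <= 0:
        raise ValueError("all binding weights are zero")
    return w / total


def _inject_errors(read: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return read, 0
    n = rng.binomial(len(read), rate)
    if n == 0:
        return read, 0
    arr = bytearray(read, "ascii")
    positions = rng.choice(len(arr), size=n, replace=False)
    for p in positions:
        choices = [b for b in b"ACGT" if b != arr[p]]
        arr[p] = choices[int(rng.integers(0, len(choices)))]
    return arr.decode(), int(n)


GROUND_TRUTH_COLUMNS = [
    "read_id", "library", "family_id", "transcript_id", "progress", "boundary",
    "molecule_start", "insert_length", "frame", "n_errors",
]


def simulate_iclap_library(
    config: SimulationConfig,
    pool: Mapping[str, Sequence[Molecule]],
    extents: Mapping[str, int],
    barcode: str,
    library: str = "iclap",
    n_tags: int = 50_000,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one iCLIP-style library: reads plus per-read ground truth.

    ``n_tags`` cross-link events (unique cDNAs) are drawn: a transcript under
    the binding model, a molecule of its pool, and an insert of
    ``tag_length_range`` nt. Under ``five_prime_restricted`` insert 5' ends
    are confined to the 5' third of the preedited region; otherwise they are
    uniform over the molecule.
    Each cDNA is amplified into a geometric-size PCR family, and sequencing
    errors are applied per copy after duplication. The ground-truth ``frame``
    records whether the insert lies entirely 5' (``preedited``) or 3'
    (``edited``) of the molecule's editing front, or spans it (``junction``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if len(barcode) != 4:
        raise ValueError("experimental barcodes are 4 nt")
    tids = [t for t in pool if len(pool[t]) > 0]
    if not tids:
        raise ValueError("empty molecule pool")
    probs = _binding_weights(config, tids, extents)
    picks = rng.choice(len(tids), size=n_tags, p=probs)
    lo, hi = config.tag_length_range

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    for fam, k in enumerate(picks):
        tid = tids[int(k)]
        mols = pool[tid]
        mol = mols[int(rng.integers(0, len(mols)))]
        L = len(mol.sequence)
        ilen = min(int(rng.integers(lo, hi + 1)), L)
        if config.binding_model == "five_prime_restricted":
            # 5' ends confined to the 5' third of the preedited region
            max_start = min(max(mol.preedited_length // 3, 1), L - ilen + 1)
        else:
            max_start = L - ilen + 1
        start = int(rng.integers(0, max_start))
        insert = mol.sequence[start : start + ilen]
        end = start + ilen
        if end <= mol.boundary:
            frame = "preedited"
        elif start >= mol.boundary:
            frame = "edited"
        else:
            frame = "junction"
        template = (barcode + insert + config.adapter)[: config.read_length]
        if config.pcr_duplication_rate > 0:
            family_size = int(rng.geometric(1.0 - config.pcr_duplication_rate))
        else:
            family_size = 1
        for copy in range(family_size):
            seq, n_err = _inject_errors(template, config.sequencing_error_rate, rng)
            read_id = f"{library}:{fam:07d}:{copy}"
            reads.append((read_id, seq))
            truth_rows.append(
                (read_id, library, fam, tid, mol.progress, mol.boundary,
                 start, ilen, frame, n_err)
            )
    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return reads, truth


def simulate_control_library(
    config: SimulationConfig,
    barcode: str = "GGCC",
    library: str = "control",
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Random-sequence control reads with valid barcode/adapter structure.

    Emulates the near-empty background library: ``control_tag_count`` inserts
    of random sequence that should almost never align to the toy references.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    lo, hi = config.tag_length_range
    reads = []
    for i in range(config.control_tag_count):
        ilen = int(rng.integers(lo, hi + 1))
        insert = rng.choice(_BASES, size=ilen).tobytes().decode()
        seq = (barcode + insert + config.adapter)[: config.read_length]
        reads.append((f"{library}:{i:07d}:0", seq))
    return reads


@dataclass
class SimulatedWorld:
    """Everything downstream stages need, generated from one config."""

    config: SimulationConfig
    genome: str
    annotations: list[TranscriptAnnotation]
    events: list[EditingEvent]
    pair: ReferencePair
    extents: dict[str, int]
    pool: dict[str, list[Molecule]]


def simulate_world(config: SimulationConfig) -> SimulatedWorld:
    """Generate genome, references, extents, and molecule pool in one call."""
    genome, annotations, events = simulate_maxicircle(config)
    pair = build_reference_pair(genome, annotations, events)
    extents = {t: x.total for t, x in editing_extents(pair).items()}
    pool = simulate_transcript_pool(config, genome, annotations, events)
    return SimulatedWorld(config, genome, annotations, events, pair, extents, pool)


# ---------------------------------------------------------------------------
# FASTQ / ground-truth output


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs as Phred+33 FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_ground_truth(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)
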