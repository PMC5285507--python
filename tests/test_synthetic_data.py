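from collections import Counter

import numpy as np
import pytest

from kredit.mito_reference import (
    EditingEvent,
    build_edited_sequence,
    count_editing_extent,
    transcript_sequence,
)
from kredit.synthetic_data import (
    Molecule,
    SimulationConfig,
    molecule_at_progress,
    simulate_control_library,
    simulate_iclap_library,
    simulate_maxicircle,
    simulate_world,
)
from oracles import random_dna


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(binding_model="sticky")
    with pytest.raises(ValueError):
        SimulationConfig(tag_length_range=(10, 50))
    with pytest.raises(ValueError):
        SimulationConfig(pcr_duplication_rate=1.5)


def test_world_is_deterministic_under_fixed_seed(default_world):
    again = simulate_world(SimulationConfig(seed=42))
    assert again.genome == default_world.genome
    assert again.annotations == default_world.annotations
    assert again.events == default_world.events
    r1, t1 = simulate_iclap_library(
        again.config, again.pool, again.extents, barcode="ACGT", n_tags=400
    )
    r2, t2 = simulate_iclap_library(
        default_world.config, default_world.pool, default_world.extents,
        barcode="ACGT", n_tags=400,
    )
    assert r1 == r2 and t1.equals(t2)


def test_default_category_partition(default_world):
    cats = Counter(a.category for a in default_world.annotations)
    assert cats == {"pan_edited": 9, "minimally_edited": 3, "never_edited": 6}
    assert len(default_world.annotations) == 18


def test_generated_extents_respect_category_ranges(default_world):
    for ann in default_world.annotations:
        total = default_world.extents[ann.transcript_id]
        if ann.category == "pan_edited":
            assert 50 <= total <= 550
        elif ann.category == "minimally_edited":
            assert 4 <= total <= 40
        else:
            assert total == 0
    pan = sorted(
        default_world.extents[a.transcript_id]
        for a in default_world.annotations
        if a.category == "pan_edited"
    )
    assert pan[0] < 150 and pan[-1] > 450  # extents span the configured range


def test_extents_round_trip_event_sums(default_world):
    """Cross-module oracle: measured extent equals the generated event sums."""
    by_tid: dict[str, list[EditingEvent]] = {}
    for e in default_world.events:
        by_tid.setdefault(e.transcript_id, []).append(e)
    ext = {
        t: count_editing_extent(
            default_world.pair.preedited_sequence(t),
            default_world.pair.edited_catalog[t],
            t,
        )
        for t in default_world.pair.edited_catalog
    }
    for tid, events in by_tid.items():
        assert ext[tid].insertions == sum(e.n_u for e in events if e.kind == "insertion")
        assert ext[tid].deletions == sum(e.n_u for e in events if e.kind == "deletion")


class TestEditingCascade:
    def test_progress_zero_is_preedited(self, default_world):
        ann = next(a for a in default_world.annotations if a.category == "pan_edited")
        pre = default_world.pair.preedited_sequence(ann.transcript_id)
        events = [e for e in default_world.events if e.transcript_id == ann.transcript_id]
        mol = molecule_at_progress(pre, events, 0, 60, ann.transcript_id)
        assert mol.sequence == pre and mol.boundary == len(pre)

    def test_full_progress_is_fully_edited(self, default_world):
        ann = next(a for a in default_world.annotations if a.category == "pan_edited")
        pre = default_world.pair.preedited_sequence(ann.transcript_id)
        events = [e for e in default_world.events if e.transcript_id == ann.transcript_id]
        mol = molecule_at_progress(pre, events, mol_blocks(pre, 60), 60, ann.transcript_id)
        assert mol.sequence == default_world.pair.edited_catalog[ann.transcript_id]
        assert mol.boundary == 0

    def test_block_windowing_applies_only_three_prime_events(self):
        pre = "ACGACGACGACGACGACGAC"  # 20 nt, block length 10
        events = [EditingEvent("TX", 3, "insertion", 2), EditingEvent("TX", 15, "insertion", 1)]
        one_block = molecule_at_progress(pre, events, 1, 10, "TX")
        assert one_block.boundary == 10
        assert one_block.sequence == build_edited_sequence(pre, [events[1]])
        assert one_block.sequence[:10] == pre[:10]

    def test_partial_molecules_are_pre_prefix_plus_edited_suffix(self, default_world):
        tid = next(
            a.transcript_id for a in default_world.annotations if a.category == "pan_edited"
        )
        pre = default_world.pair.preedited_sequence(tid)
        edited = default_world.pair.edited_catalog[tid]
        for mol in default_world.pool[tid]:
            assert mol.sequence[: mol.boundary] == pre[: mol.boundary]
            if mol.boundary < len(pre):
                suffix = mol.sequence[mol.boundary :]
                assert edited.endswith(suffix)


def mol_blocks(pre: str, block: int) -> int:
    return -(-len(pre) // block)


class TestLibrarySimulation:
    def _two_transcript_pool(self, rng):
        pool = {
            "LOW": [Molecule("LOW", 0, 1, 500, 500, random_dna(rng, 500))],
            "HIGH": [Molecule("HIGH", 0, 1, 500, 500, random_dna(rng, 500))],
        }
        return pool, {"LOW": 100, "HIGH": 300}

    def test_extent_proportional_sampling_ratio(self):
        rng = np.random.default_rng(5)
        pool, extents = self._two_transcript_pool(rng)
        config = SimulationConfig(
            seed=5, baseline_weight=0.0, pcr_duplication_rate=0.0, sequencing_error_rate=0.0
        )
        _, truth = simulate_iclap_library(config, pool, extents, "ACGT", n_tags=4000)
        share_high = (truth["transcript_id"] == "HIGH").mean()
        # binomial with p = 300/400: sd ~ 0.007 at n = 4000
        assert abs(share_high - 0.75) < 0.025

    def test_no_duplication_no_error_reads_are_unique_inserts(self):
        rng = np.random.default_rng(6)
        pool, extents = self._two_transcript_pool(rng)
        config = SimulationConfig(
            seed=6, pcr_duplication_rate=0.0, sequencing_error_rate=0.0
        )
        reads, truth = simulate_iclap_library(config, pool, extents, "ACGT", n_tags=300)
        assert len(reads) == 300 == len(truth)
        assert (truth["n_errors"] == 0).all()
        assert truth["family_id"].nunique() == 300

    def test_reads_carry_barcode_insert_adapter_structure(self):
        rng = np.random.default_rng(7)
        pool, extents = self._two_transcript_pool(rng)
        config = SimulationConfig(seed=7, sequencing_error_rate=0.0)
        reads, truth = simulate_iclap_library(config, pool, extents, "ACGT", n_tags=100)
        mol = {tid: pool[tid][0].sequence for tid in pool}
        for (rid, seq), row in zip(reads, truth.itertuples()):
            assert rid == row.read_id
            assert seq.startswith("ACGT")
            insert = mol[row.transcript_id][row.molecule_start : row.molecule_start + row.insert_length]
            expected = ("ACGT" + insert + config.adapter)[: config.read_length]
            assert seq == expected

    def test_pcr_duplicates_are_exact_copies_before_errors(self):
        rng = np.random.default_rng(8)
        pool, extents = self._two_transcript_pool(rng)
        config = SimulationConfig(seed=8, pcr_duplication_rate=0.6, sequencing_error_rate=0.0)
        reads, truth = simulate_iclap_library(config, pool, extents, "ACGT", n_tags=500)
        assert len(reads) > 500  # duplication happened
        seq_by_id = dict(reads)
        for fam, group in truth.groupby("family_id"):
            seqs = {seq_by_id[rid] for rid in group["read_id"]}
            assert len(seqs) == 1

    def test_five_prime_restricted_truth_contract(self):
        config = SimulationConfig(seed=9, binding_model="five_prime_restricted")
        world = simulate_world(config)
        _, truth = simulate_iclap_library(
            config, world.pool, world.extents, "ACGT", n_tags=2000
        )
        lens = truth["transcript_id"].map(
            {a.transcript_id: a.length for a in world.annotations}
        )
        frac = (truth["molecule_start"] < lens / 3).mean()
        assert frac >= 0.95


class TestControlLibrary:
    def test_zero_count_gives_empty_library(self):
        assert simulate_control_library(SimulationConfig(control_tag_count=0)) == []

    def test_default_count_and_structure(self):
        config = SimulationConfig(seed=3)
        reads = simulate_control_library(config, barcode="GGCC")
        assert len(reads) == 483
        for _, seq in reads[:20]:
            assert seq.startswith("GGCC")
            assert config.adapter[:5] in seq


def test_genome_too_short_raises():
    with pytest.raises(Exception, match="too short"):
        simulate_maxicircle(SimulationConfig(seed=1, genome_length=3000))


def test_transcripts_lie_within_genome(default_world):
    for a in default_world.annotations:
        assert 0 <= a.start < a.end <= len(default_world.genome)
        # transcript sequence is well-defined in both orientations
        assert len(transcript_sequence(default_world.genome, a)) == a.length
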