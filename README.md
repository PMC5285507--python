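# kredit

**Editing-aware iCLIP/iCLAP tag analysis for the trypanosome mitochondrial
(maxicircle) transcriptome.**

In the mitochondrion of *Trypanosoma brucei*, twelve of the eighteen
maxicircle-encoded mRNAs are remodelled by guide-RNA-directed **uridine
insertion/deletion editing**, proceeding 3′→5′ along the transcript.
Transcripts fall into three categories: *pan-edited* (hundreds of Us inserted
or deleted), *minimally edited* (a single small edited region), and
*never-edited*. Cross-linking protocols such as iCLIP/iCLAP capture the RNA
footprints of editing-associated RNA-binding proteins as short (~30–50 nt)
cDNA tags — but a tag's sequence depends on how far editing has progressed,
so a single reference cannot place it.

`kredit` is for researchers analyzing such cross-link tag libraries against
an editing transcriptome. It implements the dual-reference strategy: every
tag is mapped first to the **preedited** maxicircle genome and then — only if
it found no genome locus — to a **catenated catalog of fully edited
transcripts**. A tag with a unique best locus on the genome is classified
`preedited`; a unique locus on the edited catalog makes it `fully_edited`;
best-score ties are `multimapped` and discarded. Because editing only adds or
removes Us, a tag spanning an editing site cannot align ungapped to the
genome and is rescued only by the edited reference: the editing state is
discriminated by the references, not by gapped alignment.

## What it computes

- **Editing model** (`mito_reference`): U-insertion/deletion events applied
  to preedited sequences; per-transcript **editing extent**
  (total Us inserted + deleted), counted by the minimal U-only alignment of a
  sequence pair (the non-U backbone is invariant under editing).
- **Preprocessing** (`tag_preprocess`): 3′ adapter trimming (longest suffix,
  ≤ 1 mismatch), PCR-duplicate collapsing by exact sequence identity, and
  4-nt experimental barcode demultiplexing, with full read accounting.
- **Alignment/classification** (`editing_aware_align`): an exact ungapped
  seed-and-extend aligner (score = matches − mismatches, mismatch penalty 1,
  ≤ 2 mismatches, score ≥ 0.9 × length) whose seed design provably finds
  every qualifying locus, plus the sequential dual-reference classifier and
  projection into transcript coordinates.
- **Binding quantification** (`binding_quantify`): per-transcript unique-tag
  counts with preedited/fully-edited frames combined; category and region
  shares (%); tags-per-kilonucleotide densities; per-position coverage tracks
  (bedGraph); 5′-bias; and the Pearson correlation *r* between a transcript's
  total tag share and its editing extent.
- **qPCR arithmetic** (`enrichment_qpcr`): ΔΔCt relative abundance
  (fold = 2^−ΔΔCt against an 18S-type reference), percent-of-input RIP
  enrichment (%input = 100·2^[(Ct_input − log₂(1/f)) − Ct_IP]), and
  replicate pulldown ratios with SD.
- **Synthetic data** (`synthetic_data`): a seeded generator for a toy
  maxicircle world — 18 transcripts (9/3/6 pan/minimal/never), a 3′→5′
  gRNA-block editing cascade yielding partially edited molecules, binding
  models (extent-proportional, 5′-restricted, uniform), iCLIP-style reads
  with PCR duplication and sequencing error, and a 483-read background
  control — with per-read ground truth.

## Worked example

```python
from kredit import SimulationConfig, simulate_world, simulate_iclap_library
from kredit.pipeline import run_pipeline, pan_edited_correlation

config = SimulationConfig(seed=42)
world = simulate_world(config)
reads, truth = simulate_iclap_library(
    config, world.pool, world.extents, barcode="ACGT", n_tags=50_000
)
result = run_pipeline(reads, world.pair, config.adapter, {"ACGT": "iclap"})
lib = result.libraries["iclap"]

print(f"reads in: {result.preprocess.report.n_input}, "
      f"unique tags: {result.preprocess.report.per_library_unique['iclap']}")
print(lib.summary.category_shares.round(2).to_string())
region = lib.summary.region_shares
print(f"preedited {region['preedited']:.1f}% / fully edited {region['fully_edited']:.1f}%")
corr = pan_edited_correlation(lib.summary, world)
print(f"Pearson r (binding share vs editing extent, n={corr.n}): {corr.r:.3f}")
```

prints

```
reads in: 71654, unique tags: 46596
category
pan_edited          95.87
minimally_edited     3.04
never_edited         1.08
preedited 44.0% / fully edited 56.0%
Pearson r (binding share vs editing extent, n=9): 0.999
```

Reading: 50,000 simulated cross-link events became 71,654 reads after PCR
duplication and collapsed back to 46,596 unique tags. Under the
extent-proportional binding model almost all uniquely mapped tags land on
pan-edited mRNAs, split between the preedited and fully edited reference
frames, and the per-transcript binding share tracks editing extent nearly
perfectly (r = 0.999 across the nine pan-edited transcripts).

The same chain is available from the shell:

```bash
kredit simulate --seed 42 --n-tags 50000 --out sim/
kredit preprocess --fastq sim/reads.fastq --adapter AGATCGGAAGAGCGGTTCAG \
    --barcodes barcodes.tsv --out pre/
kredit map --tags pre/iclap.tags.fasta --pre sim/genome.fa \
    --ann sim/annotations.tsv --events sim/events.tsv --out assignments.tsv
kredit quantify --assignments assignments.tsv --ann sim/annotations.tsv \
    --extents sim/extents.tsv --out summary.tsv
kredit qpcr --mode ratio --signals-a 0.5,0.7 --signals-b 1,1
```

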