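# ampccs

A toolkit for analyzing pooled, dual-barcoded amplicons sequenced as
long-read circular consensus sequences (CCS). It targets the workflow in
which hundreds of independent samples — yeast mutants or recombinants,
tumor biopsy amplicons — are each PCR-tagged with a unique forward×reverse
pair of 16-nt barcodes, pooled into one single-molecule sequencing library,
and read as multi-pass consensus reads that each span the whole 1–5 kb
amplicon. Because every CCS read covers every position of its amplicon, a
sample's causative mutation, the linkage (phase) of its SNPs, and the
extent of strand exchange in recombination intermediates can all be read
directly off the aligned reads, with no statistical genotyping model.

## What it does

* **Demultiplexing** (`ampccs.demux`): reads are assigned to a
  forward×reverse barcode-pair bin when at least 12 of each barcode's 16
  positions match near the read termini, in either read orientation; a
  12-mer window prescreen plus a direct terminal scan finds candidate
  placements. Reads matching no pair, or more than one, go to an
  unassigned bin. Assigned reads are trimmed and orientation-normalized.
* **Alignment** (`ampccs.align`): end-to-end (fitting) affine-gap
  alignment of each trimmed insert against the amplicon reference, both
  strands, with deterministic tie-breaking; minimal SAM output and a
  text pileup renderer (`.`/`,` matches per strand, letters for
  mismatches, `*` for deletions).
* **Variant calling** (`ampccs.variants`): pileup allele tallies;
  threshold-based calls with zygosity (alternate fraction ≥ 0.10 and
  count ≥ 5 to report; ≥ 0.90 for homozygous-alt); identification of each
  sample's causative mutation (fraction ≥ 0.80) and its class —
  substitution, 1-bp indel, 2–5-bp deletion, large deletion, or complex;
  a pooled per-position base-substitution error landscape that excludes
  each sample's own causative site.
* **SNP phasing** (`ampccs.phasing`): per-read allele vectors over a SNP
  panel, haplotype grouping with noise filters, 2^k enumeration of
  possible haplotypes, and reciprocal-crossover inference with breakpoint
  intervals between flanking heterozygous sites.
* **Strand-exchange tract mapping** (`ampccs.recombination`): classifies
  every panel SNP of every read as recipient/donor/error, reports maximal
  donor tracts (isolated donor SNPs are flagged as putative errors), and
  boxes the population-level exchange interval.
* **Simulation** (`ampccs.simulate`): a synthetic read generator standing
  in for the instrument — templates with planted edits, single-pass
  subreads at 10–15 % error (> 90 % single-nt indels), multi-pass
  two-strand consensus building (≥ 3 passes, ≥ 2 + 1 per strand), barcode
  decoration, and truth tables that serve as the test oracle.

## Worked example

Simulate two barcoded samples — a wild type and a mutant carrying a 2-bp
deletion at position 1101 of a 2-kb amplicon — then run the pipeline:

```
$ ampccs simulate --config scenario.yaml --seed 7 --out sim
wrote 40 reads to sim.fastq (truth: sim.truth.tsv, seed 7)
$ ampccs run --config run.yaml
pipeline report -> out/report.json
```

`out/report.json` (abridged):

```json
{
  "bins": {
    "F1R1": {"causative_class": "none", "n_reads": 20},
    "F2R2": {"causative_class": "deletion-2-5bp",
             "causative_position": 1101, "n_calls": 1, "n_reads": 20}
  },
  "n_reads": 40,
  "n_unassigned": 0
}
```

All 40 reads were demultiplexed into their planted bins; the mutant bin's
single variant call is the planted 2-bp deletion, present in every read
(alternate fraction 1.0 ≥ 0.80), classified as a 2–5-bp deletion at the
planted 1-based position. The aligned reads around the deletion:

```
$ ampccs render --sam out/F2R2.sam --ref sim.ref.fasta --window 1095:1112
TCACAACCAGCATACATC
......**..........
......**..........
```

Each row is one read; dots are matches on the forward strand and the two
asterisks in every read are the deleted columns.

Other stages are exposed the same way: `ampccs demux / align / call /
errors / phase / rectract`, each a thin shell over the library functions.

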