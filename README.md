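# wheatmir

Small-RNA miRNA annotation, degradome target calling and tissue
expression profiling for plant sRNA-seq studies, packaged around a
synthetic-data generator with planted, labelled ground truth.

## The problem

Annotating miRNAs from plant small-RNA sequencing is a rule-driven
pipeline: reads are adapter-trimmed, collapsed to unique tags, mapped
perfectly to the genome, stripped of repeat/rRNA/tRNA-associated tags
(more than 500 genomic hits, or a match to an annotated ncRNA/repeat
set), and the survivors are tested against the hairpin criteria that
define a genuine MIRNA locus:

1. the mature miRNA and its miRNA\* partner come from opposite stem
   arms and form a duplex with two-nucleotide 3' overhangs;
2. at most four mismatched miRNA bases in the duplex;
3. asymmetric bulges at most 1-2 nt, at most one event;
4. the mature tag covers >= 70% of all reads within +-20 nt of its
   5' end (read-stack dominance);
5. read support above fixed count thresholds (> 20 reads in one
   library; > 5 in either).

Downstream, degradome (PARE) sequencing validates targets: a
miRNA:mRNA duplex scoring <= 4.5 (mismatch/gap 1, G:U wobble 0.5,
penalties doubled at miRNA positions 2-13) combined with >= 5 degradome
5' ends at the transcript position opposite miRNA position 10 calls a
cleavage event, localised to the 5' UTR / ORF / 3' UTR of the longest
ATG-initiated ORF of >= 70 codons.  Expression is compared across
tissues in RP10M (reads per ten million mapped) with hierarchical
clustering (1 - Pearson on log2(RP10M+1), average linkage), and mature
miRNAs are classed against a known catalog (exact / <= 2-mismatch
variant / novel) and across species genomes (wheat-specific,
wheat+barley, BEP-clade, monocot-wide, broadly conserved) by exact
genome search plus a +-200 bp refolding test.

The package implements the full pipeline as a library with a thin CLI,
and — because the real wheat genome and the SRP040143 libraries are far
beyond desk scale — ships a first-class synthetic generator that plants
hairpin loci realising (or deliberately violating) each criterion, decoy
repeat/rRNA loci, tissue-structured count matrices, and degradome peaks
opposite miRNA position 10, each carrying a truth record.

## Worked example

```bash
wheatmir all --seed 3 --out run/
```

prints, stage by stage:

```
simulated 102 truth records into run/sim
1018 unique tags, 24040 reads kept
40 accepted loci of 995 candidates
```

i.e. the simulator planted 100 miRNA loci (40 satisfying every
criterion, 10 violating each of six criteria) plus two decoy features;
preprocessing recovered 1,018 unique tags from the two 12,020-read
FASTQ libraries; and the caller accepted exactly the 40 planted true
loci, writing GFF3 coordinates, Vienna dot-bracket structures and a
reason-coded candidate table under `run/disc/`.

The library-summary worked example uses the published 11-library wheat
small-RNA table shipped with the package:

```bash
wheatmir report --summary src/wheatmir/data/wheat_srna_table1.tsv --out run/rep
# grand total reads: 118301178
```

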