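# circends

Mapping the 5' and 3' termini of mitochondrial RNAs from circularized RNA
sequencing reads.

## The problem

Mitochondrial DNA is transcribed into two genome-length polycistronic
precursors; individual rRNAs, mRNAs and tRNAs are cut out by excision of
the interleaved tRNA genes (RNase P at tRNA 5' ends, RNase Z/ELAC2 at 3'
ends). Conventional RNA-seq shows which positions are transcribed but not
where individual molecules *end*, so processing intermediates, transcript
UTR boundaries, and non-templated tails are invisible.

Circularized RNA sequencing makes ends observable: intramolecular ligation
joins each RNA's 3' terminus to its own 5' terminus, RNase R destroys
everything that stayed linear, and rolling-circle reverse transcription
copies the ligation junction — often several times per cDNA — into the
reads. A read crossing the junction contains the molecule's 3' end
immediately followed by its 5' end.

`circends` turns such reads into molecule end calls. For a read `r` whose
split alignment places segment A (earlier in the read) at genome interval
`[a₁, a₂)` and segment B at a non-contiguous `[b₁, b₂)` on the plus
strand, the original molecule's termini are

    3' = a₂ − 1,   5' = b₁

(mirrored on the minus strand), with any non-templated tail — `CCA` or a
poly(A) run sitting between the segments in read coordinates — recognised
and excluded from the termini. The exact breakpoint is chosen by a
mismatch-minimising split-point search along both segments' diagonals, so
it does not depend on where a local aligner happened to stop extending.
Calls aggregate into link tables and per-position 5'/3'-end profiles,
normalised as counts per million aligned reads (CPM); condition contrasts
are `log2((CPM_A + ψ)/(CPM_B + ψ))`; small RNAs recovered from the
rolling-circle repeats are classified by 3' tail (CCA vs poly(A), with a
per-tRNA CCA ratio and a replicate Student's t-test on per-gene poly(A)
proportions).

The package is aimed at people analysing organellar (or other small,
circular-genome) transcriptomes, and ships a full generative simulator of
the library chemistry so every stage can be validated against ground
truth.

## What is inside

| module | role |
|---|---|
| `circends.genome` | circular genome + strand-aware annotation, wraparound coordinate arithmetic |
| `circends.simulate` | library simulator with molecule/read truth tables |
| `circends.toy` | deterministic mitochondria-like toy genome and template panels |
| `circends.readprep` | 3' adapter trimming and paired-end overlap merging |
| `circends.monomerize` | rolling-circle tandem-repeat detection and consensus collapse |
| `circends.align` | seed–chain–extend local alignment with soft clips; end-to-end clip realignment |
| `circends.links` | junction ("link") calling, aggregation, log2FC, Circos export |
| `circends.coverage` | strand-aware depth, CPM, log2FC BEDGraph tracks |
| `circends.srna` | small-RNA extraction, CCA/poly(A) tail classification, statistics |
| `circends.pipeline` / `circends.cli` | orchestration and the `circends` command line |

## Worked example

Simulate a wild-type library on the toy genome and run the full analysis:

```python
from circends import (KmerIndex, SimConfig, make_default_templates,
                      prepare_pairs, simulate_library, split_fraction)
from circends.pipeline import analyze_reads
from circends.toy import toy_annotation, toy_genome

genome = toy_genome()                      # 16,299 nt circular toy genome
annotation = toy_annotation(genome)        # 37 genes, mitochondria-like layout
index = KmerIndex(genome)

templates = make_default_templates(annotation, "WT", L=genome.length)
config = SimConfig(n_molecules=500, seed=11)
sim = simulate_library(templates, genome, config)
reads, prep = prepare_pairs(sim.pairs, config.adapter1, config.adapter2)
result = analyze_reads(reads, genome, annotation, index)

print(f"pairs sequenced      {prep['pairs_in']}")
print(f"merged / R1-only     {prep['merged']} / {prep['unmerged_r1']}")
print(f"aligned reads        {result.n_aligned}")
print(f"terminus calls       {len(result.calls)}")
multi = [c for c in result.calls if c.n_genes_spanned >= 2]
print(f"multi-gene links     {len(multi)}")
print(f"split-read fraction  {split_fraction(result.n_aligned, result.calls):.4f}")
top = max(multi, key=lambda c: c.n_genes_spanned)
print(f"example precursor    5'={top.five_prime + 1} 3'={top.three_prime + 1} "
      f"({top.strand}) spanning {top.n_genes_spanned} genes")
```

This prints:

```
pairs sequenced      2011
merged / R1-only     1921 / 90
aligned reads        2011
terminus calls       678
multi-gene links     24
split-read fraction  0.0119
example precursor    5'=1088 3'=3662 (+) spanning 3 genes
```

Reading it: 500 molecules yielded 2011 read pairs, almost all merged into
full inserts; every read aligned to the circular genome; 678 reads crossed
their molecule's ligation junction and pinned both termini. Of those, 24
came from molecules spanning more than one gene — unprocessed precursors —
giving a multi-gene split-read fraction of 1.2% in this wild-type-like
population. The example precursor runs from position 1,088 to 3,662
(1-based) across a tRNA–rRNA–tRNA block, i.e. an intermediate whose
punctuating tRNAs have not yet been excised.

The same analysis from the shell:

```
circends toy --out-prefix toy        # writes toy.fa + toy.bed
circends simulate --genome toy.fa --annotation toy.bed --scenario WT \
    --n-molecules 500 --seed 11 --out-prefix wt1
circends run --genome toy.fa --annotation toy.bed \
    --r1 wt1.R1.fastq.gz --r2 wt1.R2.fastq.gz --name wt1 --out-dir out/
circends compare --genome toy.fa --annotation toy.bed \
    --sample KO:ko1:ko1.R1.fastq.gz:ko1.R2.fastq.gz \
    --sample WT:wt1:wt1.R1.fastq.gz:wt1.R2.fastq.gz --out-dir cmp/
```

Per-sample outputs: monomer table, SAM for genome-browser inspection, link
table, coverage and 5'/3'-end BEDGraph tracks, small-RNA table; the
comparison adds pooled link tables, link and coverage log2FC tracks,
Circos link/karyotype files and the per-gene poly(A) t-test table.

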