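# gms — genotyping by multiplexed sequencing

`gms` is a Python toolkit for targeted-amplicon SNP genotyping of the kind
used in crop breeding programs: thousands of short (≤150 bp) amplicons,
tagged with 8-base sample barcodes in a two-step PCR, sequenced as single
reads, and called against a *key file* — a FASTA catalogue in which each
marker's expected amplicon carries one two-base IUPAC ambiguity character
(R/Y/S/W/K/M) marking its biallelic SNP.

It is aimed at allopolyploid crops, wheat above all, where a primer pair
routinely co-amplifies the target locus together with its **homoeoallele**
(the corresponding copy on another subgenome) or a **paralog**. The toolkit
turns that nuisance into extra markers: off-target sequences are localized
to chromosomes by their absence pattern across nulli-tetrasomic aneuploid
lines, each of which lacks exactly one chromosome.

## The calling model

Per sample, reads are dereplicated into **seeds** — unique sequences with
occurrence counts (exact-string dereplication, which is what 100%-identity
clustering of equal-length reads reduces to). Each seed is scored against
every key with the SNP site excluded from the identity:

- equal lengths: `identity = matches / (L − 1)` positionally;
- unequal lengths: identity from a global pairwise alignment, the column
  holding the SNP excluded.

A seed is assigned to its best-matching marker at or above the identity
threshold (default 1.0; 0.95 in the relaxed aneuploid mode), then a seed is
kept only if it carries ≥ 10% of its marker's assigned reads (inclusive) —
the filter that separates allele seeds from PCR/sequencing noise. The
genotype is read off the surviving seeds' bases at the SNP site: both
canonical alleles → het, one → hom, none (or depth below the floor) →
missing.

Panel informativeness uses the polymorphic information content in two
forms: `PIC_het = 1 − Σ p_j²` (biallelic maximum 0.50, reported as primary)
and the full Botstein expression `1 − Σ p_j² − Σ_{j<k} 2 p_j² p_k²`
(maximum 0.375).

## Worked example

Simulate a small recombinant-inbred (RIL) run, demultiplex, call, and score
against the simulator's truth:

```bash
gms simulate --preset ril48 --seed 19 --n-markers 63 --mean-depth 60 --out sim/
gms demux --fastq sim/reads.fastq --barcodes sim/barcodes.tsv --out demuxed/
gms call --keyfile sim/panel.fa --meta sim/panel.tsv --fastq-dir demuxed/ --out called/
gms metrics --map sim/map.tsv --out metrics/
```

which prints:

```
simulated ril48 run in sim
assigned 238699 reads, 0 unassigned
called 48 samples x 63 markers -> called
panel: 63 markers, mean spacing 2.00 cM -> metrics
```

`called/snp_report.tsv` is a samples × markers table whose cells are the
observed base for homozygotes, the IUPAC two-base code for heterozygotes
(e.g. `R` for an A/G het) and `-` for missing; `called/hit_report.tsv`
holds the per-marker read totals, and `called/msa/<marker>.msa.fasta` shows
the key followed by every surviving seed. Comparing the report with the
truth matrix (`gms concordance`) on an error-free or low-error simulation
yields `overall agreement 100.00%` — near-fixed RIL material genotyped at
depth ~200 leaves no room for miscalls under the seed filter.

The same machinery handles aneuploid localization: `gms simulate --preset
nullitetra` emits one FASTQ per nulli-tetrasomic line, and `gms homoeo`
runs the 95%-identity mode, collects seeds matching a key at < 100%, and
assigns each to the single chromosome whose line lacks it, classified as
homoeoallele (same homoeologous group) or paralog (different group).

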