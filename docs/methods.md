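# Methods

## The calling procedure

`gms` genotypes targeted amplicon panels in which each marker is described
by its expected amplicon sequence with a single two-base IUPAC ambiguity
character at the SNP. Calling is deliberately parsimonious — no base
qualities, no likelihoods — because the amplicons are short, fixed by
design, and sequenced deep; the signal is carried by exact sequence
agreement and read counts.

Per sample:

1. **Dereplication.** Reads (already trimmed to the biological insert) are
   collapsed into seeds, i.e. unique sequences with counts. This is
   implemented as exact-string dereplication: 100%-identity clustering of
   equal-length reads and exact dereplication are the same operation, and
   the exact form is deterministic and order-free.
2. **Masked-identity matching.** A seed's identity against a key excludes
   the SNP site. For equal lengths this is positional:
   `matches / (L − 1)`. For discordant lengths a global pairwise alignment
   (match +1, mismatch −1, gap open −2, extend −1, via Biopython's
   `PairwiseAligner`) supplies the column correspondence; identity is
   matching columns over all columns except the one aligned to the SNP, and
   the seed base in that column is the observed allele (undefined if the
   column is a gap). Amplicons are fixed-length by design, so the
   positional path dominates in practice.
3. **Assignment.** Each seed goes to the single marker of maximal identity
   at or above the threshold (default 1.0). An exact tie between markers is
   logged and the seed excluded from both — ambiguity is never broken at
   random. At threshold 1.0 assignment uses an exact-lookup table of the
   four SNP-substituted variants per key: a seed can reach identity 1.0
   only against an equal-length key it matches everywhere outside the SNP
   (a gap column always pulls alignment identity below 1), so the lookup is
   provably equivalent to the full scan and makes large runs cheap. The
   general scan is retained for relaxed thresholds and is cross-checked
   against the fast path in the test suite.
4. **Read-fraction filter.** Within a marker, a seed survives only if its
   count is at least `min_seed_fraction` (default 10%, boundary inclusive)
   of the marker's total assigned reads. The denominator is the per-marker,
   per-sample total: the filter's job is to separate the one or two allele
   seeds from the cloud of low-count error seeds within one marker's read
   stack.
5. **Calling.** Allele depths are the summed counts of surviving seeds
   whose SNP-site base equals each canonical allele. Both depths positive →
   het; one → that homozygote; neither, or total assigned reads below
   `min_marker_depth` (default 5; set 0 to disable) → missing. Surviving
   seeds with a non-canonical base at the SNP count toward the total but
   toward neither depth.

Reports are a samples × markers SNP table (hom = observed base, het =
IUPAC two-base code, missing = `-`), a same-shaped read-count table, and a
per-marker FASTA of the key followed by every surviving seed. In the FASTA,
a length-discordant seed is projected onto key coordinates (deletions shown
as `-`, insertions relative to the key dropped) so all sequences share the
key's length.

## Aneuploid chromosome assignment

In the relaxed mode (identity threshold 0.95) a key also captures seeds
from co-amplified homoeoalleles and paralogs, which sit a few substitutions
away from the target. Every surviving seed with identity in [0.95, 1.0) is
a candidate off-target sequence. Its chromosome is inferred from
nulli-tetrasomic lines, each lacking one chromosome: the literal sequence
is searched in every line's full dereplicated seed pool, with presence
requiring at least `min_reads` occurrences (default 2, guarding against a
single-read error coinciding with the query). Exactly one absent line
assigns the sequence to that line's missing chromosome; zero absences
leave it unassigned, two or more are reported ambiguous. The presence
search deliberately bypasses the read-fraction filter: a locus whose depth
in one line happens to fall under 10% must still register as present
there, or that line would fake a second absence. Replicate lines lacking
the same chromosome are OR-ed. Classification is structural: an assigned
chromosome in the marker's homoeologous group (e.g. 5D for a 5A marker) is
a homoeoallele, any other group a paralog; the boundary between the two
terms is this package's formalization. Each off-target seed is resolved
independently; multi-copy interactions beyond that are not modelled.

## Panel metrics

Map summaries sort each chromosome's markers by cM and use successive
differences: the per-chromosome average gap is the mean gap, and the
panel-wide average spacing is the unweighted mean of the per-chromosome
averages (the convention consistent with published panel-overview tables;
count-weighted variants are available in code). Single-marker chromosomes
report 0 and are excluded from gap aggregates.

PIC is computed in two forms because the field uses the name for both: the
expected-heterozygosity form `1 − Σ p_j²` (biallelic maximum 0.50) and the
full Botstein expression `1 − Σ p_j² − Σ_{j<k} 2 p_j² p_k²` (maximum
0.375). The heterozygosity form is labelled primary, matching the 0.50
ceiling quoted for biallelic SNP panels; the discrepancy between the two
conventions is documented rather than silently resolved. Het calls
contribute half a unit to each allele frequency; missing calls are
excluded listwise per marker.

Concordance between two genotype matrices is computed over the
intersection of their sample and marker labels, excluding cells missing in
either; discordances are classified, with hom-vs-het singled out because
it is the signature of homoeoallele mis-clustering on array platforms.

## The simulator

The generator emulates the experimental designs this kind of platform is
validated on, with full truth tables so every stage is checkable:

- **Panel.** Random amplicons (default 150 bp, the platform's length
  ceiling) with one planted biallelic SNP each, dealt round-robin across
  the 21 wheat chromosomes at 2 cM spacing. By default 20% of markers
  carry a homoeoallele copy and 6.5% a paralog — the proportions implied
  by a panel of 1,912 designed markers co-amplifying 396 homoeoalleles and
  125 paralogs. An off-target copy fixes one base at the SNP-homologous
  site and adds 2–7 divergence substitutions, landing its identity in
  [0.953, 0.987] on a 150-mer: below 100%, inside the relaxed window.
- **Populations.** RIL mode draws a parental homozygote per marker per
  sample with a fair coin and injects residual heterozygosity at 2%
  (near-fixed inbred material); diversity mode draws each marker's allele
  frequency uniformly from a configurable range and genotypes under
  Hardy–Weinberg proportions.
- **Reads.** Depth per sample × locus is negative-binomial (dispersion 5)
  around the configured mean: amplicon data show strong depth variation
  essentially decoupled from nominal DNA input, which a Poisson would
  understate. Hets split depth binomially. Errors are i.i.d. substitutions
  (default 0.2%); indels and short adapter-flanked primer-dimer junk are
  separate, default-off knobs. Reads get a 5′ adapter context plus the
  sample's 8-base barcode and are shuffled; order, barcodes and errors all
  derive from one seeded generator, so a fixed seed gives byte-identical
  FASTQ.
- **Aneuploid lines.** One line per chromosome, homozygous at every
  marker; a line's reads omit every locus (marker or off-target copy)
  residing on its deleted chromosome.

What the simulator does *not* model — and what passing tests therefore do
not demonstrate about real data: PCR competition and pool-specific
amplification bias, platform-specific homopolymer error structure, barcode
cross-talk, contamination, and tetrasomic dosage in the aneuploid stocks.
The 100%-concordance experiment shows the pipeline is exact under the
stated noise model, not that any wet-lab run will be.

## Numerical and design choices

- Boundary conventions: the 10% filter is inclusive (≥); identity
  thresholds are inclusive; all tie-breaks are deterministic and logged.
- Barcodes match exactly by default (a mismatch radius and a
  reverse-orientation scan are opt-in); reads with fewer than 8 insert
  bases after trimming are routed to `unassigned` with a reason code, so
  primer-dimer artifacts never reach calling.
- The minimum-depth floor (5 reads) is this package's addition — small
  totals make the fraction filter degenerate; setting it to 0 restores
  literal threshold-free behaviour.
- Key-file metadata (category, chromosome, cM, pool) travels in a sidecar
  TSV rather than FASTA headers, keeping the key file minimal and
  byte-stable under round-trips.
- The concordance experiment in `scripts/acceptance.py` runs 48 samples ×
  200 markers at mean depth 200 (~2.3M reads, well under a minute); the
  test suite uses the same scale for the headline check and smaller runs
  elsewhere.
- `--threads` is accepted but currently a no-op; results are independent
  of thread count by construction.

## Known limitations

Quality scores are carried but unused; polyploid dosage beyond het/hom is
out of scope; linkage-map construction is an input, not a product; and the
homoeoallele/paralog classifier trusts the marker's annotated native
chromosome — an error there propagates to the classification, though not
to the chromosome assignment itself.
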