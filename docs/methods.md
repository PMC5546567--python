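# Methods

## Pipeline model and assumptions

The package treats chimeric-transcript discovery as a chain of rule-based
classifications over alignment evidence. It does not run any aligner:
BLAST-style tabular hit files (the standard 12 columns plus `nident` and
`positive`) are its inputs, and all decisions are deterministic functions
of those tables plus FASTA/GFF3/counts files. All coordinates are 1-based
inclusive; the only place a minus strand is encoded by reversed
coordinates is the raw hit record (`sstart > send`), and every derived
type carries an explicit strand. This single conversion point avoids
off-by-one drift between the BLAST and GFF3 conventions.

### Redundancy clustering

Two assembled transcripts are considered the same underlying transcript
(or isoforms of one gene) when their retained self-alignment block is at
least 95% identical across at least 100 identical bases. The "greedy"
transitive rule — a transcript joining a cluster pulls in everything it
hits — is exactly connected components of the filtered hit graph, and the
implementation is tested against an independent `networkx`
connected-components oracle on random graphs. Filters run in a fixed
order:

1. one alignment block per unordered query–subject pair, the longest
   (ties: higher bitscore, then lower E-value, then input order — the
   inputs do not determine an order beyond this);
2. transcripts from excluded assembly sources (default: 21-mer
   assemblies, tag `k21`) are removed with all their hits, because short
   k-mer mis-assemblies bridge otherwise distinct clusters;
3. optionally (default on) transcripts shorter than 300 bases are
   removed;
4. the 95% / 100-identical-bases thresholds, evaluated on the single
   retained block (not summed across blocks, since step 1 keeps one);
   self-hits passing this are kept so isolated transcripts still get
   cluster numbers.

Each cluster is represented downstream by its longest member
(ties: lexicographically smallest id). Raising the identity threshold can
only split clusters, never merge them; this monotonicity is tested.

### Annotation and chimera calling

Protein evidence is aggregated per (transcript, protein) pair: positives,
identities and aligned length are summed over HSPs, the E-value is the
minimum, and query intervals are merged. Homology is defined as
`100 · positives / aligned length` — the denominator is the summed
aligned length, not the transcript length; this is configurable because
either reading is defensible. The orthology filter keeps pairs with
homology ≥ 50%, ≥ 35 positives and E ≤ 1e-05, applied to the aggregated
pair (not per HSP).

Proteins surviving the filter are grouped into gene blocks by a sweep
along the transcript: a protein joins the current block when its merged
query span overlaps the block span by **more than 50% of the shorter**
span. Without such a merge rule every transcript hit by two homologous
proteins or isoforms at the same region would be a false chimera. Blocks
get representative proteins by highest summed positives (ties: lower
E-value, then lexicographic id). Two or more blocks make a chimera
candidate; each block is cut out with a 75-base extension on both ends
(clipped at the transcript ends) to compensate for non-orthologous first
and last exons, with sub-transcript ids `<transcript>.g<k>` numbered in
transcript order.

The six-frame ORF finder reports the longest ATG-initiated,
stop-terminated frame, requiring ≥ 100 amino acids by default for a
novel-coding call (the threshold is a package choice; it is configurable
because no canonical value exists). Ties break toward the plus strand,
then the smaller start. Contamination screening flags any transcript with
a hit to the contaminant reference at ≥ 90% identity and ≥ 100 positives;
the same thresholds drive the protein-level redundancy reduction, which
drops the shorter member of each flagged pair.

### Genomic validation

Split genes are placed on each genome by chaining their HSPs per
(gene, scaffold, strand) when subject spans lie within 10 kb, keeping
chained loci with length-weighted identity ≥ 60% and merged query
coverage ≥ 60%. The best locus is the highest summed bitscore
(ties: higher coverage, longer span, then scaffold/start for
determinism); all co-optimal loci are kept so that a pair validating at
two locus pairs is reported as *duplicated*, one summary row per extra
copy.

Pair classification runs its checks in a fixed order: identical
coordinates (both genes hitting one locus — an annotation-redundancy
artefact) → unannotated placement (only when a GFF3 is supplied; without
one the check never excludes) → different scaffolds → containment →
partial overlap → distance. The distance rule is **inclusive**: an
intervening gap of exactly 50,000 bases validates, 50,001 does not. The
gap is the count of intervening bases, `downstream.start − upstream.end −
1`, so adjacent genes score 0 and the worked convergent example scores
exactly 612.

Orientation: same strand is co-oriented. Opposite-strand disjoint pairs
are convergent when the 3' ends face each other (upstream gene on +) and
divergent when the 5' ends face. For opposite-strand overlapping or
contained pairs the facing rule is ambiguous, so the pair is convergent
iff its 3'–3' end distance is at most its 5'–5' distance (ties →
convergent); observed data suggests contained pairs are essentially
always co-oriented, so this rule is rarely exercised on real inputs. The
classifier is symmetric in its two arguments and is tested exhaustively
against an independent base-set geometric oracle.

Candidates with ≥ 3 blocks are tallied as multi-gene: their adjacent
block pairs are classified but kept out of the pair-level summary, so
chimera counts and pair counts reconcile the way published cross-genome
tables do. Summary percentages use exact round-half-up to integer
percent; a zero base reports an absent percentage rather than a number.

Lineage labels over the validated-in sets: `amaranth_specific` =
validated in the amaranth genome only; `caryophyllales_specific` =
validated in every Caryophyllales genome and no outgroup;
`conserved_all` = validated everywhere; anything else `shared_other`.
Venn-region counts over all non-empty genome subsets are emitted
alongside.

### Expression

RPKM uses the per-condition total of mapped reads from the sidecar file
as denominator (reads map to the whole transcriptome, not just the
matrix rows); column sums are available as an option. Pearson r is the
standard sample coefficient, undefined (reported absent, classified
`none`) for constant profiles. Calls: positive at r ≥ 0.6, negative at
r ≤ −0.6. Correlation is computed on RPKM by default; a log2(RPKM+1)
switch exists because the choice is not canonical.

## Synthetic study design

The generator plants, per default configuration: 45 gene pairs (5 per
overlap-category × orientation cell) across three genomes with
amaranth/Caryophyllales/outgroup roles; lineage labels cycling
amaranth-specific → Caryophyllales-specific → conserved; one pair per
study carrying the 612-base convergent worked-example gap; two
identical-coordinate false chimeras; one 3-gene chimera; one duplicated
pair (two co-optimal locus pairs ≥ 120 kb apart); ten singleton coding
genes; three contaminant transcripts; redundant copies of every
transcript from simulated 25-mer and 31-mer assemblies (plus 21-mer
copies that the clustering filters must drop) with decoy self-hits just
below the thresholds; and 16-condition counts with planted correlations
(convergent −0.9, co-oriented +0.9, divergent 0) through a shared latent
condition factor, scaled/rounded linearly so the target correlation
survives integer rounding. Non-validating genomes still place both genes,
on different scaffolds, so exclusion paths are exercised rather than
bypassed.

Hit tables are computed analytically from the planted coordinates
(ideal alignments with optional identity jitter), not by running an
aligner. Consequently the synthetic data does not emulate: alignment
noise and chained-HSP fragmentation beyond what the jitter produces,
paralogy (decoy loci near thresholds), intron structure (genomic spans
equal mRNA lengths), or read-level sampling noise in counts. Passing the
recovery tests therefore demonstrates the correctness of the decision
rules and their composition, not robustness to aligner idiosyncrasies on
real genomes.

Generation is byte-deterministic for a fixed seed; the generator
self-checks the manifest against the emitted GFF3 before returning.

## Problem sizes and numerical choices

The default synthetic study (45 pairs, 3 genomes, ~140 transcript
copies) keeps the full pipeline run under two seconds; oracle suites use
200-node random graphs over 100 seeds (clustering), a 4 × 15
strand-position grid plus fuzzing (classification), 1,000 fuzzed
sequences (ORF), and 500 replicates (correlation sign recovery). These
sizes were chosen as the smallest that exercise every rule and boundary
while leaving the statistical assertions comfortable margins.

Boundary conventions worth restating: all filter thresholds are
inclusive on the passing side (≥ 95%, ≥ 100 bases, ≥ 50% homology,
≥ 35 positives, ≤ 1e-05, ≥ 60/60, ≥ 90/100, gap ≤ 50 kb, |r| ≥ 0.6);
the block-merge overlap is strict (> 50% of the shorter span); empty
inputs yield empty outputs and a zero report rather than errors; a
percentage over a zero base and a Pearson r over a constant profile are
reported absent, never coerced.

## Known limitations

* The pipeline consumes alignment tables; it cannot detect chimeras whose
  component genes lack protein homologs.
* The unannotated-territory exclusion is skipped entirely for genomes
  without a supplied GFF3, which can overcount validations there.
* Gene-level expression relies on reads being attributable to the split
  sub-transcripts; overlapping 3' UTR regions are counted in both genes.
* The contained-pair orientation rule (3'/5' end distances) is a
  convention for a case the facing-ends definition leaves undefined.
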