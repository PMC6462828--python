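# Methods

## The reconstruction problem

A family of paralogous, highly polymorphic genes (modeled on HLA class I)
is amplified gene-by-gene with locus-specific primer pairs carrying
per-sample barcodes; the pooled products are long-read sequenced, and the
same individuals have low-error short paired reads over the loci. The goal
is a deduplicated set of full-length allele sequences — a reference panel —
in which every variant is supported by its carriers' short reads.

Two structural features make this harder than generic amplicon consensus:

* **Nested co-amplification.** One gene's primer pair can anneal inside
  another gene's amplified region (in the modeled geometry, the B pair
  inside the C amplicon, and the A pair captures the H locus full length).
  The inner product is shorter and amplifies at higher depth. If all of a
  sample's reads are assembled jointly, the inner reads dominate the column
  majority over the outer gene's flanks and the consensus truncates. The
  pipeline's defining move is to demultiplex reads by primer pair *before*
  assembly; the truncated inner products then reach assembly only in the
  inner pair's bin and are absorbed by the full-length contig during
  fusion (containment rule).
* **A deletable locus.** The H-analog locus segregates a deletion, so a
  sample carries 0–2 copies; copy number must be estimated from short-read
  depth before genotyping, and assembly must tolerate bins holding 0, 1 or
  2 haplotypes of that gene alongside another gene's amplicons.

## Stage models and parameters

### Demultiplexing (`psarp.demux`)

Primer matching is semi-global: the primer is consumed entirely and both
of its ends are free on the read window (edlib infix mode), so a terminal
truncation of the primer costs edits. A read is assigned to a primer set
only when the forward primer hits its 5′ window *and* the reverse primer
its 3′ window in the same orientation; ties across sets break by total
edit distance, then matched span, else the read is left unassigned with a
reason code (`no-5p`, `no-3p`, `ambiguous`).

Two tolerances coexist deliberately. Consensus contigs are screened with
`max_edit = 1` (the classical "edit distance < 2" containment rule — this
is the full-length criterion). Raw long reads cannot be held to that rule:
at the default error model a 25 bp primer carries ~2.75 expected edits, so
read demultiplexing uses `max_edit = 6` (≈ 24 % of primer length); the
primer pairs of distinct genes are tens of edits apart, so cross-assignment
is not a risk at that tolerance.

Gene classification of contigs uses the longest contiguous fragment shared
with any database allele, computed as the longest run of shared 15-mers
(gaps up to 100 bp bridge isolated mutations), with a unique-k-mer gene
vote as a prefilter. Ties go to higher within-fragment identity, then to
the lexicographically smaller allele name; fragments under 200 bp are
unclassified.

### Assembly (`psarp.assembly`)

Clustering is a recursive bipartition of a bin's reads:

1. *Dissimilarity pre-split.* All reads are aligned to the longest read;
   reads whose column dissimilarity exceeds 0.30 (or that fall outside the
   alignment band) split off. This separates co-amplified genes, whose
   distance (≈ 50 %) sits far above both the error scale (≈ 10–20 % between
   raw reads) and heterozygosity (≈ 1 %).
2. *Phased het split.* Candidate heterozygous columns are those where a
   second **base** reaches 25 % of covered reads (≥ 3 reads). Gaps are not
   counted as alleles: under a global alignment, reads of a nested inner
   product show the missing flanks as gap runs — a coverage pattern, not
   heterozygosity. Reads are phased by their agreement with one
   well-covered reference read across the candidate columns (per-column
   minor/major labels are arbitrary at a 50/50 ratio, agreement with a
   fixed read is not). A split is accepted only if at least two columns
   co-segregate cleanly with it (minor fraction > 0.8 on one side, < 0.2 on
   the other): alignment-shift artifacts at tandem repeats mark a
   consistent pseudo-minor base on ~1/3 of reads but are independent
   across columns and never reach that association. Each side may split
   once more (≤ 4 phased clusters per mixture group); a side smaller than
   20 % of its parent (or under 3 reads) dissolves the split.

Consensus polishing iterates (≤ 5 rounds, deterministic) two steps on a
template initialized with the longest read: (a) column majority over a
banded global alignment of the cluster's reads, ties keeping the template
base, plus strict-majority insertions per junction (insertion placements
are left-normalized through repeats first, or equivalent placements split
the vote); (b) a score-based local indel step — around short tandem
repeats the aligner distributes an equivalent indel over adjacent
junctions *and* substitution columns, so no single junction reaches a
majority; every indel suggested by ≥ 20 % of reads is therefore tested
explicitly and kept iff it lowers the reads' summed alignment cost in a
±50 bp window. Deep clusters are subsampled to 24 reads (evenly spaced);
the column majority is saturated well below that depth. On simulated data
this polisher reaches 0–1 edits from truth at 30× with the default error
model.

Fusion groups one sample-gene's contigs by single linkage at ≥ 0.995
identity measured over the shorter contig's best placement in the longer —
so a truncated inner amplicon is near-identical to its full-length
container and always merges into it, support summed. The 0.995 threshold
separates error-bearing duplicates (≤ 0.3 % apart) from true heterozygous
pairs (≈ 1 % apart). Groups rank by support; the top 2 with ≥ 3 supporting
reads survive. More than two surviving contigs for one sample and gene is
a hard contract violation.

### Refinement (`psarp.refine`)

Variants are maximal MSA column runs where ≥ 2 distinct row strings occur.
The MSA engine is mafft (FFT-NS-2) when on `PATH`; its result is kept only
if it scores at least as well (unit-cost sum of pairs) as the built-in
center-star construction, which is also the offline fallback. Every row
ungaps to its input exactly, always.

Support assessment pile-ups are **window-anchored**: an allele's footprint
at a variant (for a pure deletion, the junction of its flanking bases) is
extended by 10 anchored bases each side, and the literal read subsequence
between the anchors is compared with the allele's. This makes the check
invariant to where the MSA or the read aligner places an equivalent indel
inside a repeat — comparing bare footprint strings produces both false
support and false conflict there. Defaults: reads map semi-globally to the
carrier's candidate alleles of the read's gene (ties share weight),
`min_depth = 5` spanning reads, `support_fraction = 0.8`. An observation
below `min_depth` is *unexamined*; accuracy is supported / examined over
(allele, carrier, position) triples, and the mean accuracy is the
unweighted mean over genes.

A position is corrected iff it is unsupported in every examinable carrier
and all carriers agree on the replacement; replacements apply right to
left; alleles made identical merge (carriers united). Per-gene accuracy
must not decrease after correction — a decrease raises an error rather
than being reported.

### Genotyping and filtering (`psarp.genotype`)

Copy number of the deletable locus: reads are assigned to genes by unique
21-mers (strand-resolved, stride 7); the call is 0/1/2 by the depth ratio
of the locus against the mean of the non-deletable loci, thresholds 0.25
and 0.75 (expected ratios 0, 0.5, 1).

Genotypes are exhaustive diploid maximum likelihood: each read scores
`exp(-λ·d)` against the better allele of a candidate pair (λ = 1, edit
distance capped at 10), so a genotype's log-likelihood is the negated sum
of per-read minimum distances. Candidates (refined alleles of the gene
plus database alleles, deduplicated by sequence with the refined id
preferred) are pruned to the top 20 by total read score on an evenly
spaced read subset; reads are subsampled to 500 (evenly spaced — reads
arrive grouped by haplotype). Because the per-read maximum can only
improve when an allele is added, heterozygous calls carry a parsimony
penalty of 5 log units; a genuine second haplotype clears it by orders of
magnitude, while single-read noise does not. Ties prefer fewer distinct
alleles, then lexicographic ids. Copy number 0 is an empty, valid call.

The panel keeps refined alleles selected by ≥ 1 best genotype; a dropped
allele whose carriers were all re-typed onto one common other allele
records it as its alteration. Panel accuracy is re-assessed with carriers
taken from the genotype calls and each sample's full called pair as
mapping references — assessing the subset panel with assembly-time
carriers would pile a dropped allele's reads onto the kept allele and
misreport the improvement the filtering produces.

### Characterization (`psarp.report`)

The closest database subtype minimizes edit distance over the database
allele's span placed freely inside the panel allele; ties break to fewer
exonic edits, then name. Exon-only (cDNA) database entries are compared in
exon space against the panel CDS lifted through the closest genomic entry.
Novelty flags follow name resolution: any genomic difference within the
database span → novel at 8 digits; any exonic difference → also 6; a
protein-changing difference (including frame-length changes) → also 4; a
cDNA-only closest subtype marks the panel allele as newly adding
intron/flank sequence. Exonic substitution runs are reported with 1-based
position in exon, multi-base ref/alt strings, and amino-acid consequence
(1-based in the translated frame) or "Synonymous". Regulatory "novel
variant" counts are variant *positions* of the panel MSA whose footprints
lie outside every allele's database span (upstream/downstream separately).
Population coverage truncates allele names to 2/3/4 fields (4/6/8-digit)
and reports the fraction of typed population slots matching some panel
allele's assigned name; it is monotone non-increasing in resolution.

## The simulator (`psarp.simdata`)

Per gene, one random ancestral sequence fixes the locus; its alleles are
independent mutants at per-base rate `divergence_rate` (default 0.005, so
allele pairs sit ≈ 1 % apart, the scale at which contig fusion must keep
heterozygous pairs distinct), 90 % substitutions and 10 % short (1–4 bp)
non-exonic indels, with annotations lifted through the indels. Gene
models follow class-I-like geometry (4.1–5.2 kb spans, 8 exons totalling
1098 coding bases, long regulatory flanks). Allele names use the
four-field colon convention with fields assigned by protein / CDS
equivalence classes, so name-resolution logic is exercised for real.
Frequencies are symmetric-Dirichlet draws. The B primer pair's annealing
sites are planted inside the C ancestor (inner interval 380–4000,
covering the whole gene body) and the A pair's sites at the H termini, as
exact primer copies, so an amplified span equals the corresponding allele
span and "recovered exactly" means exact sequence identity.

Long reads are full amplicon copies (barcode + 5 bp linker + primer ...
complement at the 3′ end) on a random strand with independent per-base
errors — defaults mismatch 0.01, insertion 0.06, deletion 0.04, an
indel-dominated profile that stresses consensus polishing the way
long-read amplicon data does while staying assemblable at depth 30 (the
default per amplicon; nested targets multiply it, default ×3, giving the
inner interval 4× the outer coverage). Short reads are uniform fragments
per true haplotype (insert 420 ± 60, read length 150, per-base
substitution error 0.001, per-haplotype coverage 15 ≈ 30× diploid); a
zero-copy locus yields none. Every output is reproducible byte-for-byte
from the single config seed.

What the simulator does **not** emulate: PCR chimeras, quality-score
structure (flat Q), coverage bias along the amplicon, barcode
cross-contamination, and population structure among alleles (a star
phylogeny rather than nested allelic families). Passing tests therefore
demonstrate correctness of the pipeline's logic and its behavior under
indel-dominated noise and nested co-amplification — not performance on
real instrument artifacts.

## Numerical and scale choices

Everything deterministic: fixed seeds, lexicographic tie-breaks (longest,
then smallest), stable sorts. Alignments are banded: cluster projections
at 35 % of template length, polish rounds at 28 % (first round, against a
raw read) then 16 %, always widened by the largest read/template length
difference in the cluster so that the shorter members of a mixed-length
cluster stay in the pile-up; reads outside the band count as maximally
dissimilar (clustering) or drop from the pile-up (polishing). Refined/panel
assessments reuse the draft MSAs where nothing changed, and the panel uses
induced sub-alignments of the refined MSAs. Simulated studies in the test
suite use 30 samples × 4 genes × 20-allele pools for the error-free and
single-seed checks and 20 samples per seed for the multi-seed recovery
check; the acceptance script runs 30-sample studies throughout, plus a
200-sample short-read-only study for copy-number calling.

## Known limitations

* Assembly resolves at most two haplotypes per gene per sample and relies
  on ≥ 2 cleanly co-segregating heterozygous sites to phase; a
  heterozygous pair differing at a single site collapses to one contig
  (its partner is typically still recovered from other carriers or the
  database during genotyping).
* Variant observations within ~`min_depth`-read distance of an allele's
  termini are usually unexaminable (too few spanning read windows), so
  terminal consensus errors can survive refinement; filtering normally
  removes the affected allele instead.
* The genotype likelihood ignores base qualities and pairing (mates score
  independently) and caps per-read distance, flattening differences among
  very distant candidates.
* The exhaustive pair scan is quadratic in the pruned candidate list; the
  pruning assumes the true alleles rank inside the top 20 by read score,
  which holds easily at the simulated diversity but is a real assumption
  for databases with thousands of near-identical entries.
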