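"""End-to-end orchestration: demultiplex -> assemble -> refine -> genotype
-> filter -> panel.

The primary entry point is :func:`run_pipeline`, which takes per-sample
long reads, per-sample short read pairs, the primer sets and a reference
allele pool (the known-allele database), and produces the draft, refined
and final panel allele sets together with accuracy and selection reports.

``separate_by_primer=False`` reproduces the naive mode in which all of a
sample's reads are assembled jointly; with nested co-amplification present
this truncates the outer gene's alleles, which is exactly the failure the
primer-separation step exists to fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import revcomp
from . import demux as dx
from .assembly import (
    AssemblyParams,
    Contig,
    DraftAlleleSet,
    build_draft_set,
    cluster_bin,
    fuse_contigs,
    polish_consensus,
)
from .demux import CONTIG_POLICY, READ_POLICY, PoolKmerIndex, PrimerSet
from .genotype import (
    CopyNumberCall,
    GeneKmerClassifier,
    GenotypeCall,
    PanelSelection,
    call_copy_number,
    filter_panel,
    genotype_sample,
)
from .refine import (
    AccuracyReport,
    RefineParams,
    RefineResult,
    assess_allele_set,
    refine_draft_set,
)
from .simdata import AllelePool


@dataclass
class PipelineParams:
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    refine: RefineParams = field(default_factory=RefineParams)
    separate_by_primer: bool = True
    genotype_top_k: int = 20
    genotype_lambda: float = 1.0
    genotype_max_edit: int = 10
    genotype_max_reads: int = 500
    cn_thresholds: tuple[float, float] = (0.25, 0.75)
    deletable_gene: str = "H"
    trim_window: int = 120


@dataclass
class PipelineResult:
    contigs: list[Contig]
    discarded_contigs: list[Contig]
    unassigned: dict[str, dict[str, str]]  # sample -> read_id -> reason
    draft: DraftAlleleSet
    refinement: RefineResult
    copy_calls: dict[str, CopyNumberCall]
    genotype_calls: list[GenotypeCall | None]
    panel: DraftAlleleSet
    selection: PanelSelection
    panel_accuracy: AccuracyReport
    candidate_seqs: dict[str, str]  # every genotype candidate id -> sequence

    @property
    def refined(self) -> DraftAlleleSet:
        return self.refinement.refined

    def full_length_rate(self, gene: str) -> float:
        of_gene = [c for c in self.contigs if c.gene == gene]
        if not of_gene:
            return float("nan")
        return sum(c.full_length for c in of_gene) / len(of_gene)


def _gene_primer_map(primer_sets: dict[str, PrimerSet], pool: AllelePool):
    """Which primer set targets each gene full length (the deletable locus
    is captured by the A pair when no set carries its own name)."""
    mapping = {}
    for gene in pool.genes:
        mapping[gene] = gene if gene in primer_sets else "A"
    return mapping


def _trim_to_primers(seq: str, pset: PrimerSet, window: int) -> str:
    """Cut barcode/linker overhangs: keep the span from the forward primer
    through the reverse primer (either found within ``window`` of an end)."""
    head = seq[: window + len(pset.forward)]
    hit_f = dx.match_primer(head, pset.forward, dx.PrimerMatchPolicy(3, window))
    tail_len = window + len(pset.reverse)
    tail = seq[-tail_len:]
    hit_r = dx.match_primer(
        tail, revcomp(pset.reverse), dx.PrimerMatchPolicy(3, window)
    )
    start = hit_f.start if hit_f is not None else 0
    end = len(seq) - tail_len + hit_r.end if hit_r is not None else len(seq)
    if start >= end:
        return seq
    return seq[start:end]


def assemble_sample(
    sample_id: str,
    reads: list[tuple[str, str]],
    primer_sets: dict[str, PrimerSet],
    pool: AllelePool,
    params: PipelineParams,
    kmer_index: PoolKmerIndex,
) -> tuple[list[Contig], list[Contig], dict[str, str]]:
    """Demultiplex one sample's long reads, assemble each bin, classify
    contigs to genes and fuse per gene.  Returns (kept, discarded,
    unassigned reasons)."""
    bins, unassigned = dx.demultiplex(
        reads, primer_sets, READ_POLICY, sample_id=sample_id
    )
    seq_of = dict(reads)
    oriented_bins: dict[str, list[str]] = {}
    if params.separate_by_primer:
        for name, rb in bins.items():
            oriented_bins[name] = [
                revcomp(seq_of[rid]) if rev else seq_of[rid]
                for rid, rev in zip(rb.read_ids, rb.reversed_flags)
            ]
    else:
        pooled: list[str] = []
        for name, rb in sorted(bins.items()):
            pooled.extend(
                revcomp(seq_of[rid]) if rev else seq_of[rid]
                for rid, rev in zip(rb.read_ids, rb.reversed_flags)
            )
        oriented_bins["all"] = pooled

    gene_pset = _gene_primer_map(primer_sets, pool)
    raw: list[Contig] = []
    for bin_name in sorted(oriented_bins):
        bin_reads = oriented_bins[bin_name]
        clusters = cluster_bin(bin_reads, params.assembly)
        for cluster in clusters:
            if len(cluster) < params.assembly.min_support_reads:
                continue
            consensus, converged = polish_consensus(
                [bin_reads[i] for i in cluster],
                max_rounds=params.assembly.polish_rounds,
                max_reads=params.assembly.max_polish_reads,
            )
            trim_set = (
                primer_sets[bin_name] if bin_name in primer_sets else None
            )
            if trim_set is not None:
                consensus = _trim_to_primers(consensus, trim_set, params.trim_window)
            else:  # joint assembly: trim with whichever set matches best
                best = None
                for pset in primer_sets.values():
                    t = _trim_to_primers(consensus, pset, params.trim_window)
                    if best is None or len(t) < len(best):
                        best = t
                consensus = best if best is not None else consensus
            raw.append(
                Contig(
                    sample_id=sample_id,
                    primer_set=bin_name,
                    sequence=consensus,
                    n_support_reads=len(cluster),
                    polish_converged=converged,
                )
            )

    classified: list[Contig] = []
    for c in raw:
        call = dx.classify_gene(c.sequence, pool, index=kmer_index)
        if call is None:
            continue
        c.gene = call.gene
        own_set = primer_sets[gene_pset[call.gene]]
        has_f, has_r = dx.contains_primers(c.sequence, own_set, CONTIG_POLICY)
        c.full_length = has_f and has_r
        classified.append(c)

    kept: list[Contig] = []
    discarded: list[Contig] = []
    genes = sorted({c.gene for c in classified})
    for gene in genes:
        res = fuse_contigs([c for c in classified if c.gene == gene], params.assembly)
        kept.extend(res.kept)
        discarded.extend(res.discarded)
    return kept, discarded, unassigned


def run_pipeline(
    long_reads: dict[str, list],
    short_reads: dict[str, list],
    primer_sets: dict[str, PrimerSet],
    db: AllelePool,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Full reconstruction run.

    ``long_reads`` maps sample -> objects with ``read_id``/``sequence``
    attributes (or (id, seq) tuples); ``short_reads`` maps sample -> read
    pair objects with ``r1``/``r2`` (or plain sequence strings)."""
    params = params or PipelineParams()

    def as_pairs(items):
        out = []
        for r in items:
            if isinstance(r, tuple):
                out.append(r)
            else:
                out.append((r.read_id, r.sequence))
        return out

    def as_seqs(items):
        out = []
        for r in items:
            if isinstance(r, str):
                out.append(r)
            else:
                out.extend([r.r1, r.r2])
        return out

    kmer_index = PoolKmerIndex(db)
    contigs: list[Contig] = []
    discarded: list[Contig] = []
    unassigned: dict[str, dict[str, str]] = {}
    for sample in sorted(long_reads):
        kept, disc, un = assemble_sample(
            sample, as_pairs(long_reads[sample]), primer_sets, db, params, kmer_index
        )
        contigs.extend(kept)
        discarded.extend(disc)
        unassigned[sample] = un

    draft = build_draft_set(contigs)

    # one pass of gene assignment + strand orientation for every short
    # read; refinement and genotyping then align single-strand, per-gene
    classifier = GeneKmerClassifier(
        {g: [db.alleles[n] for n in db.alleles_of_gene(g)] for g in db.genes}
    )
    oriented_short: dict[str, dict[str, list[str]]] = {
        s: classifier.partition(as_seqs(v)) for s, v in short_reads.items()
    }
    refinement = refine_draft_set(draft, oriented_short, params.refine)
    refined = refinement.refined

    normalizers = [g for g in db.genes if g != params.deletable_gene]
    copy_calls: dict[str, CopyNumberCall] = {}
    genotype_calls: list[GenotypeCall | None] = []
    candidate_seqs: dict[str, str] = {}

    for sample in sorted(oriented_short):
        by_gene = oriented_short[sample]
        if params.deletable_gene in db.genes:
            depths = classifier.depths_from_partition(by_gene)
            norm = sum(depths[g] for g in normalizers) / len(normalizers)
            copy_calls[sample] = call_copy_number(
                sample,
                params.deletable_gene,
                depths.get(params.deletable_gene, 0.0),
                norm,
                params.cn_thresholds,
            )
        for gene in db.genes:
            cn = (
                copy_calls[sample].call
                if gene == params.deletable_gene and sample in copy_calls
                else 2
            )
            candidates: dict[str, str] = {}
            seq_to_id: dict[str, str] = {}
            for aid in refined.alleles_of_gene(gene):
                candidates[aid] = refined.alleles[aid]
                seq_to_id[refined.alleles[aid]] = aid
            for name in db.alleles_of_gene(gene):
                if db.alleles[name] not in seq_to_id:
                    candidates[name] = db.alleles[name]
            candidate_seqs.update(candidates)
            call = genotype_sample(
                sample,
                gene,
                by_gene.get(gene, []),
                candidates,
                copy_number=cn,
                top_k=params.genotype_top_k,
                lam=params.genotype_lambda,
                max_edit=params.genotype_max_edit,
                max_reads=params.genotype_max_reads,
                both_strands=False,
            )
            genotype_calls.append(call)

    panel, selection = filter_panel(refined, [c for c in genotype_calls if c])

    # panel accuracy: a sample carries a panel allele iff its best genotype
    # selected it, and its reads compete over the full called pair (non-
    # panel call members act as mapping decoys)
    call_carriers: dict[str, set[str]] = {a: set() for a in panel.alleles}
    decoys: dict[tuple[str, str], dict[str, str]] = {}
    for call in genotype_calls:
        if call is None:
            continue
        for a in call.alleles:
            if a in call_carriers:
                call_carriers[a].add(call.sample)
        decoys[(call.sample, call.gene)] = {
            a: candidate_seqs[a] for a in call.alleles
        }
    panel_for_assessment = DraftAlleleSet(
        alleles=dict(panel.alleles),
        carriers=call_carriers,
        gene_of=dict(panel.gene_of),
        support=dict(panel.support),
        full_length=dict(panel.full_length),
    )
    from .refine import subset_msa

    panel_msas = {
        gene: subset_msa(
            refinement.msas_after[gene], panel_for_assessment.alleles_of_gene(gene)
        )
        for gene in panel_for_assessment.genes
        if gene in refinement.msas_after
    }
    panel_assessment = assess_allele_set(
        panel_for_assessment,
        oriented_short,
        params.refine,
        mapping_decoys=decoys,
        msas_in=panel_msas,
    )

    return PipelineResult(
        contigs=contigs,
        discarded_contigs=discarded,
        unassigned=unassigned,
        draft=draft,
        refinement=refinement,
        copy_calls=copy_calls,
        genotype_calls=genotype_calls,
        panel=panel,
        selection=selection,
        panel_accuracy=panel_assessment.report,
        candidate_seqs=candidate_seqs,
    )


def genotype_concordance(
    result: PipelineResult, truth, pool: AllelePool
) -> float:
    """Fraction of (sample, gene) genotype calls whose allele sequences
    match the truth haplotype sequences as a multiset."""
    calls = {
        (c.sample, c.gene): c for c in result.genotype_calls if c is not None
    }
    total = correct = 0
    for sample in truth.samples:
        for gene in pool.genes:
            true_names = truth.genotypes[sample].get(gene, [])
            call = calls.get((sample, gene))
            total += 1
            if call is None:
                correct += not true_names
                continue
            called_seqs = sorted(result.candidate_seqs[a] for a in call.alleles)
            true_seqs = sorted(pool.alleles[n] for n in true_names)
            correct += called_seqs == true_seqs
    return correct / total if total else float("nan")


def recovered_truth_fraction(result: PipelineResult, truth, pool: AllelePool) -> float:
    """Fraction of carried truth alleles whose exact sequence appears in
    the final panel."""
    carried = truth.carried_alleles()
    panel_seqs = set(result.panel.alleles.values())
    if not carried:
        return float("nan")
    return sum(pool.alleles[n] in panel_seqs for n in carried) / len(carried)
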