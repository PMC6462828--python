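"""Copy-number calling, diploid genotyping and panel filtering.

The deletable locus is called 0/1/2 copies from the ratio of its short-read
depth to the mean depth over non-deletable loci.  Genotypes are then
estimated per gene by exhaustive diploid likelihood over refined-set plus
database candidates: each read contributes ``exp(-lambda * d)`` with ``d``
its edit distance to the better allele of the pair, so the genotype
log-likelihood is ``-sum_r min(d_r,a1, d_r,a2)`` at ``lambda = 1``.
Finally, only refined alleles that are selected by at least one sample's
best genotype survive into the panel; a dropped allele whose carriers were
all re-typed to one other allele records that allele as its alteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import revcomp
from .assembly import DraftAlleleSet


@dataclass(frozen=True)
class CopyNumberCall:
    sample: str
    locus: str
    locus_depth: float
    normalizer_depth: float
    call: int

    @property
    def ratio(self) -> float:
        return self.locus_depth / self.normalizer_depth


def call_copy_number(
    sample: str,
    locus: str,
    locus_depth: float,
    normalizer_depth: float,
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> CopyNumberCall:
    """Depth-ratio copy number: 0 below ``thresholds[0]``, 2 at or above
    ``thresholds[1]``, else 1.  The normalizer is the mean per-haplotype-
    pair depth over non-deletable loci, so a two-copy locus sits near 1."""
    if normalizer_depth <= 0:
        raise ValueError("normalizer depth is zero")
    low, high = thresholds
    ratio = locus_depth / normalizer_depth
    call = 0 if ratio < low else (1 if ratio < high else 2)
    return CopyNumberCall(sample, locus, locus_depth, normalizer_depth, call)


class GeneKmerClassifier:
    """Assign short reads to genes — and to a strand — by unique-k-mer
    votes against per-gene reference sequences (fast, alignment-free)."""

    def __init__(self, refs_by_gene: dict[str, list[str]], k: int = 21, stride: int = 7):
        self.k = k
        self.stride = stride
        owner: dict[str, tuple[str, int] | None] = {}
        for gene in sorted(refs_by_gene):
            for seq in refs_by_gene[gene]:
                for strand, s in ((1, seq), (-1, revcomp(seq))):
                    for i in range(len(s) - k + 1):
                        km = s[i : i + k]
                        prev = owner.get(km)
                        if prev is None:
                            owner[km] = (gene, strand)
                        elif prev != (gene, strand):
                            if prev is not False and prev[0] == gene:
                                owner[km] = (gene, 0)  # strand-ambiguous
                            else:
                                owner[km] = False  # cross-gene: uninformative
        self.owner = {km: gs for km, gs in owner.items() if gs}
        self.ref_len = {
            g: float(np.mean([len(s) for s in refs]))
            for g, refs in refs_by_gene.items()
        }

    def assign(self, read: str) -> tuple[str, int] | None:
        """(gene, strand) with strand +1 when the read matches the
        reference forward strand, -1 otherwise; None when unassignable."""
        votes: dict[str, int] = {}
        strand_votes: dict[str, int] = {}
        k = self.k
        for i in range(0, len(read) - k + 1, self.stride):
            gs = self.owner.get(read[i : i + k])
            if gs is not None:
                g, strand = gs
                votes[g] = votes.get(g, 0) + 1
                strand_votes[g] = strand_votes.get(g, 0) + strand
        if not votes:
            return None
        gene = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        return gene, (1 if strand_votes[gene] >= 0 else -1)

    def partition(self, reads: list[str]) -> dict[str, list[str]]:
        """Split reads by gene, reorienting each onto the reference
        forward strand."""
        out: dict[str, list[str]] = {}
        for r in reads:
            gs = self.assign(r)
            if gs is not None:
                gene, strand = gs
                out.setdefault(gene, []).append(r if strand > 0 else revcomp(r))
        return out

    def gene_depths(self, reads: list[str]) -> dict[str, float]:
        """Mean base depth per gene: assigned read bases / reference length."""
        bases: dict[str, int] = {}
        for r in reads:
            gs = self.assign(r)
            if gs is not None:
                bases[gs[0]] = bases.get(gs[0], 0) + len(r)
        return {g: bases.get(g, 0) / self.ref_len[g] for g in self.ref_len}

    def depths_from_partition(self, partition: dict[str, list[str]]) -> dict[str, float]:
        return {
            g: sum(len(r) for r in partition.get(g, [])) / self.ref_len[g]
            for g in self.ref_len
        }


def copy_number_from_reads(
    sample: str,
    reads: list[str],
    classifier: GeneKmerClassifier,
    locus: str,
    normalizer_genes: list[str],
    thresholds: tuple[float, float] = (0.25, 0.75),
) -> CopyNumberCall:
    depths = classifier.gene_depths(reads)
    norm = float(np.mean([depths[g] for g in normalizer_genes]))
    return call_copy_number(sample, locus, depths.get(locus, 0.0), norm, thresholds)


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    gene: str
    alleles: tuple[str, ...]  # 0-2 ids, sorted; homozygous repeats the id
    log_likelihood: float
    margin: float


def genotype_sample(
    sample: str,
    gene: str,
    reads: list[str],
    candidates: dict[str, str],
    copy_number: int = 2,
    top_k: int = 20,
    lam: float = 1.0,
    max_edit: int = 15,
    max_reads: int = 800,
    both_strands: bool = False,
    het_penalty: float = 5.0,
) -> GenotypeCall | None:
    """Exhaustive maximum-likelihood genotype over allele multisets of size
    ``copy_number``.

    Candidates are pre-pruned to the ``top_k`` alleles by total read score
    for tractability; reads beyond ``max_reads`` are deterministically
    subsampled (evenly spaced).  Reads are assumed pre-oriented onto the
    candidate strand unless ``both_strands`` is set.

    ``het_penalty`` is a parsimony prior: since the per-read maximum over
    a pair can only improve when a second allele is added, a heterozygous
    call must beat the homozygous one by more than this many log units
    (edit distance at lambda=1); a real second haplotype wins by hundreds.

    Returns None when there are no reads (no-call); copy number 0 yields
    an empty, valid call."""
    if copy_number == 0:
        return GenotypeCall(sample, gene, (), 0.0, float("inf"))
    if not reads or not candidates:
        return None
    if len(reads) > max_reads:
        idx = np.linspace(0, len(reads) - 1, max_reads).astype(int)
        reads = [reads[i] for i in idx]
    names = sorted(candidates)
    cap = max_edit + 1

    def dist_block(block_reads, block_names):
        D = np.full((len(block_reads), len(block_names)), float(cap))
        for i, read in enumerate(block_reads):
            variants = (read, revcomp(read)) if both_strands else (read,)
            for j, name in enumerate(block_names):
                best = cap
                for seq in variants:
                    d = edlib.align(
                        seq, candidates[name], mode="HW", task="distance", k=max_edit
                    )["editDistance"]
                    if 0 <= d < best:
                        best = d
                D[i, j] = best
        return D

    # two-phase: rank all candidates by total read score on an evenly
    # spaced read subset (reads arrive grouped, e.g. by haplotype, so a
    # head slice would be biased), then score every read against the
    # surviving top_k only
    n_screen = min(len(reads), max(120, max_reads // 4))
    screen_idx = np.linspace(0, len(reads) - 1, n_screen).astype(int)
    screen_set = set(int(i) for i in screen_idx)
    rest = [r for i, r in enumerate(reads) if i not in screen_set]
    D_screen = dist_block([reads[i] for i in screen_idx], names)
    score = np.exp(-lam * D_screen).sum(axis=0)
    order = np.argsort(-score, kind="stable")
    keep = sorted(order[:top_k])
    names = [names[j] for j in keep]
    D = np.vstack([D_screen[:, keep], dist_block(rest, names)])

    combos: list[tuple[int, ...]] = []
    if copy_number == 1:
        combos = [(j,) for j in range(len(names))]
    else:
        combos = [
            (i, j) for i in range(len(names)) for j in range(i, len(names))
        ]
    lls = np.empty(len(combos))
    penalized = np.empty(len(combos))
    for c, combo in enumerate(combos):
        d = D[:, combo[0]] if len(combo) == 1 else np.minimum(
            D[:, combo[0]], D[:, combo[1]]
        )
        lls[c] = -lam * d.sum()
        n_distinct = len({names[j] for j in combo})
        penalized[c] = lls[c] - het_penalty * (n_distinct - 1)
    # best call; ties prefer fewer distinct alleles, then lexicographic ids
    def sort_key(c):
        combo = combos[c]
        ids = tuple(sorted(names[j] for j in combo))
        return (-penalized[c], len(set(ids)), ids)

    ranked = sorted(range(len(combos)), key=sort_key)
    best = ranked[0]
    margin = (
        float(penalized[best] - penalized[ranked[1]])
        if len(ranked) > 1
        else float("inf")
    )
    ids = tuple(sorted(names[j] for j in combos[best]))
    return GenotypeCall(sample, gene, ids, float(lls[best]), margin)


@dataclass
class PanelSelection:
    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)  # id -> reason
    alterations: dict[str, str] = field(default_factory=dict)  # dropped -> replacement


def filter_panel(
    refined: DraftAlleleSet, calls: list[GenotypeCall]
) -> tuple[DraftAlleleSet, PanelSelection]:
    """Keep refined alleles that appear in at least one best genotype call.

    A dropped allele whose carriers were all genotyped with one common
    other allele of the same gene records that allele as its alteration."""
    selected: set[str] = set()
    by_sample_gene: dict[tuple[str, str], tuple[str, ...]] = {}
    for call in calls:
        if call is None:
            continue
        selected.update(call.alleles)
        by_sample_gene[(call.sample, call.gene)] = call.alleles

    sel = PanelSelection(kept=[])
    for aid in sorted(refined.alleles):
        if aid in selected:
            sel.kept.append(aid)
            continue
        gene = refined.gene_of[aid]
        common: set[str] | None = None
        for carrier in sorted(refined.carriers[aid]):
            called = set(by_sample_gene.get((carrier, gene), ()))
            common = called if common is None else (common & called)
        if common:
            sel.alterations[aid] = min(common)
            sel.dropped[aid] = "altered"
        else:
            sel.dropped[aid] = "never-genotyped"

    panel = DraftAlleleSet(
        alleles={a: refined.alleles[a] for a in sel.kept},
        carriers={a: set(refined.carriers[a]) for a in sel.kept},
        gene_of={a: refined.gene_of[a] for a in sel.kept},
        support={a: refined.support.get(a, 0) for a in sel.kept},
        full_length={a: refined.full_length.get(a, True) for a in sel.kept},
    )
    return panel, sel
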