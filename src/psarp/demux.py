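"""Primer-based separation of long amplicon reads and gene classification.

Reads carry ``barcode+linker+forward_primer … rc(reverse_primer)+rc(linker)+
rc(barcode)``.  A read is assigned to a primer set only when the forward
primer is found near its 5' end AND the reverse primer near its 3' end in
the same orientation; this is what keeps the nested inner amplicons (one
gene's primer pair annealing inside another gene's product) out of the
outer gene's bin and makes full-length assembly possible.

Primer matching is semi-global: the primer is consumed entirely, both of
its ends are free on the read window, so a terminally truncated primer
occurrence counts its missing bases as edits.

Two match policies coexist: consensus contigs are screened at the strict
historical tolerance (edit distance < 2), while raw long reads — whose
indel-dominated error rate puts several expected edits on a 25 bp primer —
are demultiplexed at a proportionally laxer tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import InfixHit, infix_align, revcomp


@dataclass(frozen=True)
class PrimerSet:
    """A named forward/reverse primer pair (sequences in 5'->3')."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError(f"primer set {self.name}: empty primer")


@dataclass(frozen=True)
class Barcode:
    sample_id: str
    sequence: str


@dataclass(frozen=True)
class PrimerMatchPolicy:
    """max_edit=1 reproduces the strict 'edit distance < 2' contig rule."""

    max_edit: int = 1
    search_window: int = 100

    def __post_init__(self):
        if self.max_edit < 0:
            raise ValueError("max_edit must be >= 0")


#: strict policy for consensus contigs
CONTIG_POLICY = PrimerMatchPolicy(max_edit=1, search_window=100)
#: lax policy for raw long reads (see module docstring)
READ_POLICY = PrimerMatchPolicy(max_edit=6, search_window=100)


@dataclass
class ReadBin:
    """Long reads of one sample and one primer set, with per-read
    orientation (True when the stored read must be reverse-complemented to
    match primer orientation)."""

    sample_id: str
    primer_set: str
    read_ids: list[str] = field(default_factory=list)
    reversed_flags: list[bool] = field(default_factory=list)

    def __len__(self):
        return len(self.read_ids)


def match_primer(segment: str, primer: str, policy: PrimerMatchPolicy = CONTIG_POLICY):
    """Best semi-global occurrence of ``primer`` in ``segment``.

    Returns an :class:`~psarp.align.InfixHit` or None when the minimum edit
    distance exceeds ``policy.max_edit``."""
    if not primer:
        raise ValueError("empty primer")
    if not segment:
        return None
    return infix_align(primer, segment, k=policy.max_edit)


def _end_hits(seq: str, pset: PrimerSet, policy: PrimerMatchPolicy):
    """(forward hit in the 5' window, reverse hit in the 3' window)."""
    w = policy.search_window
    head = seq[: w + len(pset.forward)]
    tail_len = w + len(pset.reverse)
    tail = seq[-tail_len:]
    hit_f = match_primer(head, pset.forward, policy)
    hit_r = match_primer(tail, revcomp(pset.reverse), policy)
    return hit_f, hit_r


def demultiplex(
    reads: list[tuple[str, str]],
    primer_sets: dict[str, PrimerSet],
    policy: PrimerMatchPolicy = READ_POLICY,
    sample_id: str = "sample",
    warn=None,
):
    """Assign ``(read_id, sequence)`` pairs to per-primer-set bins.

    A read is assigned when exactly one primer set yields both a forward
    hit at the 5' end and a reverse hit at the 3' end in one orientation;
    ties across sets are broken by total edit distance, then by the longer
    matched primer span, then the read is left ambiguous.  Returns
    ``(bins, unassigned)`` where unassigned maps read_id -> reason code in
    {no-5p, no-3p, ambiguous}.
    """
    from .align import edit_distance

    sets = sorted(primer_sets.values(), key=lambda p: p.name)
    if warn is not None:
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                for pa, pb in ((a.forward, b.forward), (a.reverse, b.reverse)):
                    d = edit_distance(pa, pb, k=2 * policy.max_edit)
                    if d != -1:
                        warn(
                            f"primer sets {a.name}/{b.name} within "
                            f"{2 * policy.max_edit} edits of each other"
                        )

    bins: dict[str, ReadBin] = {
        p.name: ReadBin(sample_id=sample_id, primer_set=p.name) for p in sets
    }
    unassigned: dict[str, str] = {}
    for read_id, seq in reads:
        candidates = []  # (total_dist, -match_span, set name, is_reversed)
        saw_f = saw_r = False
        for oriented, is_rev in ((seq, False), (revcomp(seq), True)):
            for pset in sets:
                hit_f, hit_r = _end_hits(oriented, pset, policy)
                saw_f |= hit_f is not None
                saw_r |= hit_r is not None
                if hit_f is not None and hit_r is not None:
                    candidates.append(
                        (
                            hit_f.distance + hit_r.distance,
                            -(hit_f.span + hit_r.span),
                            pset.name,
                            is_rev,
                        )
                    )
        if not candidates:
            if saw_f and not saw_r:
                unassigned[read_id] = "no-3p"
            elif saw_r and not saw_f:
                unassigned[read_id] = "no-5p"
            else:
                unassigned[read_id] = "no-5p"
            continue
        candidates.sort()
        if len(candidates) > 1 and candidates[0][:2] == candidates[1][:2] and (
            candidates[0][2] != candidates[1][2]
        ):
            unassigned[read_id] = "ambiguous"
            continue
        _, _, name, is_rev = candidates[0]
        bins[name].read_ids.append(read_id)
        bins[name].reversed_flags.append(is_rev)
    return bins, unassigned


def assign_barcode(
    read_seq: str,
    barcodes: dict[str, Barcode],
    max_edit: int = 2,
    window: int = 30,
):
    """Identify the sample barcode in the leftmost window of a read (either
    orientation); None when no barcode matches within ``max_edit``."""
    best = None
    for sid, bc in sorted(barcodes.items()):
        for oriented in (read_seq[:window], revcomp(read_seq)[:window]):
            hit = infix_align(bc.sequence, oriented, k=max_edit)
            if hit is not None and (best is None or hit.distance < best[0]):
                best = (hit.distance, sid)
    return None if best is None else best[1]


def contains_primers(
    contig: str, primer_set: PrimerSet, policy: PrimerMatchPolicy = CONTIG_POLICY
) -> tuple[bool, bool]:
    """Whether the contig contains the forward / reverse primer sequence
    (either orientation) within the policy's edit tolerance — the
    full-length criterion for an assembled allele."""
    def found(primer: str) -> bool:
        return (
            match_primer(contig, primer, policy) is not None
            or match_primer(contig, revcomp(primer), policy) is not None
        )

    return found(primer_set.forward), found(primer_set.reverse)


# ---------------------------------------------------------------------------
# gene classification of contigs
# ---------------------------------------------------------------------------


class PoolKmerIndex:
    """Per-allele k-mer sets over a reference pool, for fast longest-
    mapped-fragment classification of contigs."""

    def __init__(self, pool, k: int = 15):
        self.k = k
        self.pool = pool
        self.kmers: dict[str, set[str]] = {}
        owner: dict[str, str | bool] = {}
        for name, seq in pool.alleles.items():
            self.kmers[name] = {seq[i : i + k] for i in range(len(seq) - k + 1)}
            gene = pool.gene_of[name]
            for km in self.kmers[name]:
                prev = owner.get(km)
                if prev is None:
                    owner[km] = gene
                elif prev != gene:
                    owner[km] = False
        #: k-mer -> gene, for k-mers unique to one gene
        self.gene_owner = {km: g for km, g in owner.items() if g}

    def gene_votes(self, contig: str, stride: int = 4) -> dict[str, int]:
        votes: dict[str, int] = {}
        k = self.k
        for s in (contig, revcomp(contig)):
            for i in range(0, len(s) - k + 1, stride):
                g = self.gene_owner.get(s[i : i + k])
                if g is not None:
                    votes[g] = votes.get(g, 0) + 1
        return votes


@dataclass(frozen=True)
class GeneCall:
    gene: str
    best_allele: str
    fragment_length: int
    identity: float


def _longest_fragment(contig: str, kmers: set[str], k: int, max_gap: int):
    """Longest run of contig positions whose k-mers occur in the allele,
    tolerating gaps up to ``max_gap`` (mutations/errors break exact k-mer
    sharing locally).  Returns (fragment length, covered fraction)."""
    hits = [i for i in range(len(contig) - k + 1) if contig[i : i + k] in kmers]
    if not hits:
        return 0, 0.0
    best_len, best_cov = 0, 0.0
    run_start = prev = hits[0]
    covered = 1
    for h in hits[1:] + [hits[-1] + max_gap + k + 1]:
        if h - prev > max_gap + k:
            frag = prev - run_start + k
            if frag > best_len:
                best_len, best_cov = frag, covered * 1.0 / max(frag - k + 1, 1)
            run_start = h
            covered = 0
        covered += 1
        prev = h
    return best_len, best_cov


def classify_gene(
    contig: str,
    pool,
    index: PoolKmerIndex | None = None,
    min_fragment: int = 200,
    max_gap: int = 100,
) -> GeneCall | None:
    """Assign a contig to the gene of the pool allele sharing the longest
    contiguous fragment with it; ties go to higher identity within the
    fragment, then to the lexicographically smaller allele name.  None when
    no allele shares a fragment of ``min_fragment`` bases."""
    if not pool.alleles:
        raise ValueError("empty reference pool")
    index = index if index is not None else PoolKmerIndex(pool)
    rc = revcomp(contig)
    # cheap gene prefilter: only alleles of genes with a material share of
    # unique-k-mer votes compete on exact fragment length
    votes = index.gene_votes(contig)
    if votes:
        top = max(votes.values())
        genes = {g for g, v in votes.items() if v >= 0.2 * top}
        names = [n for n in sorted(pool.alleles) if pool.gene_of[n] in genes]
    else:
        names = sorted(pool.alleles)
    best = None  # (-fragment, -identity, name)
    for name in names:
        km = index.kmers[name]
        frag = max(
            _longest_fragment(contig, km, index.k, max_gap),
            _longest_fragment(rc, km, index.k, max_gap),
        )
        cand = (-frag[0], -frag[1], name)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    frag_len = -best[0]
    if frag_len < min_fragment:
        return None
    name = best[2]
    return GeneCall(
        gene=pool.gene_of[name],
        best_allele=name,
        fragment_length=frag_len,
        identity=-best[1],
    )
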