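"""Per-sample consensus assembly of primer-separated read bins.

Each bin (one sample, one primer set) is resolved into haplotype read
clusters by recursive phased bipartition, each cluster is polished into a
consensus contig, contigs of one sample and gene are fused (similar ones
merged, low-support ones discarded, truncated ones absorbed by the
full-length contig that contains them), and the surviving contigs across
samples are deduplicated into the draft allele set.

A bin can legitimately hold reads of two genes — a co-amplifying primer
pair places one gene's full amplicons and another gene's inner fragments
in the same bin — so clustering may return up to four read clusters per
bin; the 1–2 alleles-per-gene contract is enforced at the fusion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import infix_align, project_reads_onto_template

_SYMBOLS = b"ACGT-"


class AssemblyContractError(RuntimeError):
    """A downstream invariant (<= 2 alleles per sample and gene) failed."""


@dataclass
class AssemblyParams:
    min_cluster_fraction: float = 0.2
    min_support_reads: int = 3
    fuse_identity: float = 0.995
    max_alleles_per_bin: int = 2
    het_minor_fraction: float = 0.25
    max_split_depth: int = 2  # <= 4 phased clusters per mixture group
    far_dissimilarity: float = 0.30  # pre-split threshold for gene mixtures
    polish_rounds: int = 5
    max_polish_reads: int = 24  # column majority saturates well below this

    def __post_init__(self):
        if not 0.0 < self.min_cluster_fraction <= 1.0:
            raise ValueError("min_cluster_fraction must be in (0,1]")
        if self.max_alleles_per_bin not in (1, 2):
            raise ValueError("max_alleles_per_bin must be 1 or 2")


@dataclass
class Contig:
    sample_id: str
    primer_set: str
    sequence: str
    n_support_reads: int
    full_length: bool = False
    gene: str | None = None
    polish_converged: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty contig sequence")
        if self.n_support_reads < 1:
            raise ValueError("contig must have support")


def _pick_seed(seqs: list[str]) -> str:
    """Longest sequence; ties broken to the lexicographically smallest."""
    top = max(len(s) for s in seqs)
    return min(s for s in seqs if len(s) == top)


def _het_columns(mat: np.ndarray, min_minor: int, minor_fraction: float):
    """Columns with a second *base* at >= minor_fraction of covered reads
    and >= min_minor supporting reads.

    Gaps are deliberately not counted as a minor allele: reads of a nested
    inner amplicon show the missing flanks as long end-gap runs under a
    global alignment, which is a coverage pattern, not heterozygosity.
    Returns (columns, minor base, major base) arrays."""
    bases = _SYMBOLS[:4]  # ACGT
    counts = np.stack([(mat == s).sum(axis=0) for s in _SYMBOLS])  # (5, L)
    covered = counts.sum(axis=0)
    base_counts = counts[:4]
    order = np.argsort(-base_counts, axis=0, kind="stable")
    major = order[0]
    minor = order[1]
    minor_n = np.take_along_axis(base_counts, minor[None], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(covered > 0, minor_n / np.maximum(covered, 1), 0.0)
    cols = np.flatnonzero((minor_n >= min_minor) & (frac >= minor_fraction))
    return (
        cols,
        np.array([bases[minor[c]] for c in cols], dtype=np.uint8),
        np.array([bases[major[c]] for c in cols], dtype=np.uint8),
    )


def cluster_bin(
    reads: list[str], params: AssemblyParams | None = None
) -> list[list[int]]:
    """Split a bin's reads into haplotype clusters.

    The longest read seeds a global alignment of the whole bin; columns
    where a minor base reaches ``het_minor_fraction`` are candidate
    heterozygous sites, and the bin is bipartitioned by the per-read minor
    fraction over those sites when at least two sites co-segregate with
    the split.  Each side is split again recursively (bounded depth); a
    side smaller than ``min_cluster_fraction`` of its parent is dissolved
    back (the split is refused).  Returns lists of read indices; empty when
    the bin is below ``min_support_reads``.
    """
    params = params or AssemblyParams()
    if len(reads) < params.min_support_reads:
        return []

    def split(
        idx: list[int], depth: int, inherited: tuple[str, np.ndarray] | None = None
    ) -> list[list[int]]:
        if depth >= params.max_split_depth or len(idx) < 2 * params.min_support_reads:
            return [idx]
        seqs = [reads[i] for i in idx]
        seed = _pick_seed(seqs)
        if inherited is not None and inherited[0] == seed:
            mat = inherited[1]
        else:
            k_band = int((params.far_dissimilarity + 0.05) * len(seed)) + 2
            mat = project_reads_onto_template(seqs, seed, k=k_band)
        # gross-dissimilarity pre-split: a co-amplifying primer pair puts
        # two genes' products in one bin; their reads separate far above
        # any error or heterozygosity scale (reads beyond the alignment
        # band count as maximally dissimilar)
        seed_arr = np.frombuffer(seed.encode(), dtype=np.uint8)
        covered = mat != ord(".")
        n_cov = covered.sum(axis=1)
        dis = np.where(
            n_cov > 0,
            ((mat != seed_arr[None, :]) & covered).sum(axis=1)
            / np.maximum(n_cov, 1),
            1.0,
        )
        far = dis >= params.far_dissimilarity
        if far.any() and (~far).any():
            near_idx = [i for i, f in zip(idx, far) if not f]
            far_idx = [i for i, f in zip(idx, far) if f]
            # the seed itself lands in the near side (dis 0), whose rows of
            # this projection stay valid — no realignment needed there
            near_rows = mat[~far]
            return split(near_idx, depth, (seed, near_rows)) + split(far_idx, depth)
        cols, minor_sym, major_sym = _het_columns(
            mat, params.min_support_reads, params.het_minor_fraction
        )
        if len(cols) < 2:
            return [idx]
        sub = mat[:, cols]
        is_minor_sym = sub == minor_sym[None, :]
        informative = is_minor_sym | (sub == major_sym[None, :])
        # phase against a reference read: per-column minor/major labels are
        # arbitrary at a 50/50 haplotype ratio, but agreement with one
        # well-covered read is consistent across columns
        ref = int(np.argmax(informative.sum(axis=1)))
        shared = informative & informative[ref][None, :]
        agree = (is_minor_sym == is_minor_sym[ref][None, :]) & shared
        n_shared = shared.sum(axis=1)
        score = np.where(
            n_shared > 0, agree.sum(axis=1) / np.maximum(n_shared, 1), 1.0
        )
        is_minor = is_minor_sym.astype(float)
        side1 = score >= 0.5
        n1 = int(side1.sum())
        n0 = len(idx) - n1
        if min(n0, n1) < max(
            params.min_support_reads, params.min_cluster_fraction * len(idx)
        ):
            return [idx]
        # linkage: demand >= 2 sites that co-segregate cleanly with the
        # split (minor base near-fixed on one side, near-absent on the
        # other).  Alignment-shift artifacts at tandem repeats produce
        # candidate columns whose minor reads are independent across
        # columns; they never reach this association.
        linked = 0
        for c in range(len(cols)):
            m1 = is_minor[side1, c].mean() if n1 else 0.0
            m0 = is_minor[~side1, c].mean() if n0 else 0.0
            if (m1 > 0.8 and m0 < 0.2) or (m0 > 0.8 and m1 < 0.2):
                linked += 1
        if linked < 2:
            return [idx]
        left = [i for i, s in zip(idx, side1) if not s]
        right = [i for i, s in zip(idx, side1) if s]
        return split(left, depth + 1, (seed, mat[~side1])) + split(
            right, depth + 1, (seed, mat[side1])
        )

    clusters = split(list(range(len(reads))), 0)
    return sorted(clusters, key=lambda c: (-len(c), c))


def _consensus_once(reads: list[str], template: str) -> str:
    """One polishing round: column-majority base over a global alignment of
    all reads to the template (ties keep the template base), plus majority
    insertions between columns."""
    mat, insertions = project_reads_onto_template(
        reads, template, collect_insertions=True
    )
    return _consensus_from_projection(mat, insertions, template)


def _consensus_from_projection(
    mat: np.ndarray, insertions: list[dict[int, str]], template: str
) -> str:
    n, L = mat.shape
    counts = np.stack([(mat == s).sum(axis=0) for s in _SYMBOLS])  # (5, L)
    sym_arr = np.frombuffer(_SYMBOLS, dtype=np.uint8)
    tmpl = np.frombuffer(template.encode(), dtype=np.uint8)
    sym_row = np.full(256, 0, dtype=np.int64)
    for r, s in enumerate(_SYMBOLS):
        sym_row[s] = r
    best = counts.max(axis=0)
    argbest = counts.argmax(axis=0)
    tmpl_counts = counts[sym_row[tmpl], np.arange(L)]
    choice = np.where(tmpl_counts == best, tmpl, sym_arr[argbest])

    # insertion consensus per junction: inserted string present in a strict
    # majority of the reads covering the junction
    pooled: dict[int, dict[str, int]] = {}
    for per_read in insertions:
        for j, s in per_read.items():
            pooled.setdefault(j, {})[s] = pooled.get(j, {}).get(s, 0) + 1
    ins_strings: dict[int, str] = {}
    cov = (mat != ord(".")).astype(np.int32)
    for j, tally in pooled.items():
        if j == 0 or j >= L:
            continue
        covering = int((cov[:, j - 1] & cov[:, j]).sum())
        if covering == 0:
            continue
        top = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        if top[1] * 2 > covering:
            ins_strings[j] = top[0]

    out: list[str] = []
    for j in range(L):
        if j in ins_strings:
            out.append(ins_strings[j])
        c = choice[j]
        if c != ord("-"):
            out.append(chr(c))
    return "".join(out)


def _window_segments(
    mat: np.ndarray, per_read_ins: list[dict[int, str]], w0: int, w1: int
) -> list[str | None]:
    """Reconstruct each read's literal bases over template window [w0, w1),
    splicing in its insertions; None where the read does not cover it."""
    sub = mat[:, w0:w1]
    covered = ~(sub == ord(".")).any(axis=1)
    out: list[str | None] = [None] * mat.shape[0]
    for r in np.flatnonzero(covered):
        base = sub[r].tobytes().translate(None, b"-").decode()
        ins_here = [
            (j, s) for j, s in per_read_ins[r].items() if w0 < j <= w1
        ]
        if ins_here:
            parts = []
            prev = 0
            for j, s in sorted(ins_here):
                off = int(np.count_nonzero(sub[r, : j - w0] != ord("-")))
                parts.append(base[prev:off])
                parts.append(s)
                prev = off
            parts.append(base[prev:])
            base = "".join(parts)
        out[r] = base
    return out


def _local_indel_polish(
    reads: list[str], template: str, min_fraction: float = 0.2, window: int = 50
) -> str:
    """Score-based correction of indel errors that column majority misses.

    Around short repeats the optimal alignment of an inserted base is not
    unique, so reads split their evidence between an insertion at one
    junction and a substitution at the next column and neither reaches a
    majority.  Here every indel suggested by >= ``min_fraction`` of the
    covering reads is tested explicitly: the edit is kept iff it lowers
    the summed alignment cost of the overlapping reads within a local
    window.  Deterministic; candidates are processed left to right and
    overlapping candidates are skipped."""
    mat, per_read_ins = project_reads_onto_template(
        reads, template, collect_insertions=True
    )
    return _indel_polish_from_projection(
        mat, per_read_ins, template, min_fraction, window
    )


def _indel_polish_from_projection(
    mat: np.ndarray,
    per_read_ins: list[dict[int, str]],
    template: str,
    min_fraction: float = 0.2,
    window: int = 50,
) -> str:
    n, L = mat.shape
    votes: dict[tuple[int, str], int] = {}
    for ins in per_read_ins:
        for j, s in ins.items():
            votes[(j, s)] = votes.get((j, s), 0) + 1

    cand: list[tuple[int, str, str]] = []  # (pos, kind, payload)
    for (j, s), v in votes.items():
        if 0 < j < L and v >= max(2, min_fraction * n):
            cand.append((j, "ins", s))
    gap_frac = (mat == ord("-")).sum(axis=0) / np.maximum(
        (mat != ord(".")).sum(axis=0), 1
    )
    run_start = None
    for j in range(L + 1):
        if j < L and gap_frac[j] >= min_fraction:
            if run_start is None:
                run_start = j
        elif run_start is not None:
            cand.append((run_start, "del", template[run_start:j]))
            run_start = None
    cand.sort()

    edits: list[tuple[int, str, str]] = []
    last_end = -(10**9)
    for pos, kind, payload in cand:
        if pos - last_end < 10:
            continue
        w0 = max(0, pos - window)
        w1 = min(L, pos + window)
        orig = template[w0:w1]
        if kind == "ins":
            new = template[w0:pos] + payload + template[pos:w1]
        else:
            new = template[w0:pos] + template[pos + len(payload) : w1]
        delta = 0
        for seg in _window_segments(mat, per_read_ins, w0, w1):
            if seg is None:
                continue
            delta += edlib.align(seg, new, mode="NW", task="distance")[
                "editDistance"
            ] - edlib.align(seg, orig, mode="NW", task="distance")["editDistance"]
        if delta < 0:
            edits.append((pos, kind, payload))
            last_end = pos + (len(payload) if kind == "del" else 0)
    out = template
    for pos, kind, payload in sorted(edits, reverse=True):
        if kind == "ins":
            out = out[:pos] + payload + out[pos:]
        else:
            out = out[:pos] + out[pos + len(payload) :]
    return out


def polish_consensus(
    reads: list[str],
    template: str | None = None,
    max_rounds: int = 5,
    max_reads: int | None = None,
) -> tuple[str, bool]:
    """Iterate align-and-majority polishing (plus score-based local indel
    correction) until a fixed point or ``max_rounds``.  Returns
    (consensus, converged).

    ``max_reads`` deterministically subsamples deep clusters (evenly
    spaced): the column majority is already saturated at a few dozen
    reads, so extra depth buys nothing."""
    if not reads:
        raise ValueError("cannot polish an empty cluster")
    if template is None:
        template = _pick_seed(reads)
    if max_reads is not None and len(reads) > max_reads:
        idx = np.linspace(0, len(reads) - 1, max_reads).astype(int)
        reads = [reads[i] for i in idx]
    for round_no in range(max_rounds):
        len_spread = max(abs(len(r) - len(template)) for r in reads)
        # the first round aligns against a raw seed read (two error loads);
        # later rounds align against a near-finished consensus.  The band
        # must also cover the largest read/template length difference, or
        # shorter members of a mixed cluster silently drop from the pile-up
        frac = 0.28 if round_no == 0 else 0.16
        k_band = int(frac * len(template)) + len_spread + 60
        mat, ins = project_reads_onto_template(
            reads, template, k=k_band, collect_insertions=True
        )
        new = _consensus_from_projection(mat, ins, template)
        if new != template:
            template = new
            continue
        new = _indel_polish_from_projection(mat, ins, template)
        if new == template:
            return template, True
        template = new
    return template, False


@dataclass
class FuseResult:
    kept: list[Contig]
    discarded: list[Contig]


def fuse_contigs(
    contigs: list[Contig], params: AssemblyParams | None = None
) -> FuseResult:
    """Merge similar contigs of one sample and gene and discard weak ones.

    Single-linkage grouping at identity >= ``fuse_identity`` measured over
    the shorter contig's best placement in the longer (so a truncated inner
    amplicon is near-identical to — contained in — its full-length
    container and always merges into it).  Each group is represented by the
    containing contig when one member contains all others, otherwise by the
    most supported member; supports are summed.  Groups are then ranked by
    support and the top ``max_alleles_per_bin`` with support >=
    ``min_support_reads`` survive.
    """
    params = params or AssemblyParams()
    n = len(contigs)
    if n == 0:
        return FuseResult([], [])
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def ident(a: str, b: str) -> float:
        short, long_ = (a, b) if len(a) <= len(b) else (b, a)
        k = int(len(short) * (1.0 - params.fuse_identity)) + 2
        hit = infix_align(short, long_, k=k)
        return 0.0 if hit is None else 1.0 - hit.distance / len(short)

    for i in range(n):
        for j in range(i + 1, n):
            if ident(contigs[i].sequence, contigs[j].sequence) >= params.fuse_identity:
                parent[find(i)] = find(j)

    groups: dict[int, list[Contig]] = {}
    for i, c in enumerate(contigs):
        groups.setdefault(find(i), []).append(c)

    fused: list[Contig] = []
    for members in groups.values():
        members = sorted(
            members, key=lambda c: (-len(c.sequence), c.sequence)
        )
        longest = members[0]
        contains_all = all(
            ident(m.sequence, longest.sequence) >= params.fuse_identity
            for m in members[1:]
        )
        if contains_all and len(members) > 1:
            rep = longest
        else:
            rep = max(
                members,
                key=lambda c: (c.n_support_reads, len(c.sequence), c.sequence),
            )
        total = sum(m.n_support_reads for m in members)
        fused.append(
            Contig(
                sample_id=rep.sample_id,
                primer_set=rep.primer_set,
                sequence=rep.sequence,
                n_support_reads=total,
                full_length=rep.full_length,
                gene=rep.gene,
                polish_converged=rep.polish_converged,
            )
        )

    fused.sort(key=lambda c: (-c.n_support_reads, -len(c.sequence), c.sequence))
    kept, discarded = [], []
    for c in fused:
        if (
            len(kept) < params.max_alleles_per_bin
            and c.n_support_reads >= params.min_support_reads
        ):
            kept.append(c)
        else:
            discarded.append(c)
    return FuseResult(kept, discarded)


@dataclass
class DraftAlleleSet:
    """Deduplicated assembled alleles with their carrier samples."""

    alleles: dict[str, str]
    carriers: dict[str, set[str]]
    gene_of: dict[str, str]
    support: dict[str, int] = field(default_factory=dict)
    full_length: dict[str, bool] = field(default_factory=dict)

    def alleles_of_gene(self, gene: str) -> list[str]:
        return sorted(a for a, g in self.gene_of.items() if g == gene)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.gene_of.values()))

    def __len__(self):
        return len(self.alleles)


def build_draft_set(
    contigs: list[Contig], deletable_genes: frozenset[str] = frozenset({"H"})
) -> DraftAlleleSet:
    """Deduplicate fused contigs across samples into shared draft ids.

    Raises :class:`AssemblyContractError` when more than two contigs remain
    for one sample and gene (the fusion contract was violated)."""
    per_sample_gene: dict[tuple[str, str], int] = {}
    for c in contigs:
        if c.gene is None:
            raise ValueError("contigs must be gene-classified before drafting")
        key = (c.sample_id, c.gene)
        per_sample_gene[key] = per_sample_gene.get(key, 0) + 1
        if per_sample_gene[key] > 2:
            raise AssemblyContractError(f"sample {key[0]} gene {key[1]}: > 2 contigs")

    by_seq: dict[tuple[str, str], list[Contig]] = {}
    for c in sorted(contigs, key=lambda c: (c.gene, c.sample_id, c.sequence)):
        by_seq.setdefault((c.gene, c.sequence), []).append(c)

    alleles, carriers, gene_of, support, full = {}, {}, {}, {}, {}
    serial: dict[str, int] = {}
    for (gene, seq), members in by_seq.items():
        serial[gene] = serial.get(gene, 0) + 1
        did = f"{gene}_{serial[gene]:05d}"
        alleles[did] = seq
        gene_of[did] = gene
        carriers[did] = {m.sample_id for m in members}
        support[did] = sum(m.n_support_reads for m in members)
        full[did] = any(m.full_length for m in members)
    return DraftAlleleSet(alleles, carriers, gene_of, support, full)
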