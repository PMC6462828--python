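"""Short-read validation and correction of assembled draft alleles.

Variants are defined per gene as the multiple-sequence-alignment column
runs where draft alleles disagree.  Each allele's string at each variant
is then checked against the short reads of every sample carrying that
allele: a variant observation is *supported* when enough spanning reads
agree with the allele.  Positions unsupported in every examinable carrier,
with all carriers agreeing on the same alternative, are corrected; alleles
made identical by correction are merged.  Variant accuracy (supported /
examined observations) is reported before and after.

An *examined observation* is an (allele, carrier, position) triple whose
short-read depth over the position reaches ``min_depth``; the mean accuracy
is the unweighted mean of per-gene accuracies.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import cigar_ops, revcomp
from .assembly import DraftAlleleSet

import edlib


class RefinementContractError(RuntimeError):
    """Variant accuracy decreased after correction."""


# ---------------------------------------------------------------------------
# multiple sequence alignment
# ---------------------------------------------------------------------------


@dataclass
class GeneMSA:
    gene: str
    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("MSA rows of unequal length")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, allele_id: str) -> str:
        return self.rows[allele_id].replace("-", "")


def _star_msa(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star alignment: every sequence is globally aligned to the
    longest one and gap patterns are merged through shared center
    coordinates."""
    center_id = min(seqs, key=lambda i: (-len(seqs[i]), i))
    center = seqs[center_id]
    L = len(center)
    proj: dict[str, tuple[np.ndarray, dict[int, str]]] = {}
    for sid, seq in seqs.items():
        if sid == center_id:
            continue
        res = edlib.align(seq, center, mode="NW", task="path")
        row = np.full(L, ord("-"), dtype=np.uint8)
        ins: dict[int, str] = {}
        qpos = tpos = 0
        for length, op in cigar_ops(res["cigar"]):
            if op in "=X":
                row[tpos : tpos + length] = np.frombuffer(
                    seq[qpos : qpos + length].encode(), np.uint8
                )
                qpos += length
                tpos += length
            elif op == "D":
                tpos += length
            else:
                ins[tpos] = ins.get(tpos, "") + seq[qpos : qpos + length]
                qpos += length
        proj[sid] = (row, ins)

    ins_len = [0] * (L + 1)
    for _, (_, ins) in proj.items():
        for j, s in ins.items():
            ins_len[j] = max(ins_len[j], len(s))

    out: dict[str, list[str]] = {sid: [] for sid in seqs}
    for j in range(L + 1):
        if ins_len[j]:
            out[center_id].append("-" * ins_len[j])
            for sid, (_, ins) in proj.items():
                s = ins.get(j, "")
                out[sid].append(s + "-" * (ins_len[j] - len(s)))
        if j < L:
            out[center_id].append(center[j])
            for sid, (row, _) in proj.items():
                out[sid].append(chr(row[j]))
    return {sid: "".join(parts) for sid, parts in out.items()}


def _mafft_msa(seqs: dict[str, str]) -> dict[str, str] | None:
    """Run mafft (FFT-NS-2) when available; None on any failure."""
    if shutil.which("mafft") is None:
        return None
    ids = sorted(seqs)
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        with open(fin, "w") as fh:
            for i, sid in enumerate(ids):
                fh.write(f">s{i}\n{seqs[sid]}\n")
        try:
            res = subprocess.run(
                ["mafft", "--quiet", "--retree", "2", str(fin)],
                capture_output=True,
                text=True,
                check=True,
            )
        except (subprocess.CalledProcessError, OSError):
            return None
    rows: dict[str, list[str]] = {}
    cur = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            cur = line[1:].strip()
            rows[cur] = []
        elif cur is not None:
            rows[cur].append(line.strip())
    out = {}
    for i, sid in enumerate(ids):
        key = f"s{i}"
        if key not in rows:
            return None
        out[sid] = "".join(rows[key]).upper()
    if any(r.replace("-", "") != seqs[sid] for sid, r in out.items()):
        return None
    return out


def sum_of_pairs_cost(rows: dict[str, str]) -> int:
    """Unit-cost sum-of-pairs score of an alignment (mismatches plus
    single-gapped columns over all row pairs; lower is better)."""
    ids = sorted(rows)
    mat = np.vstack([np.frombuffer(rows[i].encode(), np.uint8) for i in ids])
    gap = mat == ord("-")
    cost = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both = ~gap[i] & ~gap[j]
            cost += int(((mat[i] != mat[j]) & both).sum())
            cost += int((gap[i] ^ gap[j]).sum())
    return cost


def build_gene_msa(
    alleles: dict[str, str], gene: str = "", engine: str = "auto"
) -> GeneMSA:
    """Multiple alignment of one gene's alleles.

    ``engine='auto'`` runs mafft when it is on PATH and keeps its result
    only if it scores at least as well (sum-of-pairs cost) as the built-in
    center-star construction, so the output never falls below that
    baseline; either way the ungapping invariant (every row reproduces its
    input exactly) is guaranteed.
    """
    if not alleles:
        raise ValueError("no alleles to align")
    if len(alleles) == 1:
        return GeneMSA(gene, dict(alleles))
    if engine == "mafft":
        rows = _mafft_msa(alleles)
        if rows is None:
            raise RuntimeError("mafft unavailable or failed")
        return GeneMSA(gene, rows)
    if engine == "builtin":
        return GeneMSA(gene, _star_msa(alleles))
    rows = _mafft_msa(alleles)
    star = _star_msa(alleles)
    if rows is None or sum_of_pairs_cost(star) < sum_of_pairs_cost(rows):
        rows = star
    return GeneMSA(gene, rows)


# ---------------------------------------------------------------------------
# variant identification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantPosition:
    """A maximal run of MSA columns where >= 2 distinct row strings occur."""

    start_col: int
    end_col: int
    strings: dict  # allele_id -> gapped string over the run

    @property
    def width(self) -> int:
        return self.end_col - self.start_col


@dataclass
class VariantTable:
    gene: str
    positions: list[VariantPosition]

    def __len__(self):
        return len(self.positions)


def identify_variants(msa: GeneMSA) -> VariantTable:
    """Mark columns with >= 2 distinct symbols, merge adjacent marked
    columns into runs, and emit each allele's string per run."""
    ids = sorted(msa.rows)
    if len(ids) < 2 or msa.n_cols == 0:
        return VariantTable(msa.gene, [])
    mat = np.vstack(
        [np.frombuffer(msa.rows[i].encode(), dtype=np.uint8) for i in ids]
    )
    variable = (mat != mat[0]).any(axis=0)
    positions: list[VariantPosition] = []
    idx = np.flatnonzero(variable)
    if idx.size == 0:
        return VariantTable(msa.gene, [])
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(idx[starts], idx[ends]):
        strings = {i: msa.rows[i][s : e + 1] for i in ids}
        positions.append(VariantPosition(int(s), int(e) + 1, strings))
    return VariantTable(msa.gene, positions)


def subset_msa(msa: GeneMSA, ids: list[str]) -> GeneMSA:
    """Induced sub-alignment: keep the given rows and drop columns that
    become all-gap.  The result is a valid alignment of the subset."""
    rows = {i: msa.rows[i] for i in ids}
    if not rows:
        return GeneMSA(msa.gene, {})
    mat = np.vstack([np.frombuffer(r.encode(), np.uint8) for r in rows.values()])
    keep = ~(mat == ord("-")).all(axis=0)
    cols = np.flatnonzero(keep)
    return GeneMSA(
        msa.gene,
        {i: mat[n, cols].tobytes().decode() for n, i in enumerate(rows)},
    )


def run_footprints(msa: GeneMSA, table: VariantTable, allele_id: str):
    """Ungapped (u0, u1) interval of each variant run on one allele; u0==u1
    marks a pure deletion (the run is all gaps on this allele)."""
    row = msa.rows[allele_id]
    nongap = np.frombuffer(row.encode(), np.uint8) != ord("-")
    pref = np.concatenate([[0], np.cumsum(nongap)])
    return [(int(pref[p.start_col]), int(pref[p.end_col])) for p in table.positions]


# ---------------------------------------------------------------------------
# read mapping and support assessment
# ---------------------------------------------------------------------------


@dataclass
class ReadPlacement:
    start: int
    end: int
    bases: np.ndarray  # uint8 over [start,end); '-' for deletions
    insertions: dict  # junction j (between allele pos j-1 and j) -> str
    weight: float


def map_reads_to_alleles(
    read_seqs: list[str],
    alleles: dict[str, str],
    max_edit_frac: float = 0.15,
    both_strands: bool = True,
) -> dict[str, list[ReadPlacement]]:
    """Semi-globally place each read on its best-scoring allele; reads
    tying across alleles count toward each with fractional weight.  Set
    ``both_strands=False`` when reads are already reference-oriented."""
    out: dict[str, list[ReadPlacement]] = {a: [] for a in alleles}
    ids = sorted(alleles)
    for read in read_seqs:
        k = max(2, int(len(read) * max_edit_frac))
        best = None
        hits = {}
        variants = (read, revcomp(read)) if both_strands else (read,)
        for aid in ids:
            target = alleles[aid]
            for seq in variants:
                d = edlib.align(seq, target, mode="HW", task="distance", k=k)[
                    "editDistance"
                ]
                if d < 0:
                    continue
                if aid not in hits or d < hits[aid][0]:
                    hits[aid] = (d, seq)
                if best is None or d < best:
                    best = d
        if best is None:
            continue
        winners = [aid for aid, (d, _) in hits.items() if d == best]
        w = 1.0 / len(winners)
        for aid in winners:
            _, seq = hits[aid]
            res = edlib.align(seq, alleles[aid], mode="HW", task="path", k=best)
            t0 = res["locations"][0][0]
            tpos = t0
            qpos = 0
            bases = np.full(res["locations"][0][1] + 1 - t0, ord("-"), np.uint8)
            ins: dict[int, str] = {}
            for length, op in cigar_ops(res["cigar"]):
                if op in "=X":
                    bases[tpos - t0 : tpos - t0 + length] = np.frombuffer(
                        seq[qpos : qpos + length].encode(), np.uint8
                    )
                    qpos += length
                    tpos += length
                elif op == "D":
                    tpos += length
                else:
                    ins[tpos] = ins.get(tpos, "") + seq[qpos : qpos + length]
                    qpos += length
            out[aid].append(ReadPlacement(t0, tpos, bases, ins, w))
    for aid in out:
        out[aid].sort(key=lambda p: (p.start, p.end))
    return out


@dataclass
class SupportAssessment:
    allele_id: str
    sample_id: str
    position_index: int
    status: str  # supported | unsupported | unexamined
    depth: float
    agreeing_reads: float
    best_alternative: str | None
    window: tuple[int, int] = (0, 0)  # ungapped allele interval compared


def _extract_string(p: ReadPlacement, u0: int, u1: int) -> str:
    base = (
        p.bases[u0 - p.start : u1 - p.start].tobytes().translate(None, b"-").decode()
    )
    if not p.insertions:
        return base
    ins_here = [(j, s) for j, s in p.insertions.items() if u0 <= j <= u1]
    if not ins_here:
        return base
    parts = []
    prev = 0
    seg = p.bases[u0 - p.start : u1 - p.start]
    for j, s in sorted(ins_here):
        off = int(np.count_nonzero(seg[: j - u0] != ord("-")))
        parts.append(base[prev:off])
        parts.append(s)
        prev = off
    parts.append(base[prev:])
    return "".join(parts)


def assess_position(
    allele_id: str,
    sample_id: str,
    position_index: int,
    u0: int,
    u1: int,
    allele_seq: str,
    placements: list[ReadPlacement],
    min_depth: float = 5,
    support_fraction: float = 0.8,
    window_flank: int = 10,
) -> SupportAssessment:
    """Pile up carrier reads over one variant footprint.

    The footprint of a pure deletion (u0 == u1) is the junction of its two
    flanking bases.  Comparison happens over the footprint extended by
    ``window_flank`` anchored bases on each side: the literal read
    subsequence between the anchors is compared with the allele's, which
    makes the check invariant to where an aligner places an equivalent
    indel inside a repeat.  Reads must span one base beyond the window.
    """
    allele_len = len(allele_seq)
    w0 = max(0, u0 - window_flank)
    w1 = min(allele_len, u1 + window_flank)
    expected = allele_seq[w0:w1]
    a0 = w0 - 1 if w0 > 0 else w0
    a1 = w1 if w1 < allele_len else w1 - 1
    depth = 0.0
    votes: dict[str, float] = {}
    agree = 0.0
    for p in placements:
        if p.start > a0 or p.end < a1 + 1:
            continue
        s = _extract_string(p, w0, w1)
        depth += p.weight
        votes[s] = votes.get(s, 0.0) + p.weight
        if s == expected:
            agree += p.weight
    if depth < min_depth:
        return SupportAssessment(
            allele_id, sample_id, position_index, "unexamined", depth, agree, None, (w0, w1)
        )
    if agree / depth >= support_fraction:
        return SupportAssessment(
            allele_id, sample_id, position_index, "supported", depth, agree, None, (w0, w1)
        )
    best_alt = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return SupportAssessment(
        allele_id, sample_id, position_index, "unsupported", depth, agree, best_alt, (w0, w1)
    )


# ---------------------------------------------------------------------------
# correction, merge, accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Correction:
    allele_id: str
    position_index: int
    u0: int
    u1: int
    old: str
    new: str
    carriers: tuple[str, ...]


def correct_allele(
    allele_id: str,
    sequence: str,
    footprints: list[tuple[int, int]],
    assessments: list[SupportAssessment],
) -> tuple[str, list[Correction]]:
    """Apply corrections to one allele.

    A position is corrected iff it is unsupported in every carrier with
    examinable depth (at least one such carrier) and all of them agree on
    the same replacement string.  Replacements are applied right to left in
    ungapped coordinates over each assessment's comparison window, so
    earlier footprints stay valid; overlapping windows are applied at most
    once."""
    by_pos: dict[int, list[SupportAssessment]] = {}
    for a in assessments:
        if a.allele_id == allele_id:
            by_pos.setdefault(a.position_index, []).append(a)
    todo: list[Correction] = []
    for pos_idx, items in by_pos.items():
        examined = [a for a in items if a.status != "unexamined"]
        if not examined or any(a.status == "supported" for a in examined):
            continue
        alts = {a.best_alternative for a in examined}
        if len(alts) != 1:
            continue  # carriers disagree on the alternative: leave as is
        alt = alts.pop()
        windows = {a.window for a in examined}
        if alt is None or len(windows) != 1:
            continue
        w0, w1 = windows.pop()
        old = sequence[w0:w1]
        if alt == old:
            continue
        todo.append(
            Correction(
                allele_id,
                pos_idx,
                w0,
                w1,
                old,
                alt,
                tuple(sorted(a.sample_id for a in examined)),
            )
        )
    todo.sort(key=lambda c: -c.u0)
    seq = sequence
    applied: list[Correction] = []
    prev_start = len(sequence) + 1
    for c in todo:
        if c.u1 > prev_start:
            continue  # overlaps an already-applied window
        seq = seq[: c.u0] + c.new + seq[c.u1 :]
        applied.append(c)
        prev_start = c.u0
    return seq, sorted(applied, key=lambda c: c.u0)


@dataclass
class AccuracyReport:
    """Examined / supported variant-observation counts per gene."""

    per_gene: dict[str, tuple[int, int]] = field(default_factory=dict)  # (examined, supported)

    def accuracy(self, gene: str) -> float:
        ex, sup = self.per_gene.get(gene, (0, 0))
        return sup / ex if ex else float("nan")

    @property
    def mean_accuracy(self) -> float:
        accs = [self.accuracy(g) for g in self.per_gene if self.per_gene[g][0] > 0]
        return float(np.mean(accs)) if accs else float("nan")

    @property
    def total_examined(self) -> int:
        return sum(ex for ex, _ in self.per_gene.values())


@dataclass
class RefineParams:
    min_depth: float = 5
    support_fraction: float = 0.8
    window_flank: int = 10
    map_max_edit_frac: float = 0.15
    msa_engine: str = "auto"


@dataclass
class AssessmentSet:
    tables: dict  # gene -> VariantTable
    msas: dict  # gene -> GeneMSA
    footprints: dict  # allele_id -> list[(u0,u1)]
    assessments: list
    report: AccuracyReport


def assess_allele_set(
    allele_set: DraftAlleleSet,
    short_reads: dict,
    params: RefineParams | None = None,
    mapping_decoys: dict | None = None,
    genes: list | None = None,
    msas_in: dict | None = None,
) -> AssessmentSet:
    """Variant tables plus per-(allele, carrier, position) support for a
    whole allele set.

    ``short_reads`` maps sample -> flat read sequences (searched on both
    strands), or sample -> {gene: reference-oriented read sequences} when
    the caller has already partitioned reads by gene.

    ``mapping_decoys`` optionally maps (sample, gene) -> {id: sequence} of
    additional references to compete for reads during mapping; needed when
    assessing a subset panel so that reads of a sample's non-panel allele
    do not pile onto its panel allele."""
    params = params or RefineParams()
    genes = allele_set.genes if genes is None else sorted(genes)
    msas, tables, footprints = {}, {}, {}
    for gene in genes:
        seqs = {a: allele_set.alleles[a] for a in allele_set.alleles_of_gene(gene)}
        if msas_in is not None and gene in msas_in:
            msa = msas_in[gene]
        else:
            msa = build_gene_msa(seqs, gene=gene, engine=params.msa_engine)
        msas[gene] = msa
        tables[gene] = identify_variants(msa)
        for aid in seqs:
            footprints[aid] = run_footprints(msa, tables[gene], aid)

    samples = sorted(
        {s for carriers in allele_set.carriers.values() for s in carriers}
    )
    placements: dict[tuple[str, str], list[ReadPlacement]] = {}
    for sample in samples:
        if sample not in short_reads:
            continue
        reads = short_reads[sample]
        partitioned = isinstance(reads, dict)
        for gene in genes:
            own = {
                aid: allele_set.alleles[aid]
                for aid in allele_set.alleles_of_gene(gene)
                if sample in allele_set.carriers[aid]
            }
            if not own:
                continue
            refs = dict(own)
            if mapping_decoys:
                for did, seq in mapping_decoys.get((sample, gene), {}).items():
                    if did not in refs and seq not in own.values():
                        refs[did] = seq
            gene_reads = reads.get(gene, []) if partitioned else reads
            mapped = map_reads_to_alleles(
                gene_reads,
                refs,
                params.map_max_edit_frac,
                both_strands=not partitioned,
            )
            for aid in own:
                placements[(sample, aid)] = mapped[aid]

    assessments = []
    report = AccuracyReport()
    for gene in genes:
        table = tables[gene]
        examined = supported = 0
        for aid in allele_set.alleles_of_gene(gene):
            fps = footprints[aid]
            seq = allele_set.alleles[aid]
            alen = len(seq)
            for sample in sorted(allele_set.carriers[aid]):
                pl = placements.get((sample, aid), [])
                starts = np.array([p.start for p in pl], dtype=np.int64)
                ends = np.array([p.end for p in pl], dtype=np.int64)
                for pos_idx, pos in enumerate(table.positions):
                    u0, u1 = fps[pos_idx]
                    w0 = max(0, u0 - params.window_flank)
                    w1 = min(alen, u1 + params.window_flank)
                    a0 = w0 - 1 if w0 > 0 else w0
                    a1 = w1 if w1 < alen else w1 - 1
                    spanning = [
                        pl[i]
                        for i in np.flatnonzero((starts <= a0) & (ends >= a1 + 1))
                    ]
                    a = assess_position(
                        aid,
                        sample,
                        pos_idx,
                        u0,
                        u1,
                        seq,
                        spanning,
                        params.min_depth,
                        params.support_fraction,
                        params.window_flank,
                    )
                    assessments.append(a)
                    if a.status != "unexamined":
                        examined += 1
                        supported += a.status == "supported"
        report.per_gene[gene] = (examined, supported)
    return AssessmentSet(tables, msas, footprints, assessments, report)


@dataclass
class RefineResult:
    refined: DraftAlleleSet
    draft_accuracy: AccuracyReport
    refined_accuracy: AccuracyReport
    corrections: list[Correction]
    merges: dict[str, str]  # merged allele id -> surviving id
    msas_after: dict = field(default_factory=dict)  # gene -> GeneMSA of refined set


def refine_draft_set(
    draft: DraftAlleleSet,
    short_reads: dict[str, list[str]],
    params: RefineParams | None = None,
    enforce_contract: bool = True,
) -> RefineResult:
    """The full refinement pass: assess, correct, merge, re-assess.

    Raises :class:`RefinementContractError` when a gene's variant accuracy
    decreases after correction (this cannot happen when corrections move
    alleles toward their carriers' reads, so it flags a defect)."""
    params = params or RefineParams()
    before = assess_allele_set(draft, short_reads, params)

    corrected: dict[str, str] = {}
    all_corr: list[Correction] = []
    for gene in draft.genes:
        for aid in draft.alleles_of_gene(gene):
            seq, corr = correct_allele(
                aid, draft.alleles[aid], before.footprints[aid], before.assessments
            )
            corrected[aid] = seq
            all_corr.extend(corr)

    merges: dict[str, str] = {}
    by_seq: dict[tuple[str, str], list[str]] = {}
    for aid in sorted(corrected):
        by_seq.setdefault((draft.gene_of[aid], corrected[aid]), []).append(aid)
    alleles, carriers, gene_of, support, full = {}, {}, {}, {}, {}
    for (gene, seq), ids in by_seq.items():
        keep = min(ids)
        for other in ids:
            if other != keep:
                merges[other] = keep
        alleles[keep] = seq
        gene_of[keep] = gene
        carriers[keep] = set().union(*(draft.carriers[i] for i in ids))
        support[keep] = sum(draft.support.get(i, 0) for i in ids)
        full[keep] = any(draft.full_length.get(i, False) for i in ids)
    refined = DraftAlleleSet(alleles, carriers, gene_of, support, full)

    changed_genes = {draft.gene_of[c.allele_id] for c in all_corr} | {
        draft.gene_of[m] for m in merges
    }
    if changed_genes:
        after_partial = assess_allele_set(
            refined, short_reads, params, genes=sorted(changed_genes)
        )
        after = after_partial
        for gene in refined.genes:
            if gene not in changed_genes:
                after.report.per_gene[gene] = before.report.per_gene[gene]
    else:
        after = before
    msas_after = {
        gene: (after.msas[gene] if gene in changed_genes else before.msas[gene])
        for gene in refined.genes
    }
    if len(refined.alleles) > len(draft.alleles):
        raise RefinementContractError("refined set larger than draft set")
    if enforce_contract:
        for gene in refined.genes:
            b = before.report.accuracy(gene)
            a = after.report.accuracy(gene)
            if not (np.isnan(b) or np.isnan(a)) and a < b - 1e-12:
                raise RefinementContractError(
                    f"{gene}: variant accuracy decreased {b:.4f} -> {a:.4f}"
                )
    return RefineResult(
        refined, before.report, after.report, all_corr, merges, msas_after
    )
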