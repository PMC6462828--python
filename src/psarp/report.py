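"""Characterization of a finished allele panel against a known-allele
database: closest-subtype matching, 4/6/8-digit novelty classes, sequence
extension and novel-variant statistics, allele frequencies and population
coverage.

Naming resolution follows the four-field colon convention: the first two
fields (4-digit) change with nonsynonymous coding differences, the third
(6-digit) with synonymous exonic differences, the fourth (8-digit) with any
other genomic difference.  A panel allele is *novel up to* a resolution
when it differs from its closest database subtype in the corresponding
sequence class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .align import cigar_ops
from .refine import build_gene_msa, identify_variants, run_footprints
from .simdata import AllelePool, truncate_name


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


@dataclass(frozen=True)
class NoveltyClass:
    novel_8digit: bool
    adds_introns: bool
    novel_6digit: bool
    novel_4digit: bool

    def __post_init__(self):
        if self.novel_4digit and not self.novel_6digit:
            raise ValueError("novel_4digit implies novel_6digit")
        if self.novel_6digit and not self.novel_8digit:
            raise ValueError("novel_6digit implies novel_8digit")


@dataclass(frozen=True)
class ExonVariant:
    """One contiguous substitution run inside an exon (Table-style record):
    1-based position within the exon, multi-base ref/alt strings, and the
    amino-acid consequence (None when frames cannot be compared)."""

    exon: int
    pos_in_exon: int
    ref: str
    alt: str
    aa_pos: int | None
    aa_change: str | None  # e.g. "G > R", or "Synonymous"


@dataclass
class ClosestMatch:
    name: str
    distance: int
    exonic_edits: int
    noncoding_edits: int
    panel_span: tuple[int, int]  # db-covered interval on the panel allele
    lifted_exons: list[tuple[int, int]]  # db exons in panel coordinates
    cdna_only: bool


@dataclass
class PanelEntry:
    allele_id: str
    gene: str
    closest: ClosestMatch
    novelty: NoveltyClass
    upstream_extension: int
    downstream_extension: int
    panel_upstream_len: int
    panel_downstream_len: int
    db_upstream_len: int
    db_downstream_len: int
    exon_variants: list[ExonVariant] = field(default_factory=list)

    @property
    def assigned_name(self) -> str:
        return self.closest.name


def _align_db_to_panel(db_seq: str, panel_seq: str):
    res = edlib.align(db_seq, panel_seq, mode="HW", task="path")
    s, e = res["locations"][0]
    return res["editDistance"], (s, e + 1), res["cigar"]


def _partition_edits(cigar: str, t_start: int, exons_db: list[tuple[int, int]]):
    """Split aligned differences into exonic and noncoding counts (per
    base), lift db coordinates to panel coordinates, and collect exonic
    substitution runs.  Query = db allele, target = panel allele."""

    def in_exon(q: int) -> int | None:
        for k, (s, e) in enumerate(exons_db, start=1):
            if s <= q < e:
                return k
        return None

    exonic = noncoding = 0
    qpos, tpos = 0, t_start
    lift = {0: t_start}
    sub_runs: list[tuple[int, int, int]] = []  # (q start, t start, length)
    for length, op in cigar_ops(cigar):
        if op in "=X":
            if op == "X":
                run_q, run_t, run_len = qpos, tpos, 0
                for i in range(length):
                    if in_exon(qpos + i) is not None:
                        exonic += 1
                    else:
                        noncoding += 1
                sub_runs.append((qpos, tpos, length))
            for i in range(1, length + 1):
                lift[qpos + i] = tpos + i
            qpos += length
            tpos += length
        elif op == "I":  # db base absent from the panel allele
            for i in range(length):
                if in_exon(qpos + i) is not None:
                    exonic += 1
                else:
                    noncoding += 1
                lift[qpos + i + 1] = tpos
            qpos += length
        else:  # D: panel bases absent from the db allele
            k = in_exon(qpos) if 0 < qpos else None
            prev_k = in_exon(qpos - 1) if qpos > 0 else None
            if k is not None and k == prev_k:
                exonic += length
            else:
                noncoding += length
            tpos += length
    return exonic, noncoding, lift, sub_runs


def closest_db_allele(
    panel_seq: str, gene: str, db: AllelePool
) -> ClosestMatch:
    """Closest database subtype by pairwise alignment.

    Genomic entries are scored by edit distance over their best placement
    inside the panel allele (free end gaps).  cDNA-only entries (exon-only
    records) are scored in exon space, against the panel CDS lifted through
    the closest genomic entry.  Ties break to fewer exonic edits, then to
    the lexicographically smaller name.
    """
    names = db.alleles_of_gene(gene)
    if not names:
        raise ValueError(f"no database alleles for gene {gene}")
    genomic = [n for n in names if not db.is_cdna_only(n)]
    cdna = [n for n in names if db.is_cdna_only(n)]
    if not genomic:
        raise ValueError(f"no genomic database entry for gene {gene}")

    scored = []
    for n in genomic:
        d, span, cig = _align_db_to_panel(db.alleles[n], panel_seq)
        scored.append((d, n, span, cig))
    scored.sort(key=lambda t: (t[0], t[1]))
    candidates = []
    best_d = scored[0][0]
    for d, n, span, cig in scored:
        exonic, noncoding, lift, subs = _partition_edits(
            cig, span[0], db.exon_intervals(n)
        )
        lifted = [
            (lift[s], lift[e]) for s, e in db.exon_intervals(n)
        ]
        candidates.append(
            ClosestMatch(n, d, exonic, noncoding, span, lifted, False)
        )
        if d > best_d:
            break  # only the distance-tied prefix needs edit partitions
    candidates.sort(key=lambda m: (m.distance, m.exonic_edits, m.name))
    anchor = candidates[0]

    panel_cds = "".join(panel_seq[s:e] for s, e in anchor.lifted_exons)
    best = anchor
    for n in cdna:
        d = edlib.align(db.alleles[n], panel_cds, mode="NW", task="distance")[
            "editDistance"
        ]
        m = ClosestMatch(
            n,
            d,
            d,
            0,
            (anchor.lifted_exons[0][0], anchor.lifted_exons[-1][1]),
            anchor.lifted_exons,
            True,
        )
        if (m.distance, m.exonic_edits, m.name) < (
            best.distance,
            best.exonic_edits,
            best.name,
        ):
            best = m
    return best


def _exon_variants(
    db: AllelePool, match: ClosestMatch, panel_seq: str
) -> list[ExonVariant]:
    """Substitution-run records within exons, with amino-acid consequences
    when both CDSs keep a comparable frame."""
    name = match.name
    db_seq = db.alleles[name]
    exons_db = db.exon_intervals(name)
    if match.cdna_only:
        res = edlib.align(
            db_seq,
            "".join(panel_seq[s:e] for s, e in match.lifted_exons),
            mode="NW",
            task="path",
        )
        cig, t0 = res["cigar"], 0
        panel_ref = "".join(panel_seq[s:e] for s, e in match.lifted_exons)
    else:
        _, _, cig = _align_db_to_panel(db_seq, panel_seq)
        t0 = match.panel_span[0]
        panel_ref = panel_seq
    _, _, _, sub_runs = _partition_edits(cig, t0, exons_db)

    db_cds = db.cds(name)
    panel_cds = "".join(panel_seq[s:e] for s, e in match.lifted_exons)
    if len(db_cds) % 3:
        raise ValueError(f"{name}: CDS length not divisible by 3")
    comparable = len(panel_cds) == len(db_cds)
    db_aa = _translate(db_cds)
    panel_aa = _translate(panel_cds) if comparable else None

    offsets = {}
    acc = 0
    for k, (s, e) in enumerate(exons_db, start=1):
        offsets[k] = (s, acc)
        acc += e - s

    out: list[ExonVariant] = []
    for q, t, length in sub_runs:
        for k, (s, e) in enumerate(exons_db, start=1):
            if s <= q < e:
                run_len = min(length, e - q)
                ref = db_seq[q : q + run_len]
                alt = panel_ref[t : t + run_len]
                aa_pos = aa_change = None
                if comparable:
                    cpos = offsets[k][1] + (q - s)
                    aa_pos = cpos // 3 + 1
                    a0 = db_aa[aa_pos - 1]
                    a1 = panel_aa[aa_pos - 1]
                    aa_change = "Synonymous" if a0 == a1 else f"{a0} > {a1}"
                out.append(
                    ExonVariant(k, q - s + 1, ref, alt, aa_pos, aa_change)
                )
                break
    return out


def classify_novelty(
    match: ClosestMatch, db: AllelePool, panel_seq: str
) -> NoveltyClass:
    """4/6/8-digit novelty flags from the closest-subtype alignment.

    Genomic difference within the database span => novel at 8 digits;
    exonic difference => also at 6; a protein-changing exonic difference
    (including any frame-length change) => also at 4.  A cDNA-only closest
    subtype means the panel newly adds intron/flank sequence."""
    if match.cdna_only:
        novel8 = True
        adds_introns = True
        exonic = match.exonic_edits > 0
    else:
        novel8 = match.distance > 0
        adds_introns = False
        exonic = match.exonic_edits > 0
    nonsyn = False
    if exonic:
        db_cds = db.cds(match.name)
        panel_cds = "".join(panel_seq[s:e] for s, e in match.lifted_exons)
        if len(db_cds) % 3:
            raise ValueError(f"{match.name}: CDS length not divisible by 3")
        if len(panel_cds) != len(db_cds):
            nonsyn = True
        else:
            nonsyn = _translate(panel_cds) != _translate(db_cds)
    return NoveltyClass(
        novel_8digit=novel8 or exonic,
        adds_introns=adds_introns,
        novel_6digit=exonic,
        novel_4digit=nonsyn,
    )


def characterize_panel(
    panel_alleles: dict[str, str],
    gene_of: dict[str, str],
    db: AllelePool,
) -> list[PanelEntry]:
    """One :class:`PanelEntry` per panel allele: closest subtype, novelty
    class, regulatory-region lengths and exonic variant records."""
    entries = []
    for aid in sorted(panel_alleles):
        seq = panel_alleles[aid]
        gene = gene_of[aid]
        match = closest_db_allele(seq, gene, db)
        novelty = classify_novelty(match, db, seq)
        variants = _exon_variants(db, match, seq)
        db_seq = db.alleles[match.name]
        db_exons = db.exon_intervals(match.name)
        entries.append(
            PanelEntry(
                allele_id=aid,
                gene=gene,
                closest=match,
                novelty=novelty,
                upstream_extension=match.panel_span[0],
                downstream_extension=len(seq) - match.panel_span[1],
                panel_upstream_len=match.lifted_exons[0][0],
                panel_downstream_len=len(seq) - match.lifted_exons[-1][1],
                db_upstream_len=db_exons[0][0],
                db_downstream_len=len(db_seq) - db_exons[-1][1],
                exon_variants=variants,
            )
        )
    return entries


def extension_and_variant_stats(
    entries: list[PanelEntry],
    panel_alleles: dict[str, str],
    msa_engine: str = "auto",
) -> pd.DataFrame:
    """Per-gene summary of panel sizes, regulatory-region lengths and the
    count of variant positions that fall outside every closest database
    allele's span (newly identified regulatory variants)."""
    by_gene: dict[str, list[PanelEntry]] = {}
    for e in entries:
        by_gene.setdefault(e.gene, []).append(e)
    rows = []
    for gene in sorted(by_gene):
        group = by_gene[gene]
        ids = [e.allele_id for e in group]
        spans = {e.allele_id: e.closest.panel_span for e in group}
        novel_up = novel_down = 0
        if len(ids) >= 2:
            msa = build_gene_msa(
                {i: panel_alleles[i] for i in ids}, gene=gene, engine=msa_engine
            )
            table = identify_variants(msa)
            fps = {i: run_footprints(msa, table, i) for i in ids}
            for pos_idx in range(len(table.positions)):
                up = all(fps[i][pos_idx][1] <= spans[i][0] for i in ids)
                down = all(fps[i][pos_idx][0] >= spans[i][1] for i in ids)
                novel_up += up
                novel_down += down
        rows.append(
            {
                "gene": gene,
                "n_alleles": len(group),
                "mean_length": np.mean([len(panel_alleles[i]) for i in ids]),
                "mean_db_length": np.mean(
                    [e.closest.panel_span[1] - e.closest.panel_span[0] for e in group]
                ),
                "mean_upstream_len": np.mean([e.panel_upstream_len for e in group]),
                "mean_db_upstream_len": np.mean([e.db_upstream_len for e in group]),
                "mean_downstream_len": np.mean([e.panel_downstream_len for e in group]),
                "mean_db_downstream_len": np.mean(
                    [e.db_downstream_len for e in group]
                ),
                "novel_upstream_variants": novel_up,
                "novel_downstream_variants": novel_down,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def allele_distribution(
    calls: list,
    deletable_gene: str = "H",
) -> pd.DataFrame:
    """Allele frequencies per gene over typed chromosome slots.

    ``calls`` are :class:`~psarp.genotype.GenotypeCall` objects (None
    entries are counted as untyped diploid slots)."""
    counts: dict[tuple[str, str], float] = {}
    typed: dict[str, int] = {}
    untyped: dict[str, int] = {}
    for call in calls:
        if call is None:
            continue
        typed[call.gene] = typed.get(call.gene, 0) + len(call.alleles)
        for a in call.alleles:
            counts[(call.gene, a)] = counts.get((call.gene, a), 0) + 1
    rows = []
    for (gene, a), c in sorted(counts.items()):
        rows.append(
            {
                "gene": gene,
                "allele": a,
                "count": int(c),
                "frequency": c / typed[gene],
            }
        )
    return pd.DataFrame(rows, columns=["gene", "allele", "count", "frequency"])


def novel_frequency_totals(
    distribution: pd.DataFrame, novelty_of: dict[str, NoveltyClass]
) -> pd.DataFrame:
    """Total frequency per gene of alleles novel at each resolution."""
    rows = []
    for gene, sub in distribution.groupby("gene"):
        row = {"gene": gene}
        for res, flag in ((8, "novel_8digit"), (6, "novel_6digit"), (4, "novel_4digit")):
            total = 0.0
            for _, r in sub.iterrows():
                nov = novelty_of.get(r["allele"])
                if nov is not None and getattr(nov, flag):
                    total += r["frequency"]
            row[f"novel_freq_{res}digit"] = total
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


@dataclass(frozen=True)
class CoverageResult:
    gene: str
    resolution: int
    covered_fraction: float


def population_coverage(
    population_names: list[str],
    panel_names: set[str],
    resolution: int,
    gene: str = "",
) -> CoverageResult:
    """Fraction of typed population allele slots whose name, truncated to
    the resolution, matches the truncation of some panel allele name."""
    if resolution not in (4, 6, 8):
        raise ValueError("resolution must be 4, 6 or 8")
    panel_trunc = {truncate_name(n, resolution) for n in panel_names}
    if not population_names:
        return CoverageResult(gene, resolution, float("nan"))
    hit = sum(
        1 for n in population_names if truncate_name(n, resolution) in panel_trunc
    )
    return CoverageResult(gene, resolution, hit / len(population_names))
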