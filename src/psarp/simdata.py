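"""Synthetic multi-gene amplicon data with the structure the pipeline assumes.

The generator emulates a small HLA-class-I-like locus family:

* four genes (``A``, ``B``, ``C`` and a deletable pseudogene ``H``), each a
  few kb long with an 8-exon body flanked by upstream/downstream regulatory
  regions;
* a pool of named alleles per gene, derived from one ancestral sequence by
  substitutions plus occasional short non-exonic indels, with population
  frequencies — this pool plays the role of the known-allele database;
* diploid samples drawn from those frequencies, with 0–2 copies of the
  deletable locus;
* indexed full-amplicon long reads per sample and primer set, including
  nested co-amplification: the ``B`` primer pair also anneals inside the
  ``C`` amplicon and amplifies its inner sub-region at higher depth (the
  geometry that truncates naive joint assembly), and the ``A`` primer pair
  co-amplifies the ``H`` locus full length;
* low-error paired short reads over each true haplotype.

All randomness flows from one integer seed through ``numpy`` generators, so
a fixed seed reproduces every output byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .align import infix_align, revcomp
from .demux import Barcode, PrimerSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

PRIMER_LEN = 25
LINKER = "GGTAG"  # 5 bp universal linker between barcode and primer
BARCODE_LEN = 16

# exon sizes of a class-I-like gene; they sum to 1098 = 366 codons
EXON_SIZES = (73, 270, 276, 276, 117, 33, 48, 5)


class SimulationError(ValueError):
    """Raised when a configuration cannot produce valid data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Geometry of one locus: total span between the designed primers,
    exon intervals (0-based half-open) and regulatory flank lengths."""

    gene_name: str
    length: int
    exon_intervals: tuple[tuple[int, int], ...]
    upstream_len: int
    downstream_len: int
    deletable: bool = False

    def __post_init__(self):
        if self.length < 2000:
            raise SimulationError(f"{self.gene_name}: length must be >= 2 kb")
        lo, hi = self.upstream_len, self.length - self.downstream_len
        prev = lo
        for s, e in self.exon_intervals:
            if not (lo <= s < e <= hi):
                raise SimulationError(f"{self.gene_name}: exon [{s},{e}) outside gene body")
            if s < prev:
                raise SimulationError(f"{self.gene_name}: exons unsorted/overlapping")
            prev = e


@dataclass
class AllelePool:
    """Named full-length allele sequences with annotations and frequencies.

    This container doubles as the known-allele database: annotations use
    labels ``exon{k}``, ``upstream`` and ``downstream``; allele names follow
    the four-field colon convention (``GENE*gg:pp:ss:nn``)."""

    alleles: dict[str, str]
    gene_of: dict[str, str]
    annotations: dict[str, list[tuple[int, int, str]]]
    frequencies: dict[str, float]

    def __post_init__(self):
        for gene in set(self.gene_of.values()):
            names = self.alleles_of_gene(gene)
            total = sum(self.frequencies.get(n, 0.0) for n in names)
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"{gene}: frequencies sum to {total}")
            seqs = [self.alleles[n] for n in names]
            if len(set(seqs)) != len(seqs):
                raise SimulationError(f"{gene}: duplicate allele sequences")
        for name in self.alleles:
            parse_allele_name(name)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.gene_of.values()))

    def alleles_of_gene(self, gene: str) -> list[str]:
        return sorted(n for n, g in self.gene_of.items() if g == gene)

    def exon_intervals(self, name: str) -> list[tuple[int, int]]:
        return [
            (s, e)
            for s, e, lab in self.annotations.get(name, [])
            if lab.startswith("exon")
        ]

    def cds(self, name: str) -> str:
        seq = self.alleles[name]
        return "".join(seq[s:e] for s, e in self.exon_intervals(name))

    def is_cdna_only(self, name: str) -> bool:
        """True when the entry catalogs only exon sequence (no introns)."""
        return sum(e - s for s, e in self.exon_intervals(name)) == len(
            self.alleles[name]
        )


def parse_allele_name(name: str) -> tuple[str, tuple[str, ...]]:
    """Split ``GENE*gg:pp:ss:nn`` into gene and resolution fields."""
    gene, _, rest = name.partition("*")
    fields = tuple(rest.split(":"))
    if not gene or len(fields) != 4 or not all(fields):
        raise SimulationError(f"allele name {name!r} not GENE*gg:pp:ss:nn")
    return gene, fields


def truncate_name(name: str, resolution: int) -> str:
    """Truncate an allele name to 4-, 6- or 8-digit resolution."""
    gene, fields = parse_allele_name(name)
    n = {4: 2, 6: 3, 8: 4}[resolution]
    return gene + "*" + ":".join(fields[:n])


@dataclass
class TruthGenotypes:
    """Per sample and gene: the list of true allele names (homozygotes
    listed twice; the deletable locus may have 0–2 entries)."""

    genotypes: dict[str, dict[str, list[str]]]
    deletable_gene: str = "H"

    def copy_number(self, sample: str, gene: str) -> int:
        return len(self.genotypes[sample].get(gene, []))

    @property
    def samples(self) -> list[str]:
        return sorted(self.genotypes)

    def carried_alleles(self, gene: str | None = None) -> set[str]:
        out: set[str] = set()
        for per_gene in self.genotypes.values():
            for g, names in per_gene.items():
                if gene is None or g == gene:
                    out.update(names)
        return out


@dataclass(frozen=True)
class NestedTarget:
    """One co-amplified inner product: a primer set amplifies ``interval``
    of every haplotype of ``gene`` at ``multiplier`` times the base depth."""

    gene: str
    interval: tuple[int, int]
    multiplier: float = 3.0


@dataclass
class SimConfig:
    n_samples: int = 30
    pool_sizes: dict[str, int] = field(
        default_factory=lambda: {"A": 20, "B": 20, "C": 20, "H": 20}
    )
    divergence_rate: float = 0.005
    long_read_depth: int = 30
    long_mismatch: float = 0.01
    long_insertion: float = 0.06
    long_deletion: float = 0.04
    nested_amplification: dict[str, list[NestedTarget]] = field(default_factory=dict)
    short_read_len: int = 150
    insert_mean: float = 420.0
    insert_sd: float = 60.0
    short_error: float = 0.001
    short_coverage: float = 15.0  # per haplotype, i.e. ~30x diploid
    deletion_freq_H: float = 0.3
    seed: int = 1

    def __post_init__(self):
        for p in (
            self.long_mismatch,
            self.long_insertion,
            self.long_deletion,
            self.short_error,
            self.deletion_freq_H,
        ):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0,1]")


# ---------------------------------------------------------------------------
# gene models and ancestors
# ---------------------------------------------------------------------------


def _layout_gene(name, length, up, down, deletable=False) -> GeneModel:
    body_len = length - up - down
    n_introns = len(EXON_SIZES) - 1
    intron_total = body_len - sum(EXON_SIZES)
    if intron_total < n_introns:
        raise SimulationError(f"{name}: gene body too short for exon layout")
    base, extra = divmod(intron_total, n_introns)
    introns = [base + (1 if i < extra else 0) for i in range(n_introns)]
    exons = []
    pos = up
    for i, size in enumerate(EXON_SIZES):
        exons.append((pos, pos + size))
        pos += size
        if i < n_introns:
            pos += introns[i]
    return GeneModel(name, length, tuple(exons), up, down, deletable)


def default_gene_models() -> dict[str, GeneModel]:
    """Four class-I-like loci with realistic spans and flank lengths."""
    return {
        "A": _layout_gene("A", 5200, 830, 1420),
        "B": _layout_gene("B", 4100, 340, 1080),
        "C": _layout_gene("C", 4500, 550, 1020),
        "H": _layout_gene("H", 5150, 820, 1440, deletable=True),
    }


# inner interval of the C amplicon that the B primer pair co-amplifies;
# endpoints sit inside the C flanks so the whole gene body is retained
C_INNER_INTERVAL = (380, 4000)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate_site(site: str, rng: np.random.Generator, n_edits: int = 1) -> str:
    """Introduce ``n_edits`` substitutions into a primer annealing site."""
    arr = bytearray(site.encode())
    pos = rng.choice(len(arr), size=n_edits, replace=False)
    for p in pos:
        cur = arr[p]
        choices = [b for b in b"ACGT" if b != cur]
        arr[p] = choices[rng.integers(0, 3)]
    return arr.decode()


def build_ancestors(
    gene_models: dict[str, GeneModel], rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, PrimerSet], dict[str, list[tuple[int, int]]]]:
    """Draw one ancestral sequence per gene, derive the primer pairs from
    the terminal 25 bp of A/B/C, and plant near-copies of cross-amplifying
    primer sites (B inside C; A at the ends of H).

    Returns (ancestors, primer_sets, protected intervals per gene)."""
    anc: dict[str, str] = {}
    protected: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_models}
    for g in ("A", "B", "C", "H"):
        anc[g] = _rand_seq(rng, gene_models[g].length)
        protected[g] = [(0, PRIMER_LEN), (gene_models[g].length - PRIMER_LEN, gene_models[g].length)]

    primer_sets = {}
    for g in ("A", "B", "C"):
        primer_sets[g] = PrimerSet(
            name=g,
            forward=anc[g][:PRIMER_LEN],
            reverse=revcomp(anc[g][-PRIMER_LEN:]),
        )

    # B annealing sites inside the C amplicon: forward site at the
    # inner-interval start, reverse-site complement at its end
    s0, s1 = C_INNER_INTERVAL
    c = anc["C"]
    fwd_site = primer_sets["B"].forward
    rev_site = revcomp(primer_sets["B"].reverse)
    anc["C"] = (
        c[:s0] + fwd_site + c[s0 + PRIMER_LEN : s1 - PRIMER_LEN] + rev_site + c[s1:]
    )
    protected["C"] += [(s0, s0 + PRIMER_LEN), (s1 - PRIMER_LEN, s1)]

    # the H locus is captured by the A primer pair: its termini carry the
    # A annealing sites
    h = anc["H"]
    anc["H"] = (
        primer_sets["A"].forward
        + h[PRIMER_LEN : len(h) - PRIMER_LEN]
        + revcomp(primer_sets["A"].reverse)
    )
    return anc, primer_sets, protected


def make_barcodes(n_samples: int, rng: np.random.Generator) -> dict[str, Barcode]:
    """One 16 bp sample barcode each, pairwise Hamming distance >= 5."""
    out: dict[str, Barcode] = {}
    seqs: list[str] = []
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        for _ in range(1000):
            cand = _rand_seq(rng, BARCODE_LEN)
            if all(sum(a != b for a, b in zip(cand, s)) >= 5 for s in seqs):
                break
        else:  # pragma: no cover - effectively impossible at 16 bp
            raise SimulationError("could not draw distinguishable barcodes")
        seqs.append(cand)
        out[sid] = Barcode(sample_id=sid, sequence=cand)
    return out


# ---------------------------------------------------------------------------
# allele pool generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthMutation:
    """Bookkeeping for one mutation placed on an allele (ancestor coords)."""

    position: int
    ref: str
    alt: str
    region: str  # upstream | downstream | exon{k} | intron
    synonymous: bool | None  # None outside exons


def _region_of(pos: int, model: GeneModel) -> str:
    if pos < model.upstream_len:
        return "upstream"
    if pos >= model.length - model.downstream_len:
        return "downstream"
    for k, (s, e) in enumerate(model.exon_intervals, start=1):
        if s <= pos < e:
            return f"exon{k}"
    return "intron"


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def _mutate_allele(
    ancestor: str,
    model: GeneModel,
    protected: list[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int, str]], list[TruthMutation]]:
    """Apply substitutions (anywhere unprotected) and occasional 1–4 bp
    indels (non-exonic, unprotected) at overall per-base ``rate``; 10 % of
    events are indels.  Returns (sequence, lifted annotations, mutations)."""
    n = len(ancestor)
    banned = np.zeros(n, dtype=bool)
    for s, e in protected:
        banned[s:e] = True
    exonic = np.zeros(n, dtype=bool)
    for s, e in model.exon_intervals:
        exonic[s:e] = True

    u = rng.random(n)
    kind = rng.random(n)
    is_event = (u < rate) & ~banned
    is_indel = is_event & (kind < 0.10) & ~exonic
    is_sub = is_event & ~is_indel

    events: list[tuple[int, str, str, str]] = []  # pos, kind, ref, alt
    for pos in np.flatnonzero(is_sub):
        ref = ancestor[pos]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        events.append((int(pos), "sub", ref, alt))
    for pos in np.flatnonzero(is_indel):
        size = int(rng.integers(1, 5))
        if rng.random() < 0.5:  # deletion, must stay non-exonic/unprotected
            end = min(int(pos) + size, n)
            if banned[pos:end].any() or exonic[pos:end].any():
                continue
            events.append((int(pos), "del", ancestor[pos:end], ""))
        else:
            events.append((int(pos), "ins", "", _rand_seq(rng, size)))

    events.sort()
    # drop overlapping deletions
    pruned: list[tuple[int, str, str, str]] = []
    cursor = -1
    for pos, k, ref, alt in events:
        if pos <= cursor and k != "ins":
            continue
        pruned.append((pos, k, ref, alt))
        if k == "del":
            cursor = pos + len(ref) - 1

    pieces: list[str] = []
    shifts: list[tuple[int, int]] = []  # (ancestor pos, cumulative offset after)
    last = 0
    offset = 0
    muts: list[TruthMutation] = []
    for pos, k, ref, alt in pruned:
        pieces.append(ancestor[last:pos])
        if k == "sub":
            pieces.append(alt)
            last = pos + 1
        elif k == "del":
            last = pos + len(ref)
            offset -= len(ref)
            shifts.append((last, offset))
        else:
            pieces.append(alt + ancestor[pos])
            last = pos + 1
            offset += len(alt)
            shifts.append((last, offset))
        muts.append(
            TruthMutation(pos, ref, alt, _region_of(pos, model), None)
        )
    pieces.append(ancestor[last:])
    seq = "".join(pieces)

    def lift(p: int) -> int:
        off = 0
        for ap, o in shifts:
            if ap <= p:
                off = o
            else:
                break
        return p + off

    ann: list[tuple[int, int, str]] = [(0, lift(model.upstream_len), "upstream")]
    for k, (s, e) in enumerate(model.exon_intervals, start=1):
        ann.append((lift(s), lift(e), f"exon{k}"))
    ann.append((lift(model.length - model.downstream_len), len(seq), "downstream"))

    # synonymous status of exonic substitutions, evaluated one at a time
    anc_cds = "".join(ancestor[s:e] for s, e in model.exon_intervals)
    exon_offsets = {}
    acc = 0
    for k, (s, e) in enumerate(model.exon_intervals, start=1):
        exon_offsets[k] = (s, acc)
        acc += e - s
    final: list[TruthMutation] = []
    for m in muts:
        if m.region.startswith("exon"):
            k = int(m.region[4:])
            s, acc0 = exon_offsets[k]
            cpos = acc0 + (m.position - s)
            mutated = anc_cds[:cpos] + m.alt + anc_cds[cpos + 1 :]
            syn = _translate(mutated) == _translate(anc_cds)
            final.append(replace(m, synonymous=syn))
        else:
            final.append(m)
    return seq, ann, final


@dataclass
class PoolTruth:
    """Mutation records per allele, kept outside the pool itself."""

    mutations: dict[str, list[TruthMutation]]


def generate_allele_pool(
    gene_models: dict[str, GeneModel],
    pool_sizes: dict[str, int],
    divergence_rate: float,
    seed: int | np.random.Generator,
    ancestors: dict[str, str] | None = None,
    protected: dict[str, list[tuple[int, int]]] | None = None,
    max_retries: int = 20,
) -> tuple[AllelePool, PoolTruth]:
    """Mutate one ancestral sequence per gene into ``pool_sizes`` distinct
    named alleles with Dirichlet-symmetric frequencies.

    Allele names encode relatedness: alleles sharing a protein share the
    first two name fields, alleles sharing a CDS share the third, so the
    4/6/8-digit resolution logic downstream is exercised for real.
    """
    if not 0.0 < divergence_rate <= 0.05:
        raise SimulationError("divergence_rate must be in (0, 0.05]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if ancestors is None:
        ancestors = {g: _rand_seq(rng, m.length) for g, m in gene_models.items()}
    protected = protected or {g: [] for g in gene_models}

    alleles: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    annotations: dict[str, list[tuple[int, int, str]]] = {}
    freqs: dict[str, float] = {}
    mut_truth: dict[str, list[TruthMutation]] = {}

    for gene in sorted(gene_models):
        size = pool_sizes.get(gene, 0)
        if size < 1:
            raise SimulationError(f"{gene}: pool size must be >= 1")
        model = gene_models[gene]
        seen: dict[str, str] = {}
        records = []
        for _ in range(size):
            for _attempt in range(max_retries):
                seq, ann, muts = _mutate_allele(
                    ancestors[gene], model, protected[gene], divergence_rate, rng
                )
                if seq not in seen:
                    break
            else:
                raise SimulationError(
                    f"{gene}: could not generate {size} distinct alleles "
                    f"at divergence {divergence_rate}"
                )
            seen[seq] = ""
            records.append((seq, ann, muts))

        # name by protein / CDS equivalence classes
        by_protein: dict[str, int] = {}
        by_cds: dict[str, tuple[int, int]] = {}
        counters: dict[tuple, int] = {}
        group_serial = 0
        for seq, ann, muts in records:
            cds = "".join(seq[s:e] for s, e, lab in ann if lab.startswith("exon"))
            prot = _translate(cds)
            if prot not in by_protein:
                group_serial += 1
                by_protein[prot] = group_serial
            g2 = by_protein[prot]
            if cds not in by_cds:
                counters[("cds", g2)] = counters.get(("cds", g2), 0) + 1
                by_cds[cds] = (g2, counters[("cds", g2)])
            g2, s3 = by_cds[cds]
            counters[("n", g2, s3)] = counters.get(("n", g2, s3), 0) + 1
            name = f"{gene}*{g2:02d}:01:{s3:02d}:{counters[('n', g2, s3)]:02d}"
            alleles[name] = seq
            gene_of[name] = gene
            annotations[name] = ann
            mut_truth[name] = muts

        f = rng.dirichlet(np.ones(size))
        names = [n for n, g in gene_of.items() if g == gene]
        f = f / f.sum()
        f[-1] = 1.0 - f[:-1].sum()  # exact unit sum
        for n2, fi in zip(names, f):
            freqs[n2] = float(fi)

    pool = AllelePool(alleles, gene_of, annotations, freqs)
    return pool, PoolTruth(mut_truth)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def draw_genotypes(
    pool: AllelePool,
    n_samples: int,
    deletion_freq_H: float,
    seed: int | np.random.Generator,
    deletable_gene: str = "H",
) -> TruthGenotypes:
    """Diploid sampling from pool frequencies; each haplotype of the
    deletable locus is independently absent with ``deletion_freq_H``."""
    if not 0.0 <= deletion_freq_H <= 1.0:
        raise SimulationError("deletion_freq_H must be in [0,1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genotypes: dict[str, dict[str, list[str]]] = {}
    for i in range(n_samples):
        sid = f"S{i + 1:03d}"
        per_gene: dict[str, list[str]] = {}
        for gene in pool.genes:
            names = pool.alleles_of_gene(gene)
            p = np.array([pool.frequencies[n] for n in names])
            picks = [str(a) for a in rng.choice(names, size=2, p=p / p.sum())]
            if gene == deletable_gene:
                picks = [a for a in picks if rng.random() >= deletion_freq_H]
            per_gene[gene] = sorted(picks)
        genotypes[sid] = per_gene
    return TruthGenotypes(genotypes, deletable_gene=deletable_gene)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _apply_long_errors(
    seq: str, rng: np.random.Generator, mismatch: float, insertion: float, deletion: float
) -> str:
    """Per-base independent mismatch / single-base insertion / deletion."""
    if mismatch == insertion == deletion == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    keep = rng.random(n) >= deletion
    sub = (rng.random(n) < mismatch) & keep
    if sub.any():
        idx = _BASE_INDEX[arr[sub]]
        arr[sub] = _BASES[(idx + rng.integers(1, 4, size=sub.sum())) % 4]
    ins = rng.random(n) < insertion
    reps = keep.astype(np.int64) + ins
    out = np.repeat(arr, reps)
    if ins.any():
        cs = np.cumsum(reps)
        ins_pos = cs[ins] - 1  # last emitted element per inserting position
        out[ins_pos] = _BASES[rng.integers(0, 4, size=ins_pos.size)]
    return out.tobytes().decode()


def _find_amplicon(allele_seq: str, primer_set: PrimerSet, anywhere: bool, k: int = 3):
    """Locate the annealing sites of a primer pair on an allele; returns the
    half-open insert interval between them (primers excluded)."""
    window = 4 * PRIMER_LEN
    fwd_region = allele_seq if anywhere else allele_seq[: window]
    hit_f = infix_align(primer_set.forward, fwd_region, k=k)
    rev_site = revcomp(primer_set.reverse)
    rev_region = allele_seq if anywhere else allele_seq[-window:]
    hit_r = infix_align(rev_site, rev_region, k=k)
    if hit_f is None or hit_r is None:
        return None
    r_off = 0 if anywhere else len(allele_seq) - len(rev_region)
    return hit_f.end, r_off + hit_r.start


@dataclass
class LongRead:
    read_id: str
    sequence: str
    sample_id: str


@dataclass
class LongReadTruth:
    """read_id -> (sample, allele name, primer set, source gene)."""

    records: dict[str, tuple[str, str, str, str]]


def amplification_plan(primer_sets: dict[str, PrimerSet]) -> dict[str, list[str]]:
    """Which genes each primer set captures full length.  The A pair also
    captures the H locus; B and C capture only their own gene."""
    plan = {name: [name] for name in primer_sets}
    if "A" in plan:
        plan["A"] = ["A", "H"]
    return plan


def simulate_long_reads(
    pool: AllelePool,
    truth: TruthGenotypes,
    primer_sets: dict[str, PrimerSet],
    config: SimConfig,
    barcodes: dict[str, Barcode],
    rng: np.random.Generator | None = None,
    full_length_plan: dict[str, list[str]] | None = None,
) -> tuple[dict[str, list[LongRead]], LongReadTruth]:
    """Emit full-amplicon long reads per sample.

    Each read is ``barcode+linker+forward_primer + insert + rc(reverse
    primer)+rc(linker)+rc(barcode)`` on a random strand, with
    indel-dominated per-base errors.  Nested targets add reads covering
    only the configured inner interval at ``multiplier`` times the depth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    plan = full_length_plan or amplification_plan(primer_sets)
    reads: dict[str, list[LongRead]] = {}
    truth_map: dict[str, tuple[str, str, str, str]] = {}
    serial = 0

    def emit(sample, pset, allele_name, gene, insert, n_reads):
        nonlocal serial
        bc = barcodes[sample].sequence
        amplicon = (
            bc
            + LINKER
            + primer_sets[pset].forward
            + insert
            + revcomp(primer_sets[pset].reverse)
            + revcomp(LINKER)
            + revcomp(bc)
        )
        for _ in range(n_reads):
            serial += 1
            seq = _apply_long_errors(
                amplicon, rng, config.long_mismatch, config.long_insertion, config.long_deletion
            )
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"lr{serial:07d}"
            reads.setdefault(sample, []).append(LongRead(rid, seq, sample))
            truth_map[rid] = (sample, allele_name, pset, gene)

    for sample in truth.samples:
        reads.setdefault(sample, [])
        for pset_name in sorted(primer_sets):
            pset = primer_sets[pset_name]
            for gene in plan.get(pset_name, []):
                for allele_name in truth.genotypes[sample].get(gene, []):
                    seq = pool.alleles[allele_name]
                    span = _find_amplicon(seq, pset, anywhere=False)
                    if span is None:
                        raise SimulationError(
                            f"primer set {pset_name} not found in flanks of {allele_name}"
                        )
                    emit(sample, pset_name, allele_name, gene, seq[span[0] : span[1]], config.long_read_depth)
            for target in config.nested_amplification.get(pset_name, []):
                for allele_name in truth.genotypes[sample].get(target.gene, []):
                    seq = pool.alleles[allele_name]
                    span = _find_amplicon(seq, pset, anywhere=True)
                    if span is None:
                        raise SimulationError(
                            f"nested primer set {pset_name} not found in {allele_name}"
                        )
                    n = int(round(config.long_read_depth * target.multiplier))
                    emit(sample, pset_name, allele_name, target.gene, seq[span[0] : span[1]], n)
    return reads, LongReadTruth(truth_map)


@dataclass
class ShortReadPair:
    read_id: str
    r1: str
    r2: str
    sample_id: str


@dataclass
class ShortReadTruth:
    """read_id -> (sample, haplotype allele name, fragment start)."""

    records: dict[str, tuple[str, str, int]]


def simulate_short_reads(
    pool: AllelePool,
    truth: TruthGenotypes,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[ShortReadPair]], ShortReadTruth]:
    """Paired short reads with substitution-only errors, uniform fragment
    starts over every true haplotype (flanks included).  A locus with copy
    number 0 yields no reads."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rl = config.short_read_len
    out: dict[str, list[ShortReadPair]] = {}
    truth_map: dict[str, tuple[str, str, int]] = {}
    serial = 0
    for sample in truth.samples:
        out.setdefault(sample, [])
        for gene in sorted(truth.genotypes[sample]):
            for allele_name in truth.genotypes[sample][gene]:
                hap = pool.alleles[allele_name]
                n_pairs = int(math.ceil(config.short_coverage * len(hap) / (2 * rl)))
                inserts = np.clip(
                    rng.normal(config.insert_mean, config.insert_sd, size=n_pairs),
                    rl,
                    len(hap),
                ).astype(np.int64)
                starts = (rng.random(n_pairs) * (len(hap) - inserts + 1)).astype(np.int64)
                for st, ins in zip(starts, inserts):
                    serial += 1
                    frag = hap[st : st + ins]
                    r1 = frag[:rl]
                    r2 = revcomp(frag[-rl:])
                    if config.short_error > 0:
                        r1 = _apply_long_errors(r1, rng, config.short_error, 0.0, 0.0)
                        r2 = _apply_long_errors(r2, rng, config.short_error, 0.0, 0.0)
                    if rng.random() < 0.5:
                        r1, r2 = r2, r1
                    rid = f"sr{serial:08d}"
                    out[sample].append(ShortReadPair(rid, r1, r2, sample))
                    truth_map[rid] = (sample, allele_name, int(st))
    return out, ShortReadTruth(truth_map)


# ---------------------------------------------------------------------------
# database views and the bundled scenario
# ---------------------------------------------------------------------------


def database_view(
    pool: AllelePool,
    keep_upstream: int = 280,
    keep_downstream: int = 260,
    cdna_only: tuple[str, ...] = (),
    drop: tuple[str, ...] = (),
) -> AllelePool:
    """Derive a known-allele database from a full-length pool: flanks are
    trimmed to what a sequence archive typically holds, selected entries are
    reduced to exon-only (cDNA) records, and ``drop`` entries are removed so
    the panel can contain database-novel alleles."""
    alleles, gene_of, annotations, freqs = {}, {}, {}, {}
    for name, seq in pool.alleles.items():
        if name in drop:
            continue
        ann = pool.annotations[name]
        up_end = next(e for s, e, lab in ann if lab == "upstream")
        down_start = next(s for s, e, lab in ann if lab == "downstream")
        if name in cdna_only:
            exons = [(s, e) for s, e, lab in ann if lab.startswith("exon")]
            new_seq = "".join(seq[s:e] for s, e in exons)
            new_ann = []
            acc = 0
            for k, (s, e) in enumerate(exons, start=1):
                new_ann.append((acc, acc + (e - s), f"exon{k}"))
                acc += e - s
        else:
            cut = max(0, up_end - keep_upstream)
            end = min(len(seq), down_start + keep_downstream)
            new_seq = seq[cut:end]
            new_ann = [
                (max(0, s - cut), min(len(new_seq), e - cut), lab)
                for s, e, lab in ann
                if e > cut and s < end
            ]
        alleles[name] = new_seq
        gene_of[name] = pool.gene_of[name]
        annotations[name] = new_ann
        freqs[name] = pool.frequencies[name]
    for gene in set(gene_of.values()):
        names = [n for n, g in gene_of.items() if g == gene]
        tot = sum(freqs[n] for n in names)
        for n in names:
            freqs[n] /= tot
        freqs[names[-1]] = 1.0 - sum(freqs[n] for n in names[:-1])
    return AllelePool(alleles, gene_of, annotations, freqs)


@dataclass
class SimulatedDataset:
    config: SimConfig
    gene_models: dict[str, GeneModel]
    ancestors: dict[str, str]
    pool: AllelePool
    pool_truth: PoolTruth
    primer_sets: dict[str, PrimerSet]
    barcodes: dict[str, Barcode]
    truth: TruthGenotypes
    long_reads: dict[str, list[LongRead]]
    long_truth: LongReadTruth
    short_reads: dict[str, list[ShortReadPair]]
    short_truth: ShortReadTruth


def default_nested() -> dict[str, list[NestedTarget]]:
    return {"B": [NestedTarget(gene="C", interval=C_INNER_INTERVAL, multiplier=3.0)]}


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete study: pool, genotypes, long and short reads.

    All child generators are spawned from ``config.seed`` so the whole
    dataset is reproducible from that single integer.
    """
    ss = np.random.SeedSequence(config.seed)
    r_anc, r_pool, r_geno, r_long, r_short, r_bc = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    models = default_gene_models()
    ancestors, primer_sets, protected = build_ancestors(models, r_anc)
    pool, pool_truth = generate_allele_pool(
        models,
        config.pool_sizes,
        config.divergence_rate,
        r_pool,
        ancestors=ancestors,
        protected=protected,
    )
    truth = draw_genotypes(pool, config.n_samples, config.deletion_freq_H, r_geno)
    barcodes = make_barcodes(config.n_samples, r_bc)
    long_reads, long_truth = simulate_long_reads(
        pool, truth, primer_sets, config, barcodes, rng=r_long
    )
    short_reads, short_truth = simulate_short_reads(pool, truth, config, rng=r_short)
    return SimulatedDataset(
        config=config,
        gene_models=models,
        ancestors=ancestors,
        pool=pool,
        pool_truth=pool_truth,
        primer_sets=primer_sets,
        barcodes=barcodes,
        truth=truth,
        long_reads=long_reads,
        long_truth=long_truth,
        short_reads=short_reads,
        short_truth=short_truth,
    )
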