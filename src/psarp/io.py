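"""File-format plumbing: FASTA/FASTQ via Biopython, BED annotations,
primer sheets and simulation configs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demux import Barcode, PrimerSet
from .simdata import AllelePool, NestedTarget, SimConfig


def write_fasta(path, seqs: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: list[tuple[str, str]], quality: int = 30) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [
        (r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")
    ]


def write_bed(path, annotations: dict[str, list[tuple[int, int, str]]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(annotations):
            for s, e, label in annotations[name]:
                fh.write(f"{name}\t{s}\t{e}\t{label}\n")


def read_bed(path) -> dict[str, list[tuple[int, int, str]]]:
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, label = line.rstrip("\n").split("\t")[:4]
            out.setdefault(chrom, []).append((int(s), int(e), label))
    return out


def write_primer_sheet(path, primer_sets: dict[str, PrimerSet]) -> None:
    rows = []
    for name in sorted(primer_sets):
        p = primer_sets[name]
        rows.append({"set": name, "role": "F", "sequence": p.forward})
        rows.append({"set": name, "role": "R", "sequence": p.reverse})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_primer_sheet(path) -> dict[str, PrimerSet]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for name, grp in df.groupby("set"):
        fwd = grp.loc[grp["role"] == "F", "sequence"].iloc[0]
        rev = grp.loc[grp["role"] == "R", "sequence"].iloc[0]
        out[str(name)] = PrimerSet(name=str(name), forward=fwd, reverse=rev)
    return out


def write_barcodes(path, barcodes: dict[str, Barcode]) -> None:
    rows = [
        {"sample": sid, "barcode": bc.sequence}
        for sid, bc in sorted(barcodes.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pool_from_files(fasta_path, bed_path) -> AllelePool:
    """Assemble an :class:`AllelePool` from a FASTA plus BED annotations;
    frequencies default to uniform per gene."""
    from .simdata import parse_allele_name

    alleles = read_fasta(fasta_path)
    annotations = read_bed(bed_path)
    gene_of = {n: parse_allele_name(n)[0] for n in alleles}
    freqs: dict[str, float] = {}
    for gene in set(gene_of.values()):
        names = sorted(n for n, g in gene_of.items() if g == gene)
        for n in names:
            freqs[n] = 1.0 / len(names)
        freqs[names[-1]] = 1.0 - sum(freqs[n] for n in names[:-1])
    return AllelePool(alleles, gene_of, {n: annotations.get(n, []) for n in alleles}, freqs)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    nested = {}
    for pset, targets in (raw.pop("nested_amplification", None) or {}).items():
        nested[pset] = [
            NestedTarget(t["gene"], tuple(t["interval"]), t.get("multiplier", 3.0))
            for t in targets
        ]
    cfg = SimConfig(**raw)
    if nested:
        cfg.nested_amplification = nested
    return cfg


def dump_sim_config(path, config: SimConfig) -> None:
    raw = asdict(config)
    raw["nested_amplification"] = {
        pset: [
            {"gene": t.gene, "interval": list(t.interval), "multiplier": t.multiplier}
            for t in targets
        ]
        for pset, targets in config.nested_amplification.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_dataset(dataset, out_dir) -> None:
    """Materialize a simulated dataset as plain-text files (FASTA/FASTQ/
    BED/TSV) under ``out_dir``."""
    out = Path(out_dir)
    (out / "short_reads").mkdir(parents=True, exist_ok=True)
    (out / "long_reads").mkdir(exist_ok=True)
    write_fasta(out / "pool.fa", dataset.pool.alleles)
    write_bed(out / "pool_annotations.bed", dataset.pool.annotations)
    write_primer_sheet(out / "primers.tsv", dataset.primer_sets)
    write_barcodes(out / "barcodes.tsv", dataset.barcodes)
    rows = []
    for sample in dataset.truth.samples:
        for gene, names in sorted(dataset.truth.genotypes[sample].items()):
            for n in names:
                rows.append({"sample": sample, "gene": gene, "allele": n})
    pd.DataFrame(rows).to_csv(out / "truth_genotypes.tsv", sep="\t", index=False)
    for sample, reads in dataset.long_reads.items():
        write_fastq(
            out / "long_reads" / f"{sample}.fastq",
            [(r.read_id, r.sequence) for r in reads],
            quality=20,
        )
    for sample, pairs in dataset.short_reads.items():
        write_fastq(
            out / "short_reads" / f"{sample}_R1.fastq",
            [(p.read_id, p.r1) for p in pairs],
        )
        write_fastq(
            out / "short_reads" / f"{sample}_R2.fastq",
            [(p.read_id, p.r2) for p in pairs],
        )
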