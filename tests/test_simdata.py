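import edlib
import numpy as np
import pytest

from psarp.align import revcomp
from psarp.simdata import (
    SimConfig,
    SimulationError,
    default_gene_models,
    draw_genotypes,
    generate_allele_pool,
    parse_allele_name,
    simulate_dataset,
    simulate_short_reads,
    truncate_name,
    database_view,
)


def small_models():
    return default_gene_models()


class TestAllelePool:
    def test_zero_divergence_rejected(self):
        with pytest.raises(SimulationError):
            generate_allele_pool(small_models(), {g: 3 for g in "ABCH"}, 0.0, seed=1)

    def test_determinism(self):
        kw = dict(pool_sizes={g: 5 for g in "ABCH"}, divergence_rate=0.005)
        p1, _ = generate_allele_pool(small_models(), seed=1, **kw)
        p2, _ = generate_allele_pool(small_models(), seed=1, **kw)
        assert p1.alleles == p2.alleles
        assert p1.frequencies == p2.frequencies

    def test_pairwise_divergence_matches_rate(self):
        """Mean pairwise aligned distance of a 20-allele pool should be
        close to 2 * rate * length (each allele mutated independently from
        one ancestor); checked with pairwise alignment over all pairs."""
        rate = 0.01
        models = {"A": small_models()["A"]}
        pool, _ = generate_allele_pool(models, {"A": 20}, rate, seed=3)
        seqs = [pool.alleles[n] for n in pool.alleles_of_gene("A")]
        L = np.mean([len(s) for s in seqs])
        dists = [
            edlib.align(a, b, mode="NW")["editDistance"]
            for i, a in enumerate(seqs)
            for b in seqs[i + 1 :]
        ]
        expected = 2 * rate * L
        assert expected * 0.7 <= np.mean(dists) <= expected * 1.3

    def test_names_and_frequencies(self):
        pool, _ = generate_allele_pool(
            small_models(), {g: 6 for g in "ABCH"}, 0.005, seed=2
        )
        for name in pool.alleles:
            gene, fields = parse_allele_name(name)
            assert gene in "ABCH" and len(fields) == 4
        for gene in pool.genes:
            total = sum(pool.frequencies[n] for n in pool.alleles_of_gene(gene))
            assert abs(total - 1.0) < 1e-9

    def test_exon_frames_translate(self):
        pool, _ = generate_allele_pool(
            small_models(), {g: 4 for g in "ABCH"}, 0.005, seed=4
        )
        for name in pool.alleles:
            assert len(pool.cds(name)) % 3 == 0


@pytest.fixture(scope="module")
def pool():
    return generate_allele_pool(
        small_models(), {g: 5 for g in "ABCH"}, 0.005, seed=5
    )[0]


class TestGenotypes:
    def test_full_deletion(self, pool):
        truth = draw_genotypes(pool, 10, 1.0, seed=1)
        assert all(truth.copy_number(s, "H") == 0 for s in truth.samples)

    def test_no_deletion(self, pool):
        truth = draw_genotypes(pool, 10, 0.0, seed=1)
        assert all(truth.copy_number(s, "H") == 2 for s in truth.samples)

    def test_homozygous_deletion_rate(self, pool):
        """With per-haplotype deletion frequency f, homozygous deletions
        occur at f^2; the observed fraction must sit within 3 SE."""
        f = 0.3
        n = 1000
        truth = draw_genotypes(pool, n, f, seed=2)
        frac = np.mean([truth.copy_number(s, "H") == 0 for s in truth.samples])
        p = f * f
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se

    def test_non_deletable_always_diploid(self, pool):
        truth = draw_genotypes(pool, 50, 0.5, seed=3)
        for s in truth.samples:
            for gene in "ABC":
                assert len(truth.genotypes[s][gene]) == 2


class TestLongReads:
    def test_error_free_reads_equal_amplicons(self, clean_dataset):
        ds = clean_dataset
        for sample, reads in ds.long_reads.items():
            for r in reads[:20]:
                _, allele, pset, gene = ds.long_truth.records[r.read_id]
                seq = r.sequence
                if gene == pset:  # own-gene amplicon spans the whole allele
                    target = ds.pool.alleles[allele]
                    assert target in seq or target in revcomp(seq)

    def test_truth_map_complete(self, clean_dataset):
        ds = clean_dataset
        ids = [r.read_id for reads in ds.long_reads.values() for r in reads]
        assert len(ids) == len(set(ids))
        assert set(ids) == set(ds.long_truth.records)

    def test_nested_depth_enrichment(self, clean_dataset):
        """With a nesting multiplier m, base coverage of the inner interval
        is (1+m) times the outer coverage (count-based, from the truth
        map): every C haplotype gets depth d full amplicons plus m*d inner
        ones."""
        ds = clean_dataset
        m = ds.config.nested_amplification["B"][0].multiplier
        by_src = {}
        for rid, (sample, allele, pset, gene) in ds.long_truth.records.items():
            if gene == "C":
                by_src[(sample, allele, pset)] = by_src.get((sample, allele, pset), 0) + 1
        inner = sum(v for (s, a, p), v in by_src.items() if p == "B")
        outer = sum(v for (s, a, p), v in by_src.items() if p == "C")
        ratio = (inner + outer) / outer
        assert abs(ratio - (1 + m)) / (1 + m) <= 0.25

    def test_error_rate_matches_expectation(self):
        """Mean read-to-amplicon edit distance under the error model,
        measured by alignment on a 100-read sample."""
        cfg = SimConfig(
            n_samples=1,
            pool_sizes={g: 2 for g in "ABCH"},
            long_mismatch=0.05,
            long_insertion=0.05,
            long_deletion=0.05,
            seed=9,
            long_read_depth=30,
        )
        ds = simulate_dataset(cfg)
        sample = ds.truth.samples[0]
        dists, lens = [], []
        for r in ds.long_reads[sample][:100]:
            _, allele, pset, gene = ds.long_truth.records[r.read_id]
            if gene != pset:
                continue
            bc = ds.barcodes[sample].sequence
            from psarp.simdata import LINKER

            amplicon = bc + LINKER + ds.pool.alleles[allele] + revcomp(LINKER) + revcomp(bc)
            d = min(
                edlib.align(r.sequence, amplicon, mode="NW")["editDistance"],
                edlib.align(revcomp(r.sequence), amplicon, mode="NW")["editDistance"],
            )
            dists.append(d)
            lens.append(len(amplicon))
        expected = np.mean(lens) * (0.05 + 0.05 + 0.05 * 0.95)
        assert expected * 0.85 <= np.mean(dists) <= expected * 1.15


class TestShortReads:
    def test_pair_count_matches_coverage(self, clean_dataset):
        ds = clean_dataset
        for sample in ds.truth.samples:
            n_hap = sum(len(v) for v in ds.truth.genotypes[sample].values())
            total_len = sum(
                len(ds.pool.alleles[a])
                for v in ds.truth.genotypes[sample].values()
                for a in v
            )
            expect = ds.config.short_coverage * total_len / (2 * ds.config.short_read_len)
            n = len(ds.short_reads[sample])
            assert abs(n - expect) / expect <= 0.2

    def test_error_free_reads_are_substrings(self, clean_dataset):
        ds = clean_dataset
        sample = ds.truth.samples[0]
        haps = [
            ds.pool.alleles[a]
            for v in ds.truth.genotypes[sample].values()
            for a in v
        ]
        for p in ds.short_reads[sample][:50]:
            for r in (p.r1, p.r2):
                assert any(r in h or revcomp(r) in h for h in haps)

    def test_deleted_locus_yields_no_reads(self):
        pool, _ = generate_allele_pool(
            small_models(), {g: 3 for g in "ABCH"}, 0.005, seed=6
        )
        truth = draw_genotypes(pool, 5, 1.0, seed=1)
        cfg = SimConfig(n_samples=5, seed=6, short_error=0.0)
        reads, truth_map = simulate_short_reads(pool, truth, cfg)
        h_alleles = set(pool.alleles_of_gene("H"))
        for rid, (sample, allele, start) in truth_map.records.items():
            assert allele not in h_alleles


class TestDatasetPlumbing:
    def test_seed_reproducibility(self):
        cfg = SimConfig(n_samples=2, pool_sizes={g: 3 for g in "ABCH"}, seed=21)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert d1.pool.alleles == d2.pool.alleles
        for s in d1.truth.samples:
            assert [r.sequence for r in d1.long_reads[s]] == [
                r.sequence for r in d2.long_reads[s]
            ]
            assert [(p.r1, p.r2) for p in d1.short_reads[s]] == [
                (p.r1, p.r2) for p in d2.short_reads[s]
            ]

    def test_truncate_name_resolutions(self):
        assert truncate_name("A*01:02:03:04", 4) == "A*01:02"
        assert truncate_name("A*01:02:03:04", 6) == "A*01:02:03"
        assert truncate_name("A*01:02:03:04", 8) == "A*01:02:03:04"

    def test_database_view_trims_flanks(self, clean_dataset):
        pool = clean_dataset.pool
        db = database_view(pool, keep_upstream=100, keep_downstream=100)
        for name in db.alleles:
            assert len(db.alleles[name]) < len(pool.alleles[name])
            assert db.alleles[name] in pool.alleles[name]

    def test_database_view_cdna_only(self, clean_dataset):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("A")[0]
        db = database_view(pool, cdna_only=(name,))
        assert db.is_cdna_only(name)
        assert db.alleles[name] == pool.cds(name)
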