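import numpy as np
import pytest

from psarp.report import (
    allele_distribution,
    characterize_panel,
    classify_novelty,
    closest_db_allele,
    extension_and_variant_stats,
    novel_frequency_totals,
    population_coverage,
)
from psarp.genotype import GenotypeCall
from psarp.simdata import database_view


@pytest.fixture(scope="module")
def db(clean_dataset):
    return database_view(clean_dataset.pool, keep_upstream=280, keep_downstream=260)


def mutate_exon(pool, name, offset=10, synonymous=False):
    """Return the allele sequence with one substitution inside exon 3; the
    codon position controls synonymy (third position chosen to be
    synonymous only when the substitution keeps the amino acid)."""
    seq = pool.alleles[name]
    exons = pool.exon_intervals(name)
    s, e = exons[2]
    from Bio.Seq import Seq

    # find a position whose substitution is (non)synonymous as requested
    cds_before = pool.cds(name)
    acc = sum(b - a for a, b in exons[:2])
    for pos in range(s, e):
        cpos = acc + (pos - s)
        old = seq[pos]
        for new in "ACGT".replace(old, ""):
            cds_after = cds_before[:cpos] + new + cds_before[cpos + 1 :]
            syn = str(Seq(cds_before).translate()) == str(Seq(cds_after).translate())
            if syn == synonymous:
                return seq[:pos] + new + seq[pos + 1 :], pos
    raise AssertionError("no suitable site found")


class TestClosest:
    def test_extended_allele_matches_its_subtype_at_distance_zero(
        self, clean_dataset, db
    ):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("B")[1]
        match = closest_db_allele(pool.alleles[name], "B", db)
        assert match.name == name
        assert match.distance == 0
        assert match.exonic_edits == 0

    def test_exonic_substitution_counted_in_exon_distance(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("C")[0]
        seq, _ = mutate_exon(pool, name, synonymous=False)
        match = closest_db_allele(seq, "C", db)
        assert match.name == name
        assert match.distance == 1
        assert match.exonic_edits == 1
        assert match.noncoding_edits == 0

    def test_deterministic_output(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("A")[0]
        m1 = closest_db_allele(pool.alleles[name], "A", db)
        m2 = closest_db_allele(pool.alleles[name], "A", db)
        assert (m1.name, m1.distance, m1.panel_span) == (
            m2.name,
            m2.distance,
            m2.panel_span,
        )

    def test_empty_gene_rejected(self, clean_dataset, db):
        with pytest.raises(ValueError):
            closest_db_allele("ACGT" * 100, "Z", db)


class TestNovelty:
    def test_extension_only_not_novel(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("A")[0]
        match = closest_db_allele(pool.alleles[name], "A", db)
        nov = classify_novelty(match, db, pool.alleles[name])
        assert not nov.novel_8digit and not nov.novel_6digit and not nov.novel_4digit

    def test_synonymous_exon_change_is_6_but_not_4_digit(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("B")[0]
        seq, _ = mutate_exon(pool, name, synonymous=True)
        match = closest_db_allele(seq, "B", db)
        nov = classify_novelty(match, db, seq)
        assert nov.novel_8digit and nov.novel_6digit and not nov.novel_4digit

    def test_nonsynonymous_exon_change_is_4_digit(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("B")[0]
        seq, _ = mutate_exon(pool, name, synonymous=False)
        match = closest_db_allele(seq, "B", db)
        nov = classify_novelty(match, db, seq)
        assert nov.novel_4digit and nov.novel_6digit and nov.novel_8digit

    def test_intronic_change_only_8_digit(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("C")[1]
        seq = pool.alleles[name]
        exons = pool.exon_intervals(name)
        p = (exons[0][1] + exons[1][0]) // 2  # mid intron 1
        seq = seq[:p] + ("A" if seq[p] != "A" else "G") + seq[p + 1 :]
        match = closest_db_allele(seq, "C", db)
        nov = classify_novelty(match, db, seq)
        assert nov.novel_8digit and not nov.novel_6digit

    def test_cdna_only_closest_flags_added_introns(self, clean_dataset):
        pool = clean_dataset.pool
        names = pool.alleles_of_gene("A")
        db2 = database_view(pool, cdna_only=(names[0],), drop=tuple(names[1:2]))
        match = closest_db_allele(pool.alleles[names[0]], "A", db2)
        if match.name == names[0]:
            nov = classify_novelty(match, db2, pool.alleles[names[0]])
            assert nov.adds_introns and nov.novel_8digit and not nov.novel_6digit

    def test_exon_variant_record_fields(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("B")[0]
        seq, pos = mutate_exon(pool, name, synonymous=False)
        entries = characterize_panel({"B_00001": seq}, {"B_00001": "B"}, db)
        (entry,) = entries
        assert len(entry.exon_variants) == 1
        v = entry.exon_variants[0]
        assert v.exon == 3
        assert len(v.ref) == 1 and len(v.alt) == 1 and v.ref != v.alt
        assert v.aa_change is not None and v.aa_change != "Synonymous"

    def test_implication_chain_on_simulated_panel(self, clean_dataset, db):
        pool = clean_dataset.pool
        carried = sorted(clean_dataset.truth.carried_alleles())
        panel = {n: pool.alleles[n] for n in carried}
        gene_of = {n: pool.gene_of[n] for n in carried}
        for e in characterize_panel(panel, gene_of, db):
            if e.novelty.novel_4digit:
                assert e.novelty.novel_6digit
            if e.novelty.novel_6digit:
                assert e.novelty.novel_8digit


class TestExtensionStats:
    def test_single_allele_gene_means(self, clean_dataset, db):
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("A")[0]
        entries = characterize_panel({name: pool.alleles[name]}, {name: "A"}, db)
        stats = extension_and_variant_stats(entries, {name: pool.alleles[name]})
        row = stats.loc["A"]
        assert row["n_alleles"] == 1
        assert row["mean_length"] == len(pool.alleles[name])
        assert row["novel_upstream_variants"] == 0

    def test_injected_flank_variants_counted(self, clean_dataset, db):
        """Two panel alleles identical except for substitutions placed in
        the upstream extension (outside the database span): each such site
        is one novel upstream variant position."""
        pool = clean_dataset.pool
        name = pool.alleles_of_gene("A")[0]
        seq = pool.alleles[name]
        v1 = seq
        arr = list(seq)
        for p in (40, 80, 120):  # well inside the trimmed-away upstream flank
            arr[p] = "A" if arr[p] != "A" else "C"
        v2 = "".join(arr)
        panel = {"A_00001": v1, "A_00002": v2}
        entries = characterize_panel(panel, {k: "A" for k in panel}, db)
        stats = extension_and_variant_stats(entries, panel)
        assert stats.loc["A", "novel_upstream_variants"] == 3
        assert stats.loc["A", "novel_downstream_variants"] == 0


class TestDistributionAndCoverage:
    def test_toy_counting(self):
        calls = [
            GenotypeCall("S001", "A", ("a", "a"), 0.0, 1.0),
            GenotypeCall("S002", "A", ("a", "b"), 0.0, 1.0),
            GenotypeCall("S003", "A", ("b", "b"), 0.0, 1.0),
            GenotypeCall("S004", "A", ("a", "b"), 0.0, 1.0),
        ]
        dist = allele_distribution(calls)
        freq = dict(zip(dist["allele"], dist["frequency"]))
        assert freq == {"a": 0.5, "b": 0.5}

    def test_all_homozygous_frequency_one(self):
        calls = [GenotypeCall(f"S{i}", "A", ("a", "a"), 0.0, 1.0) for i in range(5)]
        dist = allele_distribution(calls)
        assert dist["frequency"].tolist() == [1.0]

    def test_sampled_frequencies_match_pool(self, clean_dataset):
        """Observed truth-genotype frequencies stay within 3 SE of the pool
        frequencies they were drawn from (multinomial bound)."""
        from psarp.simdata import draw_genotypes

        pool = clean_dataset.pool
        truth = draw_genotypes(pool, 500, 0.0, seed=33)
        n = 2 * 500
        for gene in ["A"]:
            counts = {}
            for s in truth.samples:
                for a in truth.genotypes[s][gene]:
                    counts[a] = counts.get(a, 0) + 1
            for name in pool.alleles_of_gene(gene):
                p = pool.frequencies[name]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(counts.get(name, 0) / n - p) <= 3 * se + 1e-12

    def test_full_panel_covers_everything(self):
        pop = ["A*01:01:01:01", "A*02:01:01:02"]
        panel = {"A*01:01:01:01", "A*02:01:01:02"}
        for res in (4, 6, 8):
            assert population_coverage(pop, panel, res).covered_fraction == 1.0

    def test_three_of_four_covered(self):
        pop = [f"A*{i:02d}:01:01:01" for i in (1, 2, 3, 4)]
        panel = {f"A*{i:02d}:01:01:01" for i in (1, 2, 3)}
        assert population_coverage(pop, panel, 4).covered_fraction == 0.75

    def test_monotone_in_resolution(self, rng):
        for _ in range(30):
            pop = [
                f"A*{rng.integers(1, 4):02d}:{rng.integers(1, 3):02d}:"
                f"{rng.integers(1, 3):02d}:{rng.integers(1, 3):02d}"
                for _ in range(20)
            ]
            panel = set(
                f"A*{rng.integers(1, 4):02d}:{rng.integers(1, 3):02d}:"
                f"{rng.integers(1, 3):02d}:{rng.integers(1, 3):02d}"
                for _ in range(4)
            )
            c4 = population_coverage(pop, panel, 4).covered_fraction
            c6 = population_coverage(pop, panel, 6).covered_fraction
            c8 = population_coverage(pop, panel, 8).covered_fraction
            assert c8 <= c6 <= c4

    def test_novel_frequency_totals(self):
        from psarp.report import NoveltyClass

        calls = [
            GenotypeCall("S001", "A", ("a", "b"), 0.0, 1.0),
            GenotypeCall("S002", "A", ("a", "a"), 0.0, 1.0),
        ]
        dist = allele_distribution(calls)
        nov = {
            "a": NoveltyClass(True, False, False, False),
            "b": NoveltyClass(False, False, False, False),
        }
        totals = novel_frequency_totals(dist, nov)
        assert totals.loc["A", "novel_freq_8digit"] == 0.75
        assert totals.loc["A", "novel_freq_6digit"] == 0.0
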