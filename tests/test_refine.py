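import edlib
import numpy as np
import pytest

from psarp.refine import (
    GeneMSA,
    ReadPlacement,
    assess_position,
    build_gene_msa,
    correct_allele,
    identify_variants,
    refine_draft_set,
    subset_msa,
)
from psarp.assembly import DraftAlleleSet
from psarp.genotype import GeneKmerClassifier

from conftest import random_seq


def brute_force_variant_columns(rows):
    """Independent oracle: per-column set comparison."""
    ids = sorted(rows)
    n = len(rows[ids[0]])
    marked = [len({rows[i][c] for i in ids}) > 1 for c in range(n)]
    runs = []
    c = 0
    while c < n:
        if marked[c]:
            start = c
            while c < n and marked[c]:
                c += 1
            runs.append((start, c))
        else:
            c += 1
    return runs


class TestMSA:
    @pytest.mark.parametrize("engine", ["auto", "builtin"])
    def test_identical_alleles_no_gaps(self, rng, engine):
        s = random_seq(rng, 800)
        msa = build_gene_msa({"x": s, "y": s}, engine=engine)
        assert msa.rows["x"] == s and msa.rows["y"] == s

    @pytest.mark.parametrize("engine", ["auto", "builtin"])
    def test_two_bp_deletion_single_gap_run(self, rng, engine):
        s = random_seq(rng, 600)
        t = s[:300] + s[302:]
        msa = build_gene_msa({"x": s, "y": t}, engine=engine)
        gaps = msa.rows["y"].count("-")
        # pairwise alignment oracle: the pair differs by one 2 bp indel
        assert edlib.align(s, t, mode="NW")["editDistance"] == 2
        assert gaps == 2 and "-" not in msa.rows["x"]
        # the two gap columns are adjacent
        i = msa.rows["y"].index("-")
        assert msa.rows["y"][i : i + 2] == "--"

    def test_ungap_invariant(self, rng):
        seqs = {}
        base = random_seq(rng, 700)
        for i in range(6):
            arr = list(base)
            for _ in range(8):
                p = int(rng.integers(0, len(arr)))
                arr[p] = "ACGT"[rng.integers(0, 4)]
            if i % 2:
                del arr[100 : 100 + int(rng.integers(1, 4))]
            seqs[f"a{i}"] = "".join(arr)
        for engine in ("auto", "builtin"):
            msa = build_gene_msa(seqs, engine=engine)
            for aid, s in seqs.items():
                assert msa.ungapped(aid) == s

    def test_sum_of_pairs_not_worse_than_star(self, rng):
        """The default engine never scores worse (sum-of-pairs cost) than
        the center-star baseline alignment to the longest allele."""
        from psarp.refine import sum_of_pairs_cost

        base = random_seq(rng, 500)
        seqs = {}
        for i in range(10):
            arr = list(base)
            for _ in range(10):
                p = int(rng.integers(0, len(arr)))
                if rng.random() < 0.2 and len(arr) > 10:
                    arr.pop(p)
                else:
                    arr[p] = "ACGT"[rng.integers(0, 4)]
            seqs[f"a{i}"] = "".join(arr)
        auto = build_gene_msa(seqs, engine="auto")
        star = build_gene_msa(seqs, engine="builtin")
        assert sum_of_pairs_cost(auto.rows) <= sum_of_pairs_cost(star.rows)

    def test_subset_msa_is_valid_alignment(self, rng):
        seqs = {f"a{i}": random_seq(rng, 300) for i in range(4)}
        msa = build_gene_msa(seqs, engine="builtin")
        sub = subset_msa(msa, ["a0", "a2"])
        assert sub.ungapped("a0") == seqs["a0"]
        assert sub.ungapped("a2") == seqs["a2"]
        assert len(set(len(r) for r in sub.rows.values())) == 1


class TestIdentifyVariants:
    def test_identical_rows_empty(self):
        msa = GeneMSA("A", {"x": "ACGTACGT", "y": "ACGTACGT"})
        assert len(identify_variants(msa)) == 0

    def test_three_isolated_columns(self):
        msa = GeneMSA("A", {"x": "ACGTACGTAC", "y": "ACCTACATAG"})
        table = identify_variants(msa)
        assert [(p.start_col, p.end_col) for p in table.positions] == [
            (2, 3),
            (6, 7),
            (9, 10),
        ]

    def test_illustrative_gapped_variant(self):
        """One variant run whose strings are a 4-mer in one allele and a
        2-base + 2-gap string in the other (the textbook refinement
        illustration)."""
        msa = GeneMSA(
            "A",
            {
                "A-1": "CCTAGTTACC",
                "A-3": "CCTGC--ACC",
            },
        )
        table = identify_variants(msa)
        assert len(table) == 1
        pos = table.positions[0]
        assert pos.strings["A-1"] == "AGTT"
        assert pos.strings["A-3"] == "GC--"

    def test_matches_brute_force_on_random_msas(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 6))
            L = int(rng.integers(5, 40))
            rows = {}
            base = random_seq(rng, L)
            for i in range(n):
                arr = list(base)
                for _ in range(int(rng.integers(0, 6))):
                    p = int(rng.integers(0, L))
                    arr[p] = "-ACGT"[rng.integers(0, 5)]
                rows[f"r{i}"] = "".join(arr)
            msa = GeneMSA("x", rows)
            table = identify_variants(msa)
            assert [
                (p.start_col, p.end_col) for p in table.positions
            ] == brute_force_variant_columns(rows)


def placement_from(allele, read_like, start):
    """Manual placement: read_like aligned gaplessly at ``start``."""
    bases = np.frombuffer(read_like.encode(), np.uint8).copy()
    return ReadPlacement(start, start + len(read_like), bases, {}, 1.0)


class TestAssessSupport:
    def test_agreeing_reads_supported(self):
        allele = "AAAACCCCGGGGTTTT"
        pl = [placement_from(allele, allele, 0) for _ in range(8)]
        a = assess_position("x", "s", 0, 6, 8, allele, pl, window_flank=2)
        assert a.status == "supported" and a.depth == 8

    def test_unsupported_reports_plurality_alternative(self):
        """Allele holds a 2-base deletion relative to its reads ('GC--' vs
        reads showing 'GCT-'): unsupported with the read string as the
        alternative."""
        allele = "AAAGCAAA"  # footprint 'GC' at [3,5); reads carry GCT
        reads = []
        for _ in range(6):
            p = ReadPlacement(
                0,
                len(allele),
                np.frombuffer(allele.encode(), np.uint8).copy(),
                {5: "T"},  # insertion between C and the next base
                1.0,
            )
            reads.append(p)
        a = assess_position("x", "s", 0, 3, 5, allele, reads, window_flank=0)
        assert a.status == "unsupported"
        assert a.best_alternative == "GCT"

    def test_low_depth_unexamined(self):
        allele = "AAAACCCCGGGGTTTT"
        pl = [placement_from(allele, allele, 0) for _ in range(3)]
        a = assess_position("x", "s", 0, 6, 8, allele, pl, min_depth=5)
        assert a.status == "unexamined"


class TestCorrectAllele:
    def test_no_unsupported_identity(self):
        allele = "AAAACCCC"
        pl = [placement_from(allele, allele, 0) for _ in range(8)]
        a = assess_position("x", "s", 0, 3, 4, allele, pl)
        seq, corr = correct_allele("x", allele, [(3, 4)], [a])
        assert seq == allele and corr == []

    def test_consistent_alternative_applied(self):
        allele = "AAAGCAAA"
        reads = [
            ReadPlacement(
                0,
                len(allele),
                np.frombuffer(allele.encode(), np.uint8).copy(),
                {5: "T"},
                1.0,
            )
            for _ in range(6)
        ]
        a = assess_position(
            "x", "s1", 0, 3, 5, allele, reads, window_flank=0
        )
        seq, corr = correct_allele("x", allele, [(3, 5)], [a])
        assert seq == "AAAGCTAAA"
        assert len(corr) == 1 and corr[0].old == "GC" and corr[0].new == "GCT"

    def test_conflicting_carriers_leave_position(self):
        allele = "AAAGCAAA"

        def carrier(alt):
            reads = [
                ReadPlacement(
                    0,
                    len(allele),
                    np.frombuffer(allele.encode(), np.uint8).copy(),
                    {5: alt},
                    1.0,
                )
                for _ in range(6)
            ]
            return reads

        a1 = assess_position("x", "s1", 0, 3, 5, allele, carrier("T"), window_flank=0)
        a2 = assess_position("x", "s2", 0, 3, 5, allele, carrier("G"), window_flank=0)
        seq, corr = correct_allele("x", allele, [(3, 5)], [a1, a2])
        assert seq == allele and corr == []


class TestRefineEndToEnd:
    def test_injected_errors_corrected_and_merged(self, clean_dataset):
        """Take the truth alleles as a draft, corrupt one allele with an
        extra substitution, and let the carriers' reads vote it back: the
        corrupted allele must be corrected and merged with its twin, and
        accuracy must improve."""
        ds = clean_dataset
        gene = "A"
        carried = sorted(ds.truth.carried_alleles(gene))
        alleles, carriers, gene_of = {}, {}, {}
        for i, name in enumerate(carried):
            did = f"A_{i:05d}"
            alleles[did] = ds.pool.alleles[name]
            gene_of[did] = gene
            carriers[did] = {
                s
                for s in ds.truth.samples
                if name in ds.truth.genotypes[s][gene]
            }
        # corrupt a shared allele mid-sequence and register it as a twin
        # draft carried by one of its samples
        victim = max(sorted(carriers), key=lambda d: len(carriers[d]))
        assert len(carriers[victim]) >= 2
        seq = alleles[victim]
        bad = seq[:2500] + ("A" if seq[2500] != "A" else "C") + seq[2501:]
        alleles["A_99999"] = bad
        gene_of["A_99999"] = gene
        # move one carrier over to the corrupted twin
        moved = sorted(carriers[victim])[0]
        carriers["A_99999"] = {moved}
        carriers[victim] = carriers[victim] - {moved}
        draft = DraftAlleleSet(alleles, carriers, gene_of)

        cl = GeneKmerClassifier({gene: list(alleles.values())})
        oriented = {
            s: cl.partition([x for p in ds.short_reads[s] for x in (p.r1, p.r2)])
            for s in ds.truth.samples
        }
        result = refine_draft_set(draft, oriented)
        assert len(result.refined) <= len(draft)
        assert any(c.allele_id == "A_99999" for c in result.corrections)
        assert "A_99999" in result.merges or bad not in result.refined.alleles.values()
        b = result.draft_accuracy.accuracy(gene)
        a = result.refined_accuracy.accuracy(gene)
        assert a > b
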