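from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from lakevir.alignment_core import (
    NUCLEOTIDE,
    PROTEIN,
    compute_ani,
    find_crispr_arrays,
    find_orfs,
    find_trnas,
    local_align,
)
from lakevir.trna_library import CANONICAL_TRNAS

from ._oracles import (
    crispr_bruteforce,
    six_frame_orf_intervals,
    sw_score_python,
    trna_hits_windowed,
)


def random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestLocalAlign:
    def test_identical_sequences_single_perfect_alignment(self):
        seq = "ACGTACGTAC" * 10
        alns = local_align(seq, seq)
        assert len(alns) == 1
        a = alns[0]
        assert a.percent_identity == 100.0
        assert a.alignment_length == 100
        assert a.mismatches == 0
        assert (a.query_start, a.query_end) == (1, 100)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT" * 10)

    def test_mixed_alphabet_rejected(self):
        with pytest.raises(ValueError):
            local_align("ACGTPQRS", "ACGTACGT", NUCLEOTIDE)

    def test_score_equals_python_smith_waterman_on_small_pairs(self):
        """Exact-DP route matches a plain O(mn) Smith-Waterman oracle."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n1, n2 = rng.integers(20, 120, size=2)
            q, s = random_nt(rng, n1), random_nt(rng, n2)
            alns = local_align(q, s, min_score=1)
            best = max((a.score for a in alns), default=0)
            oracle = sw_score_python(q, s)
            if oracle >= 1:
                assert best == oracle
            else:
                assert best == 0

    def test_alignment_counts_are_consistent(self):
        rng = np.random.default_rng(7)
        q, s = random_nt(rng, 200), random_nt(rng, 200)
        # embed a shared segment
        shared = random_nt(rng, 80)
        q = q[:50] + shared + q[50:]
        s = s[:100] + shared + s[100:]
        for a in local_align(q, s, min_score=20):
            assert a.matches + a.mismatches + a.gaps == a.alignment_length
            assert a.percent_identity == pytest.approx(
                100.0 * a.matches / a.alignment_length
            )

    def test_bitscore_monotone_in_score(self):
        assert NUCLEOTIDE.bitscore(100) > NUCLEOTIDE.bitscore(50)
        assert NUCLEOTIDE.evalue(100, 1000, 1000) < NUCLEOTIDE.evalue(50, 1000, 1000)

    def test_lowering_min_score_never_removes_hits(self):
        rng = np.random.default_rng(3)
        q, s = random_nt(rng, 300), random_nt(rng, 300)
        strict = local_align(q, s, min_score=30)
        loose = local_align(q, s, min_score=15)
        strict_keys = {(a.query_start, a.subject_start, a.score) for a in strict}
        loose_keys = {(a.query_start, a.subject_start, a.score) for a in loose}
        assert strict_keys <= loose_keys

    def test_protein_alignment_blosum62(self):
        alns = local_align("MKVLLTAEEQ", "MKVLLTAEEQ", PROTEIN, min_score=10)
        assert alns and alns[0].percent_identity == 100.0

    def test_seed_route_finds_planted_homology_in_large_pair(self):
        rng = np.random.default_rng(11)
        shared = random_nt(rng, 1000)
        q = random_nt(rng, 10_000) + shared + random_nt(rng, 10_000)
        s = random_nt(rng, 15_000) + shared + random_nt(rng, 5_000)
        alns = local_align(q, s, min_score=100)
        best = max(alns, key=lambda a: a.score)
        assert best.alignment_length >= 990
        assert best.percent_identity > 99.0


class TestComputeAni:
    def test_self_ani_is_100(self):
        rng = np.random.default_rng(0)
        seq = random_nt(rng, 2000)
        r = compute_ani(seq, seq)
        assert r.defined
        assert r.ani == pytest.approx(100.0)
        assert r.aligned_fraction == pytest.approx(1.0)

    def test_planted_divergence_recovered(self):
        """3% random substitutions give ANI in [96, 98]."""
        rng = np.random.default_rng(1)
        seq = random_nt(rng, 10_000)
        arr = np.array(list(seq))
        idx = rng.choice(len(seq), size=300, replace=False)
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in idx:
            arr[i] = rot[arr[i]]
        r = compute_ani(seq, "".join(arr))
        assert r.defined
        assert 96.0 <= r.ani <= 98.0

    def test_symmetry_within_half_point(self):
        rng = np.random.default_rng(2)
        a = random_nt(rng, 5000)
        b = a[:2500] + random_nt(rng, 2500)
        r1, r2 = compute_ani(a, b), compute_ani(b, a)
        assert r1.defined == r2.defined
        if r1.defined:
            assert abs(r1.ani - r2.ani) <= 0.5

    def test_unrelated_sequences_undefined(self):
        rng = np.random.default_rng(3)
        r = compute_ani(random_nt(rng, 10_000), random_nt(rng, 10_000))
        assert not r.defined
        assert r.aligned_fraction < 0.05

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_ani("ACGT" * 50, "ACGT" * 200)


class TestFindOrfs:
    def _gene(self, rng, n_codons):
        middle = "".join(
            rng.choice(["GCT", "GGC", "AAA", "CTG", "TTC", "GAT"], n_codons - 2)
        )
        return "ATG" + middle + "TAA"

    def test_planted_gene_called_forward(self):
        rng = np.random.default_rng(4)
        gene = self._gene(rng, 300)  # 900 nt incl. stop
        scaffold = "TAA" + gene + "TAA"
        calls = [c for c in find_orfs(scaffold) if c.strand == 1]
        assert any(
            scaffold[c.start : c.end] == gene[: len(gene) - 3] for c in calls
        )

    def test_reverse_complement_gives_same_protein_opposite_strand(self):
        rng = np.random.default_rng(5)
        gene = self._gene(rng, 120)
        scaffold = "TAATAA" + gene + "TAGTAG"
        fwd = find_orfs(scaffold)
        rev = find_orfs(str(Seq(scaffold).reverse_complement()))
        fwd_prot = {(c.protein, c.strand) for c in fwd}
        rev_prot = {(c.protein, -c.strand) for c in rev}
        assert fwd_prot == rev_prot

    def test_random_sequence_calls_match_six_frame_scan(self):
        rng = np.random.default_rng(6)
        seq = random_nt(rng, 5000)
        calls = find_orfs(seq)
        regions = six_frame_orf_intervals(seq, 150)
        assert len(calls) > 0
        for c in calls:
            assert c.end - c.start >= 150
            assert "*" not in c.protein.rstrip("*")
            # every call lies within some stop-free maximal region
            if c.strand == 1:
                assert any(
                    s <= c.start and c.end <= e for s, e, st in regions if st == 1
                )

    def test_case_invariance(self):
        rng = np.random.default_rng(7)
        seq = random_nt(rng, 2000)
        a = [(c.start, c.end, c.strand) for c in find_orfs(seq)]
        b = [(c.start, c.end, c.strand) for c in find_orfs(seq.lower())]
        assert a == b


class TestFindTrnas:
    def test_planted_canonical_trna_detected_at_exact_coordinates(self):
        rng = np.random.default_rng(8)
        name, trna = next(iter(CANONICAL_TRNAS.items()))
        genome = random_nt(rng, 3000) + trna + random_nt(rng, 3000)
        hits = [h for h in find_trnas(genome) if h.name == name]
        assert any(h.start == 3000 and h.end == 3000 + len(trna) for h in hits)

    def test_heavily_mutated_trna_not_reported(self):
        rng = np.random.default_rng(9)
        name = "tRNA-Ala"
        trna = list(CANONICAL_TRNAS[name])
        idx = rng.choice(len(trna), size=12, replace=False)  # ~83% identity at 72 bp
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in idx:
            trna[i] = rot[trna[i]]
        genome = random_nt(rng, 2000) + "".join(trna) + random_nt(rng, 2000)
        hits = [h for h in find_trnas(genome) if h.name == name]
        assert hits == []

    def test_detection_agrees_with_windowed_identity_scan(self):
        rng = np.random.default_rng(10)
        name = "tRNA-Gly"
        trna = list(CANONICAL_TRNAS[name])
        # 4 substitutions: comfortably above the 90% bar
        for i in rng.choice(len(trna), size=4, replace=False):
            trna[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[trna[i]]
        genome = random_nt(rng, 1500) + "".join(trna) + random_nt(rng, 1500)
        oracle_starts = trna_hits_windowed(genome, CANONICAL_TRNAS[name], 90.0)
        hits = [h for h in find_trnas(genome) if h.name == name and h.strand == 1]
        assert sorted(h.start for h in hits) == sorted(oracle_starts)


class TestFindCrisprArrays:
    def _plant(self, rng, n_rep, rep_len=30, sp_len=32):
        repeat = random_nt(rng, rep_len)
        spacers = [random_nt(rng, sp_len) for _ in range(n_rep - 1)]
        content = repeat + "".join(sp + repeat for sp in spacers)
        genome = random_nt(rng, 2000) + content + random_nt(rng, 2000)
        return genome, repeat, spacers

    def test_planted_array_recovered_with_exact_spacers(self):
        rng = np.random.default_rng(11)
        genome, repeat, spacers = self._plant(rng, 5)
        arrays = find_crispr_arrays(genome)
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.repeat_sequence == repeat
        assert arr.repeat_count == 5
        assert arr.spacers == spacers

    def test_two_repeat_copies_not_an_array(self):
        rng = np.random.default_rng(12)
        genome, _, _ = self._plant(rng, 2)
        assert find_crispr_arrays(genome) == []

    def test_detection_agrees_with_exhaustive_tandem_repeat_scan(self):
        rng = np.random.default_rng(13)
        genome, _, _ = self._plant(rng, 4, rep_len=25, sp_len=28)
        genome2, _, _ = self._plant(rng, 3, rep_len=40, sp_len=45)
        combined = genome + genome2
        arrays = find_crispr_arrays(combined)
        oracle = crispr_bruteforce(combined)
        got = {(a.repeat_starts[0], len(a.repeat_sequence), a.repeat_count) for a in arrays}
        assert got == set(oracle)
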