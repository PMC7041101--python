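"""Variant extraction, the genome mutator, ASI, and the evaluator."""

import numpy as np
import pytest

from wgalign.evaluate import evaluate_calls, indels_equivalent
from wgalign.genome import Genome
from wgalign.pairalign import PairwiseAlignment
from wgalign.pipeline import align_genomes
from wgalign.simulate import MutationProfile, mutate_genome, random_genome
from wgalign.variants import (
    DEL,
    INS,
    SNV,
    Variant,
    apply_variants,
    call_variants,
    compute_asi,
    read_vcf,
    write_vcf,
)

from conftest import random_seq


class TestCallVariants:
    def test_all_match_is_empty(self):
        aln = PairwiseAlignment(ops=[("=", 50)])
        assert call_variants(aln, "A" * 50, "A" * 50) == []

    def test_single_mismatch_snv(self):
        aln = PairwiseAlignment(ops=[("=", 2), ("X", 1), ("=", 1)])
        got = call_variants(aln, "ACGT", "ACCT", chrom="c")
        assert got == [Variant(SNV, "c", 3, "G", "C")]

    def test_deletion_is_anchored(self):
        p_seq, q_seq = "AACGTTT", "AATTT"
        aln = PairwiseAlignment(ops=[("=", 2), ("D", 2), ("=", 3)])
        got = call_variants(aln, p_seq, q_seq)
        assert got == [Variant(DEL, "ref", 2, "ACG", "A")]

    def test_tandem_repeat_copy_gain_is_one_insertion(self, rng):
        """Seven ACGT copies in P vs nine in Q: one 8 bp insertion whose alt
        carries two extra repeat units."""
        left = random_seq(rng, 150)
        right = random_seq(rng, 150)
        p = Genome("r", left + "ACGT" * 7 + right)
        q = Genome("q", left + "ACGT" * 9 + right)
        res = align_genomes(p, q)
        assert len(res.variants) == 1
        v = res.variants[0]
        assert v.kind == INS and v.net_size == 8
        inserted = v.alt[1:]
        assert inserted in "ACGT" * 4  # two repeat copies, possibly rotated

    def test_applying_calls_reproduces_query_span(self, rng):
        tpl = random_genome(20_000, seed=int(rng.integers(1 << 30)))
        mut, _ = mutate_genome(tpl, MutationProfile(seed=int(rng.integers(1 << 30))))
        res = align_genomes(tpl, mut)
        for ra in res.regions:
            region = ra.region
            calls = [
                v
                for v in res.variants
                if region.p_start <= v.pos <= region.p_end
            ]
            rebuilt = apply_variants(tpl.seq, calls, region.p_start, region.p_end)
            assert rebuilt == mut.seq[region.q_start - 1 : region.q_end]


class TestMutateGenome:
    def test_1mbp_default_profile_exact_counts(self):
        tpl = random_genome(1_000_000, seed=9)
        _, truth = mutate_genome(tpl, MutationProfile(seed=10))
        n_snv = sum(v.kind == SNV for v in truth)
        small = sum(v.kind != SNV and v.net_size <= 10 for v in truth)
        large = sum(v.kind != SNV and v.net_size > 10 for v in truth)
        assert n_snv == 20_000
        assert small == 350
        assert large == 100
        assert all(11 <= v.net_size <= 20 for v in truth if v.kind != SNV and v.net_size > 10)

    def test_zero_rate_profile_is_identity(self):
        tpl = random_genome(10_000, seed=1)
        mut, truth = mutate_genome(tpl, MutationProfile(0, 0, 0, seed=2))
        assert mut.seq == tpl.seq and truth == []

    def test_truth_replay_reproduces_mutated_genome(self):
        tpl = random_genome(100_000, seed=3)
        mut, truth = mutate_genome(tpl, MutationProfile(seed=4))
        # independent replay: split template at events, splice alleles
        parts = []
        cur = 0
        for v in truth:
            if v.kind == SNV:
                parts.append(tpl.seq[cur : v.pos - 1] + v.alt)
                cur = v.pos
            else:
                parts.append(tpl.seq[cur : v.pos - 1] + v.alt)
                cur = v.pos + len(v.ref) - 1
        parts.append(tpl.seq[cur:])
        assert "".join(parts) == mut.seq

    def test_snv_alt_always_differs(self):
        tpl = random_genome(50_000, seed=5)
        _, truth = mutate_genome(tpl, MutationProfile(seed=6))
        for v in truth:
            if v.kind == SNV:
                assert v.ref == tpl.seq[v.pos - 1] and v.alt != v.ref

    def test_3x_preset_triples_only_snvs(self):
        p = MutationProfile.preset("3x")
        assert p.snv_per_mb == 60_000
        assert p.small_indel_per_mb == 350 and p.large_indel_per_mb == 100

    def test_template_too_short_for_events_rejected(self):
        # 50 SNVs with 5-base separations cannot fit into 100 bases
        with pytest.raises(ValueError):
            mutate_genome(
                Genome("t", "ACGT" * 25), MutationProfile(500_000, 0, 0, seed=1)
            )

    def test_events_avoid_n_runs(self):
        rng = np.random.default_rng(12)
        seq = list(random_genome(50_000, seed=13).seq)
        for start in rng.integers(0, 49_000, size=30):
            seq[start : start + 50] = "N" * 50
        tpl = Genome("t", "".join(seq))
        _, truth = mutate_genome(tpl, MutationProfile(seed=14))
        for v in truth:
            assert "N" not in tpl.seq[v.pos - 1 : v.pos + len(v.ref) - 1]


class TestComputeAsi:
    def test_no_variants_is_100(self):
        assert compute_asi([], 1000) == 100.0

    def test_snv_plus_deletion_formula(self):
        truth = [
            Variant(SNV, "c", 10, "A", "C"),
            Variant(DEL, "c", 100, "ACGT", "A"),
        ]
        assert compute_asi(truth, 1000) == pytest.approx(99.6)

    def test_default_profile_matches_expected_rate(self):
        # expected mismatches per Mbp: 20000 + 350*5.5 + 100*15.5 = 23475
        tpl = random_genome(2_000_000, seed=15)
        _, truth = mutate_genome(tpl, MutationProfile(seed=16))
        asi = compute_asi(truth, len(tpl))
        assert asi == pytest.approx(100 * (1 - 23_475 / 1e6), abs=0.05)

    def test_rejects_empty_genome(self):
        with pytest.raises(ValueError):
            compute_asi([], 0)


class TestIndelEquivalence:
    def test_repeat_context_either_end(self):
        # the two gap placements AGCAT----TG and AG----CATTG over AGCATGCATTG
        # describe one and the same 4 bp deletion
        ref = "AGCATGCATTG"
        a = Variant(DEL, "c", 5, "TGCAT", "T")
        b = Variant(DEL, "c", 2, "GCATG", "G")
        assert ref[:5] + ref[9:] == ref[:2] + ref[6:] == "AGCATTG"
        assert indels_equivalent(ref, a, b)

    def test_different_content_not_equivalent(self):
        ref = "AACGTTACGTAA"
        a = Variant(DEL, "c", 2, "ACG", "A")
        b = Variant(DEL, "c", 5, "TAC", "T")
        assert not indels_equivalent(ref, a, b)


class TestEvaluateCalls:
    def ref(self):
        return Genome("c", random_seq(np.random.default_rng(0), 3000))

    def test_identity_gives_perfect_scores(self):
        ref = self.ref()
        truth = [
            Variant(SNV, "c", 100, ref.seq[99], "A" if ref.seq[99] != "A" else "C"),
            Variant(DEL, "c", 500, ref.seq[499:504], ref.seq[499]),
            Variant(INS, "c", 900, ref.seq[899], ref.seq[899] + "TTT"),
        ]
        res = evaluate_calls(truth, truth, ref)
        assert res.snv.precision == res.snv.recall == 1.0
        assert res.indel.precision == res.indel.recall == 1.0

    def test_repeat_end_placement_both_count(self):
        # an indel reported at either end of a tandem repeat context matches
        seq = "A" * 100 + "AGCATGCATTG" + "A" * 100
        ref = Genome("c", seq)
        truth = [Variant(DEL, "c", 102, "GCAT", "G")]
        shifted = [Variant(DEL, "c", 105, "TGCA", "T")]
        res = evaluate_calls(shifted, truth, ref)
        assert res.indel.tp == 1 and res.indel.fp == 0 and res.indel.fn == 0

    def test_snv_one_bp_off_is_fp_plus_fn(self):
        ref = self.ref()
        truth = [Variant(SNV, "c", 100, ref.seq[99], "A" if ref.seq[99] != "A" else "C")]
        called = [Variant(SNV, "c", 101, ref.seq[100], "A" if ref.seq[100] != "A" else "C")]
        res = evaluate_calls(called, truth, ref)
        assert (res.snv.tp, res.snv.fp, res.snv.fn) == (0, 1, 1)

    def test_greedy_matching_agrees_with_maximum_matching_oracle(self, rng):
        """On sparse random indel sets, one-to-one greedy nearest matching
        finds as many pairs as an exhaustive maximum bipartite matching."""
        import networkx as nx

        ref = Genome("c", random_seq(rng, 60_000))
        for _ in range(10):
            raw = np.sort(rng.choice(np.arange(50, 59_000), size=120, replace=False))
            positions = [int(raw[0])]
            for p in raw[1:]:
                if int(p) - positions[-1] >= 30:
                    positions.append(int(p))
            positions = positions[:50]
            truth, called = [], []
            for n, pos in enumerate(positions):
                pos = int(pos)
                size = int(rng.integers(1, 6))
                v = Variant(DEL, "c", pos, ref.seq[pos - 1 : pos + size], ref.seq[pos - 1])
                truth.append(v)
                if rng.random() < 0.8:  # called, possibly with a small shift
                    shift = int(rng.integers(-12, 13))
                    cpos = pos + shift
                    called.append(
                        Variant(DEL, "c", cpos, ref.seq[cpos - 1 : cpos + size], ref.seq[cpos - 1])
                    )
            truth = sorted(truth, key=Variant.sort_key)
            res = evaluate_calls(called, truth, ref)

            g = nx.Graph()
            for i, c in enumerate(called):
                for j, t in enumerate(truth):
                    if c.kind == t.kind and c.net_size == t.net_size and abs(c.pos - t.pos) <= 10:
                        g.add_edge(("c", i), ("t", j))
            best = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
            assert res.indel.tp == len(best)

    def test_symmetry_swapping_roles_swaps_precision_recall(self, rng):
        ref = Genome("c", random_seq(rng, 20_000))
        def mk(pos, size):
            return Variant(DEL, "c", pos, ref.seq[pos - 1 : pos + size], ref.seq[pos - 1])
        truth = [mk(1000, 3), mk(2000, 2), mk(3000, 4)]
        called = [mk(1004, 3), mk(2500, 2)]
        fwd = evaluate_calls(called, truth, ref)
        rev = evaluate_calls(truth, called, ref)
        assert fwd.indel.precision == rev.indel.recall
        assert fwd.indel.recall == rev.indel.precision

    def test_overlapping_truth_rejected(self):
        ref = self.ref()
        truth = [
            Variant(DEL, "c", 100, ref.seq[99:110], ref.seq[99]),
            Variant(SNV, "c", 105, ref.seq[104], "A" if ref.seq[104] != "A" else "C"),
        ]
        with pytest.raises(ValueError):
            evaluate_calls([], truth, ref)

    def test_undefined_ratios_are_none_not_zero(self):
        ref = self.ref()
        res = evaluate_calls([], [], ref)
        assert res.snv.precision is None and res.snv.recall is None


class TestVcfRoundTrip:
    def test_write_then_read_preserves_variants(self, tmp_path, rng):
        ref = Genome("chrA", random_seq(rng, 5000))
        variants = [
            Variant(SNV, "chrA", 10, ref.seq[9], "A" if ref.seq[9] != "A" else "C"),
            Variant(DEL, "chrA", 100, ref.seq[99:103], ref.seq[99]),
            Variant(INS, "chrA", 200, ref.seq[199], ref.seq[199] + "GGG"),
        ]
        path = tmp_path / "x.vcf"
        write_vcf(variants, {"chrA": 5000}, path)
        back = read_vcf(path)
        assert back == sorted(variants, key=Variant.sort_key)

    def test_truth_vcf_self_evaluation_is_perfect(self, tmp_path):
        tpl = random_genome(50_000, seed=21)
        _, truth = mutate_genome(tpl, MutationProfile(seed=22))
        path = tmp_path / "truth.vcf"
        write_vcf(truth, {tpl.name: len(tpl)}, path)
        back = read_vcf(path)
        res = evaluate_calls(back, truth, tpl)
        assert res.snv.precision == res.snv.recall == 1.0
        assert res.indel.precision == res.indel.recall == 1.0

    def test_unknown_contig_rejected(self, tmp_path):
        v = Variant(SNV, "nope", 1, "A", "C")
        with pytest.raises(ValueError):
            write_vcf([v], {"chrA": 100}, tmp_path / "y.vcf")

    def test_empty_variant_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], {"chrA": 100}, path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        assert lines[-1].startswith("#CHROM")
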