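"""Counting, variant tallying, aggregation, down-sampling, empirical rates."""

import numpy as np
import pytest

from mertree import contexts as ctx
from mertree.contexts import flank_widths, reverse_complement
from mertree.tabulate import (
    CountTable,
    GenomeMask,
    VariantFilters,
    VariantRecord,
    aggregate_to_level,
    count_contexts,
    downsample_sfs,
    empirical_probabilities,
    tally_variants,
)


def brute_force_totals(seq: str, masked, K: int, architecture: str,
                       parity: str = "all") -> CountTable:
    """Independent per-position oracle: fold by trying both strands."""
    table = CountTable(K, architecture, provenance={"parity": parity})
    n5, n3 = flank_widths(K, architecture)
    rc = reverse_complement(seq)
    L = len(seq)
    for p in range(L):
        if not masked[p]:
            continue
        pos1 = p + 1
        if parity == "even" and pos1 % 2 or parity == "odd" and pos1 % 2 == 0:
            continue
        window = None
        if p - n5 >= 0 and p + n3 < L:
            w = seq[p - n5:p + n3 + 1]
            if w[n5] in "AC" and all(b in "ACGT" for b in w):
                window = w
        if window is None:
            q = L - 1 - p  # same site on the reverse strand
            if q - n5 >= 0 and q + n3 < L:
                w = rc[q - n5:q + n3 + 1]
                if w[n5] in "AC" and all(b in "ACGT" for b in w):
                    window = w
        if window is None:
            continue
        table.N[window[n5]][ctx.context_index(window, architecture)] += 1
    return table


def random_sequence(rng, n, n_fraction=0.0):
    bases = rng.choice(list("ACGT"), size=n)
    if n_fraction:
        bases[rng.random(n) < n_fraction] = "N"
    return "".join(bases)


class TestCountContexts:
    def test_five_base_example(self):
        # three valid 3-mer windows in ACGTA: ACG, CGT->ACG, GTA->TAC
        mask = GenomeMask.whole_sequences({"chr": 5})
        table = count_contexts({"chr": "ACGTA"}, mask, 3)
        assert table.N["C"][ctx.context_index("ACG", table.architecture)] == 2
        assert table.N["A"][ctx.context_index("TAC", table.architecture)] == 1
        assert table.total_positions == 3

    def test_all_n_sequence_empty(self):
        mask = GenomeMask.whole_sequences({"chr": 6})
        table = count_contexts({"chr": "NNNNNN"}, mask, 3)
        assert table.total_positions == 0
        assert table.provenance["skipped_windows"] == 0  # N centers are not countable

    @pytest.mark.parametrize(
        "arch,K",
        [(ctx.RIGHT_ASYMMETRIC, 1), (ctx.RIGHT_ASYMMETRIC, 3),
         (ctx.RIGHT_ASYMMETRIC, 4), (ctx.LEFT_ASYMMETRIC, 3),
         (ctx.LEFT_ASYMMETRIC, 4), (ctx.SYMMETRIC, 3), (ctx.SYMMETRIC, 5)],
    )
    def test_matches_brute_force_oracle(self, arch, K, rng):
        seq = random_sequence(rng, 2000, n_fraction=0.02)
        starts = rng.integers(0, 1900, size=5)
        mask = GenomeMask.from_intervals(
            [("chr", int(s), int(s + rng.integers(50, 300))) for s in starts]
        )
        masked = mask.boolean("chr", len(seq))
        fast = count_contexts({"chr": seq}, mask, K, arch)
        slow = brute_force_totals(seq, masked, K, arch)
        assert fast == slow

    def test_parity_partition(self, rng):
        seq = random_sequence(rng, 1500)
        mask = GenomeMask.from_intervals([("chr", 100, 1200)])
        full = count_contexts({"chr": seq}, mask, 3, parity="all")
        even = count_contexts({"chr": seq}, mask, 3, parity="even")
        odd = count_contexts({"chr": seq}, mask, 3, parity="odd")
        for c in "AC":
            np.testing.assert_array_equal(even.N[c] + odd.N[c], full.N[c])

    def test_reverse_complement_invariance(self, rng):
        seq = random_sequence(rng, 800)
        mask = GenomeMask.whole_sequences({"chr": len(seq)})
        a = count_contexts({"chr": seq}, mask, 3)
        b = count_contexts({"chr": reverse_complement(seq)}, mask, 3)
        assert a == b

    def test_missing_chromosome_hard_error(self):
        mask = GenomeMask.from_intervals([("chrX", 0, 10)])
        with pytest.raises(KeyError):
            count_contexts({"chr1": "ACGTACGT"}, mask, 3)


class TestTallyVariants:
    @pytest.fixture()
    def toy(self):
        seq = {"chr": "TTACGTT"}
        mask = GenomeMask.whole_sequences({"chr": 7})
        table = count_contexts(seq, mask, 3)
        return seq, mask, table

    def test_simple_snv_counted(self, toy):
        seq, mask, table = toy
        out = tally_variants([VariantRecord("chr", 4, "C", "T", 2, 0.1)],
                             seq, mask, table)
        i = ctx.context_index("ACG", table.architecture)
        assert out.n["C"][i, 2] == 1  # alts of C are (A, G, T)
        assert out.total_polymorphisms == 1

    def test_reverse_strand_variant_folds(self, toy):
        seq, mask, table = toy
        # G>A at 1-based position 5 is C>T on the canonical strand, context CGT->ACG
        out = tally_variants([VariantRecord("chr", 5, "G", "A", 2, 0.1)],
                             seq, mask, table)
        i = ctx.context_index("ACG", table.architecture)
        assert out.n["C"][i, 2] == 1

    def test_allele_count_filter_drops_singleton(self, toy):
        seq, mask, table = toy
        out = tally_variants([VariantRecord("chr", 4, "C", "T", 1, 0.001)],
                             seq, mask, table,
                             VariantFilters(min_allele_count=2))
        assert out.total_polymorphisms == 0
        assert out.provenance["variant_skips"]["filtered"] == 1

    def test_ref_mismatch_skipped_and_logged(self, toy):
        seq, mask, table = toy
        out = tally_variants([VariantRecord("chr", 4, "G", "A", 2, 0.1)],
                             seq, mask, table)
        assert out.total_polymorphisms == 0
        assert out.provenance["variant_skips"]["ref_mismatch"] == 1

    def test_unmasked_variant_ignored(self):
        seq = {"chr": "TTACGTT"}
        mask = GenomeMask.from_intervals([("chr", 0, 2)])
        table = count_contexts(seq, mask, 1)
        out = tally_variants([VariantRecord("chr", 4, "C", "T", 2, 0.1)],
                             seq, mask, table)
        assert out.total_polymorphisms == 0
        assert out.provenance["variant_skips"]["unmasked"] == 1


class TestAggregation:
    def test_aggregate_to_own_level_is_identity(self, rng):
        seq = random_sequence(rng, 500)
        mask = GenomeMask.whole_sequences({"chr": len(seq)})
        table = count_contexts({"chr": seq}, mask, 3)
        assert aggregate_to_level(table, 3) == table

    def test_conservation_across_levels(self, rng):
        seq = random_sequence(rng, 3000)
        mask = GenomeMask.whole_sequences({"chr": len(seq)})
        table = count_contexts({"chr": seq}, mask, 4)
        for level in (3, 2, 1):
            agg = aggregate_to_level(table, level)
            assert agg.total_positions == table.total_positions

    def test_hand_built_two_context_sum(self):
        table = CountTable(2, ctx.RIGHT_ASYMMETRIC)
        # level-2 contexts of central C: CA, CC, CG, CT -> all collapse to C
        table.N["C"][:] = [10, 20, 30, 40]
        table.n["C"][0] = [1, 0, 2]
        table.n["C"][2] = [0, 5, 1]
        agg = aggregate_to_level(table, 1)
        assert agg.N["C"][0] == 100
        np.testing.assert_array_equal(agg.n["C"][0], [1, 5, 3])


class TestEmpiricalProbabilities:
    def test_plain_mle(self):
        table = CountTable(1, ctx.RIGHT_ASYMMETRIC)
        table.N["A"][0] = 50
        table.N["C"][0] = 100
        table.n["C"][0] = [2, 1, 0]
        probs = empirical_probabilities(table, pseudocount=0.0)
        np.testing.assert_allclose(probs.p["C"][0], [0.02, 0.01, 0.0])

    def test_pure_pseudocount(self):
        table = CountTable(1, ctx.RIGHT_ASYMMETRIC)
        probs = empirical_probabilities(table, pseudocount=0.5)
        np.testing.assert_allclose(probs.p["A"][0], [0.25, 0.25, 0.25])

    def test_pseudocount_formula(self):
        table = CountTable(1, ctx.RIGHT_ASYMMETRIC)
        table.N["C"][0] = 100
        table.n["C"][0] = [2, 0, 0]
        probs = empirical_probabilities(table, pseudocount=0.5)
        assert probs.p["C"][0, 0] == pytest.approx(2.5 / 102)

    def test_zero_n_zero_pseudocount_undefined(self):
        table = CountTable(1, ctx.RIGHT_ASYMMETRIC)
        with pytest.raises(ZeroDivisionError):
            empirical_probabilities(table, pseudocount=0.0)


class TestDownsampleSfs:
    bins = {"low": (0.0, 0.05), "high": (0.05, 1.0)}

    def _variants(self, n_low, n_high):
        out = []
        for i in range(n_low):
            out.append(VariantRecord("c", i + 1, "A", "G", 1, 0.01))
        for i in range(n_high):
            out.append(VariantRecord("c", 1000 + i, "C", "T", 50, 0.5))
        return out

    def test_exact_bin_targets(self):
        sub = downsample_sfs(self._variants(10, 20), {"low": 5, "high": 20},
                             self.bins, seed=3)
        afs = [v.allele_frequency for v in sub]
        assert sum(a <= 0.05 for a in afs) == 5
        assert sum(a > 0.05 for a in afs) == 20

    def test_target_equal_source_is_permutation(self):
        src = self._variants(7, 3)
        sub = downsample_sfs(src, {"low": 7, "high": 3}, self.bins, seed=0)
        assert sorted(v.pos for v in sub) == sorted(v.pos for v in src)

    def test_deterministic_per_seed(self):
        src = self._variants(30, 30)
        a = downsample_sfs(src, {"low": 10, "high": 5}, self.bins, seed=11)
        b = downsample_sfs(src, {"low": 10, "high": 5}, self.bins, seed=11)
        assert [v.pos for v in a] == [v.pos for v in b]

    def test_infeasible_target_names_bin(self):
        with pytest.raises(ValueError, match="high"):
            downsample_sfs(self._variants(10, 2), {"low": 5, "high": 5},
                           self.bins, seed=1)


class TestCountTableIO:
    def test_tsv_round_trip(self, rng, tmp_path):
        seq = random_sequence(rng, 1000)
        mask = GenomeMask.whole_sequences({"chr": len(seq)})
        table = count_contexts({"chr": seq}, mask, 3)
        table = tally_variants(
            [VariantRecord("chr", 11, seq[10], "ACGT".replace(seq[10], "")[0], 3, 0.2)],
            {"chr": seq}, mask, table)
        path = tmp_path / "counts.tsv"
        table.write_tsv(path)
        loaded = CountTable.read_tsv(path)
        assert loaded == table
        assert loaded.provenance["parity"] == "all"

    def test_sum_nalt_bounded_by_totals(self, k5_counts):
        k5_counts.validate()
        for c in "AC":
            assert (k5_counts.n[c].sum(axis=1) <= k5_counts.N[c]).all()
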