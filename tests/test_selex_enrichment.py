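"""Unit and property tests for primer trimming and exclusive-k-mer statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from khbind.selex_enrichment import (
    KmerCountTable,
    ReadPool,
    bh_adjust,
    count_kmers,
    exclusive_kmers,
    fisher_enrichment,
    fisher_pvalues,
    trim_primers,
)
from khbind.synthetic_data import FORWARD_PRIMER, REVERSE_PRIMER

from oracles import bh_step_up_oracle, fisher_one_sided_oracle

FWD, REV = FORWARD_PRIMER, REVERSE_PRIMER


class TestTrimPrimers:
    def test_exact_primers_yield_insert(self):
        insert = "ACGTACGTACGTACGTACGT"
        pool = trim_primers([FWD + insert + REV], FWD, REV, max_mismatches=0)
        assert pool.reads == [insert]
        assert pool.n_input == 1 and pool.n_trimmed == 1

    def test_missing_reverse_primer_discards_read(self):
        read = FWD + "ACGT" * 5 + "G" * len(REV)
        pool = trim_primers([read], FWD, REV, max_mismatches=2)
        assert pool.reads == [] and pool.n_trimmed == 0

    def test_substitution_within_budget_kept(self):
        mutated_fwd = "C" + FWD[1:]
        pool = trim_primers([mutated_fwd + "A" * 20 + REV], FWD, REV, max_mismatches=2)
        assert pool.reads == ["A" * 20]

    def test_invalid_characters_discarded(self):
        pool = trim_primers([FWD + "ACGX" * 5 + REV], FWD, REV)
        assert pool.n_trimmed == 0

    def test_empty_input_is_empty_pool(self):
        pool = trim_primers([], FWD, REV)
        assert pool.n_input == 0 and pool.reads == []

    def test_empty_primer_rejected(self):
        with pytest.raises(ValueError):
            trim_primers(["ACGT"], "", REV)


class TestCountKmers:
    @pytest.mark.parametrize(
        "read,k,expected,total",
        [
            ("ACGTA", 2, {"AC": 1, "CG": 1, "GT": 1, "TA": 1}, 4),
            ("AAAA", 2, {"AA": 3}, 3),
            ("ACGTACGTACGTACGTACGT", 20, {"ACGTACGTACGTACGTACGT": 1}, 1),
        ],
    )
    def test_overlapping_counts(self, read, k, expected, total):
        table = count_kmers(ReadPool(reads=[read]), k)
        assert table.counts == expected
        assert table.total_occurrences == total

    def test_n_windows_excluded(self):
        table = count_kmers(ReadPool(reads=["ACNGT"]), 2)
        assert table.counts == {"AC": 1, "GT": 1}

    def test_k_longer_than_reads_gives_empty_table(self):
        assert count_kmers(ReadPool(reads=["ACG"]), 5).counts == {}

    @given(
        st.lists(st.text(alphabet="ACGTN", min_size=0, max_size=30), max_size=12),
        st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_conservation(self, reads, k):
        """Total occurrences equal the number of N-free length-k windows."""
        table = count_kmers(ReadPool(reads=[r.upper() for r in reads]), k)
        expected = sum(
            1
            for r in reads
            for i in range(max(0, len(r) - k + 1))
            if "N" not in r.upper()[i : i + k]
        )
        assert table.total_occurrences == expected


class TestExclusiveKmers:
    def _table(self, counts, k=5):
        return KmerCountTable(k=k, counts=counts, total_occurrences=sum(counts.values()), n_reads=1)

    def test_subtraction(self):
        pos = self._table({"AAAAA": 3, "AATCG": 2})
        ctrl = self._table({"AATCG": 1})
        assert exclusive_kmers(pos, ctrl) == ["AAAAA"]

    def test_positive_subset_of_control_is_empty(self):
        pos = self._table({"AAAAA": 1})
        ctrl = self._table({"AAAAA": 4, "CCCCC": 1})
        assert exclusive_kmers(pos, ctrl) == []

    def test_disjoint_pools_keep_everything_sorted_by_count(self):
        pos = self._table({"CCCCC": 2, "AAAAA": 5, "GGGGG": 2})
        ctrl = self._table({"TTTTT": 1})
        assert exclusive_kmers(pos, ctrl) == ["AAAAA", "CCCCC", "GGGGG"]

    def test_k_mismatch_raises(self):
        with pytest.raises(ValueError):
            exclusive_kmers(self._table({"AAAAA": 1}, k=5), self._table({"AAA": 1}, k=3))


class TestFisher:
    def test_example_tables_match_enumeration(self):
        # [[3,7],[0,10]] and [[5,5],[5,5]] frozen from the enumeration oracle
        pos = KmerCountTable(5, {"AAAAA": 3}, 10, 1)
        ctrl = KmerCountTable(5, {}, 10, 1)
        assert fisher_enrichment("AAAAA", pos, ctrl) == pytest.approx(
            fisher_one_sided_oracle(3, 7, 0, 10), abs=1e-12
        )
        assert fisher_enrichment("AAAAA", pos, ctrl) == pytest.approx(0.10526315789473684, abs=1e-12)

        pos = KmerCountTable(5, {"AAAAA": 5}, 10, 1)
        ctrl = KmerCountTable(5, {"AAAAA": 5}, 10, 1)
        p = fisher_enrichment("AAAAA", pos, ctrl)
        assert p == pytest.approx(fisher_one_sided_oracle(5, 5, 5, 5), abs=1e-12)
        assert p == pytest.approx(0.6718591, abs=1e-6)

    def test_zero_counts_give_p_one(self):
        pos = KmerCountTable(5, {}, 10, 1)
        ctrl = KmerCountTable(5, {}, 10, 1)
        assert fisher_enrichment("AAAAA", pos, ctrl) == pytest.approx(1.0)

    def test_zero_totals_error(self):
        with pytest.raises(ValueError):
            fisher_pvalues(np.array([1]), np.array([0]), 0, 10)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_agreement_with_enumeration_oracle(self, data):
        """Exact hypergeometric tail on random tables with margins <= 200."""
        a = data.draw(st.integers(0, 100))
        b = data.draw(st.integers(0, 100))
        c = data.draw(st.integers(0, 100))
        d = data.draw(st.integers(0, 100))
        tp, tc = a + b, c + d
        if tp == 0 or tc == 0:
            return
        p = fisher_pvalues(np.array([a]), np.array([c]), tp, tc)[0]
        assert p == pytest.approx(fisher_one_sided_oracle(a, b, c, d), abs=1e-12)


class TestBH:
    def test_hand_computed_example(self):
        q, sig = bh_adjust([0.01, 0.02, 0.03, 0.04], fdr=0.05)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert sig.all()

    def test_single_p(self):
        q, sig = bh_adjust([0.04])
        assert q[0] == pytest.approx(0.04) and sig[0]

    def test_none_significant(self):
        _, sig = bh_adjust([0.2, 0.9])
        assert not sig.any()

    def test_empty_input(self):
        q, sig = bh_adjust([])
        assert len(q) == 0 and len(sig) == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_matches_step_up_oracle_and_invariants(self, ps, rnd):
        q, sig = bh_adjust(ps)
        q_oracle, sig_oracle = bh_step_up_oracle(ps)
        assert np.allclose(q, q_oracle, atol=1e-12)
        assert (sig == sig_oracle).all()
        assert np.all(q >= np.asarray(ps) - 1e-15)  # q >= p elementwise
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in sorted-p order
        # permutation equivariance
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q2, sig2 = bh_adjust([ps[i] for i in perm])
        assert np.allclose(q2, q[perm]) and (sig2 == sig[perm]).all()
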