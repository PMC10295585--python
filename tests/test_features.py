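"""Unit and oracle tests for the three global-information encoders."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sequence
from ncrna_funclass.features import (
    AlignmentParams,
    InstancePropensityEncoder,
    align_global,
    build_pattern_table,
    count_occurr,
    instance_propensity,
    kmer_presence_prob,
    kmer_vector,
    pattern_propensity,
)
from ncrna_funclass.io import LabeledDataset, SequenceRecord


# ---------------------------------------------------------------- oracles
def kmer_counts_brute(seq: str, k: int) -> np.ndarray:
    """Naive sliding-window counter over the folded (U->T) sequence."""
    seq = seq.upper().replace("U", "T")
    alphabet = {c: i for i, c in enumerate("ACGT")}
    counts = np.zeros(4**k)
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in alphabet for c in w):
            idx = 0
            for c in w:
                idx = idx * 4 + alphabet[c]
            counts[idx] += 1
    return counts


def count_occurr_brute(p: str, s: str) -> int:
    return sum(1 for i in range(len(s) - len(p) + 1) if s[i : i + len(p)] == p)


def nw_score_brute(a: str, b: str, match=1.0, mismatch=0.0, gap=-1.0) -> float:
    """Recursive enumeration of all global alignment paths (memoized)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            step = match if a[i] == b[j] else mismatch
            best = max(best, rec(i + 1, j + 1) + step)
        if i < len(a):
            best = max(best, rec(i + 1, j) + gap)
        if j < len(b):
            best = max(best, rec(i, j + 1) + gap)
        return best

    return rec(0, 0)


def pattern_table_brute(ds: LabeledDataset, L: int, min_support: int):
    """Exhaustive substring enumeration across the whole corpus."""
    patterns = set()
    for r in ds.records:
        s = r.seq.upper().replace("U", "T")
        for i in range(len(s) - L + 1):
            w = s[i : i + L]
            if set(w) <= set("ACGT"):
                patterns.add(w)
    out = {}
    for p in patterns:
        counts = np.zeros(len(ds.classes))
        for r in ds.records:
            if p in r.seq.upper().replace("U", "T"):
                counts[ds.classes.index(r.label)] += 1
        if counts.sum() >= min_support:
            out[p] = counts
    return out


# ---------------------------------------------------------------- k-mers
class TestKmerVector:
    def test_single_kmer(self):
        v = kmer_vector("AAA", k=2)
        assert v.values[0] == 1.0 and v.values.sum() == 1.0

    def test_uniform_mononucleotides(self):
        np.testing.assert_allclose(kmer_vector("ACGT", k=1).values, [0.25] * 4)

    def test_k_longer_than_sequence_is_all_zero(self):
        assert kmer_vector("ACG", k=6).values.sum() == 0.0

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(30):
            seq = random_sequence(rng, 200, "ACGTUN")
            for k in (1, 3):
                expected = kmer_counts_brute(seq, k)
                total = expected.sum()
                got = kmer_vector(seq, k).values
                np.testing.assert_allclose(got, expected / total if total else expected)

    @settings(derandomize=True, max_examples=100)
    @given(seq=st.text(alphabet="ACGUN", min_size=1, max_size=100), k=st.integers(1, 4))
    def test_normalization_invariant(self, seq, k):
        v = kmer_vector(seq, k).values
        assert (v >= 0).all()
        total = v.sum()
        assert total == 0.0 or abs(total - 1.0) < 1e-9


class TestKmerPresenceProb:
    def test_single_base(self):
        assert kmer_presence_prob(1, 1) == pytest.approx(0.25)

    def test_single_window(self):
        for k in (1, 2, 5):
            assert kmer_presence_prob(k, k) == pytest.approx(4.0 ** (-k))

    def test_direct_evaluation(self):
        assert kmer_presence_prob(10, 3) == pytest.approx(1 - (63 / 64) ** 8)

    def test_monotone_in_length_and_limit(self):
        values = [kmer_presence_prob(n, 3) for n in range(3, 200)]
        assert all(0 < v < 1 for v in values)
        assert all(b > a for a, b in zip(values, values[1:]))
        assert kmer_presence_prob(100_000, 3) > 0.999999

    def test_too_short_is_an_error(self):
        with pytest.raises(ValueError):
            kmer_presence_prob(2, 3)


# ---------------------------------------------------------------- patterns
class TestCountOccurr:
    @pytest.mark.parametrize(
        "p,s,expected", [("AA", "AAA", 2), ("GATC", "TTTT", 0), ("A", "AAAA", 4)]
    )
    def test_examples(self, p, s, expected):
        assert count_occurr(p, s) == expected

    def test_matches_naive_scan(self, rng):
        for _ in range(150):
            s = random_sequence(rng, int(rng.integers(5, 60)), "ACGT")
            p = random_sequence(rng, int(rng.integers(1, 5)), "ACGT")
            assert count_occurr(p, s) == count_occurr_brute(p, s)


class TestPatternTable:
    def _dataset(self, seq_label_pairs):
        records = [
            SequenceRecord(id=f"s{i}", seq=s, label=c)
            for i, (s, c) in enumerate(seq_label_pairs)
        ]
        return LabeledDataset(records, classes=sorted({c for _, c in seq_label_pairs}))

    def test_propensity_row_from_presence_counts(self):
        # pattern ACGTA in 3 class-A sequences and 1 class-B sequence
        ds = self._dataset(
            [
                ("ACGTATT", "A"),
                ("GGACGTA", "A"),
                ("ACGTACGTA", "A"),  # two occurrences, one sequence
                ("TACGTAT", "B"),
                ("TTTTTTT", "B"),
            ]
        )
        table = build_pattern_table(ds, L=5, min_support=2)
        np.testing.assert_allclose(table.propensity("ACGTA"), [0.75, 0.25])
        assert table.n_total("ACGTA") == 4

    def test_rows_sum_to_one_and_counts_consistent(self, tiny_dataset):
        table = build_pattern_table(tiny_dataset, L=4, min_support=1)
        assert len(table) > 0
        for p in table.counts:
            assert table.counts[p].sum() == table.n_total(p)
            assert table.propensity(p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        pairs = [
            (random_sequence(rng, int(rng.integers(10, 30)), "ACGTU"), cls)
            for cls in ("x", "y", "z")
            for _ in range(4)
        ]
        ds = self._dataset(pairs)
        for min_support in (1, 2):
            table = build_pattern_table(ds, L=3, min_support=min_support)
            expected = pattern_table_brute(ds, L=3, min_support=min_support)
            assert set(table.counts) == set(expected)
            for p, counts in expected.items():
                np.testing.assert_array_equal(table.counts[p], counts)

    def test_empty_table_warns(self, tiny_dataset):
        with pytest.warns(UserWarning, match="min_support"):
            table = build_pattern_table(tiny_dataset, L=16, min_support=5)
        assert len(table) == 0

    def test_tsv_roundtrip(self, tiny_dataset, tmp_path):
        from ncrna_funclass.features import PatternPropensityTable

        table = build_pattern_table(tiny_dataset, L=4, min_support=1)
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = PatternPropensityTable.from_tsv(path)
        assert back.L == table.L and back.classes == table.classes
        assert set(back.counts) == set(table.counts)
        for p in table.counts:
            np.testing.assert_array_equal(back.counts[p], table.counts[p])


class TestPatternPropensity:
    def _table(self):
        ds = LabeledDataset(
            [
                SequenceRecord("a1", "AAAAC", label="A"),
                SequenceRecord("a2", "AAAAG", label="A"),
                SequenceRecord("b1", "AAAAT", label="B"),
                SequenceRecord("b2", "CCCCT", label="B"),
                SequenceRecord("b3", "CCCCA", label="B"),
            ],
            classes=["A", "B"],
        )
        return build_pattern_table(ds, L=4, min_support=2)

    def test_single_match_returns_row_verbatim(self):
        table = self._table()
        np.testing.assert_allclose(
            pattern_propensity("GGAAAAGG", table), table.propensity("AAAA")
        )

    def test_no_match_returns_uniform(self):
        table = self._table()
        np.testing.assert_allclose(pattern_propensity("GTGTGTGT", table), [0.5, 0.5])

    def test_occurrence_weighted_mean(self):
        table = self._table()
        # AAAAA contains AAAA twice; CCCC once -> (2*row_A + 1*row_C)/3
        seq = "AAAAATTCCCC"
        expected = (2 * table.propensity("AAAA") + table.propensity("CCCC")) / 3
        np.testing.assert_allclose(pattern_propensity(seq, table), expected)

    @settings(derandomize=True, max_examples=100)
    @given(seq=st.text(alphabet="ACGT", min_size=1, max_size=50))
    def test_sums_to_one(self, seq):
        table = self._table()
        assert pattern_propensity(seq, table).sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- alignment
class TestAlignGlobal:
    def test_self_alignment_scores_length(self, rng):
        for _ in range(10):
            s = random_sequence(rng, int(rng.integers(1, 30)), "ACGT")
            assert align_global(s, s) == len(s)

    def test_gap_example(self):
        assert align_global("ACGT", "AGT") == 2.0

    def test_u_and_t_align_as_match(self):
        assert align_global("ACGU", "ACGT") == 4.0

    def test_symmetry(self, rng):
        for _ in range(25):
            a = random_sequence(rng, int(rng.integers(1, 25)), "ACGT")
            b = random_sequence(rng, int(rng.integers(1, 25)), "ACGT")
            assert align_global(a, b) == align_global(b, a)

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(120):
            a = random_sequence(rng, int(rng.integers(1, 7)), "ACGT")
            b = random_sequence(rng, int(rng.integers(1, 7)), "ACGT")
            assert align_global(a, b) == nw_score_brute(a, b)

    def test_custom_params_against_oracle(self, rng):
        params = AlignmentParams(match_score=2.0, mismatch_score=-1.0, gap_penalty=-2.0)
        for _ in range(40):
            a = random_sequence(rng, int(rng.integers(1, 6)), "ACGT")
            b = random_sequence(rng, int(rng.integers(1, 6)), "ACGT")
            assert align_global(a, b, params) == nw_score_brute(a, b, 2.0, -1.0, -2.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(match_score=0.0, mismatch_score=0.0)


class TestInstancePropensity:
    def _reference(self, rng, n_per_class=5):
        records = []
        for cls, comp in [("A", "ACGT"), ("B", "GGCC"), ("C", "TTAA")]:
            for i in range(n_per_class):
                records.append(
                    SequenceRecord(
                        f"{cls}{i}", random_sequence(rng, 40, comp), label=cls
                    )
                )
        return LabeledDataset(records, classes=["A", "B", "C"])

    def test_perfect_self_match(self, rng):
        ref = self._reference(rng)
        seq = ref.records[7].seq  # class B
        v = instance_propensity(seq, ref, top_n=1)
        np.testing.assert_allclose(v, [0.0, 1.0, 0.0])

    def test_tied_hits_split_evenly(self):
        # two identical references of different classes tie exactly
        ref = LabeledDataset(
            [
                SequenceRecord("a", "ACGTACGT", label="A"),
                SequenceRecord("b", "ACGTACGT", label="B"),
            ],
            classes=["A", "B"],
        )
        np.testing.assert_allclose(
            instance_propensity("ACGTACGT", ref, top_n=2), [0.5, 0.5]
        )

    def test_prefilter_off_equals_all_pairs_oracle(self, rng):
        ref = self._reference(rng, n_per_class=4)
        enc = InstancePropensityEncoder(top_n=3, use_prefilter=False).fit(
            ref.sequences(), np.array(ref.labels(), dtype=object)
        )
        for _ in range(10):
            q = random_sequence(rng, 35, "ACGT")
            scores = np.array([align_global(q, r.seq) for r in ref.records])
            order = np.argsort(-scores, kind="stable")[:3]
            weights = np.maximum(scores[order], 0)
            expected = np.zeros(3)
            for idx, w in zip(order, weights):
                expected[ref.classes.index(ref.records[idx].label)] += w
            expected /= expected.sum()
            np.testing.assert_allclose(enc.transform([q])[0], expected)

    def test_prefilter_consistency_on_small_reference(self, rng):
        # with fewer references than the candidate pool the prefilter is a no-op
        ref = self._reference(rng, n_per_class=4)
        y = np.array(ref.labels(), dtype=object)
        on = InstancePropensityEncoder(candidate_pool=50, use_prefilter=True).fit(
            ref.sequences(), y
        )
        off = InstancePropensityEncoder(use_prefilter=False).fit(ref.sequences(), y)
        q = random_sequence(rng, 40, "ACGT")
        np.testing.assert_allclose(on.transform([q]), off.transform([q]))

    def test_all_nonpositive_scores_give_uniform(self):
        # gap-dominated comparison of maximally different lengths
        ref = LabeledDataset(
            [
                SequenceRecord("a", "G" * 50, label="A"),
                SequenceRecord("b", "G" * 50, label="B"),
            ],
            classes=["A", "B"],
        )
        v = instance_propensity("T" * 2, ref, top_n=2)
        np.testing.assert_allclose(v, [0.5, 0.5])

    def test_empty_reference_is_an_error(self):
        ref = LabeledDataset([], classes=[])
        with pytest.raises(ValueError):
            instance_propensity("ACGT", ref)

    def test_loo_excludes_self(self, rng):
        ref = self._reference(rng)
        enc = InstancePropensityEncoder(top_n=1, use_prefilter=False).fit(
            ref.sequences(), np.array(ref.labels(), dtype=object)
        )
        loo = enc.transform_loo()
        plain = enc.transform(ref.sequences())
        # plain transform puts all mass on the self-hit class; LOO may not
        assert plain.shape == loo.shape == (15, 3)
        for row, rec in zip(plain, ref.records):
            assert row[ref.classes.index(rec.label)] == pytest.approx(1.0)
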