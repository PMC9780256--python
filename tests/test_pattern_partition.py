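"""IUPAC two-partitions and the partition optimizers."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_indel_table, random_snv_table
from _oracles import (
    brute_force_min_loss,
    pattern_counts,
    single_pattern_loss,
    table_counts,
)
from patmut.iupac import (
    CODES,
    IUPAC_SETS,
    SET_TO_CODE,
    expand,
    matches,
    pattern_size,
    two_partitions,
)
from patmut.kmer_counting import KmerCountTable
from patmut.pattern_partition import (
    Hyperparams,
    PatternStats,
    greedy_partition,
    model_total_loss,
    optimal_partition,
    pattern_loss,
    regularized_rate,
    root_pattern,
    validate_partition,
)


class TestTwoPartitions:
    def test_n_row(self):
        assert two_partitions("N") == [("A", "B"), ("C", "D"), ("G", "H"),
                                       ("T", "V"), ("R", "Y"), ("S", "W"),
                                       ("K", "M")]

    def test_s_row(self):
        assert two_partitions("S") == [("C", "G")]

    def test_single_base_codes_have_no_splits(self):
        for code in "ACGT":
            assert two_partitions(code) == []

    def test_every_pair_is_a_disjoint_cover_and_enumeration_is_complete(self):
        """Set-algebra oracle: the listed pairs are exactly the codable
        unordered splits of each ambiguity code's base set."""
        for code in "SWRYKMBDHVN":
            s = IUPAC_SETS[code]
            listed = {frozenset((x, y)) for x, y in two_partitions(code)}
            possible = set()
            for r in range(1, len(s)):
                for sub in itertools.combinations(sorted(s), r):
                    a, b = frozenset(sub), s - frozenset(sub)
                    if a in SET_TO_CODE and b in SET_TO_CODE:
                        possible.add(frozenset((SET_TO_CODE[a], SET_TO_CODE[b])))
            assert listed == possible
            for x, y in two_partitions(code):
                assert IUPAC_SETS[x] & IUPAC_SETS[y] == frozenset()
                assert IUPAC_SETS[x] | IUPAC_SETS[y] == s

    def test_matching_and_size(self):
        assert matches("NCG", "ACG") and not matches("NCG", "ATG")
        assert pattern_size("NCG") == 4
        assert sorted(expand("SCH")) == ["CCA", "CCC", "CCT", "GCA", "GCC", "GCT"]


class TestPatternLoss:
    def test_empty_pattern_costs_only_the_penalty(self):
        hp = Hyperparams(alpha=1.0, c=3.5)
        assert pattern_loss(PatternStats("NN", 0, 0, 0.1), hp, mu=0.1) == 3.5

    def test_unregularized_rate_is_mle(self):
        assert regularized_rate(3, 1, alpha=0.0, mu=0.5) == 0.75

    def test_empty_pattern_rate_equals_mu(self):
        for alpha in (0.0, 1.0, 7.0):
            assert regularized_rate(0, 0, alpha, mu=0.037) == pytest.approx(0.037)

    def test_loss_at_c2_is_aic(self):
        """With c = 2 and alpha = 0 the partition loss equals
        2 * n_patterns - 2 * logLik (independent Bernoulli-product routine)."""
        t = random_snv_table(3)
        counts = table_counts(t)
        mu = t.mu
        model = optimal_partition(t, Hyperparams(alpha=0.0, c=2.0))
        aic = 0.0
        for p in model.patterns:
            M, U = pattern_counts(p.pattern, counts)
            r = M / (M + U)
            ll = (M * math.log(r) if M else 0.0) + (U * math.log1p(-r) if U else 0.0)
            aic += 2.0 - 2.0 * ll
        assert model.loss == pytest.approx(aic, rel=1e-12)


class TestOptimalPartition:
    def test_homogeneous_table_keeps_single_root_pattern(self):
        t = KmerCountTable(3, "C>T")
        from patmut.iupac import pattern_match_mask

        space = pattern_match_mask("NCN", 3)
        t.m[space] = 5
        t.u[space] = 995
        model = optimal_partition(t, Hyperparams(alpha=1.0, c=50.0))
        assert [p.pattern for p in model.patterns] == ["NCN"]

    @pytest.mark.parametrize("seed", range(3))
    def test_dp_equals_bruteforce_snv_k3(self, seed):
        t = random_snv_table(seed)
        hp = Hyperparams(alpha=1.0, c=2.0)
        model = optimal_partition(t, hp)
        oracle = brute_force_min_loss("NCN", table_counts(t), hp.alpha, hp.c, t.mu)
        assert model.loss == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_dp_equals_bruteforce_indel_k2(self, seed):
        t = random_indel_table(seed, k=2)
        hp = Hyperparams(alpha=0.5, c=1.0)
        model = optimal_partition(t, hp)
        oracle = brute_force_min_loss("NN", table_counts(t), hp.alpha, hp.c, t.mu)
        assert model.loss == pytest.approx(oracle, rel=1e-12)

    def test_k1_exhaustive_enumeration(self):
        """All partitions of the single-position N space, enumerated by hand."""
        t = random_indel_table(5, k=1)
        hp = Hyperparams(alpha=1.0, c=2.0)
        counts = table_counts(t)
        mu = t.mu

        def ploss(pat):
            return single_pattern_loss(pat, counts, hp.alpha, hp.c, mu)

        # direct recursive enumeration of partitions of a one-character root
        def enum(pat):
            yield [pat]
            for x, y in two_partitions(pat):
                for px in enum(x):
                    for py in enum(y):
                        yield px + py

        best = min(sum(ploss(p) for p in part) for part in enum("N"))
        model = optimal_partition(t, hp)
        assert model.loss == pytest.approx(best, rel=1e-12)

    def test_exactly_one_match_invariant(self):
        for seed in range(3):
            t = random_snv_table(seed)
            model = optimal_partition(t, Hyperparams(1.0, 2.0))
            validate_partition(model, t)
            for kmer in expand("NCN"):
                assert sum(matches(p.pattern, kmer) for p in model.patterns) == 1

    def test_count_conservation(self):
        t = random_snv_table(9)
        model = optimal_partition(t, Hyperparams(2.0, 1.0))
        assert sum(p.M for p in model.patterns) == pytest.approx(t.m.sum())
        assert sum(p.U for p in model.patterns) == pytest.approx(t.u.sum())

    def test_pattern_count_monotone_in_penalty(self):
        t = random_snv_table(21)
        sizes = [len(optimal_partition(t, Hyperparams(1.0, c)).patterns)
                 for c in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0, 200.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_memoization_soundness(self):
        t = random_snv_table(13)
        a = optimal_partition(t, Hyperparams(1.0, 2.0))
        b = optimal_partition(t, Hyperparams(1.0, 2.0))
        assert a.loss == b.loss
        assert [p.pattern for p in a.patterns] == [p.pattern for p in b.patterns]

    def test_reported_loss_consistent_with_own_stats(self):
        t = random_snv_table(17)
        model = optimal_partition(t, Hyperparams(1.0, 2.0))
        assert model_total_loss(model) == pytest.approx(model.loss, rel=1e-12)

    def test_degenerate_mu_refused(self):
        t = KmerCountTable(2, "INS")
        t.u[:] = 100  # no mutations at all: mu = 0
        with pytest.raises(ValueError, match="degenerate"):
            optimal_partition(t, Hyperparams(1.0, 2.0))

    def test_memory_guard_suggests_greedy(self):
        t = KmerCountTable(2, "INS")
        t.m[:] = 1
        t.u[:] = 10
        with pytest.raises(MemoryError, match="greedy"):
            optimal_partition(t, Hyperparams(1.0, 2.0), max_patterns_in_memory=10)


class TestGreedyPartition:
    def test_homogeneous_matches_exact(self):
        t = KmerCountTable(3, "C>T")
        from patmut.iupac import pattern_match_mask

        space = pattern_match_mask("NCN", 3)
        t.m[space] = 5
        t.u[space] = 995
        hp = Hyperparams(alpha=1.0, c=50.0)
        g = greedy_partition(t, hp)
        e = optimal_partition(t, hp)
        assert g.loss == pytest.approx(e.loss)
        assert [p.pattern for p in g.patterns] == [p.pattern for p in e.patterns]

    @pytest.mark.parametrize("seed", range(10))
    def test_never_beats_exact(self, seed):
        t = random_snv_table(seed + 100)
        hp = Hyperparams(alpha=1.0, c=2.0)
        assert greedy_partition(t, hp).loss >= optimal_partition(t, hp).loss - 1e-9

    def test_no_penalty_fully_splits_distinct_rates(self):
        rng = np.random.default_rng(4)
        t = KmerCountTable(2, "INS")
        t.u[:] = 10_000
        t.m[:] = rng.permutation(np.arange(1, 17)) * 7  # all-distinct rates
        model = greedy_partition(t, Hyperparams(alpha=1e-9, c=0.0))
        assert len(model.patterns) == 16
        assert all(pattern_size(p.pattern) == 1 for p in model.patterns)

    def test_valid_partition(self):
        t = random_indel_table(8, k=3, label="DEL")
        model = greedy_partition(t, Hyperparams(0.5, 1.0))
        validate_partition(model, t)


class TestModelIO:
    def test_tsv_roundtrip(self, tmp_path):
        t = random_snv_table(2)
        model = optimal_partition(t, Hyperparams(1.5, 3.0))
        p = tmp_path / "model.tsv"
        model.write_tsv(p)
        back = type(model).read_tsv(p)
        assert back.mut_class == model.mut_class and back.k == model.k
        assert back.mu == model.mu and back.loss == model.loss
        assert [(q.pattern, q.M, q.U, q.r) for q in back.patterns] == \
               [(q.pattern, q.M, q.U, q.r) for q in model.patterns]

    def test_rate_lookup(self):
        t = random_snv_table(2)
        model = optimal_partition(t, Hyperparams(1.5, 3.0))
        for p in model.patterns:
            for kmer in expand(p.pattern):
                assert model.rate_of(kmer) == p.r
        with pytest.raises(KeyError):
            model.rate_of("AAA")  # central A is outside a C>T model's space
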