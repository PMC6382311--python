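"""Exclusivity, entropy, coverage and composite scoring formulas."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_exclusive_sets, make_random_matrix
from unicovex.mutations import MutationMatrix, exclusivity_profiles
from unicovex.scoring import (
    dendrix_weight,
    exclusive_degree,
    exclusive_entropy,
    exclusive_score,
    min_coverage,
    unicovex_score,
    union_coverage,
)


class TestExclusiveDegree:
    def test_strictly_exclusive_gene_scores_one(self):
        m = MutationMatrix.from_pairs([("g", f"s{i}") for i in range(4)])
        (p,) = exclusivity_profiles(m, ["g"])
        assert exclusive_degree(p) == 1.0

    def test_fully_overlapped_gene_scores_zero(self):
        pairs = [("a", f"s{i}") for i in range(5)] + [("b", f"s{i}") for i in range(5)]
        m = MutationMatrix.from_pairs(pairs)
        p = exclusivity_profiles(m, ["a", "b"])[0]
        assert exclusive_degree(p) == 0.0

    def test_half_exclusive(self):
        pairs = [("a", f"s{i}") for i in range(4)] + [("b", "s0"), ("b", "s1")]
        m = MutationMatrix.from_pairs(pairs)
        p = exclusivity_profiles(m, ["a", "b"])[0]
        assert exclusive_degree(p) == 0.5


class TestExclusiveScore:
    def test_pairwise_disjoint_module_scores_one(self, balanced_exclusive_matrix):
        assert exclusive_score(balanced_exclusive_matrix, ["g0", "g1", "g2", "g3"]) == 1.0

    def test_identical_genes_score_zero(self):
        pairs = [(g, s) for g in ("a", "b") for s in ("s1", "s2", "s3")]
        m = MutationMatrix.from_pairs(pairs)
        assert exclusive_score(m, ["a", "b"]) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_mean_ratio(self, seed):
        rng = np.random.default_rng(seed)
        m = make_random_matrix(rng, 6, 8)
        module = list(rng.choice(m.gene_ids, size=3, replace=False))
        eps = brute_force_exclusive_sets(m, module)
        expected = sum(len(e) / m.coverage(g) for g, e in zip(module, eps)) / 3
        assert exclusive_score(m, module) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_ex_is_one_iff_sample_sets_pairwise_disjoint(self, seed):
        rng = np.random.default_rng(50 + seed)
        m = make_random_matrix(rng, 8, 10)
        module = list(rng.choice(m.gene_ids, size=3, replace=False))
        disjoint = all(
            not (m.samples_of(a) & m.samples_of(b))
            for a, b in itertools.combinations(module, 2)
        )
        assert (exclusive_score(m, module) == 1.0) == disjoint

    def test_extra_co_mutated_sample_never_increases_ex(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = make_random_matrix(rng, 5, 8)
            module = list(rng.choice(m.gene_ids, size=3, replace=False))
            before = exclusive_score(m, module)
            extra = "s_new"
            sets = dict(m.mutated_samples)
            for g in module[:2]:  # the new sample hits >= 2 module genes
                sets[g] = sets[g] | {extra}
            m2 = MutationMatrix(m.gene_ids, m.sample_ids + (extra,), sets)
            assert exclusive_score(m2, module) <= before + 1e-12


class TestExclusiveEntropy:
    def test_balanced_four_gene_module_is_two_bits(self, balanced_exclusive_matrix):
        assert exclusive_entropy(
            balanced_exclusive_matrix, ["g0", "g1", "g2", "g3"]
        ) == pytest.approx(2.0)

    def test_unbalanced_4211_split_is_1_75_bits(self, unbalanced_exclusive_matrix):
        # -(1/2 log 1/2 + 1/4 log 1/4 + 2 * 1/8 log 1/8) = 1.75
        assert exclusive_entropy(
            unbalanced_exclusive_matrix, ["g0", "g1", "g2", "g3"]
        ) == pytest.approx(1.75)

    def test_singleton_module_zero_entropy(self):
        m = MutationMatrix.from_pairs([("g", "s1"), ("g", "s2")])
        assert exclusive_entropy(m, ["g"]) == 0.0

    def test_no_exclusive_sample_defined_as_zero(self):
        pairs = [(g, s) for g in ("a", "b") for s in ("s1", "s2")]
        m = MutationMatrix.from_pairs(pairs)
        assert exclusive_entropy(m, ["a", "b"]) == 0.0

    def test_maximal_iff_exclusive_counts_all_equal(self):
        # exhaustive over all compositions of n'=8 into s=4 positive parts
        s, total = 4, 8
        for parts in itertools.product(range(total + 1), repeat=s):
            if sum(parts) != total:
                continue
            pairs, sid = [], 0
            for gi, c in enumerate(parts):
                for _ in range(c):
                    pairs.append((f"g{gi}", f"s{sid}"))
                    sid += 1
            # genes with zero exclusive samples still need >= 1 mutation
            for gi, c in enumerate(parts):
                if c == 0:
                    pairs += [(f"g{gi}", "shared"), ("g_other", "shared")]
            m = MutationMatrix.from_pairs(pairs)
            h = exclusive_entropy(m, [f"g{i}" for i in range(s)])
            if parts == (2, 2, 2, 2):
                assert h == pytest.approx(math.log2(s))
            else:
                assert h < math.log2(s) - 1e-12


class TestCoverageAndComposite:
    def test_min_coverage_is_smallest_per_gene_count(self):
        pairs = (
            [("a", f"s{i}") for i in range(7)]
            + [("b", f"s{i}") for i in range(3)]
            + [("c", f"s{i}") for i in range(5)]
        )
        m = MutationMatrix.from_pairs(pairs)
        assert min_coverage(m, ["a", "b", "c"]) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_min_and_union_coverage_match_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        m = make_random_matrix(rng, 7, 9)
        module = list(rng.choice(m.gene_ids, size=3, replace=False))
        assert min_coverage(m, module) == min(m.coverage(g) for g in module)
        assert union_coverage(m, module) == len(
            set().union(*(m.samples_of(g) for g in module))
        )

    def test_composite_is_product_of_components(self, balanced_exclusive_matrix):
        s = unicovex_score(balanced_exclusive_matrix, ["g0", "g1", "g2", "g3"])
        assert (s.min_coverage, s.ex_score, s.entropy) == (2, 1.0, 2.0)
        assert s.composite == pytest.approx(4.0)
        assert sum(s.ratios) == pytest.approx(1.0)

    def test_total_overlap_gives_zero_composite(self):
        pairs = [(g, s) for g in ("a", "b") for s in ("s1", "s2", "s3")]
        m = MutationMatrix.from_pairs(pairs)
        assert unicovex_score(m, ["a", "b"]).composite == 0.0

    def test_singleton_composite_zero(self):
        m = MutationMatrix.from_pairs([("g", "s1"), ("g", "s2")])
        s = unicovex_score(m, ["g"])
        assert s.entropy == 0.0 and s.composite == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_gene_order_and_sample_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        m = make_random_matrix(rng, 6, 8)
        module = list(rng.choice(m.gene_ids, size=3, replace=False))
        base = unicovex_score(m, module)
        perm = unicovex_score(m, module[::-1])
        assert perm.composite == pytest.approx(base.composite)
        relabel = {s: f"x{i}" for i, s in enumerate(m.sample_ids)}
        m2 = MutationMatrix(
            m.gene_ids,
            tuple(relabel[s] for s in m.sample_ids),
            {g: frozenset(relabel[s] for s in ss) for g, ss in m.mutated_samples.items()},
        )
        assert unicovex_score(m2, module).composite == pytest.approx(base.composite)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_score_invariants_on_arbitrary_small_matrices(data):
    """0 <= Ex <= 1, 0 <= H <= log2 s, composite >= 0, ratios sum to 1."""
    n_genes = data.draw(st.integers(2, 6), label="n_genes")
    n_samples = data.draw(st.integers(2, 8), label="n_samples")
    samples = [f"s{i}" for i in range(n_samples)]
    sets = {}
    for gi in range(n_genes):
        hit = data.draw(
            st.sets(st.sampled_from(samples), min_size=1), label=f"gene{gi}"
        )
        sets[f"g{gi}"] = frozenset(hit)
    m = MutationMatrix(tuple(sets), tuple(samples), sets)
    size = data.draw(st.integers(2, n_genes), label="module_size")
    module = list(sets)[:size]
    s = unicovex_score(m, module)
    assert 0.0 <= s.ex_score <= 1.0
    assert 0.0 <= s.entropy <= math.log2(size) + 1e-9
    assert s.composite >= 0.0
    if s.exclusive_total:
        assert sum(s.ratios) == pytest.approx(1.0)
    else:
        assert s.composite == 0.0


class TestDendrixWeight:
    def test_strictly_exclusive_module_covering_six_samples(self):
        pairs = [(f"x{i}", f"t{2 * i + j}") for i in range(3) for j in range(2)]
        m = MutationMatrix.from_pairs(pairs)
        assert dendrix_weight(m, ["x0", "x1", "x2"]) == 6

    def test_full_overlap_weight_zero(self):
        pairs = [(g, s) for g in ("a", "b") for s in ("s1", "s2", "s3")]
        m = MutationMatrix.from_pairs(pairs)
        assert dendrix_weight(m, ["a", "b"]) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_covered_minus_extra_hits_tally(self, seed):
        rng = np.random.default_rng(seed)
        m = make_random_matrix(rng, 6, 9)
        module = list(rng.choice(m.gene_ids, size=3, replace=False))
        covered = extra = 0
        for s in m.sample_ids:
            hits = sum(s in m.samples_of(g) for g in module)
            if hits:
                covered += 1
                extra += hits - 1
        assert dendrix_weight(m, module) == covered - extra
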