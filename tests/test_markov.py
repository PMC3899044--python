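"""Unit and oracle tests for Markov models and parsimonious context trees."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from parsimotif._seq import encode
from parsimotif.markov import (
    PARTITIONS,
    SUBSETS,
    HomogeneousMarkovModel,
    InhomogeneousPMM,
    PCT,
    fit_homogeneous_mm,
    fit_pmm,
    leaf_log_marginal,
    leaf_statistics,
    learn_pct,
    mm_log_prob,
    pct_lookup,
    pmm_log_prob,
)

# ---------------------------------------------------------------------------
# homogeneous Markov model
# ---------------------------------------------------------------------------


class TestHomogeneousMM:
    def test_order0_degenerate(self):
        mm = fit_homogeneous_mm(["AAAA"], order=0, ess=0.0)
        assert mm.cond_probs[0][0, 0] == pytest.approx(1.0)

    def test_order1_deterministic_chain(self):
        mm = fit_homogeneous_mm(["ACAC"], order=1, ess=0.0)
        assert mm.cond_probs[1][0, 1] == pytest.approx(1.0)  # P(C|A)
        assert mm.cond_probs[1][1, 0] == pytest.approx(1.0)  # P(A|C)

    def test_smoothed_counts_match_hand_computation(self, rng):
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 30)) for _ in range(5)]
        order, ess = 2, 4.0
        mm = fit_homogeneous_mm(seqs, order, ess)
        # independent counting oracle for the full-order table
        counts = np.zeros((16, 4))
        for s in seqs:
            c = encode(s)
            for t in range(2, len(c)):
                counts[c[t - 1] * 4 + c[t - 2], c[t]] += 1
        alpha = ess / 4**3
        expected = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + 4 * alpha)
        np.testing.assert_allclose(mm.cond_probs[2], expected, atol=1e-12)

    def test_rows_normalized(self, rng):
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 50)) for _ in range(3)]
        mm = fit_homogeneous_mm(seqs, 2, 4.0)
        for tab in mm.cond_probs:
            np.testing.assert_allclose(tab.sum(axis=1), 1.0, atol=1e-12)

    def test_log_prob_uniform(self):
        mm = HomogeneousMarkovModel(0, [np.zeros((1, 4))], ess=4.0)
        assert mm.log_prob("ACGT") == pytest.approx(math.log(1 / 256))

    def test_log_prob_empty_range(self, toy_flank):
        assert mm_log_prob(toy_flank, "ACGT", 2, 2) == 0.0

    def test_log_prob_matches_manual_chain(self, rng):
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 25)) for _ in range(4)]
        mm = fit_homogeneous_mm(seqs, 2, 4.0)
        s = "ACGTT"
        c = encode(s)
        manual = (
            math.log(mm.cond_probs[0][0, c[0]])
            + math.log(mm.cond_probs[1][c[0], c[1]])
            + sum(
                math.log(mm.cond_probs[2][c[t - 1] * 4 + c[t - 2], c[t]])
                for t in range(2, 5)
            )
        )
        assert mm.log_prob(s) == pytest.approx(manual, abs=1e-12)

    def test_prefix_supplies_context(self, toy_flank):
        # scoring a suffix with its true prefix equals the matching slice
        full = toy_flank.per_symbol_log_prob(encode("ACGTACGT"))
        tail = toy_flank.per_symbol_log_prob(encode("ACGT"), prefix=encode("ACGT"))
        np.testing.assert_allclose(tail, full[4:], atol=1e-12)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            fit_homogeneous_mm(["ACGT"], order=-1)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial leaf marginal
# ---------------------------------------------------------------------------


class TestLeafMarginal:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((0, 0, 0, 0), 1.0),
            ((1, 0, 0, 0), 1 / 4),
            ((2, 1, 0, 0), 1 / 60),
        ],
    )
    def test_closed_forms_uniform_alpha(self, counts, expected):
        assert math.exp(leaf_log_marginal(counts, (1, 1, 1, 1))) == pytest.approx(expected)

    def test_fractional_counts_via_gamma(self):
        got = leaf_log_marginal((0.5, 0.25, 0, 0), (1, 1, 1, 1))
        expect = (
            gammaln(1.5) + gammaln(1.25) + 2 * gammaln(1) - gammaln(4.75)
            - (4 * gammaln(1) - gammaln(4))
        )
        assert got == pytest.approx(expect, abs=1e-12)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            leaf_log_marginal((1, 1, 1, 1), (1, 0, 1, 1))


# ---------------------------------------------------------------------------
# PCT structure learning: limits, lookup, brute-force enumeration oracle
# ---------------------------------------------------------------------------


def brute_force_pct_score(counts: np.ndarray, depth: int, log2_kappa: float, ess: float) -> float:
    """Independent oracle: enumerate every PCT explicitly.

    Trees are enumerated as nested choices of the 15 set partitions of
    {A,C,G,T}; leaf scores are computed by direct summation over the
    context words of each leaf's product set (no sharing with the DP).
    """
    ln_kappa = log2_kappa * math.log(2)

    def leaf_score(path):
        total = np.zeros(4)
        size = 1
        for block in path:
            size *= len(block)
        for word in itertools.product(*path) if path else [()]:
            idx = tuple(word)
            total = total + counts[idx]
        alpha = ess * size / 4 ** (depth + 1)
        return leaf_log_marginal(total, np.full(4, alpha)) + ln_kappa

    def enumerate_trees(path):
        """Yield total scores of all subtrees hanging below ``path``."""
        if len(path) == depth:
            yield leaf_score(path)
            return
        for part in PARTITIONS:
            blocks = [SUBSETS[b] for b in part]
            per_block = [list(enumerate_trees(path + (blk,))) for blk in blocks]
            for combo in itertools.product(*per_block):
                yield sum(combo)

    return max(enumerate_trees(()))


class TestLearnPCT:
    def test_minimal_limit(self, rng):
        counts = rng.gamma(2.0, 5.0, size=(4, 4, 4))
        pct = learn_pct(counts, 2, log2_kappa=-1e6)
        assert pct.n_leaves == 1

    def test_maximal_limit(self, rng):
        counts = rng.gamma(2.0, 5.0, size=(4, 4, 4))
        pct = learn_pct(counts, 2, log2_kappa=1e6)
        assert pct.n_leaves == 16

    def test_depth0(self):
        pct = learn_pct(np.array([3.0, 1.0, 0.0, 2.0]), 0, log2_kappa=-2)
        assert pct.n_leaves == 1
        np.testing.assert_allclose(pct.leaves[0].theta.sum(), 1.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            learn_pct(np.zeros(4), -1, 0.0)

    @pytest.mark.parametrize("depth", [1, 2])
    @pytest.mark.parametrize("trial", range(4))
    def test_matches_bruteforce_enumeration(self, depth, trial):
        rng = np.random.default_rng(100 * depth + trial)
        counts = rng.gamma(1.5, 4.0, size=(4,) * depth + (4,))
        # fractional expected counts, as produced by EM
        counts *= rng.random(counts.shape)
        kappa = rng.uniform(-6, 2)
        pct = learn_pct(counts, depth, kappa, ess=4.0)
        oracle = brute_force_pct_score(counts, depth, kappa, ess=4.0)
        assert pct.score == pytest.approx(oracle, rel=1e-10)

    def test_leaf_count_monotone_in_kappa(self, rng):
        counts = rng.gamma(2.0, 5.0, size=(4, 4, 4))
        leaves = [
            learn_pct(counts, 2, k).n_leaves for k in (-1e6, -20, -10, -5, -2, 0, 2, 1e6)
        ]
        assert leaves == sorted(leaves)

    def test_partition_invariants(self, rng):
        counts = rng.gamma(2.0, 5.0, size=(4, 4, 4))
        pct = learn_pct(counts, 2, -3.0)
        # leaf context sets partition the 4^depth context space
        seen = set()
        for leaf in pct.leaves:
            words = leaf.context_words()
            assert not (seen & set(words))
            seen.update(words)
        assert len(seen) == 16
        # aggregated leaf counts reproduce the totals
        total = sum(l.counts.sum() for l in pct.leaves)
        assert total == pytest.approx(counts.sum())


class TestPCTLookup:
    def test_minimal_tree_single_leaf(self, rng):
        pct = learn_pct(rng.gamma(2, 5, (4, 4, 4)), 2, -1e6)
        assert pct_lookup(pct, "CA") is pct.leaves[0]

    def test_reference_partition_tree(self):
        """A hand-built depth-2 tree with the context sets
        {AA},{CA,GA},{TA},{AC,AG,AT,GC,GG,GT},{CC,CG,CT,TC,TG,TT}."""
        from parsimotif.markov import PCTLeaf

        A, C, G, T = range(4)
        # layer 1 = nearest predecessor (the word's last letter)
        paths = [
            ((A,), (A,)),
            ((A,), (C, G)),
            ((A,), (T,)),
            ((C, G, T), (A, G)),
            ((C, G, T), (C, T)),
        ]
        leaves = [
            PCTLeaf(p, np.ones(4), 0.25, np.full(4, 0.25)) for p in paths
        ]
        pct = PCT(depth=2, leaves=leaves, score=0.0, log2_kappa=0.0, ess=4.0)
        assert pct_lookup(pct, "CA") is leaves[1]
        assert pct_lookup(pct, "GA") is leaves[1]
        assert pct_lookup(pct, "AA") is leaves[0]
        assert pct_lookup(pct, "GT") is leaves[3]
        assert pct_lookup(pct, "CT") is leaves[4]

    def test_maximal_tree_singleton(self, rng):
        pct = learn_pct(rng.gamma(2, 5, (4, 4, 4)), 2, 1e6)
        leaf = pct_lookup(pct, "AG")
        assert leaf.context_words() == [(2, 0)]  # layer order: G (nearest), A

    def test_wrong_length_rejected(self, rng):
        pct = learn_pct(rng.gamma(2, 5, (4, 4, 4)), 2, 0.0)
        with pytest.raises(ValueError):
            pct_lookup(pct, "A")


# ---------------------------------------------------------------------------
# inhomogeneous PMM
# ---------------------------------------------------------------------------


def enumerate_words(width):
    return np.array(list(itertools.product(range(4), repeat=width)), dtype=np.int64)


class TestPMM:
    def test_pwm_limit_leaf_count(self, rng):
        sites = rng.integers(0, 4, (40, 20))
        pmm = fit_pmm(sites, 20, 4, log2_kappa=-1e6)
        assert leaf_statistics(pmm)[1] == 20

    def test_width1(self, rng):
        sites = rng.integers(0, 4, (30, 1))
        pmm = fit_pmm(sites, 1, 4, log2_kappa=0.0, ess=4.0)
        counts = np.bincount(sites[:, 0], minlength=4)
        expected = (counts + 1.0) / (30 + 4.0)
        np.testing.assert_allclose(pmm.pcts[0].leaves[0].theta, expected, atol=1e-12)

    def test_normalization_small_width(self, rng):
        sites = rng.integers(0, 4, (60, 3))
        pmm = fit_pmm(sites, 3, 2, log2_kappa=-2.0)
        total = np.exp(pmm.log_prob_words(enumerate_words(3))).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_depth_rule(self, rng):
        pmm = fit_pmm(rng.integers(0, 4, (30, 6)), 6, 4, -2.0)
        assert [p.depth for p in pmm.pcts] == [0, 1, 2, 3, 4, 4]

    def test_hand_chain_product_depth1(self):
        sites = ["ACG", "ACG", "ATG", "GCG"]
        pmm = fit_pmm(sites, 3, 1, log2_kappa=1e6, ess=0.004)
        # near-zero smoothing: thetas approach conditional relative frequencies
        got = pmm_log_prob(pmm, "ACG")
        manual = math.log(3 / 4) + math.log(2 / 3) + math.log(1.0)
        assert got == pytest.approx(manual, abs=1e-2)

    def test_pwm_limit_equals_direct_pwm(self, rng):
        """kappa -> -inf reproduces smoothed column-frequency likelihoods."""
        W, ess = 8, 4.0
        sites = rng.integers(0, 4, (50, W))
        weights = rng.random(50) * 2
        pmm = fit_pmm(sites, W, 4, log2_kappa=-1e6, ess=ess, weights=weights)
        words = rng.integers(0, 4, (20, W))
        direct = np.zeros(20)
        for i in range(W):
            cnt = np.bincount(sites[:, i], weights=weights, minlength=4)
            probs = (cnt + ess / 4) / (cnt.sum() + ess)
            direct += np.log(probs[words[:, i]])
        np.testing.assert_allclose(pmm.log_prob_words(words), direct, atol=1e-12)

    def test_wam_limit_equals_direct_order1(self, rng):
        """kappa -> +inf at order 1 reproduces the weight array model."""
        W, ess = 8, 4.0
        sites = rng.integers(0, 4, (50, W))
        weights = rng.random(50) * 2
        pmm = fit_pmm(sites, W, 1, log2_kappa=1e6, ess=ess, weights=weights)
        words = rng.integers(0, 4, (20, W))
        direct = np.zeros(20)
        cnt0 = np.bincount(sites[:, 0], weights=weights, minlength=4)
        direct += np.log((cnt0 + ess / 4) / (cnt0.sum() + ess))[words[:, 0]]
        for i in range(1, W):
            cnt = np.zeros((4, 4))
            np.add.at(cnt, (sites[:, i - 1], sites[:, i]), weights)
            probs = (cnt + ess / 16) / (cnt.sum(axis=1, keepdims=True) + ess / 4)
            direct += np.log(probs[words[:, i - 1], words[:, i]])
        np.testing.assert_allclose(pmm.log_prob_words(words), direct, atol=1e-12)

    def test_leaf_statistics_consistency(self, rng):
        pmm = fit_pmm(rng.integers(0, 4, (40, 5)), 5, 4, 1e6)
        per_pos, total = leaf_statistics(pmm)
        assert total == sum(n for _, n in per_pos)
        assert total == 1 + 4 + 16 + 64 + 256

    def test_json_roundtrip(self, rng, tmp_path):
        pmm = fit_pmm(rng.integers(0, 4, (30, 4)), 4, 2, -2.0)
        path = tmp_path / "pmm.json"
        pmm.to_json(path)
        back = InhomogeneousPMM.from_json(path)
        words = rng.integers(0, 4, (10, 4))
        np.testing.assert_allclose(
            pmm.log_prob_words(words), back.log_prob_words(words), atol=1e-12
        )

    def test_wrong_site_length_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pmm(rng.integers(0, 4, (10, 5)), 4, 2, 0.0)
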