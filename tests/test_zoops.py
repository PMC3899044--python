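"""Tests for the ZOOPS mixture and the MAP-EM discovery algorithm."""

import itertools
import math

import numpy as np
import pytest

from parsimotif._seq import decode, encode, revcomp_codes
from parsimotif.io import SequenceRecord
from parsimotif.markov import fit_homogeneous_mm, fit_pmm
from parsimotif.simulate import default_dependent_motif, make_benchmark, BenchmarkConfig, plant_zoops, sample_background
from parsimotif.zoops import (
    MotifDiscovery,
    ZOOPSConfig,
    ZOOPSModel,
    e_step,
    fit_zoops_em,
    m_step,
    zoops_log_likelihood,
    zoops_log_likelihood_many,
)


def brute_force_zoops(model: ZOOPSModel, seq: str) -> float:
    """Independent oracle: explicit sum over all latent configurations."""
    flank = model.flanking
    codes = encode(seq)
    L, W = codes.size, model.width
    total = (1 - model.gamma) * math.exp(flank.log_prob(codes))
    n = L - W + 1
    for ell in range(max(n, 0)):
        for strand in (0, 1):
            word = codes[ell : ell + W]
            if strand:
                word = revcomp_codes(word)
            p_site = math.exp(model.motif.log_prob_words(word[None, :])[0])
            pre = math.exp(flank.log_prob(codes, 0, ell))
            post = math.exp(flank.log_prob(codes, ell + W, L))
            p_s = model.strand_prob if strand == 0 else 1 - model.strand_prob
            total += model.gamma / n * p_s * pre * p_site * post
    if n <= 0:
        total = math.exp(flank.log_prob(codes))
    return math.log(total)


@pytest.fixture
def toy_zoops(toy_flank, rng):
    motif = fit_pmm(rng.integers(0, 4, (30, 2)), 2, 1, log2_kappa=-2.0)
    return ZOOPSModel(motif, toy_flank, gamma=0.6, strand_prob=0.5)


class TestZOOPSLikelihood:
    def test_gamma_zero_equals_flanking(self, toy_zoops):
        model = ZOOPSModel(toy_zoops.motif, toy_zoops.flanking, gamma=0.0)
        for seq in ("ACGTA", "GGGG", "TTACG"):
            assert zoops_log_likelihood(model, seq) == pytest.approx(
                model.flanking.log_prob(seq), abs=1e-12
            )

    @pytest.mark.parametrize("seq", ["ACG", "GGT", "ACGTT", "TTAGCA"])
    def test_matches_bruteforce_enumeration(self, toy_zoops, seq):
        assert zoops_log_likelihood(toy_zoops, seq) == pytest.approx(
            brute_force_zoops(toy_zoops, seq), abs=1e-10
        )

    def test_total_probability_sums_to_one(self, toy_zoops):
        total = sum(
            math.exp(zoops_log_likelihood(toy_zoops, decode(np.array(w))))
            for w in itertools.product(range(4), repeat=4)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_short_sequence_forces_no_occurrence(self, toy_zoops):
        assert zoops_log_likelihood(toy_zoops, "A") == pytest.approx(
            toy_zoops.flanking.log_prob("A"), abs=1e-12
        )

    def test_json_roundtrip(self, toy_zoops, tmp_path):
        path = tmp_path / "model.json"
        toy_zoops.to_json(path, metadata={"seed": 1})
        back = ZOOPSModel.from_json(path)
        for seq in ("ACGTT", "GGATC"):
            assert zoops_log_likelihood(back, seq) == pytest.approx(
                zoops_log_likelihood(toy_zoops, seq), abs=1e-12
            )


class TestESTep:
    def test_gamma_zero_all_mass_on_r0(self, toy_zoops, records_factory):
        model = ZOOPSModel(toy_zoops.motif, toy_zoops.flanking, gamma=0.0)
        resp = e_step(model, records_factory(["ACGTT", "GGATC"]))
        np.testing.assert_allclose(resp.r0, 1.0)

    def test_masses_sum_to_one(self, toy_zoops, records_factory):
        resp = e_step(toy_zoops, records_factory(["ACGTT", "GGATCAG", "ACT"]))
        for r0, site in zip(resp.r0, resp.site):
            assert r0 + site.sum() == pytest.approx(1.0, abs=1e-9)

    def test_near_deterministic_motif_localized(self, toy_flank):
        # near-deterministic width-3 motif GGT planted in one place
        sites = np.array([[2, 2, 3]] * 200)
        motif = fit_pmm(sites, 3, 1, log2_kappa=-2.0, ess=0.04)
        model = ZOOPSModel(motif, toy_flank, gamma=1.0)
        resp = e_step(model, [SequenceRecord(id="x", seq="ACAGGTACA")])
        site = resp.site[0]
        assert site[3, 0] >= 0.99  # window starting at 0-based 3, forward

    def test_posteriors_match_bruteforce(self, toy_zoops, records_factory):
        recs = records_factory(["ACGTT"])
        resp = e_step(toy_zoops, recs)
        codes = encode("ACGTT")
        flank, motif = toy_zoops.flanking, toy_zoops.motif
        L, W = 5, 2
        n = L - W + 1
        weights = {}
        w0 = (1 - toy_zoops.gamma) * math.exp(flank.log_prob(codes))
        for ell in range(n):
            for strand in (0, 1):
                word = codes[ell : ell + W]
                if strand:
                    word = revcomp_codes(word)
                weights[(ell, strand)] = (
                    toy_zoops.gamma / n * 0.5
                    * math.exp(flank.log_prob(codes, 0, ell))
                    * math.exp(motif.log_prob_words(word[None, :])[0])
                    * math.exp(flank.log_prob(codes, ell + W, L))
                )
        total = w0 + sum(weights.values())
        assert resp.r0[0] == pytest.approx(w0 / total, abs=1e-10)
        for (ell, strand), w in weights.items():
            assert resp.site[0][ell, strand] == pytest.approx(w / total, abs=1e-10)


class TestMStep:
    def test_r0_everywhere_gives_pseudocount_gamma(self, toy_flank, records_factory):
        recs = records_factory(["ACGTACG", "GGATCCA"])
        from parsimotif.zoops import Responsibilities

        resp = Responsibilities(r0=np.ones(2), site=[np.zeros((6, 2)), np.zeros((6, 2))])
        cfg = ZOOPSConfig(width=2, max_order=1)
        motif, gamma, _ = m_step(recs, resp, cfg, toy_flank)
        assert gamma == pytest.approx(1 / 4)  # (0 + 1) / (2 + 2)

    def test_unit_weights_equal_unweighted_fit(self, toy_flank, records_factory):
        # all mass on one window per sequence reproduces fit_pmm on those words
        from parsimotif.zoops import Responsibilities

        seqs = ["ACGTACG", "TTGGCCA", "CAGTACT"]
        recs = records_factory(seqs)
        W = 3
        resp = Responsibilities(r0=np.zeros(3), site=[])
        for s in seqs:
            site = np.zeros((len(s) - W + 1, 2))
            site[1, 0] = 1.0
            resp.site.append(site)
        cfg = ZOOPSConfig(width=W, max_order=2, log2_kappa=-2.0, em_score="marginal")
        motif, _, _ = m_step(recs, resp, cfg, toy_flank)
        direct = fit_pmm([s[1:4] for s in seqs], W, 2, -2.0)
        words = np.array(list(itertools.product(range(4), repeat=W)))
        np.testing.assert_allclose(
            motif.log_prob_words(words), direct.log_prob_words(words), atol=1e-10
        )

    def test_concentrated_responsibilities_recover_columns(self, toy_flank, rng):
        # plant identical sites; M-step with mass on the true windows
        from parsimotif.zoops import Responsibilities

        word = "GGTAC"
        seqs = []
        for _ in range(60):
            left = "".join("ACGT"[c] for c in rng.integers(0, 4, 6))
            right = "".join("ACGT"[c] for c in rng.integers(0, 4, 6))
            seqs.append(left + word + right)
        recs = [SequenceRecord(id=str(i), seq=s) for i, s in enumerate(seqs)]
        resp = Responsibilities(r0=np.zeros(60), site=[])
        for s in seqs:
            site = np.zeros((len(s) - 5 + 1, 2))
            site[6, 0] = 1.0
            resp.site.append(site)
        cfg = ZOOPSConfig(width=5, max_order=2, log2_kappa=-2.0)
        motif, gamma, _ = m_step(recs, resp, cfg, toy_flank)
        codes = encode(word)
        # the planted word should be by far the most probable
        lp = motif.log_prob_words(codes[None, :])[0]
        assert lp > math.log(0.5)


class TestEM:
    def test_trace_monotone_on_seeded_fixtures(self, toy_flank):
        for seed in range(3):
            bg = sample_background(25, (40, 60), seed=seed)
            spec = default_dependent_motif()
            recs, _ = plant_zoops(bg, spec, 0.9, 0.5, seed=seed + 100)
            flank = fit_homogeneous_mm(recs, 2, 4.0)
            cfg = ZOOPSConfig(width=20, max_order=2, log2_kappa=-3.0, restarts=1, max_iter=12, tol=0.0)
            _, trace = fit_zoops_em(recs, flank, cfg, seed=seed)
            lp = trace.log_posteriors
            assert all(b - a >= -1e-8 * max(1.0, abs(a)) for a, b in zip(lp, lp[1:]))

    def test_all_short_sequences_rejected(self, toy_flank):
        cfg = ZOOPSConfig(width=10, max_order=1)
        with pytest.raises(ValueError):
            fit_zoops_em([SequenceRecord(id="a", seq="ACGT")], toy_flank, cfg, seed=0)

    def test_recovers_planted_sites(self):
        """Discovery localizes planted sites up to the run's global
        shift/orientation (a ZOOPS motif is identifiable only up to both)."""
        from parsimotif.simulate import site_recovery

        cfg = BenchmarkConfig(n_pos=300, n_neg=300)
        ds, truth = make_benchmark(cfg, seed=11)
        flank = fit_homogeneous_mm(ds.positives + ds.negatives, 2, 4.0)
        res = MotifDiscovery(ds.positives, log2_kappa=-4.5, flanking=flank).fit(
            restarts=2, seed=7, max_iter=40, tol=1e-5
        )
        assert site_recovery(truth, ds.positives, res.site_map(), tol=1) >= 0.85

    def test_strand_symmetry_of_posteriors(self, toy_flank, rng):
        """With strand_prob = 0.5 and a strand-symmetric flanking model,
        reverse-complementing a sequence mirrors the site posteriors."""
        from parsimotif._seq import revcomp
        from parsimotif.markov import HomogeneousMarkovModel

        uniform_flank = HomogeneousMarkovModel(0, [np.zeros((1, 4))], ess=4.0)
        motif = fit_pmm(rng.integers(0, 4, (40, 4)), 4, 2, log2_kappa=-2.0)
        model = ZOOPSModel(motif, uniform_flank, gamma=0.7, strand_prob=0.5)
        seq = "ACGTTGACCATGAGGTT"
        rc = revcomp(seq)
        assert zoops_log_likelihood(model, seq) == pytest.approx(
            zoops_log_likelihood(model, rc), abs=1e-10
        )
        ra = e_step(model, [SequenceRecord(id="f", seq=seq)])
        rb = e_step(model, [SequenceRecord(id="r", seq=rc)])
        L, W = len(seq), 4
        assert ra.r0[0] == pytest.approx(rb.r0[0], abs=1e-10)
        for ell in range(L - W + 1):
            for s in (0, 1):
                assert ra.site[0][ell, s] == pytest.approx(
                    rb.site[0][L - W - ell, 1 - s], abs=1e-10
                )

    def test_summary_mentions_key_quantities(self):
        cfg = BenchmarkConfig(n_pos=40, n_neg=40, length_range=(60, 90))
        ds, _ = make_benchmark(cfg, seed=1)
        flank = fit_homogeneous_mm(ds.positives, 2, 4.0)
        res = MotifDiscovery(ds.positives, log2_kappa=-3.0, flanking=flank).fit(
            restarts=1, seed=0, max_iter=10, tol=1e-4
        )
        text = res.summary()
        assert "gamma" in text and "leaves" in text and "log2 kappa" in text
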