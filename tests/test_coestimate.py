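"""TKF91 machinery, the coestimation sampler, and the ΔBF test."""

import itertools
import math

import numpy as np
import pytest

from uca_testbed.coestimate import (
    CoestimationPriors,
    IndelModel,
    McmcParams,
    _Chain,
    _forward_and_sample,
    _mixture_P,
    decide,
    harmonic_mean_logml,
    pair_marginal_loglik,
    run_delta_bf_test,
    run_mcmc,
    tkf91_pair_hmm,
)
from uca_testbed.models import ReversibleEigensystem, get_model
from uca_testbed.phylo import parse_newick
from uca_testbed.seqs import SequenceSet, encode
from uca_testbed.simulate import evolve


class TestTkf91PairHmm:
    def test_transition_rows_sum_to_one(self):
        hmm = tkf91_pair_hmm(IndelModel(0.03, 0.04), 0.5)
        assert np.allclose(hmm.trans.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_time_limit_is_match_dominated(self):
        hmm = tkf91_pair_hmm(IndelModel(0.03, 0.04), 0.0)
        assert hmm.beta == 0.0
        assert hmm.alpha == 1.0
        assert hmm.trans[0, 0] == pytest.approx(1.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            IndelModel(0.05, 0.04)
        with pytest.raises(ValueError):
            IndelModel(0.0, 0.04)

    def test_stationary_length_is_geometric(self, rng):
        # forward-simulate the TKF91 birth-death chain (immortal link):
        # births at rate lam*(n+1), deaths at rate mu*n; the stationary
        # law of n is geometric with parameter lam/mu
        lam, mu = 0.6, 1.0
        n = 5
        n_events = 60_000
        burn = n_events // 10
        states = np.empty(n_events)
        weights = np.empty(n_events)  # exponential holding times
        for k in range(n_events):
            birth, death = lam * (n + 1), mu * n
            states[k] = n
            weights[k] = rng.exponential(1.0 / (birth + death))
            if rng.random() < birth / (birth + death):
                n += 1
            else:
                n -= 1
        states, weights = states[burn:], weights[burn:]
        kappa = lam / mu
        expected_mean = kappa / (1 - kappa)
        mean = float(np.average(states, weights=weights))
        assert abs(mean - expected_mean) < 0.12
        p0 = float(np.average(states == 0, weights=weights))
        assert abs(p0 - (1 - kappa)) < 0.02


def _enumerate_pair_marginal(s1, s2, model, indel, t):
    """Sum over all pair-HMM state sequences (independent oracle)."""
    c1, c2 = encode(s1), encode(s2)
    hmm = tkf91_pair_hmm(indel, t)
    P = _mixture_P(model, ReversibleEigensystem.from_model(model), t)
    pi = model.frequencies
    n, m = len(c1), len(c2)
    smap = {"M": 0, "D": 1, "I": 2}
    total = 0.0
    for nm in range(min(n, m) + 1):
        base = ["M"] * nm + ["D"] * (n - nm) + ["I"] * (m - nm)
        for perm in set(itertools.permutations(base)):
            prob, prev, i, j = 1.0, "M", 0, 0
            for st in perm:
                prob *= hmm.trans[smap[prev], smap[st]]
                if st == "M":
                    prob *= P[c1[i], c2[j]]
                    i, j = i + 1, j + 1
                elif st == "D":
                    i += 1
                else:
                    prob *= pi[c2[j]]
                    j += 1
                prev = st
            total += prob * hmm.end[smap[prev]]
    kappa = indel.kappa
    root = (1 - kappa) * kappa**n * float(np.prod(pi[c1])) if n else (1 - kappa)
    return math.log(total * root)


class TestPairMarginal:
    indel = IndelModel(0.05, 0.08)

    def test_two_empty_sequences_hand_calculation(self, lg_gamma):
        got = pair_marginal_loglik("", "", lg_gamma, self.indel, 0.7)
        hmm = tkf91_pair_hmm(self.indel, 0.7)
        assert got == pytest.approx(
            math.log(1 - self.indel.kappa) + math.log(1 - hmm.beta), abs=1e-12
        )

    @pytest.mark.parametrize("s1,s2", [("A", ""), ("", "AR"), ("AR", "A"),
                                       ("ARN", "RNC"), ("AA", "AAA")])
    def test_matches_exhaustive_enumeration(self, s1, s2, lg_gamma):
        got = pair_marginal_loglik(s1, s2, lg_gamma, self.indel, 0.6)
        want = _enumerate_pair_marginal(s1, s2, lg_gamma, self.indel, 0.6)
        assert got == pytest.approx(want, abs=1e-10)

    def test_marginal_at_least_best_single_alignment(self, lg_gamma):
        # log-sum over alignments can never be below the single best path
        s1, s2 = "ARN", "ARC"
        c1, c2 = encode(s1), encode(s2)
        hmm = tkf91_pair_hmm(self.indel, 0.6)
        P = _mixture_P(lg_gamma, ReversibleEigensystem.from_model(lg_gamma), 0.6)
        pi = lg_gamma.frequencies
        # best = all-match path
        best = math.log(1 - self.indel.kappa) + 3 * math.log(self.indel.kappa)
        best += float(np.log(pi[c1]).sum())
        best += 3 * math.log(hmm.trans[0, 0]) + math.log(hmm.end[0])
        best += float(np.log(P[c1, c2]).sum())
        assert pair_marginal_loglik(s1, s2, lg_gamma, self.indel, 0.6) >= best


class TestPathSampler:
    def test_sampled_paths_match_enumerated_posterior(self, lg_gamma, rng):
        """Stochastic traceback draws exactly from P(path | both sequences)."""
        indel = IndelModel(0.08, 0.12)
        t = 0.8
        c1, c2 = encode("AR"), encode("RN")
        hmm = tkf91_pair_hmm(indel, t)
        P = _mixture_P(lg_gamma, ReversibleEigensystem.from_model(lg_gamma), t)
        pi = lg_gamma.frequencies
        emm = P[np.ix_(c1, c2)]
        emi = pi[c2]

        # enumerate the exact conditional distribution over paths
        smap = {"M": 0, "D": 1, "I": 2}
        probs = {}
        for nm in range(3):
            base = ["M"] * nm + ["D"] * (2 - nm) + ["I"] * (2 - nm)
            for perm in set(itertools.permutations(base)):
                prob, prev, i, j = 1.0, "M", 0, 0
                for st in perm:
                    prob *= hmm.trans[smap[prev], smap[st]]
                    if st == "M":
                        prob *= emm[i, j]; i += 1; j += 1
                    elif st == "D":
                        i += 1
                    else:
                        prob *= emi[j]; j += 1
                    prev = st
                probs[perm] = prob * hmm.end[smap[prev]]
        z = sum(probs.values())
        exact = {k: v / z for k, v in probs.items()}

        n_draws = 20_000
        counts = {}
        for _ in range(n_draws):
            _, path = _forward_and_sample(c1, c2, P, pi, hmm.trans, hmm.end,
                                          rng.random(len(c1) + len(c2) + 2))
            key = tuple("MDI"[s] for s in path)
            counts[key] = counts.get(key, 0) + 1
        for key, p in exact.items():
            if p < 5e-4:
                continue
            observed = counts.get(key, 0) / n_draws
            se = math.sqrt(p * (1 - p) / n_draws)
            assert abs(observed - p) < 3.5 * se, (key, observed, p)


class TestHarmonicMean:
    def test_constant_trace(self):
        assert harmonic_mean_logml(np.full(5, -100.0)) == pytest.approx(-100.0)

    def test_two_sample_closed_form(self):
        got = harmonic_mean_logml(np.array([-10.0, -20.0]))
        want = -(np.logaddexp(10.0, 20.0) - math.log(2))
        assert got == pytest.approx(want, abs=1e-12)

    def test_bounded_by_max_sample(self, rng):
        ll = rng.normal(-50, 5, size=200)
        assert harmonic_mean_logml(ll) <= ll.max()

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_logml(np.array([-1.0]), burn_in=1)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (10.001, "UCA"),
            (9.999, "inconclusive"),
            (-9.999, "inconclusive"),
            (-10.001, "IO"),
            (0.0, "inconclusive"),
        ],
    )
    def test_ten_unit_band(self, delta, expected):
        assert decide(delta) == expected


class TestMcmc:
    def test_same_seed_identical_traces(self, lg_gamma, rng):
        tree = parse_newick("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);")
        seqs = evolve(tree, lg_gamma, 60, rng)
        params = McmcParams(n_iter=60, thin=3)
        t1 = run_mcmc(seqs, tree, lg_gamma, params=params, seed=5)
        t2 = run_mcmc(seqs, tree, lg_gamma, params=params, seed=5)
        assert np.array_equal(t1.log_likelihood, t2.log_likelihood)
        assert np.array_equal(t1.alignment_length, t2.alignment_length)
        assert t1.to_tsv() == t2.to_tsv()

    def test_degapping_invariant_held_by_chain(self, lg_gamma, rng):
        tree = parse_newick("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);")
        seqs = evolve(tree, lg_gamma, 40, rng)
        chain = _Chain(seqs, tree, lg_gamma, CoestimationPriors(), McmcParams(),
                       np.random.default_rng(2))
        for _ in range(30):
            chain.cycle()
        by_label = dict(seqs)
        for node in chain.postorder:
            if not chain.tree.children[node]:
                label = chain.tree.names[node]
                assert "".join("ARNDCQEGHILKMFPSTWYV"[c] for c in chain.seq[node]) == by_label[label]
        # cached branch terms must match a fresh recomputation
        for c in chain.branch_nodes:
            assert chain._branch_ll[c] == pytest.approx(chain._branch_loglik(c), abs=1e-8)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            McmcParams(n_iter=0)

    def test_mismatched_leaves_rejected(self, lg_gamma):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            run_mcmc(SequenceSet(["A", "C"], ["AR", "RN"]), tree, lg_gamma,
                     params=McmcParams(n_iter=2))


class TestDeltaBfTest:
    def test_empty_group_rejected(self, lg_gamma):
        seqs = SequenceSet(["A", "B"], ["AR", "RN"])
        with pytest.raises(ValueError):
            run_delta_bf_test(seqs, {"x": ["A", "B"], "y": []},
                              {"x": parse_newick("(A:0.1,B:0.1);")}, lg_gamma)

    def test_uca_positive_control(self, lg_gamma, rng):
        from uca_testbed.phylo import join_trees

        te = parse_newick("((E1:0.1,E2:0.1):0.05,(E3:0.1,E4:0.1):0.05);")
        tb = parse_newick("((B1:0.1,B2:0.1):0.05,(B3:0.1,B4:0.1):0.05);")
        seqs = evolve(join_trees(te, tb, 0.1), lg_gamma, 100, rng)
        groups = {"E": ["E1", "E2", "E3", "E4"], "B": ["B1", "B2", "B3", "B4"]}
        res = run_delta_bf_test(seqs, groups, {"E": te, "B": tb}, lg_gamma,
                                params=McmcParams(n_iter=400), seed=2)
        assert res.delta_bf > 10
        assert res.decision == "UCA"
        assert res.delta_bf_per_site == pytest.approx(
            res.delta_bf / res.posterior_median_alignment_length
        )
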