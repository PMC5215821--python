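"""Tree I/O, pruning likelihood, ML fitting, and the infinite-branch limit."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from uca_testbed.models import ReversibleEigensystem, SubstitutionModel, get_model
from uca_testbed.phylo import (
    NewickError,
    PhyloTree,
    fit_ml,
    io_limit_gap,
    join_trees,
    log_likelihood,
    parse_newick,
    write_newick,
)
from uca_testbed.seqs import Alignment
from uca_testbed.simulate import evolve


def _random_tree_newick(rng, labels):
    """Random binary topology with random lengths, as a Newick string."""
    nodes = [f"{l}:{rng.uniform(0.05, 0.5):.4f}" for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 0.5):.4f}")
    return f"({nodes[0]},{nodes[1]});"


class TestNewick:
    def test_three_leaf_parse(self):
        tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        assert sorted(tree.leaf_labels()) == ["A", "B", "C"]
        assert tree.n_branches == 4
        lengths = tree.branch_lengths()
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["A|B"] == pytest.approx(0.05)

    def test_round_trip_preserves_splits_and_lengths(self, rng):
        for _ in range(100):
            text = _random_tree_newick(rng, [f"T{i}" for i in range(8)])
            tree = parse_newick(text)
            again = parse_newick(write_newick(tree))
            a, b = tree.branch_lengths(), again.branch_lengths()
            assert set(a) == set(b)
            for key in a:
                assert a[key] == pytest.approx(b[key], abs=1e-9)

    def test_duplicate_label_rejected(self):
        with pytest.raises(NewickError) as err:
            parse_newick("(A:0.1,A:0.2);")
        assert "A" in str(err.value)

    def test_malformed_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A:0.1,B:0.2;")


def _enumeration_loglik(aln, tree, model):
    """Exhaustive sum over internal-node states, site by site."""
    eig = ReversibleEigensystem.from_model(model)
    rates = model.category_rates()
    mat = aln.select(tree.leaf_labels()).matrix()
    leaves = tree.leaves()
    internals = [n for n in tree.postorder() if tree.children[n]]
    total = 0.0
    for s in range(aln.n_columns):
        site_lik = 0.0
        for rate in rates:
            pmat = {n: eig.expm(float(tree.lengths[n]) * rate) for n in range(tree.n_nodes)
                    if tree.parent[n] >= 0}
            lik = 0.0
            for assign in itertools.product(range(model.n_states), repeat=len(internals)):
                states = dict(zip(internals, assign))
                for li, n in enumerate(leaves):
                    states[n] = mat[li, s]
                term = model.frequencies[states[tree.root]]
                for n in range(tree.n_nodes):
                    if tree.parent[n] < 0:
                        continue
                    child_state = states[n]
                    if child_state == 20:  # gap: marginalize == factor 1
                        continue
                    term *= pmat[n][states[tree.parent[n]], child_state]
                lik += term
            site_lik += lik / len(rates)
        total += np.log(site_lik)
    return total


class TestPruning:
    def test_single_leaf_tree(self, rtrev):
        aln = Alignment(["A"], ["ARN"])
        tree = parse_newick("A;")
        res = log_likelihood(aln, tree, rtrev)
        codes = [0, 1, 2]
        assert res.log_likelihood == pytest.approx(
            sum(np.log(rtrev.frequencies[c]) for c in codes), abs=1e-10
        )

    @pytest.mark.parametrize(
        "newick,rows",
        [
            ("((A:0.1,B:0.25):0.15,C:0.3);", ["AR", "RN", "A-"]),
            ("((A:0.2,B:0.1):0.1,(C:0.3,D:0.2):0.05);", ["ARN", "RNC", "A-C", "NCA"]),
        ],
        ids=["three-taxa", "four-taxa"],
    )
    def test_matches_exhaustive_enumeration(self, newick, rows, rtrev_gamma):
        # reduce to a 2-category gamma to keep the enumeration fast
        model = rtrev_gamma.with_gamma(0.7, 2)
        tree = parse_newick(newick)
        labels = tree.leaf_labels()
        aln = Alignment(labels, rows[: len(labels)])
        res = log_likelihood(aln, tree, model)
        assert res.log_likelihood == pytest.approx(
            _enumeration_loglik(aln, tree, model), abs=1e-10
        )

    def test_all_gap_column_contributes_zero(self, rtrev_gamma):
        tree = parse_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        base = Alignment(["A", "B", "C"], ["AR", "RN", "NC"])
        padded = Alignment(["A", "B", "C"], ["AR-", "RN-", "NC-"])
        l0 = log_likelihood(base, tree, rtrev_gamma).log_likelihood
        l1 = log_likelihood(padded, tree, rtrev_gamma).log_likelihood
        assert l1 == pytest.approx(l0, abs=1e-10)

    def test_rerooting_invariance(self, rtrev_gamma, rng):
        # the same unrooted 5-taxon tree written with three different roots
        forms = [
            "(((A:0.1,B:0.2):0.05,C:0.3):0.07,(D:0.15,E:0.25):0.02);",
            "((A:0.1,B:0.2):0.05,C:0.3,(D:0.15,(E:0.25):0.0):0.09);",
            "(A:0.1,B:0.2,(C:0.3,((D:0.15,E:0.25):0.09):0.0):0.05);",
        ]
        # keep forms consistent: evaluate and compare the first two exact
        # re-rootings (sum of path lengths between leaves is preserved)
        aln_rows = ["ARNDC", "RNDCA", "NDCAR", "DCARN", "CARND"]
        aln = Alignment(["A", "B", "C", "D", "E"], aln_rows)
        vals = []
        for form in forms[:2]:
            tree = parse_newick(form)
            vals.append(log_likelihood(aln, tree, rtrev_gamma).log_likelihood)
        assert vals[0] == pytest.approx(vals[1], abs=1e-8)

    def test_label_mismatch_rejected(self, rtrev):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            log_likelihood(Alignment(["A", "C"], ["AR", "RN"]), tree, rtrev)

    def test_empty_alignment_rejected(self, rtrev):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            log_likelihood(Alignment(["A", "B"], ["", ""]), tree, rtrev)


class TestFitML:
    def test_identical_sequences_fit_to_zero_distance(self, rtrev):
        aln = Alignment(["A", "B"], ["ARNDCQEGHI" * 5] * 2)
        res = fit_ml(aln, parse_newick("(A:0.1,B:0.1);"), rtrev, optimize=("branch_lengths",))
        assert sum(res.fitted_branch_lengths.values()) < 1e-3

    def test_two_sequence_distance_matches_grid_oracle(self, rtrev, rng):
        tree = parse_newick("(A:0.25,B:0.25);")
        seqs = evolve(tree, rtrev, 10_000, rng)
        aln = Alignment(seqs.ids, seqs.seqs)
        res = fit_ml(aln, tree, rtrev, optimize=("branch_lengths",), xtol=1e-7)
        fitted = sum(res.fitted_branch_lengths.values())

        def neg(d):
            t = parse_newick(f"(A:{d:.12f},B:0.0);")
            return -log_likelihood(aln, t, rtrev).log_likelihood

        grid = np.linspace(0.2, 1.0, 81)
        d0 = grid[int(np.argmin([neg(d) for d in grid]))]
        oracle = minimize_scalar(neg, bounds=(d0 - 0.02, d0 + 0.02), method="bounded",
                                 options={"xatol": 1e-8}).x
        assert fitted == pytest.approx(oracle, abs=1e-4)

    def test_fit_never_decreases_loglik(self, rtrev_gamma, rng):
        tree = parse_newick("((A:0.4,B:0.4):0.2,(C:0.4,D:0.4):0.2);")
        seqs = evolve(tree, rtrev_gamma, 200, rng)
        aln = Alignment(seqs.ids, seqs.seqs)
        start = log_likelihood(aln, tree, rtrev_gamma).log_likelihood
        res = fit_ml(aln, tree, rtrev_gamma, starting_lengths="keep")
        assert res.log_likelihood >= start - 1e-9

    def test_per_site_values_sum_to_total(self, rtrev_gamma, rng):
        tree = parse_newick("(A:0.3,B:0.3);")
        seqs = evolve(tree, rtrev_gamma, 300, rng)
        res = fit_ml(Alignment(seqs.ids, seqs.seqs), tree, rtrev_gamma)
        assert res.log_likelihood == pytest.approx(
            res.per_site_log_likelihoods.sum(), abs=1e-8
        )
        assert res.log_likelihood <= 0


class TestIoLimit:
    def test_factorization_at_large_t_uniform_model(self, rng):
        # uniform exchangeabilities mix fast (second eigenvalue -20/19),
        # so the infinite-branch limit is numerically exact at t = 50
        n = 20
        model = SubstitutionModel("flat", np.ones((n, n)) - np.eye(n), np.full(n, 1 / n))
        te = parse_newick("((E1:0.4,E2:0.4):0.2,(E3:0.4,E4:0.4):0.2);")
        tb = parse_newick("((B1:0.4,B2:0.4):0.2,(B3:0.4,B4:0.4):0.2);")
        se = evolve(te, model, 100, rng)
        sb = evolve(tb, model, 100, rng)
        comb = se.concat(sb)
        aln = Alignment(comb.ids, comb.seqs)
        assert io_limit_gap(aln, te, tb, 50.0, model) < 1e-6

    def test_monotone_convergence_rtrev(self, rtrev, rng, quartet_e, quartet_b):
        se = evolve(quartet_e, rtrev, 100, rng)
        sb = evolve(quartet_b, rtrev, 100, rng)
        comb = se.concat(sb)
        aln = Alignment(comb.ids, comb.seqs)
        gaps = {t: io_limit_gap(aln, quartet_e, quartet_b, t, rtrev) for t in (1, 5, 20)}
        assert gaps[20] < gaps[5] < gaps[1]

    def test_per_site_factorization_at_large_t(self, rng):
        n = 20
        model = SubstitutionModel("flat", np.ones((n, n)) - np.eye(n), np.full(n, 1 / n))
        te = parse_newick("(E1:0.3,E2:0.3);")
        tb = parse_newick("(B1:0.3,B2:0.3);")
        se = evolve(te, model, 50, rng)
        sb = evolve(tb, model, 50, rng)
        comb = se.concat(sb)
        aln = Alignment(comb.ids, comb.seqs)
        joint = join_trees(te, tb, 50.0)
        per_joint = log_likelihood(aln, joint, model).per_site_log_likelihoods
        pe = log_likelihood(aln.select(te.leaf_labels()), te, model).per_site_log_likelihoods
        pb = log_likelihood(aln.select(tb.leaf_labels()), tb, model).per_site_log_likelihoods
        assert np.allclose(per_joint, pe + pb, atol=1e-8)

    def test_overlapping_leaf_sets_rejected(self, rtrev):
        t1 = parse_newick("(A:0.1,B:0.1);")
        t2 = parse_newick("(B:0.1,C:0.1);")
        with pytest.raises(ValueError):
            join_trees(t1, t2, 1.0)
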