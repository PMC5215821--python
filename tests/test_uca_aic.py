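"""The fixed-alignment ΔAIC test and its alignment-induced bias."""

import numpy as np
import pytest

from uca_testbed.phylo import log_likelihood, parse_newick
from uca_testbed.seqs import Alignment
from uca_testbed.simulate import ScenarioConfig, generate_scenario, preset
from uca_testbed.uca_aic import (
    _criterion_score,
    delta_aic_per_site,
    run_uca_aic_test,
    split_alignment,
)


@pytest.fixture(scope="module")
def small_io_replicate():
    """One small independent-origins replicate (two quartets, 300 sites)."""
    cfg = preset("fig2-scaled", seed=17, n_replicates=1)
    cfg = ScenarioConfig(cfg.trees, cfg.model, 300, 1, seed=17, name="small")
    return cfg, next(generate_scenario(cfg))


@pytest.fixture(scope="module")
def true_topologies(small_io_replicate):
    from uca_testbed.experiment import _true_topologies

    cfg, _ = small_io_replicate
    return _true_topologies(cfg)


class TestSplitAlignment:
    def test_two_quartets_keep_all_columns(self):
        aln = Alignment([f"s{i}" for i in range(8)], ["ARNDC"] * 8)
        groups = {"x": [f"s{i}" for i in range(4)], "y": [f"s{i}" for i in range(4, 8)]}
        blocks = split_alignment(aln, groups)
        assert blocks["x"].n_rows == blocks["y"].n_rows == 4
        assert blocks["x"].n_columns == blocks["y"].n_columns == aln.n_columns

    def test_identity_partition(self):
        aln = Alignment(["a", "b"], ["AR", "ND"])
        blocks = split_alignment(aln, {"all": ["a", "b"]})
        assert blocks["all"].rows == aln.rows

    def test_non_partition_rejected(self):
        aln = Alignment(["a", "b"], ["AR", "ND"])
        with pytest.raises(ValueError):
            split_alignment(aln, {"x": ["a"]})
        with pytest.raises(ValueError):
            split_alignment(aln, {"x": ["a", "b"], "y": ["b"]})

    def test_all_gap_column_is_likelihood_neutral(self, rtrev_gamma):
        # a column gapped in every row of one block stays in that block but
        # contributes exactly zero, matching the column-dropped oracle
        tree = parse_newick("(a:0.2,b:0.3);")
        kept = Alignment(["a", "b"], ["AR-N", "RN-C"])
        dropped = Alignment(["a", "b"], ["ARN", "RNC"])
        l_kept = log_likelihood(kept, tree, rtrev_gamma).log_likelihood
        l_dropped = log_likelihood(dropped, tree, rtrev_gamma).log_likelihood
        assert l_kept == pytest.approx(l_dropped, abs=1e-10)


class TestUcaAicTest:
    def test_degenerate_partition_gives_exactly_zero(self, small_io_replicate):
        cfg, rep = small_io_replicate
        seqs = rep.groups["E"]
        topo = cfg.trees["E"]
        result = run_uca_aic_test(
            seqs, {"E": seqs.ids}, cfg.model, mode="unaligned",
            topologies={"E": topo},
        )
        assert result.delta_aic == 0.0
        assert result.decision == "IO"  # the tie is not evidence for one tree

    def test_io_replicate_unaligned_favors_io(self, small_io_replicate, true_topologies):
        cfg, rep = small_io_replicate
        result = run_uca_aic_test(
            rep.combined, cfg.groups, cfg.model, mode="unaligned",
            topologies=true_topologies,
        )
        assert result.delta_aic < 0
        assert result.decision == "IO"

    def test_io_replicate_aligned_favors_uca(self, small_io_replicate, true_topologies):
        cfg, rep = small_io_replicate
        result = run_uca_aic_test(
            rep.combined, cfg.groups, cfg.model, mode="aligned",
            topologies=true_topologies,
        )
        assert result.delta_aic > 0
        assert result.decision == "UCA"

    def test_aligned_delta_exceeds_unaligned_delta(self, small_io_replicate, true_topologies):
        cfg, rep = small_io_replicate
        deltas = {
            mode: run_uca_aic_test(
                rep.combined, cfg.groups, cfg.model, mode=mode,
                topologies=true_topologies,
            ).delta_aic
            for mode in ("aligned", "unaligned")
        }
        assert deltas["aligned"] > deltas["unaligned"]

    def test_group_order_invariance(self, small_io_replicate, true_topologies):
        cfg, rep = small_io_replicate
        g1 = {"B": cfg.groups["B"], "E": cfg.groups["E"]}
        g2 = {"E": cfg.groups["E"], "B": cfg.groups["B"]}
        r1 = run_uca_aic_test(rep.combined, g1, cfg.model, mode="unaligned",
                              topologies=true_topologies)
        r2 = run_uca_aic_test(rep.combined, g2, cfg.model, mode="unaligned",
                              topologies=true_topologies)
        assert r1.delta_aic == pytest.approx(r2.delta_aic, abs=1e-9)

    def test_information_criteria_agree_in_sign(self, small_io_replicate, true_topologies):
        cfg, rep = small_io_replicate
        result = run_uca_aic_test(rep.combined, cfg.groups, cfg.model, mode="aligned",
                                  topologies=true_topologies)
        n = result.n_columns
        jlabel = "BE"
        for criterion in ("AIC", "AICc", "BIC"):
            io_score = sum(
                _criterion_score(e.log_likelihood, e.k, n, criterion)
                for lab, e in result.entries.items() if lab != jlabel
            )
            joint = result.entries[jlabel]
            delta = io_score - _criterion_score(joint.log_likelihood, joint.k, n, criterion)
            assert np.sign(delta) == np.sign(result.delta_aic), criterion

    def test_parameter_count_bookkeeping(self, small_io_replicate, true_topologies):
        cfg, rep = small_io_replicate
        result = run_uca_aic_test(rep.combined, cfg.groups, cfg.model, mode="unaligned",
                                  topologies=true_topologies)
        # per quartet: 5 branches + gamma shape + 19 free frequencies (+F)
        assert result.entries["E"].k == 5 + 1 + 19
        # joint 8-taxon tree: 13 branches + gamma shape + 19 frequencies
        assert result.entries["BE"].k == 13 + 1 + 19
        for e in result.entries.values():
            assert e.score == pytest.approx(2 * e.k - 2 * e.log_likelihood)

    def test_bad_mode_rejected(self, small_io_replicate):
        cfg, rep = small_io_replicate
        with pytest.raises(ValueError):
            run_uca_aic_test(rep.combined, cfg.groups, cfg.model, mode="magic")


class TestDeltaAicPerSite:
    def test_recomputed_from_parts(self, small_io_replicate, true_topologies):
        cfg, rep = small_io_replicate
        result = run_uca_aic_test(rep.combined, cfg.groups, cfg.model, mode="unaligned",
                                  topologies=true_topologies)
        assert delta_aic_per_site(result) == pytest.approx(
            result.delta_aic / result.n_columns
        )
        assert result.delta_aic_per_site == pytest.approx(delta_aic_per_site(result))

    def test_zero_columns_rejected(self):
        from uca_testbed.uca_aic import UcaAicResult

        bad = UcaAicResult({}, 0.0, 0.0, 0, "unaligned", "AIC", "IO")
        with pytest.raises(ValueError):
            delta_aic_per_site(bad)
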