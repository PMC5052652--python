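"""Mk likelihood, ML model fits, RJMCMC, dependent model, stochastic maps."""

import numpy as np
import pytest

from conftest import enumerate_mk_loglik, random_tree
from ornamass import trees as T
from ornamass.discrete import (
    MkPruner,
    QMatrix,
    compare_mk_models,
    fit_dependent_discrete,
    fit_mk_ml,
    fossilize_bf,
    mk_loglik,
    rjmcmc_binary,
    stochastic_maps,
)
from ornamass.simulate import sim_bd_tree, sim_mk


class TestQMatrix:
    def test_rows_sum_to_zero(self):
        Q = QMatrix.binary(0.3, 0.7)
        assert Q.matrix.sum(axis=1) == pytest.approx([0, 0])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            QMatrix.binary(-0.1, 0.2)

    def test_dependent_forbids_double_transitions(self):
        rates = {k: 0.1 for k in
                 ("gainA_B0", "gainA_B1", "lossA_B0", "lossA_B1",
                  "gainB_A0", "gainB_A1", "lossB_A0", "lossB_A1")}
        Q = QMatrix.dependent(rates)
        # 00 <-> 11 and 01 <-> 10 are structural zeros
        assert Q.matrix[0, 3] == Q.matrix[3, 0] == 0
        assert Q.matrix[1, 2] == Q.matrix[2, 1] == 0

    def test_stationary_distribution(self):
        Q = QMatrix.binary(0.2, 0.1)
        pi = Q.stationary()
        assert pi == pytest.approx([1 / 3, 2 / 3])


class TestMkLoglik:
    def test_zero_rate_all_same_state(self, three_tip):
        states = {"A": 0, "B": 0, "C": 0}
        ll = mk_loglik(three_tip, states, QMatrix.binary(0.0, 0.0),
                       root=(1.0, 0.0))
        assert ll == pytest.approx(0.0)

    def test_two_tip_closed_form(self):
        # symmetric rate q, opposite tip states, flat root:
        # L = 2 * 0.5 * P00(t) * P01(t) with P01 = (1 - e^{-2qt}) / 2
        q, t = 0.07, 3.0
        tree = T.parse_newick(f"(A:{t},B:{t});")
        ll = mk_loglik(tree, {"A": 0, "B": 1}, QMatrix.binary(q, q), root="flat")
        e = np.exp(-2 * q * t)
        p01 = (1 - e) / 2
        p00 = (1 + e) / 2
        assert ll == pytest.approx(np.log(p00 * p01 + p01 * p00) + np.log(0.5))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        tree = random_tree(6, seed=300 + seed)
        states, _ = sim_mk(tree, QMatrix.binary(0.05, 0.02), seed=seed)
        Q = QMatrix.binary(0.04, 0.09)
        pruner = MkPruner(tree, states)
        for root in ("flat", "empirical", "stationary"):
            freq = pruner.root_freq(Q, root)
            got = mk_loglik(tree, states, Q, root=root)
            want = enumerate_mk_loglik(tree, states, Q, freq)
            assert got == pytest.approx(want, abs=1e-10)

    def test_state_relabeling_invariance(self):
        tree = random_tree(10, seed=310)
        states, _ = sim_mk(tree, QMatrix.binary(0.05, 0.05), seed=311)
        flipped = {k: 1 - v for k, v in states.items()}
        Q = QMatrix.binary(0.03, 0.08)
        Qp = QMatrix.binary(0.08, 0.03)  # permuted to match the relabeling
        a = mk_loglik(tree, states, Q, root="flat")
        b = mk_loglik(tree, flipped, Qp, root="flat")
        assert a == pytest.approx(b, abs=1e-12)

    def test_unscored_tip_raises(self, three_tip):
        with pytest.raises(ValueError, match="unscored"):
            mk_loglik(three_tip, {"A": 0, "B": 1}, QMatrix.binary(0.1, 0.1))

    def test_fossilized_node_reduces_likelihood(self):
        tree = random_tree(12, seed=320)
        states, _ = sim_mk(tree, QMatrix.binary(0.02, 0.02), root_state=0,
                           seed=321)
        Q = QMatrix.binary(0.02, 0.02)
        free = mk_loglik(tree, states, Q)
        forced = mk_loglik(tree, states, Q, constraints={tree.root: 1})
        assert forced <= free + 1e-12


class TestFitMk:
    def test_er_sym_identical_for_binary(self, bd_tree, painted_tree):
        states, _ = painted_tree
        er = fit_mk_ml(bd_tree, states, "ER")
        sym = fit_mk_ml(bd_tree, states, "SYM")
        assert er.logL == pytest.approx(sym.logL, abs=1e-8)
        assert er.score.K == sym.score.K == 1

    def test_er_wins_on_er_data(self):
        wins = 0
        for rep in range(8):
            tree = sim_bd_tree(n_tips=150, birth=0.1, death=0.04,
                               seed=400 + rep)
            states, _ = sim_mk(tree, QMatrix.binary(0.02, 0.02),
                               seed=500 + rep)
            if not 5 < sum(states.values()) < 145:
                continue
            _, scores = compare_mk_models(tree, states)
            best = max(scores, key=lambda s: s.weight)
            wins += best.name in ("ER", "SYM")
        assert wins >= 6  # >= 70% of informative replicates

    def test_invariant_trait_flagged(self, bd_tree):
        states = {t: 0 for t in bd_tree.tip_labels}
        fit = fit_mk_ml(bd_tree, states, "ER")
        assert fit.boundary_flag
        assert fit.q01 <= 1e-6


class TestRJMCMC:
    def test_equal_rates_data_prefers_one_parameter(self):
        tree = sim_bd_tree(n_tips=120, birth=0.1, death=0.04, seed=600)
        states, _ = sim_mk(tree, QMatrix.binary(0.03, 0.03), seed=601)
        post = rjmcmc_binary(tree, states, iterations=12_000, thin=12,
                             burnin=2_000, seed=602)
        freq = post.model_frequencies()
        assert freq.get("one_rate", 0.0) > 0.5

    def test_asymmetric_data_raises_two_parameter_mass(self):
        tree = sim_bd_tree(n_tips=200, birth=0.12, death=0.03, seed=610)
        states, _ = sim_mk(tree, QMatrix.binary(0.10, 0.01), root_state=0,
                           seed=611)
        post_asym = rjmcmc_binary(tree, states, iterations=12_000, thin=12,
                                  burnin=2_000, seed=612)
        f_asym = post_asym.model_frequencies()
        assert f_asym.get("two_rate", 0.0) > f_asym.get("one_rate", 1.0) * 0.5

    def test_fixed_mode_reproducible_and_traceable(self, bd_tree, painted_tree):
        states, _ = painted_tree
        a = rjmcmc_binary(bd_tree, states, iterations=1_500, thin=5,
                          burnin=300, seed=7, fixed_model="ER")
        b = rjmcmc_binary(bd_tree, states, iterations=1_500, thin=5,
                          burnin=300, seed=7, fixed_model="ER")
        assert np.array_equal(a.logL_trace, b.logL_trace)
        assert (a.draws.model == "one_rate").all()
        assert np.isfinite(a.logL_trace).all()


class TestDependentModel:
    def test_nested_independent_likelihood(self, bd_tree):
        # dependent Q with pairwise-equal rates == independent Q
        Qi = QMatrix.independent(0.03, 0.01, 0.05, 0.02)
        rates = {c: r for g, r in zip(
            ("gainA", "lossA", "gainB", "lossB"), (0.03, 0.01, 0.05, 0.02))
            for c in ((f"{g}_B0", f"{g}_B1") if g.endswith("A")
                      else (f"{g}_A0", f"{g}_A1"))}
        Qd = QMatrix.dependent(rates)
        combo, _ = sim_mk(bd_tree, Qi, seed=13)
        a = mk_loglik(bd_tree, combo, Qi, root="flat")
        b = mk_loglik(bd_tree, combo, Qd, root="flat")
        assert a == pytest.approx(b, abs=1e-8)

    def test_confounded_traits_warn(self, bd_tree, caplog):
        states = {t: i % 2 for i, t in enumerate(bd_tree.tip_labels)}
        import logging

        with caplog.at_level(logging.WARNING):
            fit_dependent_discrete(bd_tree, states, states, iterations=50,
                                   thin=1, burnin=10, seed=1)
        assert any("confounded" in r.message for r in caplog.records)


class TestFossilize:
    def test_same_state_both_chains_zero_bf(self, bd_tree, painted_tree):
        states, _ = painted_tree
        node = bd_tree.mrca(bd_tree.tip_labels[0], bd_tree.tip_labels[-1])
        a = rjmcmc_binary(bd_tree, states, iterations=1_200, thin=5,
                          burnin=200, seed=3, fixed_model="ER",
                          constraints={node: 0})
        from ornamass.model_eval import bayes_factor

        res = bayes_factor(a.logL_trace, a.logL_trace)
        assert res.bf == 0.0

    def test_known_ancestral_state_recovered(self):
        # rare gains from an unornamented root: the subtree is nearly all 0,
        # so forcing the root to 0 must be favored
        tree = sim_bd_tree(n_tips=80, birth=0.12, death=0.03, seed=620)
        states, _ = sim_mk(tree, QMatrix.binary(0.004, 0.004), root_state=0,
                           seed=623)
        assert sum(states.values()) < 40
        bf = fossilize_bf(tree, states,
                          (tree.tip_labels[0], tree.tip_labels[-1]),
                          forced_state=0, iterations=6_000, thin=6,
                          burnin=1_000, seed=624)
        assert bf.bf > 0


class TestStochasticMaps:
    def test_tiny_rate_single_regime(self, bd_tree):
        states = {t: 0 for t in bd_tree.tip_labels}
        maps = stochastic_maps(bd_tree, states, Q=QMatrix.binary(1e-8, 1e-8),
                               nmaps=3, seed=1)
        for m in maps:
            for v in m.preorder():
                if v.parent is not None:
                    assert all(s == 0 for s, _ in v.segments)

    def test_opposite_endpoints_force_change(self):
        tree = T.parse_newick("(A:2,B:2);")
        maps = stochastic_maps(tree, {"A": 0, "B": 1},
                               Q=QMatrix.binary(0.3, 0.3), nmaps=20, seed=2)
        for m in maps:
            changes = sum(len(v.segments) - 1 for v in m.preorder()
                          if v.parent is not None)
            assert changes >= 1

    def test_tip_segments_match_observed_states(self, bd_tree, painted_tree):
        states, _ = painted_tree
        maps = stochastic_maps(bd_tree, states, model="ER", nmaps=5, seed=3)
        for m in maps:
            for tip in m.tips():
                assert tip.segments[-1][0] == states[tip.label]

    def test_expected_changes_match_uniformization_oracle(self):
        # single branch, endpoints conditioned; compare the mean number of
        # changes across maps with the analytic expectation from the
        # uniformized jump distribution
        q, t = 0.25, 4.0
        tree = T.parse_newick(f"(A:{t},B:{t});")
        Q = QMatrix.binary(q, q)
        rng_maps = stochastic_maps(tree, {"A": 0, "B": 1}, Q=Q, nmaps=4000,
                                   seed=4)
        counts = []
        for m in rng_maps:
            for v in m.preorder():
                if v.parent is not None and v.label == "A":
                    counts.append(len(v.segments) - 1)
        got = np.mean(counts)

        # oracle: E[#real changes | a=0 -> b over t] via uniformization series
        from ornamass.discrete import transition_matrices

        omega = float(-Q.matrix.diagonal().min())
        R = np.eye(2) + Q.matrix / omega
        P = transition_matrices(Q.matrix, np.array([t]))[0]
        # root state posterior for the A-side branch
        # (endpoints: root state z, tip A state 0); weight by pruning:
        # p(z) prop pi_z * P[z,0] * P[z,1]
        pi = np.array([0.5, 0.5])
        w = pi * P[:, 0] * P[:, 1]
        w /= w.sum()

        def expected_real_changes(a, b):
            # E[# i: S_i != S_{i-1}] over the uniformized bridge
            tot_p, tot_e = 0.0, 0.0
            Rpows = [np.eye(2)]
            for _ in range(80):
                Rpows.append(Rpows[-1] @ R)
            logpois = -omega * t
            for n in range(80):
                pn = np.exp(logpois) * Rpows[n][a, b] / P[a, b]
                if n > 0 and Rpows[n][a, b] > 0:
                    # expected real jumps given n uniformized ones: simulate
                    # exactly by dynamic programming over the chain
                    e = 0.0
                    for i in range(1, n + 1):
                        # P(S_{i-1}=u, S_i=v | endpoints) for u != v
                        for u in range(2):
                            for v_ in range(2):
                                if u == v_:
                                    continue
                                p = (Rpows[i - 1][a, u] * R[u, v_]
                                     * Rpows[n - i][v_, b]) / Rpows[n][a, b]
                                e += p
                    tot_e += pn * e
                tot_p += pn
                logpois += np.log(omega * t) - np.log(n + 1)
            return tot_e / tot_p

        # average over the root-state posterior like the mapper does
        want = w[0] * expected_real_changes(0, 0) + w[1] * expected_real_changes(1, 0)
        se = np.std(counts) / np.sqrt(len(counts))
        assert got == pytest.approx(want, abs=4 * se + 0.02)
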