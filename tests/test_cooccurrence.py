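"""Loss-only CTMC machinery, pruning likelihood, ML fits, and the LRT."""

import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm
from scipy.stats import chi2

import phylocoev as pc
from phylocoev import synthetic_data as sd
from phylocoev.cooccurrence import (
    PAIR_STATES,
    _tip_partial_pair,
    expm_batched,
    pruning_loglik,
)
from tests.conftest import brute_force_loglik


def pair_states_of(traits, g1="gene1", g2="gene2"):
    return {
        sp: (
            None if np.isnan(traits.values.at[sp, g1]) else int(traits.values.at[sp, g1]),
            None if np.isnan(traits.values.at[sp, g2]) else int(traits.values.at[sp, g2]),
        )
        for sp in traits.species
    }


class TestGenerator:
    def test_rates_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            pc.LossGenerator.single(-0.1)
        with pytest.raises(ValueError):
            pc.LossGenerator.pair(q42=0.1, q43=-1, q31=0.1, q21=0.1)

    def test_generator_structure(self):
        Q = pc.LossGenerator.pair(q42=1, q43=2, q31=3, q21=4).Q()
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-15)
        # all gain entries exactly zero; (0,0) absorbing
        gains = [(1, 0), (2, 0), (3, 0), (3, 1), (3, 2), (1, 2), (2, 1)]
        assert all(Q[i, j] == 0.0 for i, j in gains)
        assert Q[3].tolist() == [0, 0, 0, 0]


class TestTransitionMatrix:
    def test_t_zero_is_identity(self):
        gen = pc.LossGenerator.pair(q42=0.5, q43=1.5, q31=2.0, q21=0.1)
        np.testing.assert_allclose(pc.transition_matrix(gen, 0.0), np.eye(4), atol=1e-14)

    def test_absorbing_state(self):
        gen = pc.LossGenerator.pair(q42=1, q43=1, q31=1, q21=1)
        P = pc.transition_matrix(gen, 3.7)
        np.testing.assert_allclose(P[3], [0, 0, 0, 1], atol=1e-14)

    def test_single_trait_closed_form(self):
        # P(present -> present) = exp(-beta t); at beta=1, t=ln 2 it is 1/2
        gen = pc.LossGenerator.single(1.0)
        P = pc.transition_matrix(gen, np.log(2.0))
        assert P[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert P[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            pc.transition_matrix(pc.LossGenerator.single(1.0), -0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_row_stochastic_and_semigroup(self, seed):
        """P(s) P(t) = P(s+t) and rows sum to 1 on random rates."""
        rng = np.random.default_rng(seed)
        gen = pc.LossGenerator.pair(*rng.uniform(0, 3, size=4))
        s, t = rng.uniform(0, 2, size=2)
        Ps, Pt, Pst = (pc.transition_matrix(gen, x) for x in (s, t, s + t))
        np.testing.assert_allclose(Ps.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(Ps @ Pt, Pst, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_batched_expm_matches_scipy(self, seed):
        """Includes the coincident-eigenvalue degeneracy q42+q43 = q31."""
        rng = np.random.default_rng(seed)
        q42, q43 = rng.uniform(0, 2, 2)
        gens = [
            pc.LossGenerator.pair(q42, q43, q31=q42 + q43, q21=rng.uniform(0, 2)),
            pc.LossGenerator.pair(*rng.uniform(0, 5, 4)),
        ]
        ts = rng.uniform(0, 8, size=6)
        for gen in gens:
            A = gen.Q()[None, :, :] * ts[:, None, None]
            got = expm_batched(A)
            want = np.stack([scipy_expm(gen.Q() * t) for t in ts])
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestPruningLoglik:
    def test_one_tip_closed_form(self):
        # single branch t=1 below the 2-tip crown is awkward; use a cherry
        # where one tip is missing so only A's branch informs the likelihood
        phy = pc.parse_newick("(A:1,B:1);")
        gen = pc.LossGenerator.single(1.0)
        lnl = pruning_loglik(phy, {"A": 1, "B": None}, gen)
        assert lnl == pytest.approx(-1.0, abs=1e-12)

    def test_all_present_zero_rate_gives_probability_one(self, yule20):
        gen = pc.LossGenerator.single(0.0)
        lnl = pruning_loglik(yule20, {t: 1 for t in yule20.tip_labels}, gen)
        assert lnl == pytest.approx(0.0, abs=1e-12)

    def test_impossible_data_is_minus_inf(self):
        # gene observed present below a lineage where it cannot be regained
        phy = pc.parse_newick("(A:1,B:1);")
        gen = pc.LossGenerator.single(0.0)  # no loss possible, root present
        assert pruning_loglik(phy, {"A": 0, "B": 1}, gen) == -np.inf

    def test_missing_tip_raises(self, three_tip_tree):
        gen = pc.LossGenerator.single(1.0)
        with pytest.raises(KeyError, match="C"):
            pruning_loglik(three_tip_tree, {"A": 1, "B": 0}, gen)

    @pytest.mark.parametrize("n_tips", [3, 4, 5, 6])
    def test_matches_brute_force_enumeration(self, n_tips):
        """Pruning equals the sum over internal-state assignments."""
        rng = np.random.default_rng(n_tips)
        for _ in range(8):
            phy = sd.simulate_yule_tree(n_tips, 1.0, seed=int(rng.integers(2**31)))
            gen = pc.LossGenerator.pair(*rng.uniform(0, 2, 4))
            traits = sd.simulate_trait_pair(phy, gen, seed=int(rng.integers(2**31)))
            states = pair_states_of(traits)
            got = pruning_loglik(phy, states, gen)
            want = brute_force_loglik(phy, states, gen)
            assert got == pytest.approx(want, rel=1e-10)

    def test_missing_states_match_brute_force(self):
        phy = sd.simulate_yule_tree(5, 1.0, seed=11)
        gen = pc.LossGenerator.pair(0.4, 0.8, 1.2, 0.3)
        states = {t: ((1, 0), (None, 1), (0, None), (None, None), (1, 1))[i]
                  for i, t in enumerate(phy.tip_labels)}
        got = pruning_loglik(phy, states, gen)
        want = brute_force_loglik(phy, states, gen)
        assert got == pytest.approx(want, rel=1e-10)


class TestTipPartials:
    def test_pair_partial_marginalizes_missing(self):
        np.testing.assert_array_equal(_tip_partial_pair(1, None), [1, 1, 0, 0])
        np.testing.assert_array_equal(_tip_partial_pair(None, None), [1, 1, 1, 1])
        np.testing.assert_array_equal(_tip_partial_pair(0, 0), [0, 0, 0, 1])
        assert PAIR_STATES[0] == (1, 1)


@pytest.fixture(scope="module")
def sim40():
    phy = sd.simulate_yule_tree(40, 1.0, seed=5)
    traits = sd.simulate_independent_traits(phy, 0.4, 0.6, seed=6)
    return phy, traits


class TestFits:
    def test_all_present_boundary(self, yule20):
        import pandas as pd

        df = pd.DataFrame(
            {"g1": 1.0, "g2": 1.0}, index=yule20.tip_labels, dtype=float
        )
        traits = pc.TraitMatrix(df)
        fit = pc.fit_independent(yule20, traits, "g1", "g2", restarts=3)
        assert fit.rate_estimates == {"beta1": 0.0, "beta2": 0.0}
        assert fit.log_likelihood == 0.0
        fit_d = pc.fit_dependent(yule20, traits, "g1", "g2", restarts=3)
        assert fit_d.log_likelihood == 0.0
        assert all(v == 0.0 for v in fit_d.rate_estimates.values())

    def test_independent_symmetric_in_gene_order(self, sim40):
        phy, traits = sim40
        f12 = pc.fit_independent(phy, traits, "gene1", "gene2", restarts=4, seed=1)
        f21 = pc.fit_independent(phy, traits, "gene2", "gene1", restarts=4, seed=1)
        assert f12.log_likelihood == pytest.approx(f21.log_likelihood, abs=1e-6)
        assert f12.rate_estimates["beta1"] == pytest.approx(
            f21.rate_estimates["beta2"], rel=1e-4
        )

    def test_refit_from_estimates_reproduces_loglik(self, sim40):
        phy, traits = sim40
        fit = pc.fit_independent(phy, traits, "gene1", "gene2", restarts=4, seed=1)
        lnl = 0.0
        for gene, beta in (("gene1", fit.rate_estimates["beta1"]),
                           ("gene2", fit.rate_estimates["beta2"])):
            gen = pc.LossGenerator.single(beta)
            states = {
                sp: None if np.isnan(traits.values.at[sp, gene])
                else int(traits.values.at[sp, gene])
                for sp in traits.species
            }
            lnl += pruning_loglik(phy, states, gen)
        assert lnl == pytest.approx(fit.log_likelihood, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_factorization_identity(self, seed):
        """Dependent lnL at q42=q31=b1, q43=q21=b2 equals independent lnL."""
        rng = np.random.default_rng(seed)
        phy = sd.simulate_yule_tree(25, 1.0, seed=seed)
        traits = sd.simulate_independent_traits(
            phy, rng.uniform(0.1, 0.8), rng.uniform(0.1, 0.8), seed=seed + 100
        )
        b1, b2 = rng.uniform(0.05, 1.0, 2)
        lnl_joint = pruning_loglik(
            phy, pair_states_of(traits), pc.LossGenerator.pair(b1, b2, b1, b2)
        )
        lnl_split = sum(
            pruning_loglik(
                phy,
                {sp: int(traits.values.at[sp, g]) for sp in traits.species},
                pc.LossGenerator.single(b),
            )
            for g, b in (("gene1", b1), ("gene2", b2))
        )
        assert lnl_joint == pytest.approx(lnl_split, abs=1e-8)

    def test_dependent_nests_independent(self, sim40):
        phy, traits = sim40
        fi = pc.fit_independent(phy, traits, "gene1", "gene2", restarts=4, seed=2)
        fd = pc.fit_dependent(phy, traits, "gene1", "gene2", restarts=4, seed=2,
                              independent_fit=fi)
        assert fd.log_likelihood >= fi.log_likelihood - 1e-6

    def test_asymmetric_loss_rates_recovered_in_order(self):
        """Gene1 lost much faster when gene2 is absent: q31_hat > q42_hat."""
        q31_hats, q42_hats = [], []
        for i in range(10):
            phy = sd.simulate_yule_tree(300, 1.0, seed=300 + i)
            gen = pc.LossGenerator.pair(q42=0.05, q43=0.3, q31=1.0, q21=0.3)
            traits = sd.simulate_trait_pair(phy, gen, seed=400 + i)
            fd = pc.fit_dependent(phy, traits, "gene1", "gene2", restarts=3, seed=i)
            q31_hats.append(fd.rate_estimates["q31"])
            q42_hats.append(fd.rate_estimates["q42"])
        assert np.median(q31_hats) > np.median(q42_hats)


class TestLRT:
    def test_constrained_fit_gives_lambda_zero_p_one(self):
        """When both models land on the same optimum, Lambda=0 and p=1."""
        phy = sd.simulate_yule_tree(30, 1.0, seed=9)
        traits = sd.simulate_independent_traits(phy, 0.3, 0.3, seed=10)
        fi = pc.fit_independent(phy, traits, "gene1", "gene2", restarts=4, seed=0)
        b1 = fi.rate_estimates["beta1"]
        b2 = fi.rate_estimates["beta2"]
        lnl_dep_constrained = pruning_loglik(
            phy, pair_states_of(traits), pc.LossGenerator.pair(b1, b2, b1, b2)
        )
        lam = 2 * (lnl_dep_constrained - fi.log_likelihood)
        assert max(lam, 0.0) == pytest.approx(0.0, abs=1e-8)
        assert chi2.sf(max(lam, 0.0), 2) == pytest.approx(1.0)

    def test_lrt_statistic_nonnegative_and_consistent(self):
        phy = sd.simulate_yule_tree(40, 1.0, seed=21)
        gen = pc.LossGenerator.pair(q42=0.05, q43=0.3, q31=1.5, q21=0.3)
        traits = sd.simulate_trait_pair(phy, gen, seed=22)
        res = pc.lrt_cooccurrence(phy, traits, "gene1", "gene2", restarts=4, seed=0)
        assert res.lrt_statistic >= 0
        assert res.df == 2
        assert res.lrt_statistic == pytest.approx(
            max(2 * (res.lnL_dependent - res.lnL_independent), 0.0)
        )
        assert res.p_value == pytest.approx(chi2.sf(res.lrt_statistic, 2))

    def test_power_under_strong_dependence(self):
        """q31/q42 = 50 on 200-tip trees: dependent model preferred."""
        ps = []
        for i in range(8):
            phy = sd.simulate_yule_tree(200, 1.0, seed=500 + i)
            gen = pc.LossGenerator.pair(q42=0.02, q43=0.3, q31=1.0, q21=0.3)
            traits = sd.simulate_trait_pair(phy, gen, seed=600 + i)
            res = pc.lrt_cooccurrence(phy, traits, "gene1", "gene2", restarts=3, seed=i)
            ps.append(res.p_value)
        assert np.median(ps) < 0.05

    def test_bonferroni_option(self):
        phy = sd.simulate_yule_tree(30, 1.0, seed=31)
        traits = sd.simulate_independent_traits(phy, 0.3, 0.3, seed=32)
        res = pc.lrt_cooccurrence(phy, traits, "gene1", "gene2",
                                  restarts=3, seed=0, n_tests=3)
        assert res.p_value_bonferroni == pytest.approx(min(res.p_value * 3, 1.0))

    def test_too_few_species_raises(self):
        import pandas as pd

        phy = pc.parse_newick("((A:1,B:1):0.5,C:1.5);")
        df = pd.DataFrame({"g1": [1.0, 0.0], "g2": [1.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match=">= 3"):
            pc.fit_independent(phy, pc.TraitMatrix(df), "g1", "g2")
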