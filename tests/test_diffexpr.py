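"""Two-group fit, empirical-Bayes moderation, BH, probe collapse, DE calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmark.diffexpr import (
    Contrast,
    ExpressionMatrix,
    InsufficientReplicationError,
    OCCURRENCE,
    PROGRESSION,
    PriorEstimationError,
    bh_adjust,
    collapse_probes,
    de_table,
    ebayes_moderate,
    fit_f_dist_prior,
    fit_two_group,
    select_de,
)


def brute_force_fit(values: pd.DataFrame, groups: pd.Series, contrast: Contrast):
    """Naive per-feature loops for log_fc and pooled variance."""
    a_cols = [s for s in values.columns if groups[s] in contrast.group_a]
    b_cols = [s for s in values.columns if groups[s] in contrast.group_b]
    out = {}
    for f in values.index:
        a = [values.at[f, s] for s in a_cols]
        b = [values.at[f, s] for s in b_cols]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        ss = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
        out[f] = (mb - ma, ss / (len(a) + len(b) - 2))
    return out


class TestFitTwoGroup:
    def test_constant_feature(self, two_group_matrix):
        fit = fit_two_group(two_group_matrix, OCCURRENCE)
        assert fit.loc["constant", "log_fc"] == 0.0
        assert fit.loc["constant", "s2"] == 0.0

    def test_exact_arithmetic_two_vs_two(self):
        values = pd.DataFrame({"a1": [1.0], "a2": [1.0], "b1": [3.0], "b2": [3.0]}, index=["f"])
        groups = pd.Series({"a1": "normal", "a2": "normal", "b1": "pPCa", "b2": "pPCa"})
        fit = fit_two_group(ExpressionMatrix(values, groups), Contrast("c", ("normal",), ("pPCa",)))
        assert fit.loc["f", "log_fc"] == 2.0
        assert fit.loc["f", "s2"] == 0.0
        assert fit.loc["f", "df_resid"] == 2.0

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(17)
        values = pd.DataFrame(
            rng.normal(size=(50, 12)),
            index=[f"f{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(12)],
        )
        groups = pd.Series(
            ["normal"] * 4 + ["pPCa"] * 5 + ["mPCa"] * 3, index=values.columns
        )
        m = ExpressionMatrix(values, groups)
        fit = fit_two_group(m, OCCURRENCE)
        oracle = brute_force_fit(values, groups, OCCURRENCE)
        for f, (lfc, s2) in oracle.items():
            assert fit.loc[f, "log_fc"] == pytest.approx(lfc)
            assert fit.loc[f, "s2"] == pytest.approx(s2)

    def test_insufficient_replication(self):
        values = pd.DataFrame(
            np.ones((3, 3)), index=list("fgh"), columns=["n1", "p1", "p2"]
        )
        groups = pd.Series({"n1": "normal", "p1": "pPCa", "p2": "pPCa"})
        with pytest.raises(InsufficientReplicationError):
            fit_two_group(ExpressionMatrix(values, groups), OCCURRENCE)


class TestEBayes:
    """The moment fit is cross-checked against the Bioconductor limma
    implementation on two deterministic fixtures; limma's outputs (lmFit +
    eBayes, two-group design) are frozen below."""

    @staticmethod
    def _heteroscedastic_fixture():
        rng = np.random.default_rng(321)
        n_feat, na, nb = 40, 4, 5
        s2g = 5.0 / rng.chisquare(5, n_feat)
        x = rng.normal(0, np.sqrt(s2g)[:, None], size=(n_feat, na + nb))
        x[:6, na:] += 2.0
        values = pd.DataFrame(
            x, index=[f"g{i:02d}" for i in range(n_feat)],
            columns=[f"s{i}" for i in range(na + nb)],
        )
        groups = pd.Series(["normal"] * na + ["pPCa"] * nb, index=values.columns)
        return ExpressionMatrix(values, groups)

    def test_matches_limma_on_heteroscedastic_fixture(self):
        m = self._heteroscedastic_fixture()
        fit = fit_two_group(m, Contrast("c", ("normal",), ("pPCa",)))
        prior, tab = ebayes_moderate(fit)
        assert prior.d0 == pytest.approx(4.0626515795, rel=1e-8)
        assert prior.s0_sq == pytest.approx(0.9022132200, rel=1e-8)
        frozen = {  # feature: (t, p) from limma
            "g00": (4.2883589482134, 0.001264344199317),
            "g03": (2.2208783255116, 0.048159822692347),
            "g37": (-2.7858133255715, 0.017632946278412),
        }
        for f, (t, p) in frozen.items():
            assert tab.loc[f, "t_mod"] == pytest.approx(t, rel=1e-9)
            assert tab.loc[f, "p_raw"] == pytest.approx(p, rel=1e-9)

    def test_unbounded_prior_matches_limma_on_homoscedastic_fixture(self):
        rng = np.random.default_rng(123)
        x = rng.normal(0, 1, size=(30, 11))
        x[:5, 5:] += 1.5
        values = pd.DataFrame(
            x, index=[f"f{i:02d}" for i in range(30)], columns=[f"s{i}" for i in range(11)]
        )
        groups = pd.Series(["normal"] * 5 + ["pPCa"] * 6, index=values.columns)
        fit = fit_two_group(ExpressionMatrix(values, groups), Contrast("c", ("normal",), ("pPCa",)))
        prior, tab = ebayes_moderate(fit)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.9531837495, rel=1e-8)
        assert np.allclose(prior.s_tilde_sq, prior.s0_sq)
        # limma t statistics with df.prior = Inf; p here follows the normal
        # limit of the t, whereas limma caps df at the pooled residual total,
        # so p agrees only approximately
        frozen = {"f00": (2.1669745181771, 0.03111128984129),
                  "f03": (2.8612872750041, 0.00454933417771)}
        from scipy import stats as sps
        for f, (t, p_limma) in frozen.items():
            assert tab.loc[f, "t_mod"] == pytest.approx(t, rel=1e-9)
            assert tab.loc[f, "p_raw"] == pytest.approx(2 * sps.norm.sf(abs(t)), rel=1e-9)
            assert tab.loc[f, "p_raw"] == pytest.approx(p_limma, rel=0.1)

    def test_d0_zero_recovers_ordinary_pooled_t(self):
        m = self._heteroscedastic_fixture()
        fit = fit_two_group(m, Contrast("c", ("normal",), ("pPCa",)))
        _, tab = ebayes_moderate(fit, d0=0.0)
        t_plain = fit["log_fc"] / np.sqrt(fit["s2"] * fit["v"])
        assert np.allclose(tab["t_mod"], t_plain)

    def test_moderated_t_limits(self):
        """d0 -> 0 gives the ordinary t; d0 -> inf gives the normal-limit z."""
        m = self._heteroscedastic_fixture()
        fit = fit_two_group(m, Contrast("c", ("normal",), ("pPCa",)))
        _, near_zero = ebayes_moderate(fit, d0=1e-8)
        _, plain = ebayes_moderate(fit, d0=0.0)
        assert np.allclose(near_zero["t_mod"], plain["t_mod"], rtol=1e-4)
        _, near_inf = ebayes_moderate(fit, d0=1e8)
        _, at_inf = ebayes_moderate(fit, d0=math.inf)
        assert np.allclose(near_inf["t_mod"], at_inf["t_mod"], rtol=1e-4)
        assert np.allclose(near_inf["p_raw"], at_inf["p_raw"], atol=1e-5)

    def test_shrunken_variance_between_prior_and_sample(self):
        m = self._heteroscedastic_fixture()
        fit = fit_two_group(m, Contrast("c", ("normal",), ("pPCa",)))
        prior, _ = ebayes_moderate(fit)
        lo = np.minimum(prior.s0_sq, fit["s2"])
        hi = np.maximum(prior.s0_sq, fit["s2"])
        assert ((prior.s_tilde_sq >= lo - 1e-12) & (prior.s_tilde_sq <= hi + 1e-12)).all()

    def test_moment_estimator_recovers_known_prior(self):
        """Variances drawn from s0^2 * F(d_g, d0) with d0=4, s0^2=1."""
        dg = 10.0
        for seed in range(20):
            r = np.random.default_rng(seed)
            s2 = (r.chisquare(dg, 200) / dg) / (r.chisquare(4.0, 200) / 4.0)
            d0, s0 = fit_f_dist_prior(s2, np.full(200, dg))
            assert 2.0 <= d0 <= 8.0
            assert 0.7 <= s0 <= 1.4

    def test_too_few_positive_variances(self):
        fit = pd.DataFrame(
            {"log_fc": [1.0] * 5, "s2": [0.0] * 5, "df_resid": [4.0] * 5, "v": [0.5] * 5}
        )
        with pytest.raises(PriorEstimationError):
            ebayes_moderate(fit)


class TestBHAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @staticmethod
    def step_up_oracle(p):
        """Textbook step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            q[i] = running
        return q

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_hand_rolled_step_up_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, self.step_up_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_permutation_equivariant(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        shuffled = [p[i] for i in idx]
        adj = bh_adjust(p)
        adj_shuffled = bh_adjust(shuffled)
        assert np.allclose([adj[i] for i in idx], adj_shuffled, atol=1e-12)

    def test_idempotent_on_adjusted_values(self):
        adj = bh_adjust([0.001, 0.01, 0.2, 0.9])
        again = bh_adjust(adj)
        assert (again >= adj - 1e-12).all()


class TestCollapseAndSelect:
    def _table(self):
        return pd.DataFrame(
            {
                "log_fc": [1.0, -2.0, 0.5, 3.0],
                "p_raw": [0.3, 0.001, 0.001, 0.5],
                "p_adj": [0.4, 0.004, 0.004, 0.6],
                "direction": ["Up", "Down", "Up", "Up"],
            },
            index=["pA", "pB", "pC", "pD"],
        )

    def test_one_probe_per_gene_rekeys_only(self):
        tab = self._table()
        out = collapse_probes(tab, {"pA": "G1", "pB": "G2", "pC": "G3", "pD": "G4"})
        assert sorted(out.index) == ["G1", "G2", "G3", "G4"]
        assert out.loc["G2", "log_fc"] == -2.0

    def test_smallest_raw_p_wins(self):
        tab = self._table()
        out = collapse_probes(tab, {"pA": "G", "pB": "G", "pD": "G", "pC": "H"})
        assert out.loc["G", "p_raw"] == 0.001 and out.loc["G", "log_fc"] == -2.0

    def test_tie_broken_by_larger_abs_logfc(self):
        tab = self._table()
        out = collapse_probes(tab, {"pB": "G", "pC": "G"})
        assert out.loc["G", "log_fc"] == -2.0  # |−2| beats |0.5| at equal p

    def test_matches_groupby_argmin_oracle(self):
        rng = np.random.default_rng(23)
        n = 60
        tab = pd.DataFrame(
            {
                "log_fc": rng.normal(size=n),
                "p_raw": rng.random(n),
                "p_adj": rng.random(n),
                "direction": ["Up"] * n,
            },
            index=[f"p{i}" for i in range(n)],
        )
        pmap = {f"p{i}": f"G{i % 17}" for i in range(n)}
        out = collapse_probes(tab, pmap)
        for gene, grp in tab.groupby([pmap[p] for p in tab.index]):
            best = grp["p_raw"].idxmin()
            assert out.loc[gene, "p_raw"] == tab.loc[best, "p_raw"]

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            collapse_probes(self._table(), {})

    def test_select_de_strict_inequality(self):
        tab = pd.DataFrame(
            {"p_adj": [0.05, 0.049, 1.0], "direction": ["Up", "Down", "Up"]},
            index=["at", "below", "none"],
        )
        assert select_de(tab) == {"below": "Down"}

    def test_all_insignificant_empty(self):
        tab = pd.DataFrame({"p_adj": [1.0, 1.0], "direction": ["Up", "Up"]}, index=["a", "b"])
        assert select_de(tab) == {}


class TestDETableEndToEnd:
    def test_de_table_invariants(self, two_group_matrix):
        # pad the matrix so the prior fit has enough features
        rng = np.random.default_rng(2)
        extra = pd.DataFrame(
            rng.normal(size=(30, 6)), columns=two_group_matrix.values.columns,
            index=[f"pad{i}" for i in range(30)],
        )
        m = ExpressionMatrix(
            pd.concat([two_group_matrix.values, extra]), two_group_matrix.groups
        )
        tab = de_table(m, PROGRESSION)
        assert ((tab["p_adj"] >= tab["p_raw"] - 1e-12)).all()
        assert ((tab["p_raw"] >= 0) & (tab["p_adj"] <= 1)).all()
        up = tab["log_fc"] >= 0
        assert (tab.loc[up, "direction"] == "Up").all()
        assert (tab["is_de"] == (tab["p_adj"] < 0.05)).all()
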