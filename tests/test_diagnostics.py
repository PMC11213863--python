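"""Gelman-Rubin, DIC, HDR and posterior predictive check behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msddm import (gelman_rubin, dic, select_model, hdr_interval,
                   posterior_predictive_check, Posterior,
                   build_model, variant_by_id, simulate_dataset,
                   DesignSpec, AgeGenerativeModel)
from msddm.diagnostics import DiagnosticError, DicResult
from msddm.model import PARAMS, AGE_GROUPS
from msddm.synthetic import CELLS


class TestGelmanRubin:
    def test_identically_distributed_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 20_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_flag_nonconvergence(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 5.0

    def test_hand_computed_psrf(self):
        chains = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        # W = 1.0; B/n = var([2,3]) = 0.5; var_hat = 2/3*1 + 0.5
        expected = np.sqrt((2 / 3 + 0.5) / 1.0)
        assert gelman_rubin(chains) == pytest.approx(expected)

    def test_single_chain_rejected(self):
        with pytest.raises(DiagnosticError):
            gelman_rubin(np.ones((1, 100)))

    @given(a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        chains = rng.standard_normal((3, 400)) + rng.normal(size=(3, 1))
        assert gelman_rubin(a * chains + b) == pytest.approx(
            gelman_rubin(chains), rel=1e-9)


class TestDic:
    def test_constant_trace_gives_zero_complexity(self):
        r = DicResult(mean_deviance=123.4, deviance_at_means=123.4)
        assert r.p_d == 0.0 and r.dic == 123.4

    def test_identity_holds_exactly(self):
        r = DicResult(mean_deviance=100.0, deviance_at_means=88.0)
        assert r.dic == pytest.approx(2 * 100.0 - 88.0)

    @staticmethod
    def _normal_posterior(y, rng, extra_groups=1):
        """Exact conjugate posterior for group means of y (unit variance,
        flat prior), packaged as Posterior + duck-typed model."""
        groups = np.array_split(y, extra_groups)
        n_draws = 40_000
        draws = np.empty((2, n_draws // 2, extra_groups))
        dev = np.empty((2, n_draws // 2))

        def deviance_at(thetas):
            d = 0.0
            for g, th in zip(groups, np.atleast_1d(thetas)):
                d += np.sum((g - th) ** 2) + len(g) * np.log(2 * np.pi)
            return d

        for c in range(2):
            for j in range(n_draws // 2):
                ths = [rng.normal(g.mean(), 1 / np.sqrt(len(g)))
                       for g in groups]
                draws[c, j] = ths
                dev[c, j] = deviance_at(ths)
        post = Posterior(draws=draws, deviance=dev,
                         node_names=[f"theta{g}" for g in range(extra_groups)])

        class FakeModel:
            def deviance(self, vec):
                return deviance_at(vec)

        return post, FakeModel()

    def test_toy_normal_matches_closed_form(self):
        """For y_i ~ N(theta, 1) with a flat prior, pD = 1 and
        DIC = D(theta_hat) + 2 exactly in expectation."""
        rng = np.random.default_rng(11)
        y = rng.standard_normal(50) + 2.0
        post, model = self._normal_posterior(y, rng)
        r = dic(post, model)
        assert r.p_d == pytest.approx(1.0, abs=0.05)
        d_hat = np.sum((y - y.mean()) ** 2) + 50 * np.log(2 * np.pi)
        assert r.dic == pytest.approx(d_hat + 2.0, abs=0.1)

    def test_effective_parameters_grow_with_model_size(self):
        """Splitting one mean into two adds one effective parameter."""
        rng = np.random.default_rng(12)
        y = rng.standard_normal(60)
        r1 = dic(*self._normal_posterior(y, rng, extra_groups=1))
        r2 = dic(*self._normal_posterior(y, rng, extra_groups=2))
        assert r2.p_d > r1.p_d
        assert r2.p_d == pytest.approx(2.0, abs=0.1)

    def test_missing_trace_errors(self):
        post = Posterior(draws=np.zeros((2, 3, 1)),
                         deviance=np.empty((0,)), node_names=["a"])
        with pytest.raises(DiagnosticError):
            dic(post, None)


class TestSelectModel:
    def test_clear_winner_is_substantial(self):
        s = select_model({"A": 100.0, "B": 150.0})
        assert s["best"] == "A" and s["substantial"]

    def test_close_race_is_not_substantial(self):
        s = select_model({"A": 100.0, "B": 105.0})
        assert s["best"] == "A" and not s["substantial"]
        assert s["delta_dic"] == pytest.approx(5.0)

    def test_needs_two_variants(self):
        with pytest.raises(DiagnosticError):
            select_model({"A": 1.0})


class TestHdr:
    def test_gaussian_interval_matches_quantiles(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(200_000)
        lo, hi = hdr_interval(s, 0.90)
        assert lo == pytest.approx(-1.645, abs=0.03)
        assert hi == pytest.approx(1.645, abs=0.03)

    def test_discrete_tie_breaks_low(self):
        lo, hi = hdr_interval(np.arange(1, 11), 0.9)
        assert (lo, hi) == (1.0, 9.0)

    def test_full_mass_is_range(self):
        s = np.array([3.0, -1.0, 7.0])
        assert hdr_interval(s, 1.0) == (-1.0, 7.0)

    @given(mass=st.floats(0.2, 0.95))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_width_shrinks_with_mass(self, mass):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(2000)
        lo1, hi1 = hdr_interval(s, mass)
        lo2, hi2 = hdr_interval(s, min(mass + 0.04, 0.99))
        assert hi1 - lo1 <= hi2 - lo2 + 1e-12


@pytest.fixture(scope="module")
def truth_posterior():
    """Posterior concentrated at the generating parameters."""
    spec = DesignSpec()
    gen = AgeGenerativeModel()
    trials, truth = simulate_dataset(spec, gen, 5, seed=33)
    clean = trials[~trials["timeout"].astype(bool)]
    model = build_model(variant_by_id(8), clean)
    names = model.node_names()
    tv = truth.set_index(["participant_id", "condition", "coherence"])
    rng = np.random.default_rng(0)
    base = np.empty(len(names))
    for j, name in enumerate(names):
        if name.startswith(("mu_", "sigma_")):
            stat, rest = name.split("_", 1)
            pname = rest.split("[")[0]
            cond, coh, grp = rest.split("[")[1].rstrip("]").split(",")
            grp_i = AGE_GROUPS.index(grp)
            sel = truth[(truth.condition == cond) & (truth.coherence == coh)]
            sel = sel[[(1 if a >= model.age_threshold else 0) == grp_i
                       for a in sel["age"]]]
            vals = sel[pname] if len(sel) else truth[pname]
            base[j] = vals.mean() if stat == "mu" else max(vals.std(), 0.05)
        else:
            pname = name.split("[")[0]
            pid, cond, coh = name.split("[")[1].rstrip("]").split(",")
            base[j] = tv.loc[(pid, cond, coh), pname]
    draws = base[None, None, :] + 0.004 * rng.standard_normal(
        (2, 30, len(names)))
    post = Posterior(draws=draws, deviance=np.zeros((2, 30)),
                     node_names=names)
    return post, model, clean


class TestPosteriorPredictiveCheck:
    def test_truth_centred_posterior_passes(self, truth_posterior):
        post, model, clean = truth_posterior
        report = posterior_predictive_check(post, model, clean, n_draws=50,
                                            seed=4)
        total = inside = 0
        for cell in report["cells"].values():
            total += 1 + len(cell["deciles_inside"])
            inside += cell["accuracy_inside"] + sum(cell["deciles_inside"])
        # each observed statistic is exchangeable with the simulated ones,
        # so ~90% containment is expected; allow binomial slack
        assert total == 60
        assert inside >= 45

    def test_signed_rt_convention(self, truth_posterior):
        post, model, clean = truth_posterior
        report = posterior_predictive_check(post, model, clean, n_draws=10,
                                            seed=5)
        cell = report["cells"]["A/LC"]  # lowest accuracy cell: errors exist
        assert cell["observed_signed_rt_deciles"][0] < 0

    def test_empty_cell_skipped_with_note(self, truth_posterior):
        post, model, clean = truth_posterior
        subset = clean[~((clean["condition"] == "AV")
                         & (clean["coherence"] == "LC"))]
        report = posterior_predictive_check(post, model, subset, n_draws=5,
                                            seed=6)
        assert "skipped" in report["cells"]["AV/LC"]

    def test_too_few_draws_rejected(self, truth_posterior):
        post, model, clean = truth_posterior
        with pytest.raises(DiagnosticError):
            posterior_predictive_check(post, model, clean, n_draws=1, seed=1)
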