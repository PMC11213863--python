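"""Model-graph structure and MCMC sampler correctness.

The sampler's key external check is a cross-validation against an
independently written log-posterior sampled with emcee (affine-invariant
ensemble sampler) on a small two-participant model: group-level posterior
moments must agree within Monte-Carlo error.
"""

import numpy as np
import pytest

from msddm import (DesignSpec, AgeGenerativeModel, simulate_dataset,
                   variant_by_id, build_model, assign_age_group,
                   sample_posterior, SamplerSettings, WienerParams)
from msddm.model import ModelConfigError, VARIANTS, PARAMS
from msddm.wfpt import _loglik_trials


class TestVariants:
    def test_eight_variants_are_the_subsets(self):
        labels = {v.varies for v in VARIANTS}
        assert len(labels) == 8
        assert frozenset() in labels
        assert frozenset(PARAMS) in labels
        assert VARIANTS[0].id == 1 and VARIANTS[7].id == 8

    def test_group_mean_budget(self):
        assert variant_by_id(1).n_group_means("delta") == 1
        v8 = variant_by_id(8)
        assert all(v8.n_group_means(p) == 12 for p in PARAMS)


class TestAgeGroup:
    def test_threshold_labelling(self):
        assert assign_age_group(18.08, 60.0) == "YA"
        assert assign_age_group(86.83, 60.0) == "OA"

    def test_median_split_balances_groups(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 90, size=31)
        thr = float(np.median(ages))
        labels = [assign_age_group(a, thr) for a in ages]
        assert abs(labels.count("OA") - labels.count("YA")) <= 1


class TestBuildModel:
    def test_no_variation_variant_has_three_group_means(self, clean_trials):
        m = build_model(variant_by_id(1), clean_trials)
        mus = [n for n in m.node_names() if n.startswith("mu_")]
        assert len(mus) == 3

    def test_all_varying_variant_has_twelve_per_family(self, clean_trials):
        m = build_model(variant_by_id(8), clean_trials)
        mus = [n for n in m.node_names() if n.startswith("mu_delta")]
        assert len(mus) == 12

    def test_empty_cell_raises_naming_the_cell(self, clean_trials):
        broken = clean_trials[~((clean_trials["participant_id"] == "p001")
                                & (clean_trials["condition"] == "AV")
                                & (clean_trials["coherence"] == "LC"))]
        with pytest.raises(ModelConfigError, match=r"p001.*AV.*LC"):
            build_model(variant_by_id(8), broken)

    def test_identical_participants_get_exchangeable_structure(self,
                                                               clean_trials):
        m = build_model(variant_by_id(8), clean_trials)
        per_part = {}
        for name in m.node_names():
            if "[" in name and not name.startswith(("mu_", "sigma_")):
                pid = name.split("[")[1].split(",")[0].rstrip("]")
                per_part.setdefault(pid, []).append(name.split("[")[0])
        counts = {tuple(sorted(v)) for v in per_part.values()}
        assert len(counts) == 1


@pytest.fixture(scope="module")
def tiny_fit(clean_trials):
    m = build_model(variant_by_id(8), clean_trials)
    s = SamplerSettings(n_chains=2, n_iter=400, burn_in=100, thin=2)
    return m, s, sample_posterior(m, s, seed=5)


class TestSamplerMechanics:
    def test_retained_draw_arithmetic(self, tiny_fit):
        _, s, post = tiny_fit
        assert post.n_retained == (400 - 100) // 2
        assert post.draws.shape[0] == 2

    def test_single_retained_draw_edge_case(self, clean_trials):
        m = build_model(variant_by_id(1), clean_trials)
        s = SamplerSettings(n_chains=1, n_iter=102, burn_in=100, thin=2)
        post = sample_posterior(m, s, seed=1)
        assert post.n_retained == 1

    def test_chain_determinism(self, clean_trials):
        m = build_model(variant_by_id(1), clean_trials)
        s = SamplerSettings(n_chains=2, n_iter=200, burn_in=50, thin=2)
        a = sample_posterior(m, s, seed=9)
        b = sample_posterior(m, s, seed=9)
        assert np.array_equal(a.draws, b.draws)
        c = sample_posterior(m, s, seed=10)
        assert not np.array_equal(a.draws, c.draws)

    def test_adaptation_frozen_after_burn_in(self, tiny_fit):
        _, s, post = tiny_fit
        for trace in post.meta["scale_trace"]:
            post_burn = trace[s.burn_in // 50:]
            assert np.allclose(post_burn, post_burn[0])

    def test_deviance_trace_matches_model(self, tiny_fit):
        m, _, post = tiny_fit
        row = post.draws[0, -1]
        assert post.deviance[0, -1] == pytest.approx(m.deviance(row), rel=1e-9)

    def test_posterior_roundtrip(self, tiny_fit, tmp_path):
        from msddm import Posterior
        _, _, post = tiny_fit
        post.save(tmp_path / "p.csv", tmp_path / "p.json")
        back = Posterior.load(tmp_path / "p.csv", tmp_path / "p.json")
        assert back.node_names == post.node_names
        assert np.allclose(back.draws, post.draws)


def _log_posterior_factory(model):
    """Independently written joint log density of the two-participant
    hierarchy (variant 1): participant delta/theta/tau + group mu/sigma."""
    pr = model.priors
    rt = model.rt
    correct = model.correct
    offs = model.offsets

    def logpost(vec):
        # layout: delta_p (N), theta_p (N), tau_p (N), mu (3), log_sigma (3)
        N = model.n_participants
        dl = vec[0:N]
        th = vec[N:2 * N]
        ta = vec[2 * N:3 * N]
        mu = vec[3 * N:3 * N + 3]
        sig = np.exp(vec[3 * N + 3:3 * N + 6])
        if np.any(th <= 0) or np.any(ta < 0):
            return -np.inf
        if mu[1] <= 0 or mu[2] < 0:
            return -np.inf
        lp = 0.0
        for k, (vals, lo, sc, ssc) in enumerate(
                zip((dl, th, ta), pr.mu_loc, pr.mu_scale, pr.sigma_scale)):
            lp += -0.5 * ((mu[k] - lo) / sc) ** 2
            lp += -0.5 * (sig[k] / ssc) ** 2 + np.log(sig[k])  # + Jacobian
            lp += np.sum(-0.5 * ((vals - mu[k]) / sig[k]) ** 2
                         - np.log(sig[k]))
        for i in range(N):
            if ta[i] >= model.min_rt[i]:
                return -np.inf
            s, e = offs[i, 0, 0], offs[i, 5, 1]
            lp += _loglik_trials(rt[s:e], correct[s:e], dl[i], th[i], ta[i],
                                 1e-7)
        return lp if np.isfinite(lp) else -np.inf

    return logpost


class TestAgainstEnsembleSampler:
    def test_group_posterior_moments_match_emcee(self):
        """Dual-route check: our Metropolis-within-Gibbs vs emcee on the
        same small posterior; group-mean moments must agree."""
        import emcee
        spec = DesignSpec()
        gen = AgeGenerativeModel()
        trials, _ = simulate_dataset(spec, gen, 2, seed=23)
        clean = trials[~trials["timeout"].astype(bool)]
        model = build_model(variant_by_id(1), clean)

        post = sample_posterior(
            model, SamplerSettings(n_chains=3, n_iter=4000, burn_in=1000,
                                   thin=2), seed=3)

        logpost = _log_posterior_factory(model)
        ndim = 3 * model.n_participants + 6
        rng = np.random.default_rng(1)
        p0 = np.empty((4 * ndim, ndim))
        N = model.n_participants
        for w in range(p0.shape[0]):
            p0[w, 0:N] = 1.5 + 0.3 * rng.standard_normal(N)
            p0[w, N:2 * N] = 1.5 + 0.1 * rng.standard_normal(N)
            p0[w, 2 * N:3 * N] = 0.25 + 0.02 * rng.standard_normal(N)
            p0[w, 3 * N:3 * N + 3] = [1.5, 1.5, 0.25] + \
                0.1 * rng.standard_normal(3)
            p0[w, 3 * N + 3:] = np.log(0.3) + 0.1 * rng.standard_normal(3)
        sampler = emcee.EnsembleSampler(p0.shape[0], ndim, logpost)
        state = sampler.run_mcmc(p0, 3000, progress=False,
                                 skip_initial_state_check=True)
        flat = sampler.get_chain(discard=1500, thin=5, flat=True)

        for k, pname in enumerate(("delta", "theta", "tau")):
            ours = post.pooled(f"mu_{pname}")
            ref = flat[:, 3 * N + k]
            # agreement within combined Monte-Carlo error (autocorrelated
            # chains: use a conservative effective-sample deflation)
            se = np.sqrt(ours.var() / (len(ours) / 20)
                         + ref.var() / (len(ref) / 20))
            assert abs(ours.mean() - ref.mean()) < 4 * se, pname
            assert np.isclose(ours.std(), ref.std(), rtol=0.35), pname
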