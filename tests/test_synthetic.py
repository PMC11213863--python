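"""Design balance, generator structure and simulator determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msddm import (DesignSpec, AgeGenerativeModel, build_design,
                   sample_participant_params, simulate_trial,
                   simulate_trials, simulate_dataset, WienerParams,
                   choice_probability, mean_decision_time, CELLS)
from msddm.synthetic import DesignError


class TestBuildDesign:
    def test_default_design_has_216_trials_per_participant(self, design_spec):
        d = build_design(design_spec, 1, seed=0)
        assert len(d) == 216
        assert (d.groupby("block").size() == 72).all()

    def test_full_cohort_trial_count(self, design_spec):
        d = build_design(design_spec, 212, seed=0)
        assert len(d) == 45_792

    def test_single_block_of_12_hits_each_cell_once(self):
        spec = DesignSpec(n_blocks=1, trials_per_block=12)
        d = build_design(spec, 1, seed=4)
        counts = d.groupby(["condition", "coherence", "category"]).size()
        assert len(counts) == 12 and (counts == 1).all()

    def test_indivisible_spec_raises(self):
        with pytest.raises(DesignError):
            build_design(DesignSpec(trials_per_block=70), 1, seed=0)

    @given(per_cell=st.integers(1, 4), n_blocks=st.integers(1, 4),
           seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_balance_exact_for_any_divisible_spec(self, per_cell, n_blocks,
                                                  seed):
        spec = DesignSpec(n_blocks=n_blocks, trials_per_block=12 * per_cell)
        d = build_design(spec, 2, seed=seed)
        counts = d.groupby(["participant_id", "condition", "coherence",
                            "category"]).size()
        assert (counts == n_blocks * per_cell).all()
        # equal condition / category / coherence marginals per participant
        for col, levels in (("condition", 3), ("category", 2),
                            ("coherence", 2)):
            marg = d.groupby(["participant_id", col]).size()
            assert marg.nunique() == 1 and len(marg) == 2 * levels


class TestParticipantParams:
    def test_degenerate_generator_shares_intercepts(self, gen_model):
        from dataclasses import replace
        gen = replace(gen_model, delta_spread=0.0, theta_spread=0.0,
                      tau_spread=0.0,
                      delta_slopes={c: 0.0 for c in CELLS},
                      theta_slopes={c: 0.0 for c in CELLS},
                      tau_slopes={c: 0.0 for c in CELLS},
                      av_benefit_slope=0.0)
        a = sample_participant_params(25.0, gen, seed=1)
        b = sample_participant_params(80.0, gen, seed=2)
        for cell in CELLS:
            assert a[cell] == b[cell]

    def test_av_hc_drift_is_optimal_combination_before_noise(self, gen_model):
        from dataclasses import replace
        gen = replace(gen_model, delta_spread=0.0, theta_spread=0.0,
                      tau_spread=0.0, av_benefit_slope=0.0)
        p = sample_participant_params(50.0, gen, seed=3)
        expect = np.hypot(p[("V", "HC")].delta, p[("A", "HC")].delta)
        assert p[("AV", "HC")].delta == pytest.approx(expect)

    def test_positivity_floors_respected(self, gen_model):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = sample_participant_params(float(rng.uniform(18, 90)),
                                          gen_model, rng)
            for cell in CELLS:
                assert p[cell].delta > 0
                assert p[cell].theta > 0
                assert p[cell].tau >= 0

    def test_ols_on_generator_output_recovers_age_slope(self, gen_model):
        """Regressing sampled V/HC drift on age recovers the configured
        slope within Monte-Carlo error."""
        rng = np.random.default_rng(9)
        ages = rng.uniform(18, 90, size=500)
        deltas = [sample_participant_params(a, gen_model, rng)[("V", "HC")].delta
                  for a in ages]
        slope = np.polyfit(ages, deltas, 1)[0]
        true_slope = gen_model.delta_slopes[("V", "HC")]
        # MC error: spread / (sd(age) * sqrt(n))
        se = gen_model.delta_spread / (np.std(ages) * np.sqrt(500))
        assert abs(slope - true_slope) < 3 * se

    def test_age_outside_range_raises(self, gen_model):
        with pytest.raises(ValueError):
            sample_participant_params(101.0, gen_model, seed=0)


class TestSimulateTrial:
    def test_driftless_is_even_money(self):
        p = WienerParams(0.0, 1.0, 0.2)
        _, correct, timeout = simulate_trials(p, 100_000, 30_000.0, seed=21)
        assert timeout.sum() == 0
        se = 0.5 / np.sqrt(100_000)
        assert abs(correct.mean() - 0.5) < 4 * se

    def test_mean_decision_time_matches_closed_form(self):
        p = WienerParams(2.0, 1.5, 0.3)
        rt, _, _ = simulate_trials(p, 50_000, 30_000.0, seed=22)
        expect = (p.theta / (2 * p.delta)) * np.tanh(p.delta * p.theta / 2)
        sem = np.nanstd(rt) / np.sqrt(len(rt))
        assert abs(np.nanmean(rt) - p.tau - expect) < 4 * sem + 2e-3

    def test_zero_deadline_always_times_out(self):
        out = simulate_trial(WienerParams(1.0, 1.0, 0.2), 0.0, seed=1)
        assert out.timeout and out.rt_s is None and out.correct is None

    def test_nonpositive_boundary_rejected(self):
        with pytest.raises(ValueError):
            simulate_trial(WienerParams(1.0, 0.0, 0.2), 3000.0, seed=1)

    def test_empirical_accuracy_matches_closed_form_per_cell(self):
        """Choice-probability oracle against simulation, several cells."""
        for seed, p in enumerate([WienerParams(0.4, 1.4, 0.35),
                                  WienerParams(2.6, 1.2, 0.30),
                                  WienerParams(1.0, 2.2, 0.45)]):
            _, correct, _ = simulate_trials(p, 20_000, 30_000.0, seed=seed)
            expect = choice_probability(p, "upper")
            se = np.sqrt(expect * (1 - expect) / 20_000)
            assert abs(correct.mean() - expect) < 3 * se + 1e-3


class TestSimulateDataset:
    def test_equal_seeds_are_byte_identical(self, design_spec, gen_model):
        a_t, a_g = simulate_dataset(design_spec, gen_model, 3, seed=14)
        b_t, b_g = simulate_dataset(design_spec, gen_model, 3, seed=14)
        assert a_t.equals(b_t) and a_g.equals(b_g)
        c_t, _ = simulate_dataset(design_spec, gen_model, 3, seed=15)
        assert not a_t.equals(c_t)

    def test_zero_participants_gives_empty_tables(self, design_spec,
                                                  gen_model):
        trials, truth = simulate_dataset(design_spec, gen_model, 0, seed=1)
        assert len(trials) == 0 and len(truth) == 0

    def test_timeout_iff_missing_rt_and_response(self, small_dataset):
        trials, _ = small_dataset
        tmo = trials["timeout"].astype(bool)
        assert (trials["rt"].isna() == tmo).all()
        assert (trials["response"].isna() == tmo).all()
        ok = trials.loc[~tmo, "rt"]
        assert (ok > 0).all() and (ok <= 3000.0).all()

    def test_truth_table_covers_every_cell(self, small_dataset):
        _, truth = small_dataset
        counts = truth.groupby(["participant_id"]).size()
        assert (counts == 6).all()
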