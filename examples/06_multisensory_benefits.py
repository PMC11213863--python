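"""Multisensory-benefit statistics and their age trends.

From a fitted posterior: AV-V parameter contrasts, the optimal-combination
drift gap delta_AV - sqrt(delta_V^2 + delta_A^2), and the measure of
inverse effectiveness (MoIE), each correlated with chronological age.
The generative model puts an age-increasing audiovisual drift benefit at
high coherence only, so the high-coherence gap should correlate positively
with age while the low-coherence gap stays near zero.
"""

from msddm import (DesignSpec, AgeGenerativeModel, simulate_dataset,
                   build_model, variant_by_id, sample_posterior,
                   SamplerSettings, estimates_from_posterior, benefit_report)

trials, _ = simulate_dataset(DesignSpec(), AgeGenerativeModel(), 24, seed=8)
clean = trials[~trials["timeout"].astype(bool)]
model = build_model(variant_by_id(8), clean)
post = sample_posterior(
    model, SamplerSettings(n_chains=2, n_iter=1000, burn_in=300, thin=2),
    seed=9)

estimates = estimates_from_posterior(post, model)  # posterior means
report = benefit_report(estimates)

df = report["per_participant"]
print("per-participant metrics (first rows):")
cols = ["participant_id", "age", "opt_comb_gap_HC", "opt_comb_gap_LC",
        "moie_delta"]
print(df[cols].head(5).round(3).to_string(index=False), "\n")

print("age correlations (Pearson R, p, 95% CI):")
for key in ("opt_comb_gap_HC", "opt_comb_gap_LC",
            "av_minus_v_delta_collapsed", "moie_delta"):
    c = report["age_correlations"][key]
    print(f"  {key:>28}: R={c['r']:+.3f}  p={c['p']:.4f}  "
          f"CI [{c['ci95'][0]:+.3f}, {c['ci95'][1]:+.3f}]")
print("\na positive HC gap correlation with a flat LC gap mirrors the "
      "age-increasing high-coherence multisensory benefit the generator "
      "encodes.")
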