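# Methods

## The decision model

Each trial of the audiovisual categorisation task is modelled as a Wiener
diffusion between two absorbing boundaries: evidence accumulates from a
starting point `z·θ` with drift `δ` (evidence/s) and unit diffusion
coefficient until it hits 0 or `θ`; the observed response time is the
first-passage time plus a non-decision offset `τ` (s). Under accuracy
coding the upper boundary is the correct response. The relative starting
point is fixed at the midpoint (`z = 0.5`) throughout — the design is
pseudorandomised, so no a-priori response bias is modelled — and the
trial-to-trial variabilities of all parameters are fixed to zero. There is
no contaminant/lapse mixture component.

The joint density of (boundary, t) is evaluated by the classic pair of
series expansions for the standardised first-passage density: an image
(small-time) expansion and an eigenfunction (large-time) expansion. Per
evaluation point the branch is chosen by whichever needs fewer terms for
the requested absolute error (default `eps = 1e-7` per density
evaluation); the truncation bounds follow the standard term-count
criteria, with the tolerance rescaled by the exponential drift prefactor
so `eps` bounds the error of the returned density, not of the
standardised series. The density is exactly zero at `t ≤ τ`. All internal
computation is in seconds; trial tables carry RT in milliseconds and are
converted at module boundaries.

## Synthetic data

The generator reproduces the experiment's design: 3 blocks × 72 trials,
balanced over 3 sensory conditions (V, A, AV) × 2 coherence levels
(HC, LC) × 2 categories (face, car), shuffled within block from a seeded
stream, with a 3000 ms response deadline. Ages are uniform on 18–90 years
by default.

Participant-level parameters come from linear age trends per
condition × coherence cell plus independent Gaussian between-participant
noise, truncated at positivity floors (δ ≥ 0.05, θ ≥ 0.30, τ ≥ 0.10). The
default trends encode the qualitative age structure the analysis is meant
to detect: drift declines with age in every cell (−0.010/yr); boundary
separation rises with age in A/LC, AV/LC and V/HC (+0.004/yr); non-decision
time rises with age in V/LC (+0.0015/yr). The audiovisual drift at high
coherence is not free: its cell mean is the optimal combination
`sqrt(δ_V² + δ_A²)` of the unisensory HC means plus an age-increasing
benefit (`av_benefit_slope`, default +0.008/yr), so the high-coherence
multisensory benefit grows with age. The AV/LC drift slope is set to the
age derivative of the unisensory combination at LC (−0.0141/yr), keeping
the low-coherence combination gap flat in age: the benefit is a
high-coherence phenomenon only. Reference-age intercepts (δ: 2.0/1.8 at
HC, 1.2/1.0 at LC for V/A; θ: 1.5; τ: 0.35 s; spreads 0.25/0.15/0.05) were
chosen to give plausible accuracies (~60–95%) and mean RTs well inside the
deadline, with age effects large enough that recovery tests are
informative. No quantitative effect sizes are estimates of any real
cohort.

Trials are simulated by Euler–Maruyama at `dt = 1e-4` s with all trials of
a cell stepped in parallel. Discrete boundary monitoring inflates
first-passage times by ≈0.583·√dt per boundary, so the discrete barriers
are pulled inward by that amount (the standard continuity correction);
with it, the empirical CDF of 10⁶ simulated trials agrees with the
analytic density to < 10⁻³, an order of magnitude inside the 0.01 bound
the tests enforce. A single root seed drives age, parameter and trial
noise through deterministically derived sub-streams, making datasets
byte-identical across runs.

What the generator does not emulate: stimulus rendering (phase coherence,
auditory SNR), semantic congruence of the audiovisual pairing, feedback
and inter-trial timing, attention lapses, and any non-stationarity over
blocks. Passing recovery tests therefore demonstrates that the pipeline's
inference machinery is correct under the model's own assumptions, not
that real behavioural data satisfy those assumptions.

## Preprocessing

Participants whose overall proportion of correct responses — pooled over
all trials, timeouts counted as incorrect — is below 50% are removed
entirely; a participant at exactly 50% is retained. A per-condition
variant of the criterion is available behind a flag. Then, per surviving
participant, timeouts are removed and any RT outside
`median ± 2.5·MAD` is excluded, where both statistics are computed over
that participant's non-timeout RTs pooled across conditions and MAD is
the raw median absolute deviation (no 1.4826 normal-consistency
constant). A per-condition bounds mode exists behind a flag; pooled is
the default because the rule is stated per participant. Filtering is pure
selection: surviving rows are byte-identical and keep their order, and
the exclusion report reconciles exactly.

Note that the MAD rule truncates the tails of the generating RT
distribution, so parameter-recovery checks are run on simulated data with
only timeouts removed; applying the truncation to model-faithful
synthetic data would bias drift upward and non-decision time downward
relative to the generating truth, which is a property of the filter, not
of the sampler.

## Hierarchical model and sampler

Eight variants are fit: the 2³ subsets of {δ, θ, τ} free to vary across
conditional dependencies (variant 1: nothing varies; variant 8: all
three). A varying parameter has participant-level nodes per
condition × coherence cell (6 per participant) drawn from group-level
normal distributions per condition × coherence × age group cell (12 group
means per parameter family at most); a fixed parameter has one node per
participant drawn from a single group distribution. The age split is a
configurable threshold, default 60 years.

Priors (group level, weakly informative and positivity-respecting):
δ means ~ N(0, 5); θ means ~ N(1.5, 2) truncated positive; τ means ~
N(0.3, 0.3) truncated at zero; all group spreads ~ half-normal(2).
Participant-level nodes are normal about their group mean with support
constraints enforced by proposal rejection (θ > 0; 0 ≤ τ < that
participant's minimum retained RT, which keeps the likelihood finite).

The Wiener likelihood admits no conjugate updates, so sampling is
Metropolis-within-Gibbs: per sweep, every participant-level node receives
`n_inner = 3` normal random-walk proposals (each requiring the Wiener
likelihood of only the affected cells, served from a per-cell cache),
and group means and spreads receive `n_group_inner = 10` likelihood-free
update passes, with spreads random-walked in log space. Each sweep ends
with one interweaved non-centered move per group node: a proposal that
rescales all member nodes jointly with the group spread (or translates
them jointly with the group mean), which decorrelates the hierarchical
funnel that single-site updates traverse slowly. Proposal scales adapt
multiplicatively toward 44% acceptance (30% for the joint moves) in
50-iteration windows during burn-in only and are frozen afterwards, so
detailed balance holds on all retained draws; the tests assert the
freeze. Initialisation puts group means at their prior means and
participant nodes at their group mean plus small seeded jitter (τ capped
at 80% of the participant's minimum RT); non-finite initial likelihoods
are re-drawn a bounded number of times. Chains run sequentially with
seeds derived from a single root seed; equal seeds give bit-identical
posteriors.

The default schedule is 5 chains × 11,000 iterations, 1,000 burn-in,
thinned by two — 25,000 pooled retained draws. A deviance
(−2 log likelihood) trace is recorded at every retained draw.

## Diagnostics and model comparison

Convergence uses the classic Gelman–Rubin potential scale reduction
factor on retained draws — no chain splitting, no rank normalisation —
with the pass threshold 1.02. DIC is `D̄ + pD` with
`pD = D̄ − D(θ̄)`, the deviance evaluated at the posterior mean of every
node; a DIC gap above 10 to the runner-up is flagged as substantial.
Highest-density regions are the shortest window containing `⌈mass·n⌉`
sorted draws, ties broken toward the lower start. The posterior
predictive check re-simulates each participant's per-cell trial counts
from sampled posterior draws and compares observed accuracy and nine
signed-RT deciles (incorrect responses on the negative axis) per cell
against the simulated 90% HDRs; deciles make the distributional
comparison quantitative, and cells with no observed trials are skipped
with a note.

## Derived multisensory metrics

Participant point estimates are posterior means of the participant-level
nodes (medians behind a flag). AV−V contrasts are reported per coherence
and collapsed (their mean). The optimal-combination gap is
`δ_AV − sqrt(δ_V² + δ_A²)` per coherence, squares taken as written. The
measure of inverse effectiveness is
`(X_LC^MS − X_LC^US) − (X_HC^MS − X_HC^US)` with the unisensory reference
chosen per participant per coherence from point estimates: highest drift,
lowest boundary, lowest non-decision time. Age correlations are Pearson R
with a two-sided t-test p-value and a 95% Fisher-z interval.

## Problem sizes in the test suite

The suite exercises the full protocol arithmetic but samples at reduced
scale, chosen so the checks stay sharp: density/simulator agreement at
10⁵–10⁶ trials; parameter recovery on 40 participants × 216 trials with
3 chains × 3,000 iterations (500 burn-in, thin 2); model-selection
recovery on 3 replicates of 8 participants with 2 chains × 800; the
age-pattern check on 60 participants with 3 chains × 1,200. The sampler
cross-check against an independently written log posterior (affine-
invariant ensemble sampler) runs on 2 participants with the no-variation
variant.

## Known limitations

- The sampler is a random-walk scheme; very small cells or extreme
  parameter regimes mix more slowly than gradient-based samplers would.
- DIC is computed from the deviance trace and posterior means, inheriting
  DIC's known sensitivity to parametrisation and its focus effects.
- The τ upper bound at the participant's minimum RT makes the posterior
  of τ sensitive to single fast outliers if preprocessing is skipped.
- The Euler simulator's continuity correction is asymptotic; at extremely
  small boundary separations (θ below ~0.02) the corrected barriers would
  cross and the simulator falls back to uncorrected stepping.
- Exact age-group composition depends on the configurable threshold; with
  few participants one group can be empty, in which case its cells are
  prior-dominated.
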