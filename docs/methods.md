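# Methods

This note documents the models and procedures implemented in `mgtraj`, the
parameters that matter, the numerical choices, and what the synthetic-data
validation does and does not demonstrate.

## Data model and preprocessing

Visit data are long-format observations (patient, week, variable, value) plus
a static covariate table. Time is real-valued weeks from baseline; month M
converts as 13/3·M weeks. Prednisone is stored as the daily-equivalent dose in
mg/day — half the alternate-day protocol dose — because analysis and dose
caps are naturally expressed per day while the protocol prescribes
alternate-day amounts. QMG may arrive as a total or as 13 items (summed on
read); ADL items are needed individually only for weight optimization.

Irregular series are projected onto a uniform grid by **linear
interpolation**. Linear interpolation is chosen deliberately over splines or
kernels: it obeys a maximum principle — an interpolated value is bounded by
its bracketing observations — so the rapid local fluctuations typical of
neuromuscular scoring are never amplified. The default analysis grid is weeks
10→140 in 13/3-week (monthly) steps: the first ten weeks are the forced
dose-escalation period, which carries protocol signal rather than
patient-specific signal, and 140 weeks is the span most patients' records
cover. A patient is excluded rather than imputed when observations fail to
cover the grid span or when an inter-visit gap exceeds `max_gap_weeks`
(default 26, i.e. two missed quarterly visits). The exact
interpolation-error-vs-noise criterion one would ideally use is not
quantifiable without a noise model, so the fixed configurable gap bound is
the testable surrogate.

Optional denoising is a centred moving average (default window 3 for scores,
off for dose — protocol dose steps are real and must not be smeared) that
never crosses an event boundary (hospitalisation/rescue weeks), with
symmetric shrinking windows at segment edges. The filter cannot widen a
segment's value range.

`normalize_control` divides a dose trajectory by the patient's cumulative
dose (trapezoid rule), leaving a shape whose integral is one. This removes
the between-patient sensitivity scale — two patients controlled equally well
on very different absolute doses become comparable.

## Distance and clustering

Trajectory distance is **Dynamic Time Warping** with L1 local cost
|a_i − b_j| and an unnormalised path sum over the standard monotone step set
{(1,0), (0,1), (1,1)}; no Sakoe–Chiba window by default because the series
are short (~31 points). A path-length-normalised variant and a window are
available as options. The implementation is validated exhaustively against
brute-force enumeration of all warp paths for short sequences.

Clustering is **K-Medoids (PAM)** on the DTW matrix: the cluster centre is an
actual patient trajectory, which keeps results interpretable and resistant to
outliers. The implementation is the classical BUILD + best-improvement SWAP;
because single-start SWAP descent can stall in a local optimum (~6% of small
random instances), the default adds four seeded random restarts and keeps the
best objective. The procedure is fully deterministic given (D, k, seed), so
repeated runs reproduce the same partition. The SWAP objective is asserted
non-increasing at every accepted exchange.

Cluster validation: silhouette widths from the DTW matrix (singletons score
0); Davies–Bouldin and Dunn computed from the DTW matrix with medoids as
centres; Calinski–Harabasz needs Euclidean centroids and therefore operates
on the grid-aligned value vectors — a documented divergence from the
DTW-only pipeline. `select_k` scans a k range and returns the largest k whose
negative-silhouette count is ≤ 5% of n and whose mean silhouette is within
0.1 of the best, plus the full per-k table (and a warning flag when nothing
separates). Cluster tags are permuted so cluster 1 has the lowest
time-averaged trajectory — the best outcome when the variable is a dose or a
severity score — with ties broken by cluster size.

Negative-silhouette patients are excluded from covariate profiles and
cross-tabulations (they are not reliably classified, and would blur the
contrast) but never from the clustering itself.

## Predictability index

Predictability is the continuity of the operator Φ that advances a patient
one time block: |Φ(x₁) − Φ(x₂)| ≤ K·|x₁ − x₂| with modulus K ≈ 1 required
for reliable extrapolation. Because single-patient continuity is hopelessly
noisy, the index works on neighbourhoods and on temporal blocks:

1. Trajectories are sliced into overlapping blocks of k successive grid
   values (default k = 2); block distance is Euclidean.
2. At each block index, the block vectors are partitioned by a **greedy
   maximal-covering pass**: count neighbours within distance D of every
   remaining point, take the most populous ball (ties → smallest id), remove
   it, repeat; balls that would fall below `min_occupancy` members leave
   their points "singular" (too rare for group-based prediction). The greedy
   pass is the standard heuristic for the maximal covering location problem;
   its first sphere is verified against exhaustive search on small
   instances. D is interpreted as a radius ("neighbours within distance D"),
   the algorithmically operational reading.
3. Each sphere's predicted position at the next block is the ball of the same
   radius centred at the **image of the sphere's centre trajectory** (its
   next-block vector). Members landing inside are retained; Ip is the pooled
   percentage of retained members over all transitions, singular patients
   excluded from numerator and denominator.

Centring the predicted sphere on the centre trajectory's image (rather than
on the members' mean image) is a deliberate design choice: when the
transition is an isometry — every trajectory constant in time, modulus
exactly one — distances to the centre are preserved and Ip = 100 exactly,
which is the index's defining calibration point. A mean-centred variant
(`predicted_center="mean"`) is provided; it is more robust to an outlying
centre trajectory but loses the exactness of the 100% limit. Pooling over
transitions (rather than averaging per block) is likewise declared and
configurable at the report level, where per-transition detail is retained.

Defaults: radius = 8% of the variable's observed maximum, scaled by √k so
the per-coordinate tolerance is block-length-invariant — the scale at which
dose trajectories begin to form well-populated spheres; `min_occupancy` = 10
for trial-sized cohorts (configurable down for small synthetic sets).

`partition_by_predictability` splits patients into extrapolatable vs
non-fitting (escaping in > 50% of counted transitions, or always singular)
and contrasts covariates between the groups.

## Composite-score optimization

Ip doubles as an objective for score design. The 8 ADL item weights α
(α_j > 0, Σα_j = 8) are searched with a real-coded **genetic algorithm**:
tournament selection (size 3), blend crossover, Gaussian mutation (σ = 0.3),
projection back onto the constraint after every operator, elitism 2, and the
uniform-weight individual seeded into generation 0 — so the achieved Ip can
never fall below the uniform baseline, and the best fitness is monotone
across generations. Gradient methods are useless here because Ip is piecewise
constant in the weights. The sphere radius is a fixed fraction of each
candidate composite's own maximum, making the fitness invariant to overall
score scale (verified as a property test). Fitness is cached on the weight
vector rounded to three decimals. Default budget (population 64, 60
generations) is a desk-scale choice; tests and studies use smaller budgets.

The ADL/QMG mixture γ·ADL + (2−γ)·QMG is searched exhaustively over
γ ∈ [0, 2] (default step 0.05); ties prefer γ nearest 1. The endpoints reduce
to single-score Ip by scale invariance.

## Dose-boost response maps

A drug-dosage boost (DDB) starts where the uniform dose trajectory rises by
at least `threshold_mg_day` (default 5 mg/day — exactly one 10 mg
alternate-day protocol step) in one grid step; rises within
`refractory_weeks` (default 4) of an accepted boost are merged into it, the
boost's magnitude then measuring the full rise above the original pre-boost
dose. A boost is "sustained" if the dose holds ≥ threshold above the
pre-boost level for `sustain_weeks` (default 2). The response ΔS is the score
change over `window_weeks` (default 8) from boost onset, using the lightly
smoothed score by default to damp visit noise. All four knobs are exposed;
there is no canonical operational DDB definition to inherit, so the defaults
are stated rather than fitted. Samples grouped by cluster give the response
map (n, mean ΔS, SD, fraction improved); a new patient's samples are checked
against a cluster by z-score (consistent iff all |z| ≤ 2, closed bound;
indeterminate when the cluster summary has n < 3 or zero SD). Saturation
metrics report each patient's boost count and the fraction of the timeline
spent at ≥ 90% of their protocol dose ceiling
(min(100, 1.5 mg/kg) alternate-day, 120 mg for prior prednisone users; halved
for daily equivalent). The maps are descriptive: clinicians boosted *because*
scores worsened, so no causal dose→score claim is made.

## Sigmoid dose–response model

    dS/dt = β·(Y(t)/Y_max)·S + α·S·(S_capacity − S)

Parameters (units): α > 0 per week — untreated deterioration rate toward the
severity ceiling S_capacity (score units); β ≤ 0 per week — drug-effect rate
at the protocol ceiling Y_max (mg/day). The sign convention makes the drug
term lower the score for a beneficial drug; β is a timescale whose sign is
fixed by that convention. The model enforces dose saturation and nothing
more; it is a phenomenological surrogate, not immunology.

Fixed points at constant dose y: S = 0 and
S* = S_capacity + (β/α)·(y/Y_max), classified by the sign of the local
derivative. A commonly quoted shorthand S_capacity − β·y/Y_max equals S* only
under an α = 1 convention; `equilibrium()` reports both so the discrepancy is
visible rather than silently resolved. Tests pin the literal fixed point of
the equation as written.

Numerics: fixed-step RK4 (0.5 weeks). This resolves rates up to
α·S_capacity ≈ 0.4/week to ~1e-6 over an 80-week horizon; stiffer settings
raise an explicit error suggesting a smaller step rather than returning
garbage. Sub-zero undershoot within 1e-9 is clipped; worse undershoot is an
error. Fitting (`SigmoidDoseResponse.fit`) is bounded multi-start L-BFGS-B
over (α, β, S_capacity) with Y_max fixed from the protocol — it is a known
trial property and would trade off degenerately against β if floated. Starts
are drawn from the non-stiff core of the bounds; diverging parameter sets
receive a large finite penalty so numeric gradients stay usable. A
constant-zero observed series is flagged degenerate (the S = 0 orbit carries
no information) instead of fitted. The recovery study (weekly observations,
80 weeks, dose stepping 0→40 mg/day mid-course, 5% noise) achieves ~6%/6%/1%
median relative error on α/β/S_capacity; identifiability requires the
logistic rise, the plateau and the drug-driven decline each to span several
observation points.

## Synthetic cohort generator

The generator exists because the motivating trial's data are
access-restricted; it emulates the *structure* of such a trial so that every
pipeline stage can be validated against known ground truth.

Each patient couples the published prednisone titration protocol (weekly
decision clock) to sigmoid dynamics: escalation in 10 mg alternate-day steps
from 10 mg (30 mg for prior users) up to min(100, 1.5 mg/kg) — whole steps
only, a step past the cap is not taken — with a 120 mg ceiling for prior
users lacking minimal-manifestation status after month 4; hold from month 4
until MMS with QMG < 14 and ≥ 1 below baseline; taper 10 mg / 2 weeks
stopping exactly at 40 mg, then 5 mg per month; on MMS loss, re-escalate
10 mg / 2 weeks and resume tapering 4 weeks after MMS returns. The protocol's
"monthly" slow-taper cadence is discretised to 4 weeks on the weekly clock;
the visit schedule keeps true 13/3-week months. MMS has no numeric clinical
definition, so it is synthesised as latent QMG below 8 sustained for 4 weeks.
An audit function re-checks every generated dose trace against the step, cap,
floor and spacing rules.

Four default response phenotypes (prevalences 0.40/0.25/0.20/0.15) share
α = 0.02/week and differ in severity ceiling (12/16/20/26) and drug
responsiveness (β = −1.2/−0.8/−0.5/−0.15), spanning fast responders who taper
early to refractory patients pinned at the dose cap — this is what spreads
the dose trajectories into recoverable clusters. Observed QMG adds Gaussian
noise (SD 1.5) and integer-clips to 0–39; the ADL total tracks latent QMG
with correlation 0.6 (scores correlate only moderately in practice) and is
spread over 8 items by per-profile loading vectors, each item clipped to
integers 0–3. Visits follow months 0, 3, 4, 6 and then quarterly to month 36;
5% of post-baseline visits are missing and a per-visit dropout hazard of
0.008 truncates ~10% of records (both placeholders, configurable — real
missingness rates are not published). Azathioprine (2.5 mg/kg/day) starts at
the first visit from month 12 for patients without MMS then; rescue therapy
appears as an event flag with a transient 4-point score dip.

What passing tests on this generator shows: the pipeline recovers structure
that is present (clusters, escalations, protocol compliance, planted
covariate gradients) and calibrates correctly in analytic limits. What it
does not show: performance on real trial data, whose noise is not Gaussian,
whose protocol deviations are human, and whose latent heterogeneity is not
four sigmoid phenotypes.

Separately from the full generator, three controlled trajectory sets support
calibration studies: cluster-templated trajectories with a stated
separation-to-noise ratio (adjacent templates `separation × within_sd` apart
pointwise; at 3 SD, recovery is essentially perfect — the reference
condition for the cluster-recovery battery), constant-in-time trajectories
(the Ip = 100 limit), and iid-noise trajectories (the unpredictable
extreme).

## Known limitations

- DTW is univariate; clustering is per variable. Multivariate coupling enters
  only through the γ-mixture of scores.
- Ip has no confidence interval; a patient bootstrap would be the natural
  extension.
- The GA does not jointly optimize item weights and γ.
- The continuity modulus K is only tested binarily (retained/escaped), not
  estimated.
- Treatment-failure and saturation summaries assume protocol dose ceilings
  are known per patient; deviations from protocol in real data would need
  their own handling.
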