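# mgtraj

Patient-trajectory modelling for longitudinal clinical-trial data, built
around the treatment course of generalized myasthenia gravis (MG): visit-level
severity scores (QMG, MG-ADL) and corticosteroid dosing recorded irregularly
over a multi-year trial.

Clinical trials in rare diseases are small and noisy, and patients respond to
the same protocol very differently. `mgtraj` treats each patient as a
*trajectory* — a time-path of a clinical variable on a common week grid — and
asks three questions:

1. **Do patients fall into distinct response groups?** Trajectories are
   compared with Dynamic Time Warping (DTW), which tolerates patterns shifted
   by a visit or two, and clustered with K-Medoids (PAM), whose centres are
   actual patient trajectories. Silhouette screening, Davies–Bouldin / Dunn /
   Calinski–Harabasz indices, mean ± SD cluster strips, covariate profiles and
   cross-tabulations characterise the groups.
2. **Is the evolution predictable at all?** A predictability index Ip tests
   the continuity of the transition operator Φ that advances a patient one
   time block: block vectors are partitioned into radius-D spheres by a greedy
   maximal-covering pass, and Ip is the percentage of sphere members that land
   inside the sphere predicted at the next block. Ip = 100% means
   neighbourhoods map onto neighbourhoods (continuity modulus ≈ 1); low Ip
   means mean-trajectory extrapolation is unreliable. Ip also serves as an
   objective: a genetic algorithm reweights the 8 MG-ADL items
   (max_α Ip subject to Σα_j = 8, α_j > 0), and a grid search mixes ADL and
   QMG as γ·ADL + (2−γ)·QMG, γ ∈ [0, 2].
3. **How do patients respond to dose escalations?** Isolated drug-dosage
   boosts (DDBs) are detected in the prednisone trajectory, the score change
   ΔS over a response window is recorded, and cluster-specific response maps
   plus dose-saturation metrics summarise them.

A sigmoid dose–response model ties the pieces together:

    dS/dt = β·(Y/Y_max)·S + α·S·(S_capacity − S)

(S = severity score, Y(t) = daily dose, α = untreated deterioration rate,
β ≤ 0 = drug-effect rate, S_capacity = severity ceiling). It can be simulated,
analysed at equilibrium (S* = S_capacity + (β/α)·Y/Y_max) and fitted to
observed trajectories statsmodels-style
(`SigmoidDoseResponse(obs, dose, y_max).fit().summary()`).

Because the motivating trial dataset is access-restricted, the package ships a
synthetic cohort generator (`mgtraj.synth`) that emulates its structure: the
published alternate-day prednisone titration protocol (escalate 10 mg steps to
min(100, 1.5 mg/kg); hold from month 4 until minimal-manifestation status with
QMG < 14 and ≥ 1 point under baseline; taper 10 mg / 2 weeks to 40 mg then
5 mg / month; re-escalate on relapse), coupled per patient to sigmoid dynamics
drawn from four response phenotypes, with quarterly visits, item-level ADL
scores, azathioprine rescue after month 12, missing visits and dropout — all
with exposed ground truth for validation.

## Worked example

```python
from mgtraj import (SynthConfig, generate_cohort, to_uniform_grid,
                    pairwise_matrix, pam_cluster, order_clusters_by_outcome,
                    silhouette, predictability_index, cluster_strips)
from mgtraj.predictability import default_sphere_radius

cohort, truth = generate_cohort(SynthConfig(n_patients=126, seed=0))
trajs, report = to_uniform_grid(cohort, "prednisone_daily_mg")
print(f"retained {report.retained_count} of {len(cohort)} patients")

D = pairwise_matrix(trajs)
model = order_clusters_by_outcome(pam_cluster(D, 4, seed=0), trajs)
sil = silhouette(D, model.labels)
print("cluster sizes:", model.sizes())
print(f"mean silhouette {sil.overall_mean:.3f}, negatives {len(sil.negative_ids)}")
for s in cluster_strips(trajs, model.labels):
    print(f"cluster {s.tag}: time-averaged dose {s.mean.mean():.1f} mg/day")

ip = predictability_index(trajs, default_sphere_radius(trajs, 2),
                          block_length=2, min_occupancy=10)
print(f"Ip = {ip.ip:.1f}%")
```

Output:

```
retained 112 of 126 patients
cluster sizes: {1: 56, 2: 24, 3: 16, 4: 16}
mean silhouette 0.677, negatives 1
cluster 1: time-averaged dose 7.9 mg/day
cluster 2: time-averaged dose 14.8 mg/day
cluster 3: time-averaged dose 28.5 mg/day
cluster 4: time-averaged dose 52.7 mg/day
Ip = 75.2%
```

Fourteen patients are excluded for records not covering the 140-week analysis
window (dropout) or visit gaps too wide to interpolate. The four clusters are
ordered best → worst outcome (lowest to highest time-averaged dose); here they
recover the generator's four response phenotypes almost perfectly (adjusted
Rand index 0.978 against ground truth). The index Ip = 75% says three in four
patients stay within the sphere their neighbourhood predicts one month ahead
at the default radius (8% of the maximum dose, blocks of two visits, spheres
of ≥ 10 patients).

The same pipeline is scriptable from the shell:

```bash
mgtraj synth --out-dir demo --n-patients 126 --seed 0
mgtraj run demo/visits.csv --k 4 --out-dir demo_run
```

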