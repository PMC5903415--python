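# scnet — age-resolved structural correlation networks

Structural covariance networks treat the cortex as a graph whose edges are
inter-regional Pearson correlations of a morphometric measure — here cortical
thickness (CT) — computed across participants. `scnet` implements an
age-resolved version of this analysis for adolescent cohorts: instead of one
network for the whole sample, it estimates a network inside each of a series
of overlapping age windows and asks how network organization changes with age.

The pipeline, end to end:

1. **Sliding windows.** Participants are sorted by age and grouped into
   half-overlapping windows defined in participant counts (default: five age
   strata of ~60 interpolated into 9 windows of 60, step 30).
2. **Bootstrap-thresholded networks.** Within each window (and once over the
   whole cohort, the *age-invariant* network), the region × region Pearson
   matrix is thresholded probabilistically: the window is resampled with
   replacement *B* = 1000 times, each edge gets a two-tailed sign-consistency
   p-value `p = 2·min(#{r* ≤ 0}, #{r* ≥ 0})/B`, p-values are BH-adjusted, and
   edges with `p_FDR < 0.01` keep their observed correlation.
3. **Graph metrics.** Mean correlation, edge density *D* (% of possible
   edges), node degree *k*, and Euclidean connection distance, globally,
   per node, and within/between communities.
4. **Communities.** Louvain modularity at resolution γ, with γ chosen by
   minimizing nodal *versatility* (co-assignment uncertainty across runs) and
   a Lancichinetti–Fortunato consensus over repeated runs; partitions are
   compared by normalized mutual information (NMI).
5. **Developmental trajectories.** Each windowed metric series is fitted with
   a straight line and a penalized smoothing spline (6 cubic B-splines, knots
   at age quantiles, REML smoothing, effective df ≤ 3.5); AIC selects the
   model, and the fitted curve yields Δmax (|max − min|), the age at the
   trajectory minimum (e.g. age(k_min), age(D_min)) with a bootstrap CI, and
   a linear/nonlinear, increasing/decreasing classification with BH-corrected
   significance across regions.
6. **Spin tests.** Map–map associations (e.g. Δk_max vs the regional
   myelination rate ΔMT at each of 12 cortical depths) are tested against a
   spatial-autocorrelation-preserving null built by randomly rotating the
   spherical projection of one map (mirrored rotations across hemispheres).

Because the motivating cohort data are access-restricted, the package ships a
first-class synthetic-cohort generator (`scnet.synthetic`) producing datasets
with known ground truth — an age-dependent block correlation model with a
planted minimum age, spatially contiguous bilateral modules, linear thinning
and myelination trends, and regions on mirror-symmetric hemispheric spheres —
so every stage of the pipeline is testable against what was planted.

## Worked example

```python
import numpy as np
import scnet as s

regions = s.generate_regions(308, 7, seed=7)          # two hemispheric spheres
dataset, truth = s.generate_cohort(
    s.CohortSpec(n_participants=297, seed=0), regions)  # minimum at 19.5 y

windows = s.make_windows(dataset.ages)                # 9 windows of 60
density = []
for w in windows:
    net, corr = s.build_thresholded_network(
        dataset, w.indices, s.BootstrapConfig(n_boot=200, alpha=0.01, seed=w.window_index))
    density.append(100 * net.n_edges / (308 * 307 / 2))

fit = s.fit_trajectory(s.window_median_ages(windows), np.array(density))
par = s.trajectory_params(fit)
print(fit.chosen, round(par.age_min, 2), par.direction)
```

prints

```
spline 20.13 decreasing
```

i.e. the edge-density trajectory is better described by the constrained
spline than by a line, it is decreasing (its maximum precedes its minimum),
and its minimum falls at 20.1 years — close to the planted correlation
minimum of 19.5 years. The numbered drivers under `analysis/` run the same
stages at full scale (B = 1000, 10 000 spin rotations) and write their tables
under `results/`; on the bundled seed they report, among other things, a
consensus partition with NMI 0.98 against the 7 planted modules and 80/308
regions with significant degree change (P_FDR < 0.05).

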