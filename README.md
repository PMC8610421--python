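# lumbarmorph

Comparative morphometrics of the hominid lower back: the quantitative
toolkit used to infer posture and locomotion from lumbar vertebrae,
aimed at paleoanthropologists and comparative skeletal biologists who
need reproducible versions of these analyses.

Bipedal humans differ from great apes in three measurable features of
the lumbar column, and each has its analysis here:

1. **Vertebral wedging and lordosis.** The wedging angle of a vertebral
   body is θ = arctan((D − V)/L), with D the dorsal height, V the
   ventral height and L the dorsoventral body length (mm, θ in
   degrees). Dorsal (negative) wedging of the lower lumbar levels
   produces lumbar lordosis; the combined value W = Σθ over L2–L5
   summarizes whole-column curvature. Fossil values are classified
   against extant samples (humans by sex, *Pan*, *Gorilla*, *Pongo*)
   using 95% prediction intervals, mean ± 1.96·SD.
2. **Pyramidal configuration of the neural arch.** The inter-articular
   facet index divides the maximum facet width at the lumbosacral level
   by that of the lumbar vertebra three levels higher (L2 vs L5 in
   hominins, L1 vs L4 in four-lumbar apes); values above 1 mean the
   caudally widening, hyperextension-tolerant human pattern.
3. **Overall vertebral shape.** A full 3D geometric-morphometrics
   stack on 48-landmark configurations: generalized Procrustes analysis
   (partial Procrustes, proper rotations only), shape PCA on the
   covariance matrix, pairwise Procrustes distance tables, Procrustes
   ANOVA of shape ~ centroid size × genus with sequential sums of
   squares and RRPP permutation inference, and allometric regression
   shape scores.

A synthetic-data module generates measurement tables (group-specific
normal wedging angles inverted through the wedging formula) and
landmark datasets (shared template + group offsets + allometry +
isotropic noise under random rigid motions) with stored latent truth,
so every stage is testable offline. Reference tables transcribed from
the published comparative summaries ship with the package.

## Worked example

```python
import lumbarmorph as lm

(mh2,) = lm.load_mh2_measurements()          # bundled measurement table
profile = lm.wedging_profile(mh2)
print([(a.level, a.rounded(1)) for a in profile.angles])
print(lm.facet_index_for_series(mh2).rounded(2))

apes = lm.reference_intervals("combined", groups=["Pan", "Gorilla", "Pongo"],
                              mode="printed")
cls = lm.classify_fossil("MH2", -7.3, apes)
print(cls.outside_all)
```

prints

```
[('L2', 4.1), ('L3', 1.3), ('L4', -1.5), ('L5', -10.6)]
1.43
True
```

— the L2 vertebra is ventrally (kyphotically) wedged by 4.1°, the
column switches to dorsal (lordotic) wedging between L3 and L4, the
facet index of 1.43 shows the pyramidal configuration, and the
combined wedging value −7.3° lies outside the 95% prediction interval
of every great-ape sample (it is inside both human intervals).

The shape pipeline runs the same way on any landmark set:

```python
sim = lm.gen_landmarks(lm.LandmarkSimSpec(
    group_offset_magnitudes={"A": 0.0, "B": 0.08}, n_per_group=15), seed=1)
fit = lm.GeneralizedProcrustes(sim.landmarks).fit()
res = lm.ProcrustesAnova(fit).fit(n_perm=999, seed=1)
print(res.summary())
```

```
Procrustes ANOVA (sequential SS, RRPP permutation)
==================================================
permutations: 999 (+ observed), seed=1

            Df      SS      MS     Rsq       F        Z  Pr(>F)
size         1 0.01191 0.01191 0.02658 0.86847 -0.64311 0.76000
group        1 0.06835 0.06835 0.15249 4.98211 16.17839 0.00100
size:group   1 0.01126 0.01126 0.02511 0.82052 -1.29870 0.90800
Residuals   26 0.35669 0.01372 0.79581
Total       29 0.44821
```

The generated group difference is detected (p = 0.001) while the
absent size and interaction effects are not — R² per row is the
fraction of total shape variance each term explains.

A `lumbarmorph` console script exposes the same stages
(`simulate`, `wedging`, `classify`, `facet-index`, `gpa`, `pca`,
`anova`, `allometry`, `distances`, `run`); every stochastic stage
requires `--seed` and each run writes a JSON provenance record.

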