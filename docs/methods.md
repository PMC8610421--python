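# Methods

This note documents the models and procedures implemented in
`lumbarmorph`, the defaults they use, and the design decisions taken
where conventions genuinely diverge.

## Wedging angles and combined wedging

The per-level wedging angle is θ = arctan((D − V)/L) in degrees: D and
V are the dorsal and ventral craniocaudal heights of the vertebral
body, L its dorsoventral length (all mm). Positive θ (dorsal taller)
is ventral/kyphotic wedging; negative θ is dorsal/lordotic wedging.
Combined wedging is the plain sum over a level range, by default
L2–L5; columns missing any level in the range get no combined value —
there is no imputation, matching the comparative convention of only
summing columns that preserve all four levels.

**Length policy.** Published tables do not always state which
dorsoventral length enters the denominator. The package exposes a
policy — superior endplate diameter (default), inferior, or their
mean — and records the policy used on every result. On the bundled
measurement table the superior policy reproduces the printed L2
(4.1°) and L3 (1.3°) angles at one decimal; the printed L4 and L5
values differ from any single policy by 0.1°, an irreducible
ambiguity of the source tables that the package surfaces rather than
hides.

**Rounding.** All computation is at full double precision; reporting
rounds half-away-from-zero (the convention of printed tables, so
−11.15 → −11.2), via `round_half_away`.

**Transition.** The kyphotic→lordotic transition is the first adjacent
level pair whose angles change from > 0 to ≤ 0. An exactly zero angle
counts as lordotic — a deterministic tie-break, stated here because
the opposite choice is equally defensible.

## Prediction intervals and fossil classification

Group summaries use the sample SD (n − 1). The 95% prediction interval
is mean ± 1.96·SD — the z-based construction used in comparative
practice, not a t-based or distribution-free interval. Classification
is a closed-interval test (a value exactly on a bound is inside), with
the signed distance to the violated bound reported when outside.

Intervals come in two modes. `computed` rebuilds mean ± 1.96·SD from
the mean/SD it is given; `printed` carries published bounds verbatim.
Both are needed because published tables print summaries at one
decimal: the human-male combined lower bound prints as −15.0 but
recomputes to −14.9 from its own printed mean/SD, and the *Pongo*
combined interval as printed equals mean ± 1·SD rather than ± 1.96·SD.
The mode is recorded on every interval; these two cells are treated as
documented exceptions, not reproduction targets.

## Facet index

The inter-articular facet index divides the maximum inter-IAF
(inferior articular facet) mediolateral width at the last lumbar
level by the same measurement three levels higher: (L2, L5) for
five-lumbar columns, (L1, L4) for four-lumbar great apes. Columns
with three lumbar vertebrae are excluded — no level three above the
lumbosacral joint exists. Estimated (parenthesized) source
measurements propagate an `estimated` flag into the result, and the
index is scale-invariant by construction.

## Generalized Procrustes analysis

Partial-Procrustes convention: every configuration is centered and
scaled to unit centroid size; each iteration rotates all
configurations to the current consensus and recomputes the consensus
as the renormalized (unit-CS) arithmetic mean; convergence is declared
when the consensus moves less than `tol` (root summed squared
displacement), default 1e-8, with `max_iter` 100. No additional β
rescaling is applied during rotation (full Procrustes is out of
scope). Rotations are restricted to proper rotations (det +1) via the
singular-value sign correction, because the landmarks are collected on
one anatomical side and a reflected "match" would be meaningless. The
sign correction also serves as the deterministic tie-break for
rank-deficient cross-product matrices (e.g. planar configurations).

**Initialization.** When the raw mean of the centered/scaled inputs is
non-degenerate (Frobenius norm > 0.5, which happens exactly when the
inputs already share an orientation), it is used directly as the
starting consensus — this makes GPA a fixed point on its own output
(re-running converges immediately). Otherwise — fresh data under
arbitrary rotations, where the raw mean shrinks toward zero — all
configurations are first rotated to the first configuration and the
consensus starts from that aligned mean. The choice affects iteration
count only; pairwise Procrustes distances are invariant to it (tested).

GPA output is defined up to one global rotation.
`ProcrustesAlignment.rotate_to(reference)` re-expresses the whole
alignment in a chosen frame (a rigid rotation, distance-preserving),
which is how simulation-recovery comparisons against a template-frame
latent truth are made.

## Shape PCA

PCA of the covariance matrix of flattened aligned coordinates,
computed by SVD of the centered data (never forming the 3k × 3k
matrix). Scores are the centered data projected on the eigenvectors;
eigenvalues use the n − 1 denominator. Component signs are fixed by
making the largest-magnitude loading of each eigenvector positive.
Fossils can be included in the fit or projected post hoc with
`PCAResults.project` (fit on extant, project the rest); both modes are
legitimate and the package provides both because ordination practice
varies.

## Procrustes ANOVA

Linear-model variance partition of flattened shape coordinates for
shape ~ size * group, with sequential (type I) sums of squares in that
fixed term order — the order of the model formula; alternative orders
are deliberately not exposed. SS for each term is the squared norm of
the data projected onto the term's incremental subspace (equivalent to
the residual-SS drop when the term enters, and to the Procrustes
distance-based formulation). F uses the residual mean square of the
full model. Group labels are pooled to genus for the comparative
design (`pool_genus`: chimpanzee + bonobo → Pan, western + eastern
gorilla → Gorilla); fossils are excluded from the ANOVA sample.

**Inference** is RRPP — randomization of residuals in a permutation
procedure. For each term, residuals of the reduced model (all
preceding terms) are permuted across specimens and added back to the
reduced-model fit; the term's F is recomputed on each permuted
dataset. The p-value is the proportion of the reference distribution
(observed statistic included, so p ≥ 1/(n_perm + 1)) at or above the
observed F; the default is 999 permutations. Z is the observed F
standardized within that distribution ((F_obs − mean)/SD, observed
included). Other packages log-transform the statistic before
standardizing; the two agree in sign and ordering but not numerically,
so Z values here are not claimed to be comparable across software.
Calibration: under a global null the empirical type-I error at
α = 0.05 is nominal on iid data (0.046/0.053/0.055 for the three terms
at n = 40, 1000 simulations) and within [0.02, 0.08] through the full
simulate → GPA → ANOVA pipeline at n = 32; at very small samples
(n = 16) the interaction term becomes conservative (~0.015), a
small-residual-df effect users should expect.

Degenerate designs degrade explicitly: constant size drops the size
and interaction terms with a warning, a single group drops the group
terms; groups with fewer than two members are rejected. Size enters
untransformed by default (`log_size=True` is available but off, since
the comparative convention modeled here uses raw centroid size).

## Allometric regression

Multivariate least squares of flattened shape on centroid size. The
standardized regression shape score of a specimen is its mean-centered
shape projected onto the unit-normalized slope vector; plotted against
size this visualizes the allometric trend, and predicted shapes at the
size extremes bracket it. Note an intrinsic property of in-sample
regression scores: with p shape dimensions ≫ n specimens the fitted
direction absorbs chance covariance, so the score–size correlation is
high (≈ (1 + n/p)^(−1/2)) even when no allometry was generated. The
correct null check is therefore the permutation p-value of the size
term (or projection onto an independently chosen direction), not the
in-sample score correlation — the test suite does exactly this.

## Synthetic data generators

`gen_measurements` draws per-level wedging angles from group-specific
normals — defaults transcribed from the published extant summaries —
and inverts the wedging formula: V and L fixed at baseline values
(25 mm and 30 mm, typical adult human middle-lumbar dimensions),
D = V + L·tan θ. Draws with |θ| ≥ 90° are redrawn and counted. The
drawn angles are returned as latent truth; recovery tests read them
rather than regenerating.

`gen_landmarks` builds configurations in unit-centroid-size shape
space: a deterministic 48-landmark stylized vertebra template (body
rim octagons, pedicles, articular facets, lamina, process bases — the
37 "core" landmarks — plus 11 spinous/costal process landmarks
mirroring the reduced-analysis subset), plus a group mean-shape offset
of specified magnitude in a random tangent direction, an optional
allometric displacement slope·(size − mean size) along a shared unit
direction, and iid isotropic Gaussian noise per coordinate. The result
is then randomly rotated, scaled to a log-normal centroid size
(median 180 mm, log-SD 0.08 — middle-lumbar scale) and translated, so
superimposition is genuinely exercised. Offsets, allometry direction
and sizes are all returned as latent truth.

What the generators do **not** emulate: realistic vertebral surface
anatomy, correlated (anatomically structured) landmark noise,
measurement error on linear dimensions, missing data patterns, or
unbalanced lumbar counts within a group. Passing recovery tests
therefore show the estimators are correct under the stated model, not
that real vertebral data satisfy that model.

**Simulation sizes used by the test suite** (the package's own
choices): type-I calibration runs 500 null datasets of 32 specimens
with 199 permutations each; allometry recovery uses 60 specimens with
slope 0.005 shape-units/mm against noise SD 0.01 — a strong, clearly
identifiable signal for which the expected recovery correlation
(slope/√(slope² + (σ√p/(SD_CS·√n))²) ≈ 0.97) sits well above the 0.95
acceptance line; group-offset recovery uses an offset magnitude of
0.08 against the same noise.

## Known limitations

- Wedging-angle reproduction at one decimal is limited by the length
  policy ambiguity of the source tables (L4/L5 differ by 0.1° between
  policies).
- Prediction intervals are z-based with no small-sample correction;
  at n = 10 (the smallest extant sample) the nominal 95% coverage is
  optimistic.
- The Z effect size is package-specific (see above).
- GPA assumes complete configurations: no missing-landmark estimation,
  sliding semilandmarks, or bilateral symmetrization.
- The facet index supports the documented substitute-width route (SAF
  of the subjacent element) only through the input table; it does not
  itself articulate adjacent elements.
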