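# Methods

This note documents the models implemented in `floravision`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that affect results.

## Spectral substrate

All spectra live on a shared wavelength grid, by default 300–700 nm at 1 nm
(401 points). Instruments typically sample finer (e.g. 0.4 nm); readers
resample by linear interpolation onto the analysis grid, discard values
outside it, and refuse to extrapolate when coverage is narrower than the
grid. Reflectance is stored on a percent scale (0–100); files on a 0–1
scale are auto-detected (maximum ≤ 1.5) and rescaled, with a log message.

**Smoothing.** `smooth_spectrum` is a locally weighted linear regression
(LOWESS, tricube weights, no robustness iterations) with a span of 0.20 —
the fraction of the grid entering each local fit. The span value follows
the convention of reflectance-processing tools in this field, where 0.20
suppresses instrument noise without eroding the chlorophyll valley near
670 nm. Constants and linear trends are preserved by construction, and the
smoother commutes with adding a constant.

**Negative correction.** Minor calibration artefacts can push reflectance
below zero. `fix_negative` adds |min| to the whole spectrum so the minimum
becomes exactly 0 (the additive reading of "set the minimum to zero and
scale the rest accordingly"). A multiplicative rescaling variant is a
defensible alternative reading; it is not implemented because the additive
form preserves reflectance differences, which is what the contrast models
consume. This is flagged here as a deliberate interpretation.

**Aggregation.** Replicate spectra are averaged per species with the
per-wavelength sample standard deviation (ddof = 1) retained. Pipeline
order is smooth-each-sample, then aggregate; with the linear smoother the
reverse order gives the same mean, so the choice is immaterial for the
mean spectrum but keeps the per-sample residual structure in the sd.
Singleton groups pass through untouched, making aggregation idempotent.

## Vision models

Both models share the chain: quantum catch (rectangle rule on the grid,
Q = Σ R·S·I·Δλ) → von Kries adaptation (divide by the background catch per
receptor) → colour-space projection. Von Kries adaptation makes every
locus exactly invariant to the illuminant's absolute scale; the test suite
enforces this to 1e-12, and the adapting background itself always maps to
the achromatic centre.

**Receptor sensitivities.** Curves are generated from the standard A1
visual-pigment nomogram (alpha plus beta band), parameterised only by the
peak wavelength, and peak-normalised. Defaults: bee trichromat at
344/436/544 nm (UV/blue/green, the standard honeybee set) and a
Lucilia-type fly tetrachromat R7p/R7y/R8p/R8y at 330/350/460/530 nm. The
beta band can displace the realised peak of UV pigments by 2–3 nm from the
nominal value; the container tolerates a 5 nm discrepancy. Fly R7
photoreceptors in vivo owe part of their UV sensitivity to screening and
sensitising pigments that a rhodopsin nomogram cannot capture; the
nomogram set is therefore a documented convention, and tabulated curves
can be supplied (`receptor_from_table`) to reproduce any other convention.
All numeric outputs are sensitive to this choice, which is one reason
species-level agreement with published EU values is not a test target.

**Illuminant.** CIE standard daylight D65, tabulated at 5 nm, interpolated
onto the grid and normalised to unit mean (the scale is irrelevant under
von Kries).

**Background.** The canonical green-foliage adaptation background is the
deterministic foliage spectrum of the synthetic generator (midpoint
pigment strengths, no noise): ~4–6 % reflectance in UV and blue, ~14 %
peak near 530–550 nm, chlorophyll valley at ~670 nm. This is a synthetic
stand-in for published multi-species foliage averages, chosen so that the
whole pipeline is self-contained; a measured background can be supplied
via configuration for literature comparability.

**Bee colour hexagon.** Relative catches are transduced hyperbolically,
E = q/(q+1), so the background sits at E = 0.5 and excitations are bounded
in [0, 1). Coordinates: x = (√3/2)(E_G − E_UV), y = E_B − (E_UV + E_G)/2.
Every locus lies inside the regular hexagon with circumradius 1. Hue
sectors are six 60° sextants centred on the receptor axes (blue at 90°,
green at −30°, UV at 210°), half-open counter-clockwise at the boundaries;
loci within 1e-9 EU of the centre are labelled "achromatic".

**Fly tetravariant space.** The fly model keeps catches linear (no
hyperbolic transduction — transduction is treated as part of the bee-specific
hexagon convention). The four adapted catches are normalised to unit sum
("signals") and combined into opponent axes x = s(R7p) − s(R8p) and
y = s(R7y) − s(R8y), each bounded in [−1, 1]; the unadapted background
lands exactly at (0, 0). The sign pair selects a categorical quadrant.
The quadrant-name table is configuration; the default places *yellow* at
(x ≥ 0, y < 0), the quadrant reached by a 580 nm narrowband stimulus under
the default curves (a smoke test pins this), *blue* at (x < 0, y ≥ 0),
*uv* at (+,+) and *purple* at (−,−). Whether the opponent axes should be
scaled differently is not settled in the literature; the unit-sum
direct-difference convention used here is documented as such.

**Contrasts and thresholds.** Chromatic contrast is the Euclidean distance
of a locus from the achromatic centre (EU); achromatic contrast (bee only)
is |E_G − 0.5|, bounded by 0.5. Discriminability thresholds default to
0.11 EU (bee) and 0.096 EU (fly); a contrast exactly at threshold counts
as discriminable (≥). Both thresholds are overridable, since empirically
determined thresholds are context-dependent.

## Marker points

A marker point is the wavelength of a sharp reflectance transition. The
detector is a reconstruction from its published settings, not a bit-exact
clone of any binary: (1) centred moving-average smoothing with half-width
10 grid points (windows truncated at the spectrum edges); (2) slope by
forward difference over a look-ahead of 5 points, assigned to the midpoint
of the interval so symmetric transitions stay centred on their inflection;
(3) candidates are strict local maxima of |slope| (with a 1e-9 numerical
floor); (4) a candidate survives only if the smoothed reflectance range
within ±25 nm reaches 10 units; (5) survivors closer than 25 nm merge to
the steeper one, so no two reported points are closer than half the
amplitude window. The "≥10 %" amplitude criterion is read as 10 absolute
percentage points; a relative-change variant is available by flag. On
sigmoidal transitions with amplitudes ≥ 15 pp the detector recovers the
analytic inflection within ±3 nm (tested over 200 seeded fixtures).

With these settings, the ~670 nm chlorophyll dip of green presets yields a
single marker point on its steep short-wavelength flank (the 670→700 nm
recovery is too shallow to pass the amplitude gate); fixture tests pin
this behaviour.

**Fit metrics.** Against discrimination optima (bees: 400 and 500 nm),
minAD(o) is the distance from the nearest marker point to optimum o, and
MAD is the mean over marker points of the distance to the *nearest*
optimum. The published verbal definition of MAD is ambiguous between this
nearest-optimum reading and an all-pairs mean; both are implemented
(`method="nearest"` default, `"all_pairs"` by flag). Spectra without
marker points are excluded from metric summaries and reported explicitly.
For any point set entirely above 500 nm, minAD_400 − minAD_500 = 100
exactly; this consistency relation is enforced in tests.

## Phylogenetic ANOVA

The omnibus statistic is the classical one-way F. Its null distribution is
generated by simulating Brownian motion on the phylogeny: the BM rate σ²
is estimated once from the observed traits by maximum likelihood under the
tree covariance (GLS mean; σ̂² = r'C⁻¹r/n), and `n_sim` datasets (default
10 000) are drawn as multivariate normals with covariance σ̂²·C, with group
labels held fixed on the tips — a phylogenetic, not a permutation, null.
Estimating the rate from the raw traits (not residuals) matches the
default of the published method; under a true group effect it inflates the
simulated variance and is therefore conservative.

P-values use the add-one estimator p = (1 + #{F_sim ≥ F_obs})/(n_sim + 1),
which is never zero and never below 1/(n_sim+1) — a documented divergence
from implementations that report the raw exceedance proportion. Post hoc
pairwise comparisons use pooled-variance t statistics (Welch by flag),
each referenced to the same simulated draws as the omnibus test (shared
draws; cheaper, and the comparisons remain mutually consistent), then
Holm-adjusted by an explicit step-down with monotonicity enforcement.

Degenerate inputs: zero within-group variance with unequal means yields an
F = +inf sentinel; groups need ≥ 2 observations; unmatched tree/trait
labels raise an error listing the offenders. On a star tree the simulated
null reduces to the iid parametric F test, and under a correctly specified
Brownian null the test is calibrated — both properties are verified by
Monte-Carlo experiments in the test suite (500 null replicates at
n_sim = 400 on 30-tip Yule trees with a 19/11 group split, and binomial
99 % bounds on the rejection rate).

## Synthetic data

The generator is a pigment-absorption model:
R(λ) = baseline · exp(−Σ_k strength_k · G(λ; centre_k, width_k)) + noise,
clipped to [0, 100] %. Band centres follow literature-style absorption
maxima — chlorophyll a ~430/670 nm, chlorophyll b ~455/645 nm, a
carotenoid triplet ~425/450/480 nm, anthocyanin ~540–560 nm, plus a broad
UV absorber — and strengths/baselines are drawn uniformly within
class-specific ranges (editable YAML presets). The noise is
Gaussian-kernel-smoothed white noise (correlation length 15 nm, default sd
0.5 pp), smooth enough not to create spurious marker points at the default
detector settings.

Class presets were set once so that (a) absolute reflectances are
realistic for petals and leaves, and (b) the class-level outputs mirror
the qualitative structure reported for real European green-flowered
species: green flowers similar in spectral shape to foliage but brighter
(hence low chromatic but substantial achromatic contrast, most spectra
below the 0.11 EU bee threshold), green–yellow flowers with
carotenoid-suppressed blue and an elevated long-wavelength plateau (hence
roughly four-fold higher chromatic contrast, all above threshold, loci in
the fly yellow quadrant), marker points clustering near 500 and 600 nm for
the study classes and near 400/500/620 nm for blue–violet flowers. Default
class counts (19/11/28/25/9/38) copy the emulated study design.

What the generator does *not* emulate: structural colour, specular and
geometry effects, sensor noise spikes, UV-reflecting nectar guides,
pigment covariance across the phylogeny (spectra are drawn independently
of the tree), and real within-species replicate structure. Passing tests
on synthetic data therefore establish that the *machinery* is correct and
that the qualitative class contrasts follow from the assumed pigment
composition — not that any particular real species has these values.

Trees are pure-birth (Yule) trees, grown by exponential waiting times with
all active branches extended in lockstep (hence exactly ultrametric), tip
labels shuffled onto tips. Trait datasets add group mean shifts to BM tip
values for power/type-I experiments.

## Reproducibility and problem sizes

Every stochastic component takes a seed (numpy `Generator`); the pipeline
derives per-stage streams from one master seed via `SeedSequence`, records
the seed and a configuration hash in every output header, and writes
byte-identical tables on repeated runs. The test suite exercises the
statistical claims at sizes chosen to keep Monte-Carlo error well inside
the asserted bounds: 10 000 BM draws for moment checks, 500 replicates for
type-I calibration, 200 fixtures for marker recovery, seeds 1–20 for the
directional end-to-end reproduction; the acceptance script runs the full
130-species study with n_sim = 10 000.

## Known limitations

* Receptor curves, foliage background and the exact smoother/detector
  internals of the software used in the emulated study are conventions,
  not published data; species-level EU values are therefore comparable
  only in structure, not digit-for-digit.
* Achromatic contrast is defined for the bee model only; fly achromatic
  processing is not modelled.
* Receptor-noise-limited (ΔS) discrimination models, tetrahedral spaces
  and brightness/saturation metrics are out of scope.
* The BM rate is held fixed across simulations; non-Brownian nulls
  (OU, rate shifts) are not implemented.
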