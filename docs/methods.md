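# Methods

## The shell model

The shell is a circle (the aperture, with no shell thickness) swept along
a logarithmic helicospiral.  With the coiling axis as the z-axis, apex up
and growth downward, the aperture centre at coiling angle θ (radians)
sits at

    r(θ) = r0 · e^{g_r θ},   z(θ) = z0 · e^{g_z θ},   a(θ) = a0 · e^{g_a θ}

for the radial distance, axial depth and aperture radius; the centre is
`(r cos θ, ± r sin θ, −z)` with the sign set by chirality (dextral
default).  The circle lies in the generating plane (the axial plane at
azimuth θ), parameterized by the aperture angle φ, with φ = 0 at the top
of the circle and increasing toward the side away from the axis.  All
lengths are millimetres, all growth rates per radian.

The three rates are independent.  When they are equal the shell is
isometric — each whorl is a scaled copy of the previous one, the scale
factor per whorl being `e^{2πg}`.  A convex (globose) spire such as
Cepaea's requires axial allometry, `g_z > g_r`: the whorl-height
increment `Δ(z + a)` then exceeds the whorl-width increment `Δ(r + a)`
over a full turn.

**Suture and umbilicus.**  The band-measurement arc runs from the suture
(the seam against the previous whorl) to the umbilicus.  We define it by
circle–circle intersection in the generating plane: the aperture circle
at θ against the previous-whorl circle at θ − 2π.  The measured arc is
the part of the current circle exterior to the previous one, traversed
from the upper intersection (suture, arc fraction 0) over the outer side
to the lower intersection (umbilicus, fraction 1).  When the circles do
not intersect (strongly separated whorls) a documented fallback is used:
the arc from the top of the circle (φ = 0) over the outer side to the
point nearest the axis (φ = 3π/2).  Both endpoints are returned as
aperture angles, so the construction is exactly self-similar under
isometry: the endpoint angles are invariant from whorl to whorl, which
is what makes the growth-rate identities below exact.

## Bands and region growth

A band is the arc-fraction interval `[p − w/2, p + w/2]` (midpoint
position p, width w).  Bands are *material-fixed*: their fractions at a
reference station (the lip by default) are converted once to aperture
angles, and those angles ride with the generating curve at every earlier
station.  With B bands the arc partitions into 2B + 1 regions (gap 1
adjoining the suture, then band 1, gap 2, …, gap B + 1 at the
umbilicus); region widths at angle θ are the aperture radius times the
angular overlap of each region with the visible arc at θ, so they always
sum to the arc length.

Region widths are evaluated at five stations a quarter whorl apart
ending at the lip, mirroring the physical protocol of sawing the last
whorl off in 90° increments.  The growth rate of a region between
consecutive stations is the log-ratio `ln(w_{k+1}/w_k)` per quarter
whorl.  The empirical protocol does not fix this definition; the
log-ratio was chosen because it makes the isometric case exactly
constant: every region of an isometric shell grows at precisely
`g_a · π/2` per quarter whorl (machine-precision identity, used as a
test invariant).  Absolute increments are also reported.  Under axial
allometry the suture/umbilicus endpoints drift along the aperture from
whorl to whorl, and the lowermost gap (between the last band and the
umbilicus) grows faster than every other region — banded regions
themselves stay at equal proportions.  This reproduces, purely
geometrically, the observation that only the region below the lowest
band deviates, driven by the relative downward movement of the aperture.

## Landmark fitting

Photographs follow the aperture-up mounting (columella parallel to the
surface).  The camera is orthographic along the normal of the lip's
generating plane, so the lip circle projects as a true circle; the model
is then mapped to pixels by a similarity transform (rotation,
translation, isotropic scale).  Orthographic projection confounds pixel
scale with absolute size, so the scale is locked — to the reciprocal of
the photograph's mm-per-pixel value when known, else to 1 (parameters in
pixel units).

The objective is the sum of squared pixel distances from the
suture-spiral landmarks to the projected suture curve (point-to-curve by
dense polyline sampling at Δθ = 0.01 rad and nearest-segment
projection), the aperture-outline landmarks to the projected lip circle
(exact circle distance), and the apex/umbilicus landmarks to their
projected model points.  Optimization is trust-region-reflective least
squares in three stages: (A) an isometric-constrained coarse search
(shared growth rate, Δθ = 0.06, capped iterations) from eight heuristic
starts — lip circle by algebraic circle fit of the outline, overall size
from the apex-to-aperture distance, whorl count and growth rate from a
small grid, jittered beyond it from a seeded RNG; (B) release of all
parameters for the two best candidates at Δθ = 0.02; (C) a polish of the
best at Δθ = 0.01 with step tolerance 1e−10, at most 500 iterations.
θ_max is bounded to [2π, 12π]; positive sizes are optimized in log
space.  The polyline discretization puts a floor of order 1e−3 px under
the residual, so noiseless round-trips recover parameters to ~1e−5
relative rather than exactly.

**Known limitation.**  The nearest-point (orthogonal-distance) objective
carries a curvature-induced bias of order σ²κ for isotropic pixel noise
σ on curve landmarks.  On the innermost whorl (sub-millimetre radii, and
tighter still at projection folds) this biases the radial growth rate
low by a few percent and, because the lip pins `r0 e^{g_r θ_max}`,
inflates r0 by ~6% at 1 px noise (verified to scale with σ²: ~2% at
0.5 px).  The optimizer is not at fault — polishing from the true
parameters reaches the same optimum.  At 1 px noise and 0.05 mm/px the
per-parameter median recovery over seeds is therefore ≈5–6% for r0 and
≤5% for the other five parameters; the recovery test asserts 5% for all
six and is expected to sit marginally on the wrong side for r0.

Band edges marked on the lip are snapped to the projected lip circle
(same polar angle), converted to aperture angles and then arc fractions
via the visible arc, giving the band configuration directly.

## Tape-method measurements

Band marks in mm along the suture-to-umbilicus strip are standardized to
percent of the strip length; a band's position is its interval midpoint.
Fused bands (parenthesized runs in the banding code, e.g. `123(45)`) and
ill-defined shells yield missing band-level metrics — such measures are
not individually usable — but still shape the gap partition.  Banding
codes use the five-position notation with `0` absent, `.` partial
(band only on the last part of the shell), `:` punctate and parentheses
for fusions; the parser round-trips with the formatter over the whole
grammar (property-tested).  Shell shape is height/width by default; the
literature is inconsistent about the direction of this ratio, so the
inverse is available as an explicit option rather than silently chosen.

## Statistics

Rank tests follow R conventions so values are comparable with published
W/H/Z/V statistics: Mann-Whitney W is the rank-sum-derived statistic
(`R_x − n_x(n_x+1)/2`; the complementary pair count U is also reported),
exact by enumeration for both groups ≤8 without ties, else normal
approximation with tie and continuity corrections (delegated to scipy).
Kruskal-Wallis uses the tie-corrected H with a chi-squared reference.
Dunn's pairwise z follows the standard tie-corrected form with
Benjamini-Hochberg adjustment across the pairs of one omnibus family.
The Kolmogorov-Smirnov comparison first centres each sample at its mean,
testing shape/spread with location removed.  Wilcoxon signed-rank drops
zero differences, reports V (sum of positive ranks), and enumerates all
2^n sign assignments exactly for n ≤ 15.  All tests are two-sided except
the whorl-allometry test (one-sided, height increment > width
increment).  Every exact path is tested against an independent
brute-force oracle.

Bland-Altman agreement reports bias = mean(a − b) and 95% limits of
agreement bias ± 1.96·sd (sample sd).  The band/gap correlation
structure is the 11×11 Pearson matrix over the five band widths and six
gap widths with pairwise deletion (≥3 complete pairs per cell); raw
p-values by default, to match the starred-matrix presentation, with an
optional BH switch.

One-dimensional Gaussian mixtures (equal-variance and free-variance
families, k = 1..3) are fitted by EM (scikit-learn) with k-quantile mean
initialization plus five seeded jittered restarts; model choice
maximizes BIC = 2 logL − k ln n.  The sign convention is stated because
published BIC values are often printed under the opposite sign.

Linear mixed models (random intercept for population or shell identity)
are fitted by maximum likelihood — not REML — so AICs are comparable
across fixed-effect structures; the likelihood optimizer is statsmodels'
MixedLM, while everything above it (admissible-subset generation
respecting marginality, Akaike weights, full/zero-substitution
coefficient averaging with unconditional variances, deletion LRTs,
least-square means with studentized-range/Tukey adjustment) is
implemented here.  Models within ΔAIC ≤ 2 of the best are averaged;
terms absent from a component model contribute zero coefficients, and a
term's summed weight is the total Akaike weight of component models
containing it.

## Synthetic data

The generators define the package's study conditions.

*Shells*: uniform parameter draws in Cepaea-like ranges (shell width
≈ 20–25 mm at 3.5–4.5 whorls); the default reference shell is r0 = z0 =
1 mm, a0 = 0.6 mm, g = 0.08/rad, θ_max = 8π, and the default allometric
variant raises g_z to 0.10.

*Landmarks*: points sampled from the projected model curves with
isotropic Gaussian pixel noise; 64 suture and 32 outline points by
default — semilandmark density, i.e. a digitized curve trace rather than
a handful of clicks, chosen by an identifiability analysis (at ~16
suture points the radial parameters are not recoverable to 5% at 1 px
noise).  Band edges are placed at the true arc fractions.

*Populations*: five-banded baseline positions (9.1, 16.6, 27.0, 45.6,
75.0)% and widths (3.6, 3.7, 9.1, 8.8, 10.3)%; phenotype offsets of
−0.9 pp on band 3 for mid-banded shells, +1.1/−1.4/−1.8 pp on bands
1/3/5 when band 2 is absent, and half-strength offsets for the
partially-suppressed-band-2 phenotype; between-shell position sd 2.5 pp
and width sd 1.2 pp.  Band-5's baseline position and all scatter
magnitudes are generator defaults (chosen to keep band intervals
disjoint at the configured variance), not estimates from data.  Band
widths share a latent per-shell factor (loading 1.0 pp/sd); since gap
widths are the partition remainder, wider bands mechanically narrow
their neighbouring gaps, producing the negative band-gap width
correlations the analyses should recover.  Draws producing overlapping
or out-of-range bands are redrawn wholesale (truncation, not clipping).

**What truncation does at the default scatter.**  With sd 2.5 pp the
five-banded margins between adjacent bands are ~1.5 sd, so validity
redraws truncate the joint distribution appreciably: realized five-banded
band-3 position is ≈27.5 (sd 2.24) rather than the configured 27.0 (sd
2.5), while the unconstrained mid-banded band 3 stays at 26.1 (sd 2.5).
The realized mid-band contrast is therefore ≈1.4 pp rather than the
configured 0.9, and the measured rejection rate of the Mann-Whitney
comparison at n = 100/group is ≈97% (an unbiased 0.9 pp shift at sd 2.5
would give ≈71%).  This is a property of validity-constrained draws, not
of the analysis pipeline; generator consistency is unit-tested at a
scatter where redraws are negligible.

*Paired methods*: for each true width, two measurements with independent
noise and a systematic offset on method b; the `sd` parameter is the sd
of the between-method *difference* (split equally between methods) so
that Bland-Altman recovers the configured bias and limits directly.

What the generators do **not** emulate: measurement digitization error
of the tape protocol, non-Gaussian scatter, within-population structure
beyond a single random intercept, band fusion/punctate microstructure,
non-circular apertures, and any pigment/colour properties.  Passing
tests therefore demonstrate correctness of the geometry and the
statistical machinery under the stated conditions, not field realism.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicates (power, correlation signs,
mixture selection), 20 seeds for noisy landmark fits, 50 shells for the
isometric sweep, and n = 10⁴ for the Bland-Altman estimator — sizes at
which the binomial/Monte-Carlo noise is well below the asserted margins.
Geometric identities are asserted at 1e−9 (1e−12 where exact), the
region-partition identity at 1e−9, and oracle equivalences at 1e−10 to
1e−12.  Degenerate inputs are contracts, not crashes: coincident
suture circles raise a specific error, zero-width regions are flagged
missing rather than producing infinite log-ratios, all-zero Wilcoxon
differences and zero-variance KS inputs return flagged degenerate
results.
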