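# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that were genuinely open.

## Pseudoexon inclusion from splice junctions

Junction records follow the STAR `SJ.out.tab` convention: 1-based inclusive
intron coordinates, where `intron_start` is the first and `intron_end` the
last intronic base. No internal re-encoding is performed; every coordinate
comparison in the package uses this convention.

Junctions with fewer than `min_count = 3` unique reads are discarded before
classification ("below 3" is strict, so a count of exactly 3 is retained).
Inclusion is then estimated from the donor-side junction pair:

    psi = n(donor -> pseudoexon) / [n(donor -> pseudoexon) + n(donor -> acceptor)]

The donor side is the default because each transcript contributes exactly
one donor-side splicing event; counting both of the pseudoexon's flanking
junctions would weight included transcripts twice. `side="acceptor"` and
`side="both"` (average of the two inclusion counts) are available for
sensitivity checks. If neither informative junction has reads the estimate
is undefined and an error is raised rather than returning 0 or NaN.

Junction abundances are normalized as counts per million mapped reads.
Transcript-length normalization is meaningless for point-like junction
events, so no length term enters.

Because "an X% reduction in inclusion" is ambiguous, `inclusion_reduction`
reports both conventions: relative (1 − after/before, in %) and absolute
(percentage points). For 0.945 → 0.064 these are 93.2% and 88.1 pp.

PTC detection translates the pseudoexon from a caller-supplied
`frame_offset` (0–2, set by the phase of the upstream exon) in steps of 3,
flagging TAA/TAG/TGA under the standard nuclear code; a trailing partial
codon is ignored. Alternative genetic codes are deliberately unsupported.

## Thin filament length from phalloidin profiles

Each actin band in a 1D intensity profile is modelled as a rectangle of
height A on baseline B, width W, flanked by two half-Gaussians of widths
σ_left and σ_right that start at the plateau edges (continuous by
construction). Derived quantities:

* TFL = W/2 + FWHM/2, with FWHM = 2·√(2 ln 2)·σ̄ and σ̄ the mean of the two
  edge sigmas. Averaging the sides was an open choice; the two sigmas are
  reported separately in the per-band output so either convention can be
  recomputed.
* SL = distance between centers of adjacent fitted bands. Each band's TFL
  is attributed the mean of its adjacent SLs (its single adjacent SL at
  profile ends) and retained only if that value lies in the inclusive
  window [2.4, 2.8] µm, the sarcomere-length range in which thin-filament
  measurements are comparable across images.

Fitting is a bounded trust-region least squares (scipy) in two passes per
band: pass 1 uses all samples in the window; pass 2 re-fits with samples
within ±`mask_fraction`·W/2 of the pass-1 center de-activated, which removes
the small central intensity bump caused by actin overlap across the Z-disk.
`mask_fraction` defaults to 0.25 — the bump is small and central, and a
quarter of the half-width removes it (±2.9 bump sigmas for a bump whose
FWHM is 10% of W) while leaving ≥ 75% of the plateau to pin W. The extent
is configurable because no canonical value exists.

Band centers are initialized from local maxima of a smoothed profile
(smoothing σ = min_separation/4), then refined to the midpoint of the
half-maximum crossings: on a flat-topped band the smoothed argmax wanders
with noise while the steep edges barely move. Multi-band profiles are
fitted band-by-band with windows of ±0.75·SL clipped at the midpoints
between neighbouring centers, followed by two refinement rounds in which
each band is re-fitted on the profile minus the modelled contribution of
the other bands. The clipping matters: beyond the midpoint the *neighbour*
dominates the signal, and including that region makes the single-band
residual sensitive to neighbour-parameter error, slowing the refinement
from ~10× error reduction per round to ~1.5×. On noiseless three-band
profiles the scheme recovers TFL to ~4×10⁻⁵ µm after two rounds.

Degenerate fits raise instead of returning junk: non-convergence, a width
collapsing below two sample spacings, or a fitted amplitude smaller than
3× the residual RMS (no credible band, e.g. pure noise).

A helper extracts 1D profiles from 2D grayscale arrays by bilinear sampling
along a line with averaging across a configurable line width; image
deconvolution and 2D segmentation are out of scope, and profiles are the
canonical input.

## Ex vivo mechanics

PCSA (cm²) = m·cos θ / (ρ · L₀ · Lf/Lm), with muscle density ρ defaulting
to 1.056 g/cm³, the standard physiological value; pennation angle and the
fiber-to-muscle length ratio are per-muscle inputs. Specific force is
force/PCSA in mN/cm² (an N/cm² toggle exists since conventions differ).

The force–frequency relation is the four-parameter sigmoid
P₀(F) = P₀min + (P₀max − P₀min)/(1 + exp((F½ − F)/k)), increasing in F for
k > 0 — the exponent sign is chosen so that F½ is the half-activation
frequency. Fits are bounded (all parameters positive) with data-driven
initialization (min/max force, frequency nearest mid-force, span/4); a flat
force profile is rejected as unfittable. Encoded stimulation protocols:
soleus {1, 5, 10, 20, 40, 60, 80, 100, 150} Hz, EDL the same plus
{200, 250} Hz; the fatigue protocol is 74 tetani at 3 s intervals, with the
fatigue index = mean(last 5)/mean(first 5) peak forces.

Two genotype curves are compared by the extra-sum-of-squares F-test:
F = [(SS_shared − SS_sep)/(df_shared − df_sep)] / (SS_sep/df_sep) with
df = n − p (p = 4 shared, 8 separate), upper-tail p from the F
distribution. The test is approximate for nonlinear models; on null
simulations at 2% noise its type-I error is close to nominal (checked in
the test suite). No multiple-testing correction is applied — one
comparison per muscle.

## Histomorphometry

Area is the absolute shoelace value (orientation-independent, repeated
consecutive vertices collapsed). The minimum Feret diameter is computed by
rotating calipers on the convex hull: the minimum projection width of a
convex polygon is attained perpendicular to one of its edges, so scanning
hull edges and taking the farthest-vertex distance per edge is exact. The
test suite cross-checks against a brute-force direction grid (0.01° scan
with 1000× local refinement, since the width function has V-shaped minima
at which a uniform grid's error is linear in the step).

Fibers with area < 300 (native input unit — the threshold is unit-agnostic
configuration) are discarded as segmentation artifacts; exactly 300 is
retained. Min-Feret histograms use half-open bins [i·w, (i+1)·w) with
default width 5 µm from 0. Fiber-type calls (I/IIa/IIx/IIb) are summarized
as per-sample percentages and group mean ± SD.

## Densitometry

Within the linear range of a protein stain, OD grows linearly with loaded
volume; the OLS slope of OD on volume estimates concentration while
cancelling per-lane loading error. The intercept is estimated rather than
forced through zero because background staining produces nonzero OD at zero
load (a through-origin toggle exists). R² < 0.9 triggers a saturation
warning. Expression = target slope / MHC slope of the same sample, then
100 × ratio / mean(WT ratios). The same ratio/percent operations serve the
single-load Western-blot variant when a background-subtracted band
intensity is supplied in place of a slope.

## Synthetic data generators

Every generator is a pure function of (config, seed) and returns the data
plus a truth record holding the generating parameters and the quantities
the pipeline should recover; recovery tests compare against truth, never
against hard-coded constants. Defaults encode the study conditions:
junction depth 200 at inclusion probability 0.945 with 3 spurious 1–2-read
junctions; profiles with W = 1.72 µm, σ = 0.16986 µm (TFL 1.06 µm),
SL 2.6 µm, A/B = 100/10 AU, 0.02 µm sampling; sigmoid (5, 25, 40 Hz, 8 Hz)
over the soleus protocol with 2% noise; fatigue decay
F₀·(r + (1−r)·e^(−i/τ)) with r = 0.4, τ = 12 over 74 tetani; lognormal
min-Feret targets (median 38 µm, shape 0.25) realized as regular hexagons
(exact closed-form min Feret for even and odd vertex counts); fiber-type
proportions from the wild-type TA composition, with the mutant composition
available as a constant; dilution series over volumes 1–6 µL with
nebulin:titin:MHC slopes 0.5:0.8:1.0 and 5% noise.

Published fiber-type compositions carry rounding error (they sum to
1.0001); proportions are renormalized when within 0.5% of 1 and rejected
otherwise.

Noise models are deliberately simple: binomial/multinomial for counts,
multiplicative Gaussian for profile intensity, additive Gaussian for forces
and ODs, lognormal sizes. Real data add features the generators do not
emulate — optical blur correlated across samples, out-of-focus myofibrils
crossing a line profile, gel smiling, partially sectioned fibers, junction
mapping artifacts that survive the count filter. Passing the recovery
tests therefore demonstrates the estimators are correct and calibrated
under the stated noise models, not that they are robust to every artifact
of acquisition.

## Problem sizes and numerics

Simulation-based checks use 100–500 seeded replicates (500 for null
calibration of the F-test and densitometry bias, 200 for noisy TFL
recovery and the min-Feret oracle, 100 for sigmoid noise), sizes at which
binomial counting error on an empirical rate is a few percent — adequate
to detect miscalibration without excessive runtime. Optimizer tolerances
are scipy defaults (≈1e-8); noiseless recovery tests assert at 1e-4–1e-6
relative, leaving two orders of magnitude of headroom. Ties and degenerate
inputs raise typed errors (`NoInformativeJunctionsError`, `BandFitError`,
`ValueError`) rather than returning sentinel values.

## Known limitations

* Inclusion estimation assumes the locus model's coordinates are exact;
  cryptic splice-site micro-heterogeneity would need fuzzy junction
  matching.
* The band model assumes an isolated myofibril axis; profiles crossing
  obliquely through multiple myofibrils violate the single-band-per-
  sarcomere assumption.
* The extra-SS F-test treats points as independent; repeated measures per
  animal are not modelled.
* Min-Feret on heavily concave outlines equals that of the convex hull by
  definition of a caliper — this is the standard convention, not an
  approximation, but it differs from "minimal inscribed width" notions.
* The fatigue index depends on the first five tetani already including
  decay; for fast decay (τ comparable to 5 tetani) the index exceeds the
  asymptotic floor r of the generator's decay model, and the closed form
  mean(last 5)/mean(first 5) of the decay curve is the correct expectation.
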