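# Methods

This package implements the quantitative analyses used to characterize
polymer-supported lipid bilayers and early T cell signaling on them:
single-particle diffusion, FRAP, calcium-transient metrics, two-channel
receptor-exclusion quantification, and AFM force-curve analysis. Every stage
has a matching synthetic-data generator with known ground truth, so the
whole pipeline is testable without experimental data. This note records the
models, the defaults that matter, and the numerical choices that were
genuinely open.

## Single-particle diffusion (`softslb.spt`)

**Detection and linking.** Spots are candidate maxima on a lightly smoothed
frame refined by local 2D Gaussian least-squares fits; SNR is reported as
(peak − local background) / background noise sd, with the local background
and its noise taken from the fit-window border (median / scaled MAD).
Linking is greedy mutual-nearest-neighbor between consecutive frames within
a maximum displacement, without gap closing: a missed detection terminates
the track. Ties are broken by smallest distance, then lowest index.
Positions are in pixels at the detection layer (origin at the center of the
top-left pixel, x right, y down) and converted to um by the caller.

**Track filter.** Only tracks longer than five frames (≥ 6 localizations)
enter diffusion analysis.

**Ensemble MSD.** Squared displacements are pooled over all tracks and all
(overlapping) start frames; the per-lag SEM comes from the pooled sample.
The first five lags are fitted with

    MSD(t) = 4 D t + 4 σ² − (4/3) D t_E

where σ is the static localization precision and t_E the camera
exposure/integration time (motion-blur correction). The printed form of
this model is ambiguous about whether the last `t` is the lag or the
exposure; both readings are implemented (`model="exposure"`, the default,
vs `model="lag"`, which collapses to (8/3) D t + 4 σ²). Published MSD
intercepts are quoted in different conventions (σ, σ², or the full 4σ²
offset), so the fit object exposes all three. Negative fitted D or σ² are
clamped to zero and flagged, never silently reported.

**Jump-distance analysis.** One-step squared displacements r² follow the
mixture density Σ_j [f_j/(4 D_j Δt)] exp(−r²/(4 D_j Δt)) — an exponential
mixture in r². The default fit is maximum likelihood on the raw r² sample
via EM (closed-form M-step, so the likelihood is non-decreasing every
iteration); a binned least-squares mode exists for cross-checking. At least
30 displacements are required. When the two fitted coefficients are within
a factor 2 the fit collapses to one component and is flagged. Components
are returned fast-first. Localization noise inflates the apparent
coefficient by σ²/Δt; the JD layer does not correct for this.

## FRAP (`softslb.frap`)

Recovery after Gaussian-beam bleaching is fitted with Axelrod's series

    F(t) = M_f Σ_{n≥0} [(−K)ⁿ/n!] / (1 + n(1 + 2t/τ_D)) + (1 − M_f) F0

truncated when the coefficient magnitude Kⁿ/n! < 1e−10 or at n = 60. Useful
limits: F(0) = M_f (1−e^{−K})/K + (1−M_f) F0 and F(∞) = M_f + (1−M_f) F0.
The diffusion coefficient is D = w²/(4 τ_D) with w the effective beam
radius, obtained by fitting the post/pre bleach ratio image to
exp(−K exp(−2r²/w²)). The simplified half-time estimate
D = 0.224 w²/t_{1/2} is reported alongside the Axelrod value, since
published numbers may use either.

The immobile-baseline level F0 is read off the first post-bleach frame by
default. That convention is self-consistent only when the bleach profile
satisfies F(0) = (1−e^{−K})/K; the synthetic generator derives its default
F0 the same way, and `fit_axelrod` accepts an explicit F0 for worlds where
the two are decoupled.

Normalization subtracts a background trace, divides by a
prebleach-normalized reference region (acquisition photobleaching), and
scales the mean of the last 10 pre-bleach frames to 1. The bleach frame is
the largest single-frame drop and must exceed both 5× the robust noise of
the remaining frame-to-frame differences and 5% of the pre-bleach level;
otherwise "no bleach event" is raised. Optimizer bounds: K ∈ (0, 10],
τ ∈ (0, 10 t_max], M_f ∈ [0, 1]; initialization from the bleach depth, the
measured half-recovery time, and the last-decile mean.

## Calcium metrics (`softslb.calcium`)

Cells are segmented per frame by Otsu thresholding of a log-compressed,
Gaussian-smoothed frame (log compression keeps the background/cell split
stable when single cells flare far above baseline), tracked by greedy
centroid linking, and measured as the mean of pixels above a per-region
half-max cut (excluding the smoothing-blurred rim). The baseline is the
median of the first 10 valid frames. Peaks are local maxima with height
≥ 1.5× baseline and prominence ≥ 0.5× baseline (both configurable; the
original criteria are unpublished, so quantitative agreement with published
population plots is not claimed). A cell responds when ≥ 1 peak passes,
blinks when > 1; the multipeak fraction is defined over responders only and
reported as missing — not 0 — when there are no responders. All metrics are
baseline-relative and hence invariant under rescaling the movie.

## Receptor exclusion (`softslb.exclusion`)

Channels are frame-averaged, rolling-ball background-subtracted
(radius 50 px default), and thresholded with Otsu's method over a 256-bin
histogram between image min and max (ties take the lowest threshold; the
implementation is checked against exhaustive inter-class-variance search).
The contact mask is the Otsu mask of the adhesion channel; the cell mask is
its union with the probe channel's own Otsu mask — the only set reading that
leaves an "outside the contact" region restricted to the cell footprint.

    Exclusion = 1 − mean(probe | contact) / mean(probe | cell \ contact)

Values may be negative (enrichment) and are never clamped. No morphological
cleanup by default; multifocal contacts are pooled into one mask.

## AFM force curves (`softslb.afm`)

**Contact point.** Baseline fitted on the leading 10% of the approach; the
first persistent crossing of baseline + 3 sd, refined by a local power-law
fit F = A (z − c)^p. Baseline-relative, so constant force offsets do not
move it.

**Hertz modulus.** Spherical indenter: F = (4/3)[E/(1−ν²)]√R δ^{3/2};
four-sided pyramid (Sneddon): F = [tan α/√2][E/(1−ν²)] δ², with ν = 0.5
(incompressible default for PDMS-like elastomers) and α = 35° as the
default face half-angle of a pyramidal probe. Indenter geometry is always a
required input, never inferred. The modulus fit jointly adjusts E (as
log E), the contact point, and a constant force offset, making it invariant
to baseline offsets.

**Push-through detection.** A bilayer breakthrough interrupts the
positive-stiffness branch with a near-constant or falling stretch whose z
extent (the z-jump) measures bilayer thickness. The detector scans a
change-point statistic: lines fitted to `w` samples before and after each
split point are extrapolated to the split and their offset compared with
the baseline force noise (estimated from first differences of the
pre-contact stretch, which is insensitive to contact-onset leakage). On a
smooth branch the curvature bias of the two extrapolations cancels; across
a breakthrough the offset equals (local slope) × (z-jump). Events exceed
5× the offset noise (one-sided); stacked events are resolved by recursive
segmentation. The window defaults to ~1/6 of the curve (capped at 1001
points): the offset noise scales as sd·√(8/w) while the breakthrough signal
does not decay with w, so wide windows are required to resolve nm-scale
jumps at sub-nm sampling (a 7-point window would have a noise floor above
the entire contact slope at 0.5 nm sampling and 0.02 nN noise). The
vicinity of the contact point (±1.2 w) is excluded because the stiffness
onset itself bends the extrapolations.

The z-jump is measured as the horizontal offset between quadratic fits of
the two flanking branches evaluated at the breakthrough force; when the
branch slopes agree within ~20% (bilayer on a stiffness-matched support) a
joint piecewise fit with shared parabola refines it. For a single curve at
a 2 nN breakthrough with 0.02 nN noise this estimator sits at the
Cramér–Rao bound of the piecewise model, ~0.3 nm sd — the information limit
of one curve, not an algorithmic ceiling. Slopes before/after are the
branch-fit derivatives at the event; their ratio near 1 indicates a
stiffness-matched support.

## Synthetic data (`softslb.synth`)

What the generators emulate — and what they deliberately do not:

- **Tracks**: per-axis Gaussian steps with variance 2DΔt, one or two
  populations, static localization noise added to positions. No sub-frame
  motion blur (the MSD fit's exposure term is the only blur model), no
  blinking or bleaching photophysics.
- **Image stacks**: Gaussian spots of fixed photon budget on a constant
  background with Poisson noise; `photons_for_snr` maps a target peak SNR
  to a photon budget. No EMCCD excess noise, drift, or aberrations.
- **FRAP traces**: exact Axelrod series plus Gaussian noise, sampled at 1 s
  over 3 min by default (the acquisition protocol of the experiments this
  models).
- **Calcium populations**: Gaussian transients (height in baseline
  multiples, FWHM 8 s) at exponential latencies (mean 120 s) on a constant
  baseline over 10 min at 1 s; the real waveform is not specified anywhere,
  so any unimodal pulse satisfying the prominence rule is equivalent for the
  detector. Default 70% responders, 30% of responders multi-peaked —
  representative of the reported 60–80% responder range.
- **Contact images**: disk/ellipse contact inside a larger cell footprint;
  the probe channel inside the contact is the depletion factor times its
  cell level, so mask-level exclusion equals 1 − depletion exactly in the
  noiseless, gradient-free case. No membrane topography.
- **Force curves**: flat baseline, Hertz contact, and an optional
  breakthrough implemented literally as a z-jump-wide bridge at the
  breakthrough force connecting to a substrate branch whose contact point
  is shifted by the z-jump (a flat plateau when layer and substrate
  stiffness match — the slope-ratio ≈ 1 observation). A force *drop* model
  was rejected: under a Hertz-shallow contact law a visible drop would
  correspond to a z offset far larger than a bilayer thickness. Defaults:
  4.59 kPa modulus, 3.9 nm jump at 2 nN, 0.5 nm sampling, 0.02 nN noise.
  No viscoelastic creep, no adhesion on retract.

All generators are bit-reproducible given (ground truth, seed).

Green tests on these worlds establish that each estimator recovers its own
forward model at realistic noise; they do not establish robustness to
drift, heterogeneous backgrounds, segmentation errors on irregular cell
shapes, or non-Hertzian mechanics.

## Degenerate inputs and tie-breaks

Constant images are rejected by Otsu ("degenerate histogram"); empty masks,
zero outside-means, all-zero force curves, missing bleach events, and
sub-30-displacement JD fits raise explicit errors rather than returning
numbers. Mobile fractions and diffusion coefficients outside their physical
ranges are clamped with warnings/flags. Otsu ties take the lowest
threshold; linking ties take the smallest distance.

## Known limitations

- JD fitting ignores localization-noise inflation of D (σ²/Δt).
- The calcium segmenter assumes non-touching, roughly convex cells; no
  merge/split handling.
- The push-through z-jump from a single curve carries ~0.3 nm statistical
  uncertainty at the default noise; population statements need tens of
  curves, as in practice.
- `estimate_beam_radius` assumes the bleach spot is fully inside the field
  and the frames are registered.
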