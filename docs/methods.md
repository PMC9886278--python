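# Methods

`sarcopaint` extracts the axial positions of protein epitopes relative to
the sarcomeric Z-disc from single-molecule localization tables, as
produced by DNA-PAINT imaging of striated muscle (the motivating system
is *Drosophila* indirect flight muscle, whose titin homologs Sallimus and
Projectin decorate the I-band and the myosin filament start at
reproducible nanometre offsets). This note documents the model behind
each stage, the parameters that matter, and the choices made where the
procedure was genuinely open.

## Pipeline model

A reconstructed DNA-PAINT acquisition yields a table of localizations
(`x`, `y` in camera pixels, pixel pitch 130 nm by default, frame index,
photon count, and the per-spot Gaussian-fit widths `sx`, `sy`). The
pipeline assumes reconstruction, drift correction and myofibril picking
have already happened upstream; its input is the localization table plus
rotated-rectangle picks.

1. **Multi-emitter filtering.** Localizations produced by two imagers
   bound simultaneously fit wider than the single-emitter PSF. The
   joint (`sx`, `sy`) distribution is histogrammed (bin 0.05 px); rows
   farther than 0.2 px (inclusive boundary) from the mode are discarded.
   The mode is computed per channel because dyes differ. The histogram
   bin and the inclusive boundary are our conventions; the 0.2 px radius
   is the established value for this filter. Ties between equally
   populated bins go to the narrower-width bin, since narrower fits are
   likelier single emitters.

2. **Axis alignment and projection.** Localizations are rotated into the
   pick frame (`r' = R(-angle)(r - center)`); rows outside the pick
   rectangle are dropped so neighbouring myofibrils cannot contaminate
   profiles. The axial coordinate (in nm) is histogrammed at the camera
   pixel pitch (130 nm) to form a low-resolution intensity profile. Bin
   grids are anchored at integer multiples of the bin size for
   reproducibility. The pick angle is authoritative; it is what the
   user drew around the myofibril.

3. **Z-disc detection.** Every epitope band cluster flanks a Z-disc, so
   Z-discs dominate the coarse profile. Candidate peaks (prominence
   ≥ 0.2 × profile maximum) are chained under the physiological
   constraint that neighbouring Z-discs are one sarcomere apart
   (3.5 µm ± 25%). The longest consistent chain wins; ties go to higher
   summed prominence, then leftmost. A missing Z-disc splits chains
   rather than being bridged, which keeps the spacing invariant simple.
   Positions carry up to one coarse bin (130 nm) of error; all
   nm-precision statements downstream come from band fitting, not from
   these peaks.

4. **Band extraction.** Around each Z-disc a ±600 nm window of the
   axial positions is histogrammed at 13 nm. Because DNA-PAINT
   accumulates stochastic binding events the raw histogram fluctuates;
   it is convolved with a unit-area Gaussian kernel (σ = 25 nm,
   truncated at ±4σ, edge-renormalized per source bin so counts are
   conserved exactly) and rough band positions are taken as local maxima
   (prominence ≥ 0.05 × window maximum, spacing ≥ 30 nm). Each rough
   position is refined by least squares on the *raw* counts with
   `A·exp(-(u-µ)²/2σ²) + c` in a ±40 nm window; the constant baseline
   `c` absorbs tissue background. Two robustness layers sit on top:

   - *Smoothing ladder.* Epitopes a few tens of nm apart (e.g. inner and
     outer bands at 50 and 98 nm from the Z-disc, 48 nm apart) merge
     under 25 nm smoothing. When fewer rough peaks than expected bands
     appear, σ is halved (down to one bin) and detection rerun. This
     automates the per-dataset tuning a user would otherwise do by hand.
   - *Joint refinement.* Single-band windowed fits are biased by a few
     nm when a neighbour's tail leaks into the window. All selected
     bands in a window are therefore refit together as a sum of
     Gaussians with one shared baseline, initialized from the windowed
     fits. When a doublet is merged beyond peak detection entirely, the
     widest fitted bump is split into two seed components and the joint
     fit separates them on the raw counts (at 48 nm separation and
     ~13 nm band width this is a well-conditioned mixture problem even
     though the smoothed profile shows a single maximum). Components the
     joint fit collapses back together are re-merged, so an absent band
     stays absent.

   Bands are partitioned left/right of the Z-disc. With exactly 2k
   bands (k epitopes per channel) the sorted midpoint splits them —
   robust to the half-bin error of the coarse Z-disc position, which can
   exceed the innermost offset — and the midpoint must agree with the
   coarse position within one coarse bin. Within a side, band identity
   follows sarcomere topology: the configured innermost epitope takes
   the band nearest the Z-disc. Pair midpoints of all epitopes at one
   Z-disc must agree within 15 nm; otherwise the topology is ambiguous
   and the Z-disc is skipped with a recorded reason. Each epitope's
   distance from the Z-disc is half the separation of its own band pair,
   which cancels the coarse-bin error and any residual asymmetry of the
   detected peak.

5. **Statistics.** Per-sarcomere half-distances are pooled unweighted
   across myofibrils and experiments. Point estimates are sample means;
   uncertainty comes from a nonparametric bootstrap (1000 replicates of
   the dataset's own size drawn with replacement; 95% interval from the
   2.5/97.5% empirical quantiles with linear interpolation — the
   quantile convention is ours). Dual-epitope ordering counts strict
   per-sarcomere inequalities, matched by Z-disc; ties count as
   not-closer. The separation-vs-sarcomere-length regression checks the
   pooling assumption: a slope consistent with zero means epitope
   distances do not scale with the (slightly variable) sarcomere length.

## Synthetic data

The generator emulates the *output* of reconstruction, not the camera:
a 1-D Z-disc lattice with period 3500 ± 100 nm (jitter), two bands per
epitope per Z-disc at ± its offset, axial spread
`sqrt(band_sigma² + precision²)` with band σ 12 nm and localization
precision 5 nm (inside the 4–8 nm range the technique delivers),
300 localizations per band, a uniform axial background (default
30 /µm ≈ 10% of signal), transverse Gaussian spread (SD = half the
900 nm myofibril width), arbitrary in-plane orientation, and frame
indices uniform over 15 000 frames (bookkeeping only — blinking kinetics
are deliberately not modelled, since the analysis consumes
localizations).

Two defaults deserve justification:

- **Per-sarcomere offset jitter (`offset_sd_nm`, default 3.5 nm).**
  Real sarcomeres show a few nm of biological spread in where an epitope
  sits; pooled 95% CIs of a few nm at n in the tens, and dual-epitope
  orderings that are strong but not unanimous (~42/45 at an 8 nm
  offset, implying a pair-difference SD near 5 nm), both point to a
  per-epitope SD of ≈3.5 nm. The jitter is drawn once per (epitope,
  Z-disc) and applied symmetrically to both bands, so the pooled mean
  remains the configured offset. Without it the generator would be
  unrealistically clean (per-sarcomere spread < 1 nm, pure fit noise).
- **Multi-emitter outliers.** An *additional* population (default 5% of
  rows) near band centres with doubled axial spread and (`sx`, `sy`)
  inflated by +0.3–0.8 px beyond the nominal 1.0 ± 0.04 px, so the
  0.2 px disc filter is meaningfully exercised and band-row counts per
  Z-disc stay exact for oracle tests.

What the generator does **not** emulate: frame-level blinking and
repeated-localization correlations, drift residuals, non-Gaussian band
shapes (real epitope arrangements near the actin lattice may be more
structured), depth-dependent background, and label-efficiency gaps.
Passing tests therefore demonstrate correctness of the extraction and
statistics under the stated geometric model, not robustness to every
artifact of real tissue data.

## Numerical choices and degenerate inputs

- Gaussian fits use bounded trust-region least squares; centres are
  bounded to the fit window, σ to [bin/4, 4 × fit half-width], baseline
  to [0, window max]. Non-convergence or a centre escaping the window
  marks the band failed (recorded per Z-disc, never fatal).
- Histogram grids: half-open bins `[left, right)`, edges at integer
  multiples of the bin size (coarse stage) or anchored at the window
  centre (band stage, so per-Z-disc windows share a relative grid and
  composites are exact bin-wise sums).
- Pick angles are normalized to (−π/2, π/2]; a pick with width > length
  is swapped with a warning. An empty pick, an empty profile, or a
  fully rejected filter input warn and return empty results rather than
  raising.
- All randomness (generator, bootstrap) flows from explicit integer
  seeds through `numpy.random.default_rng`; identical seeds give
  byte-identical tables and bit-identical statistics.

## Problem sizes

The validation suite simulates 30-sarcomere myofibrils (≈40 000
localizations) for parameter recovery, 45 sarcomeres per channel for the
dual-colour ordering check, and 500 datasets of n = 30 for bootstrap
coverage — sizes matching the scale of the experiments the pipeline is
modelled on, and comfortably desk-sized.

## Known limitations

- Bands closer than ~2× the band width cannot be separated by peak
  finding alone; the split-and-joint-fit rescue assumes at most two
  bands hide in one bump.
- Z-discs at pick edges keep only one flank's data; their bands still
  pair if both bands of each epitope lie inside the window.
- The coarse Z-disc stage assumes the band cluster is symmetric enough
  that its centroid tracks the Z-disc within one coarse bin; heavily
  one-sided labelling would violate this.
- `distance_vs_length` uses ordinary least squares and assigns each
  Z-disc the mean of its adjacent sarcomere lengths; measurement error
  in lengths (one coarse bin) attenuates steep slopes but is negligible
  for the near-zero slopes of interest.
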