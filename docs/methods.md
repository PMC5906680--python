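# Methods

This note records the models, parameter choices and numerical decisions
behind each module, and what the synthetic-data validation does and does
not demonstrate.

## Acquisition model and coordinates

All generators and estimators share one acquisition configuration:
107 nm pixels, 19 ms frame interval, a Gaussian PSF of σ = 128 nm
(≈1.2 px, typical for a ×150/NA 1.45 objective at far-red wavelengths),
and localization precisions of 19 nm (channel 0, AF647-like) and 25 nm
(channel 1, rhodamine-like). Positions are physical µm with the origin at
the field corner; pixel (i, j) covers the half-open square
[i·px, (i+1)·px) × [j·px, (j+1)·px); frames are 0-based. A single integer
seed makes every synthetic output bit-reproducible.

Emitter brightness (500 photons/frame) and background (10 photons/px/frame)
are package defaults chosen so that a single fluorophore is comfortably
detectable and the 70-photon state-separation threshold used in step
counting sits well below one molecule's level; they are configuration
values, not measured constants.

## Synthetic data (simkit)

* **Planar trajectories.** 2D Brownian steps with per-coordinate variance
  2DΔt; independent Gaussian localization noise per coordinate and frame.
  The displacement between consecutive *observed* positions therefore has
  per-coordinate variance 2DΔt + 2ε², matching the MSD model intercept.
  The immobile fraction is carved out first; the population fractions
  split the mobile remainder by largest-remainder rounding, so the
  per-population counts always sum to n.
* **Nanotube trajectories.** The axial coordinate is 1D Brownian motion
  with reflecting tube ends (finite tubes with particles bouncing off the
  ends); the transverse coordinate is the projection of a uniform angle
  on the tube circle — an arcsine-distributed wall position with variance
  (d/2)²/2 — plus localization noise, giving a closed-form transverse
  std of sqrt(ε² + d²/8) used in the width tests.
* **Movies.** Emitters are drawn as pixel-integrated Gaussians (error
  function differences), so photon mass is conserved exactly; Poisson
  shot noise applies to signal plus background.
* **Bleaching traces.** Per-fluorophore exponential lifetimes with mean
  150 frames — long enough that genuine dwells usually survive the
  50-frame filter while still exercising it — with levels at multiples of
  the single-fluorophore intensity plus white Gaussian noise.
* **Point-pattern pairs.** Pattern A is CSR at the requested density; B
  keeps a Bernoulli(α) subset of A jittered by an isotropic Gaussian and
  refills the remainder uniformly, so both patterns have equal expected
  density and the persisting fraction is exactly α in expectation.
* **Binding curves.** Exact pseudo-first-order phases with optional
  additive Gaussian noise.

What this emulates — and what it does not: the generators produce ideal
Poisson/Gaussian statistics, no drift, no out-of-focus blur, no motion
blur within a frame, no fluorophore re-activation, and exactly known
densities. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated stochastic models, not robustness to
every artefact of real recordings.

## Localization (localize)

Detection: difference-of-Gaussians band-pass (scales 1× and 2× the PSF
width), local maxima above the frame mean plus 4 robust standard
deviations (MAD/0.6745) of the filtered image, duplicate maxima within
2 PSF widths merged keeping the brightest. Refinement: bounded
least-squares fit of a pixel-integrated 2D Gaussian (position, photons,
background, width). The precision estimate uses the Thompson-style photon
formula σ² = (s² + a²/12)/N + 8πs⁴b²/(a²N²). Empirically the fitted
spread runs ~15–20% above this bound (the fit is least-squares, not
maximum-likelihood), which the tests account for by measuring the spread
directly; the photon level that reproduces a 19 nm spread at background
10 is ≈200 photons/frame.

The transverse width of elongated structures is fitted on the raw
projected localizations (5 nm binning of the perpendicular offsets)
rather than on a rendered image, avoiding bin-width bias;
FWHM = 2√(2 ln 2)·σ. The reported width convolves structure and
precision; `FwhmResult.deconvolved_width_nm` removes the precision in
quadrature under that stated convolution model but no claim is made that
this equals a physical tube diameter.

## Trajectories (trackstats)

Linking is per-frame optimal bipartite assignment (Hungarian algorithm on
squared displacements) with gap closing: a track end stays available for
`max_gap` missed frames and the allowed displacement grows linearly with
the gap. Merge/split modelling is deliberately omitted — at the pM-range
labelling densities this pipeline targets, trajectory crossings are rare,
and the tests use fields sparse enough that the assumption holds. Every
detection belongs to exactly one trajectory by construction.

Mobile/immobile classification thresholds the per-trajectory MSD-fitted D
at 0.05 µm²/s: an order of magnitude below the slow membrane-spanning
population (1 µm²/s) and safely above the apparent D of a stationary,
precision-limited emitter once the intercept term absorbs the noise.
Trajectories shorter than 5 frames stay unclassified. DBSCAN prefiltering
of immobile localizations uses eps = 3σ_loc (57 nm), 10 samples minimum,
100-frame windows and a 50-frame minimum cluster lifetime: an immobile
emitter deposits a precision-limited cloud, while a membrane-diffusing
emitter moves several pixels between frames.

Registration is a closed-form 2D Kabsch solution (rotation + translation);
collinear bead sets are flagged. Co-localization uses per-frame *mutual*
nearest neighbours within 107 nm (one pixel) to avoid double counting.

## Diffusion (diffusion)

MSD(lag) is the mean squared jump magnitude pooled over trajectories at
that lag; the fit is weighted least squares of MSD = d(2Dt + 2ε²) with
the per-lag jump counts as weights. Default lag windows: 1–5 for 1D
nanotube data, 10–50 for planar membranes (overridable). A negative
fitted slope yields D = 0 with a flag; ε is floored at zero. The
intercept-based ε estimate is noisy on a single dataset (sd ≈ 6 nm at
2000 30-frame trajectories) because MSD values at different lags share
jumps and are strongly correlated; tests therefore check unbiasedness of
the mean over seeds rather than single-run precision.

The jump-distance fit maximizes the likelihood of a half-normal (1D) or
Rayleigh (2D) mixture with per-component scale m_i = 2(D_iΔt + ε²) and a
*shared* ε supplied by the caller — one optical precision per dataset.
The scale inside the printed densities is deliberately the per-dimension
MSD: with this reading the 2D density is exactly a Rayleigh density,
which the simulation oracle confirms (reading it as the full 2D MSD 4Dt
would double the variance). EM updates are closed-form; each component
count k seeds one start from the (k−1) optimum with its heaviest
component duplicated, making the maximized likelihood provably
non-decreasing in k, plus a quantile-based and random restarts. Model
selection uses BIC with 2k−1 free parameters. MLE was chosen over
histogram least squares for being bin-free; the pdf values can still be
compared to histograms via the closed-form CDF (the χ² oracle test).

Oligomer profiling normalizes per-trajectory median intensity to a single
fluorophore reference and partitions trajectories (≥10 jumps) by their
MSD-fitted D, reproducing the brightness-vs-mobility analysis: in
synthetic mixtures where brighter particles diffuse more slowly, the
slow-D bin shows the higher normalized intensity.

## Step counting (stepcount)

The noise amplitude is estimated once per trace from the median absolute
first difference divided by √2·0.6745 (a Haar-type robust estimator,
insensitive to the sparse level changes). Recursive binary segmentation
splits each segment at the maximum-|t| point (ties broken by earliest
frame, segments processed largest-|t| first); a split is accepted while
its t statistic exceeds the Bonferroni-corrected two-sided normal
quantile for a 2% family false-positive probability over the candidate
split positions. Segments are then merged agglomeratively by level, and
the state count is chosen by a two-part description length
MDL = N/2·ln(SSE/N) + (k/2 + n_cp)·ln N subject to a 70-photon minimum
state separation; the constants are fixed in code and shared with the
exhaustive-search oracle used in validation.

Counting filters, in order: (1) dwells shorter than 50 frames that are
*local extrema* of the level sequence (transient excursions — blinking or
a molecule diffusing through) are removed; short dwells inside a monotone
staircase are genuine states and kept; (2) successive downward
transitions within 6 frames merge into one bleaching event; (3) counting
runs over the strictly decaying part, starting at the brightest state and
stopping at the first upward transition. On noiseless traces satisfying
both thresholds the segmentation is exact. Under exponential lifetimes
with mean 150 frames the 6-frame merge itself caps 3-fluorophore
recovery at ≈89% (two inter-bleach gaps, each short with probability
1−e^(−Δ/τ)); the counter is therefore validated both by its ≥90%
recovery on 2-fluorophore traces and by exact agreement with a
filter-aware oracle that applies the same merge rule to the true bleach
frames. No correction for incomplete labelling is attempted.

## PICCS (piccs)

C_cum(r) is computed by KD-tree pair counting with margin-exclusion edge
correction: only A-points farther than r_max from every edge act as
centres, so all counts are complete and
C_cum(r_max) = pairs/|A| holds exactly. The radii grid is 5 nm steps to
0.5 µm by default. The fit proceeds in two regimes: a linear fit of
C_cum against πr² for r ≥ 3σ (slope = background density ρ, intercept =
correlated fraction α), then a one-parameter least-squares fit of the
residual with α(1 − e^{−r²/2σ_c²}) for the correlation length, with α
held fixed; the window is refined once after σ_c is first estimated.
The Gaussian displacement kernel is the natural model for precision- or
jitter-limited persistence. The Monte Carlo null resamples B uniformly at
matched density and reports the 2.5/97.5 percentiles of the null α. A
single 50×50 µm field at 2 clusters/µm² yields α with sd ≈ 1.8
percentage points, so recovery of the 9.2% reference value averages ten
fields.

## Kinetics (kinetics)

Dissociation is fitted first (R₀e^{−k_d t}), pinning k_d; association is
then fitted with Req(1 − e^{−k_obs t}); k_a = (k_obs − k_d)/C and
K_D = k_d/k_a follow. k_obs ≤ k_d flags k_a as non-identifiable. An
optional global fit shares k_d across phases; on clean data it agrees
with the sequential fit. Note that K_D computed from the rounded
reference rates 1.5×10⁵ /(M s) and 4.1×10⁻⁴ /s is ≈2.7 nM; the module
reports k_d/k_a and does not adjust it toward any other quoted value.
The surface-density conversion is Γ·N_A/M with unit handling
(ng/mm² → g/µm²); the default molar mass of 96 kDa corresponds to a
six-helix-bundle DNA nanopore of ≈300 nt, and a helper sums average
nucleotide masses from strand sequences when the actual composition is
available (dye and cholesterol modifications, a few kDa, are not
included).

## Pipeline and problem sizes

`run_pipeline` executes all stages on synthetic data and emits one JSON
report; with a fixed seed the report is byte-identical across reruns.
The default problem sizes — 2000 planar trajectories of 30 frames, 200
nanotube trajectories of 60 frames, 100–200 bleaching traces, 50×50 µm
point patterns at 2 µm⁻², ten fields for the PICCS average — were chosen
so every recovery lands well inside its target tolerance while the whole
analysis completes in minutes on a single core. The test suite uses the
same or smaller sizes.

## Known limitations

* The detector/linker is a standard simplified stack, not a
  reimplementation of the published multi-target tracking and u-track
  algorithms; merge/split events and dense fields are out of scope.
* ε from the MSD intercept is imprecise on single datasets (see above).
* Step counting undercounts when bleach events coincide within the lag
  window — an intrinsic property of the filter, quantified above.
* PICCS assumes isotropic Gaussian displacement of persisting points and
  CSR background; structured backgrounds would bias the intercept.
* No drift correction, 3D PSF modelling, anomalous diffusion, or
  mass-transport-limited binding models.
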