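# Methods

`ulmflow` implements ultrasound localization microscopy (ULM) for planar
microchannel flow phantoms, together with a simulator that generates the
image sequences the pipeline consumes. This note documents the models, the
parameters that matter, and the choices made where the design was open.

## Flow model

A phantom is a planar graph of straight channel segments with rectangular
cross sections (width `w`, height `h`, both in µm; `h` defaults to 300 µm).
Flow is steady, laminar and one-dimensional per segment:

* **Conservation of mass.** Given the inlet volumetric rate `Q` (mL/min),
  the sectional mean velocity is `V = Q/A` with `A = w·h`. At every
  junction, daughter flows sum to the parent flow exactly. For equal-area
  daughters the symmetric rule applies (equal split), so a bifurcation
  halves and a trifurcation thirds the mean velocity.
* **Unequal daughters.** The split between unequal daughter channels is
  closed with a hydraulic-resistance rule, `R ∝ L/(w³h)` (rectangular-slit
  approximation, valid for `w ≫ h` and adopted uniformly), and
  `Q_i ∝ 1/R_i`. For a 300 µm main continuing past a 100 µm branch of equal
  length this gives a 27:1 split. This is a modelling choice, not a
  measured quantity: the real split also depends on outlet tubing and
  inlet leakage, which are not modelled.
* **Velocity profile.** Across the imaged width each channel carries a
  plane-Poiseuille parabola, `v(u) = 1.5·V·(1 − u²)` with `u` the lateral
  offset in units of the half width; the non-imaged height dimension is
  absorbed into `V`. The flux-weighted mean speed of bubble-carrying
  streamlines is `E[v²]/E[v] = 1.2·V`, the reference value for track-speed
  recovery.

Junctions are ideal zero-length nodes; there is no secondary flow, wall
elasticity, or CFD.

## Simulator

The simulator emulates ultrafast contrast acquisitions at the image level
(no RF beamforming): 250 Hz framing, 1500-frame blocks, 25 µm pixels,
Gaussian point spread functions (isotropic, σ = 1.5 px on the original
grid), and either CPS or B-mode.

* **Arrivals.** Bubbles enter the inlet as a Poisson stream with rate
  `λ = C·Q` (concentration × flow rate, per second); at the medium dose of
  6.4×10⁶ MB/mL and 0.02 mL/min this is ≈ 2133 s⁻¹. Entry offsets are
  flux-weighted (density ∝ local velocity) and truncated to |u| ≤ 0.95:
  a bubble of finite size cannot have its centre on the wall, and without
  truncation zero-velocity streamlines accumulate unbounded numbers of
  static bubbles.
* **Detectable fraction.** Only a fraction (default 0.01) of the nominal
  arrival stream is rendered and tracked. A real sequence images a thin
  elevation slab and only bubbles returning a strong, isolated nonlinear
  echo are localizable; at the nominal rate the channel would be a solid
  bright band with no resolvable peaks (over-concentration is known to
  break peak-based tracking). Thinning a Poisson stream keeps it Poisson.
  The default yields a handful of trackable PSFs in a 1.6 mm tiny field
  and stable saturation statistics over a 3000-frame window; it is a
  dial for detectability studies, not a physical constant.
* **Transport.** Per frame, each bubble advances by its local profile
  velocity; at a junction it enters a daughter with probability
  proportional to daughter flow, keeping its lateral offset; bubbles
  leaving an outlet are removed. An optional radiation-force term adds a
  constant +z drift and a per-step sticking probability at the far wall
  (defaults 0.05 mm/s and 0.02 — illustrative magnitudes only; the effect
  is qualitative).
* **Rendering.** CPS applies the pulse weights (0.5, −1, 0.5) to linear
  scatterers, whose contribution therefore cancels *exactly*; bubbles
  contribute a nonlinear residual with configurable amplitude (default
  1.0, no oscillation physics). B-mode sums both populations. Additive
  Gaussian noise (default sd 0.02 of bubble amplitude) is clipped at zero.
  Static scatterer fields place Binomial(n_px, density) point scatterers
  outside the channel footprint.

What the simulator does **not** reproduce: RF-domain effects (attenuation,
aberration, compounding artefacts), bubble resonance/destruction, red blood
cell crowding, elevation-plane geometry, flow pulsatility. Passing tests
therefore demonstrate the correctness of the processing chain under the
stated image-formation model, not performance on experimental data.

## Localization chain

Order: upsample → SVD clutter filter → temporal high-pass → rectify →
detect → localize, per acquisition block.

* **Upsampling** (default 2×) uses deterministic bicubic-spline
  interpolation on an extent-preserving grid, behind an interface so a
  learned super-resolution model could be swapped in. A learned upsampler's
  weights are not part of this package's contribution and would not be
  testable here.
* **SVD clutter filter** removes the first `n` (default 2) singular
  components of the Casorati matrix (pixels × frames). It is computed from
  an exact eigendecomposition of the frame–frame Gram matrix — identical
  to zeroing singular values of a full SVD, but never materializing the
  full decomposition.
* **Temporal high-pass**: second-order Butterworth along frames, applied
  forward–backward (zero phase) so bubble positions are not delayed.
  Default cutoff 0.02 × Nyquist (2.5 Hz at 250 Hz framing). At 1–17 mm/s a
  bubble dwells tens of milliseconds per pixel, so its per-pixel signal
  lives around 5–30 Hz; a 2.5 Hz cutoff rejects DC and slow drift while
  passing transits. (A 0.1 × Nyquist cutoff measurably destroys most
  genuine bubble signal at these speeds.)
* **Rectification and detection.** Detection operates on the magnitude of
  the filtered stack. Candidate peaks are 3×3 local maxima above an
  adaptive threshold with two terms: a robust noise floor
  (median + k·1.4826·MAD, k = 4) and a sidelobe floor of 0.4 × the frame
  maximum. The second term exists because subtracting low-rank components
  from sparse bubble data leaves structured residual (measured at
  ~0.2–0.5 of a bubble peak) that a global MAD — dominated by empty
  background — cannot see. Peaks closer than 4 px (upsampled grid) are
  suppressed keeping the brightest; exact ties resolve to the smaller
  (row, col), making detection deterministic.
* **Localization** refines each peak with a background-subtracted
  (window-minimum) intensity-weighted centroid in a 5×5 window, clipped at
  image edges; subpixel coordinates convert to mm via the upsampled pitch
  with pixel centres at index + 0.5.

## Tracking and maps

Localizations in consecutive frames are paired greedily in ascending
distance order (mutual nearest neighbours), gated at twice the largest
expected per-frame displacement (2·1.5·V_max/f in upsampled px); tie-breaks
follow table order, so linking is deterministic. No gap closing: a missed
frame ends the track. Tracks kept for velocity analysis must span strictly
more than 10 consecutive frames (≥ 11 localizations). Step speeds are
Euclidean displacements × frame rate; each step paints its speed onto every
grid cell its segment crosses (Bresenham), velocity cells average the
contributions, density cells count localizations. Channel mean speeds are
computed per track (one vote per bubble, which reproduces flux weighting)
and exclude steps within 0.2 mm of a junction, where channel footprints
overlap. Cross-channel profiles average 25 successive cross sections
perpendicular to the channel axis.

## Saturation statistics

Within a 25×25 px ROI (upsampled grid) placed just downstream of a
junction, the saturation curve is the fraction of vessel-mask pixels with
at least one localization by time `t` (time origin = first analyzed frame),
computed over a 3000-frame window and normalized by its maximum. The vessel
mask comes from simulation ground truth; for real data the pixels localized
over the full acquisition would serve as a surrogate. The curve is fitted
by least squares with the single-parameter form `S(t) = 1 − exp(−t/τ)`, so
τ is the time to 63 % (1 − 1/e) of the asymptote by construction; fits with
R² < 0.98 are flagged. Replicate τ groups are compared with an unpaired
two-tailed pooled-variance t-test at α = 0.05, and channel-width effects
summarized as percent increase of the branch τ over the main τ (both the
ratio of means and the mean of per-replicate ratios are computable; the
summary reports the ratio of means).

Normalization caveat: a channel receiving very few bubbles in the analysis
window produces a sparse staircase whose max-normalization can fabricate an
early plateau (the fitted τ then reflects the accidental timing of a
handful of events, not the fill rate); curves with no events at all are
flagged and not fitted. Saturation analyses therefore use the full
3000-frame (12 s) window by default, and studies of strongly starved
channels — e.g. the 100 µm branch carrying 1/28 of the flow under the
resistance split — extend the window to 6000 frames (24 s) so the branch
staircase resolves.

## Problem sizes and defaults

Two scales are built in. `tiny` (64×64 px, 300 frames, segment lengths
≈ 0.5–1 mm) runs in seconds and drives the test suite; saturation analyses
at this scale extend to 3000 frames (6000 for the starved-branch study
above). `full` (128×128 px, 9000-frame
velocity runs, 3000-frame saturation windows, 1500-frame blocks) matches
the full acquisition protocol. Tolerances used in validation: junction
conservation to machine precision; localization RMS < 0.25 upsampled px on
clean frames; detection precision/recall ≥ 0.95 for ≤ 10 well-separated
bubbles at SNR ≥ 10; track-speed recovery within 15 % of ground truth;
τ recovery median error < 10 % at noise sd 0.02.

## Known limitations

* The resistance split is a model; measured splits in physical phantoms
  will differ (tubing, leakage, wall compliance).
* The CPS model is an idealization: real linear-echo cancellation is
  imperfect, so experimental CPS frames contain residual clutter that the
  SVD filter then has real work to remove.
* The >10-frame rule plus the consecutive-frame requirement discards slow
  or intermittently detected bubbles, biasing velocity maps toward faster
  streamlines; the same bias exists in the emulated protocol.
* Sub-wavelength effects (PSF anisotropy, depth dependence, speckle) are
  not modelled; the Gaussian PSF makes localization accuracy optimistic
  relative to experimental data.
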