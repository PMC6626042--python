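# Methods

`omeflux` quantifies the surface dynamics of outer-membrane (OM) proteins in
rod-shaped bacteria — fluorescence recovery after photobleaching (FRAP),
kymograph/demograph profile analysis, protease-accessibility statistics and
contact-dependent cargo exchange — and ships a particle-based synthetic-
microscopy generator so that every estimator can be validated by parameter
recovery against known ground truth.

## The simulation model

**Geometry.** A cell is a centerline polyline with a width; all dynamics run
on the 1-D arc-length axis `s ∈ [0, L]`. This is deliberate: every
quantification in the package is a 1-D profile along the cell's long axis, so
the lateral coordinate matters only for rendering, where each particle keeps
a fixed random offset across the width. Poles are reflecting boundaries (the
membrane is a closed surface; axial projection of diffusion on it reflects at
the poles).

**Diffusion.** Particles take Gaussian steps of standard deviation
`sqrt(2·D·dt)`, folded into `[0, L]`. Folding a Gaussian proposal is the
*exact* transition kernel of reflected Brownian motion, so free diffusion is
sampled correctly at any step size; the simulator therefore steps once per
frame in pure-diffusion runs. A step-resolution check
(`sqrt(2·D·dt) ≤ length_scale`) is enforced only when binding or transfer
kinetics are active, because those discretize continuous rates into per-step
probabilities and assume positions change little within `dt` relative to the
capture region (a contact zone, by default half a pixel).

**Species.** Receptor-like species (TraA-like) carry an allele label, diffuse
slowly (default `D = 0.005 µm²/s`) and are never transferred between cells.
Cargo species (lipoprotein-like, SS_OM-GFP-like) have no allele, diffuse fast
(default `0.1 µm²/s`) and may be transferable. The defaults reflect the
qualitative contrast the data show — receptor mobility is visibly slower than
lipoprotein mobility — absolute values are free parameters of the generator,
not measured claims.

**Photobleaching.** A bleach event is a fast pulse train (positions frozen):
each fluorophore in the ROI goes dark independently with probability
`1 − (1 − p)^k` for `k` pulses (defaults `p = 0.6`, `k = 4`, within the 3–5
pulse range typical of confocal FRAP on these cells).

**Contact zones and the handshake.** A `ContactZone` is a pair of equal-length
arc intervals on two (possibly identical) cells. In an active zone whose
opposing cell carries a *compatible* receptor allele, free receptors bind the
zone with probability `1 − exp(−k_on·dt)` and release with
`1 − exp(−k_off·dt)`; deactivating a zone (cell separation) releases every
bond immediately. Binding is pairwise-free — a receptor binds "the zone", not
an enumerated partner — because no stoichiometry of the receptor clusters is
established. Incompatible zones never bind by construction. `k_on = 1/s`,
`k_off = 0.1/s` are package defaults chosen so foci form within tens of
seconds of contact, matching the observed ≤30 s focus formation timescale;
they are not measured rate constants.

**Cargo transfer.** A zone that holds at least one bound receptor pair (bound
receptors on both apposed intervals) lets transferable cargo inside either
interval switch cells with probability `1 − exp(−k_transfer·dt)`, mapped
interval-to-interval. Receptors never switch cells; global per-species counts
are conserved. Gating transfer on engaged receptor pairs reproduces the
control behaviour that recipients without the receptor machinery acquire
nothing. Motility is not modelled: contacts are declared, not emergent, and
the observation that motility is required for transfer but not for focus
formation is out of scope.

**Rendering.** Each fluorescent particle deposits a fixed photon count at its
2-D position (bilinear split over four pixels, so deposited signal is exact),
the image is blurred with a single 2-D Gaussian PSF (`σ = 0.1 µm`; no 3-D
optics), and noise is Poisson shot noise on signal + background plus Gaussian
read noise (defaults: 50 photons/particle, 100-count background, 2-count read
noise, 65 nm pixels — a typical 100× sCMOS configuration). Identical seed and
configuration reproduce every stack bit for bit; per-operation RNG substreams
are derived from `(seed, operation, call)` so operation order cannot perturb
reproducibility.

## FRAP quantification

With `I_FRAP(t)` the bleached-area and `I_total(t)` the whole-cell intensity
(pre-bleach frame labelled 0, first post-bleach frame t0):

1. **Relative recovery** `I_FRAP(t)/I_total(t)` — the ratio cancels
   acquisition photobleaching.
2. **Double normalization**
   `I(t) = I_FRAP(t)/I_FRAP(0) · I_total(0)/I_total(t)`,
   `I_norm(t) = (I(t) − I(t0)) / (I(0) − I(t0))`,
   so `I_norm(pre) = 1` and `I_norm(t0) = 0` exactly — both identities are
   asserted to machine precision in the tests.
3. **Recovery kinetics** `Y(t) = A·(1 − e^{ln(0.5)/t_half · t})` fitted by
   least squares to post-bleach `I_norm`, times measured from t0.
   Initialization is parameter-free (`A₀` = last observed value; `t_half,0` =
   interpolated first crossing of `A₀/2`). `A` is bounded at 1.05 rather than
   1 so that normalization problems surface as a warning instead of being
   silently truncated. The fit is unweighted; weighting is available nowhere
   because no replicate-variance model is assumed.
4. **Diffusion coefficient.** Per-frame axial profiles are normalized to
   their own mean (the kymograph normalization), post-bleach profiles are
   subtracted from the pre-bleach profile, each difference profile is fitted
   with a Gaussian, and the depth series follows
   `C(t) = C0·R0·(R0² + 8·D·t)^{−1/2}` with `C0, R0` from the first
   post-bleach frame.

**Gaussian convention (load-bearing).** The difference profile is fitted as
`C·exp(−2(s−µ)²/R²)`, i.e. `R` is the 1/e² half-width with `R² = 4σ²`. This
is the only convention under which the depth-decay law above is the exact
solution of 1-D free diffusion (`σ²(t) = σ0² + 2Dt ⇒ R(t)² = R0² + 8Dt`).
Fitting with the 1/e convention `exp(−(s−µ)²/R²)` while using the `8Dt` law
silently halves the recovered D — we verified this on simulated data.

**Immobile pools.** The decay law assumes every bleached molecule is mobile.
Two documented extensions handle an immobile fraction:

* *Constant floor*: `C(t) = C_inf + (C0 − C_inf)·R0(R0²+8Dt)^{−1/2}`, where
  `C_inf` absorbs the non-recovering part of the bleach
  (`estimate_D(..., immobile_floor=True)`; the stack analyzer enables it
  automatically when the recovery fit gives `A < 0.9`).
* *Late-reference subtraction* (preferred, `late_reference=True`): one or
  more reference frames are acquired long after the bleach, when the mobile
  pool has equilibrated. Their difference profile contains exactly the frozen
  immobile bleach pattern plus a uniform mobile deficit; subtracting it from
  every earlier difference profile cancels the immobile component
  identically, leaving a pure mobile Gaussian over a uniform offset. Those
  corrected profiles are fitted with a free baseline and the plain decay law
  applies. This is the analysis used by the reference parameter-recovery
  experiment.

Frames whose Gaussian fit fails are excluded from the depth regression, never
imputed. A rising depth series raises "no measurable spreading". A residual
bootstrap (default 200 resamples) provides a 95% CI on D when requested.

## Profile analysis

`extract_profile` samples bilinearly interpolated pixel values perpendicular
to the centerline (within an averaging width ≤ the cell width) at an axial
step of one pixel; it is exactly linear in the image. Kymographs divide each
frame's profile by its own mean — by construction every column has mean 1 and
the kymograph is invariant to per-frame global intensity drift. Demographs
resample junction profiles to the smallest input step, align them at the
junction midpoint (an explicit convention; no alignment is canonical), pad
with NaN and sort rows by junction length with a stable tie-break.
Dual-channel normalization scales each channel group by a single factor — the
one that brings the group's global peak to 1 — preserving relative signal
across a time series. The phrase "normalized based on signal correlation with
the peak signal" in common protocol descriptions is ambiguous; shared-scale
normalization is this package's reading, and users are warned accordingly in
the docstring.

Background handling: profile extraction subtracts an optional constant
background (known exactly for synthetic data, an annotated ROI otherwise);
the default is no subtraction.

## Exchange statistics

* `transfer_fraction`: `f_d = F_d/(F_d+F_r)` and `f_r = 1 − f_d` per time
  point; common acquisition-loss factors cancel and the fractions sum to 1 to
  the last ulp.
* `pk_accessibility`: per-cell `F_PK/F_0` ratios; groups are compared with an
  unpaired two-tailed pooled-variance t-test (Welch behind a flag). Pooled
  variance is the default reading of "unpaired two-tailed t-test" when no
  further detail is given.
* `junction_coloc` (package-defined, and labelled as such in its output):
  peak-position offset and Pearson correlation of the two junction profiles;
  a constant channel yields an explicit "correlation undefined" flag.
* `homogenization_index` (package-defined): per-cell balance
  `b_i = ch1/(ch1+ch2)` and `H = 1 − 2·mean|b_i − 0.5|`, clamped to [0, 1].
  `H = 0` for a perfectly bimodal population, `H = 1` when every cell is
  evenly labelled; invariant to channel swap and global rescaling. Cells with
  zero total signal are excluded with a warning.

## Reference experiments and problem sizes

The in-silico reference experiments (in `workbench`) use a 4 × 0.5 µm cell
and two acquisitions per condition, the way a microscopist would schedule
them:

* **Recovery series** — 0.6 µm central bleach stripe (good ROI counting
  statistics), 48 frames spanning six diffusive equilibration times
  `τ = L²/(π²D)` of the cell, 6 000 particles. Yields A and t_half.
* **Spreading series** — 0.26 µm near-diffraction-limited bleach spot (so the
  first difference profile is already Gaussian, the validity regime of the
  depth-decay law), 20 frames cadenced at `2R0²/(8D)` with `R0 = 0.17 µm`
  nominal, plus three late reference frames at `6τ`, 12 000 particles. The
  depth regression uses the first 12 frames, where the spreading Gaussian
  stays clear of the cell poles. Yields D via the late-reference analysis.

Cadencing the acquisition to the expected mobility mirrors real practice
(slow reporters are imaged over ~5 min, fast ones over ~2.5 min) and is part
of the study design, not of the estimator. Across
D ∈ {0.005, 0.02, 0.05} µm²/s × immobile fraction ∈ {0, 0.3, 0.6} with 20
replicates, the condition medians recover the mobile fraction within ±0.05
and D within ±20% (the acceptance suite asserts exactly this; observed worst
cases are ≈0.01 and ≈6–14% depending on seed).

The exchange experiment simulates 8 labelled cell pairs (200 receptors and
300 cargo per cell per label, `k_transfer = 0.2/s`) for 600 s: compatible
alleles homogenize to `H > 0.9`, incompatible alleles stay at `H ≈ 0` with
zero bound receptors throughout.

## What the generator does and does not emulate

It emulates: rod-cell geometry, species of different mobility, partial
sub-cellular photobleaching, contact-dependent receptor trapping with
allele-gated compatibility (including self-contact of filamentous cells),
bidirectional cargo exchange, PSF blur, shot and read noise, acquisition
series with metadata. It does not emulate: 3-D optics or axial defocus,
membrane curvature effects on the PSF, motility and emergent contacts,
crowded fields requiring segmentation (annotations are inputs by design),
receptor cluster stoichiometry, acquisition photobleaching (the
normalizations that correct for it are instead tested by applying synthetic
per-frame decay factors), or the biology of toxin-mediated kin
discrimination. Passing parameter-recovery tests therefore demonstrates
estimator correctness under this generative model, not robustness to every
artefact of real microscopy.

## Numerical choices

* ROIs and contact intervals are half-open `[lo, hi)` in µm; images are
  0-based pixel-indexed; the arc origin is the first centerline vertex.
* The closed-form bleach profile is a truncated Neumann cosine series; mass
  is conserved exactly at every truncation order, and 2 000 terms agree with
  an explicit finite-volume solver to < 10⁻³ everywhere (asserted).
* Fits use `scipy.optimize.curve_fit` with analytic-scan initial values and
  physical bounds (`A ∈ [0, 1.05]`, `R > 0`, `D ≥ 0`); non-convergence raises
  a typed error carrying the starting values.
* Degenerate inputs fail loudly: zero `I_total`, no detectable bleach, flat
  difference profiles, zero-mean frames, empty ROIs (warning + no-op).
* All randomness flows from explicit seeds; derived seeds stay below 2³¹.
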