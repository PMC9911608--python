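# Methods

## Decay model and fitting

The TCSPC histogram of a pixel or ROI is modelled as a two-component
exponential convolved with a Gaussian instrument response (IRF):

F(t) = F0 [P1 H(t; t0, τ1, τG) + (1−P1) H(t; t0, τ2, τG)], with
H(t; t0, τ, τG) = ½ exp(τG²/2τ² − (t−t0)/τ) · erfc((τG² − τ(t−t0))/(√2 τ τG)),
the closed form of exp(−(t−t0)/τ)·θ(t−t0) ⊗ N(0, τG²), normalised so
H → exp(−(t−t0)/τ) as τG → 0. The exponent τG²/2τ² is required by
dimensional analysis and verified against brute-force quadrature to 1e−8
relative; the pre-pulse branch (erfc argument ≥ 0) is evaluated through the
scaled complementary error function erfcx with the identity
erfc(x)·exp(a) = erfcx(x)·exp(−(t−t0)²/2τG²), which cannot overflow, and
the tail branch uses the plain product, whose exponent is already small.

Component labels are gauge freedom; the constructor enforces τ1 ≤ τ2 and
swaps P1 ↔ 1−P1 when reordering. P1 weights component *amplitudes*; the
photon fraction of component 1 is P1τ1/τ_a with
τ_a = P1τ1 + (1−P1)τ2 — the amplitude-weighted lifetime that enters
E = 1 − τ_a,DA/τ_a,D.

Fitting maximises the Poisson likelihood of the observed bin counts under
μ_i = F_periodic(t_i) + b, where b is the expected background per bin and
F_periodic sums F over three excitation periods: the generator (like TCSPC
hardware) wraps photons emitted after the window end into the next period,
and ignoring that truncates the tail and biases τ_a. Weighted least
squares would mis-weight the low-count tail bins that carry most of the
lifetime information, hence the likelihood objective. Parameters are
optimised by L-BFGS-B in log/logit space from four starts,
(τ1, τ2) ∈ {(0.5, 2.5), (1.0, 3.0)} × P1 ∈ {0.3, 0.7}, with t0 and τG
initialised from the histogram peak and leading-edge rise; bi-exponential
likelihoods are multimodal and a single start occasionally lands on a
spurious mode. τG and t0 are instrument properties, so per-cell fits can
pin them for all ROIs via `fix_tauG` / `fix_t0`. Standard errors come from
a finite-difference observed-information matrix with a delta-method
transform back to natural parameters. Fits with τ2 − τ1 < 0.05 ns are
flagged effectively mono-exponential: in that regime only τ_a is
identifiable (and it is recovered to ~2%), so τ_a remains the supported
summary. Below 10,000 total photons (configurable) the fit refuses and
callers fall back to the center-of-mass mean lifetime, which is computed
over the full window with no background subtraction; its time reference
is an explicit argument — all downstream comparisons are per-cell
differences, so only consistency of the reference matters.

## Synthetic data generator

The generator replaces the microscope and defines the conditions every
test runs under: 80 nm FLIM pixels, 150 accumulated frames, ~10⁴ expected
photons per structure, Gaussian IRF τG = 0.15 ns, excitation offset
t0 = 2 ns in a 12.5 ns window with 256 bins, uniform background at 0.5
photons/pixel (signal-to-background well above 100), donor-only reference
lifetime 2.6 ns. Photon times are t0 + Exp(τ) + N(0, τG) with the
component chosen by its photon fraction; late photons wrap modulo the
window, keeping histogram totals exact. The wrap shifts the center of mass
down by W·e^{−(W−t0)/τ}/(1−e^{−W/τ}) (≈0.08 ns at τ = 2.1 ns), a closed
form the tests use as the expectation for simulated mean lifetimes.
Structures are hard disks convolved with a Gaussian PSF of σ = 1.3 pixels;
pixel counts are Poisson with no read noise (photon-counting detector).
Pulse pile-up is not simulated: acquisition at <0.1 peak counts per pulse
is assumed. Acceptor photobleaching scales the effective efficiency by
(1−β)^frame in the frame-series simulator.

Default curvature-class true efficiencies are flat 0.30, domed 0.26,
sphere 0.22 — a monotone decrease of the size suggested by lifetime shifts
of order 0.1 ns on a 2.6 ns donor, chosen once as a plausible
conformational-change scale. What passing tests show is that the analysis
chain recovers direction and approximate magnitude of class-dependent
lifetime differences under Poisson noise at the stated photon budget; they
do not validate segmentation, curvature classification (manual in the
underlying experiment and out of scope), optical sectioning, detector
afterpulsing, or cell-to-cell biological variability beyond expression
differences.

## Lattice FRET

Only the acceptor-bearing state of the four heavy-chain site states
(empty / endogenous CLC / EGFP-CLC / ShadowY-CLC) quenches the donor, so
the four-state model collapses to independent Bernoulli(occupancy) draws
per site, with occupancy = ShadowY-bound / total. For one configuration,
independent-acceptor rate additivity gives E = S/(1+S),
S = Σ (R0/rᵢ)⁶ — the physically standard combination rule for a donor
with several independent acceptors. The expectation enumerates all 2ⁿ
configurations with binomial weights and averages the *efficiencies*
(not the rates): averaging rates first would overweight crowded
configurations. Enumeration is refused above 20 sites; a Monte-Carlo path
(vectorised Bernoulli draws) covers larger systems and doubles as the
independent oracle in tests. The reference geometry is five sites on a
70 Å ring (the surrounding heavy chains); coordinates are plain Å tables,
and deriving them from structural models is left to the user. The donor
orientation factor κ² = 2/3 is absorbed into R0 (flexible linkers).
Position scans step the donor on a lateral grid (default 0.6 Å spacing,
bounds ±30 Å) at a fixed 25 Å axial offset above the site plane.

## Membrane (DPA) quenching

No published functional form exists for this quenching geometry in the
workflow the package models; we adopt the textbook point-to-infinite-plane
Förster integral E = S/(1+S), S = πσR0⁶/(2z⁴), and validate it only by
what the analysis needs: strict monotonicity in z and σ (checked against a
2-D numerical rate integration to 0.5%). σ maps to DPA concentration by a
single proportionality constant in config, not fitted; DPA in the far
leaflet is ignored. Consequently the deliverable of
`delta_lifetime_axial_rank` is a *ranking* of constructs by lifetime loss
(Δτ = τ_control − τ_DPA, ties kept in input order), never an absolute
height.

## Registration and ROI statistics

The FLIM→EM map is a full 6-parameter affine fitted by linear least
squares to fiducial centroids; flat and domed structures serve as
fiducials (spheres can move during critical point drying). Degeneracy
(fewer than 3 pairs, collinear points) raises before fitting. FLIM is
resampled into the EM frame (the higher-resolution target) by
nearest-neighbour inverse mapping: each output pixel copies its nearest
source pixel, so photon counts stay integral and lattice-preserving maps
round-trip exactly. Pixel centers sit on integer coordinates, origin
top-left, x = column, y = row, 0-based, everywhere.

ROI lifetime is the photon-pooled mean Σ(lifetime sums)/Σ(counts) over a
square of the structure bounding box plus a 2-pixel margin (configurable);
structures closer than twice the ROI side to a neighbour are excluded as
not isolated. Per-cell summaries report class means and Δ(class) =
mean(class) − mean(flat) in ns (Δ(flat) ≡ 0; absent classes are NaN, and a
cell without flat structures is excluded with a log entry). The cellular
average lifetime is photon-weighted across all structures; in
donor+acceptor mode only cells strictly below 2.1 ns are analysed.
Morphometrics count label pixels: area = pixels × pixel², density =
count/membrane area, occupied % = class area/membrane area × 100, which
conserves total area exactly by construction.

## Problem sizes

The default pipeline demonstration uses 6 cells of 12 structures each on
72×72-pixel FLIM frames, with the synthetic EM frame at 8 nm/pixel — a
correlation scale factor of 10 that keeps the resampled rasters small
while exercising the same code paths; the affine recovery at the full
80 nm/1.2 nm scale ratio (×66.7) is verified point-based. Monte-Carlo
checks use 50–100 replicate fits and 10⁶-draw configuration samples.

## Known limitations

- The mean-lifetime time reference and the per-cell vs per-ROI scope of
  the instrument parameters are exposed as options rather than fixed;
  different vendor software makes different choices.
- The plane-quenching functional form is a modelling choice validated
  only by monotonicity; absolute axial distances are out of scope.
- No automated EM segmentation or curvature classification; labeled masks
  are inputs.
- Homo-FRET, anisotropy, phasor analysis, optical sectioning and detector
  afterpulsing are not modelled.
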