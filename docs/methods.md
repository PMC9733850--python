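# Methods

This note records the models implemented in `lamellaflex`, the defaults
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Buckle-delamination mechanics

The width law λ/t^{3/2} = π√(2E̅_f ε/Γ) treats the film as a linear
elastic plate whose in-film strain is negligible compared with the
applied substrate strain; bending, compression and adhesion energies
balance at the delamination edge. All internal arithmetic is SI; the nm
interface converts on entry and exit, and the two routes agree to
1e-12 relative (tested).

**Inversion.** Because the law is exactly linear in √ε after
normalizing λ by t^{3/2}, we invert by *unweighted through-origin least
squares* of y = λ/t^{3/2} on x = √ε, then Γ̂ = 2π²E̅_f/m². Weighting is
a genuinely open choice (the error structure of manual AFM width
measurements is unknown); unweighted is the simplest defensible option
and is near-unbiased under multiplicative width noise (tested: median
bias < 5% at 10% noise, n = 12). The uncertainty is first-order
(delta-method) propagation σ_Γ = 2Γ̂σ_m/m from the slope standard error
σ_m² = SS_res/((n−1)Σx²); it quantifies fit scatter, not systematic
uncertainty in E̅_f, which enters Γ̂ proportionally.

**Modulus.** The default treatment uses the supplied in-plane Young's
modulus as-is (the literature value for gel-phase DPPC films is
42 ± 16 MPa). A `poisson_ratio` flag applies the plane-strain correction
E/(1−ν²) for sensitivity analysis; it is off by default.

**Thickness band.** Width–thickness comparisons are considered reliable
for films 70–150 nm thick (thinner/thicker films differ in roughness);
observations outside the band trigger a warning, never a hard filter.

**Topography.** RMS roughness supports three detrend modes: `none`
(global mean removal), `plane` (least-squares plane, for sample tilt)
and `line` (per-scan-line levelling, the common AFM correction). Buckle
extraction uses a running-median baseline (window 5× the largest
expected buckle width, or a global median if none is given), a detection
threshold of max(3·1.4826·MAD, 2 nm), a 3-pixel merge of split cores,
and reads the width at the baseline-crossing level. The 2 nm floor sits
above typical uncompressed-film roughness (~1.9 nm RMS) so wrinkles are
not misread as buckles; all three knobs are exposed as keyword
arguments.

## Scattering peak analysis

Within a user-chosen window, intensity is modelled as one Lorentzian on
a background linear in (q − q₀). The broad elastomer-substrate
scattering near q ≈ 1 Å⁻¹ is handled by window choice, not modelled.
Initialization takes q₀ from the window maximum, the FWHM from the
half-height crossings and the background from the window edges; the
Levenberg–Marquardt fit (via lmfit) is restarted with doubled width
guesses up to three times before raising a fit-failure error with
diagnostics. An independent brute-force oracle (grid over (q₀, FWHM)
with the linear parameters solved exactly) bounds the optimizer in the
test suite; the optimizer must never return a worse sum of squares.

Conversions use the d-spacing convention throughout: spacing = 2π/q₀
and ξ = 2π/FWHM. For chain-packing peaks indexed on a 2D hexagonal
lattice the alternative a_hex = 4π/(√3 q₀) is available behind a flag;
reported lipid spacings conventionally quote 2π/q₀, which is the
default. No instrument-resolution deconvolution is applied, so ξ is an
apparent (lower-bound) correlation length. Lamellar indexing regresses
q₀ on the order index through the origin and rejects assignments whose
q₀/n ratios scatter by more than 10%.

## Directors, tilt and order parameters

The director is the unit vector from the head bead to the mean terminal
bead position, flipped to the upper hemisphere so tilt lives on
[0°, 90°]; a principal-axis alternative (leading SVD axis of the bead
cloud, oriented head→tail) is available and agrees to 1e-9 for straight
chains. Tilt histograms default to 1° bins on [0°, 90°], with modal
ties broken toward the smaller angle.

P₂ averages (3cos²θ − 1)/2 over consecutive-bead bond vectors,
*excluding the head–first-tail bond* by default (headgroup orientation
is not tail order; `include_head_bond=True` restores it). The reference
axis is either the global z (membrane normal) or the owning lipid's
director. For rigid straight chains the renormalized P₂ is identically
1 at every undulation amplitude and noise level — the computational
statement that tilt, not conformational change, carries the order loss
for rigid-rod inputs.

The inter-layer tilt correlation divides the lateral box into an
S × S grid (default 50, configurable for small systems) of half-open,
periodically wrapped bins on lipid *base (head-bead) positions*, and
averages products of scalar tilt angles over all cross-layer pairs
sharing a bin, then over bins (and frames, if several are given). The
normalization ⟨θ(l₁)θ(l₁)⟩ is asymmetric in the two layers and is
computed over all ordered same-layer pairs *including self-pairs*: that
is the reading under which two identical tilt fields give exactly 1,
which we take as the defining property of the normalization. A
symmetric Pearson variant is available via `mode="pearson"`. Binning by
head-bead position (rather than center of mass) and folding angles to
nonnegative values are documented defaults, not claims about any
particular upstream convention.

## Synthetic-data generators

The generators define the study conditions for all tests:

* **Multilayer** — L layers of rigid straight bead chains (default 12
  beads, 1.5 Å bonds) on mid-surfaces z_l(x) = l·d + A sin(2πx/λ_u + lφ),
  with d = 56 Å by default, chains along the local surface normal, bases
  on a uniform sheared lattice of 8 Å spacing (≈64 Ų per lipid, the
  gel-phase scale). The shear offsets each row by 1/n_y of the lattice
  constant so every lipid samples a distinct undulation phase; a square
  lattice would alias the slope distribution onto n_x discrete phases
  and distort the histogram near its arcsine-divergent mode at maximum
  slope arctan(2πA/λ_u). Director noise rotates each chain by
  |N(0, σ)| (truncated at 90°) about a uniformly random azimuth. The
  undulation is one-dimensional and in-phase across layers by default;
  `phase_per_layer` de-correlates the stack for testing.
* **Scattering** — sum of Lorentzians plus a linear background and
  Gaussian noise, clipped at zero.
* **Topography** — a sinusoidal wrinkle field varying along x (ridges
  perpendicular to the compression axis) plus raised-cosine buckle
  ridges whose support equals their nominal width, plus Gaussian noise.
* **Buckles** — thicknesses uniform on 70–150 nm, strains cycled
  round-robin through the requested levels (guaranteeing the balanced
  multi-strain design of a twelve-buckle survey), and multiplicative
  Gaussian noise on λ (geometry measurement error scales with feature
  size), redrawn if nonpositive.

What the generators deliberately do **not** emulate: thermal undulation
spectra (the sinusoid is a single mode), conformational chain disorder
(rods are rigid — so renormalized-P₂ tests verify the machinery, not
chain physics), 2D undulations, substrate interactions, instrument
resolution and detector artefacts. Passing tests therefore demonstrate
that the analyses recover known ground truth under the stated models,
not that those models exhaust real data.

All generators take an integer seed and are bit-reproducible; the
undulation amplitude/wavelength are free parameters (no canonical values
exist for the simulated undulations), and slope-matched settings such as
2πA/λ_u = tan 22.5° are constructed where a known tilt mode is needed.

## Problem sizes and numerical choices

Default validation sizes — 4 layers × 2 500 lipids (10⁴ directors),
200 replicates × 12 buckles for the estimator study, 10⁵ bonds for the
isotropic P₂ check, 512×512 topographies, ≤ 700-point scattering
windows — were chosen so each check's sampling error is comfortably
below its assertion tolerance while the whole suite stays interactive.
Degenerate inputs raise typed errors (zero-length directors or bonds
name the offending lipid; empty fit windows, inconsistent lamellar
orders, all-zero reference tilts each have a dedicated exception).
P₂ is clamped to its analytic range [−0.5, 1] against rounding at the
boundaries. GRO files quantize coordinates to 0.001 nm, so round-tripped
configurations reproduce rigid-rod identities only to that precision.

## Limitations

The ruga model covers delamination buckles only — wrinkle-wavelength
selection, folds, creases and the full morphology phase diagram are out
of scope, as are substrate viscoelasticity and time-dependent
relaxation. The scattering module fits 1D profiles (no 2D detector
reduction, form factors or electron-density reconstruction). Binary MD
trajectory formats are not read; configurations arrive as GRO-dialect
or labeled-XYZ text.
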