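# Methods

This note documents the models implemented in `prrtdose`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Dose-point kernel and convolution engine

Per-decay absorbed-dose maps are computed deterministically: the voxel
activity distribution (normalized to decay probabilities) is convolved via
FFT with a radial ¹⁷⁷Lu electron dose-point kernel (DPK) in water. The grid
is implicitly zero-padded, so energy crossing the array boundary is lost —
physically, β particles escaping the tissue.

**Kernel generation.** The packaged table
(`dose_engine/data/lu177_dpk_water_synthetic.csv`) is produced by a
condensed-history random walk (`scripts/make_kernel.py`, fixed seed,
4×10⁵ histories):

- β spectra for the three branches (endpoints 497.8, 384.8, 176.5 keV at
  79.3%, 9.0%, 12.2% intensity) with the allowed shape and the
  nonrelativistic Fermi Coulomb correction for the ¹⁷⁷Hf daughter (Z=72);
  discrete conversion-electron lines grouped to carry 14.6 keV/decay.
- Continuous energy loss at the Berger–Seltzer collision stopping power of
  water (I = 75 eV), 60 steps per history, 1 keV residual cutoff deposited
  locally.
- Highland multiple-scattering angle per step, which produces the detour
  that makes real electron kernels more compact than their CSDA path
  length: the generated kernel absorbs 90% of the emitted energy within
  X90 ≈ 0.63 mm, in line with published ¹⁷⁷Lu kernels (≈0.6 mm), where a
  scatter-free straight-ahead model would give ≈0.76 mm.
- The radial cumulative absorbed fraction is normalized so the kernel's
  total equals the evaluated mean electron energy per ¹⁷⁷Lu decay,
  147.9 keV (mean β 133.3 keV + discrete 14.6 keV).

**Deliberate omissions** (documented biases, all low-percent for mm-scale
geometries): γ/x-ray photons (their absorbed fraction in a ≤2 mm water
volume is small, biasing S values slightly low versus full Monte Carlo),
bremsstrahlung (<1% below 0.5 MeV in water), and energy-loss straggling.
The table is truncated at the maximum electron range (~1.77 mm; the stored
grid ends at 1.9 mm) — padding further would only inflate FFT sizes, since
the kernel is identically zero beyond the endpoint range.

**Voxelization.** The radial kernel is resampled onto (possibly
anisotropic) voxels by volume integration, not point sampling: far-field
voxels use 2³ subsamples of the energy density ε(r) = C′(r)/(4πr²); the
5×5×5-voxel near field, where ε diverges as 1/r², is integrated on a 9×
finer subgrid whose central element receives the closed-form energy within
the equivalent-radius sphere. The voxelized kernel is renormalized to the
exact table total, so discretized convolution conserves energy to machine
precision when the kernel is contained. Anisotropy beyond 5:1 is rejected.

**Reference sphere.** The homogeneous comparison phantom is a voxelized
water sphere (default 24.1 mm³ ≈ the full-resolution study stack volume,
radius 1.79 mm) with uniform activity, at 20 μm pitch (≥3×10⁶ voxels). At
this pitch the sphere run takes seconds on one CPU; pitch is configurable.
With the packaged kernel it yields S = 8.73×10⁻¹⁰ Gy/decay (sphere
absorbed fraction 0.89) and 63.3% of the volume at or above the mean dose.

## Kinetics

Dose rate after injection: Ṙ(t) = (R₀−P)e^(−λₑt) + Pe^(−λₚt) (mGy/h, t in
hours), with invariants λₑ > λₚ > 0 and R₀ ≥ P ≥ 0; cumulative dose has the
obvious closed form and a finite asymptote. λₚ is fixed at ln2/159.53 h⁻¹
(¹⁷⁷Lu half-life 6.647 d) — physical decay is never a free parameter.
Fitting uses multistart nonlinear least squares (log-spaced λₑ starts,
ties broken by AICc then smaller λₑ) and reports the AICc-preferred model
between the biexponential and its mono-exponential (P=0) reduction, with
R² ≥ 0.7 as the adequacy flag. With a small plateau (P/R₀ ≈ 5%) and n=8
points the plateau itself is weakly identified and AICc often selects the
mono-exponential; the effective rate is still recovered well (median error
~11% at 10% measurement CV), which is the quantity downstream stages use.

Dose-rate and interval-dose maps multiply the per-decay dose map by the
decay rate implied by the injected activity (default 30 MBq) and the
normalized bound-fraction shape Ṙ(t)/R₀. Normalizing to 1 at t=0 treats
the injected activity as fully bound at injection — an upper bound used
consistently on both sides of every comparison.

## Survival model

In vivo survival per voxel: E(t) = e^(γt)·exp(−αD(t) − G(t)βD(t)²), with
repopulation γ = ln2/T_D applied continuously over elapsed time (once —
not again at chaining).

**Lea–Catcheside factor.** For biexponential delivery with amplitudes
A = R₀−P, B = P and rates a = λₑ, b = λₚ, writing
I(p,q) = (1−e^(−(p+q)t))/(p+q),

G(t) = (2/D(t)²)·[ A²(I(a,a)−I(a,μ))/(μ−a) + AB(I(a,b)−I(a,μ))/(μ−b)
     + AB(I(a,b)−I(b,μ))/(μ−a) + B²(I(b,b)−I(b,μ))/(μ−b) ],

derived directly from the generic double integral
G = (2/D²)∫₀ᵗ Ṙ(t′)∫₀^t′ Ṙ(t″)e^(−μ(t′−t″)) dt″dt′. The closed form is
property-tested against adaptive double quadrature (100-draw random
parameter sweep, 10⁻⁶ relative). Near rate degeneracies (|λ−μ| < 10⁻⁶ h⁻¹,
removable singularities) evaluation falls back to quadrature. Limits:
G → 1 as μ → 0; G(∞) = λₑ/(λₑ+μ) for P = 0.

**Per-voxel maps.** Every voxel shares the kinetics template's normalized
time shape; the voxel amplitude R₀ᵢ scales it, so Dᵢ = R₀ᵢ·τ(t) and G is
common to all voxels. The *average approach* replaces the amplitude map by
its tumor-region mean and is exactly the scalar pipeline on that mean; by
Jensen's inequality the heterogeneous mean log-survival never exceeds the
average-approach log-survival. Optional per-voxel α draws (gaussian,
truncated at zero) model radiosensitivity heterogeneity; they provably
widen the survival dispersion at a fixed dose map.

**Interval chaining.** The treatment course (default boundaries 0, 2, 5,
11, 14 d) is chained by Monte Carlo: each sample multiplies one draw per
interval, drawn independently across intervals because each interval's
distribution comes from an independent tissue section (different animals
per time point). Default 10⁵ samples from the empirical per-voxel
distributions; a gaussian approximation of each interval is available as
an option. A single interval reduces exactly to the survival map, and
uniform-dose intervals multiply exactly.

**Growth and repair fits.** Tumor volume follows
V(t) = V₀·exp(k₀t − k₁·max(t−T₀,0) + k₂·max(t−T₁,0)) — exponential growth,
shrinkage onset at T₀ (imposed, default 3 d), regrowth onset at the free
parameter T₁. Fitting is done in log-volume space, where the model is
linear given T₁; T₁ is profiled on a grid and refined continuously, which
recovers noiseless curves to ≥4 significant digits. The regrowth doubling
time is T_D = ln2/(k₀−k₁+k₂), flagged undefined when the net late rate is
not positive. Log-space fitting weights relative errors — appropriate for
multiplicative (lognormal) volume noise. γH2AX foci decay is fitted as
A·e^(−μt), with an additive baseline admitted when AICc prefers it
(n ≥ 5); non-decaying series are an error, near-flat fits are flagged.

**Minimal effective dose rate.** At constant rate R, long exposure with
repair rate μ gives a protracted quadratic term 2βR²/μ per unit time, so
the steady-state kill rate is αR + (2β/μ)R². The threshold is the positive
root of αR + (2β/μ)R² = γ, solved by bisection to 10⁻⁶ mGy/h. The
defining equation is this package's choice of formalization; with
α/β = 100 Gy, T_μ = 60 h, T_D = 14.5 d it gives 13.89 mGy/h (α = 0.14 Gy⁻¹)
and 7.45 mGy/h (α = 0.264 Gy⁻¹), within ~1.3% of the reference values this
construction targets; β = 0 reduces exactly to γ/α. RBE is reported as the
ratio of fitted α values, the appropriate comparison when the quadratic
term is negligible at therapeutic dose rates.

## Dose metrics

DVH uses 256 equal-width bins by default; the fraction of volume at or
above the mean dose is computed from the raw voxel sample, never from the
binned histogram. gEUD is the power mean of order *a* of voxel doses;
*a* = −1 is the default for tumors (the study's exponent is not published,
so it is a configurable flag). For *a* < 0, zero-dose voxels collapse the
power mean to zero; they are excluded with a warning reporting the count,
which under-penalizes cold coverage but keeps the metric finite — callers
comparing coverage should inspect the reported count. Normality reports
pair Shapiro–Wilk with the Q–Q correlation against normal quantiles.

## DSB analysis

Dose–DSB regression: per-tumor simple slopes (≥2 sections each) with a
Shapiro–Wilk normality check across tumors, and pooled OLS with intercept;
the 95% CI uses the t distribution on the OLS slope standard error.

Template matching slides a window over the large section and scores the χ²
distance between 32-bin intensity histograms of min-max normalized
patches. Histogram χ² was chosen over pixelwise χ² (available behind a
flag) because staining intensities are not comparable across scans and
patch alignment at sub-window scale is meaningless; min-max normalization
makes the score respond to intensity *texture*, not absolute level, so a
smooth global gradient is invisible to it by design. Default stride is a
quarter of the template side (full resolution is O(N²) and available). The
overlap report ranks window similarity against window-mean dose (Spearman)
and reports top-decile overlap.

## Synthetic data: what it does and does not emulate

Expression fields are exponentiated gaussian random fields with a
squared-exponential kernel — the generative model is a package choice (no
generative model of SSTR2 patterns is published): it gives strictly
positive intensities, a controllable correlation length ℓ (defined by
ρ(ℓ) = e^(−1/2); default 50 μm, the scale of a few cell diameters) and a
high/low-mode contrast ratio (default 4). Tissue occupies an ellipsoid;
tumor voxels are the top quantile of an independent correlated field,
rank-thresholded so the tumor fraction (default 0.97, the study's 94–100%
range) is exact to one voxel. Activity is proportional to expression in
tumor voxels with a uniform non-specific remainder (specificity default
0.9) and sums exactly to the requested total.

The default phantom is 128×128×64 voxels at 11.4×11.4×20 μm — a
2×-coarsened version of the full-resolution stack so complete runs take
minutes, with the full 507×507×289 grid supported. Time-series truth:
R₀ = 40 mGy/h, P = 0.05·R₀, λₑ = ln2/55 h⁻¹ (the study's fitted
biodistribution parameters are unpublished; these values deliver ~42% of
the asymptotic dose in days 0–2, matching the reported front-loading),
T_μ = 60 h, T_D = 14.5 d (k₀ = 0.12/d, k₁ = 0.25/d, k₂ chosen to match
T_D, T₀ = 3 d, T₁ = 20 d), DSB yield 0.0223 per cell per mGy, 8 foci/cell
at t = 0. DSB counts are Poisson around yield × local dose (the noise
model for foci counts is unpublished; Poisson is the natural counting
model).

Not emulated: microscopy artifacts (PSF, bleaching, autofluorescence),
nuclei segmentation, vascular architecture, cell-cycle structure. Passing
closed-loop tests therefore demonstrates that the estimators recover their
generating parameters under the stated noise models — not that those noise
models exhaust real tissue variability.

## Numerical conventions

- Arrays are indexed (x, y, z), 0-based, with spacing (μm) and origin
  metadata; physical coordinates are never 1-based. NRRD I/O (SimpleITK)
  handles the (z, y, x) storage transpose internally.
- Time is hours internally; days at interfaces where conventional
  (schedules, growth curves). Dose rate mGy/h, dose Gy, S values Gy/decay.
- Water density 1 g/cm³ everywhere; 1 μm³ of water = 10⁻¹⁵ kg.
- Every stochastic function takes an explicit seed; there is no hidden
  global RNG state. Pipeline stage seeds are derived from the run seed.
- FFT convolution may produce tiny negative ringing values; dose maps are
  clipped at zero.

## Problem sizes used in the shipped checks

The reference-sphere computation runs at 20 μm pitch (3.0×10⁶ sphere
voxels). Closed-loop recoveries use the study-scale designs: 8 costained
sections of 2000 cells over 1600–1800 mGy for the DSB slope (200
replicates for the CI-coverage property), 6 foci time points over 0–150 h
at 500 cells, 15 volume time points over 0–42 d. The pipeline smoke
configuration is a 24³-scale phantom at 40 μm pitch, chosen to exercise
every stage in seconds.

## Known limitations

- The kernel is electron-only; reported S values carry a low-percent
  negative bias versus transport codes that include photons.
- The condensed-history generator uses the Highland small-angle formula at
  energies where scattering is large; the kernel's mid-range shape is
  approximate even though its integral and range are anchored to evaluated
  data.
- The average-approach equivalence and the shared-G factorization assume
  every voxel follows one bound-fraction time shape; receptor
  internalization kinetics that vary spatially would break this.
- Chaining treats intervals as independent; within-animal correlation
  between intervals is not representable with per-interval sections.
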