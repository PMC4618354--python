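# Methods

## The problem and the model

A pulse of labelled auxin applied to the apical end of a stem or coleoptile
segment travels basipetally at a roughly constant velocity *v* while its
spatial variance grows at a roughly constant *spreading rate* ρ. This package
models that experiment mechanistically and asks what (v, ρ) imply about the
underlying transport machinery.

The tissue is represented as parallel **channels** — files of cells, or
subcellular compartments treated analogously — running down the stem. Between
successive cells in a channel the flux per unit area is either

* linear, φ = p·a₁ + q·(a₁ − a₂), with a polar permeability *p* (basipetal
  only) and a diffusion-like permeability *q*; or
* saturating Michaelis–Menten, φ = κ⁽¹⁾a₁/(K_m+a₁) − κ⁽²⁾a₂/(K_m+a₂).

The linear law is not an ad-hoc form: eliminating the apoplastic
concentrations between an exporting face (total exporter permeability α₁),
an importing face (α₂ on the opposing cell, importer/passive permeability β
on both), and diffusion D₀ across an apoplast of width L₀ gives exactly
φ = (α₁a₁ − α₂a₂)/(2+r) with r = βL₀/D₀, i.e. p = (α₁−α₂)/(2+r),
q = α₂/(2+r), q/p = α₂/(α₁−α₂). Polar PIN localisation means α₁ ≫ α₂ and
hence a *small* q/p — which is the crux: measured pulses imply q/p of 5–12.

Adjacent channels exchange laterally through every compartment face:
symmetric (permeability *s*), asymmetric (s_fwd·a₁ − s_rev·a₂, e.g. the
tonoplast), or saturating. Weak-acid chemistry enters through
Henderson–Hasselbalch: the passive permeability out of a compartment at pH is
P_IAAH/(1+10^(pH−pK)) with pK = 4.7.

Closed forms used for inference (module `analytics`):

* rapid intracellular mixing: v = p, ρ = L(p+2q);
* finite intracellular diffusion D: 1/v = 1/p + (L/2D)(1+2q/p) and
  ρ ≤ Lv(1+2q/p), equality as D → ∞;
* inversion q/p = (ρ/(Lv) − 1)/2, and the diffusion floor D ≥ ρ/2 (the
  p → ∞ limit of the two relations combined);
* lateral effective diffusion of a channel stack: 1/D_eff = 1/D + 1/(w·s).

## Simulator

Cells (default 100 µm long, 20 µm wide) are divided lengthwise into N
compartments (default 5). Within a cell, adjacent compartments exchange at
rate D·N·(N−1)/L² s⁻¹; this convention makes the discrete pulse velocity obey
the finite-D velocity relation essentially exactly (measured agreement ~0.01%
over a (p, q, D) grid) and corresponds to the computational-unit conversions
p = p′L/(NΔ), D = D′L²/(N(N−1)Δ). Updates are forward Euler with Δ = 1/20 s
by default. Choices a user should know:

* **Stability guard.** At grid construction, every compartment's worst-case
  fractional outflow per step (treating saturating laws by their linear-limit
  permeability κ/K_m) must stay below 0.5; otherwise the run aborts naming
  the offending compartment. This turns silent blow-up into a diagnostic.
  Scenarios with strong couplings ship with correspondingly smaller Δ.
* **Boundaries.** No-flux at both stem ends. The default stem (300 cells =
  30 mm) keeps pulses clear of the basal end on the simulated horizons; if
  more than 1% of the mass reaches the basal cell a warning is raised. The
  original computations do not state their boundary handling; this is our
  assumption.
* **Lateral width splitting.** When any coupling satisfies w·s > 0.1·D the
  cell's lateral interior matters, and each channel is split width-wise into
  two sub-columns coupled by the diffusive permeability 2D/w. The 0.1
  threshold is our choice; it reproduces the series law
  1/D_eff = 1/D + 1/(ws) where the membrane term no longer dominates.
* **Unequal widths.** Cytosol (1 µm) / vacuole (9 µm) channels use
  volume-weighted bookkeeping with a shared interface area; permeabilities
  follow the width-rescaling convention s(d/20 µm).
* **Normalisation.** "Distribution normalised to a total of 1" is applied to
  recorded snapshots only, never to the evolving state — saturating laws
  depend on the absolute concentration scale.
* **Loading.** Either instantaneous (first computational cycle) or constant
  rate over a duration, as a uniform concentration increment into the
  apical-most cell of the target channels. The classic protocol is 15 min of
  constant-rate uptake, a 15 min wait ("zero time" at 30 min), and 30 more
  minutes to the nominal 30-minute profile.

A readable pure-numpy `step()` is the reference implementation; long runs use
a numba kernel verified against it bit-for-bit in the tests.

## Measurement methodology (module `fitting`)

Profiles are binned into 2 mm segments (the historical counting protocol).
Each profile is fitted with a gaussian: plain unweighted least squares, or
**maximal fit**, which grows a window from the 5 bins around the global
maximum, extending one bin at a time on the side whose re-fitted gaussian has
the smaller normalised RMS residual, while that residual stays ≤ 5% of the
amplitude (ties extend apically). The published description of the procedure
("selects the peak region and ignores flanking regions") does not include an
exact criterion; this greedy rule is our stated interpretation, deterministic
by construction. Velocity and spreading rate are the OLS slopes of fitted
means and variances against time; an `empirical_spreading_rate` shortcut uses
exact (unbinned) field variances at two times. Where variance grows faster
than linearly (weak lateral coupling leaves a streak and ρ proper is
undefined) the surrogate |Var(t) − Var(0)|/t is used; the published surrogate
is printed with the opposite (negative) sign, which we read as a typo for the
magnitude.

Nonlinear fits initialise from profile moments and bound σ at half a bin
width; unweighted least squares matches the apparent original usage, with
weighting available.

## Synthetic data

`synthetic` generates segment-count experiments with the structure of the
historical data sets: expected profiles from the gaussian N(µ₀+vt, σ₀²+ρt)
(or from a full tissue model), exactly integrated over 2 mm bins and scaled
to an expected 10⁴ counts per profile; Poisson counting noise (the natural
model for radioactivity counts; no gaussian option); and an optional
exponential "trailing" component mixed in toward the apical end (default
fraction 10%, decay length 3 mm in the coleoptile-like fixture). The
historical record establishes that trailing components exist, not their
shape — exponential is an assumption. The fixture defaults (v = 10.7 mm/hr,
ρ = 26 mm²/hr, six times over 0–2 hr) mirror the least-squares estimates for
the classic coleoptile data. What passing recovery tests show is that the
fit-then-regress pipeline is unbiased under count noise plus a trailing
component of this shape; they cannot certify behaviour under the unknown
true contamination shape, segment-length variation, or detector effects.

## Scenario presets and problem sizes

The named presets encode the published parameter sets: the failing single
channel (p = 4×10⁻⁴ cm/s, q/p = 0.05, D = 5×10⁻⁶ cm²/s); the two-channel
minimal model (polar p = 1.4×10⁻³ cm/s + apolar, lateral s swept, best fit
s = 7.1×10⁻⁶ cm/s); its scaled versions (n = 2, 6, 21, 30 with the tabulated
s and p, apolar channels taking p = 0, q = s); unequal polar pairs
(α:1−α); cytosol/vacuole with asymmetric tonoplast permeabilities (passive
1.2×10⁻⁷ / 5.6×10⁻⁶ cm/s or width-rescaled best-fit values); axial
saturation (κ = 10⁻⁶, K_m = 10⁻³); and the high-uptake six-channel models
with saturable lateral (K_m = 10⁻⁴, s = 2.4×10⁻⁵ cm/s, weakened to 4×10⁻⁷
between channels 5 and 6) versus axial saturation. The n = 30 polar/apolar
split (10/20) is not stated in the original and follows the 1:2 pattern of
the other models. High-uptake amounts in nanograms map to model
concentration through one calibration constant (10⁻⁴ concentration units
per ng) chosen once so the uptake:K_m ratios span the linear-to-saturated
transition; only qualitative orderings are meaningful on that axis.

Default runs use the full resolution (N = 5, Δ = 1/20 s, stems of 30–70 mm).
The test suite and acceptance checks run the wide scaled models at coarser
resolution (N = 2–3, Δ up to 0.08 s, shorter horizons) — grid-refinement
tests show v and ρ move by <3% under N-doubling, so these sizes are a
deliberate accuracy/size trade-off, stated here as the package's choice.

## Results the package reproduces, and two honest discrepancies

The simulator reproduces the central published diagnostics: the
single-channel spreading deficit (fitted ρ ≈ 0.9 mm²/hr against measured
16–26), the three lateral-coupling regimes of the minimal model
(synchronised / broadened-gaussian / split), the ρ(s) curve including its
superlinear "streak" region, the equal-spread family of scaled models, the
polarity-ratio ceiling on ρ, and the lateral-vs-axial saturation contrast in
the high-uptake experiments.

Two numbers come out differently from the published values and are asserted
at their computed values in the tests with the discrepancy documented:

* At the best-fitting minimal-model coupling s = 7.1×10⁻⁶ cm/s the simulated
  ρ is 9.4 mm²/hr (matching the two-state dispersion closed form
  2f(1−f)Δv²/(k₁₂+k₂₁) plus the single-channel baseline), an order of
  magnitude above the single-channel bound but below the ρ ≈ 16–26 of the
  least-squares coleoptile estimates; the plateau of the ρ(s) curve just
  before the velocity split (s ≈ 1.8–3.5×10⁻⁶) reaches the tens.
* The passive cytosol/vacuole coupling contributes ≈ 4.2 mm²/hr of
  broadening at the stated parameters, versus a reported ≈ 2.6; the
  two-state closed form confirms the simulated value, and the polar
  permeability of the original run (not printed) would need to be
  ≈ 8×10⁻⁴ cm/s to yield 2.6.

Similarly small, documented mismatches: Henderson–Hasselbalch with
P_IAAH = 4×10⁻⁵ cm/s gives 1.26×10⁻⁷ and 5.47×10⁻⁶ cm/s for the passive
tonoplast permeabilities where the literature rounds to 1.2×10⁻⁷ and
5.6×10⁻⁶ (the scenario presets use the literature values, which are the ones
the coupling analysis quotes).

## Known limitations

One-dimensional channel geometry only (no 2-D/3-D tissue, no growth); no
auxin metabolism or decay (the metabolic explanation for trailing label is
out of scope); receiver blocks at the basal end are not modelled; Table-1
style analysis of the real historical counts requires the original data
files, which are supported as input but not bundled.
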