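# Methods

## The measurement this package models

A ligand that engages a protein inside cells usually changes that protein's
thermal stability. In a thermal-shift difference-gel experiment, aliquots of
drug-treated and vehicle-treated cells are heated across a temperature
series; after centrifugation the remaining soluble proteomes are labeled
with amine-reactive fluorescent dyes — Cy3 for vehicle, Cy5 for drug — and an
equal amount of *unheated* proteome labeled with Cy2 is added to every gel
as an internal standard. All three are co-separated on one 2D gel per
temperature (isoelectric point horizontally, molecular weight vertically).
A protein whose melting midpoint (Tm) is unchanged by the drug gives equal
Cy3/Cy5 signal at every temperature (yellow in an overlay); a stabilized
target retains more drug-channel signal near its Tm (red), a destabilized
target less (green). The Cy2 standard, identical across gels, lets
per-spot melting curves be reconstructed across the series.

## Forward model (`tsfitge.synthetic`)

Thermal denaturation of each virtual protein follows a three-parameter
logistic in temperature,

    f(T) = p + (1 − p) / (1 + exp(k (T − Tm))),

with midpoint `Tm`, steepness `k` (per °C) and a non-denaturable floor
`p ∈ [0, 0.3)`. This is the simplest sigmoid with a plateau and matches
standard practice for cellular thermal-shift and thermal-proteome-profiling
melting curves. Drug binding shifts the midpoint by `delta_tm` (signed) for
target species only.

Channel amounts per species and gel are: Cy2 = abundance (the internal
standard is treated as perfectly heat-independent — an idealization of an
unheated reference proteome); Cy3 = abundance × f(T) under vehicle;
Cy5 = abundance × f(T) under drug. Drug-induced post-translational
modification (PTM) of a substrate converts a fraction

    φ = ptm_fraction_max × (1 − exp(−treatment_minutes / ptm_tau_min))

of the drug channel to a satellite spot displaced in pI by `ptm_delta_pi`
— single-exponential kinetics approaching a ceiling, the simplest model
consistent with PTM extent growing with treatment duration. Mass is
conserved exactly: parent (1 − φ) plus satellite φ equal the no-PTM amount.

Rendering deposits an elliptical Gaussian point-spread (default
σx = 1.3 px, σy = 0.9 px — gel spots are slightly wider in the pI
direction) whose discrete sum matches the analytic integral 2π·A·σx·σy to
well under 1% at these widths. Imaging nuisances: a per-gel multiplicative
gain applied equally to all three channels (so Cy2 normalization can cancel
it exactly), a per-gel affine warp of spot positions (default ±2 px random
shifts for heated gels), an optional vertical misregistration of the Cy5
raster, and noise = flat background (100 counts) + additive Gaussian
(σ = 5 counts) + signal-proportional Gaussian (CV = 3%, a shot-noise
approximation adequate at 16-bit scale). Everything is deterministic given
the design seed.

Default study conditions: 8 temperatures from 37 to 64 °C with the 37 °C
gel as unheated baseline; ~200 proteins per run; abundances log-normal
(median ≈ 4×10⁴ integrated counts, GSD ≈ 1.5); Tm ~ N(50, 5) °C clipped to
[40, 65]; slopes log-normal around 1 /°C; pI uniform on [3.5, 10.5] and
log10 mass uniform on [1.1, 2.4]. Stabilization scenarios use one target at
ΔTm = +8 °C, destabilization one target at ΔTm = −5 °C plus three PTM
substrates at 20 min treatment.

A second forward route, `simulate_spot_tables`, emits pre-quantified spot
tables directly (positions + warp + 0.3 px jitter; intensities with the
same CV and an additive term scaled to the ~3σ footprint area). It skips
rendering and detection and is used where many replicate runs are needed
(the 100-seed null control and parameter-recovery studies).

### What the generator does *not* emulate

Electrophoretic physics (streaks, smears, crowding in the acidic region),
dye chemistry, detergent effects on membrane proteins, saturated or
clipped scans, and non-affine gel distortion are not modeled. Passing
tests therefore demonstrate the *analysis logic* — quantification,
normalization, curve fitting, classification — under realistic noise and
registration error, not robustness to every artifact of real gels.

## Analysis pipeline

**Background** is estimated per channel by a morphological grey opening
with a disk (default radius 8 px ≳ 6σ of the spot PSF), lightly smoothed,
and subtracted; the result is clipped at zero.

**Detection** runs on the per-pixel maximum of the three corrected
channels, so a spot present in only one channel (a PTM satellite, a fully
destabilized protein) is found with the same sensitivity as a three-channel
spot; summing channels would dilute it. Candidates are local maxima of the
lightly smoothed raster above median + 5 × robust σ. The robust σ is the
larger of 1.4826·MAD and the upper-percentile spread (P84.1 − median),
which stays calibrated when background subtraction has clipped the lower
half of the noise distribution. Candidate windows overlapping by more than
30% are refined jointly as a sum of elliptical Gaussians (this resolves
vertically split misregistration doublets); others independently. Each
channel is then integrated over the *identical* fitted 3σ ellipse, so
per-spot ratios compare like with like; the 3σ footprint captures 98.9% of
a Gaussian's mass, a ≈1.1% systematic loss common to all channels that
cancels in every ratio.

**Ratios** are stored as log2(Cy5/Cy3), computed only for spots whose Cy3
and Cy5 both exceed an intensity floor (default 3 × background MAD scaled
to the footprint area); below-floor spots are excluded rather than clamped
to avoid fabricated extremes. Box-plot summaries use linear-interpolation
percentiles with whiskers at the 1st/99th percentiles, and entries beyond
the whiskers are flagged as candidate outliers — an operationalization of
visual candidate picking; the full ranked list is always emitted so the
cut is advisory.

**Tracking** designates the lowest temperature as baseline, registers each
heated gel to it with a least-squares affine estimated from
mutual-nearest-neighbor spot pairs (one round of 3×MAD outlier rejection;
identity fallback below 3 pairs), then assigns spots greedily by nearest
neighbor within 3 px. Spots absent at baseline start no track: without a
baseline point they have no internal-standard reference.

**Normalization**: rel_c(T) = [I_c(T)/I_Cy2(T)] / [I_c(T₀)/I_Cy2(T₀)] for
c ∈ {Cy3, Cy5}. Per-gel gain cancels exactly in the first ratio; the
second pins both curves to 1 at baseline. Vehicle and drug are
self-normalized separately (the natural reading of fractional melting
curves; it also makes a constant PTM-induced Cy5 deficit cancel, so PTM
parents do not masquerade as shifts). Cy2 below floor leaves the point
missing, never zero.

**Melting fits** use the same three-parameter logistic, requiring ≥ 4
points spanning the apparent midpoint and a ≥ 0.2 dynamic range (else
`converged = False` with NaN parameters — flat curves are never assigned a
Tm). Initialization is a vectorized grid over Tm (16 values spanning the
observed range) × k ∈ {0.2, 0.5, 1, 2} × p ∈ {0, 0.2}, followed by bounded
least squares (0 ≤ p ≤ 0.5, k ∈ (10⁻³, 10], analytic Jacobian). Noiseless
logistic data are recovered to well within 0.1 °C.

**Shift scoring** computes two criteria per track: the transverse
ΔTm = Tm(drug) − Tm(vehicle) from the two fits (reported only when both
converged), and the longitudinal y-deviation — max and trapezoidal area of
|rel_drug − rel_vehicle| — computed from the *data points*, not the fits,
so a steep-slope shift with marginal ΔTm is still detected and tracks with
failed fits are still scored. Tracks missing more than half their heated
points are scored by y-deviation only. z-scores standardize y_dev_max
across all tracks of the run; no formal multiple-testing procedure is
applied (none exists for this readout), which is stated rather than hidden.

## Classification

Baseline-gel rules run on the unheated spot table, using a regularized
color score log2((I_Cy5 + floor)/(I_Cy3 + floor)) so single-channel spots
(satellites with no Cy3) still score strongly:

* **PTM pair**: one red and one green spot beyond the color threshold τ,
  |Δy| ≤ 2 px and Δx in (2 px, 8σx) — "horizontally adjacent"; matched
  greedily by combined color strength, each spot in at most one pair.
* **Registration artifact**: red/green pair with |Δx| ≤ 1 px, Δy in
  (0.5, 4) px, and total intensities and Gaussian widths agreeing within
  30% — a genuinely shifted target fails the equal-intensity test.

Final calls follow a fixed precedence — artifact > ptm_pair > thermal >
unchanged — and a track colored at baseline can never be called thermal
(its color difference predates heating); uncolored-pair leftovers of that
rule are labeled `ambiguous`. A thermal call requires **both** z ≥ 3
(across-track standardization) **and** y_dev_max ≥ 0.30 in absolute terms.
The absolute floor is derived from the forward model's noise budget:
propagating the default 3% CV through the double ratio gives a per-point
null sd of ≈ 0.06, so the maximum over seven heated temperatures across a
few hundred tracks reaches ≈ 0.2 by chance, while the smallest shifts of
interest (|ΔTm| ≥ ~3 °C at typical slopes) produce deviations ≥ 0.45.
Direction (stabilized vs destabilized) is the sign of rel_drug −
rel_vehicle at the temperature of maximum deviation. The default color
threshold τ = 0.25 is ≈ 4 null standard deviations of the baseline log2
ratio at 3% CV (`classify.color_threshold` recomputes the 99th-percentile
value for other noise levels). All thresholds are configurable
(`CallThresholds`).

**Dose–response confirmation** fits the four-parameter logistic
r(c) = bottom + (top − bottom)·cʰ/(cʰ + EC50ʰ) by bounded least squares in
log-dose, EC50 initialized at the median dose, requiring ≥ 5 distinct
doses; an EC50 inside the dosed range is flagged interpolated. Responses
flat relative to replicate scatter return `converged = False`.

## Numerical and degenerate-input choices

* Logistic exponents are clipped at ±500 before `exp` — no overflow, no
  effect within 15 decades of the transition.
* Equal detection maxima tie-break in row-major order; candidate pair
  ties break on combined color strength, then spot id.
* Zero-variance rasters detect nothing (warning, empty list); empty ratio
  input yields an empty table; fewer than 2 entries refuse a box-plot
  summary.
* Output tables are written with a fixed `%.6g` float format, making
  identical (config, seed) reruns byte-identical.

## Problem sizes used in validation

Image-route checks run 8 gels of 384×384 px with 200 proteins
(stabilization/destabilization scenarios) or 80 proteins (misregistration
scenario). Replicated statistics use the spot-table route: the null
control runs 100 seeds × 120 inert proteins; ΔTm and EC50 recovery run 100
seeds each at the curve level (8 temperatures / 8 doses × 3 replicates).

## Known limitations

* Co-migrating proteins (one spot, several species) are not deconvolved;
  real gels resolve ~10²–10³ spots, and identity still requires excision
  and mass spectrometry, which is outside this package's scope.
* The affine registration model cannot follow local gel distortion;
  severely warped gels would need elastic registration before tracking.
* Sensitivity falls for shifts whose y-deviation stays under the 0.30
  floor (shallow slopes with |ΔTm| ≲ 1–2 °C); raising sensitivity means
  lowering `y_dev_min` at the cost of null specificity.
* The internal standard is assumed ideal; real Cy2 channels carry their
  own noise, which the normalization propagates rather than cancels.
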