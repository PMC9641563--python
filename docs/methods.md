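# Methods

## Scattering geometry and Q maps

Momentum transfer per pixel uses the exact relation
Q = (4π/λ) sin(½ atan(r/L)) with r the in-plane distance from the beam
center and L the sample–detector distance; at typical small-angle
geometries (76 µm pixels 8 m downstream, λ ≈ 1.13 Å at 10.94 keV) this
differs from the small-angle form 2πr/(Lλ) by ~10⁻⁶ relative, but the
exact form costs nothing. Pixel indexing is 0-based (row, col); the beam
center may be fractional and may sit off the detector (it is rejected
only beyond 10× the detector extent).

Three partition schemes hang off the Q map:

* **fine** — contiguous bins of width 1×10⁻³ nm⁻¹ (≈ 2 pixels) starting
  at the minimum unmasked Q; the trailing partial bin is kept rather
  than discarded. Fine bins are narrow so the mean intensity is nearly
  constant inside each, which is what makes binning the correlator sums
  safe (intensity variation inside a bin raises the g₂ baseline).
* **coarse** — 10 consecutive fine bins (≈ 1×10⁻² nm⁻¹), the reporting
  granularity for g₂.
* **saxs** — 270 logarithmically spaced bins spanning the unmasked Q
  range for the 1D intensity. Pixels at exactly Q = 0 cannot sit on a
  log grid and are left out of this scheme.

The representative Q of every partition is the pixel-count-weighted mean
of the member pixels' Q — the same weighting the intensity average uses,
keeping ⟨I(Q)⟩ self-consistent.

For simulated ring data each ring is one fine partition and its own
coarse partition; there is no further Q rebinned structure to exploit.

## Synthetic speckle generator

The generator emulates the statistical structure of coherent scattering
from a dilute Brownian suspension, per pixel:

* the scattered field is a sum of `n_modes` independent complex
  Gaussian modes; each mode evolves as a stationary Ornstein–Uhlenbeck
  process advanced with the exact one-frame update
  `E(t+Δt) = E e^{−ΓΔt} + ξ (1 − e^{−2ΓΔt})^{1/2}`, Γ = DQ², implemented
  as an AR(1) IIR filter so 50 000-frame sequences are generated at
  C speed;
* the mode-summed intensity has unit mean and normalized
  autocorrelation 1 + (1/n_modes) e^{−2ΓΔtτ}: partial coherence enters
  only through the mode count, so the realized contrast is exactly
  β = 1/n_modes (0.143 for the default 7 modes, recorded alongside the
  nominal 0.14 it approximates);
* detection is a per-pixel per-frame Poisson draw around the intensity
  scaled to the configured count rate, optionally shaped in Q by the
  polydisperse sphere form factor (normalized to 1 at a reference Q).

Defaults reproduce the study conditions the package targets: 18.7 nm
particles at T = 279 K in η = 1.520×10⁻³ Pa·s, 52 kHz frames, 100 000
frames per sequence, 7×10⁻⁵ photons/pixel/frame, β ≈ 0.14.

What the generator deliberately does **not** emulate: inter-pixel
speckle correlations (the analysis uses only per-pixel time correlations
and pixel averages, so independence changes no measured quantity),
detector artifacts such as double-counter gating overlap (only the
symptom — a too-high correlation plateau — is handled, by the flagger),
flat-field/solid-angle corrections, and any structure-factor S(Q)
physics (dilute limit). Passing tests therefore demonstrate correctness
of the analysis chain under the stated model, not robustness to detector
systematics absent from the model.

## Multi-tau correlator

Level 0 correlates the raw stream at lags 1..8 (8 channels per level,
the classic DLS layout; configurable); each further level block-averages
frames by 2 (non-overlapping means, intensity-preserving) and correlates
at channels 5..8, so lag spacing doubles per level. Lags beyond
n_frames/4 are dropped as a statistical-reliability floor (configurable).
Windows are symmetric: at lag τ the products average over t ∈ [0, T−τ)
while IF and IP average I(t) and I(t+τ) over the same pair set, which
cancels linear intensity drift to first order (verified numerically:
|g₂−1| < (bT/a)² for I = a + bt). On integer streams the level-0 sums
are bit-exact against a brute-force all-pairs oracle, and a constant
stream gives G2 = IF·IP at every level exactly.

Normalization order matters at sparse count rates: within each fine
partition the pixel-averaged sums are divided —
g₂ = ⟨G2⟩ᵢ / (⟨IF⟩ᵢ⟨IP⟩ᵢ) — and only then is g₂ averaged
(pixel-count-weighted) into coarse partitions. The per-pixel ratio
G2/(IF·IP) is biased by denominator shot noise when pixels hold a few
photons; the test suite demonstrates the binned estimator sits closer to
the true plateau at 7×10⁻⁵ counts/pixel/frame. The reported error bar is
the *population* standard deviation of per-pixel g₂ within the coarse
partition — deliberately conservative; divide by √n_pixels for a SEM
(the stability check does).

Bad pixels are flagged from the small-lag plateau statistic
s = median over the 5 smallest lags of G2/(IF·IP): within each fine
partition, s > median + 5·1.4826·MAD flags the pixel. The rule is robust
and parameter-light; partitions under 10 pixels are skipped. An epsilon
on the threshold keeps degenerate (identical-pixel) partitions unflagged.

Repeated measurements are merged by weight-proportional averaging of
G2/IF/IP *before* normalization (pair-count weights), identical to
correlating the gap-concatenated stream with no cross-boundary pairs.

## SAXS reduction and form-factor fit

Time averaging is a per-pixel mean count rate; azimuthal averaging is
the per-SAXS-partition mean with SEM from the population spread of
member pixels. The sphere amplitude uses the Taylor series
1 − x²/10 + x⁴/280 below x = 10⁻²: the direct formula's cancellation
error grows as ε/x² (≈ 2×10⁻¹² at the branch point) while the series
truncation is < 10⁻¹⁶, so the branches agree to well under 10⁻¹⁰. The
Gaussian size average (number-weighted, V(R)² intensity weighting) is a
Simpson quadrature on a fixed 129-point grid over R₀ ± 4σ truncated at
R > 0; against a 10× finer grid it agrees to better than 10⁻⁶ relative
over the fitted Q range, and σ_R > R₀/2 triggers a truncation-bias
warning. The fit minimizes weighted residuals of log I (intensities span
decades, so log residuals weight the decades evenly), with free
(R₀, σ_R, scale, background); reported residuals are log(data) −
log(model), so an unmodeled low-q aggregation upturn shows as positive
low-q residuals.

## Dynamics fits

Per coarse Q, Δg₂ = β e^{−2τ/τ₀} is fitted by weighted nonlinear least
squares with β fixed to the static-reference contrast by default (a
free-β mode exists for diagnostics). τ₀ is bounded to [10⁻⁷, 10³] s;
hitting a bound, or a relative τ₀ error above 10 (the signature of a
flat, unidentifiable signal), marks the entry unconverged and excludes
it downstream. Decay rates are then fitted linearly, Γ = DQ² through
the origin, weighted by σ_Γ = σ_τ₀/τ₀², using points with Q ≤ 0.1 nm⁻¹
(above which simple-diffusion scaling is not guaranteed); the linear-
in-Γ formulation gives unbiased weighting compared with fitting τ₀
against 1/Q² directly. Finally R_H = kT/(6πηD) with σ_R_H/R_H = σ_D/D;
viscosities for electrolyte-containing samples are configuration
constants (the electrolyte corrections themselves are outside scope).

## Pipeline, stability, provenance

`run_pipeline` chains simulate → correlate → fit; any stage error is
re-raised carrying the stage name. Every container written carries the
config hash and seed; identical configs give bit-identical deterministic
outputs. The stability diagnostic splits an acquisition into subsets and
compares SAXS curves and g₂(τ) per Q pairwise by reduced chi-square with
combined SEM errors; the default pass threshold of 2.0 is this package's
choice for "no observable drift/damage".

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the acceptance script: 8 rings
× 200 pixels × 50 000 frames at 0.05 photons/pixel/frame for end-to-end
R_H recovery (the elevated count rate substitutes statistics for the
~10⁹ frames a real low-count measurement accumulates); 2000 pixels ×
20 000 frames for contrast recovery; ≤ 64 × 16 integer fixtures for
bit-exact correlator oracles. Under these conditions the end-to-end
R_H estimates scatter by a few tenths of a nm around truth across
seeds. Random number use is fully ordered (rings, then modes, then
Poisson) so a seed fixes the byte-exact event stream.

## Known limitations

* Frame-clock correlation only: no event-clock lags, no two-time
  correlation functions, no detector dead-time correction.
* Single-exponential decays only (no stretched/double exponentials), so
  strongly aggregating samples are diagnosed (low-q SAXS residuals,
  stability check) rather than modeled.
* The multi-tau level/channel layout is the classic DLS one; beamline
  correlators may use different channel counts, so absolute lag grids
  can differ between implementations even though g₂ values at shared
  lags agree.
* g₂ error bars ignore pixel-to-pixel correlation of the speckle field
  (none in the generator; weak in real data at these geometries).
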