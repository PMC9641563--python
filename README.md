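# virusxpcs

Small-angle X-ray photon correlation spectroscopy (XPCS) + SAXS analysis
for dilute suspensions of nanoscale particles such as icosahedral plant
viruses (~15 nm radius). The package turns sparse photon-counting
detector frames — tens of kHz frame rates, count rates down to
~10⁻⁴ photons · pixel⁻¹ · frame⁻¹ — into two complementary sizes:

* the **geometric radius R₀** from the time-averaged scattering: the 1D
  azimuthally averaged intensity is fitted with the form factor of
  spheres with a Gaussian radius distribution,
  `P(q) = ⟨V(R)² A(qR)²⟩_N / ⟨V(R)²⟩_N`, `A(x) = 3(sin x − x cos x)/x³`;
* the **hydrodynamic radius R_H** from the speckle dynamics: the
  multi-tau intensity autocorrelation `g₂(τ, Q)` is fitted per Q with
  `Δg₂ = β exp(−2τ/τ₀)`, the decay rates follow `1/τ₀ = DQ²` for
  Brownian motion, and `R_H = kT/(6πηD)` (Stokes–Einstein).

Because real beamline datasets at these count rates run to ~10⁹ frames,
the package ships a synthetic Brownian-speckle generator with the exact
statistical structure the analysis assumes (Ornstein–Uhlenbeck coherent
modes, partial coherence as an incoherent mode sum with contrast
β = 1/n_modes, Poisson detection), so the whole chain is testable at
desk scale and parameter recovery can be verified against known ground
truth.

Correlator details that matter in the sparse-photon regime and are
implemented here exactly:

* multi-tau lag grid (frames recursively block-averaged by 2 per level);
* symmetric normalization `g₂ = ⟨I(t)I(t+τ)⟩ / (⟨I⟩_[0,T−τ] ⟨I⟩_[τ,T])`;
* pixel binning of the sums G2, IF, IP within narrow Q partitions
  *before* the division (per-pixel ratios are hopelessly noisy at these
  count rates), then a further 10× binning in Q of the resulting g₂;
* robust flagging of pixels with abnormally high correlation plateaus;
* error bars as the per-pixel g₂ population spread within the reported
  Q partition.

## Worked example

Simulate four Q rings of Brownian speckle for a 18.7 nm particle in a
279 K, 1.52 mPa·s buffer, then run the full correlate → fit chain:

```python
from virusxpcs import SimulationConfig
from virusxpcs.pipeline import RunConfig, FitConfig, run_pipeline

sim = SimulationConfig(
    ring_spec=[(0.03, 100), (0.05, 100), (0.07, 100), (0.09, 100)],
    n_frames=20_000, mean_count_rate=0.05, seed=42,
)
cfg = RunConfig(simulation=sim, fit=FitConfig(beta=1/7, q_max=0.1), seed=42)
res = run_pipeline(cfg)
print(f"D   = {res.diffusion.d:.3e} m^2/s")
print(f"R_H = {res.r_h:.2f} nm")
for e in res.g2_fits.entries:
    print(f"  Q = {e.q:.3f} nm^-1  tau0 = {e.tau0:.3e} s")
```

prints

```
D   = 6.873e-12 m^2/s
R_H = 19.56 nm
  Q = 0.030 nm^-1  tau0 = 1.469e-04 s
  Q = 0.050 nm^-1  tau0 = 6.661e-05 s
  Q = 0.070 nm^-1  tau0 = 3.130e-05 s
  Q = 0.090 nm^-1  tau0 = 1.429e-05 s
```

The fitted decay times fall as 1/Q² (1.47×10⁻⁴ s at 0.03 nm⁻¹ down to
1.4×10⁻⁵ s at 0.09 nm⁻¹), the slope of 1/τ₀ vs Q² gives the diffusivity
D, and Stokes–Einstein converts it to R_H = 19.6 nm — within one
combined error of the 18.7 nm ground truth at this short desk-scale
sequence length (the quoted uncertainty is the conservative per-pixel
population spread propagated through both fits).

The same stages are available from a shell:

```sh
virusxpcs simulate --config sim.yaml --out events.h5
virusxpcs reduce-saxs --events events.h5 --out saxs.dat
virusxpcs correlate --events events.h5 --out g2.h5
virusxpcs fit --g2 g2.h5 --temperature 279 --viscosity 1.520e-3 --qmax 0.1
virusxpcs pipeline --config run.yaml --out results.h5
virusxpcs check-stability --g2 part1.h5 --g2 part2.h5
```

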