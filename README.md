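# raftspt

High-speed single-particle-tracking (SPT) analysis of lipid diffusion in
raft-mimetic supported bilayers, with a matched synthetic-data generator.

Membranes with coexisting liquid-ordered (Lo, raft-mimetic) and
liquid-disordered (Ld) phases slow and subtly reshape the lateral diffusion of
single lipids. At 50 kHz frame rates and a few nanometres of localization
precision — the regime of interferometric scattering (iSCAT) tracking with
gold-nanoparticle labels — the motion inside Lo domains is *subdiffusive* on
microsecond timescales and shows transient trapping in nanoscopic subdomains.
`raftspt` implements the full analysis chain for this kind of experiment and a
simulator that emulates it, so every statistic can be exercised by parameter
recovery on synthetic data:

- **Trajectory analysis** — time-averaged mean-squared displacement (MSD)
  with overlapping pairs, length-weighted ensemble averaging, and the
  anomalous-diffusion model

  MSD(Δt) = 4 Γ Δt^α + offset

  fitted with Γ (transport coefficient), α (anomalous exponent; α = 1 is
  Brownian) and the offset (dynamic localization error) all free. The
  microscopic diffusion rate is the two-point slope
  D = [MSD(2Δt) − MSD(Δt)] / 4Δt, which cancels any constant offset.
  Transient diffusion rates are computed on fixed 146-step segments.
- **Transient-confinement detection** — the probability-level statistic
  (Simson–Sheets–Jacobson): over a forward window of 25 steps with maximal
  displacement R from the window start, log₁₀ψ = 0.2048 − 2.5117·DΔT/R², and
  L = −log₁₀ψ − 1 for ψ < 0.1 (else 0). Smoothed runs of L above a critical
  level of 1 (99% confidence) become confinement events with residence times
  and diameters (2√2 × RMS spread, noise-corrected). False positives are
  calibrated on matched Brownian controls.
- **Imaging chain** — synthesis of iSCAT-like frames (dark Gaussian spot,
  ~300 nm FWHM, SNR 20 on 48 nm pixels, over a stationary non-uniform
  background with ~1% domain contrast), temporal-median background removal,
  sub-pixel 2D Gaussian localization, and nearest-neighbor track linking.
- **Membrane simulator** — 2D diffusion at 20 µs frames with motion blur and
  3 nm/axis localization noise; micron-scale Lo domains in an Ld background;
  circular nano-traps (32 ± 10 nm diameter) inside Lo with reflecting
  boundaries and Poisson escape (0.62 ms mean residence); trap density
  calibrated so the measured microscopic D matches a target (0.24 µm²/s by
  default).

The statistical core is exposed statsmodels-style:
`AnomalousDiffusionModel(curve).fit()` returns an `AnomalousFitResults` with
parameters, standard errors, diagnostics and a `summary()` table.

## Worked example

Simulate a single lipid track deep inside an Lo domain with the default trap
field, then run the MSD fit and the confinement detector:

```python
import raftspt as r

cfg = r.SimConfig(n_steps=2000, d_free=0.28, seed=1)          # 20 us frames
model = r.MembraneModel.uniform_lo(trap_area_fraction=0.31, seed=1)
traj = r.simulate_membrane(cfg, model, d_lo_free=0.28, burn_in_steps=250)

curve = r.time_averaged_msd(traj, max_lag_s=1e-3)
print(r.fit_anomalous(curve, fit_range_s=(2e-5, 1e-3)).summary())

events = r.detect_confinements(
    traj, r.ConfinementParams(d_ref_um2_s=1.0, loc_noise_nm=3.0)
)
```

This prints:

```
Anomalous diffusion MSD fit
    MSD(dt) = 4*Gamma*dt^alpha + offset
  lags fitted     : 22 (2e-05-0.001 s)
  Gamma           : 0.01767 +/- 0.00086 um^2 s^-alpha
  alpha           : 0.7176 +/- 0.0062
  offset          : 2.033e-05 +/- 6.4e-07 um^2
  D (2-point)     : 0.2417 um^2/s
  alpha (log-log) : 0.7177
  fit RMS         : 3.11e-06 um^2
  classification  : SUB
```

The track is strongly subdiffusive (α ≈ 0.72) although its microscopic
diffusion rate at the 20 µs lag is an ordinary-looking 0.24 µm²/s — the
signature of nanoscale trapping that only microsecond-resolution tracking can
see. The fitted offset (2 × 10⁻⁵ µm²) is the dynamic localization error: 4σ²
from the 3 nm noise minus the motion-blur deflation. The detector finds 27
transient confinements in this track (mean diameter ~21 nm) when referenced
to the unhindered lipid mobility.

A shell interface wraps the same functions:

```bash
raftspt simulate --kind lo-traps --seed 1 --outdir out --n-traj 8 --n-steps 2000
raftspt msd out/trajectory_lo_000.csv --outdir out
raftspt confine out/trajectory_lo_000.csv --outdir out
raftspt report --which both --seed 1 --outdir out
```

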