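# brainmre

Multifrequency cerebral magnetic-resonance-elastography (MRE) analysis:
from time-resolved shear-wave images to viscoelastic tissue constants and
cohort-level diagnostic statistics.

Cerebral MRE drives gentle acoustic vibrations into the head and encodes
the resulting shear waves into MR phase images. Because the mechanical
scaffold of brain tissue degrades with diffuse disease processes — such
as chronic neuroinflammation in progressive multiple sclerosis — the
frequency-resolved complex shear modulus G\*(ω) is a sensitive global
marker of parenchymal integrity, often changing more strongly than
volumetric atrophy measures. This package implements the complete
analysis chain used in multifrequency brain MRE studies, plus a synthetic
wave-field and cohort generator so every stage can be exercised and
validated without patient data.

## The analysis chain

1. **Temporal Fourier decomposition** — wave series u(x, y, t), sampled
   64 times over one 80 ms vibration period, are decomposed into complex
   wave images U(x, y, ω) at the drive frequencies f ∈ {25, 37.5, 50,
   62.5} Hz (harmonics 2–5 of 12.5 Hz).
2. **k-space bandpass** — each U is filtered with an annular isotropic
   passband (per-frequency thresholds 5.56–50.0, 8.33–66.67, 10.0–90.9
   and 10.0–100.0 cycles/m) to suppress compression-wave components and
   noise.
3. **Helmholtz inversion** — per-pixel algebraic inversion
   G\*(x, y, ω) = −ρω²U/ΔU with the 2D five-point Laplacian and
   ρ = 1000 kg/m³, then arithmetic averaging of complex G\* over the
   parenchyma ROI.
4. **Springpot fit** — the four ROI-averaged moduli are fitted by the
   two-parameter fractional ("springpot") model

   G\*(ω) = κ·(iω)^α,  κ = μ^(1−α)·η^α,  η = 3.7 Pa·s (fixed),

   yielding the shear elasticity μ (network strength, Pa) and powerlaw
   exponent α (network topology, dimensionless).
5. **Cohort statistics** — group percent differences, Mann–Whitney U,
   Spearman correlations, standardized multivariate regression,
   ROC/maximum-Youden cutoffs and brain-parenchymal-fraction (BPF)
   arithmetic.

## Worked example

```python
from brainmre import (AcquisitionSpec, MediumSpec, simulate_wavefield,
                      analyze_wavefield)

medium = MediumSpec(mu=3278.0, alpha=0.2934)   # healthy-control brain, Pa
series = simulate_wavefield(medium, AcquisitionSpec(), seed=1)
fit, samples = analyze_wavefield(series)
for s in samples:
    print(f"{s.frequency:5.1f} Hz  |G*| = {abs(s.g_star):7.1f} Pa "
          f"({s.n_pixels} px)")
print(f"mu = {fit.mu:.1f} Pa, alpha = {fit.alpha:.4f}")
```

prints

```
 25.0 Hz  |G*| =  1924.6 Pa (4756 px)
 37.5 Hz  |G*| =  2290.3 Pa (4715 px)
 50.0 Hz  |G*| =  2418.1 Pa (4432 px)
 62.5 Hz  |G*| =  2572.9 Pa (4308 px)
mu = 3302.9 Pa, alpha = 0.2970
```

The per-frequency moduli rise as ω^α (the powerlaw dispersion), and the
fit recovers the generating medium (μ = 3278 Pa, α = 0.2934) to within a
fraction of a percent despite 2% displacement noise and a 20%
compression-wave contaminant. The same chain is available from the shell:

```bash
brainmre run-all --seed 1 --output-dir runs/demo   # writes NIfTI/CSV + manifest
brainmre stats runs/demo/cohort.csv                # group deltas, U tests, ROC
```

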