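# Methods

## Physical model

Brain tissue is modelled as a homogeneous, isotropic, linearly
viscoelastic medium whose complex shear modulus follows the springpot
(fractional element) powerlaw

    G*(ω) = κ (iω)^α,    κ = μ^(1−α) η^α,

interpolating between a Hookean spring (α = 0, G\* = μ) and a Newtonian
dashpot (α = 1, G\* = iωη). μ (Pa) quantifies the inherent strength of
the tissue's mechanical network, α its geometry/topology, and η is a
fixed viscosity convention constant — 3.7 Pa·s for human brain — chosen
a priori so fitted moduli are comparable across studies; η is never
fitted. Two useful identities follow from the principal branch of i^α:
the loss tangent Im G\*/Re G\* = tan(απ/2) is frequency-independent, and
|G\*| grows monotonically as ω^α.

A time-harmonic shear displacement field in such a medium obeys the
Helmholtz equation ρω²U + G\*ΔU = 0 with ρ = 1000 kg/m³, so the modulus
can be recovered pointwise by algebraic inversion G\* = −ρω²U/ΔU. The
complex shear wavenumber is k\*(ω) = ω√(ρ/G\*), with the square-root
branch chosen so Im k\* ≤ 0 and a wave exp(i(ωt − k\*ξ)) decays along
its propagation direction. At the Table-level tissue parameters the
predicted shear wavelengths at 25–62.5 Hz are 2.4–5.8 cm and the 1/e
decay lengths 1.8–3.9 cm — the medium is strongly lossy (quality factor
≈ 2), which drives most numerical choices below.

## Synthetic wave fields

The generator emulates a single transverse image slice: the field is the
real part of a superposition of attenuating plane shear waves, one per
(drive frequency, direction) pair, each entering at the edge of the
field of view with amplitude A and decaying along its path (the path
coordinate is referenced to the entry edge, so no component ever grows).
Defaults:

| parameter | default | why |
|---|---|---|
| grid | 128×128 px, 1.5 mm | 192 mm field of view / 128 matrix |
| time axis | 64 samples / 80 ms | drive harmonics 2–5 of 12.5 Hz resolve exactly |
| frequencies | 25, 37.5, 50, 62.5 Hz | the multifrequency protocol |
| directions | 8 evenly spaced azimuths | circumferential skull excitation; with Q ≈ 2 damping, 4 azimuths leave the deep ROI noise-dominated at 62.5 Hz |
| amplitude A | 50 µm | in-brain displacement scale; configurable, no claim of realism |
| noise | white Gaussian, SD = 2% of A | displacement-domain measurement noise |
| contaminant | 20% of A, 0.05 cycles/m | compression-wave residue; its spatial frequency is the physical compressional scale (c ≈ 1.5 km/s ⇒ λ of tens of meters, i.e. near-DC across a 19 cm FoV) |
| mask | centered ellipse, ~60% of grid | parenchyma ROI including CSF spaces |

Cohort tables are independent Gaussian draws per variable from per-group
(mean, SD) parameters; defaults reproduce the study groups (23
chronic-progressive patients, 38 controls; μ 2.607 ± 0.482 vs
3.278 ± 0.314 kPa; α 0.2756 ± 0.0108 vs 0.2934 ± 0.0086; volume
1.513 ± 0.178 vs 1.636 ± 0.068 dm³; BPF means 0.9610 vs 0.9775). BPF
SDs, disease duration and the pooled patient age/EDSS spread are not
tabulated per group and were set to plausible clinical values (BPF SD
0.012/0.008; duration 16 ± 8 y; age 51.7 ± 8 y; EDSS 5.5 ± 1.4).
Variables are drawn independently, so cross-variable correlations
(e.g. μ with volume) are absent: tests on synthetic cohorts validate the
statistical machinery, not any claim about real covariance structure.

## What the simulation does not capture

Plane-wave superpositions in a homogeneous medium have no scattering,
reflections, mode conversion, standing-wave resonances, or spatial
heterogeneity (lesions, ventricles, anisotropic tracts), and the single
encoded component is taken as the scalar field. Passing tests therefore
demonstrate the correctness and calibration of the processing chain
under its own model assumptions — not accuracy on in-vivo data, where
algebraic Helmholtz inversion is known to carry noise- and
heterogeneity-dependent bias.

## Numerical choices in the inversion chain

**Temporal decomposition** uses the exp(−iωt) kernel scaled by 2/N so a
pure sinusoid of amplitude A returns |U| = A. Requested frequencies must
be integer harmonics of 1/period below Nyquist.

**Bandpass.** The annular thresholds are interpreted as spatial
frequency in cycles per meter (the simulated shear wavenumbers,
17–41 cycles/m, then fall inside every band; a rad/m reading would put
them outside). The filter window is a hard-edged annulus by default at
the operation level, with an optional raised-cosine band-edge taper.

**Mask-edge apodization.** Filtering a boolean-masked image is not
benign: the amplitude discontinuity at the mask edge scatters broadband
energy across k-space, and the annulus' removal of the out-of-band part
re-enters the ROI as in-band ringing. Because the Laplacian weights
spectral content by k², this contamination biases the per-pixel ratio
−ρω²U/ΔU low by tens of percent — measured at 35–55% on noiseless
simulated fields at default geometry. The pipeline therefore multiplies
the masked image by a raised-cosine ramp over the outer 16 px of the
mask before the FFT (zeros outside the mask are retained), and the
inversion erodes its mask by 18 px so the attenuated ramp never enters
the average. The residual end-to-end error decreases monotonically with
ramp width; 16 px leaves ≤ ~2% modulus error while keeping ≈ 4500 ROI
pixels. The bare `bandpass_filter` operation applies no apodization
unless asked.

**Mask-aware DC removal.** The DFT's k = 0 bin conflates the mask shape
with the field's mean, so a near-constant compression component leaks
past the annulus through the mask's own spectral tails. The filter
subtracts the in-mask mean before windowing, which removes a uniform
contaminant exactly and is a no-op for zero-mean wave fields.

**Inversion guards.** The five-point Laplacian marks the boundary ring
invalid; its plane-wave eigenvalue (2cos kh − 2)/h² differs from −k² by
≈ (kh)²/12 — 0.2% at 25 Hz up to 1.3% at 62.5 Hz at 1.5 mm spacing —
which is the irreducible bias floor of the chain and the bound the
acceptance tests use. Pixels with |ΔU| below a fraction of the in-mask
median |ΔU| are excluded before averaging: the bare operation uses a
pure divide-by-zero guard (10⁻³), while the pipeline default is 0.3,
sized to sit at the filtered-noise floor of ΔU. Without it, pixels whose
Laplacian is noise-dominated contribute heavy-tailed ratio outliers that
both bias the ROI mean and inflate its seed-to-seed scatter. Surviving
complex values are averaged arithmetically (multiple slices pool by
valid-pixel count); no other outlier exclusion is applied.

**Springpot fit.** Deterministic bounded trust-region least squares on
the complex misfit (real and imaginary parts jointly, unweighted across
frequencies), started from the fixed 3×3 grid μ ∈ {1, 3, 10} kPa ×
α ∈ {0.1, 0.3, 0.6}; the best residual wins, ties to the smaller α.
Noiseless dispersion data are recovered to ~10⁻⁶ relative error from any
of the starts. Classical Voigt, Maxwell and Zener forward models are
provided for comparison only; the three-parameter Zener model is not
fitted because its second modulus obscures interpretation.

**End-to-end calibration.** With all defaults (8 azimuths, 2% noise,
20% near-DC contaminant), the median recovery over 20 seeds is within
1.8% in μ and 0.002 in α for both group media; the acceptance suite
asserts 3% and 0.01.

## Statistics

Percent group differences use the control mean as denominator. The
Mann–Whitney U test uses midranks, switching from the exact permutation
distribution (min n ≤ 8, no ties) to the tie- and continuity-corrected
normal approximation. Spearman correlation is Pearson on midranks with
the t-approximation p-value. Standardized regression z-scores response
and covariates and reports OLS betas with two-sided p. ROC curves sweep
midpoint thresholds; AUC is the trapezoid area (equal to the
concordant-pair fraction with half credit for ties); the diagnostic
cutoff maximizes Youden's J = sensitivity + specificity − 1, ties
resolved toward higher specificity; the default direction treats lower
scores as diseased, since patients have lower μ and α. P-values are
reported raw — no multiple-testing adjustment — matching the exploratory
design. Published per-subject AUROC values and cutoffs are not
reproducible from group summaries, so the suite asserts only a
qualitative level (AUC > 0.8 for μ on a synthetic cohort).

## Known limitations

* The 25 Hz band clips part of the attenuation-broadened (Lorentzian)
  wavenumber line of strongly damped media; the 25 Hz modulus sample
  carries the largest residual bias (~5%), partially absorbed by the
  four-frequency fit.
* Mean-of-ratios inversion remains sensitive to any in-band broadband
  contamination; the apodization/erosion defaults trade ~40% of mask
  pixels for that robustness.
* The cohort generator draws variables independently and clips EDSS/BPF
  to their valid ranges, slightly perturbing means when an SD is large
  relative to the distance to a bound (not the case at the defaults).
* Multiple slices are pooled as one ROI weighted by valid-pixel count;
  no inter-slice weighting scheme is modelled.
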