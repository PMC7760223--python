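# Methods

This note documents the statistical models, the parameter choices that
matter, the synthetic-data generator, and the numerical decisions behind
`alidose`. Notation: y for observed well viabilities (% of control), θ_j
for the plate-level mean of plate j, μ for the across-plate consensus.

## Viability normalization

Each well's percentage viability is computed per plate as

    v = 100 · (A_test − A_blank) / (A_control − A_blank)

where A_blank is the mean absorbance of the plate's medium-blank wells
and A_control the mean of its negative-control (incubator) wells.
Technical replicates of a well are averaged before normalization.
Negative values (test below blank) are kept, not clipped: they carry
information for the downstream consensus model and are flagged rather
than censored. A plate whose control mean does not exceed its blank mean
is invalid and rejected. An optional interference flag marks wells whose
reference-wavelength (562 nm) signal exceeds a configurable multiple
(default 2×) of the plate's median, indicating particle or debris
interference; an infinite factor disables the flag.

## Multi-plate consensus model

Plates measured on different days disagree by more than their
within-plate scatter, so per-condition viabilities are pooled with a
Gaussian hierarchical random-effects model:

    y_ij | θ_j, σ_j ~ N(θ_j, σ_j²)      well i on plate j
    θ_j  | μ, τ     ~ N(μ, τ²)
    μ ~ N(100, 1000²)                    (effectively flat on the viability scale)
    σ_j ~ Half-Cauchy(25),  τ ~ Half-Cauchy(25)

All measurements are assumed Gaussian. The Half-Cauchy scale of 25
viability points is weakly informative: it admits both near-zero
between-plate heterogeneity and spreads far larger than any plausible
assay scatter, while its heavy tail avoids the boundary pile-up that
inverse-gamma priors produce when the number of plates is small (here
typically 3).

**Sampler.** Metropolis-within-Gibbs. μ and the θ_j have conjugate
Gaussian full conditionals and are Gibbs-updated from sufficient
statistics; σ_j and τ are updated by random-walk Metropolis on the log
scale (with the log-Jacobian term), step sizes adapted every 50
iterations during burn-in toward a 0.44 acceptance rate and frozen
afterwards, with a floor of log(10⁻⁶) to keep the scales positive.
Default 4 chains × 10 000 iterations, first half discarded; the test
suite and worked examples run 2 chains × 2 000 iterations, which
calibration experiments in the test suite show is sufficient for
3-plate problems (95% intervals cover a known truth at nominal rate).
Fixing τ = 0 and σ to a constant collapses the model to a single-level
conjugate Gaussian update, which is the closed-form oracle used to
validate the sampler.

**Diagnostics and fallback.** Convergence is assessed with
rank-normalized split-R̂ and effective sample size (via `arviz`);
R̂ > 1.05 on any parameter rejects the fit. Rank-normalized split-R̂
saturates (≈2 for completely disjoint chains), so thresholds are read
against 1.05, not against large values. On rejection the package falls
back to a DerSimonian–Laird random-effects combination of the per-plate
posterior means and standard deviations:

    w_j = 1/s_j²,  Q = Σ w_j (m_j − m̄_w)²,  C = Σw − Σw²/Σw
    τ̂² = max(0, (Q − (J−1))/C)
    consensus = Σ m_j/(s_j²+τ̂²) / Σ 1/(s_j²+τ̂²),  95% CI via z = 1.96

Degenerate limits: a single plate passes through with its own interval;
all-zero uncertainties reduce to equal weights with τ̂² equal to the
sample variance of the plate means. The implementation is authored here
and cross-checked in tests against
`statsmodels.stats.meta_analysis.combine_effects(method_re="dl")`.

**Decision rules.** A condition is called below control when
P(μ < 100) > 0.95 under the posterior. Two conditions are called
statistically indistinguishable when 0 lies inside the central 95%
interval of the difference of their μ draws. Significance for per-ion
spectral comparisons (below) uses p ≤ 0.05.

## Aerosol characterization

A number size distribution (bin midpoint diameters dᵢ in nm, number
concentrations Nᵢ in cm⁻³) is converted to mass concentration assuming
spherical particles of bulk density ρ (default 7.3 g/cm³, CeO₂):

    M [mg/m³] = Σᵢ Nᵢ ρ (π/6) dᵢ³ · 10⁻²¹ · 10⁹

(the factors convert nm³→cm³ and g/cm³→mg/m³). A diameter cutoff
(typically 50 nm) removes the nebulized-water residual mode that cannot
be separated from the particle signal; removing bins can only reduce
mass, the cutoff is idempotent, and a cutoff of 0 is the identity.
Mode detection applies a centered 3-bin moving average with
edge-replicate padding (zero padding would create boundary dips that
turn flat distributions into spurious interior plateau peaks) and
reports interior local maxima via `scipy.signal.find_peaks`; a flat
distribution therefore has no modes. On a 64-bin log grid spanning
10–1000 nm one bin is a factor ≈1.075 in diameter, which bounds the
mode-location resolution.

## Dosimetry

With aerosol mass concentration C (mg/m³ ≡ ng/mL), feed flow Q (mL/min)
and insert area A (cm²), the theoretical 100%-deposition rate is

    r_max = C · Q · 60 / A          [ng cm⁻² h⁻¹; reported in µg cm⁻² h⁻¹]

and the deposition efficiency is the measured areal rate divided by
r_max, as a percentage. The in-vivo reference rate is lung burden ÷
alveolar surface area ÷ exposure duration; in-vitro and in-vivo uptake
rates are called comparable when their ratio lies within a factor-of-two
band (0.5–2.0), an order-of-magnitude screen rather than an equivalence
test. The surface-coverage fraction of a deposited areal mass m on
spheres of diameter d and density ρ is

    f = (3/2) · m / (ρ d)

— each sphere of projected area π d²/4 and mass ρ π d³/6 covers area per
mass of 3/(2ρd). At the default 90 nm principal mode and the measured
deposition this is ≈8×10⁻⁴, i.e. far below a monolayer. Unit handling is
centralized in `alidose.units` (1 mg/m³ = 1 ng/mL; 1 nm = 10⁻⁷ cm).

## ICP-MS quantification

Blank correction subtracts the mean of the method blanks (six by
default). Detection and quantification limits are 3× and 10× the blank
standard deviation (ddof = 1). Below-LOD results are flagged, not
censored. Spike recoveries are accepted in the inclusive 86–120% window.
Total deposited mass per insert is the blank-corrected sum over the
cells, apical-wash and basal compartments; the intracellular fraction is
the cells share of that sum.

## Assay quality control

The negative-control chart takes per-day means of control-well
absorbance; the center line is their grand mean and the control limits
are ±3 standard deviations of the per-day means (≥2 days required). Note
that with n days a single outlier cannot exceed limits computed from all
n days unless (n−1)/√n > 3, i.e. n ≥ 11 — short series cannot flag
anything by construction. Day-wise coefficients of variation are
100·sd/mean over a day's wells (≥2 wells, ddof = 1). Because the sample
standard deviation is biased low in small samples (Gaussian c₄ factor:
≈0.886 at n = 3, ≈0.952 at n = 6), a generator configured at well COV
0.12 yields mean day-wise COV near 10.6% with 3 wells/day and near 11.4%
with 6; calibration tests use 6 wells per day so the estimate sits near
the configured value rather than at the edge of its tolerance band. The
dynamic-range check asks whether the killed-cell positive control is
statistically indistinguishable from the medium blank, using the
consensus model's pairwise-equality call on viability-scale records of
both.

## ToF-SIMS spectral statistics

Raw m/z–intensity pairs are binned to unit mass by round-half-up
(⌊x+0.5⌋; ties at .5 go up), restricted to 200–1200 u, and normalized so
the binned intensities sum to 100%. The preprocessing is idempotent on
already-binned, already-normalized input. Spectra are assembled on the
union mass grid (absent bins are 0) for multivariate analysis: centered
PCA (`sklearn`), and a Fisher linear discriminant with leave-one-out
cross-validated accuracy. Because bins far outnumber spectra per group
(n = 6), the within-group scatter is regularized by shrinking toward a
scaled identity (`LinearDiscriminantAnalysis(solver="lsqr",
shrinkage=0.1)`); shrinkage toward the identity rather than the diagonal
was adopted because it is the standard, well-tested estimator available
in `sklearn` and serves the same purpose of making the scatter
invertible. Zero-variance inputs report explained-variance ratios of 0
rather than NaN. Per-ion yield comparison reports each target bin's mean
intensity in the exposed group as a percentage of the control-group mean
(control = 100%), with a two-sample Welch test at p ≤ 0.05 per bin and
no multiple-testing correction by default, mirroring per-ion asterisk
reporting; a Benjamini–Hochberg option is provided. A bin with zero
control mean is reported missing.

**Permutation-null validation.** The discriminant pipeline is validated
against its own chance level: LOOCV accuracy on label-permuted data is
recomputed over 200 shuffles, and the pipeline passes when the 0.5
chance level lies inside the central 95% interval of the permuted
accuracies and the null mean lies in [0.35, 0.65]. The interval is
deliberately asymmetric-tolerant because LOOCV permutation nulls are
known to center slightly below chance (each held-out point's class is
under-represented in its training fold).

## Synthetic-data generator

All generators derive independent streams from one seed via
`np.random.default_rng([seed, offset])` with fixed per-generator
offsets, so consuming one stream never shifts another and every output
is byte-identical under a fixed seed.

- **Plates:** per-plate Gaussian plate effect (sd 5 viability points) on
  non-control conditions, per-well Gaussian absorbance with relative sd
  `well_cov` (default 0.12), blank wells at `blank_fraction` (default
  0.03) of the control absorbance, and a low-constant 562 nm channel.
- **SMPS scans:** mixture of lognormal modes (defaults: 20 nm/GSD
  1.45/7×10⁵ cm⁻³ residual + 90 nm/GSD 1.6/1.35×10⁵ cm⁻³ particle) on a
  64-bin log grid over 10–1000 nm, bin counts from lognormal CDF
  differences, multiplicative lognormal scan noise (GSD 1.1) and bin
  noise (GSD 1.05). The defaults put the analytic mass near 1.06 mg/m³
  whole-distribution and ≈4% lower above 50 nm.
- **ICP-MS:** deterministic uptake-rate × time × area deposition split
  into cells/wash/basal compartments (intracellular fraction 0.56),
  blank offset plus noise, six method blanks.
- **Spectra:** group-specific Gaussian peak intensities on fixed m/z
  positions (four phospholipid-region peaks, downregulated ×0.55 in the
  exposed group) plus common peaks, 6 spectra per group.

The generator reproduces the *statistical structure* the analysis
assumes — Gaussian well noise, plate-level random effects, lognormal
aerosol modes, compartment partitioning, group-separated spectra. It
does not emulate instrument artifacts (plate-edge effects, SMPS charge
correction, ICP-MS drift, detector dead time), non-Gaussian
contamination, or day-to-day trends, so passing calibration tests shows
the inference is correct under its own model, not that real data meet
that model. The scan-to-scan spread (GSD 1.1, giving ≈±0.12 mg/m³) is
narrower than the variability typical of nebulized aerosols; no result
here depends on that spread.

## Numerical choices

- z for 95% normal intervals: 1.959963984540054 (not 1.96 rounded) in
  the DerSimonian–Laird combiner; posterior intervals are empirical
  2.5/97.5 percentiles of the draws.
- Standard deviations use ddof = 1 throughout (blanks, COV, scan mass).
- Metropolis step adaptation only during burn-in; log-scale floor 10⁻⁶.
- Half-up binning uses ⌊x+0.5⌋ explicitly because `round()` banker's
  rounding would send ties to even masses.
- Degenerate inputs: a size cutoff removing every bin returns a single
  zero bin; a single MCMC chain is rejected by the convergence check;
  a single plate passes through the fallback combiner; an empty binned
  mass range raises.
- Test and example problem sizes (2 chains × 2000 iterations, 100
  replicate synthetic studies, 200 permutations, 50 simulated QC days)
  were chosen as the smallest sizes at which the calibration statements
  are stable, and are stated in the relevant docstrings.

## Known limitations

- The consensus model assumes Gaussian wells and exchangeable plates;
  heavy-tailed contamination or systematic plate trends are not modeled
  (the fallback combiner is a diagnostic escape hatch, not a robust
  estimator).
- The spherical-particle mass conversion ignores agglomerate porosity
  and effective density; for agglomerated aerosols it overestimates
  mass.
- The coverage fraction is a geometric monolayer bound, not a transport
  model; it says nothing about local dose heterogeneity.
- LOOCV with n = 6 per group has high variance; the permutation null,
  not the point accuracy, is the meaningful reference.
- The CLI wraps the library thinly and performs no unit inference on
  input files beyond the documented column conventions.
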