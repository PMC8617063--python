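# Methods

This note documents the models implemented in `thrombokit`, the
assumptions behind them, the synthetic-data generators used to exercise
them, and the numerical choices that matter. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Tight-binding inhibition kinetics

**Model.** For a fast-binding inhibitor at total concentration I_t and
enzyme at E_t, the steady-state velocity follows the Morrison equation

v_s = (v_o / 2E_t)·(√[(K_i′ + I_t − E_t)² + 4K_i′E_t] − (K_i′ + I_t − E_t)),

the physically admissible root of the quadratic mass-balance for the
enzyme–inhibitor complex. It is required whenever K_i′ ≲ E_t, the
regime of picomolar DTIs assayed at sub-nanomolar thrombin, where free
and total inhibitor differ materially. v_s is monotone non-increasing
in I_t, non-decreasing in K_i′, and bounded in [0, v_o].

**Velocities.** Steady-state velocities are the OLS slope of the
absorbance trace over a configurable window (default: the full
10-minute read). Fast-binding inhibitors give linear progress curves,
so no burst-phase or slow-onset handling is implemented; r² is
reported as a linearity diagnostic. Fractional velocities v_s/v_o are
formed against the mandatory I_t = 0 reference of each group; values
above 1 are retained as activation (observed for some cleavage
products) rather than clipped.

**Fit.** `MorrisonModel` minimises least squares in log10 K_i′
(positivity by construction) with Levenberg–Marquardt from four spread
starting points; the log-exponent is clipped to ±12 to keep
exploratory steps finite. By default v_o is fixed at the measured
reference velocity (1.0 on the fractional scale) since the assay
measures v_o directly; a fitted-v_o mode exists for robustness checks.
Standard errors come from the Jacobian covariance at the optimum,
delta-method-propagated to the pM scale. For K_i′ ≫ E_t the velocity
expression uses the conjugate (rationalised) form to avoid
catastrophic cancellation.

**Competitive-mode K_i.** For competitive inhibition
K_i′(S) = K_i(1 + S/K_m). `CompetitiveKiModel` regresses K_i′ on S —
inverse-variance weighted when K_i′ standard errors are supplied,
unweighted otherwise (the weighting choice is not dictated by the
assay; both are available) — giving K_i as the intercept and
K_m = intercept/slope as a derived diagnostic. K_m for the chromogenic
substrate is treated as a free synthetic-truth parameter (default
100 µM) since it is not independently pinned by the assays modelled
here. The mechanism call is `competitive_consistent` when the
regression r² ≥ 0.9 (configurable) with a positive slope; a flat
series leaves K_m undefined and flags a non-competitive pattern.

**IC50.** The four-parameter logistic is fitted as
y = A₂ + (A₁ − A₂)/(1 + 10^(H·(x − x₀))) with x = log10 C and
IC50 = 10^x₀. This is the standard log-logistic parametrisation of the
sigmoid on the log-dose axis; the equivalent "ratio" notation
(x/x₀)^H is ill-defined for negative log-concentrations and is not
used. At x = x₀ the curve passes through (A₁+A₂)/2. Asymptotes default
to unconstrained; a constrained mode pins A₁ = 0, A₂ = 100 since
percent inhibition is bounded. For non-competitive inhibitors
K_i = IC50; `noncompetitive_ki` relabels the estimate with that mode
annotation so reports carry its provenance.

**Selectivity.** `selectivity_fold` reports a conservative lower bound:
the lowest off-target concentration whose inhibition stays below the
threshold (default 20%) divided by the highest target concentration at
or above it. With a target active at 0.1 nM and off-targets quiet at
100 µM this bound is 10⁶. Ratios below 1 are flagged non-selective.

## Plasma coagulation traces

**Clot waveform analysis.** Derivatives of the transmittance curve are
estimated with Savitzky–Golay local-polynomial filters (default window
11 samples, polynomial order 5; order ≥ 4 is required for a third
derivative) because raw finite differences amplify read noise
quadratically per derivative order. min1/min2/min3 are the minima of
the first/second/third derivatives, searched outside the filter's
half-window edge region where the local polynomial is one-sided. Clot
time is defined as the time of min1 — the moment of the fastest
transmittance fall. Commercial analyzers use unpublished threshold
rules, so this operational definition is deliberate and prominent: it
is reproducible from the trace alone. Traces whose total drop is below
2% transmittance return an explicit no-clot result rather than an
exception. Near-uniform sampling (spread of time steps within 5% of
the mean) is required.

**Thrombogram parameters.** peak is the curve maximum and TTpeak its
time; the lag time LT is the first crossing of 10% of peak (linearly
interpolated between samples so grid alignment does not bias it), with
an absolute-threshold mode (default 2 nM) as the common alternative
convention; ETP is the trapezoidal area under the curve; the velocity
index is VI = peak/(TTpeak − LT), flagged undefined when the rise is
instantaneous. All parameters are invariant under time shifts, and
peak/ETP/VI scale linearly with the curve amplitude.

**Intensity gradients.** Dose–response of any trace parameter is
summarised by OLS of log10(value) on log10(dose), i.e.
Y = 10^(m·log10 X + C) with log ≡ log10. Values are normalised to the
vehicle control first (fold change); this shifts only C, never the
slope m, so gradient ratios |m_a|/|m_b| between drugs are unaffected
by the normalisation choice. Gradient ratios require fits of the same
parameter.

## Censored in-vivo dose–response

**Model.** The mean response time (occlusion or bleeding) follows a
Hill saturation between the saline baseline and the observation cap,
RT(d) = baseline + (cap − baseline)/(1 + (RT50/d)^h). The baseline is
fixed at the saline-group mean (shipped defaults: 8.82 min occlusion,
4.25 min tail bleeding) rather than estimated, since it is measured
directly in the saline arm. By construction RT(RT50) =
(baseline + cap)/2, so the RT50 parameter *is* the half-maximal-response
dose. The interpolation model is a package choice: source experiments
of this type report RT50 from the fitted curves without naming a
functional form, and the Hill form is the standard saturating
dose–response.

**Likelihood.** Residuals are multiplicative log-normal: log T ~
N(log RT(d), σ²). Observations at the cap are censored and contribute
the survival term P(T ≥ cap) instead of a density — they are neither
discarded nor treated as exact. Optimisation is Nelder–Mead over
(log RT50, log h, log σ), seeded by a least-squares fit to the
uncensored records; σ is floored at 1e-10 so the noiseless limit is
well-behaved. Standard errors come from the numerical Hessian in
log-parameter space. The fit is equivariant under dose rescaling
(doses × k ⇒ RT50 × k, h unchanged). An all-censored data set is
rejected ("no information below cap").

**Therapeutic index.** TI = RT50(bleeding)/RT50(occlusion). Dose units
(mg/kg vs U/kg) are carried as tags and must match; they are never
auto-converted — the UFH activity-to-molar conversion is a separate,
opt-in step. The saphenous-vein metric is the observation window
divided by the number of haemostatic events; zero events yield a
censored "no haemostasis" result at ≥ window. Pearson correlation
(two-tailed p via the t-transform) and Student/Welch two-sample t
tests cover the cross-model consistency analyses.

## Biolayer interferometry

**Model.** The 1:1 Langmuir interpretation of the instrument's kinetic
model: dR/dt = kon·C·(Rmax − R) − koff·R, giving a mono-exponential
association R(t) = Rmax·C/(C + K_D)·(1 − e^(−(kon·C + koff)t)) and
dissociation R_end·e^(−koff·t), with K_D = koff/kon (an identity, not
a fitted quantity). Rmax is the saturating-response parameter of the
loaded sensor. Traces are zeroed to the mean of the final 30 s of the
baseline phase, mirroring reference-well subtraction. Mass-transport
limitation and bivalent-analyte models are out of scope.

**Fits.** The default global fit shares (kon, koff, Rmax) across a
dilution series in log10 space, which matches vendor practice for
multi-concentration series; a per-curve mode exists for diagnostics
(a single association phase only identifies kobs = kon·C + koff; the
dissociation phase pins koff). Designs with all concentrations ≥ 100×
away from the fitted K_D are flagged ill-conditioned. R_eq is the
fitted plateau of the association exponential, not the last sample, so
non-saturated traces extrapolate correctly; plateaus with standard
error above 50% of the value (near-linear traces) are flagged
unreliable. The steady-state isotherm R_eq = Rmax·C/(K_D + C) provides
the independent equilibrium route; the two K_D routes agree on clean
1:1 data and their comparison is a model-adequacy check.

## Unit conversions

UFH activity converts to molarity via its specific activity
(default 183.5 U/mg, a measured constant shipped as the default) and
average molecular weight (10 900 g/mol): 1 U/ml ≈ 0.50 µM. Peptide
concentrations come from Beer–Lambert with Gill–von Hippel 280-nm
coefficients (1490·Tyr + 5500·Trp + 125·cystine, cystines counted as
Cys pairs); aromatic-free peptides have ε₂₈₀ = 0 and are routed to a
linear A205 standard curve built from reference peptides of known
concentration.

## Synthetic data

The generators emulate each assay's read-out with known truth:

* progress curves — straight lines with slope v₀ × Morrison fractional
  velocity (shared code with the fitter) plus additive Gaussian
  absorbance noise; in competitive mode K_i′ is derived from
  (K_i, K_m, S);
* inhibition panels — fractional-velocity points with Gaussian noise,
  the I_t = 0 reference held at exactly 1;
* clot waveforms — monotone logistic transmittance drop (minimum slope
  −drop/4·scale at the midpoint) plus Gaussian noise;
* thrombograms — a gamma-density pulse (default shape 3) shifted by
  LT and rescaled to the requested peak, a phenomenological stand-in
  for instrument output whose exact shape is proprietary; the sidecar
  reports the analytic ETP of the truncated pulse;
* in-vivo records — latent Hill response times with multiplicative
  log-normal noise (positivity of times by construction), cap-censored
  generator-side with an explicit flag;
* sensorgrams — the closed-form 1:1 model plus Gaussian response noise.

Noise is additive Gaussian for optical signals and log-normal for
times; raw-trace noise magnitudes are not constrained by published
data, so defaults are chosen for test power rather than instrument
realism. One integer seed drives each spec; per-replicate sub-streams
are spawned deterministically, so identical specs are byte-identical.
Zero-noise output equals the consuming module's forward model exactly.

What passing tests show — and what they do not: the recovery suites
demonstrate that the estimators are unbiased and well-calibrated under
the stated noise models and designs (e.g. 4–5 dose levels at n = 5–8
per dose for the rodent design, a 7-point three-fold dilution series
for BLI). Real data add structure the generators omit: baseline drift
and burst phases in progress curves, platelet-dependent thrombogram
shapes, inter-animal covariates, sensor drift and mass-transport
effects. Conclusions about those failure modes require real traces.

## Problem sizes and determinism

Simulation-based checks use 100 random parameter draws for noiseless
Morrison round trips, 200 seeds for the noisy Morrison, competitive-K_i
and therapeutic-index recovery studies, and dense (0.05–0.1 unit) time
grids for trace analysis — sizes chosen so each study completes in
seconds to tens of seconds while estimating medians stably. All
randomness flows through integer seeds; `scripts/acceptance.py --seed N`
is bit-reproducible.

## Known limitations

* Clot time and LT follow documented operational definitions that may
  differ from proprietary analyzer rules by a constant offset.
* The Savitzky–Golay window trades derivative bias against noise; very
  sharp clot transitions need a smaller window than the default.
* The censored Hill fit assumes a common σ across doses and a fixed
  baseline; strong baseline uncertainty propagates into RT50.
* The 1:1 BLI model cannot represent heterogeneous ligand or avidity
  effects; systematic misfit of the dilution series is the intended
  symptom.
* No slow-binding (onset-kinetics) analysis: progress curves are
  assumed linear over the read window.
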