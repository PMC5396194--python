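# Methods

This note documents the statistical and biophysical models behind `kdrkit`,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Probit dose–response

The mortality model is binomial with a probit link on the log₁₀ dose
metameter: p(c) = Φ(α + β·log₁₀ c). log₁₀ is the toxicology convention and
matches the behaviour of the classical PROBIT procedures. Fitting is
maximum likelihood via iteratively reweighted least squares (statsmodels
GLM, deviance tolerance 1e-10); replicates at the same concentration are
pooled before fitting.

- **LC quantiles.** LC_p = 10^((Φ⁻¹(p) − α)/β). Confidence limits use
  Fieller's theorem on the ratio (Φ⁻¹(p) − α)/β with the fitted parameter
  covariance. When g = z²·var(β)/β² ≥ 1 the denominator is not
  significantly non-zero and the interval is reported as undefined (NaN)
  rather than an arbitrary finite band.
- **Goodness of fit.** Pearson χ² over pooled concentration groups with
  df = k − 2. When the lack-of-fit P < 0.05, the parameter covariance is
  inflated by the heterogeneity factor χ²/df and the normal quantile is
  replaced by a t quantile with k − 2 df, the standard correction for
  extra-binomial variation.
- **Resistance ratio.** RR = LC₅₀(R)/LC₅₀(S). The variance of log₁₀ RR is
  the sum of the delta-method variances of the two log₁₀ LC₅₀s;
  CI = 10^(log₁₀ RR ± 1.96·SE). The ratio is significant when the CI
  excludes 1. Simulation tests confirm ≈95% coverage for a true ratio of 1.
- **Control mortality.** Handled by a separate Abbott pre-correction,
  p' = max(0, (p − p_c)/(1 − p_c)) carried as effective counts, not by a
  natural-response parameter inside the likelihood. This keeps the fitted
  model two-parameter and matches how control jars are normally used.
- **Degenerate data.** All-0/all-1 response patterns raise a separation
  error (no finite MLE); a non-positive fitted slope raises a non-monotone
  error. Neither is silently "fixed".

## Synergist comparison

Replicate mortality proportions (one per jar or vial) are compared across
treatment groups by classical one-way fixed-effects ANOVA, implemented
directly from the between/within sum-of-squares decomposition. Pairwise
contrasts use the Scheffé bound
√((k−1)·F₍α;k−1,N−k₎) · √(MSW·(1/nᵢ + 1/nⱼ)), which controls the
family-wise error over all contrasts; with k = 2 it reduces exactly to the
F test. Proportions are analysed untransformed by default (no
arcsine/logit); this mirrors common practice in synergist bioassays and is
deliberate — the tests confirm the procedure stays conservative on null
data at the replicate counts used (4–5 per group).

## Tail-current analysis and the M statistic

Pyrethroid-modified channels fail to deactivate on repolarization and carry
a slowly decaying tail current. The percentage of modified channels is

M = {[I_tail/(E_h − E_Na)] / [I_Na/(E_t − E_Na)]} × 100,

a tail-to-peak chord-conductance ratio: I_tail is the maximal tail-current
amplitude after the final repolarization of a 100 × 5 ms / 0 mV pulse train
(5-ms gaps, holding −120 mV), I_Na the peak current during depolarization
before drug exposure (a paired pre-drug trace is carried with every
recording), E_h = −120 mV, E_t = 0 mV, and E_Na the reversal potential
interpolated from the IV curve. Driving forces are signed, so M ≥ 0 for
physically consistent inputs and the formula is invariant to uniform trace
scaling.

Extraction choices (configurable):

- baseline = mean holding current before pulse 1 (makes amplitudes
  offset-invariant);
- capacitive blanking: the first 0.3 ms after the final voltage step is
  excluded from the tail window;
- both peak and tail are taken as the extremum of a boxcar-smoothed trace
  (0.2 ms for the peak, 0.5 ms for the tail), smoothing applied *within*
  the analysis window only. The smoothing suppresses the upward bias of a
  raw max over thousands of noisy samples while costing < 1% on noiseless
  traces (tail decay time constant ≈ 50 ms ≫ window).

**Hill dose–response.** M(c) = M_max·cʰ/(cʰ + EC₅₀ʰ) with free slope and
plateau, fitted by bounded least squares over (M_max, log₁₀ EC₅₀, h) from a
grid of starts (EC₅₀ at the concentration quantiles × h ∈ {0.5, 1, 2});
standard errors from the Gauss–Newton covariance. The Hill form is the
standard model for channel-modification curves; the source data never state
an explicit equation, so this is a design choice of the package. Per-oocyte
M values enter the fit directly (no pre-averaging across oocytes).
Sensitivity fold-shifts are EC₅₀ ratios with CIs from the propagated
log₁₀ EC₅₀ standard errors.

## Sequence analysis

Translation uses the standard genetic code (Biopython's table). CDS
comparison requires equal-length, equally numbered sequences — alignment is
explicitly out of scope, unequal input is an error with guidance to
pre-align. Residue numbers map through a per-sequence offset because kdr
positions are conventionally numbered against a reference channel protein;
the bundled synthetic template uses offset 0.

Diploid genotype calls expand a codon's IUPAC codes: one expansion →
homozygote, two → heterozygote, more → ambiguous (never silently resolved).
Allele frequency = (2·hom_mutant + het) / (2·n) × 100, ambiguous
individuals excluded with a warning. Population screens count *carriers*
(any expansion translating to the mutant residue), not zygosity, because
screen rows summarize whole populations.

## Synthetic-data generators

The generators state a world and keep its truth available to tests.

- **Mortality.** Deaths ~ Binomial(n, π₀ + (1−π₀)·Φ(α + β·log₁₀ c)).
  Default design mirrors the monitored bioassays: five concentrations at
  probit-equispaced quantiles spanning 5–95% mortality, ~125–134 insects
  per concentration, control group included.
- **Traces.** Unmodified channels follow deterministic m³h gating with
  Boltzmann steady states and bell-shaped voltage-dependent time constants
  (unmodified deactivation τ ≈ 0.1 ms at −120 mV, well inside the blanking
  window; peak open probability ≈ 0.67 at 0 mV). The command voltage is
  piecewise constant, so gating relaxes analytically within each segment —
  no ODE solver, no discretization error. Modified channels open to the
  same peak open probability as the unmodified transient, accumulate over
  the cumulative depolarized time of the train (τ_build = 25 ms, so the
  buildup factor is 1 − e⁻²⁰ after 100 pulses), are treated as held open
  across the 5-ms interpulse gaps (their deactivation τ_slow = 50 ms ≫
  5 ms; the neglected per-gap decay is a documented simplification), and
  decay with τ_slow in the final window. Consequently the closed-form
  expectation is expected_M = 100·f·(1 − e^(−500/τ_build)) ≈ 100·f, and
  the extracted M matches it within 1% on noiseless traces — this is the
  oracle the extraction tests use. Noise is additive Gaussian per sample;
  no capacitive transients, leak, series resistance or oocyte batch
  effects are modelled, so a green test validates the estimator chain, not
  instrument artefact handling. `tail_noise_scale` converts "x% of the
  dose-response plateau" into current units (the convention used by the
  recovery tests: sd = 2% of plateau).
- **Dose–response experiments.** modified fraction
  f(c) = (M_max/100)·cʰ/(cʰ + EC₅₀ʰ) with defaults M_max = 70%, h = 1 —
  typical of pyrethroid modification curves, where even saturating drug
  does not modify every channel.
- **Sequences.** A deterministic synthetic 1600-codon open reading frame
  (ATG start, TAA stop, GTA at codon 410, TTC at codon 1534, no internal
  stops; not derived from any real record) is the default template. The
  default plant is six single-base synonymous changes plus V410L
  (GTA→TTA) and F1534C (TTC→TGC): eight nucleotide differences, two amino
  acid substitutions. Heterozygotes are represented Sanger-style as IUPAC
  codes in one consensus amplicon (no read pairs, no chromatograms). The
  default panel zygosity at 410 — 3 hom-mutant, 4 het, 3 hom-wild — is one
  configuration consistent with 7 carriers of 10 and a 50% allele
  frequency; the underlying study prints only the summary, not the
  per-individual calls.

All generators are deterministic given their seed; identical spec + seed
gives bit-identical output.

## Known limitations

- The probit module fits only the probit link (no logit/cloglog) and does
  not model time-to-death.
- Fieller intervals are reported as undefined when the slope is too poorly
  determined (g ≥ 1) instead of falling back to a delta approximation.
- The gating parameter set is a plausible invention: only the tail/peak
  conductance ratio is calibrated, so the traces should not be used to
  study activation/inactivation kinetics.
- The Hill fit can return M_max slightly above 100 on noisy data; the bound
  is 200 by design so that plateau uncertainty shows up in the standard
  error rather than being clipped.
- Sequence comparison assumes pre-aligned, equal-length CDSs and a diploid
  organism.
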