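# Methods

This note documents the models, the statistical machinery, the synthetic
data the package uses to exercise that machinery, and the design choices
made where the design was genuinely open. Units: all energies are in kBT
(β ≡ 1; there is no temperature parameter anywhere), concentrations in μM,
copy numbers in repressors per cell.

## Thermodynamic model

The simple-repression motif is modelled at equilibrium: a promoter is
either free or occluded by an active repressor, and the repressor itself
is a two-state (MWC) allosteric protein whose active/inactive equilibrium
is shifted by inducer binding. The package evaluates

- `pact(c) = (1 + c/KA)^n / [(1 + c/KA)^n + e^(−ΔεAI) (1 + c/KI)^n]`,
- `fold_change(c) = (1 + pact(c)·R/NNS·e^(−ΔεRA))⁻¹`,
- the Bohr parameter `F = −log pact − log(R/NNS) + ΔεRA` and its logistic
  (Fermi) master curve,
- `ΔF = F(mut) − F(wt)` with its exact three-term decomposition
  (allosteric, copy-number, DNA), and the closed-form saturating-inducer
  limit of the allosteric term.

Assumptions inherited from the model: a single specific operator per cell,
weak-promoter (no RNAP competition) limit, nonspecific background of
`NNS = 4.6×10⁶` sites (the genome length; configurable because different
strains/plasmids change it), and `n = 2` inducer sites. Multi-promoter
corrections, RNAP competition and Hill-function phenomenology are out of
scope by design.

Reference constants shipped with the package: operator binding energies
O1 = −15.3, O2 = −13.9, O3 = −9.7 kBT and the wild-type LacI allosteric
triplet KA = 139 μM, KI = 0.53 μM, ΔεAI = 4.5 kBT.

### Numerical choices

- `c = 0` is evaluated exactly — the expressions reduce algebraically, no
  epsilon offset is used. There `pact` depends on ΔεAI alone.
- All exponentials go through `log1p`/`logaddexp`/`expit` rearrangements,
  so energies up to several hundred kBT in magnitude neither overflow nor
  produce NaN (probabilities may round to 0 or 1 in float at |ΔεAI| ≳ 40).
- The ΔF decomposition reports its three terms and computes the total as
  `(allosteric + copy_number) + dna` in exactly that order, so
  "total = sum of terms" is exact in floating point, and the total matches
  the difference of Bohr parameters to ≤ 1e−12.
- "Saturating inducer" for numeric limit checks means `c = 10⁸ μM`. The
  finite-concentration remainder of the allosteric ΔF term is
  `O(n·ΔKA/c)`, so the documented 1e−6 kBT tolerance applies to
  binding-constant shifts up to tens of μM — the scale actually observed
  for inducer-binding mutants; larger shifts converge correspondingly
  more slowly.

## Synthetic data generator

The generator emulates the structure of the study's flow-cytometry
experiments, not the cytometry itself:

- a 12-point IPTG ladder: 0, then log-spaced from 10⁻² to 5×10³ μM;
- operators O1/O2/O3 at the constants above; copy numbers
  {60, 124, 260, 1220} (≈20-fold span);
- 10 biological replicates per condition, each drawn
  `Normal(model fold-change, noise_sd)` with `noise_sd = 0.05`, **not
  clipped** to [0, 1] — real measurement noise spills past the physical
  bounds and the censoring logic must see that;
- a single seed determines the dataset byte-for-byte.

`noise_sd = 0.05` is a fixture choice, not an instrument claim: it is set
so that leakiness conditions of strong operators fall inside the
detection-limit (censoring) regime, deliberately exercising that code
path. What the generator does *not* emulate: event-level FCS data and
gating, day-to-day batch effects, growth-condition covariates, or
fold-change-dependent noise. Passing tests on generated data therefore
demonstrate correctness of the estimation machinery under the stated noise
model, not robustness to those real-data complications.

`perturb_parameters` builds labelled mutants for the classifier, with
`magnitude` acting as an effect size in kBT-equivalents:
DNA class shifts ΔεRA by exactly `magnitude`; copy-number class scales R
by `e^(−magnitude)`; the KA/KI class multiplies both constants by
`exp(magnitude·U(0.5, 1.5))` (both weaken, generically changing their
ratio, as real inducer-binding mutants do); the ΔεAI-involved class drops
ΔεAI by `magnitude·U(3, 5)` with a milder K drift
(`exp(0.3·magnitude·U(0.5, 1.5))`). The ΔεAI scale mirrors the reported
conformational-equilibrium mutants (shifts of ≈7 kBT); keeping the K
drift mild keeps the mutant inducible inside the measurable window, where
the concentration dependence of ΔF — the classifier's evidence — is
actually observable.

## Bayesian inference

All likelihoods are homoscedastic Gaussian on replicate fold change —
the same model the generator uses, so parameter recovery is well posed.

**Priors** (weakly informative stand-ins, overridable):
ΔεRA ~ N(−12, 6) kBT; log10(KA/μM), log10(KI/μM) ~ N(2, 2) truncated to
[−3, 7]; ΔεAI ~ N(0, 5) kBT; σ ~ HalfNormal(0.1). These span the plausible
biophysical range by ≥ 2 SD without forcing any particular estimate. KA
and KI are sampled on log10 scale (plausible values span ~5 decades) with
no ordering constraint between them — real mutants can collapse or invert
the ratio.

**Sampler.** The profile fits use the affine-invariant ensemble sampler
(emcee) with differential-evolution moves (0.8 DE / 0.2 DE-snooker),
which mix far better than the stretch move on the correlated
(log KA, log KI, ΔεAI) posterior. Initialisation is a Nelder–Mead MAP
search from a small grid of starts followed by a tight Gaussian ball of
walkers. Defaults: 32 walkers × (1000 warmup + 2000 kept) for the
single-energy fit, 48 × (1000 + 4000) for the joint allosteric fit —
sized so rank-normalised split R-hat (walkers treated as chains, computed
with arviz) reaches ≤ 1.01 on the standard fixture of 12 concentrations ×
10 replicates. Posteriors failing diagnostics are flagged, and prediction
refuses them unless forced. A warning is emitted when ≥ 5% of posterior
mass for a dissociation constant sits within 0.2 decades of a prior
bound — the "only a one-sided limit is identified" situation.

**Per-condition moments and empirical free energy.** For each strain ×
concentration, the posterior over the mean μ and SD σ of the replicate
fold changes is sampled *exactly* under the Jeffreys reference prior
p(μ, σ²) ∝ σ⁻²: σ² is scaled-inverse-χ²(n−1), μ|σ is Gaussian about the
sample mean. This closed form is seeded, fast (the classifier calibration
runs ~2000 such posteriors) and agrees with an MCMC backend retained for
cross-checking. Each μ draw inside (0, 1) maps to a free-energy draw
`F = log(μ/(1−μ))`; out-of-support draws are dropped and counted.

**Censoring.** Free-energy inference is systematically biased where the
fold change approaches its detection limits, so a condition is flagged
(and excluded from ΔF analysis) when `median(μ) < median(σ)` or
`1 − median(μ) < median(σ)`. The rule is stated in terms of μ and σ;
using their posterior medians as the estimator is this package's choice.

## ΔF profiles and classification

ΔF(c) is formed per concentration by differencing independent bootstrap
resamples of the mutant and reference free-energy posteriors (the two
experiments are independent; any correlation would itself be an epistasis
model). The reference strain must share operator and copy number. Censored
conditions carry no value.

The classifier is a deterministic decision table on 95% credible
intervals (interval tests, not point tests — mirroring how overlapping
credible regions are read off an induction figure):

1. every interval covers 0 → `no_change`;
2. all intervals share a common value (nonempty intersection, not
   containing 0) → `dna_or_copy_number`;
3. otherwise the profile varies with c: if ΔF at the smallest uncensored
   concentration covers 0 → `ka_ki_only`, else → `epsai_involved`.

At least 4 uncensored points are required. When c = 0 itself is censored
the smallest uncensored concentration stands in for it — faithful as long
as that concentration is well below KA. Nonmonotonicity (a sign change in
successive median differences larger than `tol`, default 0.2 kBT) is
reported as evidence but does not enter the table; it can only arise from
KA/KI changes and corroborates that class. There is no canonical numeric
threshold for "constant"; the interval-intersection test and the 0.2 kBT
tolerance are this package's operationalisation.

Master-curve collapse maps each replicate-mean point to (F, fold change)
using per-strain parameters; residuals from the logistic curve are
mean-zero with SD ≈ noise_sd/√n on correctly specified data, and a
mis-specified strain stands off-curve by many times that.

## Prediction

`predict_strain` pushes posterior draws through the model at a new
operator/copy-number context and takes percentile bands: the default band
is the credible region of the model curve; `predictive="mean"` folds in
σ/√n measurement noise (the correct band to compare against observed
replicate means), `predictive="replicate"` full single-replicate noise.

`predict_double_mutant` implements the additive null: 10⁴ independent
draw pairs from the ΔεRA posterior (DNA mutant) and the joint allosteric
posterior (inducer mutant), evaluated with no free parameters. At point
parameters the additivity identity is exact by construction.
`epistasis_residual` compares an observed ΔF profile with the predicted
band: ≥ 90% band overlap → `consistent`; otherwise a residual spread
≤ 0.5 kBT → `constant_offset` (suggesting DNA-binding epistasis), else
`c_dependent_offset` (allosteric epistasis). The 90% and 0.5 kBT cutoffs
are operational choices; there is no canonical epistasis threshold.

## Problem sizes used in the shipped checks

Calibration checks run 20 seeded datasets per scenario at the standard
design (12 concentrations × 10 replicates, noise SD 0.05): the 95%
interval covers the simulated ΔεRA and allosteric-triplet truths in
≥ 17/20 runs; the classifier confusion matrix over 4 classes × 20 seeds
(wild type O3/R = 1220, magnitude 1.5) stays ≥ 90% diagonal; additive
synthetic doubles are covered by the 10⁴-draw prediction bands at ≥ 90%
of uncensored points. Published estimates for the real LacI mutants
(e.g. Y17I, Q18M, Q291K) derive from experimental flow-cytometry data not
shipped here; the suite instead validates the machinery on synthetic
stand-ins simulated at those published values.

## Known limitations

- The Gaussian, homoscedastic noise model understates heteroscedasticity
  of real cytometry-derived fold changes near 0 and 1; censoring absorbs
  the worst of it but is a blunt instrument.
- Ensemble-sampler walkers are not independent chains; treating them as
  chains makes R-hat a heuristic (a conservative one in practice here).
- The classifier cannot distinguish DNA-binding from copy-number
  mutations (they are energetically degenerate, differing only in the
  logarithmic vs linear scaling of their effect), and a ΔεAI mutant whose
  concentration dependence lies outside the measurable window is
  indistinguishable from a constant-shift mutant — a physical, not
  algorithmic, limit.
- Cross-domain additivity is the null model; intra-domain double mutants
  and explicit epistasis coefficients are out of scope.
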