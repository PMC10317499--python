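# Methods

## Model and assumptions

The package analyses equilibrium activation of a two-conformation receptor
(C resting/closed, O active/open) with two equivalent and independent agonist
sites. Binding is characterized by the equilibrium dissociation constants
KdC (to C, weak) and KdO (to O, strong); gating by the equilibrium constants
L0, L1, L2 with 0/1/2 agonists bound. Because the scheme is a thermodynamic
cycle with no external energy input, L2/L0 = (KdC/KdO)² and L1/L0 = KdC/KdO.
The open probability along the main activation pathway (x = [A]/KdC) is

    PO([A]) = x²L2 / (1 + 2x + x² + x²L2),

which neglects unliganded and mono-liganded opening (L0 ~ 1e-6, so the
correction is far below the measurement error of cluster PO). Setting
PO = POmax/2 gives the exact midpoint relation used for the inversion,
EC50 = KdC·(1+√(L2+2))/(L2+1).

Energies are referenced to a 1 M standard state: dG = RT·ln(Kd/1 M), with
RT = 0.59 kcal/mol at 23 °C (configurable). The standard state matters: the
efficiency η = 1 − dG_LA/dG_HA is a ratio of logarithms and changes if
concentrations are not molar. The API therefore carries all concentrations
internally in molar and requires units to be declared at every I/O boundary
(CSV files need a `concentration_unit` column or an explicit default;
unknown units raise).

η is invariant to RT and to the logarithm base, and equals m/(m+2) where m is
the slope of an efficiency plot, log10 L2 versus log10(1/KdC), whose
intercept is log10 L0.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| RT | 0.59 | kcal/mol | 23 °C recording temperature |
| L0 (wild type, −100 mV) | 7.4e-7 | — | unliganded gating of the adult receptor |
| L0 (+70 mV + eS450W) | 5.2e-7 | — | measured constant for the depolarization-compensated background; stored explicitly because the e-fold/60 mV rule applied to 7.4e-7 gives 4.49e-7 at −70 mV, i.e. the published constant derives from an unrounded rule |
| e-fold voltage | 60 | mV per e-fold of L0 | depolarization reduces unliganded gating |
| background folds | eS450W 1.0, eL269F 179, eE181W 5.5, dV269A 250 | — | L0 multipliers of the shipped constructs; folds multiply (no interaction) and eS450W is defined as exact compensation of the −100→+70 mV depolarization |
| dead time td | 0.025 | ms | recording resolution of the reference instrumentation; for synthetic data use td well below the fastest dwell component (the validation chain uses 0.002 ms, chosen from the generator's rate constants) |
| tcrit | 20 | ms | shut intervals longer than this are desensitized gaps between clusters |
| mixture growth rule | ΔlogL ≥ 10 | — | a new exponential component must improve the log likelihood by 10 units |
| Hill nH bounds | [0.5, 3] | — | nH is fitted for curve shape but not used downstream (site count known) |
| x-means k_max / min class size | 8 / 2 | — | classes must carry at least two members |

## Fitting choices

**Hill fit.** Unweighted least squares of
PO = POmax/(1+(EC50/[A])^nH) with POmin fixed at 0 (liganded baselines are
~1e-6). Start values: POmax from the top of the data, EC50 by log-linear
interpolation to the half-max crossing, nH = 1.5; EC50 is fitted on a log10
scale for conditioning. Inverse-variance weighting is available when
per-point sems exist (then the covariance is not rescaled by the reduced
chi-square). Non-convergence returns a flagged result, never a silent one;
a fitted EC50 outside the sampled range extended ten-fold either side is
flagged. Fitting is invariant to the declared concentration unit.

**Error propagation.** First-order delta method with analytic partial
derivatives of the closed forms, through the full chain
(EC50, POmax) → L2 → KdC → KdO → energies → η. The (EC50, POmax) estimation
covariance from the fit is included — the two are ~50% correlated and
ignoring the cross term understates the η sem by ~20% (coverage calibration
in the test suite checks the 1-sigma interval covers truth at 68 ± 10%).
For independent tabulated values the covariance is zero. Delta-method sems
are cross-checked against a parametric bootstrap (within 15%).

**Dwell mixtures.** Intra-cluster open and shut durations are fitted with
mixtures of dead-time-shifted exponentials. By memorylessness, a left-
truncated exponential is exactly a shifted one, so the MLE of each time
constant is unbiased under censoring (the naive mean overestimates τ by td).
EM with responsibilities in log space, 8 seeded restarts per component count,
convergence at ΔlogL < 1e-8; the count grows from 1 until the gain is below
10 units. Weights are reported on the truncated scale. "Predominant
component" means largest weight, ties broken by longer τ.

**Cluster PO from time constants.** PO = τo/(τs+τo). Two conventions for
choosing the τs are provided. The *predominant-component* convention matches
practice for recordings whose intra-cluster distributions are dominated by a
single component. On simulated scheme data away from saturation, however,
the shut distribution splits into a fast flicker component (~tens of µs,
returns to open) and a slower excursion component (unbinding wanderings), and
the predominant convention is then badly biased in either direction. The
*mixture-mean* convention (τ = td + Σwᵢτᵢ for each class) estimates the
stationary open fraction for any component structure and is robust to
dead-time merging (total time is conserved by the merge rule); it is the
default in `analyze_intervals`. The two agree whenever one component carries
most of the weight.

**Dead-time imposition.** An interval shorter than td is unresolvable; it
and its following interval are absorbed into the current resolved interval
(same conductance class), conserving total duration exactly and preserving
alternation. Unresolved intervals at the sequence edges cannot be merged and
are trimmed with a warning. The operation is idempotent. Exact missed-event
correction of the time constants (beyond the truncation-shifted likelihood)
is out of scope; the mixture-mean PO convention makes the pipeline's target
quantity insensitive to the residual distortion.

**Unliganded L0.** From two-state C⇌O interval lists: f0 = 1/(mean resolved
shut − td), b0 likewise from open durations, L0 = f0/b0 (unit-invariant).

## x-means classification

k-means (32 seeded restarts per k, values sorted internally so the result is
permutation-invariant) is run for k = 1..k_max; partitions with any class
below the minimum size (2) are discarded; the survivor with the lowest AICc
wins, ties broken by lower SSR then lower k. The criterion is the
shared-variance Gaussian *classification* likelihood,

    −2 logL = −2·Σ nⱼ ln(nⱼ/n) + n·ln(2π·SSR/n) + n,

with k′ = k + 1 parameters (centers + variance) and the usual small-sample
AICc correction (plain AIC when n ≤ k′+1, where the correction is undefined).
The membership term Σ nⱼ ln(nⱼ/n) is essential: without it, splitting any
Gaussian class cuts its within-class SSR by ~64% (half-normal variance
1 − 2/π), so an SSR-only criterion prefers more classes all the way to k_max
at realistic sample sizes. Reported per-class means/sds are descriptive
statistics of the final partition. Absolute AICc/SSR values are
implementation-specific and not comparable across x-means variants.

ANCOVA (slope homogeneity across classes) is the nested-model F test of
`y ~ x * class` against `y ~ x + class`; a reduced model that already fits
exactly returns F = 0, p = 1. Pearson correlation uses the exact
t-distributed two-tailed p-value.

## Synthetic data generator

`scheme_from_constants` converts equilibrium truth (KdC, KdO, L0) into rate
constants: association to C at 1e8 M⁻¹s⁻¹ per site (koff = kon·Kd),
association to O at the diffusion limit (1e9), di-liganded opening
f2 = 5e4 s⁻¹ with b2 = f2/L2 (agonist dependence on the opening direction),
desensitization A2O→A2D at 20 s⁻¹ with resensitization 2 s⁻¹ so that
inter-cluster gaps (~500 ms) are cleanly separated from intra-cluster shut
times at tcrit = 20 ms. The default five-state scheme is the main pathway
plus desensitization; `full_cycle=True` adds unliganded/mono-liganded open
states with f1/b1 = L1. Every constructed scheme passes a hard Kolmogorov
cycle-product check of detailed balance (exact in the rates; agonist factors
cancel around any cycle), and the stationary distribution of the main-pathway
sub-model reproduces the theoretical PO curve to ~1e-15.

Trajectories are sampled exactly (exponential holding times, categorical
jumps) and aggregated to alternating open/shut intervals in ms. Planted
populations draw η per class (Normal, resampled into (0,1)) and KdC
log-uniform over 1 µM–10 mM, then set ln KdO = ln KdC/(1−η), so each member
is exactly cycle-consistent.

What the generator does *not* emulate: amplitude noise and filtering
artifacts, sublevels, idealization errors, multiple channels per patch,
modal gating, and correlated per-patch variability. Passing recovery tests
therefore demonstrates the correctness and calibration of the analysis chain
on data that satisfy the model assumptions — not robustness to the
idealization step, which is upstream of this package's inputs.

Validation problem sizes: the end-to-end η recovery uses 10⁴ dwell events at
each of 6 concentrations (η error ~0.005 against a 0.02 tolerance); Monte-Carlo
calibrations use 200–500 replicates; planted-class recovery uses 25 values
(5 classes × 5) with generative sd 0.008 — at that spread the five observed
class means are cleanly identifiable, whereas the published within-class sds
(up to 0.035 for the extreme classes, which in the real data contain only
2–3 members each) do not define an identifiable 5-per-class generative
condition.

## Degenerate inputs and tie-breaks

All-equal PO values or fewer than 3 distinct concentrations: degenerate-data
error. PO outside [0,1], non-positive Kd/L/fold/τ: domain error naming the
offending value. Identical η values: k = 1 with SSR = 0 (log floored).
Zero-variance correlation inputs: error. Equal-weight mixture components:
the longer τ is "predominant". POmin = POmax is allowed in the CRC container
(the degenerate flat curve of a non-coupling ligand) but rejected by fitting.

## Known limitations

- The Hill fit of data generated by the two-site curve carries a small model
  mismatch (KdC up to a few percent at 6 concentrations); η, a ratio of
  logarithms, is insensitive to it (≲0.005).
- Tabulated per-construct constants were derived by averaging per-CRC
  estimates; re-inverting mean EC50/POmax therefore does not reproduce every
  published row exactly. Both modes (per-CRC profiles then average, or
  average then profile) are supported; on noiseless data they coincide.
- No kinetic (rate-constant) fitting of CRCs, no channel-block correction,
  no idealization of raw current traces, no exact missed-event correction.
- x-means class counts at class boundaries closer than ~3 generative sds are
  seed-dependent; the package reports the information criterion so users can
  inspect near-ties.
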