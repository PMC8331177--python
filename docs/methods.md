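# Methods

## The task and its staircase

Each block of the discounting task fixes a delayed reward (amount *A*,
delay *D*) and titrates the immediate alternative over six binary
choices. The first offer is *A*/2 and the first adjustment *A*/4 (half
of the first-trial difference between the immediate and delayed
amounts). After a "delayed" choice the next offer rises by the current
adjustment, after an "immediate" choice it falls, and the adjustment
halves each trial, rounded to the nearest currency unit. The immediate
amount that would have been offered on a seventh trial estimates the
indifference point; dividing by *A* gives the normalized subjective
value SV ∈ [0, 1].

Numerical choices that the verbal description of such staircases leaves
open, fixed here once:

* **Rounding.** Each new adjustment halves the previously *rounded*
  adjustment, with ties (x.5) rounded away from zero. This reproduces
  the canonical $2000/3-year trace 1000 → 1500 → 1250 and keeps every
  offer integral. Under this rule the six adjustments for *A* = 2000
  are 500, 250, 125, 63, 32, 16, so an all-"delayed" block ends at
  1986 and an all-"immediate" block at 14.
* **Offer capping.** For small amounts the rounding residue can push a
  degenerate (all-delayed) sequence past *A*; offers are therefore
  clamped to [0, *A*] — the task never offers more immediately than the
  delayed reward itself. For *A* ≥ 2000 the cap is never reached.
* **Resolution.** Ignoring rounding, the adjustments halve
  geometrically from *A*/4 to *A*/128, so for any deterministic
  threshold chooser the returned SV lies within *A*/64 of the true
  threshold; integer rounding adds at most 0.5 per step, giving the
  bound |SV − θ| ≤ *A*/64 + 5 units that the property tests enforce.
* **Delay units.** Delays are labelled in months (1 week = 0.25,
  10 years = 120). Where a delay enters a discounting model in days we
  use 7, 30, 90, 180, 365, 1095 and 3650 days; the AuC x-axis instead
  normalizes months by the 120-month maximum. The two conventions are
  deliberate: discount rates are conventionally per day, while the AuC
  normalization follows the task's printed month scale.
* **Block order.** The 14 blocks (2 amounts × 7 delays) per condition
  are presented in an order drawn from the run's seeded generator and
  recorded in the output for auditability. The episodic-imagination
  interval of the cued condition is metadata only; no timing is
  modelled.

## Discounting measures

**Hyperbolic fit.** SV = 1/(1 + k·D), D in days, fitted per
participant × condition × magnitude by least squares over k ∈ [0, 10]
per day. The single-parameter objective is minimized by bounded
L-BFGS-B from the fixed starts {10⁻⁴, 10⁻², 1} (plus the k = 0
endpoint), which makes the fit deterministic; the test suite checks it
against a 1000-point log-spaced grid search with one refinement pass.
R² = 1 − SSres/SStot and may be negative for nonmonotone curves. A
flat curve has SStot = 0 and is flagged degenerate (R² = 1 when the
residuals are zero, NaN otherwise).

**Area under the discounting curve (AuC).** Delays as proportions of
120 months on x, normalized SVs on y, summed trapezoids
(x₂ − x₁)(y₁ + y₂)/2. A point (0, 1) is prepended before forming
trapezoids: at zero delay the delayed amount is worth exactly itself,
and only with this anchor does a non-discounter attain the measure's
stated maximum of 1. Whether the original analyses used the anchor is
not documented; the choice is fixed here and applied uniformly, so
within-study contrasts are unaffected.

**Consistency screen.** An indifference point is counted inconsistent
when it exceeds the one at the preceding delay by more than 10% of the
delayed amount (normalized: svⱼ > svⱼ₋₁ + 0.1, strict), over the six
consecutive-delay pairs only.

## Group-level inference

The design is one between-subject factor (patient vs control, sizes 12
and 41) crossed with two two-level within-subject factors (condition,
reward magnitude). `mixed_anova` implements the classical univariate
repeated-measures decomposition: per-subject scores are projected onto
orthonormal within-subject contrasts; each within effect and its group
interaction are tested against the corresponding contrast-by-subject
error (df = N − g = 51), and the group effect against
subjects-within-groups. With unequal groups, within main effects test
the unweighted mean of group means (the Type-III convention of SPSS,
Statistica and R's `car`; development checks against `car::Anova`
agreed to machine precision). Partial η² = SS_effect/(SS_effect +
SS_error). No sphericity correction is applied — every within factor
here has two levels, where sphericity is trivial.

Fisher LSD post hocs compare two design cells with no multiplicity
correction, using pooled error terms: for cells differing only in
within levels, per-subject difference scores with variance pooled
within groups across the whole sample (df = N − g); for between-group
comparisons at fixed within levels, subject-level cell scores with
variance pooled over the two groups. The error term for mixed-design
post hocs is not uniquely standardized across packages; the pooled
forms above are stated explicitly so results are reproducible.

Demographic matching uses Student's pooled-variance t from group
summaries and Pearson's χ² on the 2 × 2 gender table without
continuity correction (the corrected statistic would not reproduce the
conventional uncorrected value reported for such tables).

**Bayes factors.** The two-sample default-prior (JZS) Bayes factor
places a Cauchy(0, r) prior, r = √2/2, on the standardized effect;
after analytic marginalization the Bayes factor is a one-dimensional
integral over g ~ InverseGamma(1/2, r²/2), evaluated by adaptive
quadrature with the null kernel factored out for numerical headroom.
The implementation agrees with an independent noncentral-t quadrature
and with pingouin to six significant figures. Note that the BF is
steeply nonlinear in t near |t| ≈ 3: two-decimal rounding of group
means/SDs can shift a summary-derived BF by tens of percent relative
to one computed from raw data.

## The synthetic cohort

Simulated choosers discount hyperbolically with per-day rate k,
modulated multiplicatively by magnitude (k_large = m·k_small) and by
the cued condition (k_EFT = e·k_Standard). Choice is logistic in the
value difference normalized by the delayed amount — normalization makes
the noise scale-invariant across the two reward magnitudes — plus a
lapse rate of uniform random choices. Low inverse temperature and
lapses generate the nonmonotone curves the consistency screen is meant
to catch. Population heterogeneity is log-normal in k, m and e
(discount rates are positive and strongly right-skewed empirically).

Shipped defaults (frozen after a one-time Monte-Carlo calibration, 60+
studies per evaluation):

| parameter | patients | controls |
|---|---|---|
| n | 12 | 41 |
| k_small median (per day) | 2.6 × 10⁻³ | 3.2 × 10⁻³ |
| ln k SD | 1.1 | 1.0 |
| magnitude multiplier m, median (ln SD) | 1.00 (0.25) | 0.33 (0.55) |
| EFT multiplier e, median (ln SD) | 0.20 (1.2) | 0.13 (1.0) |
| inverse temperature β | 6 | 8 |
| lapse | 0.06 | 0.03 |

Under these defaults the simulated group means reproduce the target
pattern: control EFT effect (AuC_EFT − AuC_Standard) ≈ 0.26, control
magnitude effect ≈ 0.14, patient magnitude effect ≈ 0.01, patient EFT
effect ≈ 0.18–0.20; the group × condition interaction is
non-significant in roughly three quarters of simulated studies while
the condition effect and the group × magnitude interaction are almost
always detected.

What the generator does *not* emulate: per-participant effect SDs come
out somewhat narrower (≈ 0.10–0.16) than the study's printed 0.17/0.21
because β and lapse are shared within group; there is no session
structure, practice, fatigue or carryover; condition order is not
modelled (the real baseline was always run first); and the choice-noise
form is a modelling stand-in, not an inference about participants.
Passing calibration tests therefore demonstrates that the analysis
stack recovers the effects a hyperbolic-agent population plants — not
that real participants behave like these agents.

## Problem sizes in the test and acceptance runs

The property suite uses a 200-point threshold grid for staircase
convergence, 100 seeded curves for the fit-vs-grid-search check, 1000
random curves for the consistency brute force, a 600-point grid for
the AuC closed-form limit, and 200 simulated studies (53 participants,
8904 choices each, vectorized over blocks) for the calibration check;
the whole suite completes in well under a minute on one core.

## Known limitations

* The ANOVA supports one between factor; multi-factor between designs
  are out of scope.
* Only the hyperbolic discount function is fitted; the curve container
  is the extension point for exponential or Green–Myerson forms.
* `fisher_lsd` error-term conventions, while classical, are one of
  several defensible choices for mixed designs (documented above).
* Trial-level likelihood-based estimation of k from choices is
  deliberately not provided; indifference points are the interface
  between the task and the analytics.
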