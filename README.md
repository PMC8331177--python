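# ddcurve

Analysis pipeline for **delay discounting** (DD) studies that use the
adjusting-amount titration task — in particular lesion-study designs
comparing a small patient group against matched controls across a
cueing manipulation (standard vs episodic-future-thinking cues) and
two reward magnitudes.

Delay discounting is the decline in a reward's subjective value with
the delay to its receipt. The task estimates, for each delayed reward
(amount *A*, delay *D*), the *indifference point*: the immediate
amount subjectively equal to the delayed one, obtained from six
titrated binary choices whose adjustments halve geometrically. From
the resulting seven-delay curves the package computes

* the **hyperbolic discount rate** k from SV = 1/(1 + k·D) by
  nonlinear least squares (D in days),
* the model-free **area under the empirical discounting curve**
  (AuC ∈ [0, 1]; trapezoid rule on delay/120-month vs normalized SV,
  anchored at (0, 1); 0 = maximal discounting, 1 = none),
* the count of **inconsistent preferences**
  (svⱼ > svⱼ₋₁ + 0.1, a standard screen for nonsystematic data),

and, at the group level, a mixed within-between ANOVA (group ×
condition × magnitude) with partial η² and Fisher LSD post hocs,
pooled-variance t and Pearson χ² matching tests from summary
statistics, and default-prior (JZS) Bayes factors for two-sample
comparisons. A calibrated synthetic-cohort generator (hyperbolic
agents with logistic choice noise) emulates the full 12-patient /
41-control design so every stage runs and is testable without any
external data.

## Worked example

Simulate a study under the shipped calibrated defaults, replay its
staircases, and run the group analysis:

```sh
ddcurve simulate --seed 1 --out choices.csv     # 8904 choice rows
ddcurve replay   --choices choices.csv --out svs.csv
ddcurve analyze  --svs svs.csv --out auc.csv
ddcurve stats    --auc auc.csv --out results.json
```

or in Python:

```python
import dataclasses
from ddcurve import calibrate_defaults, simulate_auc_panel, reproduce

panel = simulate_auc_panel(dataclasses.replace(calibrate_defaults(), seed=1))
bundle = reproduce(panel)
print(bundle.auc_anova.round(3).to_string(index=False))
```

```
                       effect  df_effect  df_error  ss_effect  ss_error      F     p  partial_eta_sq
                        group          1        51      0.504     2.537 10.142 0.002           0.166
                    condition          1        51      2.839     1.506 96.155 0.000           0.653
            group * condition          1        51      0.077     1.506  2.614 0.112           0.049
                    magnitude          1        51      0.173     0.703 12.540 0.001           0.197
            group * magnitude          1        51      0.226     0.703 16.378 0.000           0.243
        condition * magnitude          1        51      0.067     0.441  7.695 0.008           0.131
group * condition * magnitude          1        51      0.004     0.441  0.479 0.492           0.009
```

This synthetic cohort shows the pattern the generator is calibrated
for: a strong condition (cueing) effect — both groups discount less
under future-event cues — a group × magnitude interaction — controls,
but not patients, discount large rewards less steeply — and no
group × condition interaction. The post hocs make the interaction
concrete (`bundle.post_hoc`): controls large vs small t(51) = 7.97,
p < 0.0001; patients large vs small t(51) = −0.29, p = 0.77.

Bayes factors from published-style group summaries need no raw data:

```sh
$ ddcurve bf --n1 12 --m1 0.17 --sd1 0.21 --n2 41 --m2 0.26 --sd2 0.17
t(51) = -1.529, p = 0.1325, BF10 = 0.788 (Cauchy scale 0.707)
```

BF10 < 1 favors the null (no group difference in the cueing effect);
here the evidence is anecdotal.

A deposited per-participant AuC table can be analyzed directly —
`ddcurve reproduce --auc source.csv --column-map '{auc: AUC_value}'
--out results.json` — and `--exclude-ids` re-runs the analysis without
named participants for sensitivity checks.

## Layout

| module | contents |
|---|---|
| `ddcurve.staircase` | titration state machine, replay validation |
| `ddcurve.curves` | hyperbolic fit, AuC, consistency screen |
| `ddcurve.inference` | mixed ANOVA, Fisher LSD, t/χ², JZS Bayes factors |
| `ddcurve.synthetic` | agent model, study simulator, calibrated defaults |
| `ddcurve.io` / `ddcurve.cli` | CSV schemas, results bundle, `ddcurve` CLI |

See `docs/methods.md` for the model, the numerical conventions
(rounding, delay units, the AuC anchor, ANOVA error terms) and the
generator's calibration and limitations.
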