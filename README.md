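# ovatriage

Pre-operative triage of pelvic (adnexal) masses, and the machinery to
evaluate how well a triage strategy does it.

When an ovarian or pelvic mass is found on ultrasound, the key question is
whether it is benign — manageable by a general gynaecologist — or malignant,
requiring referral to a gynaecological oncologist. A cyst cannot be biopsied
without risking rupture and up-staging, so the call must be made from imaging
and serum markers. `ovatriage` implements the three scoring systems most used
in practice, the combined strategies built from them, and the paired
diagnostic-accuracy statistics needed to compare them, plus a synthetic
cohort generator with exactly known operating characteristics so the whole
pipeline can be exercised and validated without patient data.

## The scores and strategies

**IOTA simple rules.** Five benign ultrasound features (B-features:
unilocular cyst; solid components all < 7 mm; acoustic shadows; smooth
multilocular tumour < 100 mm; no blood flow, colour score 1) and five
malignant features (M-features: irregular solid tumour; ascites; ≥ 4
papillary structures; irregular multilocular solid tumour ≥ 100 mm; very
strong flow, colour score 4). ≥ 1 M-feature and no B-feature → malignant;
≥ 1 B-feature and no M-feature → benign; otherwise (both kinds, or none)
→ **inconclusive**, which happens in roughly a quarter of women.

**ROMA** (Risk of Malignancy Algorithm), on serum HE4 (pmol/L) and CA125
(U/mL):

    premenopausal:  PI = −12.0 + 2.38·ln(HE4) + 0.0626·ln(CA125)
    postmenopausal: PI = −8.09 + 1.04·ln(HE4) + 0.732·ln(CA125)
    ROMA = 100·e^PI / (1 + e^PI)      high risk at ≥ 7.4 (pre) / ≥ 25.3 (post)

**RMI** (Risk of Malignancy Index, variant I): `RMI = U × M × CA125` with
ultrasound score U ∈ {0, 1, 3} (zero / one / two-plus of: multilocular cyst,
solid areas, metastases, ascites, bilaterality), menopausal score M ∈ {1, 3};
high risk at RMI ≥ 200.

**Strategies.** `IOTA_EXPERT`, `IOTA_ROMA` and `IOTA_RMI` apply the simple
rules first and send only inconclusive masses to the fallback (a recorded
subjective expert-ultrasound call, ROMA, or RMI); `ROMA_ALONE` and
`RMI_ALONE` ignore IOTA. Histology (borderline tumours counted as malignant)
is the reference standard.

**Evaluation.** Sensitivity / specificity / accuracy with exact
Clopper–Pearson 95% CIs (Wilson selectable); paired strategy comparisons via
the exact McNemar test on discordant pairs; subgroup tables by menopausal
status, hospital type, FIGO stage and histology class; and a
restricted-MLE score test with Monte-Carlo power for non-inferiority of two
correlated accuracy rates.

## Worked example

```python
from ovatriage import TwoByTwo, sens_spec_accuracy
from ovatriage.report import format_estimate

# inconclusive-IOTA stratum, expert ultrasound vs histology: tp fp fn tn
est = sens_spec_accuracy(TwoByTwo(64, 26, 15, 66))
for name, e in est.items():
    print(name, format_estimate(e.point, e.ci_low, e.ci_high))
```

prints

```
sensitivity 81.0% (70.6–89.0%)
specificity 71.7% (61.4–80.6%)
accuracy 76.0% (68.9–82.2%)
```

— of 79 malignant masses in this stratum the expert called 64 high risk
(81.0%), of 92 benign masses 66 were called low risk (71.7%), and 130 of
171 women were classified correctly (76.0%), each with its exact binomial
interval. The `examples/` scripts walk through the other capabilities:
simulating and analysing a full cohort (`simulate_and_analyze.py`), paired
McNemar comparisons (`compare_strategies_mcnemar.py`), and non-inferiority
power (`power_calculation.py`). The same operations are scriptable from the
shell:

```
ovatriage simulate --n 690 --seed 7 --out cohort.csv
ovatriage analyze --cohort cohort.csv --out-dir report/
ovatriage power --n 160 --accuracy-reference 0.8 --true-difference 0.05 --correlation 0.4
```

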