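# doee — detection and outline error estimates for paired segmentations

`doee` measures how well two raters (or a rater and an automated method)
agree when drawing lesion ROIs on medical image slices — the setting is
multiple-sclerosis lesion marking on FLAIR MRI, but any paired set of 2D
binary masks or closed contours works.

The usual agreement score, the similarity index (Dice coefficient)

SI = 2 |R1 ∩ R2| / (|R1| + |R2|),

conflates two very different disagreements and rewards high lesion burden:
scans with lots of lesion area are "easy". `doee` decomposes the
disagreement instead. Each connected region of the union of the two masks
is classified by who drew it — CR1 (rater 1 only), CR2 (rater 2 only),
CR12 (both) — and

- **Detection error** DE = Σ area of CR1 and CR2 regions (did they mark the
  same things?),
- **Outline error** OE = Σ (union − intersection) over CR12 regions (did
  they draw the same boundary?).

With MTA = (|R1| + |R2|)/2 the mean total area (lesion burden) and
OER = OE/MTA the outline error rate, SI decomposes exactly:

SI = 1 − OER/2 − DE/(2·MTA).

DE and OER are roughly burden-free rater properties, so their study means
predict SI as a function of burden: SI_est(MTA) = 1 − meanOER/2 −
meanDE/(2·MTA). The package fits this two-parameter model against mean,
linear and quadratic fits of SI on MTA, ranks them by finite-sample AICc,
and builds two diagnostics: the **cumulative detection error** curve
(single-rater regions above an area threshold) and the **outline error
distribution** (histogram of (|R2|−|R1|)/|R1∪R2| over matched regions).

## Worked example

Generate a synthetic 17-scan paired study (burdens log-uniform over
850–18000 mm², outline jitter calibrated to OER ≈ 0.4), score every scan
and fit the burden models:

```python
from doee import (SyntheticConfig, calibrate_jitter, generate_study,
                  score_pair, fit_study)

cfg = calibrate_jitter(SyntheticConfig(seed=7))
pairs, truth = generate_study(cfg)
fit = fit_study([score_pair(p) for p in pairs])
print(fit.summary())
```

```
Similarity vs lesion burden — study fit
=======================================================
scans: 17
meanDE:       303.9 mm^2
meanOER:     0.4143
best model by AICc: quadratic

           k      RSS   AICc  rel_likelihood
model
mean       1   0.0399 -100.7       2.315e-05
linear     2   0.0111 -119.8          0.3338
quadratic  3 0.008186   -122               1
doee       2   0.0214 -108.7        0.001265

Spearman rank correlations:
  MTA_vs_DE          rho =   0.061   p = 0.815
  MTA_vs_OE          rho =   0.961   p = 9.25e-10
  MTA_vs_OER         rho =  -0.299   p = 0.244
  MTA_vs_SI          rho =   0.865   p = 7.32e-06
Pearson correlations:
  SI_vs_SIestimate   r   =   0.807   p = 9.14e-05
  residual_vs_MTA    r   =  -0.131   p = 0.617
```

Reading it: detection error is flat across burden (rho = .06, n.s.) while
outline error tracks burden almost perfectly (rho = .96), so raw SI is
strongly burden-dependent (rho = .87) even though the raters' behaviour
never changed — exactly the confound the DE/OER decomposition removes. The
two study means predict each scan's SI well (r = .81). On mask-level
studies with heteroscedastic SI noise the AICc winner varies between the
burden law and the quadratic (as here); on tables simulated directly from
the burden law with homoscedastic noise the two-parameter model is
selected in >90% of replicates (see `tests/test_acceptance.py`).

The same pipeline runs from the shell on NIfTI masks or contour JSON:

```
doee synth --seed 7 --n-scans 17 --out study/
doee score --manifest study/manifest.tsv --out results/
doee graphs --regions results/regions.tsv --normalize-per-scan --out results/
```

`score` writes `per_scan.tsv` (MTA, DE, OE, OER, SI, JI, region counts per
scan), `regions.tsv`, `study.json` (model table, correlations) and both
diagnostic graphs.

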