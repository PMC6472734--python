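# fcharm

Decomposition of multisite resting-state functional-connectivity site
differences into **measurement bias** and **sampling bias**, and
harmonization across imaging sites using a traveling-subject dataset.

## The problem

Large psychiatric neuroimaging samples are collected at many sites. Site
differences then contaminate every downstream analysis, and they are not one
thing: scanners and protocols shift values (engineering *measurement bias*),
and each site recruits a different slice of the population (biological
*sampling bias*). The two are confounded in an ordinary multisite sample.
A traveling-subject design — the same healthy participants scanned at every
site — isolates measurement bias and makes the decomposition identifiable.

`fcharm` is for methodologists and consortium analysts who need to (a)
quantify how large each bias is relative to disorder effects and individual
differences, (b) understand what drives them, and (c) remove only the
measurement bias, leaving biology in the data.

## The model

For each connectivity edge (Fisher-z Pearson correlation between two atlas
regions), over the pooled multisite and traveling rows:

```
Connectivity = x_m' m + x_shc' s_hc + x_smdd' s_mdd + x_sscz' s_scz
             + x_d' d + x_p' p + const + e,        e ~ N(0, gamma^-1)
```

with 1-of-K indicators: `m` per-site measurement bias, `s_*` per-site
sampling bias for healthy controls and each patient class sampled at
several sites, `d` disorder factors (HC baseline), `p` traveling-participant
factors. Each constrained block sums to zero across its levels. Estimation
is equality-constrained ridge (`||y - Xw||^2 + lambda ||w_pen||^2` s.t.
`Cw = 0`) solved exactly by null-space elimination, one shared factorization
for all edges; the ridge weight can be selected by minimizing the spurious
correlation between bias families. Four harmonizers are provided
(traveling-subject, GLM, adjusted GLM, empirical-Bayes ComBat), along with
the two sampling-bias population models (`E[V_k] = xi^2/N_k` vs
`xi^2/N_k + sigma^2`, compared by AICc/BIC and leave-one-site-out
prediction), factor summaries, a PCA view, and a 2-fold cross-validated
benchmark. A synthetic generator reproduces the full study design
(six multisite sites, 513 patient rows, nine travelers, 411 sessions over
twelve sites) with known ground truth. See `docs/methods.md` for details.

## Worked example

```python
import numpy as np
import fcharm as f

ms, tr, truth = f.generate_study(f.paper_scale_config(n_edges=2000), seed=1)
combined = f.concat_datasets(ms, tr)

model = f.SiteBiasModel(lam=1.0).fit(combined)
dec = model.decomposition_
for name in ("participant", "measurement", "disorder", "sampling_hc"):
    print(f"{name:12s} {f.factor_sd(dec, name):.4f}")

pts = f.compute_site_variance_points(dec, combined, "HC")
for m in ("single", "different"):
    fit = f.fit_population_model(pts, m)
    print(f"{m:10s} AICc {fit.aicc_:8.2f}  BIC {fit.bic_:8.2f}")

rep = f.run_cv_evaluation(*f.generate_study(
    f.paper_scale_config(n_edges=500), seed=1)[:2], seed=1)
print(f.reduction_and_snr(rep).round(1).to_string(index=False))
```

prints

```
participant  0.0652
measurement  0.0396
disorder     0.0339
sampling_hc  0.0279
single     AICc   -98.00  BIC   -99.21
different  AICc  -120.94  BIC  -125.36
   method  bias_reduction_pct  snr_participant_improvement_pct  snr_disorder_improvement_pct
      raw                 0.0                              0.0                           0.0
traveling                73.4                             73.4                          73.3
      glm                 5.1                              5.1                          14.9
   adjglm                 5.0                              5.0                          24.9
   combat                 4.1                              4.1                          21.3
```

Reading it: the fitted factor SDs reproduce the generating magnitudes —
individual differences (0.065) exceed measurement bias (0.040), which
exceeds disorder effects (0.034) and sampling bias (0.028), the ordering
that makes site harmonization a prerequisite for multisite psychiatry. The
information criteria strongly prefer the different-subpopulation variance
law (each site samples its own subpopulation; collecting from more sites
beats collecting more subjects at few sites). In the cross-validated
benchmark only the traveling-subject method removes most of the measurement
bias; GLM-family methods barely touch it here because the refitted bias is
pinned by traveling sessions they cannot correct, and what they do remove
includes biology.

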