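# pollenflow

Evaluation of field sampling schemes for predicting adventitious GM
(cross-pollination) content in smallholder maize fields.

When GM and non-GM maize flower side by side, donor pollen sires a
fraction of the recipient's kernels. Monitoring programs need to
estimate the field-average cross-pollination (CP) rate against labeling
thresholds without harvesting every plot. This package is for
biostatisticians and coexistence researchers who want to ask: *which
sampling layout, at what sample size, predicts the whole field well
enough?* — in the small, border-strip-separated fields typical of Asian
smallholder agriculture.

It provides:

* a synthetic full-plots survey generator (grid of sampling plots,
  purple-kernel binomial/beta-binomial observation noise) emulating
  three survey designs, including unplanted field-border strips;
* the field-border pollen dispersal model
  `CP = P0 · 10^(a·FB + b·D)`, where `D` (m) is the distance from the
  pollen-source edge, `FB` (m) the border width, `b < 0` the log10
  distance decay and `a > 0` the border (open-ground) effect — with
  log-scale OLS, count-scale Poisson-GLM and raw-scale NLS fitters, and
  the actual-CP statistic `ActualCP = Σ Earᵢ / (n · AVK)`;
* nine sampling layouts — two/four/six transects, cross transect,
  V transect, the JM stratified method (low/high expected flow),
  systematic (SYS) and simple random sampling (SRS);
* a bootstrap pipeline that resamples the survey B times, applies each
  scheme, fits, predicts every plot and scores against the raw survey
  (RMSE, Pearson r, relative error, percentile-bootstrap CIs, CI
  coverage of the field mean, box-plot spread of the predicted mean).

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from dataclasses import replace
import pollenflow as pf

cfg = pf.with_two_strips(pf.preset("2009-1", seed=3), fb_m=6.75)
cfg = replace(cfg, geometry=replace(cfg.geometry, plants_per_plot=5, avk=400))
field = pf.generate_field(cfg)

fit = pf.fit_dispersal(field, method="glm")
print(fit.a, fit.b, fit.p0)
```

prints (one binomial-noise realization, generated with
`a = 0.6261, b = -0.6784, p0 = 0.3`):

```
0.6318  -0.6818  0.2967
```

i.e. the count-scale fit recovers the border coefficient, the distance
decay and the edge-row CP rate to within sampling noise, from a field
where over 90% of plots are below the one-kernel detection limit. The
bootstrap comparison (`examples/compare_schemes_bootstrap.py`, B = 100)
then prints per-scheme summaries like:

```
    scheme    n  rmse_mean  rmse_sd  rel_err_mean  iqr
full_plots 1640    0.00132  0.00003       0.17622  0.00004
     T_two   14    0.00159  0.00037       0.18942  0.00020
     T_six   42    0.00140  0.00013       0.18770  0.00010
       SRS  322    0.00143  0.00018       0.18322  0.00011
```

Read: the full survey is the accuracy ceiling; six transects (42 plots)
come close to SRS (322 plots) at an eighth of the sample size, and the
sparse two-transect layout pays with a doubled RMSE spread and a wider
predicted-CP IQR. The other examples generate fields, fit the model and
print each scheme's plot positions:

```sh
python examples/generate_field.py
python examples/fit_dispersal_model.py
python examples/place_sampling_schemes.py
python examples/compare_schemes_bootstrap.py
```

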