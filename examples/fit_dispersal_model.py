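"""Fit the field-border dispersal model CP = p0 * 10**(a*FB + b*D).

Generates a bordered field (half the columns behind a 6.75 m unplanted
strip), fits the model with the count-scale Poisson likelihood and with
ordinary least squares on log10 CP, and compares the recovered
coefficients with the generating values. a > 0 means an unplanted border
transmits pollen better than planted ground at the same total distance;
b < 0 is the per-metre log10 decay of CP with distance.
"""

from dataclasses import replace

import pollenflow as pf

cfg = pf.with_two_strips(pf.preset("2009-1", seed=3), fb_m=6.75)
cfg = replace(cfg, geometry=replace(cfg.geometry, plants_per_plot=5, avk=400))
field = pf.generate_field(cfg)

print(f"generating coefficients: a = {cfg.a} /m, b = {cfg.b} /m, p0 = {cfg.p0}")
for method in ("glm", "log_ols"):
    fit = pf.fit_dispersal(field, method=method)
    print(f"{method:>8}: a = {fit.a:+.4f}  b = {fit.b:+.4f}  p0 = {fit.p0:.4f}  "
          f"(plots used: {fit.n_plots_used}, below detection: {fit.n_zero_cp})")

fit = pf.fit_dispersal(field, method="glm")
print("\npredicted CP at FB=0:", [round(pf.predict_cp(fit, 0.0, d), 5) for d in (0, 2.5, 5, 10)])
print("The count-scale fit (glm) is unbiased under the one-kernel detection "
      "limit; log_ols drops censored plots and sits slightly closer to zero.")
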