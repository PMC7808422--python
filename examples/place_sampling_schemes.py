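"""Place the nine sampling-scheme layouts on the 1640-plot field.

Each scheme is a parameterized rule on the grid: transect layouts sample
fixed distances from the source edge, the JM layouts stratify by
distance from every field edge, SYS is a lattice with random start, and
SRS draws plots uniformly. Prints each scheme's sample size n — the
cost side of the accuracy-versus-cost trade-off the bootstrap
comparison quantifies.
"""

import pollenflow as pf

geo = pf.preset("2009-1").geometry
print(f"grid: {geo.n_rows} x {geo.n_cols} plots\n")
print(f"{'scheme':>8}  {'n':>4}  first plots (row, col)")
for name, params in pf.default_scheme_specs("2009-1"):
    layout = pf.build_scheme(name, geo, dict(params), seed=42)
    head = ", ".join(map(str, layout.positions[:4]))
    print(f"{name:>8}  {layout.n:>4}  {head}, ...")

jm_l = pf.layout_jm(geo, "low")
jm_h = pf.layout_jm(geo, "high")
print(f"\nJM low-flow plots are a subset of high-flow plots: "
      f"{set(jm_l.positions) <= set(jm_h.positions)}")
print("Fixed-layout schemes (all but SYS/SRS) place identical plots on every "
      "call — field crews can stake them out once.")
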