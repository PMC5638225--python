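"""Partition projection variance among its sources, cell by cell.

Runs a reduced factorial experiment and decomposes the per-cell richness
change C - F over the 2 x 3 x 2 x 5 design (data type x ensemble family x
emission pathway x forecast) into variance components: each factor's share
of the total sum of squares from a hierarchical ANOVA without replication.
"""

import warnings

import numpy as np

import nichevar as nv
from nichevar import io as nvio

cfg = nv.ExperimentConfig(n_rows=20, n_cols=20, n_species=4, n_repeats=3)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = nv.run_experiment(cfg, seed=5)

comp = res.components
print(f"design: {res.design.n_rows} projections per cell "
      f"({' x '.join(map(str, map(len, res.design.factors.values())))})")
print(f"cells partitioned: {len(comp.total_ss)}, degenerate (zero variance): "
      f"{int(comp.flagged.sum())}")

print("\nmedian variance component (share of total SS) per factor:")
for name, value in res.median_components().items():
    label = "method (ensemble family)" if name == "family" else name
    print(f"  {label:26s} {value:.3f}")
print("the largest share identifies the dominant source of projection uncertainty")

maps = nv.uncertainty_maps(comp, cfg.grid)
for name in list(res.design.factors) + ["residual", "total_ss"]:
    nvio.write_ascii_grid(f"scratch_unc_{name}.asc", maps[name], cfg.grid)
print(f"\nwrote {len(res.design.factors) + 2} uncertainty maps (scratch_unc_*.asc); "
      "flagged cells are NODATA")

if res.shift_regression is not None:
    reg = res.shift_regression
    print(f"\nprojection disagreement vs range size: slope {reg['slope']:+.2e}, "
          f"F = {reg['F']:.2f} on (1, {reg['df_resid']}) df")
    print("  a negative slope means small-ranged species get more divergent projections")
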