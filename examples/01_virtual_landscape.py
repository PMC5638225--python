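"""Generate a virtual landscape: climate, species, range map, point records.

Builds the synthetic inputs the pipeline consumes and prints their summary
statistics; writes the first climate layer as an ESRI ASCII grid.
"""

import numpy as np

import nichevar as nv
from nichevar import io as nvio

grid = nv.GridSpec(50, 50, cell_size=25.0)
climate = nv.gen_climate(grid, n_vars=5, gradient_strength=1.0, autocorr_range=150.0, seed=1)
print(f"climate stack: {climate.n_variables} variables on a {grid.n_rows}x{grid.n_cols} "
      f"grid of {grid.cell_size:.0f} km cells")
for v in climate.variables:
    layer = climate.layer(v)
    print(f"  {v}: mean={layer.mean():+.2f} sd={layer.std():.2f}")

species = nv.gen_species(climate, n_species=3, seed=2)
for sp in species:
    # prevalence is the fraction of landscape cells the species truly occupies
    print(f"{sp.species_id}: target prevalence {sp.prevalence_target:.3f}, "
          f"occupied cells {sp.n_occupied} (of {grid.n_cells})")

sp = species[0]
rmap = nv.gen_range_map(sp, grid, dilation_cells=2, smoothing=0.7, seed=3)
print(f"range map for {sp.species_id}: support {int(rmap.support().sum())} cells "
      f"(true occupancy {sp.n_occupied}) -> expert maps over-cover the true range")

occ = nv.gen_point_records(sp, grid, n_records=60, seed=4)
cells = grid.cell_of(occ.points[:, 0], occ.points[:, 1])
print(f"point records: {len(occ)} records in {len(np.unique(cells))} distinct cells, "
      f"all inside truly occupied cells")

nvio.write_ascii_grid("scratch_v1.asc", climate.layer("v1"), grid)
print("wrote scratch_v1.asc (ESRI ASCII grid of variable v1)")
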