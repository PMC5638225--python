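"""Fit all nine distribution models on one virtual species and score them.

Shows the shared-protocol contract: one pseudo-absence sample and one set of
75/25 train/test partitions feed every method; each model is thresholded at
its ROC-optimal cutpoint and scored with TSS on the held-out quarter.
"""

import numpy as np

import nichevar as nv
from nichevar.methods import METHOD_FAMILIES

grid = nv.GridSpec(30, 30, 25.0)
climate = nv.gen_climate(grid, 5, seed=10)
sp = nv.gen_species(climate, 1, seed=11)[0]
rmap = nv.gen_range_map(sp, grid, 1, 0.6, seed=12)
pa = nv.pa_from_range_maps([rmap], grid)

presences = np.nonzero(pa.column(sp.species_id))[0]
pseudo = nv.sample_pseudo_absences(pa, sp.species_id, "match", seed=13)
splits = nv.make_splits(presences, pseudo, train_fraction=0.75, n_repeats=10, seed=14)
print(f"{len(presences)} presences, {len(pseudo)} pseudo-absences, {len(splits)} partitions")

table = climate.table()
print(f"{'method':8s} {'family':16s} {'TSS mean':>8s} {'sd':>6s}")
for method in METHOD_FAMILIES:
    tss_values = []
    for split in splits:
        spec = nv.ModelSpec(method, {"random_state": 0} if method in ("rndfor", "nnet") else {})
        model = nv.fit(spec, split, climate, sp.species_id, "range_map")
        cols = [climate.variables.index(v) for v in model.kept_variables]
        scores = np.asarray(model.algorithm.predict(table[split.test_cells][:, cols]))
        tss_values.append(nv.roc_threshold(scores, split.test_labels).tss)
    print(f"{method:8s} {METHOD_FAMILIES[method]:16s} {np.mean(tss_values):8.3f} "
          f"{np.std(tss_values):6.3f}")
print("TSS = sensitivity + specificity - 1: 1 is perfect, <= 0 is no better than random.")
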