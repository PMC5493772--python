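"""Simulate a pooled deletion-collection screen with planted ground truth.

Generates a 200-strain pool with 10% dropouts, two conditions with planted
fitness defects, renders it as barcode-array feature intensities, and shows
that the noiseless rendering is exact.
"""

import numpy as np

import ykofit as yk

truth = yk.generate_truth(
    200,
    collections=("YKO",),
    dropout_fracs={"YKO": 0.10},
    effect_spec={"condA": (10, [2.0]), "condB": (8, [1.0])},
    seed=42,
)
present = truth.present_by_collection["YKO"]
print(f"strains: {len(truth.strains)}, present in pool: {len(present)}, "
      f"dropouts: {len(truth.strains) - len(present)}")
print(f"planted defects: {len(truth.fitness_coeff)} strain-condition pairs, "
      f"growth for {truth.generations} doublings")

design = yk.make_screen_design(conditions=("condA", "condB"))
print(f"design: {len(design)} arrays "
      f"({(design.role == 'control').sum()} control, "
      f"{(design.role == 'treatment').sum()} treatment)")

sim = yk.generate_array_screen(truth, yk.ArraySimParams(noise_sd=0.3), design, seed=43)
print(f"feature table: {len(sim.features)} rows "
      f"(tags x arrays, 5 replicate features each)")

# at noise 0 the rendered intensities equal the model means exactly
exact = yk.generate_array_screen(truth, yk.ArraySimParams(noise_sd=0.0), design, seed=43)
ctrl = design.loc[design.role == "control", "array_id"].iloc[0]
trt = design.loc[design.condition == "condA", "array_id"].iloc[0]
strain = next(s for (s, c) in truth.fitness_coeff if c == "condA")
drop = (exact.matrix.values.loc[f"{strain}_up", ctrl]
        - exact.matrix.values.loc[f"{strain}_up", trt])
print(f"{strain} (planted FD {truth.planted_fd(strain, 'condA'):.1f} in condA): "
      f"noiseless control-minus-treatment log2 drop = {drop:.3f}")
assert np.isclose(drop, truth.planted_fd(strain, "condA"))
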