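"""Call strain presence from control arrays and compare collection rosters.

Two collections built from the same genome carry different dropout sets. A
two-component Gaussian mixture fit to each control array separates present
from absent tags; a strain is present only if every tag passes on every
control replicate. The rosters are then intersected Venn-style.
"""

import ykofit as yk

truth = yk.generate_truth(
    300,
    collections=("YKO", "PB"),
    dropout_fracs={"YKO": 0.12, "PB": 0.05},
    seed=7,
)
library = yk.make_random_library(truth.strains, seed=8)
design = yk.make_screen_design(collections=("YKO", "PB"))
sim = yk.generate_array_screen(truth, yk.ArraySimParams(noise_sd=0.3), design, seed=9)
matrix = yk.summarize_to_tags(sim.features, sim.matrix.manifest)

calls = {}
for coll in ("YKO", "PB"):
    call = yk.call_presence(matrix, library, coll, "SC")
    calls[coll] = call
    true_present = truth.present_by_collection[coll]
    acc = sum(call.present[s] == (s in true_present) for s in truth.strains) / 300
    print(f"{coll}: called {int(call.present.sum())} of 300 present "
          f"(truth {len(true_present)}), call accuracy {acc:.3f}")

venn = yk.compare_rosters(calls)
print(f"roster universe (present somewhere): {len(venn.universe)}")
print(f"  present in both:     {venn.count('YKO', 'PB')}")
print(f"  only in YKO:         {venn.count('YKO')}")
print(f"  only in PB:          {venn.count('PB')}")

report = yk.missing_strain_report(venn, calls, sorted(venn.universe))
print(report.to_string(index=False))
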