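"""Quantify the pool by barcode sequencing and score count-based fitness.

Reads are trimmed, barcodes located by their primer context and matched
against the library (up to 2 mismatches, unique best hit). Tags are filtered
on control coverage, uptag+downtag counts summed per strain, depth-corrected
by median-of-ratios size factors and turned into log2 FD scores.
"""

import tempfile
from pathlib import Path

import ykofit as yk

truth = yk.generate_truth(150, effect_spec={"drugX": (10, [2.0])}, seed=21)
library = yk.make_random_library(truth.strains, seed=22)
design = yk.make_screen_design(conditions=("drugX",))

with tempfile.TemporaryDirectory() as tmp:
    paths, expected = yk.generate_barseq_reads(
        truth, library, design, Path(tmp), depth=30000, error_rate=0.01, seed=23
    )
    cm = yk.trim_and_match(paths, library, design)

print(cm.stats.to_string())
frac = cm.stats["matched"].sum() / cm.stats["total"].sum()
print(f"matched {frac:.4f} of reads at 1% per-base error")

strain_counts, dropped = yk.filter_and_combine(cm, library, min_control_count=50)
print(f"strains quantified: {len(strain_counts)}, "
      f"tags/strains dropped by the 50-count control filter: {len(dropped)}")

table = yk.count_fitness(strain_counts, design)
est = table.fd_median["drugX"]
planted = [s for (s, c) in truth.fitness_coeff if c == "drugX" and s in est.index]
null = est.drop(planted)
print(f"planted FD 2.0: recovered mean {est[planted].mean():.3f} "
      f"(n={len(planted)}); null strains mean {null.mean():+.3f}, "
      f"sd {null.std():.3f}")
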