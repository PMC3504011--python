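"""Mine microsatellite marker candidates from a survey library.

Builds a small synthetic library with 30 planted perfect repeat loci,
runs the full filtering cascade (length floor, repeat search, 100%
perfection, primer feasibility, simplicity screen, single-read
restriction) and prints the funnel plus one designed candidate.
"""

from gsurveyminer import (
    PlantedRepeat,
    SimConfig,
    SimplicityParams,
    simulate_library,
    run_marker_pipeline,
)
from gsurveyminer.marker_pipeline import retention_percent
from gsurveyminer.tandem_repeat import BUILTIN_PROFILES

plants = tuple(PlantedRepeat(motif="AC", n_units=15) for _ in range(15)) + \
    tuple(PlantedRepeat(motif="AAG", n_units=10) for _ in range(15))
lib, truth = simulate_library(
    SimConfig(seed=42, n_contigs=100, planted_repeats=plants)
)

candidates, funnel = run_marker_pipeline(
    lib,
    BUILTIN_PROFILES["mayer_micro"],
    simplicity_params=SimplicityParams(seed=1),
)

print("filtering funnel (stage -> surviving count):")
for stage, count in funnel.stage_counts():
    print(f"  {stage:<20}{count}")
print(
    "retention:",
    retention_percent(funnel.n_retained, funnel.n_repeats),
    "% of detected repeats survive all filters",
)

best = next(c for c in candidates if c.retained)
pair = best.chosen_pair
print(f"\nexample candidate on {best.contig_id}:")
print(f"  repeat  {best.repeat.motif} x {best.repeat.region_bp} bp "
      f"at [{best.repeat.start}, {best.repeat.end})")
print(f"  left    5'-{pair.left_seq}-3'  Tm {pair.left_tm:.1f} C")
print(f"  right   5'-{pair.right_seq}-3'  Tm {pair.right_tm:.1f} C")
print(f"  product {pair.product_size} bp spanning the repeat")
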