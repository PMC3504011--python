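"""Genome coverage from C-values and repeat density of a library.

Coverage: a survey of N sequenced bp covers 100*N/(C*978 Mbp) percent
of a genome whose haploid size is C picograms.  Density: repeat-covered
bp per Mbp of scanned sequence; dividing by 10^4 gives the percent of
the genome that is tandem repeat.
"""

from gsurveyminer import (
    GenomeSizeRecord,
    SimConfig,
    PlantedRepeat,
    find_tandem_repeats,
    repeat_density,
    genome_coverage,
    simulate_library,
)
from gsurveyminer.tandem_repeat import BUILTIN_PROFILES

# coverage of two real-scale libraries against related-species C-values
krill = GenomeSizeRecord(species="Euphausia superba", c_value_pg=48.5)
amphipod = GenomeSizeRecord(species="Anonyx nugax", c_value_pg=27.0)
print("survey coverage from C-values:")
print(f"  12,098,817 read bp vs 48.5 pg -> "
      f"{genome_coverage(12_098_817, krill)}% of the genome")
print(f"  15,482,430 read bp vs 27.0 pg -> "
      f"{genome_coverage(15_482_430, amphipod)}% of the genome")

# microsatellite density of a simulated library
plants = tuple(PlantedRepeat(motif="AG", n_units=20) for _ in range(12))
lib, _ = simulate_library(
    SimConfig(seed=3, n_contigs=60, planted_repeats=plants)
)
matches = []
for contig in lib:
    matches.extend(
        find_tandem_repeats(
            contig.sequence, BUILTIN_PROFILES["mayer_micro"],
            contig_id=contig.id,
        )
    )
d = repeat_density(matches, lib.total_contig_bp)
print(f"\nmicrosatellite density of the simulated library:")
print(f"  {len(matches)} repeats covering {d['repeat_bp']:.0f} bp")
print(f"  {d['bp_per_mbp']:.0f} bp/Mbp = "
      f"{d['percent_of_sequence']:.2f}% of the sequence")
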