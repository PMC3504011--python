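# Methods

This note documents the models, parameter choices and numerical
conventions behind `gsurveyminer`, and what the synthetic validation
does and does not demonstrate.

## Scope and data model

The pipeline's contract starts *after* assembly: its unit of analysis
is the contig — any unique library sequence, including unassembled
single reads — annotated with the number of reads assembled into it.
Read counts are first-class because two downstream rules depend on
them: the final marker filter keeps only single-read contigs (a
multi-read contig at sub-1% coverage is evidence of a repeated or
over-represented locus, hence a paralogy risk), and the functional
profile weights orthology classes by reads. Raw-read totals
(`n_raw_reads`, `raw_read_bp`) are carried as library metadata for
coverage and read-fraction statistics; they are never derived from the
contigs. Coordinates are 0-based half-open everywhere internally;
only GFF3 output is 1-based inclusive.

## Tandem repeat model

A tandem repeat of unit length *u* is a gapless local self-alignment
at lag *u*: column *i* compares base *i* with base *i + u*, scoring +1
for a match and the profile's penalty (default −5) for a mismatch.
`N` matches nothing, including another `N`. A candidate is any
column segment that starts and ends on a match, meets the profile's
minimum score, and spans at least the profile's minimum region length
(region = columns + one trailing unit). The final set is chosen
greedily: highest score first, ties to the smaller unit, then the
leftmost start, then the smaller end; a chosen region blocks all
overlapping candidates at every lag. This makes the output
deterministic, pairwise non-overlapping, and biased to the smallest
period of a repeat (a perfect array scores *R − u*, maximal at the
true period).

Consequences of the gapless choice: `n_gap` is always zero in
reported matches, and an indel inside a repeat array appears as two
segments or as a neighbouring-lag segment rather than as a gapped
column. The per-profile penalties keep the published thresholds
meaningful as effective length floors. Exact-mode profiles are the
same machinery with mismatches forbidden outright.

Perfection is 100 × matches / aligned columns. The perfection filter
is inclusive at its threshold (a 95.0% repeat passes a 95% filter).

The optimised detector (prefix-sum window search with iterative
region blocking) is checked against `reference.brute_force_tandem_repeats`,
a literal enumerate-all-segments-and-greedily-select implementation
that shares no code with it. Equivalence is exercised on random and
repeat-enriched sequences up to 200 bp across all five built-in
profiles; at that length the brute force is exhaustive over every
(lag, start, end) triple.

Interpretation of the published profile flags that have no stated
semantics: the minisatellite profile's region floor is taken as 30 bp
(units of 7–50 bp need a span floor to be meaningful); the most
restrictive exact di–hexa profile is implemented with minimum score 8
and no region floor, since its printed parameter string is truncated.
Per-library repeat totals from the original instrument data are
treated as non-reproducible; only the density→percent arithmetic and
the score/perfection formulas are asserted.

Motifs are reported as the lexicographically smallest rotation of the
per-column majority consensus; forward and reverse-complement motifs
are not merged.

## Cryptic simplicity

The simplicity score counts, over all ordered position pairs at
distance 1..4 (the half-window) and motif lengths 1–4 (equal weights),
the motif copies that agree between the two positions. Any monotone
short-motif repetitiveness score preserves the screen's semantics as
long as the null is built the same way; this one is chosen for being
exactly enumerable (the brute-force reference is a three-line triple
loop) and vectorisable. The null is 50 composition-preserving
single-nucleotide shuffles; significance is the add-one permutation
p-value (1 + #{null ≥ observed}) / 51, so the minimum attainable p is
1/51 ≈ 0.0196 and a homopolymer — whose shuffles are all identical to
itself — is never significant. By permutation exchangeability the
type-I rate at α = 0.05 is at most 2/51 ≈ 3.9%, which the Monte-Carlo
calibration confirms. Each primer sequence (not the whole flank) is
tested; a pair is clean when neither primer is significant.

## Primer feasibility

The checker is exhaustive over flank windows rather than heuristic:
every 18–27-mer in each flank is screened for ≤1 ambiguous base,
homopolymer runs ≤4, GC between 20 and 80%, and nearest-neighbour Tm
between 57 and 63 °C (SantaLucia unified parameters via Biopython, 50
mM monovalent salt, 50 nM oligo; ambiguous bases are approximated as
A, a destabilising choice). Feasible windows are paired so the
product (100–300 bp) spans the candidate repeat while neither primer
overlaps any masked repeat, with pair ΔTm ≤ 8 °C. Pairs are ranked by
|Tm − 60| + |length − 20| summed over both primers, ties by left then
right start; the best three are returned. Dimer/hairpin
thermodynamics are deliberately out of scope — the question answered
is structural and thermal feasibility — and the pipeline takes the
designer as a parameter so a full external designer can be swapped in.

## Filtering cascade

Stages run in the order: length floor (100 bp) → repeat search →
perfection → primers → simplicity → single-read. The filters are
independent predicates, so order affects only wasted work, never the
final set; the chosen order defers the expensive stages. Each repeat
match is one candidate, so a contig with several repeats contributes
several loci; the funnel report counts both loci and contigs at the
end to keep the two bookkeepings distinct.

## Contamination triage

Keyword matching is case-insensitive; terms of ≤3 characters must
match between non-alphanumeric boundaries (so "5S" never fires inside
"S5"), longer terms as substrings — mirroring free-text search over
definition lines. General-database hits must clear e ≤ 10⁻¹²; calls
of viral origin additionally require e ≤ 10⁻⁶⁰ against viral
reference proteins (both thresholds inclusive). Prokaryote calls use
only the lineage root. Because the original searches were run
independently per database, a precedence was needed for contigs
triggering several rules; this implementation orders most-specific
evidence first — virus > prokaryote > transposable element > rRNA >
mitochondrial — then other eukaryote, and logs the triggering hit as
evidence. The precedence is configurable. "Best hit" means lowest
e-value, ties by bitscore, then accession.

The contamination-free dataset removes exactly the viral, prokaryotic
and mobile-element contigs: rRNA and mitochondrial sequences are
intra-genomic and stay.

The holobiont partition assigns each hit to host, symbiont-nuclear or
plastid by lineage tokens plus a plastid term in the title; a contig
with hits in more than one category is labelled `conflict`, reflecting
contradictory database annotations rather than chimerism.

Mitochondrial gene presence merges hit intervals on the reference
mitogenome per gene; ≥95% merged coverage counts as full, any
coverage as partial. Recovered mitochondrial bp sums distinct contig
lengths when lengths are supplied, otherwise merged query spans.

## Functional weighting

Each BRITE class of a contig receives reads / classes, with the
divisor taken *before* hiding the imprecise classes ("Organismal
Systems", "Human Diseases", "Enzyme Families") so the pre-exclusion
scores conserve reads exactly; a post-exclusion divisor is available
as an option. Conservation is asserted to 10⁻⁹ absolute (floating
division only).

## Coverage and report conventions

Genome size in bp is C-value × 978 Mbp/pg — the conversion constant is
the standard one and configurable, and the survey-table coverages are
consistent with it. Percentages are rounded half-up to 2 decimals and
mean lengths to 1 decimal, for parity with the survey tables
(bankers' rounding would disagree on exact .5 boundaries). Both
Spearman and Pearson correlations are offered for the
library-size-versus-mitochondrial-recovery relation; neither is
asserted against original values, which depend on instrument data.
Raw-read average lengths are reported but never used as a checked
quantity, since they are internally inconsistent in the original
survey tables.

## Synthetic libraries

The generator emulates the post-assembly shape of a 454 survey
library: contig lengths normal(272, 80) bp with a 100 bp floor
(clipped-read scale), i.i.d. background sequence at 40% GC (a typical
invertebrate value), and a quarter of background contigs multi-read
with 2 + geometric read counts, giving reads/contigs ratios near the
observed ~1.4. Planted repeats sit on dedicated contigs between
140 bp GC-balanced flanks — the flanks model primer-amenable unique
sequence — with the boundary bases adjusted so the planted
coordinates are exactly recoverable. Contaminant read counts are
binomial draws at the configured fractions of the planned read total
(defaults follow the observed scales: viral up to ~7.5%, bacterial
~1.6%); viral, bacterial and mobile-element reads stay single reads
while rRNA and mitochondrial reads are packed into few high-count
contigs to mimic over-represented multi-copy loci. Fabricated hits
carry titles, lineages and e-values that deterministically trigger
the true category; decoy rows (flanking-region clones, e-values just
above a threshold) are engineered misses for boundary testing.

What passing the synthetic suite shows: the detector, filters, rules
and bookkeeping implement their definitions exactly, end to end. What
it does not show: performance on real 454 data, which additionally has
homopolymer sequencing errors, assembly artefacts, compositional
heterogeneity, and hit tables with partial, conflicting or missing
annotation — the keyword rules in particular are only as good as the
definition lines they grep.

## Problem sizes

Validation sizes were chosen to make the checks exhaustive where
possible and well-powered where stochastic: oracle equivalence on
1,000 sequences ≤200 bp (brute force is exhaustive at that length),
simplicity calibration on 2,000 random 100-mers (standard error
~0.5%), cascade recovery on 50 planted loci over a 200-contig
library, contaminant spiking over ~20,000 reads (binomial bounds a
fraction of a percent wide), and 100 random tables for score
conservation.
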