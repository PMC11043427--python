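# Methods

## The problem

Kataegis is localized somatic hypermutation: a cluster of closely spaced
single-base substitutions (SBSs) on one chromosome of one tumor genome,
typically strand-coordinated C>T and C>G changes in a TpC context produced
by APOBEC cytidine deaminases. `katascan` detects such clusters in
per-sample SBS catalogs, characterizes them at cohort level (spectra,
sizes, genome-wide recurrence), quantifies how kataegis-associated SBSs
distribute over genomic-context tracks (open chromatin, repeats, chromatin
states), and runs the nonparametric association statistics used in
breast cancer cohort analyses of this phenomenon. Because the real WGS
cohorts such analyses are run on are controlled-access, the package ships a
ground-truth simulator that reproduces the statistical structure those
analyses assume, so every stage is testable end to end.

## Detection model

Within one sample and one chromosome, let `p_1 <= ... <= p_n` be the sorted
SBS positions and `g_i = p_{i+1} - p_i` the intermutation distances (IMDs).
IMDs are never computed across chromosome boundaries or across samples;
same-position multi-allelic records contribute an IMD of 0.

Two rule variants define a kataegis locus (threshold `T = 1000` bp, minimum
run length `m = 6` by default):

* **max rule** (default): loci are the maximal runs of consecutive SBSs in
  which *every* adjacent IMD is `<= T`, kept when the run holds `>= m`
  SBSs. This matches detectors configured as "at least six consecutive
  SBSs with a maximum intermutation distance of 1000 bp".
* **mean rule**: the textbook definition — any window `[i, j]` with
  `j - i + 1 >= m` whose *average* adjacent IMD is `<= T` qualifies.
  The average telescopes, so the window qualifies iff
  `(p_j - p_i) / (j - i) <= T`. Overlapping qualifying windows are merged
  by union into maximal disjoint loci, which makes the output deterministic
  and the member sets pairwise disjoint.

The two rules genuinely differ: the catalog `[1, 101, 201, 301, 5301,
5401, 5501]` has no max-rule locus (longest all-gaps-<=1000 run is 4) but
one 7-SBS mean-rule locus (mean IMD 5500/6 ~ 917). The max rule is the
default because it reflects the settings under which the headline breast
cancer analyses were actually run; the mean rule remains available as the
classical definition.

Reported locus statistics: `span_bp = end - start + 1`,
`mean_imd = (end - start) / (n_sbs - 1)` (telescoped mean of adjacent
gaps), `max_imd`, and member counts over the six pyrimidine-normalized
substitution classes.

### Confidence tiers

Published detectors attach a confidence score whose formula is not public;
`katascan` uses an explicitly documented surrogate based on APOBEC
consistency: tier 1 = passes detection; tier 2 = additionally >= 70% of
member substitutions are C>N after strand normalization; tier 3 = tier 2
with >= 10 members. The default filter keeps tier >= 1, so for headline
analyses the tier is a pure annotation and never removes a locus. The
filter also restricts loci to chromosomes 1–22 and X ("chromosomes 1–23",
X aliased to index 23); Y records are read but excluded from analysis.

## Coordinate conventions

Variant positions are 1-based inclusive (VCF convention); bins and
annotation intervals are 0-based half-open (BED convention). Conversion
happens exactly once, at comparison time: a 1-based position `p` is inside
`[start, end)` iff `start <= p - 1 < end`. Chromosome names are
canonicalized on read (strip `chr`, `23 -> X`, `24 -> Y`). Exact duplicate
records are dropped with a logged count; same-position different-alt
records are kept.

Substitutions are pyrimidine-normalized: purine-reference changes are
reverse-complemented together with their trinucleotide context, giving the
six classes C>A, C>G, C>T, T>A, T>C, T>G. Trinucleotide context is
optional throughout — without a FASTA source, spectra are reported at
6-class resolution, which is the resolution of the headline figures.

## Characterization

* **Merged spectra** pool every member SBS of every locus of every tumor in
  a subgroup into one set; the merged spectrum therefore equals the sum of
  per-tumor spectra.
* **Locus sizes** are emitted as raw span/SBS-count vectors plus quantiles;
  kernel smoothing is treated as a plotting device and not computed.
* **Recurrence** tiles the genome with consecutive 2-Mbp half-open bins
  (last bin of each chromosome truncated, never dropped, so every base is
  in exactly one bin). Each locus maps to exactly one bin by its midpoint
  `floor((start - 1 + end) / 2)` in 0-based coordinates — locus spans
  (typically a few kb) are far below the bin width, and the midpoint makes
  the assignment unambiguous without splitting events. Counts accumulate
  events, not tumors (several loci of one tumor in one bin all count), and
  frequency = count / group size with kataegis-negative tumors included in
  the denominator. Per-chromosome event counts use chromosomes 1–22 by
  default, with the chromosome set exposed as an option. Bins are reported
  by coordinates; cytoband labels are presentation, not computation.

## Context enrichment

For a track and subgroup, three SBS pools are compared: (1) kataegis SBSs
(members of loci of kataegis-positive tumors), (2) all SBSs of the same
kataegis-positive tumors, (3) all SBSs of kataegis-negative tumors.
Pooling is at SBS level across all tumors of the subgroup (no per-tumor
re-weighting; a per-tumor weighted variant would be a caller-side
aggregation of per-sample flags from `annotate_sbs`). The enrichment ratio
is proportion(1)/proportion(2), flagged undefined on a zero denominator.
Tracks are independent — an SBS may belong to many — and no p-value is
attached to ratios; they are descriptive, with optional binomial CIs.
Exon/intron/intergenic and similar calls are consumed as BED tracks rather
than derived from a gene model, keeping the module annotation-source
agnostic.

## Cohort statistics

* **Binary status**: positive iff the event count on chromosomes 1–23
  reaches the cut-off (default >= 1). Frequency curves over cut-offs are
  monotone non-increasing by construction.
* **TMB** = (SBS + indel count) per Mbp; the denominator defaults to the
  summed lengths of the analyzed chromosomes and is configurable, since
  "per million base pairs" leaves the callable-genome size open.
* **Metagene rank scores** are single-sample: all measured genes are ranked
  ascending by expression (average ranks on ties) and the score is the mean
  rank of the set members divided by the gene count, in (0, 1], with no
  cross-sample normalization. This is a documented reconstruction of the
  cited rank-score approach, oriented so higher expression gives higher
  scores.
* **Tests**: Wilcoxon rank-sum (exact enumeration when both n <= 8 with no
  ties, else normal approximation with tie and continuity corrections),
  Kruskal–Wallis (tie-corrected H against chi-square with k-1 df; the
  all-values-equal case is flagged degenerate rather than an error), and
  Pearson chi-square (continuity correction OFF by default for all table
  sizes as a single consistent rule, Yates available by flag; zero
  marginals flagged degenerate). All p-values are two-sided. The rank and
  chi-square machinery delegates to scipy; the method-selection policy and
  degenerate-input handling are the module's own.
* **Driver association**: per-gene 2x2 chi-square of alteration vs binary
  status within a subgroup, BH-adjusted across that subgroup's gene panel
  (BH families are per analysis); degenerate genes are excluded from the
  family and logged.

## The simulator

The generator emulates the cohort structure the analyses assume, with
defaults fixed at the study conditions:

| parameter | default | meaning |
|---|---|---|
| genome | 23 chromosomes, ~304 Mb | human chromosome lengths scaled to 10%; all rates are per-Mb so results transfer |
| subgroups | TNBC/ERpHER2n/ERpHER2p/ERnHER2p, 50 tumors each | clinical receptor-defined subgroups |
| positivity | 0.38 / 0.48 / 0.94 / 0.89 | P(tumor carries >= 1 cluster), mirroring observed subgroup kataegis frequencies — simulator inputs to recover, never reproduction targets |
| background rate | 2 SBS/Mb | uniform per chromosome, Poisson counts; realistic breast cancer WGS order of magnitude |
| locus count | Geometric(0.25), cap 50 | clusters per positive tumor (mean 4, matching a few-events-per-tumor regime) |
| cluster size | Uniform{6..25} | SBSs per cluster |
| spacing | Uniform{10..300} bp | adjacent distances within a cluster, well inside the 1000 bp rule |
| cluster classes | C>T 0.45, C>G 0.40, rest 0.15/4 | APOBEC-like spectrum |
| strand coordination | on | each cluster all-C>N or all-G>N before normalization; 6-class normalization must erase this, which is itself a test |
| tracks | ATAC 10%, DHS 15% coverage | regular tilings with exact coverage; clusters placed into ATAC with probability enrichment x coverage (default 2 x 0.10) |
| TMB effect | multiplier 1.0 | optional background-rate multiplier for positive tumors |
| drivers | 20 genes, base rate 0.15, one gene at OR 4 | conditional Bernoulli flags given status |
| expression | 400 log-scale Gaussian genes, 25-gene metagenes | members shifted by +0.8 (mitotic metagene) in positive tumors |

Placement details: a cluster's chromosome is drawn length-weighted; inside
an enriched track, the interval is drawn length-weighted and the start
uniform with room for the cluster's span; outside, uniform over the track
complement, so the in-track probability is exactly `enrichment x coverage`.
Placement collisions with a chromosome end are resampled with a retry cap.
A single numpy Generator drives everything, so a fixed seed makes every
output bit-reproducible.

What the simulator does **not** emulate: replication-timing or chromatin
covariation of the background mutation rate, rearrangement breakpoints
(real kataegis co-localizes with them), 96-channel signature realism, and
sequencing artifacts. Passing tests therefore demonstrate the pipeline's
correctness under its stated model — uniform background plus injected
clusters — not detector performance on real tumors, where background
inhomogeneity can inflate false calls at loose thresholds.

### Truth matching

A truth cluster counts as recovered iff a detected locus of the same
sample/chromosome contains all its member positions or overlaps it
reciprocally by >= 50%; a detected locus sharing no member with any truth
cluster is a false call. Exact boundary recovery (detected start/end =
min/max injected positions) is asserted for clusters isolated from the
background, with a rule-dependent isolation margin: under the max rule a
gap > T breaks the run, so T suffices; under the mean rule an n-member
cluster of span S can absorb a background SBS up to `T*n - S` bp away
(the tight interior subsidizes the flanking gap in the window average), so
the margin is `max(T, T*n - S)` per cluster.

## Numerical and scale choices

* Desk-scale problem sizes: the default cohort (200 tumors, ~304 Mb genome,
  ~130k SBSs) simulates and analyzes in seconds; detector–oracle
  equivalence uses 1,000 random catalogs of up to 500 SBSs; statistical
  calibration uses 10,000 null replicates at n = 30 per group. These sizes
  give binomial standard errors small enough for the recovery tolerances
  (±0.03 on spectrum proportions at >= 5,000 clustered SBSs; type-I error
  ±0.01 at 10,000 replicates).
* Mean-rule detection enumerates qualifying windows per window size with
  vectorized span checks (O(n^2) worst case, vectorized; n per chromosome
  is small in practice).
* Interval membership uses `searchsorted` on merged, sorted interval
  arrays; merging treats exact half-open adjacency as mergeable.
* Output tables are written with fixed column orders, deterministic sort
  keys, and no timestamps, so identical runs are byte-identical; the run
  manifest hashes the configuration minus the output directory.
* Seeds: every stochastic component takes an explicit integer seed;
  derived seeds stay below 2^31.

## Known limitations

* The surrogate confidence score is not the unpublished original; with the
  default filter this has no effect on which loci are reported.
* The per-locus gene-model annotation (promoter/intron/distal-intergenic
  labels) is out of scope; users wanting it supply their own BED tracks to
  the SBS-level machinery.
* Whether X-chromosome events should enter per-figure analyses is
  ambiguous in the source conventions (binary status uses 1–23,
  per-chromosome views 1–22); both chromosome sets are exposed as options
  with those defaults.
* A single-seed 95%-CI recovery check fails ~5% of seeds by construction;
  the acceptance checks therefore pool replicate cohorts where runtime
  allows.
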