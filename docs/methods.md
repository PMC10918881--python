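# Methods

## Data model and filtering

A repertoire observation is either a bag of paired-chain B cells
(single-cell mode) or a bag of unpaired chains with read support (bulk
mode). Both normalise to `ChainRecord` (locus, V/J/C calls, CDR3
nucleotide and amino-acid strings, isotype, read count).

Single-cell filtering requires, per barcode, exactly one complete
productive IgH contig and exactly one complete productive IgK/IgL
contig, each with a CDR3aa drawn solely from the 20 standard residues.
Barcodes with more than one productive chain of a class are dropped by
default (`multiplet_policy="drop"`); the alternative policy keeps the
highest-UMI chain per class. Dropping is the conservative choice: a
multi-heavy barcode is more likely a doublet than a biological
double-producer, and keeping a "best" chain risks chimeric pairings.

Bulk filtering retains chains with non-placeholder V, J **and** C calls
(reconstruction tools mark missing segments with `.`), a complete CDR3aa
free of the wildcard characters `* _ X ? .` and of any non-standard
letter, and (for IgH) a C call that maps onto one of the nine isotypes
by case-insensitive prefix match. Unparseable read counts become 1 with
a warning (strict mode raises instead); locus is inferred from the
V-gene prefix, falling back to J then C. Filtering is idempotent by
construction and tested as such.

## Clonal networks

Nodes are single cells (each cell is its own node, so identical CDR3s on
distinct cells are distinct nodes) or unique CDR3aa sequences (bulk and
downsampled networks, duplicates collapsed before sampling). Edges join
nodes whose CDR3aa Levenshtein distance lies in `[d_min, d_max]`:

- single-chain networks default to `0..3` ("distance < 4"), so
  identical sequences from distinct cells are connected;
- strict paired-chain networks use the **sum** of heavy- and light-chain
  CDR3aa distances with bounds `1..3`. The sum (rather than the max)
  preserves the metric property and reads naturally as a total edit
  budget across the receptor; `max` is available as a configurable
  alternative.

Distances come from edlib (exact unit-cost edit distance with an
optional band `k`). The all-pairs search prunes with two exact lower
bounds — the length difference, and half the L1 distance between
residue-composition vectors (one substitution moves the composition by
at most 2, one indel by 1) — then verifies survivors with the banded
computation. The pruned search provably returns the same edge set as the
naive O(n²) scan, and the tests compare it against a brute-force DP
oracle on random inputs.

Edge-match gating on V/J gene identity (a common clonotype-clustering
convention) is deliberately **not** applied by default: the network
definition used here is distance-only, matching the caption-level rule
the analysis mirrors; callers can pre-partition inputs by V/J if they
want gated networks.

Local clustering coefficients are `C_v = 2 T_v / (k_v (k_v − 1))` with
`C_v = 0` for degree < 2; the network average runs over **all** nodes of
the (retained) network, matching the default of the graph tool this
analysis convention comes from. Averaging over degree-≥2 nodes only is
available via `include_low_degree=False`.

## Repertoire metrics

- Clonotype definitions: single-cell — identical paired (heavy, light)
  CDR3aa; bulk — identical (V, J, CDR3aa), with diversity computed on
  CDR3aa identity alone so that bulk samples of different V-call
  resolution remain comparable.
- Shannon entropy `H = −Σ p_i ln p_i` (nats) over CDR3aa abundances;
  read-count-weighted in bulk mode by default (transcript-level), with
  record weighting available.
- Adjusted Shannon: `H / ln N`, `N` the total weighted count. This maps
  to [0, 1], equals 1 exactly when all N chains are distinct, and
  removes the mechanical dependence of `H` on sequencing depth;
  dividing by raw `N` is exposed as an alternative scale factor. Any
  cross-sample comparison uses a single scale rule throughout a run, so
  conclusions do not depend on the choice.
- Morisita–Horn similarity
  `MH = 2 Σ x_i y_i / ((Σx_i²/X² + Σy_i²/Y²) X Y)`, union-indexed,
  invariant to proportional rescaling of either composition.
- Isotype usage: fractions over the nine IgH classes; per-cell voting in
  single-cell populations, weighted chain totals in bulk. Undetected
  isotypes report 0 (IgE in particular is computed but typically ~0).
- κ–λ ratio: weighted IgK total over weighted IgL total; reported
  missing when no IgL is observed (the ratio is undefined, not
  infinite).

## Group comparisons

The downsampled-network comparison pools each group's **unique** CDR3aa
sequences, draws `n_downsample` of them without replacement per
replicate (replicate i re-seeds the RNG with `seed + i`; draws are
independent across groups and replicates), builds the `d ≤ 3` network on
unique-sequence nodes, and records the connected-node count (degree ≥ 1)
and the network-average clustering coefficient. Groups are compared per
metric with a two-tailed t-test across replicates. The t-test defaults
to the Welch (unequal-variance) form everywhere — that is also the
default of the R `stats` t-test this convention follows — with pooled
variance as an option; p > 0.05 is labelled N.S. Raw p-values are
reported; no multiplicity correction is applied across panels, matching
field practice for descriptive repertoire contrasts (a Benjamini–
Hochberg helper can be layered on by the caller).

A caveat the tests make explicit: replicates are subsamples of one fixed
pool per group, so they are positively correlated through that pool.
When the two pools genuinely differ (e.g. different realised planted-
cluster content), the replicate t-test detects that fixed difference
with very high power; the null-calibration test therefore compares two
cohorts from the identical *pure-background* generator, where the test
is well calibrated.

ESSDAI correlations use Pearson's r per tissue stratum, restricted to
pSS samples, with pairwise-complete observations and an undefined result
below n = 3. Paired labial↔parotid sharing computes, per patient and
chain locus, Morisita–Horn similarity of the CDR3aa compositions and the
absolute adjusted-Shannon difference.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes,
not V(D)J biology. Defaults (each a `SimConfig` field):

- CDR3aa: random over the 20 residues, length uniform on 12–18, flanked
  by the junction motif `C…W` (cosmetic). Planted clusters: 25 seed
  sequences shared cohort-wide; a clonotype is cluster-derived with
  probability 0.05 (background) and is then the seed with 0–1 interior
  point substitutions, so intra-cluster pairwise distance ≤ 2. Random
  background sequences of this length collide (d ≤ 3) in well under 1%
  of pairs, so network signal is governed by the planted structure.
- Clone sizes / read counts: geometric(p = 0.35), mean ≈ 2.9 reads per
  chain — a skewed, singleton-dominated law.
- Isotype profiles per (tissue, population): IgM/IgD dominate naive
  cells; switched populations carry IgG/IgA with IgA enriched in glands.
  The case group's profile can be perturbed per isotype via
  `isotype_case_multiplier` (e.g. ×0.3 on IgA2 to emulate depressed
  usage).
- Light chains: κ with probability 2/3 (the physiological ≈2:1 κ:λ
  ratio), with per-patient heterogeneity (truncated normal, sd 0.05) so
  the realised ratio varies between samples.
- Tissue overlap: 30% of a sample's clonotypes are drawn from a
  patient-level shared pool, giving labial↔parotid sharing that rises
  monotonically with the parameter.
- ESSDAI: for pSS samples, `slope × (realised κ/λ ratio) + intercept +
  N(0, σ)`, truncated at 0. σ can be given directly or derived from the
  realised between-sample ratio spread to hit a target latent
  correlation (`target_r`, default 0.6); the targeting mechanism is what
  makes small-cohort parameter-recovery tests meaningful.
- Case/control planting multiplies the case group's cluster membership
  probability by an enrichment factor (capped at 1).

What the generator does **not** emulate: germline gene frequencies,
somatic hypermutation lineages, isotype–clone-size coupling, sequencing
error, or any mechanistic link between disease activity and repertoire
composition beyond the configured linear coupling. Passing tests
therefore demonstrate that the pipeline recovers planted statistical
structure at realistic sizes — not that real pSS glands behave this way.

## Problem sizes and numerical choices

The statistical tests in the suite run the comparison machinery at a
downsampling depth of 2000 unique sequences (5 replicates), cohorts of
2–40 patients and 250–1200 chains per sample, 50–100 seeded repetitions
per property — sizes at which the planted effects are comfortably
detectable and the null is calibrated. The demo uses 1000-sequence
downsamples. All randomness flows from explicit integer seeds
(replicate i uses seed + i; planted cohorts derive case/control seeds
from the base seed), and every run is byte-reproducible. Degenerate
inputs are defined errors, not silent results: all-zero count vectors,
totals below 2 for the adjusted Shannon, empty light-chain sets, single
replicates for the t-test, and downsample depths exceeding a pool all
raise with instructions.

## Known limitations

- The paired-chain distance prefilter bounds each chain's distance by
  the total budget, which is exact but conservative; extremely long
  CDR3s (> ~60 aa) would make the composition bound weak, though such
  junctions do not occur after filtering.
- Bulk locus inference relies on gene-name prefixes; reconstructions
  with fully non-standard gene names would need an explicit locus
  column.
- The downsampled comparison treats replicates as independent; see the
  correlation caveat above when interpreting p-values against fixed
  pools.
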