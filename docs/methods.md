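# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `oligoscope`. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Entropy decomposition

Oligotyping treats an OTU's gapped alignment as a character matrix over
`{A, C, G, T, -, .}`. The internal gap `-` is information — two oligotypes
may legitimately differ by an indel — whereas `.` marks missing terminal
coverage and is excluded from all frequency counts. Column entropy is
Shannon information in **base 2**; the base is fixed by the calibration the
threshold is quoted in (a 1:5 minority gives 0.65 bits; natural log would
give 0.45 and make the published threshold meaningless).

The recursion splits a read group at the maximum-entropy position whenever
the group holds at least `min_reads_for_round = 21` sequences **and** the
maximum entropy strictly exceeds `min_entropy = 0.6` bits; OTUs enter only
with strictly more than `min_otu_reads = 100` reads. Comparisons are
inclusive on the count and strict on the entropy — the literal reading of
"at least 21" and "greater than 0.6". Ties between equally entropic
positions go to the leftmost position; one position is consumed per round,
with multi-position discrimination arising through recursion. This makes
the decomposition deterministic; selecting several tied positions at once
would produce the same partition in the error-free limit but an
implementation-dependent one under noise.

Reads carrying `.` at a position chosen for a split cannot be assigned a
character there and are set aside. Two removal policies are implemented:
`retain_complete` (default — the oligotype keeps its complete reads) and
`drop_oligotype` (any oligotype descending from a split that shed reads is
removed wholly). The default is the milder reading; the per-site retained
fraction is reported so the cost of either policy is visible.

No minimum-abundance output filtering is applied during decomposition.
Absolute singletons — rows of the final table with total count ≤ 1 — are
removed afterwards and counted.

## Synthetic communities

The generator is first-class code, not a fixture: it defines the study
conditions every downstream test runs under.

* **Sampling design.** 13 stations by default: six bathymetric
  (HGI–HGVI, depths pinned to the 1284–3535 m range, monotone), and
  seven latitudinal stations around ~2500 m (N4…N1, S1…S3), with HGIV
  belonging to both transects. CPE pigment (18.86–44.26 µg cm⁻³)
  declines linearly with depth plus noise (r ≤ −0.6 by construction),
  porosity (51.8–72.3 %vol) rises with depth, particulate protein tracks
  CPE. Easting spans the bathymetric transect, Northing the latitudinal
  one (UTM metres within the study-area ranges).
* **OTUs.** One random 400-base sequence per OTU; reads per OTU drawn
  from [100, 3000]. Variant positions (1–5 by default, drawn away from
  the terminal 10% of the alignment) carry sub-population-specific
  characters, including gaps. Sub-population counts are drawn
  2 + Poisson(4), truncated to 31 (the observed range of oligotypes per
  OTU is 2–31 with median ~6) and to one sub-population per ~60 reads —
  the latter guarantees every planted group is large enough (≥ 21 reads
  with high probability) and every split has minority fraction above the
  1:6 entropy threshold, so the error-free decomposition provably
  recovers the planted partition. Character tuples follow a mixed-radix
  (base-5) assignment so the recursive splits can peel sub-populations
  apart position by position in any order.
* **Scenarios.** Per-site expected counts follow one of five occurrence
  scenarios: `depth_linear` and `cpe_linked` (expectation
  `exp(b · z(variable))`, slopes ±U(0.6, 1.3) with alternating sign, the
  linear-response structure RDA assumes), `checkerboard_pair` (two
  sub-populations on complementary site sets), `aggregated_block`
  (shared half-size site block) and `neutral` (lognormal jitter).
  Sub-population totals are equalised before Poisson sampling so planted
  groups stay comparably sized. Realised counts are stored as ground
  truth.
* **Errors and coverage.** Substitution errors are independent per base
  at rate 0.001 by default (uniform over the three alternatives; gaps
  and missing characters are never mutated) — a per-base rate of the
  order reported for denoised 454 data. A 2% fraction of reads has its
  terminal segment masked to `.` to exercise the incomplete-alignment
  rule. No chimeras, quality scores or flowgram-level error structure
  are modelled; the per-site read-depth distribution is uniform unless a
  per-site multiplier is supplied, since no printed depth distribution
  exists to emulate.

What passing tests show, and do not show: recovery results demonstrate the
decomposition logic is correct under the planted model (site-independent
base sequences, independent substitution errors, balanced sub-populations);
they do not certify behaviour on real alignments with alignment error,
chimeras, or strongly unbalanced oligotypes near the entropy threshold.

## Screening

C and T scores are computed on presence/absence (`count > 0`) after
singleton removal, as raw unit counts — C from
`(r_i − S)(r_j − S)`, T from `S · A` — and averaged over all unordered
pairs within each OTU. The third quartile uses linear interpolation (the
"type 7" rule); selection requires both means to strictly exceed their Q3,
so a flat score distribution selects nothing. Hellinger transformation
enters only the display ordering (UPGMA on Bray–Curtis dissimilarities),
never the scores themselves, which are binary by construction.

## Constrained ordination

RDA is implemented directly (least-squares projection of the centred
Hellinger response on the centred z-scored constraints, SVD of the fitted
values); the raw sums of squares it exposes drive the permutation pseudo-F
and forward selection. `scikit-bio`'s RDA serves as an independent
cross-check in the tests, never as the implementation. Numerical choices:
singular values below 1e−9 of the largest are treated as rank-null; the
explanatory matrix must be full rank (a rank-deficient one raises a
collinearity error); constant environment columns are dropped with a
warning before z-scoring.

The permutation test permutes response rows and uses the add-one rule,
p = (1 + #{F ≥ F_obs}) / (1 + n_perm), with `n_perm = 999` by default.
Forward selection follows the double-stopping idea: nothing is selected
unless the global model (all candidates) is significant at α = 0.05; then
candidates enter greedily by explained variance while their marginal
permutation test (partial F, residuals-permutation under the reduced
model) stays at or below α. Selection halts once the cumulative adjusted
R² reaches the global model's adjusted R², **retaining** the variable that
reaches the cap. The retain-then-stop form matters with few sites: at
n = 13 the df-penalised adjusted R² of a six-candidate global model
routinely sits *below* that of a single strong predictor, and rejecting
the capping variable would systematically discard genuine signal while the
type-I control of the procedure lives in the global gate, which is
unchanged.

The candidate set defaults to {protein, CPE, Easting, Northing, Depth,
Porosity}. Porosity appears in reported models though not in every listing
of the candidate pool, and phospholipid concentration is measured but
never selected anywhere; the set is therefore configurable, with the union
as default and phospholipids omitted. Reported models need constrained
variation strictly above 50% and BH-adjusted P < 0.05; the BH family is
the set of final per-OTU model p-values. P-values are global-model tests,
not per-axis tests.

## Association networks

Whittaker's IA is computed on percentage-scaled profiles; pairwise values
come from an L1 distance matrix. The permutation null shuffles the site
order independently within every profile (n = 200) and recomputes all
pairwise IA per permutation. The per-pair p-value is
`#{IA_perm ≥ IA_obs} / n_perm`, so a pair that beats every permutation
scores p = 0. A strictly positive floor (add-one) is deliberately **not**
used here: with 200 permutations the floor would be 1/201, and under a BH
family spanning all unordered pairs a floor makes FDR significance at 0.05
unattainable once the table exceeds a few dozen rows (the smallest
adjusted p is floor × m / R, needing more than m/10 pairs at the floor) —
the network would be structurally empty regardless of signal. The cost is
that p = 0 is an artefact of permutation resolution, not certainty; edge
p-values should be read as "below 1/200".

Edges require IA > 85 and adjusted p < 0.05; nodes require total
abundance ≥ 2 (the "relative abundance greater than one" rule, read as
read count ≥ 2 consistently with singleton removal). Topology statistics
use the standard formulas (density 2E/N(N−1); mean local clustering with
degree-<2 nodes contributing 0; heterogeneity = CV of degree;
centralization = [N/(N−2)]·[k_max/(N−1) − density]); the degree power law
is a least-squares fit of log count on log degree over the raw degree
histogram — approximate by nature and flagged as such.

MCL runs on edge weights linearly rescaled from [85, 100] to
[0.001, 0.15] (increasing map: stronger association, heavier walk). The
stochastic matrix gets self-loops equal to each node's maximum incident
weight (regularisation that keeps the walk from oscillating), is column
normalised, then alternates expansion (matrix square) and inflation
(entrywise power 2.5, renormalise) with pruning below 1e−5 until the
iterate changes by less than 1e−8, capped at 200 iterations (a cap hit
raises a convergence error). Clusters are read off attractor rows, merged
over shared members; any node orphaned by pruning attaches to its heaviest
attractor, making the output a partition.

## Pipeline

One global seed deterministically derives per-stage seeds (SeedSequence
spawning, reduced below 2³¹), so a full run is reproducible bit for bit;
the manifest records parameter echo, per-stage counts and the read
conservation identity (reads in = retained + set aside + in skipped OTUs +
removed singletons). Configuration is YAML; paths are excluded from the
manifest echo so identical analyses yield identical manifests.

Default problem sizes (20 OTUs in the pipeline default, 40 in the
acceptance script, 50 in the recovery test, 200 forward-selection
replicates at 199 permutations) were chosen to make every stochastic check
well resolved while keeping a full test-and-acceptance cycle to a few
minutes on one core.

## Known limitations

* The decomposition is unsupervised; no post-hoc merging or supervised
  refinement of oligotype sets is provided.
* C/T screening is presence/absence only — abundance-weighted variants
  are out of scope.
* No partial RDA, variation partitioning or spatial eigenvector
  (PCNM/MEM) construction; spatial structure enters only as raw UTM
  coordinates.
* The degree-distribution power-law fit is descriptive, not a test of
  scale-freeness.
* Network p = 0 values reflect permutation resolution (1/200), not exact
  nulls; increase `ia_permutations` for finer resolution.
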