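# oligoscope

Sub-OTU microdiversity analysis of aligned 16S rRNA amplicons.

Operational taxonomic units (OTUs) clustered at 97% 16S identity routinely
lump together organisms with ecologically meaningful differences. *Oligotyping*
recovers that hidden structure: within one OTU's alignment it finds the
positions where reads genuinely disagree — positions of high Shannon entropy —
and partitions the reads by the characters they carry there. `oligoscope`
implements this decomposition together with the downstream ecology used to
interpret it in a deep-sea sediment setting: screening oligotype occurrence
matrices for checkerboard and togetherness structure, relating oligotype
abundances to environmental and spatial gradients by redundancy analysis (RDA)
with forward selection, and building permutation-tested co-occurrence networks
partitioned by Markov clustering. A synthetic community generator emulating a
two-transect deep-sea sampling design (a bathymetric transect spanning
1284–3535 m and a latitudinal transect at ~2500 m, intersecting at one central
station) supplies ground-truthed inputs for every stage.

It is intended for microbial ecologists who want a tested, scriptable,
pure-Python version of this analysis chain, and for method developers who need
a simulation scaffold with known planted structure.

## The method in brief

**Entropy decomposition.** For an alignment column with character frequencies
$f_c$ over $\{A, C, G, T, -\}$ (the gap is a legitimate character; `.` marks
missing terminal coverage and is excluded), the column entropy is
$H = -\sum_c f_c \log_2 f_c$. OTUs with more than 100 reads are decomposed
recursively: while a read group holds at least 21 sequences and a position
with $H > 0.6$ bits exists, the group is split by character at the
(leftmost) maximum-entropy position. Terminal groups are the oligotypes,
labelled by their discriminant characters. The 0.6-bit threshold corresponds
to one alternative character per six dominant ones (85.7% dominance), i.e.
roughly the point below which 454-style sequencing error becomes hard to
distinguish from real variation. Absolute singletons (one read in the whole
dataset) are removed.

**Distribution screening.** For every oligotype pair within an OTU, with
$r_i$ occupied sites, $S$ jointly occupied and $A$ jointly empty sites, the
checkerboard score is $C_{ij} = (r_i - S)(r_j - S)$ and the togetherness
score is $T_{ij} = S \cdot A$. OTUs whose mean C **and** mean T strictly
exceed the third quartile of the respective score distribution carry
"resolving" oligotypes.

**Constrained ordination.** Oligotype counts are Hellinger-transformed,
environmental variables (depth, CPE pigment, porosity, particulate protein,
UTM Easting/Northing) z-scored. RDA projects the centred response onto the
constraints; forward selection applies the double-stopping rule (a
significant global model gates selection; additions require a significant
marginal permutation test and stop at the global adjusted R²). Models with
constrained variation > 50% and BH-adjusted permutation P < 0.05 are
reported; variance inflation factors are checked to be < 10.

**Association networks.** For percentage-scaled profiles $p$ and $q$,
Whittaker's index of association is
$\mathrm{IA} = 100 - \tfrac12 \sum_s |p_s - q_s|$. Edges join oligotype
pairs (total abundance ≥ 2) with IA > 85 whose permutation p-value (200
independent row shuffles, BH-corrected over all pairs) is below 0.05. The
graph is summarised (density, clustering, heterogeneity, centralization,
degree power law) and partitioned by Markov clustering at inflation 2.5
after rescaling IA weights from [85, 100] to [0.001, 0.15].

## Worked example

```python
import pandas as pd
from oligoscope import (generate_env_table, CommunityDesign, generate_community,
                        decompose, tabulate, hellinger, zscore, RDA)

env = generate_env_table(13, seed=1)
design = CommunityDesign(n_otus=1, scenarios=["depth_linear"],
                         reads_per_otu=(800, 800), error_rate=0.0,
                         missing_tail_fraction=0.0, seed=1)
read_sets, truth = generate_community(design, env)

oligotypes, log = decompose(read_sets[0])
table = tabulate(oligotypes, list(env.index))
print(table.counts)

Y = pd.DataFrame(hellinger(table.counts.to_numpy(float).T),
                 index=table.counts.columns, columns=table.counts.index)
X = zscore(env[["depth", "cpe", "easting", "northing", "protein", "porosity"]])
res = RDA(Y, X[["depth"]]).fit()
res.permutation_test(n_perm=999, seed=1)
print(res.summary())
```

prints

```
site        HGI  HGII  HGIII  HGIV  HGV  HGVI  N4  N3  N2  N1  S1  S2  S3
OTU0000:-    72    28      3     0    2     1  12   5   3   8   4   3   4
OTU0000:A    31    19      8     6    4     1  10   9   3   4   8  10  10
OTU0000:C-   38    26      7     2    2     7   4   7  11   9  10   9  15
OTU0000:CA    1     1      3    17   23    45   4   4   4   4   5   2   5
OTU0000:G     0     2      7    21   21    38   9  10   7   2   4   9  13
OTU0000:T     1     5      8    24   19    31   9  10   4   9   7   7   9
Redundancy analysis
  model:                 Y ~ Depth
  sites, oligotypes:     13 , 6
  constrained variation: 74.9%
  adjusted R2:           0.726
  pseudo-F:              32.809
  permutation P:         0.001
  VIF:                   depth=1.00
```

The single OTU decomposed into six oligotypes (two rounds, at alignment
positions 31 and 216 with entropies 2.26 and 0.99 bits), matching the six
planted sub-populations. Their labels are the characters carried at those
positions — note `-`, an internal gap, acting as an ordinary discriminant
character. The count matrix shows the planted bathymetric structure (columns
HGI…HGVI are ordered shallow→deep; N4…S3 sit at ~2500 m): some oligotypes
peak at the shallow stations, others at depth. RDA on the
Hellinger-transformed matrix confirms it — water depth alone constrains 74.9%
of the variation, with the smallest attainable permutation P at 999
permutations (0.001).

The same analysis runs end to end from the shell:

```bash
oligoscope all --out run1 --seed 7
oligoscope simulate --out sim --seed 7 --n-otus 20
oligoscope oligotype --alignments sim/alignments --env-table sim/env_table.tsv --out otypes
```

`run1/` then holds the environment table, per-OTU aligned FASTA, the
oligotype × site table, the screening and RDA reports, the network
(edge list, GraphML, SIF), MCL cluster membership and a manifest with
read-count accounting.

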