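# ethnocore

Structural-core analysis of free-list interview data for quantitative
ethnobiology: who knows which medicinal plants, which of those plants form
the culturally "important" core of the domain, and whether that core's
composition differs between groups (interview periods, life stages,
communities).

## What it computes

**Cultural salience.** A free list is the ordered list of items an
informant recalls for a domain. Smith's salience of item *i* is

S_i = (1/N) Σ_j (L_j − r_ij + 1)/L_j

summed over the informants *j* who cite *i* at recall rank r_ij in a list
of length L_j, and divided by the total number of informants N (non-citers
contribute 0). Frequently cited, early-recalled items score high.

**Salience threshold (structural core vs satellites).** Ranking items by
salience gives a smooth continuum with no obvious cutoff. The threshold is
obtained from a Monte-Carlo null model: B (default 1000) free-list datasets
are simulated with the same N, the same item-pool size M and the same
citation effort per informant as the observed data, but with items cited
uniformly at random in random order. The observed salience at salience
rank k is compared with the B simulated values at the same rank; the
per-item p-value is the smaller empirical tail. The structural core is the
maximal salience-ranked prefix of items sitting *above* the null mean with
p < α (default 0.05); everything after the first non-significant entry is a
satellite.

**Core comparison.** Participants are encoded as binary presence/absence
vectors over the union of the two compared cores (participants citing no
core plant are dropped — Jaccard is undefined between empty sets),
dissimilarity is binary Jaccard (b+c)/(a+b+c), and group difference is
tested by one-factor PERMANOVA (pseudo-F on the distance decomposition,
permutation p with the add-one rule, exact enumeration when feasible),
with homogeneity of multivariate dispersions (PERMDISP, group centroids,
negative-eigenvalue correction) as the companion check and PCoA for
visualisation.

A synthetic generator (`ethnocore.syndata`) plants a known core (items
cited more often, recalled earlier via Plackett–Luce weights) with
controllable between-group core overlap, so every stage is testable
without field data.

## Worked example

Simulate two 40-informant groups whose planted 6-item cores share half
their items, then run the full comparison:

```
ethnocore simulate --informants 40 --items 40 --k-core 6 --overlap 0.5 \
    --group-sizes 40 40 --seed 7 --out demo.csv
ethnocore compare demo.csv --runs 1000 --permutations 999 --seed 7 --out demo_out
```

prints

```
Core sizes: {'group1': 6, 'group2': 6}
Core union (9 plants): plant_001, plant_002, plant_003, plant_004, plant_005, plant_006, plant_007, plant_008, plant_009
Rows compared: 80 (dropped all-zero: 0)

## PERMANOVA

| Source | df | SS | MS | pseudo-F | R2 | p |
|---|---|---|---|---|---|---|
| between | 1 | 5.7265 | 5.72645 | 57.318 | 0.42358 | 0.001 |
| residuals | 78 | 7.7928 | 0.09991 | | 0.57642 | |
| total | 79 | 13.5192 | | | 1 | |

## Dispersion homogeneity

F = 0.3914, p = 0.556
```

Both planted cores are recovered exactly (size 6 each; their union has 9
plants because 3 are shared). Core composition differs strongly between
the groups: the group factor explains R² ≈ 42% of the distance variance
and the permutation p sits at the smallest reportable value, 1/(999+1) =
0.001, while the dispersion test finds no difference in within-group
spread (so the PERMANOVA signal is a location, not a dispersion, effect).
`demo_out/` holds the JSON/markdown report, per-group salience tables, the
composition matrix and the PCoA ordination plot.

The same analysis is available as library calls (`run_comparison`,
`compute_salience`, `null_salience_distribution`, `classify_core`,
`permanova`, ...), and `ethnocore compare-matrix` /
`run_matrix_comparison` enter the pipeline at a pre-built 0/1 matrix.

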