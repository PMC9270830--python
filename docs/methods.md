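# Methods

## Salience

Smith's salience is used as the popularity measure: for item *i*,
S_i = (1/N) Σ_j (L_j − r_ij + 1)/L_j over citing informants *j*, with N
the total number of informants. Two consequences the tests rely on:

* **Conservation.** One informant's scores sum to (L+1)/2, so
  Σ_i S_i = (1/N) Σ_j (L_j+1)/2 for any dataset (checked to 1e-9).
* **Monotonicity.** Appending a citation of *i* to the end of a
  non-citing informant's list adds 1/(L+1) ≥ 0 to *i*'s total, so S_i
  never decreases.

Ties in salience are broken by higher citation frequency, then item name,
making the rank assignment a deterministic permutation of 1..M.

## The null model and the salience threshold

The null scenario matches the observed data on three quantities: number
of informants N, item-pool size M, and citation effort per informant.
Effort is matched by resampling list lengths with replacement from the
observed length multiset (`length_model="resample_observed"`, the
default), which preserves the observed mean *and* spread; `fixed_mean`
and `poisson_mean` are available when only the mean is to be matched.
Within a simulated list, items are drawn uniformly without replacement
from the M-item pool and ordered uniformly: under the null, no item is
more cited or earlier-recalled than any other.

Comparison is **rank-matched**: the observed salience at salience rank k
is compared with the B simulated values at rank k (runs realizing fewer
than M items contribute zeros at the unused ranks). The per-item p-value
is the smaller of the two inclusive empirical tails,
p_k = min(#{null ≥ s_k}, #{null ≤ s_k})/B. This produces the
characteristic U-shaped p profile down a ranked list — top-of-list items
are significantly *high*, bottom-of-list items significantly *low*, and
mid-list items sit near 0.5 — and it is the only reading consistent with
published per-rank p columns of this method. Because the smaller tail is
two-sided, items can be significant by being *less* salient than chance;
the `side` annotation (prominent = above the rank's null mean) separates
the two cases. Note the corollary: under the null ~10% of items have
p < 0.05 (5% per tail), while the *false-core* rate stays at ~5% because
core membership additionally requires prominence.

Raw tail proportions are reported by default (so a value above all B
simulations prints p = 0.0, as in published tables); the add-one
(b+1)/(B+1) estimator is available via `corrected_pvalues=True`.

The **structural core** is the maximal salience-ranked prefix whose
entries are all prominent with p < α. The prefix rule (rather than
labelling every significant item) reflects the published usage, where the
core/satellite boundary falls exactly at the first entry with p ≥ α.
When a table lacks the `side` column — published rankings print only p —
entries are treated as prominent; the prefix still stops at the first
p ≥ α, so classification of published columns is unaffected.

RNG discipline: one master seed; each of the B runs uses a spawned
`SeedSequence` substream, so results are independent of evaluation order
and the loop could be parallelized without changing output.

## Comparison stage

All-zero rows (participants citing no plant of the core union) are
removed before distances and reported; binary Jaccard then equals the
quantitative Jaccard on 0/1 data. PERMANOVA uses the distance-based
decomposition SS_total = (1/n) Σ_{i<j} d²_ij,
SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij, F = MS_between/MS_within. The
permutation p uses the add-one rule with 999 permutations by default
(smallest reportable p = 0.001); when the number of distinct relabelings
is ≤ the requested permutations, every relabeling is enumerated and the
exact p reported. Only a single two-level factor is supported — the
designs this package targets are single-factor — so no strata or
sequential sums of squares.

Dispersion homogeneity follows Anderson's centroid procedure: embed all
PCoA axes, measure each row's distance to its group centroid with
squared contributions from negative-eigenvalue axes subtracted (clamped
at zero), then a one-way ANOVA F on those distances with a permutation p
obtained by shuffling the distances across groups. Group centroids (not
spatial medians) are used. An equivalent distance-only closed form,
z_i² = (1/n_g) Σ_j d²_ij − (1/n_g²) Σ_{j<k} d²_jk, serves as an
independent oracle in the tests.

PCoA is classical scaling (Gower double-centering, `eigh`); coordinates
span positive-eigenvalue axes only, negative eigenvalues are reported,
and proportion explained is taken over positive eigenvalues. Jaccard
matrices routinely produce small negative eigenvalues; they affect the
dispersion correction but not the plotted axes.

scikit-bio's `permanova`, `permdisp` and `pcoa` are used in the test
suite as independent cross-checks of the statistics, never as the
implementation (the implementation needs the full SS decomposition, R²,
seeded/exact permutation p and the centroid dispersion variant).

## Synthetic data

The generator emulates exactly the structure the salience threshold
assumes: a planted core of k items cited independently with probability
p_core (satellites: p_sat ≤ p_core) and recalled earlier via
Plackett–Luce sampling with log-weight `recall_bias` for core items
(sampled by the Gumbel trick; bias 0 = uniform order). Citation and
order are independent given the item sets; there is no informant-level
heterogeneity, no semantic clustering of recall, and no item covariance —
so passing calibration/recovery tests demonstrates correctness of the
machinery under the model's own assumptions, not robustness to the richer
structure of real interviews. Lists are redrawn (capped at 1000 attempts)
until `min_list_length` is met.

The default configuration is the package's reference power fixture: 60
informants, 50 items, 8 core items, p_core 0.8, p_sat 0.1, recall_bias 2.
The two-group generator shares `round(overlap·k)` core items between the
groups; non-shared core items of one group are ordinary satellites of the
other, so overlap 1 is an exact null for compositional tests and overlap
0 a strong alternative.

## Calibration and problem sizes

The statistical acceptance checks run at desk scale, chosen once:

* **Null calibration** — 500 replicates of a 30-informant, 40-item null
  dataset (lengths 5–12), each thresholded against B = 1000 null runs;
  the top-ranked item is falsely declared core in ≈ α = 5% of replicates
  (asserted within ±2 binomial SE).
* **Planted-core recovery** — 100 replicates of the power fixture,
  B = 1000; exact recovery of the 8 planted items required in ≥ 90.
* **End-to-end type-I / power** — 200 replicates each of the full
  pipeline on two 50-informant groups (B = 500 per group, 999
  permutations): rejection rate at α = 0.05 within 0.05 ± 2 SE at full
  core overlap; p at the 0.001 floor in ≥ 95% of replicates at zero
  overlap.

## Known limitations

* The pipeline tests one two-level factor; multi-factor, nested or
  abundance-weighted designs are out of scope.
* The null model treats informants as exchangeable and items as
  interchangeable; domains with strong informant heterogeneity will see
  a more dispersed null than this model simulates.
* Published rankings can be re-classified from their printed p columns,
  but their salience values themselves cannot be recomputed without the
  original ordered free lists, and the published PERMANOVA decompositions
  require the deposited participant × core-plant matrices.
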