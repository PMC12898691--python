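# Methods

## Profile model

The unit of analysis is a dense gene × species matrix of conservation
values. The raw value is the length-normalized bitscore ratio (LNPP):
best-hit bitscore of gene *g* in species *s* divided by the bitscore of
*g*'s human self-hit. Dividing by the self-hit corrects for protein
length; the ratio is clipped at a ceiling (default 1.0, configurable)
because a best hit can marginally exceed the self-hit, and conservation is
more interpretable when bounded in [0, 1]. Missing (gene, species) hit
records mean "no detectable homolog" and yield 0. Genes with zero values
across every species carry no information and are removed before any
normalization.

The per-species normalization (NPP) is, per species column,
log2(LNPP + ε) followed by standardization to mean 0, sd 1 across genes
(sample sd, ddof = 1). The log makes the heavy-tailed ratio scale roughly
symmetric; the column z-score removes the component of conservation that
every gene shares with the species — its phylogenetic distance from the
query — which would otherwise dominate all pairwise correlations. ε
(default 0.01) floors absent genes at log2(0.01) ≈ −6.6, a finite "absent"
level. Constant columns have no standardizable signal and map to zero with
a warning. A rank-based column transform is available
(`normalize_npp(..., method="rank")`) as a sensitivity alternative; the
z-score variant is the default and the one all defaults are calibrated
against. Standardization is computed over the full gene universe before
any clade restriction, mirroring how a precomputed matrix would be used.

Conservation per clade is judged on the raw LNPP values: a gene counts as
conserved when its value exceeds `value_floor` (default 0.05, i.e. ≥5% of
the self-hit score) in at least `min_fraction` (default 0.2) of the
clade's species. Both knobs are exposed; the defaults drop genes absent
from ≥80% of a clade, which keeps flat all-but-absent profiles out of the
correlation and null machinery. Non-conserved genes are excluded from both
the query correlations and the random-set background.

## Scores

For a clade-restricted query of N conserved genes, Pearson correlations
are computed between NPP profile rows across the clade's species.
Zero-variance profiles get r = 0 against all partners (they cannot
evidence co-evolution, and NaNs would otherwise propagate).

* **Threshold score** = 100 × #{pairs with r ≥ t} / (N(N−1)/2), t default
  0.7. The comparison is ≥ (not >) everywhere, including the network, for
  internal consistency; ties have measure zero on continuous data.
* **Cluster score**: complete-linkage agglomeration on d = 1 − r, cut at
  height h = 0.2. Complete linkage guarantees every within-cluster pair
  satisfies r ≥ 1 − h = 0.8 at the cut. The score is Σᵢ (sᵢ/c)² over
  cluster sizes sᵢ and cluster count c — squaring sizes up-weights large
  coherent modules, dividing by c² penalizes fragmentation. Two
  alternative algebraic readings (Σsᵢ²/c and Σsᵢ/c²) are selectable via
  `cluster_score(part, form=...)` for comparison; all defaults and tests
  use the fraction-squared form. For every N the single-cluster partition
  maximizes the score (Σ(sᵢ/c)² ≤ (Σsᵢ)²/c² = N²/c²).

Linkage is scipy's complete-linkage implementation; cluster labels are
relabelled by first gene occurrence, so identical inputs give identical
partitions across runs and platforms. The threshold score is most
informative for small sets; the cluster score is designed for larger sets
(> ~50 genes) that split into several independent modules.

## Significance

Each observed score is compared with R size-matched random gene sets
(default 1000) drawn uniformly without replacement from the clade's
conserved background (drawing from the full universe is available via
`null_background="all"`; restricting to conserved genes prevents deflated
nulls built from never-conserved flat profiles). Random sets are scored by
exactly the same code path as the query. The empirical p-value uses the
add-one estimator p = (1 + #{null ≥ obs}) / (R + 1): strictly positive,
with floor 1/(R+1), so significance is never overstated beyond the
permutation resolution. R is configurable upward when smaller p-values
are required. FDR is Benjamini–Hochberg across the clades tested in one
query, separately for the threshold-score and cluster-score p-vectors.

Because the threshold score of a small set takes few distinct values, the
null distribution is discrete; p-values are uniform only on the grid of
achievable values, and P(p ≤ α) can genuinely undershoot α when the grid
is chunky around the α-quantile. The calibration check therefore uses an
acceptance band ([0.02, 0.08] at α = 0.05 over 200 replicate queries)
rather than exact uniformity, and individual dataset realizations can
fall somewhat below the band's center.

A positive-control score is reported per clade: the threshold score of a
Krebs-cycle (TCA) gene set, a pathway with one of the strongest known
pathway-level co-evolution signals. When the query is larger than the
control, the control is padded with uniform random draws from the
background (excluding control members) to match size, since the threshold
score's null level depends on set size. Per-clade child seeds are derived
from the master seed and the clade name (CRC32 mix), so adding or
reordering clades never shifts another clade's random stream.

## Network

An edge connects two genes when r ≥ t in at least one clade; the edge
records every qualifying clade with its correlation. Edges are computed on
genes conserved per clade, unioned across the selected clades (per-clade
networks can be built by passing a single matrix). The export is one CSV
row per (edge, clade) with lexicographically ordered gene pairs and fully
sorted rows, so identical networks export identical bytes. Raising t
always yields a subgraph.

## Synthetic data

The generator emulates the features of a real conservation matrix that the
method exploits, with ground truth recorded:

* **Clade structure**: species come in named clades; baseline conservation
  decreases with the clade's distance rank (0.9, 0.75, 0.6, 0.45, …,
  floored at 0.15), mimicking the distance gradient the NPP normalization
  removes. Default panel: 4 clades of 100/50/25/25 species.
* **Lineage-specific losses**: with probability `loss_prob` (default 0.2)
  per gene and clade, the gene's block is scaled by a random retention
  depth in (0, 0.3) — partial rather than binary loss, emulating divergent
  or undetectable orthologs. Genes are generated independently, so
  inter-gene correlation arises only from chance sharing of loss patterns;
  this chance sharing is what gives the null score distribution realistic
  spread at the whole-matrix level.
* **Noise**: independent Gaussian noise (scale 0.08) per cell, truncation
  to [0, 1].
* **Planted modules**: all genes of a module share a latent per-species
  factor z_s in the designated clades; gene g receives
  √ρ·z_s + √(1−ρ)·e_gs. The mixture is built on the log2 conservation
  scale — the scale on which the analysis correlates profiles — and mapped
  back through 2^(μ + a·signal) − ε (μ = log2 0.56, a = 0.25), so the
  realized within-module correlation matches the target ρ both on raw
  values and after the pipeline's log transform (realized ≈ 0.90 at
  ρ = 0.9). Background genes and non-signal clades are untouched.
* All randomness flows from one spec seed through named substreams
  (CRC32-keyed), so the clade map, null matrix and modules are
  individually reproducible.

What the generator does **not** model: tree-structured species covariance
within clades, gene families/paralogy, genome-quality artifacts, and
correlated loss between different modules. Passing tests on synthetic data
therefore demonstrate the statistical machinery (calibration, recovery,
determinism), not detection power on real proteome panels, where
phylogenetic autocorrelation makes effective species counts smaller.

## Numerical and design choices

* Pearson matrices are symmetrized ((r + rᵀ)/2), clipped to [−1, 1], unit
  diagonal enforced; distances clipped at 0 before linkage.
* Duplicate (gene, species) bitscore records resolve to the maximum (best
  hit); gene symbols are uppercased everywhere; unknown query symbols are
  reported and skipped rather than fatal.
* Queries are capped at 100 matched genes (configurable), and clades with
  fewer than 3 conserved query genes are skipped with a logged reason —
  correlation and clustering are meaningless below that.
* The fast null scorer pre-standardizes profile rows once per clade, so a
  random set's correlation matrix is a small inner product; a test pins
  its agreement with the public per-set scorer.
* Problem sizes in the test and benchmark suites (e.g. 210 genes × 200
  species for the planted-module study, 1000 × 200 for calibration) are
  chosen as the smallest instances at which the studied effects are
  cleanly measurable.

## Limitations

* The per-species z-score is one reasonable realization of
  distance-normalization; published NPP pipelines differ in detail, so
  absolute score values are comparable only within one normalization
  choice.
* Empirical p-values are bounded below by 1/(R+1); claims like
  p < 0.0001 require R ≥ 10⁴.
* Only best-hit scores are used; paralogy can inflate pairwise
  correlations within gene families.
* FDR is computed across clades within one query; multi-query studies
  need their own correction layer.
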