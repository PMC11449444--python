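# Methods

## Scope and model

The package implements a temporal-phase analysis for two-structure
regeneration time courses. The measured object is a gene-level count matrix
per structure (jaw, limb) with two biological replicates per time point.
Time is unified to hours since injury (intact = 0 h; 5 dpi = 120 h;
3 hpa = 3 h) so the jaw grid {0, 120, 336, 840} and the limb grid
{0, 3, 6, 12, 24, 72, 120, 168, 240, 336, 504, 672} share one axis. The limb
grid is the package's representative dense early sampling for a 28-day
amputation course; labels (3hpa … 28dpa) are preserved for reporting.

## Normalization and filtering

CPM is plain library-size scaling (no between-sample scaling factors such as
TMM); the choice is surfaced as the only normalization and kept deliberately
simple. Filtering happens in four ordered stages with thresholds exposed in
`FilterConfig`:

| stage | statistic | default rule | computed on |
|---|---|---|---|
| mean | mean CPM | keep ≥ 0.8 | all samples |
| variance | sample variance, ddof 1 | keep ≥ 0.4 | all samples |
| maximum | max over time | keep > 20 CPM | replicate-averaged profile |
| ratio | max / max(min, ε) | keep > multiplier(min) | replicate-averaged profile |

The abundance-dependent multiplier is a non-increasing step function —
5 below 1 CPM, 3 below 5 CPM, 2 otherwise — demanding larger fold changes of
low-abundance genes, with an ε = 0.1 CPM floor so near-zero minima cannot
produce unbounded ratios. The exact functional form of such a multiplier is
a free design choice; the step function is fully specified, configurable,
and monotone (raising any threshold never enlarges the kept set, a property
the suite checks). Mean/variance use all samples (a *sample* variance);
max/min use the replicate-averaged profile (a property of the time course).
Boundary conventions are strict where the rule says "greater than"
(max > 20, score > 0.75) and weak complements elsewhere (mean ≥ 0.8).

## Standardization, k selection, clustering, scoring

Replicate averaging precedes z-scoring because the cluster objects of
interest are time profiles, not samples. Each kept gene's profile is
standardized with ddof 1; zero-variance profiles are rejected with the
offending ids (filtering makes them impossible in practice).

k is selected by the gap statistic with W_k the total within-cluster sum of
squared Euclidean distances:

    Gap(k) = (1/B) Σ_b log W*_kb − log W_k
    s_k    = sd_b(log W*_kb) · sqrt(1 + 1/B)

Reference datasets are uniform over the observed per-dimension range box
(the simplest reference in the method), B = 50 by default, all randomness
seeded. k\* is the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}, falling back
to argmax Gap when the rule never fires (it can, on gap curves that rise
monotonically through the search range). The default search range 1–15
matches the scale of cluster counts such time courses produce and leaves
k-means enough capacity to keep noise genes from forcing distinct temporal
shapes into one cluster.

k-means is Lloyd's algorithm with k-means++ initialization, best of
n_init = 25 restarts by inertia (scikit-learn's implementation; empty
clusters are re-seeded at the point farthest from its centroid). This is a
deliberate, reproducible contract — ecosystem defaults elsewhere (e.g.
Hartigan–Wong) may produce different but equally valid partitions, so exact
cluster counts are not comparable across implementations.

Each gene is scored by the Pearson correlation between its z-profile and its
cluster centroid; genes with r > 0.75 (strict) are the genes of interest. A
constant centroid has no defined correlation; its members score 0 and never
pass the threshold.

## Phase classification

Clusters are assigned to named phase groups by an explicit rule on the
centroid (visual grouping made deterministic):

1. peak at intact (argmax at 0 h) → **unassigned** (down-regulated);
2. peak at the final time *and* non-decreasing within τ (no step down by
   more than τ = 0.25 z-units) → **general rise**;
3. otherwise the phase bin whose half-open interval (lo, hi] contains the
   peak time; a non-monotone profile peaking at the final time goes to the
   last bin; a peak outside every bin is unassigned.

Jaw bins are (0,120], (120,336], (336,840] h ("5/14/35 dpi peak") — point
peaks on the jaw grid, intervals so off-grid centroid peaks remain
well-defined. Limb bins follow the quoted day ranges: early (0,72], mid
(72,336], late rise (336,672]. Genes inherit their cluster's label; genes in
unassigned clusters stay in the genes-of-interest universe but are excluded
from phase-restricted statistics. The rule is shift-invariant and invariant
to positive rescaling (with τ rescaled accordingly).

A structural degeneracy worth knowing: on a short grid, a clean peak at the
final time is monotone within tolerance and is therefore labelled general
rise — the last-bin "peak" label is reachable only by non-monotone profiles.
This is the intended reading of the rule, and it is why the default jaw
fixture plants peaks only at interior times.

## Cross-structure statistics

Shared genes are the exact intersection of the two genes-of-interest sets
(both structures are assumed quantified against one genome annotation; no
ortholog mapping). The overlap table reports, per jaw group g and limb group
h, count = |shared ∩ g ∩ h| and pct = 100·count/|shared ∩ g|; cells with an
empty denominator are missing, and per jaw group the cell counts plus the
shared genes sitting in unassigned limb clusters conserve the denominator.

The early-transient fraction of a gene set is the percentage with z-profile
argmax exactly at 3 hpa and z(1 dpa) ≤ z(intact) + tol, tol = 0 by default
("returned to basal levels or lower", basal = the intact value, on the
z scale; the tolerance is config-exposed for sensitivity analysis).

## Morphometry

Inputs are measurement tables (the output of manual tracing): lengths in mm,
polygon vertices and angle landmarks in mm coordinates. Relative defect
size is 100·defect/hemimandible and 100·defect/full-mandible perimeter,
with cohort summaries as plain means over animals; polygon area is the
shoelace formula (absolute value); the stump-displacement angle is the
interior angle at the resection-margin vertex in [0, 180]°; perimeter change
is 100·(intact − resected)/intact. Closed defects are explicit zero records,
not missing values. Significance testing (ANOVA with post-hoc corrections)
is intentionally left to standard statistical software; the module emits
tidy per-time-point tables ready for it.

## Synthetic data: what it emulates, and what it does not

`simulate_counts` draws counts NB(mean m, dispersion φ) with
m = μ_g(t)·library/10⁶ and var = m + φm² (φ = 0 → Poisson; default φ = 0.05,
a typical biological-replicate dispersion for bulk RNA-seq). Expected CPM
trajectories come from archetypes:

* **gaussian-peak**(peak, width): rise to amplitude_fold × baseline and back;
* **logistic-rise**(midpoint, slope): monotone sigmoid, normalized to peak at
  the last time;
* **intact-decline**(τ): exponential decay from the intact maximum —
  transcription stops at injury and the transcript decays (time constant
  150 h jaw, 48 h limb);
* **flat**: constant expectation (pure noise).

Per-gene lognormal baseline jitter (σ = 0.25 log-units) varies absolute
levels without changing shapes. A 2000-gene flat background block at
~450 CPM carries most of the library so per-sample totals are dominated by
stable genes — without it, the planted programme itself dominates the
library and CPM becomes strongly compositional, distorting every profile
whenever one block peaks. Library sizes are heterogeneous
(1.5–2.5 M counts), a deliberately scaled-down sequencing depth that keeps
per-gene counts in a realistic CPM-to-count ratio.

Default fixtures plant two replicates per time point and the archetype
census a regeneration course would show: interior-time peaks, a general
rise, down-regulated decline, and flat noise. The limb early group is split
60/40 into a sharp 3-hpa transient (sd 2 h — an immediate-early wound
response, gone by 12 hpa) and a sustained 36-hpa peak, so the
early-transient statistic has planted structure (~60%). Archetype shapes
were chosen so that all planted z-profiles are mutually well separated
(pairwise centroid distances ≳ 2.5 in z-space); the constructed guarantee
that clean archetypes are recovered (≥ 95% of planted phase labels among
genes of interest) holds by design, and the suite verifies it end to end.

`simulate_paired` draws both structures over one shared gene universe with a
fixed joint allocation (`PAIRED_JOINT`) emulating the cross-structure
correspondence a shared regenerative programme produces: most jaw
first-peak genes behave as limb early-peak genes (mostly 3-hpa transients),
the jaw mid peak splits between limb early and mid peaks, and the jaw
general rise maps mostly onto the limb mid peak — the slower structure
lagging the faster one.

What passing tests on these fixtures show: the pipeline's stages implement
their definitions exactly (oracle equivalence), the gap statistic recovers
planted k on well-separated archetypes, and the end-to-end chain recovers
planted phase structure under NB noise at the study's replicate count. What
they do not show: behaviour under batch effects, unmodelled library
composition shifts, ambiguous intermediate temporal shapes, or annotation
mismatches between structures — real-data properties the generator does not
emulate.

`simulate_morphometry` follows the observed closure dynamics as a piecewise
curve: contraction within 1 dpi, a plateau to 5 dpi, second closure from
7 dpi, zero area from 35 dpi (explicit zeros), an angle minimum at 35 dpi
with recovery by 90 dpi, and a 90-dpi resected perimeter ~9% below the
intact control; Gaussian measurement noise (sd 0.2 mm) on lengths.

## Numerical choices and degenerate inputs

Variances and standard deviations use ddof 1 throughout. Ratio filtering
floors the denominator at ε = 0.1 CPM. Pearson scores with undefined
correlation (constant centroid) are 0. argmax ties resolve to the earliest
time (numpy convention) — relevant only for exactly tied centroids. The
summary JSON rounds floats to 4–6 decimals and sorts keys, making replays
byte-comparable; all randomness (simulation, gap references, k-means
restarts) flows from explicit seeds, and reruns with the same config and
seed are byte-identical.

## Known limitations

* Exact cluster counts from other k-means variants or gap-reference choices
  will differ; only the contract here (Lloyd, k-means++, range-box uniform
  reference, first-crossing rule) is reproducible.
* The phase rule labels edge-case centroids (near-monotone late peaks,
  plateaus at intact) by hard thresholds; τ is exposed precisely because
  such centroids exist in real data.
* CPM carries no compositional correction; strongly asymmetric programmes
  could bias profiles in real data.
* The morphometry module reproduces the arithmetic downstream of manual
  tracing only; tracing itself (and its observer variance) is out of scope.
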