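# regenphase

Temporal-phase analysis of regeneration time-course RNA-seq, built around the
axolotl (*Ambystoma mexicanum*) mandible-vs-limb comparison: both structures
regenerate through shared molecular phases — wound response, blastema
formation, then differentiation — but on different clocks, and this package
provides the full computational chain used to show that, as a tested,
reusable library with a CLI.

## What it computes

Starting from gene-level count matrices (genes × samples) with sample
metadata (structure ∈ {jaw, limb}, time point, replicate):

1. **CPM normalization** — counts per million, plain library-size scaling:
   `CPM_gs = counts_gs / Σ_g counts_gs × 10⁶`.
2. **Expression filtering** — four stages: mean CPM ≥ 0.8; sample variance
   (ddof = 1) ≥ 0.4; profile maximum > 20 CPM; and a max/min fold-change that
   must exceed an abundance-dependent multiplier (5× below 1 CPM, 3× below
   5 CPM, 2× otherwise).
3. **Z-scoring** — each gene's replicate-averaged time profile is
   standardized to mean 0 / sd 1 so clustering compares shapes.
4. **Gap-statistic k-means** — the number of clusters k is chosen by the gap
   statistic, `Gap(k) = E*[log W_k] − log W_k`, comparing the within-cluster
   dispersion `W_k` against B uniform reference datasets over the data's
   range box; k\* is the smallest k with `Gap(k) ≥ Gap(k+1) − s_{k+1}`.
   Genes with Pearson r > 0.75 to their cluster centroid become the **genes
   of interest**.
5. **Phase groups** — each cluster centroid is labelled by an explicit
   peak/monotonicity rule: peak at intact → unassigned (down-regulated);
   monotone rise to the final time → *general rise*; otherwise the time bin
   containing the peak (jaw: *5/14/35 dpi peak*; limb: *early* 3 hpa–3 dpa,
   *mid* 3–14 dpa, *late rise* 14–28 dpa).
6. **Cross-structure comparison** — shared genes (set intersection of the
   two genes-of-interest lists), the overlap-percentage matrix (what share of
   each jaw group's shared genes falls into each limb group), and the
   early-transient fraction (genes peaking at 3 hpa and back to basal by
   1 dpa in the limb).
7. **Morphometry** — relative defect size, shoelace polygon area,
   stump-displacement angle, and perimeter change for resection cohorts.

A negative-binomial simulator (`regenphase.synthetic`) generates count
matrices with planted temporal archetypes — including a paired jaw/limb mode
over one shared gene universe — so the entire pipeline is testable without
sequencing data.

## Worked example

```sh
regenphase simulate --structure paired --seed 1 --out-dir fixtures/
regenphase run --config config.yaml
```

with `config.yaml`:

```yaml
out_dir: out
counts:
  jaw: fixtures/jaw_counts.tsv
  limb: fixtures/limb_counts.tsv
metadata:
  jaw: fixtures/jaw_metadata.tsv
  limb: fixtures/limb_metadata.tsv
clustering:
  seed: 1
```

or equivalently, in Python:

```python
from regenphase import pipeline, synthetic

jaw_cm, jaw_truth, limb_cm, limb_truth = synthetic.simulate_paired(seed=1)
cfg = pipeline.ClusteringConfig(seed=1)
jaw = pipeline.analyze_structure(jaw_cm, "jaw", cluster_cfg=cfg)
limb = pipeline.analyze_structure(limb_cm, "limb", cluster_cfg=cfg)
comp = pipeline.compare_structures(jaw, limb)
print(len(jaw.goi), len(limb.goi), len(comp.shared.genes))
print(round(comp.shared.pct_of_jaw, 2), round(comp.early_transient_pct, 2))
```

prints

```
247 310 163
65.99 61.11
```

meaning: of 2420 simulated genes, 247 jaw and 310 limb genes survive the
filters and correlate with their cluster centroid at r > 0.75; 163 genes
(65.99% of the jaw list) are shared between the structures; and 61.11% of the
shared genes in the (jaw first-peak × limb early-peak) cell spike at 3 hours
post amputation and return to basal by 1 day — the wound-response genes the
slower structure keeps expressing for days. The full stage-by-stage output
(filter survivor counts, gap curves, cluster→phase labels, the overlap
matrix) lands in `out/summary.json` and per-stage TSVs.

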