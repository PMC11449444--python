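"""End-to-end orchestration: normalize -> filter -> z-score -> cluster ->
phase -> compare, with machine-readable outputs.

``analyze_structure`` runs one structure from a count matrix to a phase
assignment; ``compare_structures`` computes the shared-gene statistics
between two analyzed structures; ``run_pipeline`` drives both from a config
(paths or in-memory matrices) and writes every stage's table plus a
``summary.json`` that records all counts, seeds and thresholds used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from regenphase import clustering, comparison, expression, filtering, phasing
from regenphase.exceptions import ConfigError
from regenphase.expression import CountMatrix

logger = logging.getLogger("regenphase")


@dataclass
class ClusteringConfig:
    k: int | str = "auto"  # "auto" = gap statistic, or a fixed integer
    k_min: int = 1
    k_max: int = 15
    B: int = 50
    n_init: int = 25
    theta_r: float = 0.75
    seed: int = 0


@dataclass
class StructureResult:
    structure: str
    cpm: expression.CpmMatrix
    profile: expression.TimeProfile
    filter_report: filtering.FilterReport
    zprofile: clustering.ZProfile
    gap: clustering.GapResult | None
    clusters: clustering.ClusterResult
    goi: set[str]
    phases: phasing.PhaseAssignment


def analyze_structure(
    cm: CountMatrix,
    structure: str,
    filter_cfg: filtering.FilterConfig | None = None,
    cluster_cfg: ClusteringConfig | None = None,
    phase_cfg: phasing.PhaseConfig | None = None,
) -> StructureResult:
    """Run one structure from raw counts to gene-phase labels."""
    filter_cfg = filter_cfg or filtering.FilterConfig()
    cluster_cfg = cluster_cfg or ClusteringConfig()
    phase_cfg = phase_cfg or phasing.default_config(structure)

    cpm = expression.compute_cpm(cm)
    tp = expression.average_replicates(cpm, structure)
    report = filtering.apply_filters(cpm, tp, filter_cfg)
    logger.info(
        "%s: %d genes in, survivors per stage %s",
        structure,
        report.n_input,
        report.n_after_each_stage,
    )
    kept = expression.TimeProfile(
        values=tp.values.loc[report.kept_gene_ids],
        structure=structure,
        time_labels=tp.time_labels,
    )
    zp = clustering.zscore_profiles(kept)

    gap = None
    if cluster_cfg.k == "auto":
        gap = clustering.select_k_gap(
            zp,
            k_min=cluster_cfg.k_min,
            k_max=cluster_cfg.k_max,
            B=cluster_cfg.B,
            seed=cluster_cfg.seed,
        )
        k = gap.k_star
        logger.info("%s: gap statistic selected k=%d", structure, k)
    else:
        k = int(cluster_cfg.k)
    cr = clustering.cluster_kmeans(zp, k, seed=cluster_cfg.seed, n_init=cluster_cfg.n_init)
    goi = clustering.select_genes_of_interest(cr, theta_r=cluster_cfg.theta_r)
    pa = phasing.assign_gene_phases(cr, goi, phase_cfg)
    return StructureResult(
        structure=structure,
        cpm=cpm,
        profile=tp,
        filter_report=report,
        zprofile=zp,
        gap=gap,
        clusters=cr,
        goi=goi,
        phases=pa,
    )


@dataclass
class ComparisonResult:
    shared: comparison.SharedGenes
    overlap: comparison.OverlapTable
    early_transient_pct: float | None
    transient_gene_count: int


def compare_structures(jaw: StructureResult, limb: StructureResult) -> ComparisonResult:
    """Shared genes, the overlap-percentage table and the early-transient
    fraction of the (jaw first-peak x limb early-peak) shared genes."""
    shared = comparison.intersect_goi(jaw.goi, limb.goi)
    table = comparison.overlap_percentages(jaw.phases, limb.phases, shared.genes)
    jaw_first = jaw.phases.config.bins[0][0]
    limb_first = limb.phases.config.bins[0][0]
    focus = shared.genes & jaw.phases.genes_in(jaw_first) & limb.phases.genes_in(limb_first)
    transient = comparison.early_transient_fraction(focus, limb.zprofile)
    return ComparisonResult(
        shared=shared,
        overlap=table,
        early_transient_pct=transient,
        transient_gene_count=len(focus),
    )


@dataclass
class PipelineConfig:
    out_dir: str
    counts: dict[str, str] = field(default_factory=dict)  # structure -> path
    metadata: dict[str, str] = field(default_factory=dict)
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    monotone_tolerance: float = 0.25
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "out_dir",
            "counts",
            "metadata",
            "filter",
            "clustering",
            "monotone_tolerance",
            "log_level",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        filt = filtering.FilterConfig(**raw.get("filter", {}))
        clus = ClusteringConfig(**raw.get("clustering", {}))
        return cls(
            out_dir=raw["out_dir"],
            counts=raw.get("counts", {}),
            metadata=raw.get("metadata", {}),
            filter=filt,
            clustering=clus,
            monotone_tolerance=raw.get("monotone_tolerance", 0.25),
            log_level=raw.get("log_level", "INFO"),
        )


def _summary_dict(results: dict[str, StructureResult], comp: ComparisonResult | None) -> dict:
    out: dict = {"structures": {}, "comparison": None}
    for structure, res in results.items():
        gap = res.gap
        out["structures"][structure] = {
            "n_genes_input": res.filter_report.n_input,
            "survivors_per_stage": res.filter_report.n_after_each_stage,
            "k": res.clusters.k,
            "k_mode": "gap" if gap is not None else "fixed",
            "gap_curve": None
            if gap is None
            else {
                "k_candidates": gap.k_candidates,
                "gap": [round(float(g), 6) for g in gap.gap],
                "s_k": [round(float(s), 6) for s in gap.s_k],
                "B": gap.B,
            },
            "seed": res.clusters.seed,
            "n_genes_of_interest": len(res.goi),
            "phase_group_sizes": {
                label: int((res.phases.gene_phase == label).sum())
                for label in sorted(set(res.phases.gene_phase))
            },
            "cluster_phases": {str(c): p for c, p in sorted(res.phases.cluster_phase.items())},
        }
    if comp is not None:
        out["comparison"] = {
            "n_shared": len(comp.shared.genes),
            "shared_pct_of_jaw": round(comp.shared.pct_of_jaw, 4),
            "overlap_counts": {
                g: {h: int(comp.overlap.counts.loc[g, h]) for h in comp.overlap.limb_groups}
                for g in comp.overlap.jaw_groups
            },
            "overlap_pct": {
                g: {
                    h: None
                    if comp.overlap.pct.loc[g, h] != comp.overlap.pct.loc[g, h]
                    else round(float(comp.overlap.pct.loc[g, h]), 4)
                    for h in comp.overlap.limb_groups
                }
                for g in comp.overlap.jaw_groups
            },
            "n_shared_in_jaw_group": comp.overlap.n_shared_in_jaw_group,
            "early_transient_pct": None
            if comp.early_transient_pct is None
            else round(comp.early_transient_pct, 4),
            "early_transient_n": comp.transient_gene_count,
        }
    return out


def run_pipeline(
    cfg: PipelineConfig,
    matrices: dict[str, CountMatrix] | None = None,
) -> dict:
    """Execute the full chain and write per-stage tables plus summary.json.

    Count matrices are read from ``cfg.counts``/``cfg.metadata`` unless
    passed in-memory via ``matrices``.  Jaw-only configs skip the
    comparison stage.  Returns the summary dictionary.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if matrices is None:
        matrices = {}
        for structure, path in cfg.counts.items():
            meta_path = cfg.metadata.get(structure)
            if meta_path is None:
                raise ConfigError(f"no metadata path for structure {structure!r}")
            matrices[structure] = expression.read_counts(path, meta_path)
    if not matrices:
        raise ConfigError("no input count matrices")

    results: dict[str, StructureResult] = {}
    for structure, cm in matrices.items():
        try:
            res = analyze_structure(
                cm,
                structure,
                filter_cfg=cfg.filter,
                cluster_cfg=cfg.clustering,
                phase_cfg=phasing.PhaseConfig(
                    structure=structure,
                    bins=phasing.default_config(structure).bins,
                    monotone_tolerance=cfg.monotone_tolerance,
                ),
            )
        except Exception as exc:
            raise RuntimeError(f"stage failure while analyzing {structure!r}: {exc}") from exc
        results[structure] = res
        filtering.write_report(res.filter_report, out_dir / f"{structure}_filter_report.tsv")
        clustering.write_clusters(res.clusters, out_dir / f"{structure}_clusters.tsv")
        if res.gap is not None:
            clustering.write_gap(res.gap, out_dir / f"{structure}_gap.tsv")
        phasing.write_phases(res.phases, res.clusters, out_dir / f"{structure}_phases.tsv")
        phasing.write_gene_phases(res.phases, out_dir / f"{structure}_gene_phases.tsv")
        expression.write_time_profile(res.profile, out_dir / f"{structure}_time_profile.tsv")

    comp = None
    if "jaw" in results and "limb" in results:
        comp = compare_structures(results["jaw"], results["limb"])
        comparison.write_overlap(comp.overlap, out_dir / "overlap.tsv")

    summary = _summary_dict(results, comp)
    summary["config"] = {
        "filter": {
            "theta_mean": cfg.filter.theta_mean,
            "theta_var": cfg.filter.theta_var,
            "theta_max": cfg.filter.theta_max,
            "ratio_floor_epsilon": cfg.filter.ratio_floor_epsilon,
        },
        "clustering": {
            "k": cfg.clustering.k,
            "k_min": cfg.clustering.k_min,
            "k_max": cfg.clustering.k_max,
            "B": cfg.clustering.B,
            "n_init": cfg.clustering.n_init,
            "theta_r": cfg.clustering.theta_r,
            "seed": cfg.clustering.seed,
        },
        "monotone_tolerance": cfg.monotone_tolerance,
    }
    with open(out_dir / "summary.json", "w", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
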