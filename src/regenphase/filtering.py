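"""Expression filters defining candidate genes before clustering.

Four stages, applied in order:

1.  mean:     drop genes with mean CPM (over all samples) below ``theta_mean``;
2.  variance: drop genes with sample variance (ddof=1, over all samples)
              below ``theta_var``;
3.  maximum:  drop genes whose replicate-averaged profile never exceeds
              ``theta_max`` CPM;
4.  ratio:    drop genes whose max/min CPM fold change (on the averaged
              profile) does not surpass an abundance-dependent multiplier —
              low-abundance genes must show a larger fold change.

Stages 1-2 act on the per-sample CPM matrix (replicates included, because the
variance is a sample variance); stages 3-4 act on the replicate-averaged time
profile, where max and min are taken over time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from regenphase.exceptions import ConfigError, ConsistencyError, ParameterError
from regenphase.expression import CpmMatrix, TimeProfile

#: default abundance-dependent fold-change requirement: (upper bound on min CPM,
#: required multiplier), evaluated in order; stricter folds at lower abundance.
DEFAULT_MULTIPLIER_STEPS: tuple[tuple[float, float], ...] = (
    (1.0, 5.0),
    (5.0, 3.0),
    (float("inf"), 2.0),
)


@dataclass
class FilterConfig:
    theta_mean: float = 0.8
    theta_var: float = 0.4
    theta_max: float = 20.0
    multiplier_steps: tuple[tuple[float, float], ...] = DEFAULT_MULTIPLIER_STEPS
    ratio_floor_epsilon: float = 0.1

    def __post_init__(self) -> None:
        if min(self.theta_mean, self.theta_var, self.theta_max) <= 0:
            raise ConfigError("filter thresholds must be > 0")
        if self.ratio_floor_epsilon <= 0:
            raise ConfigError("ratio_floor_epsilon must be > 0")
        bounds = [b for b, _ in self.multiplier_steps]
        if bounds != sorted(bounds) or any(m < 1 for _, m in self.multiplier_steps):
            raise ConfigError("multiplier steps must have increasing bounds and values >= 1")
        if bounds[-1] != float("inf"):
            raise ConfigError("last multiplier step must cover all minima (bound inf)")

    def ratio_multiplier(self, min_cpm: float) -> float:
        """Required max/min fold change given a gene's minimum CPM."""
        for bound, mult in self.multiplier_steps:
            if min_cpm < bound:
                return mult
        raise AssertionError("unreachable: last bound is inf")


@dataclass
class FilterReport:
    n_input: int
    n_after_each_stage: list[int]
    kept_gene_ids: list[str]
    stage_names: list[str] = field(
        default_factory=lambda: ["mean", "variance", "max", "ratio"]
    )


def prefilter_low_info(cpm: CpmMatrix, cfg: FilterConfig) -> set[str]:
    """Genes passing both the mean and variance floors on per-sample CPM."""
    if cpm.cpm.shape[1] < 2:
        raise ParameterError("variance undefined with fewer than 2 samples")
    mean = cpm.cpm.mean(axis=1)
    var = cpm.cpm.var(axis=1, ddof=1)
    keep = (mean >= cfg.theta_mean) & (var >= cfg.theta_var)
    return set(cpm.cpm.index[keep])


def strict_filter(tp: TimeProfile, cfg: FilterConfig) -> set[str]:
    """Genes passing the maximum-expression and abundance-scaled ratio stages."""
    vmax = tp.values.max(axis=1)
    vmin = tp.values.min(axis=1)
    mult = vmin.map(cfg.ratio_multiplier)
    ratio = vmax / np.maximum(vmin, cfg.ratio_floor_epsilon)
    keep = (vmax > cfg.theta_max) & (ratio > mult)
    return set(tp.values.index[keep])


def apply_filters(cpm: CpmMatrix, tp: TimeProfile, cfg: FilterConfig | None = None) -> FilterReport:
    """Run all four stages in order and report survivor counts per stage."""
    cfg = cfg or FilterConfig()
    if set(cpm.cpm.index) != set(tp.values.index):
        raise ConsistencyError("CPM matrix and time profile carry different gene ids")
    genes = list(cpm.cpm.index)
    if not genes:
        return FilterReport(n_input=0, n_after_each_stage=[0, 0, 0, 0], kept_gene_ids=[])

    mean = cpm.cpm.mean(axis=1)
    var = cpm.cpm.var(axis=1, ddof=1)
    after_mean = [g for g in genes if mean[g] >= cfg.theta_mean]
    after_var = [g for g in after_mean if var[g] >= cfg.theta_var]

    vmax = tp.values.max(axis=1)
    vmin = tp.values.min(axis=1)
    after_max = [g for g in after_var if vmax[g] > cfg.theta_max]
    after_ratio = [
        g
        for g in after_max
        if vmax[g] / max(vmin[g], cfg.ratio_floor_epsilon) > cfg.ratio_multiplier(vmin[g])
    ]
    return FilterReport(
        n_input=len(genes),
        n_after_each_stage=[len(after_mean), len(after_var), len(after_max), len(after_ratio)],
        kept_gene_ids=after_ratio,
    )


def write_report(report: FilterReport, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("stage\tn_remaining\n")
        fh.write(f"input\t{report.n_input}\n")
        for name, n in zip(report.stage_names, report.n_after_each_stage):
            fh.write(f"{name}\t{n}\n")
        fh.write("kept_gene_id\n")
        for g in report.kept_gene_ids:
            fh.write(f"{g}\n")
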