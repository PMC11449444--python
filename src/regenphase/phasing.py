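"""Assign k-means clusters to named temporal phase groups.

Cluster centroids (z-space profiles over time) are classified by an explicit
peak-position/monotonicity rule:

1.  peak at the intact time point (0 h)            -> 'unassigned'
    (down-regulated pattern, excluded from the named groups);
2.  peak at the final time point AND non-decreasing within a tolerance
    tau (no step down by more than tau z-units)    -> 'general rise';
3.  otherwise, the phase bin whose time interval contains the peak;
    a non-monotone profile peaking at the final time falls in the last
    bin, and a peak outside every bin is 'unassigned'.

Jaw bins cover the 5/14/35 days-post-injury peaks; limb bins cover
'early peak' (3 h - 3 days post amputation), 'mid peak' (3-14 dpa) and
'late rise' (14-28 dpa), as half-open (lo, hi] intervals in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regenphase.clustering import ClusterResult
from regenphase.exceptions import ConfigError, ConsistencyError

UNASSIGNED = "unassigned"
GENERAL_RISE = "general rise"

HOURS_PER_DAY = 24.0


@dataclass
class PhaseConfig:
    structure: str
    bins: list[tuple[str, float, float]]  # (label, lo, hi], hours
    rise_label: str = GENERAL_RISE
    monotone_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if self.monotone_tolerance < 0:
            raise ConfigError("monotone_tolerance must be >= 0")
        prev_hi = -np.inf
        for label, lo, hi in self.bins:
            if not lo < hi:
                raise ConfigError(f"bin {label!r} has empty interval ({lo}, {hi}]")
            if lo < prev_hi:
                raise ConfigError("phase bins must be ordered and non-overlapping")
            prev_hi = hi

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.bins] + [self.rise_label]


def jaw_default() -> PhaseConfig:
    return PhaseConfig(
        structure="jaw",
        bins=[
            ("5 dpi peak", 0.0, 5 * HOURS_PER_DAY),
            ("14 dpi peak", 5 * HOURS_PER_DAY, 14 * HOURS_PER_DAY),
            ("35 dpi peak", 14 * HOURS_PER_DAY, 35 * HOURS_PER_DAY),
        ],
    )


def limb_default() -> PhaseConfig:
    return PhaseConfig(
        structure="limb",
        bins=[
            ("early peak", 0.0, 3 * HOURS_PER_DAY),
            ("mid peak", 3 * HOURS_PER_DAY, 14 * HOURS_PER_DAY),
            ("late rise", 14 * HOURS_PER_DAY, 28 * HOURS_PER_DAY),
        ],
    )


def default_config(structure: str) -> PhaseConfig:
    if structure == "jaw":
        return jaw_default()
    if structure == "limb":
        return limb_default()
    raise ConfigError(f"no default phase bins for structure {structure!r}")


@dataclass
class PhaseAssignment:
    cluster_phase: dict[int, str]
    gene_phase: pd.Series  # gene -> label, genes of interest only
    config: PhaseConfig = field(repr=False, default=None)

    def genes_in(self, label: str) -> set[str]:
        return set(self.gene_phase.index[self.gene_phase == label])


def classify_centroid(centroid, times, cfg: PhaseConfig) -> str:
    """Label one centroid by the peak/monotonicity rule described above."""
    centroid = np.asarray(centroid, dtype=float)
    times = np.asarray(times, dtype=float)
    if centroid.shape != times.shape:
        raise ConsistencyError("centroid and times must have the same length")
    if len(times) < 3:
        raise ConsistencyError("need at least 3 time points to classify a centroid")
    peak = int(np.argmax(centroid))
    if peak == 0:
        return UNASSIGNED
    steps = np.diff(centroid)
    monotone = bool((steps >= -cfg.monotone_tolerance).all())
    if peak == len(times) - 1:
        if monotone:
            return cfg.rise_label
        return cfg.bins[-1][0]
    t_peak = times[peak]
    for label, lo, hi in cfg.bins:
        if lo < t_peak <= hi:
            return label
    return UNASSIGNED


def assign_gene_phases(cr: ClusterResult, goi, cfg: PhaseConfig) -> PhaseAssignment:
    """Label every cluster and map each gene of interest to its cluster's label.

    Genes in 'unassigned' clusters stay in the genes-of-interest universe but
    carry the 'unassigned' label, excluding them from phase-restricted
    statistics.
    """
    goi = set(goi)
    missing = goi - set(cr.assignment.index)
    if missing:
        raise ConsistencyError(f"genes of interest not in clustering: {sorted(missing)[:5]}")
    times = np.asarray(cr.centroids.columns, dtype=float)
    cluster_phase = {
        int(c): classify_centroid(cr.centroids.loc[c].to_numpy(), times, cfg)
        for c in cr.centroids.index
    }
    goi_sorted = [g for g in cr.assignment.index if g in goi]
    gene_phase = pd.Series(
        [cluster_phase[int(cr.assignment[g])] for g in goi_sorted],
        index=goi_sorted,
        name="phase",
    )
    return PhaseAssignment(cluster_phase=cluster_phase, gene_phase=gene_phase, config=cfg)


def write_phases(pa: PhaseAssignment, cr: ClusterResult, path) -> None:
    times = np.asarray(cr.centroids.columns, dtype=float)
    rows = []
    for c in sorted(pa.cluster_phase):
        peak_t = times[int(np.argmax(cr.centroids.loc[c].to_numpy()))]
        n = int((pa.gene_phase.index.map(lambda g: int(cr.assignment[g])) == c).sum())
        rows.append({"cluster": c, "label": pa.cluster_phase[c], "peak_time_hours": peak_t, "n_genes": n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_gene_phases(pa: PhaseAssignment, path) -> None:
    out = pa.gene_phase.to_frame()
    out.insert(0, "structure", pa.config.structure if pa.config else "")
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
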