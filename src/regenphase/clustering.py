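"""Z-scoring, gap-statistic model selection, k-means and cluster scoring.

Each gene's replicate-averaged time profile is standardized to mean 0 /
sd 1 (ddof=1) so clustering compares shapes, not magnitudes.  The number of
clusters is chosen by the gap statistic: the within-cluster dispersion
``W_k`` of the data is compared, on a log scale, against ``B`` reference
datasets drawn uniformly over the per-dimension range box of the data,

    Gap(k) = mean_b log(W*_kb) - log(W_k),
    s_k    = sd_b(log W*_kb) * sqrt(1 + 1/B),

and the selected k* is the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}
(argmax of the gap curve if the rule never fires).  Genes are then retained
as "genes of interest" when the Pearson correlation between their z-profile
and their cluster centroid exceeds a threshold (default 0.75, strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from regenphase.exceptions import ParameterError
from regenphase.expression import TimeProfile


@dataclass
class ZProfile:
    """Row-standardized time profiles: each row mean 0, sd 1 (ddof=1)."""

    z: pd.DataFrame  # genes x times
    structure: str

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.z.columns, dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    def subset(self, genes) -> "ZProfile":
        return ZProfile(z=self.z.loc[list(genes)], structure=self.structure)


@dataclass
class GapResult:
    k_candidates: list[int]
    gap: np.ndarray
    s_k: np.ndarray
    log_wk: np.ndarray
    B: int
    k_star: int
    seed: int


@dataclass
class ClusterResult:
    k: int
    assignment: pd.Series  # gene -> cluster id in 1..k
    centroids: pd.DataFrame  # k x times, index 1..k
    score: pd.Series  # gene -> Pearson r to own centroid
    inertia: float
    seed: int


def zscore_profiles(tp: TimeProfile) -> ZProfile:
    """Standardize each gene's profile across time points (ddof=1)."""
    values = tp.values.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    zero = sd <= 0
    if zero.any():
        offenders = [g for g, z in zip(tp.values.index, zero) if z]
        raise ParameterError(f"zero-variance profiles cannot be z-scored: {offenders}")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ZProfile(
        z=pd.DataFrame(z, index=tp.values.index, columns=tp.values.columns),
        structure=tp.structure,
    )


def _fit_kmeans(x: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    km.fit(x)
    return km


def select_k_gap(
    zp: ZProfile,
    k_min: int = 1,
    k_max: int = 10,
    B: int = 50,
    seed: int = 0,
    n_init: int = 10,
    ref_n_init: int = 1,
) -> GapResult:
    """Choose the number of clusters by the gap statistic.

    Reference datasets are sampled uniformly over the observed per-dimension
    range box of the z-profiles; all randomness derives from ``seed``.
    """
    x = zp.z.to_numpy(dtype=float)
    n = x.shape[0]
    if k_max >= n:
        raise ParameterError(f"k_max={k_max} must be below the number of genes ({n})")
    if k_min < 1 or k_min > k_max:
        raise ParameterError("need 1 <= k_min <= k_max")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks = list(range(k_min, k_max + 1))

    log_wk = np.empty(len(ks))
    for i, k in enumerate(ks):
        log_wk[i] = np.log(_fit_kmeans(x, k, seed, n_init).inertia_)

    log_wkb = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=x.shape)
        ref_seed = int(rng.integers(2**31 - 1))
        for i, k in enumerate(ks):
            log_wkb[b, i] = np.log(_fit_kmeans(ref, k, ref_seed, ref_n_init).inertia_)

    gap = log_wkb.mean(axis=0) - log_wk
    s_k = log_wkb.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)

    k_star = ks[int(np.argmax(gap))]
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            k_star = ks[i]
            break
    return GapResult(
        k_candidates=ks, gap=gap, s_k=s_k, log_wk=log_wk, B=B, k_star=k_star, seed=seed
    )


def pearson_to_centroid(z: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between each profile and its assigned centroid."""
    own = centroids[labels]
    zc = z - z.mean(axis=1, keepdims=True)
    cc = own - own.mean(axis=1, keepdims=True)
    num = (zc * cc).sum(axis=1)
    den = np.sqrt((zc**2).sum(axis=1) * (cc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    # a constant centroid has no defined correlation; such genes never pass
    # the score threshold, so report 0
    return np.where(np.isfinite(r), r, 0.0)


def cluster_kmeans(zp: ZProfile, k: int, seed: int = 0, n_init: int = 25) -> ClusterResult:
    """Lloyd k-means (k-means++ init, best of ``n_init`` restarts) on z-profiles.

    Empty clusters are re-seeded internally at the point farthest from its
    centroid, so every cluster id 1..k is populated in well-posed inputs.
    Deterministic for a fixed seed.
    """
    x = zp.z.to_numpy(dtype=float)
    if not 1 <= k <= x.shape[0]:
        raise ParameterError(f"k={k} outside [1, {x.shape[0]}]")
    km = _fit_kmeans(x, k, seed, n_init)
    labels = km.labels_
    score = pearson_to_centroid(x, km.cluster_centers_, labels)
    return ClusterResult(
        k=k,
        assignment=pd.Series(labels + 1, index=zp.z.index, name="cluster"),
        centroids=pd.DataFrame(
            km.cluster_centers_, index=range(1, k + 1), columns=zp.z.columns
        ),
        score=pd.Series(score, index=zp.z.index, name="score"),
        inertia=float(km.inertia_),
        seed=seed,
    )


def select_genes_of_interest(cr: ClusterResult, theta_r: float = 0.75) -> set[str]:
    """Genes whose Pearson cluster score strictly exceeds ``theta_r``."""
    return set(cr.score.index[cr.score > theta_r])


def write_clusters(cr: ClusterResult, path) -> None:
    out = pd.DataFrame({"cluster": cr.assignment, "score": cr.score})
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def write_gap(gr: GapResult, path) -> None:
    out = pd.DataFrame({"k": gr.k_candidates, "gap": gr.gap, "s_k": gr.s_k})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
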