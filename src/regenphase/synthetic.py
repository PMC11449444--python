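"""Negative-binomial time-course simulator with planted temporal archetypes.

The generator emulates the study design of a two-structure regeneration
time course: two biological replicates per time point, a jaw grid of
{intact, 5, 14, 35 days post injury} and a limb grid running from intact
through 3 hours post amputation to 28 days post amputation.  Genes are drawn
from temporal archetypes —

* ``gaussian-peak``:  expression rises to ``amplitude_fold`` x baseline
  around ``peak_time`` and falls back (a transient wound-response or
  blastema programme);
* ``logistic-rise``:  monotone sigmoid increase over the course
  (differentiation/ossification programmes);
* ``intact-decline``: maximal in the intact tissue and decaying
  exponentially after injury with time constant ``width`` (down-regulated
  homeostatic genes whose transcription shuts off, the 'unassigned' pattern);
* ``flat``:           constant expectation, pure noise.

Expected CPM is converted to a per-sample count mean via the sample's
library size and counts are drawn negative-binomially with dispersion
``phi`` (var = m + phi*m^2; phi = 0 falls back to Poisson).  Everything is
deterministic given the seed.

A companion generator produces defect-morphometry cohorts following the
observed closure dynamics: tissue contraction within 1 day post injury, a
second closure phase from 7 dpi, full closure by 35 dpi, and a stump
displacement angle that dips to its minimum at 35 dpi before recovering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regenphase.exceptions import ConfigError
from regenphase.expression import CountMatrix

HOURS_PER_DAY = 24.0

JAW_TIMES = {0.0: "intact", 120.0: "5dpi", 336.0: "14dpi", 840.0: "35dpi"}

LIMB_TIMES = {
    0.0: "intact",
    3.0: "3hpa",
    6.0: "6hpa",
    12.0: "12hpa",
    24.0: "1dpa",
    72.0: "3dpa",
    120.0: "5dpa",
    168.0: "7dpa",
    240.0: "10dpa",
    336.0: "14dpa",
    504.0: "21dpa",
    672.0: "28dpa",
}


@dataclass
class Archetype:
    label: str  # planted truth label (phase group, 'flat' or 'unassigned')
    n_genes: int
    shape: str  # gaussian-peak | logistic-rise | intact-decline | flat
    baseline_cpm: float = 3.0
    amplitude_fold: float = 30.0
    peak_time: float | None = None  # hours (gaussian-peak)
    width: float | None = None  # hours: sd (gaussian-peak) or decay constant (intact-decline)
    midpoint: float | None = None  # hours (logistic-rise)
    slope: float | None = None  # 1/hours (logistic-rise)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("each archetype needs n_genes >= 1")
        if self.baseline_cpm <= 0 or self.amplitude_fold < 1:
            raise ConfigError("baseline_cpm > 0 and amplitude_fold >= 1 required")
        needed = {
            "gaussian-peak": ("peak_time", "width"),
            "logistic-rise": ("midpoint", "slope"),
            "intact-decline": ("width",),
            "flat": (),
        }
        if self.shape not in needed:
            raise ConfigError(f"unknown shape {self.shape!r}")
        for attr in needed[self.shape]:
            value = getattr(self, attr)
            if value is None or value <= 0:
                raise ConfigError(f"shape {self.shape!r} needs positive {attr}")

    def mean_cpm(self, times: np.ndarray) -> np.ndarray:
        """Expected CPM trajectory; peak value = amplitude_fold x baseline."""
        t = np.asarray(times, dtype=float)
        if self.shape == "flat":
            s = np.zeros_like(t)
        elif self.shape == "gaussian-peak":
            s = np.exp(-((t - self.peak_time) ** 2) / (2 * self.width**2))
        elif self.shape == "intact-decline":
            s = np.exp(-t / self.width)  # exponential decay, time constant = width
        else:  # logistic-rise, normalized so the last time point is the peak
            raw = 1.0 / (1.0 + np.exp(-self.slope * (t - self.midpoint)))
            s = raw / raw.max()
        return self.baseline_cpm * (1.0 + (self.amplitude_fold - 1.0) * s)


@dataclass
class SyntheticConfig:
    structure: str
    times: dict[float, str]  # hours -> label, must include 0 (intact)
    archetypes: list[Archetype]
    replicates_per_time: int = 2
    phi: float = 0.05  # NB dispersion; 0 = Poisson
    library_size_range: tuple[int, int] = (1_500_000, 2_500_000)
    #: stably expressed background transcriptome: carries most of the library
    #: mass so per-sample totals are dominated by genes with constant
    #: expectation, as in real RNA-seq, keeping CPM distortions from the
    #: regeneration programme itself small
    n_background: int = 2000
    background_cpm: float = 450.0
    #: sd (log scale) of the per-gene lognormal baseline jitter
    baseline_jitter_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        hours = sorted(self.times)
        if not hours or hours[0] != 0.0:
            raise ConfigError("time grid must include 0 h (the intact condition)")
        if self.replicates_per_time < 1:
            raise ConfigError("need at least one replicate per time point")
        if self.phi < 0:
            raise ConfigError("dispersion phi must be >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("library_size_range must be positive and ordered")
        if self.n_background < 0 or self.background_cpm <= 0:
            raise ConfigError("need n_background >= 0 and background_cpm > 0")

    @property
    def n_genes(self) -> int:
        return sum(a.n_genes for a in self.archetypes) + self.n_background


@dataclass
class SyntheticTruth:
    labels: pd.Series  # gene -> planted label
    archetypes: dict[str, Archetype] = field(default_factory=dict)
    seed: int = 0


def jaw_default_config(seed: int = 0) -> SyntheticConfig:
    """Default jaw fixture: 5/14 dpi peaks, general rise, flat, intact decline."""
    return SyntheticConfig(
        structure="jaw",
        times=dict(JAW_TIMES),
        archetypes=[
            Archetype("5 dpi peak", 60, "gaussian-peak", peak_time=120.0, width=60.0),
            Archetype("14 dpi peak", 60, "gaussian-peak", peak_time=336.0, width=120.0),
            Archetype("general rise", 60, "logistic-rise", midpoint=400.0, slope=0.01),
            Archetype("flat", 40, "flat", baseline_cpm=50.0, amplitude_fold=1.0),
            Archetype("unassigned", 40, "intact-decline", width=150.0),
        ],
        seed=seed,
    )


def limb_default_config(seed: int = 0, transient_fraction: float = 0.6) -> SyntheticConfig:
    """Default limb fixture: early (split transient/sustained), mid, late,
    rise, flat and intact-decline archetypes.

    ``transient_fraction`` of the early-peak genes spike at 3 hours post
    amputation and return to basal by 1 day; the rest peak at 1 day.
    """
    n_early = 60
    n_transient = round(n_early * transient_fraction)
    return SyntheticConfig(
        structure="limb",
        times=dict(LIMB_TIMES),
        archetypes=[
            # immediate-early wound response: spikes at 3 hpa, gone by 12 hpa
            Archetype("early peak", n_transient, "gaussian-peak", peak_time=3.0, width=2.0),
            Archetype(
                "early peak", n_early - n_transient, "gaussian-peak", peak_time=36.0, width=14.0
            ),
            Archetype("mid peak", 60, "gaussian-peak", peak_time=168.0, width=60.0),
            Archetype("late rise", 60, "gaussian-peak", peak_time=504.0, width=100.0),
            Archetype("general rise", 60, "logistic-rise", midpoint=300.0, slope=0.01),
            Archetype("flat", 40, "flat", baseline_cpm=50.0, amplitude_fold=1.0),
            # homeostatic transcripts decay over the first days
            Archetype("unassigned", 40, "intact-decline", width=48.0),
        ],
        seed=seed,
    )


def default_config(structure: str, seed: int = 0) -> SyntheticConfig:
    if structure == "jaw":
        return jaw_default_config(seed)
    if structure == "limb":
        return limb_default_config(seed)
    raise ConfigError(f"no default synthetic config for structure {structure!r}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)  # mean r(1-p)/p = mean; var = mean + phi*mean^2
    return rng.negative_binomial(r, p)


def simulate_counts(
    cfg: SyntheticConfig, shared_gene_ids: list[str] | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix plus the planted truth for every gene.

    ``shared_gene_ids`` optionally fixes the gene identifiers (to simulate a
    second structure over the same annotation); its length must match the
    total number of genes in the config.
    """
    rng = np.random.default_rng(cfg.seed)
    hours = np.array(sorted(cfg.times), dtype=float)
    n_genes = cfg.n_genes

    if shared_gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    else:
        if len(shared_gene_ids) != n_genes:
            raise ConfigError("shared_gene_ids length must equal total gene count")
        gene_ids = list(shared_gene_ids)

    # sample metadata
    rows = []
    for t in hours:
        for rep in range(1, cfg.replicates_per_time + 1):
            rows.append(
                {
                    "sample_id": f"{cfg.structure}_{cfg.times[t]}_r{rep}",
                    "structure": cfg.structure,
                    "time_label": cfg.times[t],
                    "time_hours": t,
                    "replicate": rep,
                }
            )
    meta = pd.DataFrame(rows)
    lib = rng.integers(*cfg.library_size_range, size=len(meta), endpoint=True)

    # expected CPM per gene and time, with mild per-gene baseline jitter
    mu = np.empty((n_genes, len(hours)))
    labels = []
    arch_index: dict[str, Archetype] = {}
    i = 0
    for arch in cfg.archetypes:
        base_curve = arch.mean_cpm(hours)
        jitter = rng.lognormal(mean=0.0, sigma=cfg.baseline_jitter_sigma, size=arch.n_genes)
        mu[i : i + arch.n_genes] = jitter[:, None] * base_curve[None, :]
        labels.extend([arch.label] * arch.n_genes)
        arch_index.setdefault(arch.label, arch)
        i += arch.n_genes
    if cfg.n_background:
        jitter = rng.lognormal(mean=0.0, sigma=cfg.baseline_jitter_sigma, size=cfg.n_background)
        mu[i:] = jitter[:, None] * cfg.background_cpm
        labels.extend(["flat"] * cfg.n_background)

    # per-sample count means and the NB draw
    time_index = {t: j for j, t in enumerate(hours)}
    counts = np.empty((n_genes, len(meta)), dtype=np.int64)
    for s, row in enumerate(meta.itertuples()):
        m = mu[:, time_index[row.time_hours]] * lib[s] / 1e6
        counts[:, s] = _nb_draw(rng, m, cfg.phi)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=meta["sample_id"]),
        samples=meta,
    )
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=gene_ids, name="label"),
        archetypes=arch_index,
        seed=cfg.seed,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# planted blobs in z-space (for model-selection experiments)


def planted_profile_blobs(
    k: int,
    n_genes: int = 300,
    n_times: int = 8,
    sigma: float = 0.1,
    seed: int = 0,
    min_separation_sigma: float = 5.0,
):
    """Standardized-profile blobs with k planted, well-separated archetypes.

    Archetype centres are drawn standard-normal in profile space and re-drawn
    until every pair is at least ``min_separation_sigma`` x ``sigma`` apart
    per dimension (Euclidean distance over sqrt(n_times)); genes scatter
    isotropically (sd ``sigma``) around their centre.  Returns a ZProfile —
    the input expected by the gap-statistic and k-means stages.
    """
    from regenphase.clustering import ZProfile

    if k < 1 or n_genes < k:
        raise ConfigError("need 1 <= k <= n_genes")
    rng = np.random.default_rng(seed)
    min_dist = min_separation_sigma * sigma * np.sqrt(n_times)
    while True:
        centers = rng.normal(0.0, 1.0, size=(k, n_times))
        if k == 1:
            break
        dists = [
            np.linalg.norm(centers[i] - centers[j])
            for i in range(k)
            for j in range(i + 1, k)
        ]
        if min(dists) >= min_dist:
            break
    sizes = np.full(k, n_genes // k)
    sizes[: n_genes % k] += 1
    rows = np.vstack(
        [c + rng.normal(0.0, sigma, size=(s, n_times)) for c, s in zip(centers, sizes)]
    )
    z = pd.DataFrame(
        rows,
        columns=np.arange(n_times, dtype=float),
        index=[f"g{i:05d}" for i in range(n_genes)],
    )
    truth = np.repeat(np.arange(1, k + 1), sizes)
    return ZProfile(z=z, structure="limb"), pd.Series(truth, index=z.index, name="blob")


# ---------------------------------------------------------------------------
# paired two-structure simulation over one gene universe

#: joint allocation of the gene universe: for each jaw archetype label, how
#: many of its genes fall into each limb archetype (by index into the limb
#: default archetype list).  The pattern emulates the observed cross-structure
#: correspondence: most jaw 5-dpi-peak genes behave as limb early-peak genes
#: (a majority of them 3-hpa transients), jaw 14-dpi-peak genes split between
#: limb early and mid peaks, and the jaw general rise maps mostly onto the
#: limb mid peak (the slower structure lagging the faster one).
PAIRED_JOINT: dict[str, list[tuple[int, int]]] = {
    "5 dpi peak": [(0, 22), (1, 14), (2, 6), (3, 2), (4, 2), (5, 14)],
    "14 dpi peak": [(0, 14), (1, 10), (2, 20), (3, 2), (4, 2), (5, 12)],
    "general rise": [(2, 28), (3, 8), (4, 12), (5, 12)],
    "unassigned": [(6, 16), (5, 24)],
    "flat": [(2, 6), (3, 48), (4, 44), (5, 78), (6, 24)],
}

PAIRED_JAW_SIZES = {
    "5 dpi peak": 60,
    "14 dpi peak": 60,
    "general rise": 60,
    "unassigned": 40,
    "flat": 200,
}


def paired_configs(seed: int = 0) -> tuple[SyntheticConfig, SyntheticConfig]:
    """Jaw and limb configs over a common 420-gene universe (see PAIRED_JOINT)."""
    jaw = jaw_default_config(seed)
    sizes = dict(PAIRED_JAW_SIZES)
    arches = []
    for arch in jaw.archetypes:
        n = sizes[arch.label]
        arches.append(
            Archetype(
                arch.label,
                n,
                arch.shape,
                baseline_cpm=arch.baseline_cpm,
                amplitude_fold=arch.amplitude_fold,
                peak_time=arch.peak_time,
                width=arch.width,
                midpoint=arch.midpoint,
                slope=arch.slope,
            )
        )
    jaw = SyntheticConfig(structure="jaw", times=dict(JAW_TIMES), archetypes=arches, seed=seed)
    limb = limb_default_config(seed + 1)
    # resize limb blocks to the joint column totals
    col_totals = [0] * len(limb.archetypes)
    for cells in PAIRED_JOINT.values():
        for idx, n in cells:
            col_totals[idx] += n
    limb_arches = []
    for idx, arch in enumerate(limb.archetypes):
        limb_arches.append(
            Archetype(
                arch.label,
                col_totals[idx],
                arch.shape,
                baseline_cpm=arch.baseline_cpm,
                amplitude_fold=arch.amplitude_fold,
                peak_time=arch.peak_time,
                width=arch.width,
                midpoint=arch.midpoint,
                slope=arch.slope,
            )
        )
    limb = SyntheticConfig(
        structure="limb", times=dict(LIMB_TIMES), archetypes=limb_arches, seed=seed + 1
    )
    return jaw, limb


def simulate_paired(seed: int = 0):
    """Simulate jaw and limb count matrices over one shared gene universe.

    Returns ``(jaw_cm, jaw_truth, limb_cm, limb_truth)``; gene identifiers
    are shared so the downstream overlap statistics are meaningful, with the
    cross-structure label correspondence planted per ``PAIRED_JOINT``.
    """
    jaw_cfg, limb_cfg = paired_configs(seed)
    universe = [f"g{i:05d}" for i in range(jaw_cfg.n_genes)]
    jaw_cm, jaw_truth = simulate_counts(jaw_cfg, shared_gene_ids=universe)

    # allocate each jaw block's ids to limb archetypes per the joint table
    per_limb_arch: list[list[str]] = [[] for _ in limb_cfg.archetypes]
    cursor = 0
    for arch in jaw_cfg.archetypes:
        block = universe[cursor : cursor + arch.n_genes]
        cursor += arch.n_genes
        offset = 0
        for idx, n in PAIRED_JOINT[arch.label]:
            per_limb_arch[idx].extend(block[offset : offset + n])
            offset += n
        if offset != arch.n_genes:
            raise ConfigError(
                f"joint allocation for jaw block {arch.label!r} covers {offset} "
                f"of {arch.n_genes} genes"
            )
    limb_ids = [g for ids in per_limb_arch for g in ids]
    limb_ids.extend(universe[cursor:])  # shared background transcriptome
    limb_cm, limb_truth = simulate_counts(limb_cfg, shared_gene_ids=limb_ids)
    return jaw_cm, jaw_truth, limb_cm, limb_truth


# ---------------------------------------------------------------------------
# morphometry cohorts


@dataclass
class ClosureCurve:
    """Piecewise-linear defect-closure and stump-angle dynamics (days, mm)."""

    area_by_dpi: dict[int, float] = field(
        default_factory=lambda: {0: 12.0, 1: 7.0, 3: 7.0, 5: 6.8, 7: 5.0, 14: 1.5, 35: 0.0, 90: 0.0}
    )
    angle_by_dpi: dict[int, float] = field(
        default_factory=lambda: {0: 150.0, 1: 145.0, 3: 142.0, 5: 138.0, 7: 128.0, 14: 112.0, 35: 95.0, 90: 122.0}
    )
    defect_length: float = 5.0
    hemi_perimeter: float = 11.55
    full_perimeter: float = 24.15
    intact_perimeter_90dpi: float = 30.0
    resected_deficit_90dpi: float = 0.092  # fraction smaller than intact at 90 dpi


def simulate_morphometry(
    n_animals: int = 6,
    curve: ClosureCurve | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a measurement cohort following the closure dynamics.

    Returns a tidy table (one row per animal x time point) with defect area,
    displacement angle, and the 0-dpi length measurements; areas are clipped
    at zero and forced to exactly zero wherever the curve reaches zero
    (closed defects are recorded as explicit zeros).
    """
    if n_animals < 1:
        raise ConfigError("n_animals must be >= 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    curve = curve or ClosureCurve()
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(1, n_animals + 1):
        animal = f"A{a:02d}"
        defect = curve.defect_length + rng.normal(0, noise_sd)
        hemi = curve.hemi_perimeter + rng.normal(0, noise_sd)
        full = curve.full_perimeter + rng.normal(0, noise_sd)
        for dpi, area in curve.area_by_dpi.items():
            if area == 0:
                obs_area = 0.0  # tissue continuity observed: explicit zero
            else:
                obs_area = max(0.0, area + rng.normal(0, noise_sd))
            angle = curve.angle_by_dpi[dpi] + rng.normal(0, noise_sd * 10)
            rows.append(
                {
                    "animal_id": animal,
                    "time_dpi": dpi,
                    "defect_area_mm2": obs_area,
                    "angle_deg": angle,
                    "defect_length_mm": defect,
                    "hemi_perimeter_mm": hemi,
                    "full_perimeter_mm": full,
                    "resected_perimeter_90dpi_mm": curve.intact_perimeter_90dpi
                    * (1 - curve.resected_deficit_90dpi)
                    + rng.normal(0, noise_sd),
                    "intact_perimeter_90dpi_mm": curve.intact_perimeter_90dpi
                    + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


def write_fixture(cm: CountMatrix, truth: SyntheticTruth, out_dir) -> None:
    """Write counts, metadata and truth TSVs for a simulated structure."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure = cm.samples["structure"].iloc[0]
    counts = cm.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(out / f"{structure}_counts.tsv", sep="\t", lineterminator="\n")
    cm.samples.to_csv(out / f"{structure}_metadata.tsv", sep="\t", index=False, lineterminator="\n")
    truth_frame = truth.labels.to_frame()
    truth_frame.index.name = "gene_id"
    truth_frame.to_csv(out / f"{structure}_truth.tsv", sep="\t", lineterminator="\n")
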