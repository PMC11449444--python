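"""Count-matrix I/O, CPM normalization and replicate averaging.

Raw gene-level counts arrive as a TSV (first column gene id, one column per
sample) together with a sample-metadata TSV (``sample_id``, ``structure``,
``time_label``, ``time_hours``, ``replicate``).  Time is unified internally
to hours since injury so the jaw (days post injury) and limb (hours/days
post amputation) grids share one axis; ``time_hours == 0`` is the intact
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regenphase.exceptions import ConsistencyError, EmptySelectionError, FormatError

STRUCTURES = ("jaw", "limb")

METADATA_COLUMNS = ["sample_id", "structure", "time_label", "time_hours", "replicate"]


def _validate_metadata(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"metadata missing columns: {missing}")
    samples = samples.copy()
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    bad = set(samples["structure"]) - set(STRUCTURES)
    if bad:
        raise FormatError(f"unknown structures {sorted(bad)}; expected one of {STRUCTURES}")
    if (samples["time_hours"] < 0).any():
        raise FormatError("time_hours must be non-negative")
    if (samples["replicate"] < 1).any():
        raise FormatError("replicate numbers must be positive integers")
    return samples


@dataclass
class CountMatrix:
    """Raw integer counts (genes x samples) with per-sample metadata.

    ``counts`` is a DataFrame indexed by gene id with one column per
    sample id, ordered as in ``samples``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = _validate_metadata(self.samples)
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        matrix_samples = list(self.counts.columns)
        meta_samples = list(self.samples["sample_id"])
        if set(matrix_samples) != set(meta_samples):
            only_matrix = sorted(set(matrix_samples) - set(meta_samples))
            only_meta = sorted(set(meta_samples) - set(matrix_samples))
            raise ConsistencyError(
                f"sample mismatch: only in matrix {only_matrix}, only in metadata {only_meta}"
            )
        # order columns as in metadata
        self.counts = self.counts[meta_samples]
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if (values < 0).any():
            raise FormatError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise FormatError("counts must be integral")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class CpmMatrix:
    """Counts-per-million: each sample's counts scaled to sum to 1e6."""

    cpm: pd.DataFrame
    samples: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)


@dataclass
class TimeProfile:
    """Replicate-averaged CPM per time point for one structure.

    ``values`` is genes x times; ``times`` (hours) strictly increasing.
    """

    values: pd.DataFrame  # columns = time_hours, ascending
    structure: str
    time_labels: dict[float, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.values.columns, dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ConsistencyError("time points must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    meta = pd.read_csv(path, sep="\t")
    return _validate_metadata(meta)


def read_counts(path, metadata_path) -> CountMatrix:
    """Read a counts TSV plus its metadata TSV into a validated CountMatrix."""
    meta = read_metadata(metadata_path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=table, samples=meta)


def write_counts(cm: CountMatrix, path, metadata_path=None) -> None:
    """Write counts (and optionally metadata) back to TSV, LF line endings."""
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
    if metadata_path is not None:
        cm.samples.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")


def compute_cpm(cm: CountMatrix) -> CpmMatrix:
    """Scale each sample to counts per million: counts / library size * 1e6.

    Plain library-size scaling; no between-sample scaling factors.
    """
    lib = cm.counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise EmptySelectionError(f"zero library size for samples: {list(zero.index)}")
    cpm = cm.counts / lib * 1e6
    return CpmMatrix(cpm=cpm, samples=cm.samples.copy())


def average_replicates(cpm: CpmMatrix, structure: str) -> TimeProfile:
    """Collapse replicates to the mean CPM per (gene, time point) for one structure."""
    mask = cpm.samples["structure"] == structure
    if not mask.any():
        raise EmptySelectionError(f"no samples for structure {structure!r}")
    meta = cpm.samples[mask]
    sub = cpm.cpm[meta["sample_id"].tolist()]
    groups = sub.T.groupby(meta.set_index("sample_id")["time_hours"])
    means = groups.mean().T  # genes x times
    means = means[sorted(means.columns)]
    labels = (
        meta.drop_duplicates("time_hours").set_index("time_hours")["time_label"].to_dict()
    )
    return TimeProfile(values=means, structure=structure, time_labels=labels)


def write_time_profile(tp: TimeProfile, path) -> None:
    out = tp.values.copy()
    out.columns = [f"{t:g}" for t in out.columns]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
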