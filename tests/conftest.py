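import numpy as np
import pandas as pd
import pytest

from regenphase.expression import CountMatrix, CpmMatrix, TimeProfile


def make_metadata(structure="jaw", times=(0.0, 120.0, 336.0, 840.0), reps=2):
    rows = []
    for t in times:
        for r in range(1, reps + 1):
            rows.append(
                {
                    "sample_id": f"{structure}_t{t:g}_r{r}",
                    "structure": structure,
                    "time_label": f"{t:g}h",
                    "time_hours": t,
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def jaw_metadata():
    return make_metadata()


@pytest.fixture
def small_counts(jaw_metadata):
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(5, len(jaw_metadata))),
        index=[f"g{i}" for i in range(5)],
        columns=jaw_metadata["sample_id"],
    )
    return CountMatrix(counts=counts, samples=jaw_metadata)


def profile_from_rows(rows, times, structure="jaw", gene_ids=None):
    """Build a TimeProfile straight from a values matrix."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    gene_ids = gene_ids or [f"g{i}" for i in range(rows.shape[0])]
    return TimeProfile(
        values=pd.DataFrame(rows, index=gene_ids, columns=list(times)),
        structure=structure,
    )


def cpm_from_rows(rows, metadata, gene_ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    gene_ids = gene_ids or [f"g{i}" for i in range(rows.shape[0])]
    return CpmMatrix(
        cpm=pd.DataFrame(rows, index=gene_ids, columns=metadata["sample_id"]),
        samples=metadata,
    )
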