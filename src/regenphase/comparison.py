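"""Cross-structure shared-gene statistics.

Jaw and limb genes of interest live in the same gene-identifier space
(both datasets quantified against one genome annotation), so "shared genes"
is a plain set intersection.  The overlap table reports, for each jaw phase
group, what percentage of its shared genes falls into each limb phase group;
per jaw group the limb-group counts plus the genes sitting in unassigned
limb clusters add up to the group's shared-gene count.

The early-transient fraction quantifies how many genes of a given set peak
at 3 h post amputation in the limb and return to (or below) their intact
level by 1 day post amputation — the wound-response genes whose expression
the slower structure sustains for days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from regenphase.clustering import ZProfile
from regenphase.exceptions import ConsistencyError, EmptySelectionError, ParameterError
from regenphase.phasing import PhaseAssignment


@dataclass
class SharedGenes:
    genes: set[str]
    pct_of_jaw: float  # 100 * |shared| / |jaw genes of interest|


@dataclass
class OverlapTable:
    jaw_groups: list[str]
    limb_groups: list[str]
    n_shared_in_jaw_group: dict[str, int]
    counts: pd.DataFrame  # jaw groups x limb groups, int
    pct: pd.DataFrame  # jaw groups x limb groups, float (NaN when denominator 0)


def intersect_goi(jaw_goi, limb_goi) -> SharedGenes:
    """Shared genes between structures, with the jaw-relative percentage."""
    jaw_goi, limb_goi = set(jaw_goi), set(limb_goi)
    if not jaw_goi:
        raise EmptySelectionError("jaw gene set is empty; shared percentage undefined")
    shared = jaw_goi & limb_goi
    return SharedGenes(genes=shared, pct_of_jaw=100.0 * len(shared) / len(jaw_goi))


def overlap_percentages(
    jaw_pa: PhaseAssignment, limb_pa: PhaseAssignment, shared
) -> OverlapTable:
    """Count and percentage of each jaw group's shared genes per limb group.

    pct[g, h] = 100 * |shared ∩ jaw group g ∩ limb group h| / |shared ∩ jaw group g|;
    cells with an empty denominator are reported missing (NaN).
    """
    shared = set(shared)
    jaw_universe = set(jaw_pa.gene_phase.index)
    limb_universe = set(limb_pa.gene_phase.index)
    stray = shared - (jaw_universe & limb_universe)
    if stray:
        raise ConsistencyError(
            f"shared genes outside both genes-of-interest universes: {sorted(stray)[:5]}"
        )
    jaw_groups = [lab for lab in jaw_pa.config.labels] if jaw_pa.config else sorted(
        set(jaw_pa.gene_phase)
    )
    limb_groups = [lab for lab in limb_pa.config.labels] if limb_pa.config else sorted(
        set(limb_pa.gene_phase)
    )
    counts = pd.DataFrame(0, index=jaw_groups, columns=limb_groups, dtype=int)
    denominators: dict[str, int] = {}
    for g in jaw_groups:
        in_g = shared & jaw_pa.genes_in(g)
        denominators[g] = len(in_g)
        for h in limb_groups:
            counts.loc[g, h] = len(in_g & limb_pa.genes_in(h))
    denom = pd.Series(denominators)
    pct = counts.div(denom, axis=0).where(denom > 0) * 100.0
    return OverlapTable(
        jaw_groups=jaw_groups,
        limb_groups=limb_groups,
        n_shared_in_jaw_group=denominators,
        counts=counts,
        pct=pct,
    )


def early_transient_fraction(
    genes,
    limb_zp: ZProfile,
    peak_hours: float = 3.0,
    return_hours: float = 24.0,
    basal_tolerance: float = 0.0,
) -> float | None:
    """Percentage of ``genes`` peaking at 3 hpa and back to basal by 1 dpa.

    A gene counts as an early transient when its z-profile attains its maximum
    at ``peak_hours`` and z(``return_hours``) <= z(intact) + tolerance, with
    the intact (0 h) value taken as basal.  Returns None for an empty set.
    """
    genes = list(genes)
    times = limb_zp.times
    for needed in (0.0, peak_hours, return_hours):
        if not np.any(np.isclose(times, needed)):
            raise ParameterError(f"limb profile lacks required time point {needed} h")
    missing = set(genes) - set(limb_zp.gene_ids)
    if missing:
        raise ConsistencyError(f"genes absent from limb profiles: {sorted(missing)[:5]}")
    if not genes:
        return None
    i0 = int(np.flatnonzero(np.isclose(times, 0.0))[0])
    ip = int(np.flatnonzero(np.isclose(times, peak_hours))[0])
    ir = int(np.flatnonzero(np.isclose(times, return_hours))[0])
    z = limb_zp.z.loc[genes].to_numpy(dtype=float)
    transient = (np.argmax(z, axis=1) == ip) & (z[:, ir] <= z[:, i0] + basal_tolerance)
    return 100.0 * float(transient.sum()) / len(genes)


def write_overlap(table: OverlapTable, path) -> None:
    rows = []
    for g in table.jaw_groups:
        for h in table.limb_groups:
            pct = table.pct.loc[g, h]
            rows.append(
                {
                    "jaw_group": g,
                    "limb_group": h,
                    "count": int(table.counts.loc[g, h]),
                    "pct": "" if pd.isna(pct) else f"{pct:.4f}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
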