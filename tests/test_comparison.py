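"""Shared-gene intersection, overlap percentages and the early-transient rule."""

import numpy as np
import pandas as pd
import pytest

from regenphase import comparison
from regenphase.clustering import ZProfile
from regenphase.exceptions import EmptySelectionError, ParameterError
from regenphase.phasing import PhaseAssignment, jaw_default, limb_default

LIMB_TIMES = [0.0, 3.0, 6.0, 12.0, 24.0, 72.0, 168.0, 336.0, 672.0]


def make_assignment(mapping, config):
    return PhaseAssignment(
        cluster_phase={},
        gene_phase=pd.Series(mapping, name="phase"),
        config=config,
    )


class TestIntersect:
    def test_partial_overlap_percentage(self):
        shared = comparison.intersect_goi({"a", "b", "c"}, {"b", "c", "d"})
        assert shared.genes == {"b", "c"}
        assert shared.pct_of_jaw == pytest.approx(66.6667, abs=1e-3)

    def test_disjoint_and_identical_sets(self):
        assert comparison.intersect_goi({"a"}, {"b"}).pct_of_jaw == 0.0
        assert comparison.intersect_goi({"a", "b"}, {"a", "b"}).pct_of_jaw == 100.0

    def test_empty_jaw_set_rejected(self):
        with pytest.raises(EmptySelectionError):
            comparison.intersect_goi(set(), {"a"})


class TestOverlapPercentages:
    def test_counts_and_unaccounted_remainder(self):
        jaw = make_assignment(
            {g: "5 dpi peak" for g in "abcd"} | {"x": "14 dpi peak"}, jaw_default()
        )
        limb = make_assignment(
            {"a": "early peak", "b": "early peak", "c": "mid peak", "d": "unassigned", "x": "early peak"},
            limb_default(),
        )
        table = comparison.overlap_percentages(jaw, limb, {"a", "b", "c", "d"})
        assert table.n_shared_in_jaw_group["5 dpi peak"] == 4
        assert table.pct.loc["5 dpi peak", "early peak"] == pytest.approx(50.0)
        assert table.pct.loc["5 dpi peak", "mid peak"] == pytest.approx(25.0)
        # gene d sits in an unassigned limb cluster: counted in the denominator
        # but in no limb-group cell (the unaccounted remainder)
        accounted = table.counts.loc["5 dpi peak"].sum()
        assert table.n_shared_in_jaw_group["5 dpi peak"] - accounted == 1

    def test_empty_shared_set_gives_all_missing_cells(self):
        jaw = make_assignment({"a": "5 dpi peak"}, jaw_default())
        limb = make_assignment({"a": "early peak"}, limb_default())
        table = comparison.overlap_percentages(jaw, limb, set())
        assert table.pct.isna().all().all()

    def test_single_limb_group_concentration(self):
        jaw = make_assignment({g: "14 dpi peak" for g in "abc"}, jaw_default())
        limb = make_assignment({g: "mid peak" for g in "abc"}, limb_default())
        table = comparison.overlap_percentages(jaw, limb, {"a", "b", "c"})
        assert table.pct.loc["14 dpi peak", "mid peak"] == pytest.approx(100.0)
        assert table.pct.loc["14 dpi peak", "early peak"] == pytest.approx(0.0)

    def test_matches_exhaustive_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        jaw_labels = jaw_default().labels + ["unassigned"]
        limb_labels = limb_default().labels + ["unassigned"]
        genes = [f"g{i}" for i in range(200)]
        jaw = make_assignment(
            {g: jaw_labels[rng.integers(len(jaw_labels))] for g in genes}, jaw_default()
        )
        limb = make_assignment(
            {g: limb_labels[rng.integers(len(limb_labels))] for g in genes}, limb_default()
        )
        shared = set(rng.choice(genes, size=120, replace=False))
        table = comparison.overlap_percentages(jaw, limb, shared)
        for g_lab in table.jaw_groups:
            denom = {g for g in shared if jaw.gene_phase[g] == g_lab}
            assert table.n_shared_in_jaw_group[g_lab] == len(denom)
            for h_lab in table.limb_groups:
                cell = {g for g in denom if limb.gene_phase[g] == h_lab}
                assert table.counts.loc[g_lab, h_lab] == len(cell)
                if denom:
                    assert table.pct.loc[g_lab, h_lab] == pytest.approx(
                        100 * len(cell) / len(denom)
                    )
                else:
                    assert pd.isna(table.pct.loc[g_lab, h_lab])

    def test_permutation_of_gene_order_is_irrelevant(self):
        genes = [f"g{i}" for i in range(30)]
        jaw_map = {g: "5 dpi peak" for g in genes}
        limb_map = {g: ("early peak" if i % 3 else "mid peak") for i, g in enumerate(genes)}
        jaw = make_assignment(jaw_map, jaw_default())
        limb = make_assignment(limb_map, limb_default())
        t1 = comparison.overlap_percentages(jaw, limb, set(genes))
        rev_jaw = make_assignment(dict(reversed(list(jaw_map.items()))), jaw_default())
        rev_limb = make_assignment(dict(reversed(list(limb_map.items()))), limb_default())
        t2 = comparison.overlap_percentages(rev_jaw, rev_limb, set(genes))
        pd.testing.assert_frame_equal(t1.counts, t2.counts)


def zprofile(rows, genes):
    return ZProfile(
        z=pd.DataFrame(rows, index=genes, columns=LIMB_TIMES), structure="limb"
    )


class TestEarlyTransient:
    def test_spike_at_three_hours_counts_as_transient(self):
        zp = zprofile([[0, 2, 1, 0.5, -0.5, -1, -0.5, -1, -0.5]], ["g"])
        assert comparison.early_transient_fraction({"g"}, zp) == pytest.approx(100.0)

    def test_hand_built_cohort_gives_sixty_percent(self):
        rows = [
            [0, 2, 1, 0.2, -0.5, -1, -0.5, -0.7, -0.5],  # transient
            [0, 2.2, 1, 0.1, -0.6, -1, -0.5, -0.7, -0.5],  # transient
            [-0.2, 1.9, 1, 0.2, -0.4, -1, -0.5, -0.6, -0.4],  # transient
            [0, 1.5, 2, 1, 0.5, -1, -1.5, -1.3, -1.2],  # peaks at 6 h
            [-0.5, 2, 1, 0.5, 0.4, -1, -0.8, -0.9, -0.8],  # not back to basal by 1 dpa
        ]
        zp = zprofile(rows, [f"g{i}" for i in range(5)])
        pct = comparison.early_transient_fraction({f"g{i}" for i in range(5)}, zp)
        assert pct == pytest.approx(60.0)

    def test_empty_gene_set_reports_missing(self):
        zp = zprofile([[0, 2, 1, 0.5, -0.5, -1, -0.5, -1, -0.5]], ["g"])
        assert comparison.early_transient_fraction(set(), zp) is None

    def test_missing_required_time_point_rejected(self):
        times = [0.0, 6.0, 24.0]
        zp = ZProfile(
            z=pd.DataFrame([[0, 1, -1]], index=["g"], columns=times), structure="limb"
        )
        with pytest.raises(ParameterError):
            comparison.early_transient_fraction({"g"}, zp)
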