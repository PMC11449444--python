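"""Count-matrix parsing, CPM normalization and replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from regenphase import expression
from regenphase.exceptions import ConsistencyError, EmptySelectionError, FormatError
from regenphase.expression import CountMatrix

from conftest import make_metadata


def write_tables(tmp_path, counts: pd.DataFrame, meta: pd.DataFrame):
    cpath, mpath = tmp_path / "counts.tsv", tmp_path / "meta.tsv"
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(cpath, sep="\t")
    meta.to_csv(mpath, sep="\t", index=False)
    return cpath, mpath


class TestReadCounts:
    def test_well_formed_table_parses_to_matching_shape(self, tmp_path):
        meta = make_metadata(times=(0.0, 120.0), reps=2)
        counts = pd.DataFrame(
            [[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]],
            index=["g1", "g2", "g3"],
            columns=meta["sample_id"],
        )
        cm = expression.read_counts(*write_tables(tmp_path, counts, meta))
        assert cm.counts.shape == (3, 4)
        assert cm.gene_ids == ["g1", "g2", "g3"]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        meta = make_metadata(times=(0.0, 120.0), reps=1)
        cpath = tmp_path / "counts.tsv"
        mpath = tmp_path / "meta.tsv"
        meta.to_csv(mpath, sep="\t", index=False)
        sample_cols = "\t".join(meta["sample_id"])
        cpath.write_text(f"gene_id\t{sample_cols}\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(FormatError, match="duplicate gene ids"):
            expression.read_counts(cpath, mpath)

    @pytest.mark.parametrize("bad_value", [-2, 1.5])
    def test_negative_or_fractional_count_rejected(self, tmp_path, bad_value):
        meta = make_metadata(times=(0.0, 120.0), reps=1)
        counts = pd.DataFrame(
            [[1, bad_value]], index=["g1"], columns=meta["sample_id"]
        )
        with pytest.raises(FormatError):
            expression.read_counts(*write_tables(tmp_path, counts, meta))

    def test_sample_mismatch_between_matrix_and_metadata(self, tmp_path):
        meta = make_metadata(times=(0.0, 120.0), reps=1)
        counts = pd.DataFrame(
            [[1, 2]], index=["g1"], columns=["other_a", "other_b"]
        )
        with pytest.raises(ConsistencyError, match="sample mismatch"):
            expression.read_counts(*write_tables(tmp_path, counts, meta))

    def test_write_read_round_trip_is_bit_identical(self, tmp_path, small_counts):
        cpath, mpath = tmp_path / "c.tsv", tmp_path / "m.tsv"
        expression.write_counts(small_counts, cpath, mpath)
        back = expression.read_counts(cpath, mpath)
        pd.testing.assert_frame_equal(back.counts, small_counts.counts, check_names=False)


class TestComputeCpm:
    def test_forced_by_formula(self, jaw_metadata):
        meta = jaw_metadata.iloc[:1]
        cm = CountMatrix(
            counts=pd.DataFrame(
                [[2], [3], [5]], index=["a", "b", "c"], columns=meta["sample_id"]
            ),
            samples=meta,
        )
        cpm = expression.compute_cpm(cm)
        assert cpm.cpm.iloc[:, 0].tolist() == [200000.0, 300000.0, 500000.0]

    def test_single_count_in_million_read_library(self, jaw_metadata):
        meta = jaw_metadata.iloc[:1]
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1
        counts[1, 0] = 999_999
        cm = CountMatrix(
            counts=pd.DataFrame(counts, index=["a", "b"], columns=meta["sample_id"]),
            samples=meta,
        )
        assert expression.compute_cpm(cm).cpm.loc["a"].iloc[0] == pytest.approx(1.0)

    def test_columns_sum_to_one_million(self, small_counts):
        cpm = expression.compute_cpm(small_counts)
        np.testing.assert_allclose(cpm.cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_scale_invariance_per_sample(self, small_counts):
        scaled = small_counts.counts.copy()
        scaled.iloc[:, 0] *= 7
        cm2 = CountMatrix(counts=scaled, samples=small_counts.samples)
        a = expression.compute_cpm(small_counts).cpm
        b = expression.compute_cpm(cm2).cpm
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_names_offending_sample(self, jaw_metadata):
        meta = jaw_metadata.iloc[:2]
        counts = pd.DataFrame(
            [[5, 0], [5, 0]], index=["a", "b"], columns=meta["sample_id"]
        )
        cm = CountMatrix(counts=counts, samples=meta)
        with pytest.raises(EmptySelectionError, match=meta["sample_id"].iloc[1]):
            expression.compute_cpm(cm)


class TestAverageReplicates:
    def test_mean_of_two_replicates(self, jaw_metadata):
        meta = jaw_metadata[jaw_metadata["time_hours"] == 0.0]
        cpm = pd.DataFrame([[10.0, 20.0]], index=["g"], columns=meta["sample_id"])
        tp = expression.average_replicates(
            expression.CpmMatrix(cpm=cpm, samples=meta), "jaw"
        )
        assert tp.values.loc["g", 0.0] == 15.0

    def test_single_replicate_passes_through(self, jaw_metadata):
        meta = jaw_metadata[jaw_metadata["replicate"] == 1]
        rng = np.random.default_rng(0)
        cpm = pd.DataFrame(
            rng.uniform(0, 100, size=(3, len(meta))),
            index=["a", "b", "c"],
            columns=meta["sample_id"],
        )
        tp = expression.average_replicates(
            expression.CpmMatrix(cpm=cpm, samples=meta), "jaw"
        )
        np.testing.assert_allclose(tp.values.to_numpy(), cpm.to_numpy())

    def test_matches_brute_force_per_cell_mean(self, small_counts):
        cpm = expression.compute_cpm(small_counts)
        tp = expression.average_replicates(cpm, "jaw")
        for g in cpm.gene_ids:
            for t in tp.times:
                ids = small_counts.samples.loc[
                    small_counts.samples["time_hours"] == t, "sample_id"
                ]
                expected = np.mean([cpm.cpm.loc[g, s] for s in ids])
                assert tp.values.loc[g, t] == pytest.approx(expected)

    def test_commutes_with_gene_subsetting(self, small_counts):
        cpm = expression.compute_cpm(small_counts)
        full = expression.average_replicates(cpm, "jaw")
        sub_cpm = expression.CpmMatrix(
            cpm=cpm.cpm.loc[["g1", "g3"]], samples=cpm.samples
        )
        sub = expression.average_replicates(sub_cpm, "jaw")
        pd.testing.assert_frame_equal(sub.values, full.values.loc[["g1", "g3"]])

    def test_missing_structure_raises(self, small_counts):
        cpm = expression.compute_cpm(small_counts)
        with pytest.raises(EmptySelectionError):
            expression.average_replicates(cpm, "limb")
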