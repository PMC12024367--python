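"""Domain types, CSV round-trips, replicate averaging and subject splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spectrafuse as sf
from spectrafuse.data_model import (
    BiochemPanel,
    Cohort,
    LabeledSample,
    SpectraFormatError,
    SpectrumRecord,
    SplitError,
    WavenumberGrid,
    average_replicates,
    grouped_split,
    harmonize_grid,
    read_spectra_table,
    write_spectra_table,
)


def _record(sample_id, subject_id, absorbance, grid, rep=None):
    return SpectrumRecord(sample_id, subject_id, np.asarray(absorbance, float),
                          grid, replicate_index=rep)


class TestWavenumberGrid:
    def test_default_instrument_grid_has_1801_points(self):
        grid = WavenumberGrid()
        assert (grid.start, grid.stop, grid.step) == (400.0, 4000.0, 2.0)
        assert grid.n_points == 1801
        assert grid.values()[0] == 400.0 and grid.values()[-1] == 4000.0

    @pytest.mark.parametrize(
        "kwargs", [dict(start=500, stop=400), dict(step=0.0), dict(step=-2.0)]
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WavenumberGrid(**{"start": 400, "stop": 4000, "step": 2, **kwargs})

    def test_non_uniform_axis_rejected(self):
        with pytest.raises(SpectraFormatError):
            WavenumberGrid.from_values([400.0, 402.0, 405.0])


class TestSpectraTable:
    def test_three_row_default_grid_round_trip(self, tmp_path):
        grid = WavenumberGrid()
        rng = np.random.default_rng(0)
        records = [
            _record(f"s{i}", f"p{i}", rng.normal(size=grid.n_points), grid)
            for i in range(3)
        ]
        path = tmp_path / "spectra.csv"
        write_spectra_table(records, path)
        back = read_spectra_table(path)
        assert len(back) == 3
        for a, b in zip(records, back):
            assert b.absorbance.shape == (1801,)
            assert np.array_equal(a.absorbance, b.absorbance)  # text round-trip
            assert (a.sample_id, a.subject_id) == (b.sample_id, b.subject_id)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("sample_id,subject_id,400,402,404\n")
        assert read_spectra_table(path) == []

    def test_grid_mismatch_is_format_error(self, tmp_path):
        path = tmp_path / "coarse.csv"
        path.write_text("sample_id,subject_id,400,404,408\ns0,p0,1,2,3\n")
        with pytest.raises(SpectraFormatError):
            read_spectra_table(path, grid=WavenumberGrid(400, 408, 2))

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,subject_id,400,402\ns0,p0,1.0,oops\n")
        with pytest.raises(SpectraFormatError, match=r"402.*row 0|oops"):
            read_spectra_table(path)

    def test_replicate_column_round_trips(self, tmp_path):
        grid = WavenumberGrid(400, 404, 2)
        recs = [_record("s0", "p0", [1, 2, 3], grid, rep=r) for r in range(2)]
        path = tmp_path / "reps.csv"
        write_spectra_table(recs, path)
        assert "replicate" in path.read_text().splitlines()[0]
        back = read_spectra_table(path)
        assert [r.replicate_index for r in back] == [0, 1]


class TestAverageReplicates:
    grid = WavenumberGrid(400, 408, 2)

    def test_identical_replicates_average_to_themselves(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        recs = [_record("s0", "p0", v, self.grid, rep=r) for r in range(5)]
        out = average_replicates(recs)
        assert len(out) == 1
        assert np.array_equal(out[0].absorbance, v)
        assert out[0].replicate_index is None

    def test_midpoint_of_two_replicates(self):
        recs = [
            _record("s0", "p0", np.zeros(5), self.grid, rep=0),
            _record("s0", "p0", np.full(5, 2.0), self.grid, rep=1),
        ]
        assert np.array_equal(average_replicates(recs)[0].absorbance,
                              np.ones(5))

    def test_single_replicate_unchanged_and_idempotent(self):
        rec = _record("s0", "p0", [1, 2, 3, 4, 5], self.grid)
        once = average_replicates([rec])
        twice = average_replicates(once)
        assert np.array_equal(once[0].absorbance, rec.absorbance)
        assert np.array_equal(twice[0].absorbance, once[0].absorbance)

    def test_mismatched_grids_rejected(self):
        recs = [
            _record("s0", "p0", [1, 2, 3, 4, 5], self.grid),
            _record("s0", "p0", [1, 2, 3], WavenumberGrid(400, 404, 2)),
        ]
        with pytest.raises(SpectraFormatError):
            average_replicates(recs)


class TestHarmonizeGrid:
    def test_identity_on_matching_grids(self):
        grid = WavenumberGrid(400, 440, 2)
        rec = _record("s0", "p0", np.arange(grid.n_points), grid)
        out = harmonize_grid(rec, grid)
        assert np.array_equal(out.absorbance, rec.absorbance)

    def test_linear_ramp_resampled_exactly(self):
        src = WavenumberGrid(400, 440, 2)
        ramp = 0.5 * src.values() + 3.0  # affine signal: linear interp exact
        rec = _record("s0", "p0", ramp, src)
        target = WavenumberGrid(400, 440, 4)
        out = harmonize_grid(rec, target)
        assert np.allclose(out.absorbance, 0.5 * target.values() + 3.0,
                           rtol=0, atol=1e-12)

    def test_extrapolation_refused(self):
        src = WavenumberGrid(400, 4000, 2)
        rec = _record("s0", "p0", np.zeros(src.n_points), src)
        with pytest.raises(ValueError, match="extrapolat"):
            harmonize_grid(rec, WavenumberGrid(400, 4100, 2))


def _subject_cohort(n_pos, n_neg):
    """Minimal cohort with one tiny sample per subject."""
    grid = WavenumberGrid(400, 404, 2)
    names = ("a", "b")
    samples = []
    for i in range(n_pos + n_neg):
        label = int(i < n_pos)
        sid = f"subj{i:03d}"
        samples.append(
            LabeledSample(
                spectrum=_record(f"{sid}_s0", sid, [0.1, 0.2, 0.3], grid),
                panel=BiochemPanel(f"{sid}_s0", sid, np.array([1.0, 2.0]),
                                   names),
                label=label,
                subject_id=sid,
                group="aml" if label else "healthy",
            )
        )
    return Cohort(samples=samples)


class TestGroupedSplit:
    def test_94_subjects_partition_to_66_5_23(self):
        # 36 positive + 58 negative subjects at 7:0.5:2.5
        cohort = _subject_cohort(36, 58)
        split = grouped_split(cohort, seed=0).split
        from collections import Counter

        totals = Counter(split.values())
        assert (totals["train"], totals["val"], totals["test"]) == (66, 5, 23)
        labels = cohort.subject_labels()
        pos = Counter(split[s] for s in split if labels[s] == 1)
        assert (pos["train"], pos["val"], pos["test"]) == (25, 2, 9)

    def test_same_seed_reproduces_assignment(self, small_cohort):
        a = grouped_split(small_cohort, seed=42).split
        b = grouped_split(small_cohort, seed=42).split
        assert a == b

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_partitions_disjoint_cover_all_and_keep_both_classes(self, seed):
        cohort = _subject_cohort(10, 14)
        split = grouped_split(cohort, seed=seed).split
        assert set(split) == set(cohort.subject_ids())
        labels = cohort.subject_labels()
        for part in ("train", "val", "test"):
            members = [s for s, p in split.items() if p == part]
            assert members, part
            assert {labels[s] for s in members} == {0, 1}

    def test_too_small_cohort_raises_split_error(self):
        with pytest.raises(SplitError):
            grouped_split(_subject_cohort(2, 2), seed=0)

    def test_partition_view_contains_only_its_subjects(self, split_small_cohort):
        test_part = split_small_cohort.partition("test")
        split = split_small_cohort.split
        assert all(split[s.subject_id] == "test" for s in test_part.samples)
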