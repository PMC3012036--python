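"""Data model, I/O, normalization, missingness summaries, filtering."""

import numpy as np
import pytest
from scipy import stats as sps

from gelimpute import (
    FormatError,
    GroupDesign,
    SpotMatrix,
    SyntheticConfig,
    ValidationError,
    completeness_by_quartile,
    filter_majority_present,
    generate_complete_dataset,
    mean_normalize,
    missingness_by_gel,
    read_design,
    read_matrix,
    remove_at_random,
    remove_intensity_dependent,
    write_design,
    write_matrix,
)

from conftest import make_design, make_matrix


class TestGroupDesign:
    def test_two_groups_required(self):
        with pytest.raises(ValidationError):
            GroupDesign(("g1", "g2"), {"g1": "A", "g2": "A"})

    def test_min_two_gels_per_group(self):
        with pytest.raises(ValidationError):
            GroupDesign(("g1", "g2", "g3"), {"g1": "A", "g2": "A", "g3": "B"})

    def test_indices_align_with_gel_order(self):
        d = make_design(2, 3)
        assert list(d.indices("A")) == [0, 1]
        assert list(d.indices("B")) == [2, 3, 4]


class TestReadWrite:
    def test_read_counts_missing_cells(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "spot_id\tA1\tA2\tB1\tB2\n"
            "S1\t1.0\t2.0\t3.0\t4.0\n"
            "S2\tNA\t4.0\t1.0\t2.0\n"
            "S3\t5.0\t6.0\t7.0\t8.0\n"
        )
        m = read_matrix(path, make_design(2, 2))
        assert m.n_missing == 1
        assert np.isnan(m.values[1, 0])

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_matrix(path, make_design())

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("spot_id\tA1\tA2\tB1\tB2\nS1\t1\t2\t3\n")
        with pytest.raises(FormatError):
            read_matrix(path, make_design())

    def test_negative_volume_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("spot_id\tA1\tA2\tB1\tB2\nS1\t1\t-2\t3\t4\nS2\t1\t2\t3\t4\n")
        with pytest.raises(ValidationError):
            read_matrix(path, make_design())

    def test_duplicate_spot_id_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "spot_id\tA1\tA2\tB1\tB2\nS1\t1\t2\t3\t4\nS1\t1\t2\t3\t4\n"
        )
        with pytest.raises(ValidationError):
            read_matrix(path, make_design())

    def test_write_missing_token_counts(self, tmp_path):
        m = make_matrix([[1, 2, 3, np.nan]])
        out = write_matrix(m, tmp_path / "w.tsv")
        body = out.read_text().splitlines()[1:]
        assert sum(line.count("NA") for line in body) == 1
        complete = make_matrix([[1, 2, 3, 4]])
        out2 = write_matrix(complete, tmp_path / "w2.tsv")
        assert "NA" not in out2.read_text().split("\n", 1)[1]

    def test_round_trip_on_synthetic_matrix(self, tmp_path):
        ds = generate_complete_dataset(SyntheticConfig(seed=11))
        masked, _ = remove_at_random(ds.matrix, 0.21, seed=3)
        path = write_matrix(masked, tmp_path / "rt.tsv")
        back = read_matrix(path, masked.design)
        assert back.spot_ids == masked.spot_ids
        assert np.array_equal(np.isnan(back.values), np.isnan(masked.values))
        # identity up to the documented 6-significant-digit format
        ok = ~np.isnan(masked.values)
        np.testing.assert_allclose(back.values[ok], masked.values[ok], rtol=1e-5)

    def test_design_round_trip(self, tmp_path):
        d = make_design(3, 3)
        path = write_design(d, tmp_path / "d.tsv")
        assert read_design(path) == d


class TestMeanNormalize:
    def test_column_proportions(self):
        m = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0]]).repeat(4, axis=1))
        norm = mean_normalize(m)
        np.testing.assert_allclose(norm.values[:, 0], [0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(norm.values.sum(axis=0), 1.0)

    def test_missing_excluded_from_total(self):
        col = np.array([[5.0], [np.nan], [5.0]])
        m = make_matrix(np.hstack([col] * 4))
        norm = mean_normalize(m)
        np.testing.assert_allclose(norm.values[[0, 2], 0], [0.5, 0.5])
        assert np.isnan(norm.values[1, 0])

    def test_idempotent(self, default_matrix):
        once = mean_normalize(default_matrix)
        twice = mean_normalize(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_observed_sums_to_one_with_missing(self, default_matrix):
        masked, _ = remove_at_random(default_matrix, 0.2, seed=9)
        norm = mean_normalize(masked)
        np.testing.assert_allclose(np.nansum(norm.values, axis=0), 1.0, atol=1e-12)
        assert np.array_equal(np.isnan(norm.values), np.isnan(masked.values))

    def test_all_missing_gel_rejected(self):
        vals = np.ones((3, 4))
        vals[:, 2] = np.nan
        with pytest.raises(ValidationError):
            mean_normalize(make_matrix(vals))


class TestMissingness:
    def test_group_means_from_planted_counts(self):
        vals = np.ones((4, 4))
        vals[0, 0] = np.nan  # A1: 1 missing
        vals[0, 1] = np.nan  # A2: 1 missing
        vals[:3, 2] = np.nan  # B1: 3 missing
        vals[1:, 3] = np.nan  # B2: 3 missing
        s = missingness_by_gel(make_matrix(vals))
        assert s.group_means == {"A": 1.0, "B": 3.0}

    def test_identical_pattern_gives_p_one(self):
        vals = np.ones((4, 4))
        vals[0, :] = np.nan
        s = missingness_by_gel(make_matrix(vals))
        assert s.between_group_p == 1.0

    def test_welch_p_matches_closed_form(self):
        vals = np.ones((8, 6))
        counts = [5, 6, 7, 5, 7, 6]
        for j, c in enumerate(counts):
            vals[:c, j] = np.nan
        s = missingness_by_gel(make_matrix(vals, 3, 3))
        t, p = sps.ttest_ind([5.0, 6.0, 7.0], [5.0, 7.0, 6.0], equal_var=False)
        assert s.between_group_p == pytest.approx(p, rel=1e-12)


class TestCompletenessByQuartile:
    def test_counts_conserved_on_complete_matrix(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(1, 10, size=(8, 4)))
        counts = completeness_by_quartile(m)
        assert sum(counts.values()) == 8

    def test_low_intensity_missing_empties_bottom_quartile(self):
        vals = np.arange(1.0, 33.0).reshape(8, 4)  # rows ordered by mean
        vals[0, 0] = np.nan
        vals[1, 1] = np.nan
        counts = completeness_by_quartile(make_matrix(vals))
        assert counts[1] == 0
        assert sum(counts.values()) == 6

    def test_intensity_dependent_masking_yields_rising_profile(self, default_matrix):
        rising = 0
        for rep in range(100):
            masked, _ = remove_intensity_dependent(
                default_matrix, steepness=2.0, target_fraction=0.2, seed=rep
            )
            c = completeness_by_quartile(masked)
            if c[1] <= c[2] <= c[4] or c[1] <= c[3] <= c[4]:
                rising += 1
        assert rising > 50


class TestMajorityFilter:
    def test_strict_majority_boundary(self):
        vals = np.ones((2, 12))
        # spot 0: observed 4+4 of 6+6 -> kept; spot 1: observed 6+3 -> dropped
        vals[0, 4:6] = np.nan
        vals[0, 10:12] = np.nan
        vals[1, 6:9] = np.nan
        m = make_matrix(vals, 6, 6)
        kept = filter_majority_present(m)
        assert kept.spot_ids == ("S001",)

    def test_identity_on_complete(self, default_matrix):
        out = filter_majority_present(default_matrix)
        assert out.spot_ids == default_matrix.spot_ids
        np.testing.assert_array_equal(out.values, default_matrix.values)

    def test_idempotent(self, default_matrix):
        masked, _ = remove_at_random(default_matrix, 0.25, seed=1, min_per_group=1)
        once = filter_majority_present(masked)
        twice = filter_majority_present(once)
        assert once.spot_ids == twice.spot_ids

    def test_whole_matrix_rule(self):
        vals = np.ones((1, 4))
        vals[0, :2] = np.nan  # 2 of 4 observed: not a strict majority
        m = make_matrix(vals)
        assert filter_majority_present(m, per_group=False).n_spots == 0
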