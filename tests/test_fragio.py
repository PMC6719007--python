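"""Fragment reading, profile construction, tables and standardization."""

import numpy as np
import pytest

from fetalfrac.fragio import (FragmentSet, LengthProfile, ValidationError,
                              apply_standardizer, build_length_profile,
                              fit_standardizer, load_profile_table,
                              read_fragments, write_profile_table)
from fetalfrac.simulate import write_sam_fixture


class TestReadFragments:
    def test_counts_proper_pairs_once(self, tmp_path):
        sam = tmp_path / "s.sam"
        write_sam_fixture(sam, {"chr1": [166, 166], "chrY": [143]})
        fs = read_fragments(sam, min_mapq=40)
        assert fs.length_histogram == {166: 2, 143: 1}
        assert fs.per_chrom_fragments == {"chr1": 2, "chrY": 1}
        assert fs.total_fragments == 3

    def test_mapq_filter_excludes_everything(self, tmp_path):
        sam = tmp_path / "s.sam"
        write_sam_fixture(sam, {"chr1": [166, 166], "chrY": [143]})
        fs = read_fragments(sam, min_mapq=61)  # fixture reads are MAPQ 60
        assert fs.total_fragments == 0
        assert fs.length_histogram == {}

    def test_histogram_matches_generator_tally(self, tmp_path, rng):
        lengths = rng.integers(60, 210, size=1000).tolist()
        sam = tmp_path / "big.sam"
        tally = write_sam_fixture(sam, {"chr2": lengths}, seed=5)
        fs = read_fragments(sam)
        assert fs.length_histogram == tally
        assert fs.total_fragments == 1000

    def test_record_order_invariance(self, tmp_path, rng):
        lengths = rng.integers(60, 210, size=200).tolist()
        sam = tmp_path / "a.sam"
        write_sam_fixture(sam, {"chr1": lengths}, seed=3)
        lines = sam.read_text().splitlines(keepends=True)
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        rng.shuffle(body)
        shuffled = tmp_path / "b.sam"
        shuffled.write_text("".join(header + body))
        assert (read_fragments(sam).length_histogram
                == read_fragments(shuffled).length_histogram)

    def test_unreadable_source(self, tmp_path):
        bad = tmp_path / "x.sam"
        bad.write_text("not a sam file\n")
        with pytest.raises((IOError, ValueError)):
            read_fragments(bad)

    def test_chry_fraction(self, tmp_path):
        sam = tmp_path / "s.sam"
        write_sam_fixture(sam, {"chr1": [166] * 9, "chrY": [143]})
        fs = read_fragments(sam)
        assert fs.chry_fraction() == pytest.approx(0.1)
        # 'Y' and 'chrY' spellings are interchangeable
        assert fs.chrom_count("Y") == 1


class TestBuildLengthProfile:
    def test_basic_proportions(self):
        fs = FragmentSet("s", {166: 3, 143: 1}, {"chr1": 4})
        prof = build_length_profile(fs)
        assert prof.proportion_at(166) == 0.75
        assert prof.proportion_at(143) == 0.25
        assert prof.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_excluded_from_denominator(self):
        fs = FragmentSet("s", {40: 5, 166: 5}, {"chr1": 10})
        prof = build_length_profile(fs)
        assert prof.proportion_at(166) == 1.0

    def test_uniform_histogram(self):
        fs = FragmentSet("s", {l: 1 for l in range(50, 221)}, {"chr1": 171})
        prof = build_length_profile(fs)
        np.testing.assert_allclose(prof.proportions, 1 / 171)

    def test_empty_in_range_errors(self):
        fs = FragmentSet("s", {30: 5}, {"chr1": 5})
        with pytest.raises(ValidationError):
            build_length_profile(fs)


class TestProfileTable:
    def test_round_trip(self, tmp_path, small_cohort):
        sub = small_cohort.subset(range(10))
        path = tmp_path / "profiles.tsv"
        write_profile_table(sub, path)
        back = load_profile_table(path)
        assert back.n == 10
        for a, b in zip(sub.records, back.records):
            assert a.sample_id == b.sample_id
            np.testing.assert_allclose(a.profile.proportions,
                                       b.profile.proportions, atol=1e-12)
            assert b.true_ff == pytest.approx(a.true_ff, abs=1e-12)
            assert b.reference_ff == pytest.approx(a.reference_ff, abs=1e-12)

    def test_count_rows_normalized(self, tmp_path):
        cols = "\t".join(f"L{i}" for i in range(50, 221))
        vals = "\t".join("2" for _ in range(171))
        (tmp_path / "c.tsv").write_text(f"sample_id\t{cols}\nA\t{vals}\n")
        ds = load_profile_table(tmp_path / "c.tsv")
        assert ds.n == 1
        np.testing.assert_allclose(ds.records[0].profile.proportions, 1 / 171)

    def test_bad_proportion_sum_names_sample(self, tmp_path):
        cols = "\t".join(f"L{i}" for i in range(50, 221))
        vals = "\t".join(["0.5"] + ["0"] * 170)  # sums to 0.5
        (tmp_path / "c.tsv").write_text(f"sample_id\t{cols}\nbadrow\t{vals}\n")
        with pytest.raises(ValidationError, match="badrow"):
            load_profile_table(tmp_path / "c.tsv")

    def test_missing_length_columns(self, tmp_path):
        (tmp_path / "c.tsv").write_text("sample_id\tL50\nA\t1\n")
        with pytest.raises(Exception, match="missing length columns"):
            load_profile_table(tmp_path / "c.tsv")


class TestStandardizer:
    def test_two_point_feature(self):
        X = np.tile([[0.2], [0.4]], (1, 171)) * np.ones((2, 171))
        std = fit_standardizer(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z[0], -1.0)
        np.testing.assert_allclose(Z[1], 1.0)

    def test_constant_feature_maps_to_zero(self, random_profiles):
        X = random_profiles.copy()
        X[:, 5] = 0.123
        std = fit_standardizer(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z[:, 5], 0.0, atol=1e-12)
        assert np.all(np.isfinite(Z))

    def test_training_set_mean_zero_var_one(self, random_profiles):
        std = fit_standardizer(random_profiles)
        Z = std.transform(random_profiles)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.var(axis=0), 1.0, atol=1e-10)

    def test_mean_profile_maps_to_zero_row(self, random_profiles):
        std = fit_standardizer(random_profiles)
        z = std.transform(random_profiles.mean(axis=0)[None, :])
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_needs_two_profiles(self, random_profiles):
        with pytest.raises(ValidationError):
            fit_standardizer(random_profiles[:1])

    def test_applies_unchanged_to_held_out(self, random_profiles):
        std = fit_standardizer(random_profiles[:40])
        Z = apply_standardizer(std, random_profiles[40:])
        expect = (random_profiles[40:] - std.mean_) / std.scale_
        np.testing.assert_allclose(Z, expect)
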