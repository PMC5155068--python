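import numpy as np
import pandas as pd
import pytest

from damscan.ingest import (
    IpdObservationSet,
    SampleMetadata,
    clean_observations,
    cleaned_frame,
    partition_by_site,
    read_ipd_table,
    read_metadata,
)
from damscan.motifs import MotifSite
from damscan.synthetic import write_table

META = [
    SampleMetadata("s1", "timepoint", 8.0),
    SampleMetadata("dam", "dam_control"),
]


def write_tsv(tmp_path, rows, name="ipd.tsv"):
    header = "genome_id\tposition\tstrand\tbase\tipd\tsample_id\n"
    path = tmp_path / name
    path.write_text(header + "".join(rows))
    return path


class TestReadTable:
    def test_well_formed_rows_all_accepted(self, tmp_path):
        path = write_tsv(
            tmp_path,
            [f"g\t{p}\t+\tA\t1.5\ts1\n" for p in (10, 20, 30)],
        )
        df, report = read_ipd_table(path, META)
        assert len(df) == 3
        assert report.n_rejected == 0
        assert set(df["role"]) == {"timepoint"}

    def test_na_ipd_rejected_with_line_number_and_parse_continues(self, tmp_path):
        path = write_tsv(
            tmp_path,
            ["g\t10\t+\tA\t1.5\ts1\n", "g\t20\t+\tA\tNA\ts1\n", "g\t30\t+\tA\t2.0\ts1\n"],
        )
        df, report = read_ipd_table(path, META)
        assert len(df) == 2
        assert report.rejects == [(3, "non-positive or non-numeric ipd")]

    def test_unknown_sample_rejected(self, tmp_path):
        path = write_tsv(tmp_path, ["g\t10\t+\tA\t1.5\tmystery\n"])
        df, report = read_ipd_table(path, META)
        assert df.empty
        assert report.rejects[0][1] == "unknown sample_id"

    def test_position_bounds_enforced(self, tmp_path):
        path = write_tsv(tmp_path, ["g\t999\t+\tA\t1.5\ts1\n"])
        df, report = read_ipd_table(path, META, genome_length=100)
        assert df.empty and report.rejects[0][1] == "invalid position"

    def test_missing_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genome_id\tposition\tipd\n" "g\t1\t2.0\n")
        with pytest.raises(ValueError, match="missing required"):
            read_ipd_table(path, META)

    def test_simulator_output_roundtrips(self, tmp_path, small_timecourse):
        path = tmp_path / "ipd.tsv"
        write_table(small_timecourse.ipd_table, path)
        meta = read_metadata_from(small_timecourse.metadata, tmp_path)
        df, report = read_ipd_table(path, meta)
        assert report.n_rejected == 0
        assert len(df) == len(small_timecourse.ipd_table)
        np.testing.assert_allclose(
            df["ipd"].to_numpy(), small_timecourse.ipd_table["ipd"].to_numpy()
        )


def read_metadata_from(metadata_df, tmp_path):
    path = tmp_path / "meta.tsv"
    write_table(metadata_df, path)
    return read_metadata(path)


class TestClean:
    def make_records(self, values, sample="s1", position=10, strand="+"):
        return pd.DataFrame(
            {
                "position": position,
                "strand": strand,
                "sample_id": sample,
                "ipd": np.asarray(values, dtype=float),
            }
        )

    def test_outlier_cutoff_application(self):
        sets, report = clean_observations(self.make_records([3, 7, 60_000]), min_coverage=1)
        obs = sets[(10, "+", "s1")]
        assert sorted(obs.kept_values) == [3, 7]
        assert obs.n_raw == 3 and obs.n_kept == 2
        assert report.outliers_removed["s1"] == 1

    def test_coverage_threshold_is_inclusive(self):
        at19, _ = clean_observations(self.make_records(range(1, 20)))
        at20, _ = clean_observations(self.make_records(range(1, 21)))
        assert at19[(10, "+", "s1")].excluded
        assert not at20[(10, "+", "s1")].excluded

    def test_cleaning_is_idempotent(self, small_timecourse):
        sets, _ = clean_observations(small_timecourse.ipd_table)
        flat = cleaned_frame(sets)
        again, report2 = clean_observations(flat, min_coverage=1)
        assert sum(report2.outliers_removed.values()) == 0
        assert report2.n_raw_total == report2.n_kept_total

    def test_conservation_against_report(self, small_timecourse):
        sets, report = clean_observations(small_timecourse.ipd_table)
        n_raw = sum(o.n_raw for o in sets.values())
        n_kept = sum(o.n_kept for o in sets.values())
        assert n_raw == report.n_raw_total == len(small_timecourse.ipd_table)
        assert n_kept == report.n_kept_total
        assert n_raw - n_kept == sum(report.outliers_removed.values())

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            clean_observations(self.make_records([1.0]), outlier_cutoff=0)
        with pytest.raises(ValueError):
            clean_observations(self.make_records([1.0]), min_coverage=0)


class TestPartition:
    def sites(self):
        return [MotifSite("g", 10, "+"), MotifSite("g", 20, "+")]

    def build_sets(self):
        rows = []
        for pos in (10, 20):
            for sid in ("s1", "s2", "dam"):
                rows.append(
                    pd.DataFrame(
                        {"position": pos, "strand": "+", "sample_id": sid, "ipd": np.ones(25)}
                    )
                )
        sets, _ = clean_observations(pd.concat(rows, ignore_index=True))
        return sets

    def test_full_grid_of_cells(self):
        table = partition_by_site(self.build_sets(), self.sites())
        assert len(table) == 6
        assert all(v is not None for v in table.values())

    def test_excluded_cell_marked_missing_not_dropped(self):
        sets = self.build_sets()
        key = (10, "+", "s1")
        sets[key] = IpdObservationSet(10, "+", "s1", np.ones(5), np.ones(5), excluded=True)
        table = partition_by_site(sets, self.sites())
        assert table[((10, "+"), "s1")] is None
        assert len(table) == 6

    def test_unknown_site_key_errors(self):
        with pytest.raises(KeyError, match="non-motif"):
            partition_by_site(self.build_sets(), self.sites()[:1])

    def test_kept_totals_conserved(self):
        sets = self.build_sets()
        table = partition_by_site(sets, self.sites())
        total_cells = sum(v.n_kept for v in table.values() if v is not None)
        assert total_cells == sum(o.n_kept for o in sets.values())
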