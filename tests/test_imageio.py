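import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from camphen import imageio as cio


class TestFilenameParsing:
    @pytest.mark.parametrize(
        "name, site, ts",
        [
            ("snipelake_2017_06_21_120000.jpg", "snipelake",
             dt.datetime(2017, 6, 21, 12, 0, 0)),
            ("acadia_2011_01_01_000000.jpg", "acadia",
             dt.datetime(2011, 1, 1, 0, 0, 0)),
            ("two_part_2015_12_31_235959.jpeg", "two_part",
             dt.datetime(2015, 12, 31, 23, 59, 59)),
        ],
    )
    def test_valid_names(self, name, site, ts):
        assert cio.parse_image_filename(name) == (site, ts)

    @pytest.mark.parametrize(
        "name, fragment",
        [
            ("a_b_2017_13_40_999999.jpg", "month 13"),
            ("x_2017_06_21_250000.jpg", "hour 25"),
            ("x_2017_02_30_120000.jpg", "day 30"),
            ("no_timestamp_here.jpg", "does not match"),
        ],
    )
    def test_malformed_names_name_the_component(self, name, fragment):
        with pytest.raises(cio.FilenameParseError, match=fragment):
            cio.parse_image_filename(name)

    @settings(max_examples=50, derandomize=True)
    @given(
        site=st.from_regex(r"[a-z]{1,8}(_[a-z]{1,8})?", fullmatch=True),
        ts=st.datetimes(
            min_value=dt.datetime(2000, 1, 1),
            max_value=dt.datetime(2030, 12, 31, 23, 59, 59),
        ).map(lambda t: t.replace(microsecond=0)),
    )
    def test_format_parse_roundtrip(self, site, ts):
        name = cio.format_image_filename(site, ts)
        assert cio.parse_image_filename(name) == (site, ts)


class TestMasks:
    def _write(self, tmp_path, arr):
        path = tmp_path / "m.tif"
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
        return path

    def test_full_frame_roi(self, tmp_path):
        mask = cio.read_mask(self._write(tmp_path, np.zeros((4, 4))))
        assert mask.n_inside == 16
        assert mask.mask.all()

    def test_empty_roi_rejected(self, tmp_path):
        with pytest.raises(cio.ValidationError, match="empty ROI"):
            cio.read_mask(self._write(tmp_path, np.full((4, 4), 255)))

    def test_zero_pixels_counted(self, tmp_path):
        mask = cio.read_mask(self._write(tmp_path, np.array([[0, 255], [255, 0]])))
        assert mask.n_inside == 2

    def test_multiband_rejected(self, tmp_path):
        path = tmp_path / "rgb.tif"
        Image.fromarray(np.zeros((4, 4, 3), dtype=np.uint8)).save(path)
        with pytest.raises(cio.FormatError):
            cio.read_mask(path)

    def test_read_matches_bruteforce_count_and_is_idempotent(self, tmp_path):
        rng = np.random.default_rng(0)
        for _ in range(5):
            arr = rng.choice([0, 255], size=(6, 7))
            if (arr == 0).sum() == 0:
                arr[0, 0] = 0
            path = self._write(tmp_path, arr)
            m1, m2 = cio.read_mask(path), cio.read_mask(path)
            brute = sum(
                1 for i in range(6) for j in range(7) if arr[i, j] == 0
            )
            assert m1.n_inside == brute
            assert np.array_equal(m1.mask, m2.mask)

    def test_invert_flag_flips_polarity(self, tmp_path):
        path = self._write(tmp_path, np.array([[0, 255], [255, 255]]))
        assert cio.read_mask(path).n_inside == 1
        assert cio.read_mask(path, invert=True).n_inside == 3


class TestROIDefinition:
    def _write_csv(self, tmp_path, rows, name="x_DB_1000_roi.csv"):
        path = tmp_path / name
        lines = ["# test ROI list", "start_date,start_time,end_date,end_time,maskfile"]
        lines += rows
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_single_interval(self, tmp_path):
        path = self._write_csv(
            tmp_path,
            ["2015-01-01,00:00:00,2016-01-01,00:00:00,x_DB_1000_01.tif"],
        )
        rd = cio.read_roi_definition(path)
        assert (rd.site, rd.veg_type, rd.roi_id) == ("x", "DB", 1000)
        assert len(rd.intervals) == 1
        assert rd.mask_path_for(dt.datetime(2015, 6, 1)) == "x_DB_1000_01.tif"
        assert rd.mask_path_for(dt.datetime(2017, 6, 1)) is None

    def test_open_ended_final_interval(self, tmp_path):
        path = self._write_csv(
            tmp_path, ["2015-01-01,00:00:00,9999-01-01,00:00:00,x_DB_1000_01.tif"]
        )
        rd = cio.read_roi_definition(path)
        assert rd.intervals[0][2] == cio.OPEN_END
        assert rd.mask_path_for(dt.datetime(2030, 1, 1)) == "x_DB_1000_01.tif"

    def test_overlapping_intervals_rejected(self, tmp_path):
        path = self._write_csv(
            tmp_path,
            [
                "2015-01-01,00:00:00,2016-01-01,00:00:00,a.tif",
                "2015-06-01,00:00:00,2017-01-01,00:00:00,b.tif",
            ],
        )
        with pytest.raises(cio.ValidationError, match="overlap"):
            cio.read_roi_definition(path)

    def test_unknown_veg_type_rejected(self, tmp_path):
        path = self._write_csv(
            tmp_path,
            ["2015-01-01,00:00:00,2016-01-01,00:00:00,a.tif"],
            name="x_ZZ_1000_roi.csv",
        )
        with pytest.raises(cio.ValidationError, match="ZZ"):
            cio.read_roi_definition(path)


def _random_roistats(rng, n=10):
    dates = [dt.date(2018, 3, 1) + dt.timedelta(days=i) for i in range(n)]
    df = pd.DataFrame(
        {
            "filename": [f"f{i}.jpg" for i in range(n)],
            "date": dates,
            "local_std_time": ["12:00:00"] * n,
            "doy": [d.timetuple().tm_yday for d in dates],
            "r_mean": rng.uniform(0, 255, n).round(5),
            "r_std": rng.uniform(0, 30, n).round(5),
            "g_mean": rng.uniform(0, 255, n).round(5),
            "g_std": rng.uniform(0, 30, n).round(5),
            "b_mean": rng.uniform(0, 255, n).round(5),
            "b_std": rng.uniform(0, 30, n).round(5),
            "rcc": rng.uniform(0, 1, n).round(5),
            "gcc": rng.uniform(0, 1, n).round(5),
            "bcc": rng.uniform(0, 1, n).round(5),
            "brightness": rng.uniform(0, 1, n).round(5),
            "darkness": rng.uniform(0, 1, n).round(5),
            "contrast": rng.uniform(0, 1, n).round(5),
            "delta": rng.uniform(0, 0.5, n).round(5),
            "haze_degree": rng.uniform(0, 100, n).round(5),
            "qc_flag": rng.integers(0, 16, n),
        }
    )
    return cio.RoiStatsTable("rt", "GR", 1, df)


class TestDataRecordRoundTrip:
    def test_roistats_roundtrip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(1)
        table = _random_roistats(rng)
        path = tmp_path / "rt_GR_0001_roistats.csv"
        cio.write_data_record(table, path)
        back = cio.read_data_record(path)
        assert (back.site, back.veg_type, back.roi_id) == ("rt", "GR", 1)
        pd.testing.assert_frame_equal(back.df, table.df, check_dtype=False)

    def test_summary_roundtrip_preserves_missing_windows(self, tmp_path):
        dates = [dt.date(2019, 1, 1) + dt.timedelta(days=i) for i in range(6)]
        df = pd.DataFrame(
            {
                "date": dates,
                "year": [2019] * 6,
                "doy": list(range(1, 7)),
                "image_count": [3, 0, 2, 1, 0, 5],
                "midday_gcc": [0.41, np.nan, 0.42, 0.4, np.nan, 0.44],
                "gcc_90": [0.42, np.nan, 0.43, 0.41, np.nan, 0.45],
                "rcc_90": [0.3] * 6,
                "bcc_90": [0.27] * 6,
                "smooth_gcc": [0.42, 0.42, 0.43, 0.42, 0.43, 0.44],
                "ci_low": [0.41] * 6,
                "ci_high": [0.45] * 6,
                "outlier_flag": [0, 0, 0, 1, 0, 0],
            }
        )
        series = cio.SummarySeries("s", "EN", 2, 1, df)
        path = tmp_path / "s_EN_0002_1day.csv"
        cio.write_data_record(series, path)
        back = cio.read_data_record(path)
        assert back.interval == 1
        pd.testing.assert_frame_equal(back.df, df, check_dtype=False)

    def test_empty_summary_writes_header_and_columns_only(self, tmp_path):
        series = cio.SummarySeries(
            "s", "EN", 2, 3,
            pd.DataFrame(columns=["date", "year", "doy", "image_count", "gcc_90"]),
        )
        path = tmp_path / "empty.csv"
        cio.write_data_record(series, path)
        text = path.read_text().splitlines()
        assert text[0].startswith("#")
        assert "date,year,doy,image_count,gcc_90" in text
        back = cio.read_data_record(path)
        assert back.df.empty and list(back.df.columns) == list(series.df.columns)

    def test_transition_roundtrip_with_ci_columns(self, tmp_path):
        df = pd.DataFrame(
            {
                "cycle_id": [0, 0, 0],
                "direction": ["rising"] * 3,
                "threshold_percent": [10, 25, 50],
                "transition_date": [dt.date(2018, 5, 9), dt.date(2018, 5, 15),
                                    dt.date(2018, 5, 20)],
                "ci_low_date": [dt.date(2018, 5, 8), dt.date(2018, 5, 14),
                                dt.date(2018, 5, 19)],
                "ci_high_date": [dt.date(2018, 5, 10), dt.date(2018, 5, 16),
                                 dt.date(2018, 5, 21)],
                "gcc_at_threshold": [0.34, 0.355, 0.38],
            }
        )
        tset = cio.TransitionSet("s", "DB", 1, 3, df)
        path = tmp_path / "tr.csv"
        cio.write_data_record(tset, path)
        back = cio.read_data_record(path)
        assert set(back.df.columns) >= {
            "threshold_percent", "transition_date", "ci_low_date", "ci_high_date"
        }
        pd.testing.assert_frame_equal(back.df, df, check_dtype=False)

    def test_roundtrip_fuzzed_tables(self, tmp_path):
        rng = np.random.default_rng(7)
        for i in range(5):
            table = _random_roistats(rng, n=int(rng.integers(1, 20)))
            path = tmp_path / f"fuzz{i}.csv"
            cio.write_data_record(table, path)
            back = cio.read_data_record(path)
            pd.testing.assert_frame_equal(back.df, table.df, check_dtype=False)
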