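"""Tests for minute-epoch ingest, per-minute PAL and non-wear detection."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import nonwear_grammar_sequences, nonwear_oracle
from tailorpa.accel import (
    EpochParseError,
    MinuteSeries,
    detect_nonwear,
    pal_per_minute,
    read_minute_epochs,
    summarize_day,
    write_minute_epochs,
)

LOW, HIGH = 1.30, 1.50


def make_series(tmp_path, rows):
    path = tmp_path / "epochs.csv"
    pd.DataFrame(rows, columns=["participant_id", "timestamp", "counts", "position"]).to_csv(
        path, index=False
    )
    return path


class TestReadMinuteEpochs:
    def test_two_day_file_round_trip(self, tmp_path):
        idx = pd.date_range("2013-03-01", periods=2880, freq="min")
        frame = pd.DataFrame({"counts": np.arange(2880.0), "position": "belt"}, index=idx)
        series = MinuteSeries("P1", frame)
        path = tmp_path / "out.csv"
        write_minute_epochs(series, path)
        back = read_minute_epochs(path)
        assert back.n_epochs == 2880
        assert back.participant_id == "P1"
        np.testing.assert_allclose(back.frame["counts"], frame["counts"])

    def test_duplicate_timestamp_rejected(self, tmp_path):
        path = make_series(
            tmp_path,
            [
                ("P1", "2013-03-01T10:00:00", 5, "belt"),
                ("P1", "2013-03-01T10:00:00", 7, "belt"),
            ],
        )
        with pytest.raises(EpochParseError, match="2013-03-01 10:00"):
            read_minute_epochs(path)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        path = make_series(
            tmp_path,
            [
                ("P1", "2013-03-01T10:01:00", 5, "belt"),
                ("P1", "2013-03-01T10:00:00", 7, "belt"),
            ],
        )
        with pytest.raises(EpochParseError, match="increasing"):
            read_minute_epochs(path)

    def test_malformed_counts_named_with_line(self, tmp_path):
        path = make_series(
            tmp_path,
            [
                ("P1", "2013-03-01T10:00:00", 5, "belt"),
                ("P1", "2013-03-01T10:01:00", "oops", "belt"),
            ],
        )
        with pytest.raises(EpochParseError, match="line 3"):
            read_minute_epochs(path)

    def test_position_change_mid_stream_preserved(self, tmp_path):
        idx = pd.date_range("2013-03-01", periods=1440, freq="min")
        positions = np.where(np.arange(1440) < 720, "belt", "pocket")
        frame = pd.DataFrame({"counts": 1.0, "position": positions}, index=idx)
        path = tmp_path / "pos.csv"
        write_minute_epochs(MinuteSeries("P1", frame), path)
        back = read_minute_epochs(path)
        assert (back.frame["position"].iloc[:720] == "belt").all()
        assert (back.frame["position"].iloc[720:] == "pocket").all()


class TestPalPerMinute:
    def test_zero_counts_gives_intercept(self, position_table):
        assert pal_per_minute(0, "belt", position_table) == 1.354

    def test_constant_rate_matches_daily_equation(self, position_table):
        # 1440 minutes at c counts/min -> per-minute PAL equals the daily
        # equation applied to counts_day = 1440 c
        c = 500.0
        from tailorpa.energy import daily_pal

        assert pal_per_minute(c, "belt", position_table) == pytest.approx(
            daily_pal(1440 * c)
        )

    def test_nonwear_threshold_count_rate(self, position_table):
        # counts solving pal_min = 1.3889: corrected counts*1440 = (1.3889-1.354)/256e-9
        counts_min = (1.3889 - 1.354) / 256e-9 / 1440
        assert pal_per_minute(counts_min, "belt", position_table) == pytest.approx(
            1.3889
        )


class TestDetectNonwear:
    def test_90_minutes_low_is_nonwear(self):
        pal = np.array([HIGH] * 10 + [LOW] * 90 + [HIGH] * 10)
        wear = detect_nonwear(pal)
        assert (~wear).sum() == 90
        assert not wear[10:100].any()

    def test_89_minutes_low_is_wear(self):
        pal = np.array([HIGH] * 10 + [LOW] * 89 + [HIGH] * 10)
        assert detect_nonwear(pal).all()

    def test_two_minute_spike_absorbed(self):
        pal = np.array([LOW] * 50 + [HIGH] * 2 + [LOW] * 50)
        assert (~detect_nonwear(pal)).sum() == 102

    def test_three_minute_spike_splits_runs(self):
        pal = np.array([LOW] * 50 + [HIGH] * 3 + [LOW] * 50)
        assert detect_nonwear(pal).all()

    def test_spike_with_only_short_flanks_terminates(self):
        # flanks of 29 on both sides: spike inadmissible, runs split (<90)
        pal = np.array([HIGH] * 5 + [LOW] * 29 + [HIGH] * 2 + [LOW] * 29 + [HIGH] * 5)
        assert detect_nonwear(pal).all()

    def test_one_sided_flank_suffices(self):
        # 30 low upstream, 60 low downstream: both windows together >= 90
        pal = np.array([LOW] * 30 + [HIGH] * 2 + [LOW] * 60)
        assert (~detect_nonwear(pal)).sum() == 92

    def test_missing_epochs_count_as_subthreshold(self):
        pal = np.array([np.nan] * 90 + [HIGH] * 10)
        assert (~detect_nonwear(pal)).sum() == 90

    def test_idempotent_under_masking(self, rng):
        pal = rng.choice([LOW, HIGH], size=500, p=[0.7, 0.3])
        wear = detect_nonwear(pal)
        masked = np.where(wear, pal, LOW)
        np.testing.assert_array_equal(detect_nonwear(masked), wear)

    def test_matches_brute_force_on_random_run_grammar(self, rng):
        for _ in range(60):
            lengths = rng.integers(1, 95, size=rng.integers(1, 7))
            start_low = bool(rng.integers(0, 2))
            seq = []
            is_low = start_low
            for ln in lengths:
                seq.extend([LOW if is_low else HIGH] * int(ln))
                is_low = not is_low
            pal = np.array(seq)
            np.testing.assert_array_equal(
                ~detect_nonwear(pal), nonwear_oracle(pal), err_msg=str(lengths)
            )

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.sampled_from([LOW, HIGH]), min_size=1, max_size=140),
    )
    def test_matches_brute_force_on_arbitrary_sequences(self, values):
        pal = np.array(values)
        np.testing.assert_array_equal(~detect_nonwear(pal), nonwear_oracle(pal))

    def test_lengthening_a_low_run_never_unmarks_nonwear(self, rng):
        # monotonicity: growing a sub-threshold run keeps non-wear minutes non-wear
        for _ in range(25):
            pal = rng.choice([LOW, HIGH], size=200, p=[0.6, 0.4])
            nonwear_before = ~detect_nonwear(pal)
            low_pos = np.flatnonzero(pal == LOW)
            if low_pos.size == 0:
                continue
            p = int(rng.choice(low_pos))
            extended = np.insert(pal, p, [LOW] * 5)
            nonwear_after = ~detect_nonwear(extended)
            # map original indices onto the extended series
            orig_idx = np.concatenate([np.arange(p), np.arange(p + 5, 205)])
            assert not np.any(nonwear_before & ~nonwear_after[orig_idx])


class TestSummarizeDay:
    def make_mask(self, wear_minutes):
        mask = np.zeros(1440, dtype=bool)
        mask[:wear_minutes] = True
        return mask

    @pytest.mark.parametrize(
        "wear,valid",
        [(600, True), (599, False), (1080, True), (1081, False), (900, True)],
    )
    def test_validity_bounds_inclusive(self, wear, valid):
        s = summarize_day(dt.date(2013, 3, 6), self.make_mask(wear))
        assert s.wear_time == wear
        assert s.nonwear_time == 1440 - wear
        assert s.is_valid is valid

    def test_saturday_and_sunday_are_weekend(self):
        assert summarize_day(dt.date(2013, 3, 9), self.make_mask(700)).is_weekend
        assert summarize_day(dt.date(2013, 3, 10), self.make_mask(700)).is_weekend
        assert not summarize_day(dt.date(2013, 3, 8), self.make_mask(700)).is_weekend

    def test_missing_epochs_are_nonwear(self):
        present = np.zeros(1440, dtype=bool)
        present[:700] = True
        s = summarize_day(dt.date(2013, 3, 6), np.ones(1440, bool), present)
        assert s.wear_time == 700
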