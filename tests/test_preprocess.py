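import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hyraxnet.preprocess import (
    ACTIVE,
    DAY,
    NIGHT,
    PASSIVE,
    PhaseConfig,
    classify_context,
    deduplicate,
    discretize,
    label_phase,
    preprocess_records,
)

PC = PhaseConfig(start_date=dt.date(2017, 7, 1), n_days=27)
EPOCH = PC.epoch


def rec(reporter, partner, start, duration_s):
    return {"reporter": reporter, "partner": partner,
            "start": pd.Timestamp(start), "duration_s": duration_s}


# ---------------------------------------------------------------------------
# PhaseConfig


def test_27_days_give_54_periods():
    assert PC.n_periods == 54


def test_period_slot_counts_match_window_lengths():
    # day 06:00-19:30 = 13.5 h = 162 slots; night 19:30-06:00 = 10.5 h = 126
    assert PC.n_slots(0) == 162
    assert PC.n_slots(1) == 126
    assert sum(PC.n_slots(p) for p in range(PC.n_periods)) == 27 * 288


def test_period_bounds_are_contiguous_and_ordered():
    prev_end = None
    for p in range(PC.n_periods):
        lo, hi = PC.period_bounds(p)
        assert lo < hi
        if prev_end is not None:
            assert lo == prev_end
        prev_end = hi
    assert PC.period_bounds(0)[0] == PC.epoch
    assert prev_end == PC.span_end


def test_locate_closed_left_at_dawn_and_dusk():
    d, ph, p = PC.locate(pd.Timestamp("2017-07-01 06:00:00"))
    assert (ph, p) == (DAY, 0)
    d, ph, p = PC.locate(pd.Timestamp("2017-07-01 19:30:00"))
    assert (ph, p) == (NIGHT, 1)


def test_locate_after_midnight_belongs_to_preceding_night():
    d, ph, p = PC.locate(pd.Timestamp("2017-07-02 00:15:00"))
    assert d == dt.date(2017, 7, 1)
    assert (ph, p) == (NIGHT, 1)


def test_locate_rejects_timestamps_outside_span():
    with pytest.raises(ValueError):
        PC.locate(pd.Timestamp("2017-07-01 05:59:59"))
    with pytest.raises(ValueError):
        PC.locate(PC.span_end)


def test_per_date_overrides_shift_the_boundary():
    pc = PhaseConfig(
        start_date=dt.date(2017, 7, 1), n_days=2,
        overrides={dt.date(2017, 7, 2): (dt.time(5, 0), dt.time(20, 0))},
    )
    assert pc.locate(pd.Timestamp("2017-07-02 05:30:00"))[1] == DAY
    with pytest.raises(ValueError):
        PhaseConfig(start_date=dt.date(2017, 7, 1), n_days=1,
                    day_start=dt.time(20, 0), day_end=dt.time(6, 0))


# ---------------------------------------------------------------------------
# classify_context


def test_threshold_exactly_25_minutes_is_active():
    assert classify_context(1500) == ACTIVE
    assert classify_context(1501) == PASSIVE
    assert classify_context(11) == ACTIVE


def test_context_partition_is_exhaustive_and_exclusive():
    out = classify_context(np.array([11, 1500, 1501, 25605]))
    assert set(out) <= {ACTIVE, PASSIVE}


# ---------------------------------------------------------------------------
# discretize


def test_11_second_record_inside_one_slot_gives_one_event():
    df = pd.DataFrame([rec("a", "b", EPOCH + pd.Timedelta(seconds=30), 11)])
    ev = discretize(df, EPOCH)
    assert len(ev) == 1
    assert ev["context"].iloc[0] == ACTIVE


def test_120_second_record_straddling_a_boundary_gives_two_events():
    df = pd.DataFrame([rec("a", "b", EPOCH + pd.Timedelta(seconds=240), 120)])
    ev = discretize(df, EPOCH)
    assert len(ev) == 2
    assert ev["interval_index"].tolist() == [0, 1]


def test_25605_second_record_at_slot_boundary_gives_86_events():
    df = pd.DataFrame([rec("a", "b", EPOCH, 25605)])
    ev = discretize(df, EPOCH)
    assert len(ev) == 86
    assert (ev["context"] == PASSIVE).all()


def test_overlapping_same_dyad_records_merge_keeping_longest_parent():
    df = pd.DataFrame([
        rec("a", "b", EPOCH + pd.Timedelta(seconds=10), 60),
        rec("b", "a", EPOCH + pd.Timedelta(seconds=20), 2000),
    ])
    ev = discretize(df, EPOCH)
    slot0 = ev[ev["interval_index"] == 0]
    assert len(slot0) == 1
    assert slot0["source_duration_s"].iloc[0] == 2000
    assert slot0["context"].iloc[0] == PASSIVE


def test_dyad_endpoints_are_stored_in_canonical_order():
    df = pd.DataFrame([rec("z", "a", EPOCH, 30)])
    ev = discretize(df, EPOCH)
    assert ev["dyad_a"].iloc[0] == "a"
    assert ev["dyad_b"].iloc[0] == "z"


def test_non_positive_duration_rejected():
    df = pd.DataFrame([rec("a", "b", EPOCH, 0)])
    with pytest.raises(ValueError):
        discretize(df, EPOCH)


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=7),   # reporter
            st.integers(min_value=0, max_value=7),   # partner
            st.integers(min_value=0, max_value=5000),  # start offset (s)
            st.integers(min_value=1, max_value=2000),  # duration
        ),
        min_size=1,
        max_size=25,
    )
)
def test_event_count_equals_brute_force_overlap_count(raws):
    rows = [
        rec(f"i{a}", f"i{b}", EPOCH + pd.Timedelta(seconds=off), dur)
        for a, b, off, dur in raws
        if a != b
    ]
    if not rows:
        return
    df = pd.DataFrame(rows)
    ev = discretize(df, EPOCH)
    expected = set()
    for a, b, off, dur in raws:
        if a == b:
            continue
        lo, hi = sorted((f"i{a}", f"i{b}"))
        for slot in range(off // 300, (off + dur - 1) // 300 + 1):
            expected.add((lo, hi, slot))
    got = set(zip(ev["dyad_a"], ev["dyad_b"], ev["interval_index"]))
    assert got == expected


# ---------------------------------------------------------------------------
# deduplicate


def _mirrored(pairs):
    rows = []
    for a, b, start, dur in pairs:
        rows.append(rec(a, b, start, dur))
        rows.append(rec(b, a, start, dur))
    return pd.DataFrame(rows)


def test_mirrored_records_halve_and_keep_one_side_per_dyad_date():
    df = _mirrored([
        ("a", "b", "2017-07-01 07:00", 100),
        ("a", "b", "2017-07-01 09:00", 200),
        ("a", "b", "2017-07-02 07:00", 300),
    ])
    out = deduplicate(df, retrieved={"a", "b"}, seed=0)
    assert len(out) == 3
    for _, day_group in out.groupby(out["start"].dt.date):
        assert day_group["reporter"].nunique() == 1


def test_deduplicate_is_deterministic_under_seed():
    df = _mirrored([("a", "b", "2017-07-01 07:00", 100), ("c", "d", "2017-07-01 08:00", 50)])
    out1 = deduplicate(df, retrieved={"a", "b", "c", "d"}, seed=3)
    out2 = deduplicate(df, retrieved={"a", "b", "c", "d"}, seed=3)
    pd.testing.assert_frame_equal(out1, out2)


def test_lost_collar_side_is_kept_untouched():
    df = pd.DataFrame([rec("a", "b", "2017-07-01 07:00", 100)])
    out = deduplicate(df, retrieved={"a"}, seed=0)
    assert len(out) == 1
    assert out["reporter"].iloc[0] == "a"


def test_record_from_non_retrieved_collar_is_an_error():
    df = pd.DataFrame([rec("a", "b", "2017-07-01 07:00", 100)])
    with pytest.raises(ValueError):
        deduplicate(df, retrieved={"b"}, seed=0)


def test_missing_columns_rejected():
    with pytest.raises(ValueError):
        deduplicate(pd.DataFrame({"reporter": []}), retrieved=set(), seed=0)


# ---------------------------------------------------------------------------
# label_phase / full chain


def test_label_phase_assigns_every_event_inside_the_span():
    df = pd.DataFrame([
        rec("a", "b", "2017-07-01 06:00:00", 300),     # first day slot
        rec("a", "b", "2017-07-01 19:29:00", 120),     # straddles dusk
        rec("a", "b", "2017-07-02 00:10:00", 60),      # after midnight
    ])
    ev = label_phase(discretize(df, EPOCH), PC)
    assert ev["phase"].tolist() == [DAY, DAY, NIGHT, NIGHT]
    assert ev["period"].tolist() == [0, 0, 1, 1]
    assert ev["date"].tolist() == [dt.date(2017, 7, 1)] * 4


def test_full_chain_produces_labelled_unique_events():
    df = _mirrored([
        ("a", "b", "2017-07-01 07:00", 700),
        ("a", "c", "2017-07-01 21:00", 3000),
    ])
    ev = preprocess_records(df, retrieved={"a", "b", "c"}, phase_config=PC, seed=1)
    assert not ev.duplicated(["dyad_a", "dyad_b", "interval_index"]).any()
    assert set(ev.columns) >= {"dyad_a", "dyad_b", "interval_index", "context",
                               "date", "phase", "period"}
    assert set(ev["phase"]) == {DAY, NIGHT}
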