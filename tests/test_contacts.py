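import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trackforge import (ContactEvent, detect_contacts, filter_dead,
                        filter_divisions, summarize_contacts)

from conftest import make_table


def brute_force_contacts(table, limit, dt):
    """Independent all-pairs/all-frames re-computation of contact events."""
    df = table.df
    t0 = df["t"].min()
    cells = sorted(df["cell_id"].unique())
    by_cell = {
        c: {round((r.t - t0) / dt): (r.x, r.y, r.z)
            for r in df[df["cell_id"] == c].itertuples()}
        for c in cells
    }
    events = []
    for a, b in itertools.combinations(cells, 2):
        shared = sorted(set(by_cell[a]) & set(by_cell[b]))
        hits = [f for f in shared if math.dist(by_cell[a][f], by_cell[b][f]) < limit]
        run = []
        for f in hits:
            if run and f != run[-1] + 1:
                events.append((a, b, run[0], run[-1]))
                run = []
            run.append(f)
        if run:
            events.append((a, b, run[0], run[-1]))
    return sorted(events)


def event_tuples(events, t0, dt):
    return sorted(
        (e.cell_a, e.cell_b, round((e.t_start - t0) / dt), round((e.t_end - t0) / dt))
        for e in events
    )


def random_table(seed, max_cells=15, max_frames=30):
    rng = np.random.default_rng(seed)
    n_cells = rng.integers(2, max_cells + 1)
    n_frames = rng.integers(2, max_frames + 1)
    rows = []
    for cid in range(1, n_cells + 1):
        start = rng.integers(0, max(1, n_frames // 2))
        end = rng.integers(start + 1, n_frames + 1)
        pos = rng.uniform(0, 20, size=(end - start, 3))
        rows += [(cid, float(start + i), *p) for i, p in enumerate(pos)]
    return make_table(rows, frame_interval=1.0)


class TestDetect:
    def test_stationary_pair_single_event(self):
        rows = [(1, float(t), 0, 0, 0) for t in range(10)] + [
            (2, float(t), 3, 0, 0) for t in range(10)]
        events = detect_contacts(make_table(rows, frame_interval=1.0), 5.0)
        assert len(events) == 1
        e = events[0]
        assert (e.cell_a, e.cell_b, e.n_frames) == (1, 2, 10)
        assert e.duration == e.t_end - e.t_start + 1.0 == 10.0

    def test_strict_inequality_at_limit(self):
        rows = [(1, 0.0, 0, 0, 0), (2, 0.0, 3, 0, 0)]
        assert detect_contacts(make_table(rows, frame_interval=1.0), 3.0) == []

    def test_interrupted_contact_two_events(self):
        rows = []
        for t in range(10):
            rows.append((1, float(t), 0, 0, 0))
            near = t in (1, 2, 3, 7, 8, 9)
            rows.append((2, float(t), 1.0 if near else 50.0, 0, 0))
        events = detect_contacts(make_table(rows, frame_interval=1.0), 5.0)
        assert event_tuples(events, 0.0, 1.0) == [(1, 2, 1, 3), (1, 2, 7, 9)]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        table = random_table(seed)
        limit = 6.0
        events = detect_contacts(table, limit)
        assert event_tuples(events, table.df["t"].min(), 1.0) == brute_force_contacts(
            table, limit, 1.0)

    def test_monotone_in_limit(self):
        table = random_table(99)
        def pairs_frames(limit):
            out = set()
            for e in detect_contacts(table, limit):
                for k in range(e.n_frames):
                    out.add((e.cell_a, e.cell_b, e.t_start + k))
            return out
        small, large = pairs_frames(3.0), pairs_frames(8.0)
        assert small <= large


def ev(a, b, t0=0.0, t1=2.0):
    return ContactEvent(a, b, t0, t1, t1 - t0 + 1.0, int(t1 - t0) + 1)


class TestFilters:
    def test_division_filter_removes_adjacent_ids(self):
        events = [ev(7, 8), ev(7, 9), ev(12, 13)]
        kept = filter_divisions(events)
        assert [(e.cell_a, e.cell_b) for e in kept] == [(7, 9)]
        assert filter_divisions([]) == []

    def test_dead_filter_strict_boundary(self):
        summaries = pd.DataFrame(
            {"cell_id": [1, 2, 3, 4],
             "arrest_coefficient": [0.95, 0.2, 0.9, 0.2]})
        events = [ev(1, 2), ev(2, 4), ev(2, 3)]
        kept = filter_dead(events, summaries, arrest_limit=0.9)
        # 0.95 > 0.9 removed; 0.9 == 0.9 kept (strict)
        assert [(e.cell_a, e.cell_b) for e in kept] == [(2, 4), (2, 3)]

    def test_dead_filter_drops_unknown_cells(self):
        summaries = pd.DataFrame({"cell_id": [1], "arrest_coefficient": [0.0]})
        assert filter_dead([ev(1, 5)], summaries, 0.9) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_filters_commute(self, seed):
        rng = np.random.default_rng(seed)
        ids = rng.integers(1, 12, size=(10, 2))
        events = [ev(int(min(a, b)), int(max(a, b))) for a, b in ids if a != b]
        summaries = pd.DataFrame(
            {"cell_id": np.arange(1, 13),
             "arrest_coefficient": rng.uniform(0, 1, 12)})
        one = filter_dead(filter_divisions(events), summaries, 0.5)
        other = filter_divisions(filter_dead(events, summaries, 0.5))
        assert one == other


class TestSummarize:
    def test_median_and_total(self):
        table = make_table([(c, 0.0, c * 10.0, 0, 0) for c in (1, 2, 3)],
                           frame_interval=1.0)
        events = [ev(1, 2, 0, 1), ev(1, 3, 0, 3), ev(1, 2, 5, 10)]
        # durations for cell 1: 2, 4, 6
        summ = summarize_contacts(events, table).set_index("cell_id")
        assert summ.loc[1, "n_contacts"] == 3
        assert summ.loc[1, "total_contact_time"] == 12.0
        assert summ.loc[1, "median_contact_duration"] == 4.0

    def test_cell_without_contacts_gets_zeros(self):
        table = make_table([(1, 0.0, 0, 0, 0), (2, 0.0, 100, 0, 0)],
                           frame_interval=1.0)
        summ = summarize_contacts([], table).set_index("cell_id")
        assert summ.loc[2, "n_contacts"] == 0
        assert summ.loc[2, "total_contact_time"] == 0.0
        assert np.isnan(summ.loc[2, "median_contact_duration"])

    def test_single_event_median(self):
        table = make_table([(1, 0.0, 0, 0, 0), (2, 0.0, 1, 0, 0)],
                           frame_interval=1.0)
        summ = summarize_contacts([ev(1, 2, 0, 4)], table).set_index("cell_id")
        assert summ.loc[1, "median_contact_duration"] == 5.0
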