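"""DR-to-SN latency matching, fiber classification and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drgfilter.errors import (DomainError, InsufficientDataError,
                              ParameterError)
from drgfilter.match import (MatchParams, classify_fiber,
                             correlate_prominence_filtering, match_spikes,
                             pct_delta_spikes, summarize_propagation)

from conftest import greedy_match_oracle

MS = 1e-3


# --------------------------------------------------------------------------
# match_spikes worked examples
# --------------------------------------------------------------------------

def test_middle_spike_fails_when_outnumbered():
    table = match_spikes([0.0, 10 * MS, 20 * MS], [5 * MS, 25 * MS])
    pairs = table.pairs
    assert pairs.loc[0, "matched"] and pairs.loc[0, "latency_s"] == pytest.approx(5 * MS)
    assert pairs.loc[2, "matched"] and pairs.loc[2, "latency_s"] == pytest.approx(5 * MS)
    assert not pairs.loc[1, "matched"]
    assert table.n_matched == 2 and table.n_sn == 3
    assert len(table.orphan_dr) == 0


def test_dr_spike_outside_window_is_orphan():
    table = match_spikes([0.0], [50 * MS])
    assert table.n_matched == 0
    assert list(table.orphan_dr) == [0]


def test_minimum_latency_rule_prefers_nearest_preceding():
    table = match_spikes([0.0, 4.999 * MS], [5 * MS])
    pairs = table.pairs
    assert not pairs.loc[0, "matched"]
    assert pairs.loc[1, "matched"]
    assert pairs.loc[1, "latency_s"] == pytest.approx(1e-6, rel=1e-6)
    assert pairs.loc[1, "velocity_mps"] == pytest.approx(4000.0, rel=1e-6)
    assert pairs.loc[1, "fiber_class"] == "A"


def test_simultaneous_timestamps_never_match():
    table = match_spikes([5 * MS], [5 * MS])
    assert table.n_matched == 0


def test_exclusive_matching_skips_claimed_origin():
    # second DR spike must fall back to the earlier, unclaimed SN spike
    table = match_spikes([0.0, 10 * MS], [11 * MS, 12 * MS])
    pairs = table.pairs
    assert pairs.loc[1, "dr_index"] == 0
    assert pairs.loc[0, "dr_index"] == 1
    assert pairs.loc[0, "latency_s"] == pytest.approx(12 * MS)


def test_unsorted_input_rejected():
    with pytest.raises(ParameterError):
        match_spikes([0.01, 0.0], [0.02])


# --------------------------------------------------------------------------
# oracle equivalence and conservation properties
# --------------------------------------------------------------------------

def random_instance(rng):
    n_sn = rng.integers(0, 13)
    n_dr = rng.integers(0, 13)
    sn = np.sort(rng.uniform(0, 0.5, n_sn))
    dr = np.sort(rng.uniform(0, 0.5, n_dr))
    v_min = rng.uniform(0.05, 1.0)
    return sn, dr, MatchParams(v_min=v_min)


def test_matcher_equals_oracle_on_random_micro_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        sn, dr, params = random_instance(rng)
        table = match_spikes(sn, dr, params)
        oracle_pairs, oracle_orphans = greedy_match_oracle(sn, dr, params.window)
        got = {int(r.sn_index): int(r.dr_index)
               for r in table.pairs.itertuples() if r.matched}
        assert got == {i: j for i, (j, _) in oracle_pairs.items()}
        assert list(table.orphan_dr) == oracle_orphans


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1), max_size=20),
       st.lists(st.floats(0, 1), max_size=20),
       st.floats(0.05, 2.0))
def test_conservation_and_window_monotonicity(sn, dr, v_min):
    sn = np.unique(np.asarray(sn))
    dr = np.unique(np.asarray(dr))
    wide = match_spikes(sn, dr, MatchParams(v_min=v_min, v_split=100.0))
    narrow = match_spikes(sn, dr, MatchParams(v_min=2 * v_min, v_split=100.0))
    assert wide.n_matched <= min(len(sn), len(dr))
    assert len(wide.orphan_dr) == len(dr) - wide.n_matched
    assert narrow.n_matched <= wide.n_matched  # shrinking w never adds matches


# --------------------------------------------------------------------------
# classify_fiber
# --------------------------------------------------------------------------

def test_fiber_classification_examples():
    assert classify_fiber(4 * MS) == "C"     # 1 m/s
    assert classify_fiber(1 * MS) == "A"     # 4 m/s
    assert classify_fiber(2 * MS) == "A"     # exactly 2 m/s -> A by convention


def test_fiber_classification_domain_errors():
    with pytest.raises(DomainError):
        classify_fiber(0.0)
    with pytest.raises(DomainError):
        classify_fiber(-1 * MS)
    with pytest.raises(DomainError):
        classify_fiber(41 * MS)  # beyond the 40 ms window


# --------------------------------------------------------------------------
# summaries and bulk formulas
# --------------------------------------------------------------------------

def test_summary_counts_and_percentages():
    rng = np.random.default_rng(0)
    sn = np.sort(rng.uniform(0, 10, 10))
    # propagate 7 of 10 spikes with a 1 ms latency
    dr = np.sort(sn[:7] + 1 * MS)
    table = match_spikes(sn, dr, unit_labels=np.zeros(10, dtype=int))
    summary = summarize_propagation(table)
    assert len(summary) == 1
    row = summary.iloc[0]
    assert row["n_sn"] == 10 and row["n_matched"] == 7
    assert row["success_pct"] == pytest.approx(70.0)
    assert row["failure_pct"] == pytest.approx(30.0)
    assert row["fiber_class"] == "A"


def test_summary_excludes_unassigned_spikes():
    table = match_spikes([0.0, 1.0], [1 * MS], unit_labels=np.array([0, -1]))
    summary = summarize_propagation(table)
    assert list(summary["unit_id"]) == [0]


def test_binomial_failure_estimate_on_bernoulli_thinning():
    rng = np.random.default_rng(1)
    sn = np.cumsum(rng.uniform(0.045, 0.055, size=1000))
    kept = rng.uniform(size=1000) >= 0.4
    dr = sn[kept] + 2 * MS
    table = match_spikes(sn, dr, unit_labels=np.zeros(1000, dtype=int))
    failure = summarize_propagation(table)["failure_pct"].iloc[0]
    assert failure == pytest.approx(40.0, abs=4.0)  # ~1.96 binomial SE


def test_pct_delta_spikes_formula():
    assert pct_delta_spikes(100, 50) == pytest.approx(50.0)
    assert pct_delta_spikes(17, 17) == pytest.approx(0.0)
    assert pct_delta_spikes(25.4, 10.7) == pytest.approx(57.87, abs=0.005)
    with pytest.raises(DomainError):
        pct_delta_spikes(0, 5)


def test_prominence_correlation_on_colinear_points():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    slope, intercept, r2 = correlate_prominence_filtering(x, 2 * x + 1)
    assert slope == pytest.approx(2.0)
    assert intercept == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)


def test_prominence_correlation_flat_response():
    x = np.array([1.0, 2.0, 3.0])
    slope, _, r2 = correlate_prominence_filtering(x, np.full(3, 5.0))
    assert slope == pytest.approx(0.0)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_prominence_correlation_needs_three_units():
    with pytest.raises(InsufficientDataError):
        correlate_prominence_filtering([1.0, 2.0], [3.0, 4.0])
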