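"""Transition tables, confusion deltas, discordance, screening projection."""

import numpy as np
import pandas as pd
import pytest

from octnorm import (
    TransitionTable,
    accuracy_of_flagging,
    delta_confusion,
    screening_projection,
    transition_table,
)
from octnorm.compare import round_percent
from octnorm.flags import COLORS

from _oracles import count_transitions


def flags_frame(colors, metric="g_cpRNFL", rdb="rdb"):
    return pd.DataFrame(
        {
            "eye_id": [f"e{i}" for i in range(len(colors))],
            "metric": metric,
            "rdb": rdb,
            "value": 0.0,
            "cutoff_5": 0.0,
            "cutoff_1": 0.0,
            "color": list(colors),
        }
    )


def test_identical_flags_all_diagonal():
    f = flags_frame(["green"] * 5 + ["yellow"] * 3 + ["red"] * 2)
    tab = transition_table(f, f)
    assert tab.n_changed() == 0
    assert tab.percent_changed() == 0.0
    assert tab.counts[("green", "green")] == 5


def test_disease_transition_totals_match_published_table():
    """8 green-to-yellow and 22 yellow-to-red among 183 eyes gives a total of
    30 changed (16.4%)."""
    tab = TransitionTable.from_counts(183, cohort="disease", g_to_y=8, y_to_r=22)
    assert tab.n_changed() == 30
    assert round_percent(tab.percent_changed()) == 16.4
    rows = tab.paper_rows()
    assert rows["G to Y"] == 8 and rows["Y to R"] == 22 and rows["R to Y"] == 0


def test_transition_counts_match_loop_oracle():
    rng = np.random.default_rng(4)
    a = rng.choice(COLORS, 250)
    b = rng.choice(COLORS, 250)
    tab = transition_table(flags_frame(a), flags_frame(b))
    oracle = count_transitions(a, b)
    for pair, n in oracle.items():
        assert tab.counts[pair] == n
    assert sum(tab.counts.values()) == 250


def test_transition_eye_set_mismatch():
    fa = flags_frame(["green"] * 4)
    fb = flags_frame(["green"] * 5)
    with pytest.raises(ValueError, match="differ"):
        transition_table(fa, fb)


def test_delta_confusion_published_values():
    """Confusion-delta arithmetic on the published transition counts."""
    tabH = TransitionTable.from_counts(175, cohort="healthy", g_to_y=1)
    tabD = TransitionTable.from_counts(183, cohort="disease", g_to_y=8, y_to_r=22)
    d5 = delta_confusion(tabH, tabD, "5%")
    assert d5.delta_tp == 8
    assert round_percent(d5.delta_sensitivity) == 4.4
    assert d5.delta_fp == 1 and round_percent(d5.delta_specificity) == -0.6
    d1 = delta_confusion(tabH, tabD, "1%")
    assert d1.delta_tp == 22
    assert round_percent(d1.delta_sensitivity) == 12.0
    assert round_percent(d1.delta_accuracy) == 6.1  # (22 + 0) / 358


def test_delta_confusion_gclplus_accuracy_conventions():
    """The 1% accuracy delta differs between the TP+TN and TP-only
    conventions when the healthy cohort loses a red flag."""
    tabH = TransitionTable.from_counts(175, g_to_y=1, r_to_y=1)
    tabD = TransitionTable.from_counts(183, g_to_y=2, y_to_r=10)
    d1 = delta_confusion(tabH, tabD, "1%")
    assert d1.delta_tp == 10 and d1.delta_tn == 1
    assert round_percent(d1.delta_accuracy_tp_only) == 2.8  # 10 / 358
    assert round_percent(d1.delta_accuracy) == 3.1  # (10 + 1) / 358
    d5 = delta_confusion(tabH, tabD, "5%")
    assert round_percent(d5.delta_accuracy) == 0.3  # (2 - 1) / 358
    assert round_percent(d1.delta_specificity) == 0.6


def test_empty_transitions_zero_deltas():
    tabH = TransitionTable.from_counts(175)
    tabD = TransitionTable.from_counts(183)
    for lvl in ("5%", "1%"):
        d = delta_confusion(tabH, tabD, lvl)
        assert d.delta_tp == d.delta_tn == 0
        assert d.delta_sensitivity == d.delta_specificity == d.delta_accuracy == 0.0
    with pytest.raises(ValueError):
        delta_confusion(tabH, tabD, "10%")


def test_swapping_rdbs_negates_deltas():
    rng = np.random.default_rng(9)
    a = rng.choice(COLORS, 150)
    b = rng.choice(COLORS, 150)
    h1 = transition_table(flags_frame(a), flags_frame(b))
    h2 = transition_table(flags_frame(b), flags_frame(a))
    d12 = delta_confusion(h1, h1, "5%")
    d21 = delta_confusion(h2, h2, "5%")
    assert d12.delta_tp == -d21.delta_tp
    assert d12.delta_tn == -d21.delta_tn


def test_deltas_agree_with_direct_confusion_matrices():
    """Deltas derived from transition cells equal before/after positive
    counts computed directly from the flag vectors."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        a = rng.choice(COLORS, 120)
        b = rng.choice(COLORS, 120)
        tab = transition_table(flags_frame(a), flags_frame(b))
        for lvl, positive in (("5%", {"yellow", "red"}), ("1%", {"red"})):
            d = delta_confusion(tab, tab, lvl)
            direct = sum(c in positive for c in b) - sum(c in positive for c in a)
            assert d.delta_tp == direct


def test_accuracy_of_flagging_identity_and_trace():
    rng = np.random.default_rng(12)
    a = rng.choice(COLORS, 200)
    b = rng.choice(COLORS, 200)
    fa, fb = flags_frame(a), flags_frame(b)
    truth = pd.Series(
        ["healthy"] * 120 + ["disease"] * 80, index=[f"e{i}" for i in range(200)]
    )
    res = accuracy_of_flagging(fa, fb, truth)
    tab = transition_table(fa, fb)
    trace = sum(tab.counts[(c, c)] for c in COLORS)
    assert res["percent_discordant"] == pytest.approx(100.0 * (1 - trace / 200))
    same = accuracy_of_flagging(fa, fa, truth)
    assert same["percent_discordant"] == 0.0
    with pytest.raises(ValueError, match="truth"):
        accuracy_of_flagging(fa, fb, truth.iloc[:50])


def test_screening_projection_published_example():
    """1000 screened, 3% prevalence, +16.4% sensitivity -> ~5 extra cases,
    0.5% of the population but >16% of the disease group."""
    res = screening_projection(1000, 0.03, 0.164)
    assert res["cases"] == 30
    assert res["additional_detected"] == 5
    assert round_percent(res["percent_of_population"]) == 0.5
    assert res["percent_of_disease"] > 16.0
    assert screening_projection(1000, 0.03, 0.0)["additional_detected"] == 0
    assert screening_projection(2000, 0.03, 0.164)["additional_detected"] == 10
    with pytest.raises(ValueError):
        screening_projection(-5, 0.03, 0.1)


def test_round_percent_half_up():
    assert round_percent(16.39) == 16.4
    assert round_percent(0.25) == 0.3
    assert round_percent(-0.649) == -0.6
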