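"""Preference/learning indices and the arena generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kcmod import (
    ArenaFrameCounts,
    PreferenceSeries,
    generate_arena_experiment,
    learning_index,
    pool_olfactory,
    pool_visual,
    preference_index,
    signed_preference,
)


@pytest.mark.parametrize(
    "a,b,expected", [(20, 20, 0.0), (40, 0, 1.0), (30, 10, 0.5), (0, 40, -1.0)]
)
def test_preference_index_values(a, b, expected):
    assert preference_index(np.array([a]), np.array([b]))[0] == pytest.approx(expected)


def test_preference_index_empty_frame_flagged():
    pi = preference_index(np.array([0, 10]), np.array([0, 10]))
    assert np.isnan(pi[0]) and pi[1] == 0.0


def test_signed_preference_orientation():
    # punished A, flies all on B -> perfect avoidance -> +1
    g = ArenaFrameCounts("g", "A", np.zeros(3, int), np.full(3, 40), 40)
    assert np.allclose(signed_preference(g).pi_per_frame, 1.0)
    g = ArenaFrameCounts("g", "B", np.zeros(3, int), np.full(3, 40), 40)
    assert np.allclose(signed_preference(g).pi_per_frame, -1.0)


def test_learning_index_mean_of_signed_pis():
    s1 = PreferenceSeries("g1", "A", np.full(90, 0.4))
    s2 = PreferenceSeries("g2", "B", np.full(90, 0.2))
    res = learning_index(s1, s2)
    assert np.allclose(res.li_per_frame, 0.3)
    assert pool_visual(res) == pytest.approx(0.3)


def test_learning_index_null_and_same_pairing_rejected():
    z = PreferenceSeries("g1", "A", np.zeros(90))
    assert learning_index(z, PreferenceSeries("g2", "B", np.zeros(90))).pooled_li == 0.0
    with pytest.raises(ValueError):
        learning_index(z, PreferenceSeries("g2", "A", np.zeros(90)))


def test_flagged_frames_excluded_from_pooling():
    pi = np.full(90, 0.5)
    pi[10:20] = np.nan
    res = learning_index(
        PreferenceSeries("g1", "A", pi), PreferenceSeries("g2", "B", np.full(90, 0.5))
    )
    assert res.n_valid_frames == 80
    assert res.pooled_li == pytest.approx(0.5)


def test_pool_visual_ramp():
    ramp = np.linspace(0, 1, 90)
    res = learning_index(
        PreferenceSeries("g1", "A", ramp), PreferenceSeries("g2", "B", ramp)
    )
    assert pool_visual(res) == pytest.approx(ramp.mean())


def test_pool_olfactory_last_10s():
    # 120 s at 1 Hz; last 10 samples average 0.4 in each group
    tail = np.concatenate([np.full(5, 0.2), np.full(5, 0.6)])
    pi = np.concatenate([np.zeros(110), tail])
    s1 = PreferenceSeries("g1", "A", pi)
    s2 = PreferenceSeries("g2", "B", pi)
    assert pool_olfactory(s1, s2) == pytest.approx(0.4)


def test_pool_olfactory_constant_and_short_series():
    s1 = PreferenceSeries("g1", "A", np.full(120, 0.4))
    s2 = PreferenceSeries("g2", "B", np.full(120, 0.4))
    assert pool_olfactory(s1, s2) == pytest.approx(0.4)
    short = PreferenceSeries("g", "A", np.full(5, 0.4))
    with pytest.raises(ValueError):
        pool_olfactory(short, PreferenceSeries("g2", "B", np.full(5, 0.4)))


def test_generator_extremes():
    g1, g2 = generate_arena_experiment(40, 1.0, 90, seed=1)
    res = learning_index(signed_preference(g1), signed_preference(g2))
    assert np.allclose(res.li_per_frame, 1.0)
    with pytest.raises(ValueError):
        generate_arena_experiment(40, 1.5, 90, seed=1)


def test_generator_null_centered():
    lis = []
    for s in range(100):
        g1, g2 = generate_arena_experiment(40, 0.0, 90, seed=s)
        lis.append(learning_index(signed_preference(g1), signed_preference(g2)).pooled_li)
    lis = np.asarray(lis)
    se = lis.std(ddof=1) / np.sqrt(len(lis))
    assert abs(lis.mean()) < 2 * se + 1e-12


def test_label_symmetry():
    # swapping stimulus labels together with the pairing labels leaves LI fixed
    g1, g2 = generate_arena_experiment(40, 0.3, 90, seed=4)
    res = learning_index(signed_preference(g1), signed_preference(g2))
    swap = lambda g: ArenaFrameCounts(
        g.group_id, "B" if g.punished == "A" else "A", g.counts_b, g.counts_a, g.n_flies
    )
    res2 = learning_index(signed_preference(swap(g1)), signed_preference(swap(g2)))
    assert np.allclose(res.li_per_frame, res2.li_per_frame, equal_nan=True)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a1=st.lists(st.integers(0, 40), min_size=12, max_size=12),
    a2=st.lists(st.integers(0, 40), min_size=12, max_size=12),
)
def test_li_bounded_for_any_counts(a1, a2):
    g1 = ArenaFrameCounts("g1", "A", np.asarray(a1), 40 - np.asarray(a1), 40)
    g2 = ArenaFrameCounts("g2", "B", np.asarray(a2), 40 - np.asarray(a2), 40)
    res = learning_index(signed_preference(g1), signed_preference(g2))
    valid = res.li_per_frame[np.isfinite(res.li_per_frame)]
    assert np.all(np.abs(valid) <= 1.0 + 1e-12)
    assert abs(res.pooled_li) <= 1.0 + 1e-12


def test_counts_exceeding_flies_rejected():
    with pytest.raises(ValueError):
        ArenaFrameCounts("g", "A", np.array([30]), np.array([20]), 40)
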