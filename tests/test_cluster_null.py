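import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spineclust.cluster_null import (
    EventSet,
    adjacent_gaps,
    clustering_probability,
    concatenate,
    count_clustered_generated,
    crosstalk_distances,
    events_from_dataset,
    exhaustive_observed_clustering,
    monte_carlo_null,
    observed_clustering,
    threshold_sweep,
)
from spineclust.synthetic_data import VPA_PRESET, generate_spine_dataset

from conftest import make_dataset


def _events(positions, lengths, event_type="generated"):
    return EventSet(event_type, {k: np.asarray(v, float) for k, v in positions.items()},
                    dict(lengths))


def test_concatenate_offsets_and_conservation():
    ev = _events({"d1": [2.0], "d2": [3.0]}, {"d1": 10.0, "d2": 10.0})
    total, pos = concatenate(ev, ["d1", "d2"])
    assert total == 20.0 and pos.tolist() == [2.0, 13.0]
    _, pos = concatenate(ev, ["d2", "d1"])
    assert pos.tolist() == [3.0, 12.0]
    single = _events({"d1": [1.0, 4.0]}, {"d1": 10.0})
    _, pos = concatenate(single, ["d1"])
    assert pos.tolist() == [1.0, 4.0]
    with pytest.raises(ValueError):
        concatenate(ev, ["d1", "d1"])


def test_adjacent_gaps():
    np.testing.assert_allclose(adjacent_gaps(np.array([1.0, 4.0, 9.0])), [3.0, 5.0])
    assert adjacent_gaps(np.array([5.0])).size == 0
    assert adjacent_gaps(np.arange(86.0)).size == 85  # n events -> n-1 pairs


def test_clustering_probability():
    assert clustering_probability(np.array([1.0, 5.0, 2.9]), 3.0) == pytest.approx(2 / 3)
    assert clustering_probability(np.array([1.0, 5.0]), 0.0) == 0.0
    assert clustering_probability(np.array([3.0]), 3.0) == 1.0  # inclusive
    assert clustering_probability(np.empty(0), 3.0) == 0.0


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    gaps=st.lists(st.floats(0.01, 50.0), min_size=1, max_size=40),
    t1=st.floats(0.0, 25.0),
    t2=st.floats(0.0, 25.0),
)
def test_clustering_probability_monotone_in_threshold(gaps, t1, t2):
    lo, hi = sorted((t1, t2))
    g = np.asarray(gaps)
    assert clustering_probability(g, lo) <= clustering_probability(g, hi)


def test_observed_clustering_single_dendrite_is_exact():
    ev = _events({"d1": [1.0, 2.0, 9.0]}, {"d1": 20.0})
    assert observed_clustering(ev, 3.0, seed=0) == pytest.approx(0.5)


def test_observed_clustering_far_interior_events_never_cluster():
    ev = _events({"d1": [10.0], "d2": [10.0]}, {"d1": 20.0, "d2": 20.0})
    # any join keeps the two events >= 10 um apart
    assert observed_clustering(ev, 3.0, n_permutations=50, seed=1) == 0.0


def test_observed_clustering_matches_exhaustive_average():
    rng = np.random.default_rng(5)
    positions = {f"d{i}": np.sort(rng.uniform(0, 15, size=rng.integers(1, 4)))
                 for i in range(4)}
    ev = _events(positions, {f"d{i}": 15.0 for i in range(4)})
    exact = exhaustive_observed_clustering(ev, 3.0)
    approx = observed_clustering(ev, 3.0, n_permutations=4000, seed=2)
    assert approx == pytest.approx(exact, abs=0.01)


@pytest.mark.parametrize("n,L,d", [(10, 100.0, 3.0), (86, 379.2, 3.0), (30, 200.0, 6.0)])
def test_null_mean_matches_closed_form(n, L, d):
    """Concatenated-null mean equals 1 - (1 - d/L)^n: every spacing of n
    uniform points has survival (1 - d/L)^n, and adjacent gaps are spacings."""
    ev = _events({"d1": np.linspace(1, L - 1, n)}, {"d1": L})
    res = monte_carlo_null(ev, d, iterations=10_000, seed=3, keep_null=True)
    closed = 1 - (1 - d / L) ** n
    se = res.null_probs.std(ddof=1) / np.sqrt(res.iterations)
    assert abs(res.null_mean - closed) < 3 * se


def test_empirical_p_one_when_observed_zero():
    ev = _events({"d1": [10.0], "d2": [10.0]}, {"d1": 20.0, "d2": 20.0})
    res = monte_carlo_null(ev, 3.0, iterations=500, seed=4, n_permutations=50)
    assert res.observed_prob == 0.0 and res.empirical_p == 1.0


def test_strong_clustering_beats_95th_percentile(clustered_dataset):
    ev = events_from_dataset(clustered_dataset, (0, 1), "generated")
    res = monte_carlo_null(ev, 3.0, iterations=5000, seed=5, n_permutations=300)
    assert res.observed_prob > res.null_p95
    assert res.empirical_p < 0.05


def test_per_dendrite_mode_and_single_dendrite_agreement():
    ev = _events({"d1": [1.0, 2.0, 9.0]}, {"d1": 20.0})
    con = monte_carlo_null(ev, 3.0, iterations=4000, mode="concatenated", seed=6)
    per = monte_carlo_null(ev, 3.0, iterations=4000, mode="per_dendrite", seed=6)
    assert con.observed_prob == per.observed_prob == pytest.approx(0.5)
    # same single-dendrite geometry: null distributions share the same law
    assert per.null_mean == pytest.approx(con.null_mean, abs=0.02)


def test_count_clustered_generated_examples_and_bruteforce(vpa_dataset):
    ds = make_dataset(
        [("d1", 30.0), ("d2", 30.0)],
        [("a", "d1", 10.0, (0, 1, 1)), ("b", "d1", 12.0, (0, 1, 0)),
         ("c", "d2", 12.0, (0, 1, 1)), ("p", "d1", 5.0, (1, 1, 1))],
    )
    flags, per_dendrite = count_clustered_generated(ds, (0, 1), 3.0)
    assert flags == {"a": True, "b": True, "c": False}
    assert per_dendrite["d1"] == pytest.approx(100 * 2 / 1)
    # brute-force all-pairs oracle on a generated dataset
    flags, _ = count_clustered_generated(vpa_dataset, (0, 1), 3.0)
    events = [
        s for s in vpa_dataset.spines if not s.present[0] and s.present[1]
    ]
    for s in events:
        expect = any(
            o is not s and o.dendrite_id == s.dendrite_id
            and abs(o.position_um - s.position_um) <= 3.0
            for o in events
        )
        assert flags[s.spine_id] == expect


def test_threshold_sweep_youden_argmax_and_tie_rule(clustered_dataset):
    ev = events_from_dataset(clustered_dataset, (0, 1), "generated")
    results, youden = threshold_sweep(ev, [3.0, 6.0, 9.0], iterations=3000, seed=7,
                                      n_permutations=300)
    diffs = {t: r.observed_prob - r.null_mean for t, r in results.items()}
    assert youden == max(sorted(diffs), key=diffs.get)
    assert youden == 3.0  # generator cluster_scale_um recovered
    with pytest.raises(ValueError):
        threshold_sweep(ev, [3.0])


def test_crosstalk_distances():
    gen = _events({"d1": [5.0], "d2": [1.0]}, {"d1": 20.0, "d2": 20.0})
    elim = _events({"d1": [2.0, 9.0], "d2": []}, {"d1": 20.0, "d2": 20.0},
                   "eliminated")
    out = crosstalk_distances(gen, elim)
    assert out["d1"] == [3.0]
    assert out["d2"] == [None]


def test_crosstalk_matches_bruteforce(vpa_dataset):
    gen = events_from_dataset(vpa_dataset, (0, 1), "generated")
    elim = events_from_dataset(vpa_dataset, (0, 1), "eliminated")
    out = crosstalk_distances(gen, elim)
    for d_id, dists in out.items():
        g, e = gen.positions[d_id], elim.positions[d_id]
        for pos, got in zip(g, dists):
            if e.size == 0:
                assert got is None
            else:
                assert got == pytest.approx(min(abs(x - pos) for x in e))


def test_null_calibration_under_null_generator():
    """With the clustering bias off, the empirical P is ~uniform over seeds."""
    from scipy import stats

    ps = []
    for seed in range(120):
        cfg = dataclasses.replace(VPA_PRESET, n_dendrites=12, cluster_bias=0.0,
                                  seed=seed)
        ds = generate_spine_dataset(cfg)
        ev = events_from_dataset(ds, (0, 1), "generated")
        if ev.n_events < 2:
            continue
        res = monte_carlo_null(ev, 3.0, iterations=1000, seed=seed + 50_000,
                               n_permutations=150, keep_null=False)
        ps.append(res.empirical_p)
    assert stats.kstest(np.asarray(ps), "uniform").pvalue > 0.01
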