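import numpy as np
import pytest

from spineclust.spine_dynamics import (
    FateLabel,
    carryover_fraction,
    classify_fates,
    elimination_rate,
    generation_rate,
    normalized_spine_volume,
    small_large_partition,
    survival_rate,
    zstack_moving_average,
)
from spineclust.synthetic_data import generate_zstack

from conftest import make_dataset


def _uniform_spines(n, present, dendrite="d1", start=0):
    return [
        (f"s{start + i}", dendrite, 1.0 + 2.0 * i, present[i])
        for i in range(n)
    ]


def test_generation_rate_ten_percent():
    spines = _uniform_spines(10, [(1, 1, 1)] * 10) + [("new", "d1", 0.5, (0, 1, 1))]
    ds = make_dataset([("d1", 30.0)], spines)
    res = generation_rate(ds, (0, 1))
    assert res.pooled_pct == pytest.approx(10.0)
    assert res.n_events == 1 and res.n_baseline == 10
    assert generation_rate(make_dataset([("d1", 30.0)],
                                        _uniform_spines(10, [(1, 1, 1)] * 10)),
                           (0, 1)).pooled_pct == 0.0


def test_elimination_rate_twenty_percent_and_zero_baseline_flagged():
    present = [(1, 0, 0), (1, 0, 0)] + [(1, 1, 1)] * 8
    ds = make_dataset([("d1", 30.0), ("d2", 20.0)],
                      _uniform_spines(10, present) + [("x", "d2", 1.0, (0, 1, 1))])
    res = elimination_rate(ds, (0, 1))
    assert res.per_dendrite.set_index("dendrite_id").loc["d1", "pct"] == pytest.approx(20.0)
    assert "d2" in res.undefined_dendrites
    assert np.isnan(res.per_dendrite.set_index("dendrite_id").loc["d2", "pct"])


def test_turnover_matches_brute_force_recount(ue_dataset):
    for iv in [(0, 1), (1, 2)]:
        gen = generation_rate(ue_dataset, iv)
        n_gen = sum(
            (not s.present[iv[0]]) and s.present[iv[1]] for s in ue_dataset.spines
        )
        n_base = sum(s.present[iv[0]] for s in ue_dataset.spines)
        assert gen.n_events == n_gen
        assert gen.pooled_pct == pytest.approx(100 * n_gen / n_base)
        elim = elimination_rate(ue_dataset, iv)
        n_elim = sum(
            s.present[iv[0]] and (not s.present[iv[1]]) for s in ue_dataset.spines
        )
        assert elim.n_events == n_elim


def test_turnover_conservation_exact(ue_dataset, vpa_dataset, clustered_dataset):
    """baseline - eliminated + generated = next-session count, exactly."""
    for ds in (ue_dataset, vpa_dataset, clustered_dataset):
        for iv in [(0, 1), (1, 2)]:
            gen = generation_rate(ds, iv)
            elim = elimination_rate(ds, iv)
            n_next = sum(s.present[iv[1]] for s in ds.spines)
            assert gen.n_baseline - elim.n_events + gen.n_events == n_next


@pytest.mark.parametrize(
    "present,label",
    [
        ((False, True, True), FateLabel.GENERATED_SURVIVED),
        ((False, True, False), FateLabel.GENERATED_LOST),
        ((True, True, True), FateLabel.PRE_EXISTING_SURVIVED),
        ((True, True, False), FateLabel.PRE_EXISTING_LOST),
        ((True, False, False), FateLabel.ELIMINATED_EARLY),
        ((True, False, True), FateLabel.ELIMINATED_EARLY),
        ((False, False, True), FateLabel.LATE_GENERATED),
    ],
)
def test_fate_patterns(present, label):
    ds = make_dataset([("d1", 30.0)], [("s1", "d1", 5.0, present)])
    assert classify_fates(ds)["s1"] is label


def test_fate_labels_partition(vpa_dataset):
    fates = classify_fates(vpa_dataset)
    core = {
        FateLabel.PRE_EXISTING_SURVIVED,
        FateLabel.PRE_EXISTING_LOST,
        FateLabel.GENERATED_SURVIVED,
        FateLabel.GENERATED_LOST,
    }
    n_core = sum(f in core for f in fates.values())
    n_early = sum(f is FateLabel.ELIMINATED_EARLY for f in fates.values())
    n_s2 = sum(s.present[1] for s in vpa_dataset.spines)
    n_elim12 = sum(s.present[0] and not s.present[1] for s in vpa_dataset.spines)
    assert n_core == n_s2
    assert n_core + n_early == n_s2 + n_elim12
    assert len(fates) == len(vpa_dataset.spines)


def test_carryover_fraction_printed_counts_arithmetic():
    # 22 carryover / 355 total -> 6.2%
    assert 100 * 22 / 355 == pytest.approx(6.2, abs=0.05)
    spines = _uniform_spines(9, [(1, 1, 1)] * 9) + [("c", "d1", 0.2, (0, 1, 1))]
    ds = make_dataset([("d1", 30.0)], spines)
    frac, k, n = carryover_fraction(ds, "all")
    assert (k, n) == (1, 9)
    assert frac == pytest.approx(1 / 9)
    # no GS spines -> zero numerator
    ds0 = make_dataset([("d1", 30.0)], _uniform_spines(5, [(1, 1, 1)] * 5))
    assert carryover_fraction(ds0, "all") == (0.0, 0, 5)


def test_carryover_clustered_vs_nonclustered_split():
    spines = _uniform_spines(10, [(1, 1, 1)] * 10)
    # two new surviving spines 2 um apart (clustered), one isolated
    spines += [("n1", "d1", 24.0, (0, 1, 1)), ("n2", "d1", 26.0, (0, 1, 1)),
               ("n3", "d2", 5.0, (0, 1, 1))]
    ds = make_dataset([("d1", 30.0), ("d2", 30.0)], spines)
    _, kc, _ = carryover_fraction(ds, "clustered", threshold_um=3.0)
    _, knc, _ = carryover_fraction(ds, "non_clustered", threshold_um=3.0)
    _, kall, _ = carryover_fraction(ds, "all")
    assert (kc, knc, kall) == (2, 1, 3)


def test_survival_rates():
    spines = [
        ("g1", "d1", 1.0, (0, 1, 1)),
        ("g2", "d1", 3.0, (0, 1, 0)),
        ("p1", "d1", 5.0, (1, 1, 1)),
        ("p2", "d1", 7.0, (1, 1, 1)),
    ]
    ds = make_dataset([("d1", 30.0)], spines)
    assert survival_rate(ds, "newly_generated") == pytest.approx(50.0)
    assert survival_rate(ds, "pre_existing") == pytest.approx(100.0)
    empty = make_dataset([("d1", 30.0)], [("p1", "d1", 5.0, (1, 1, 1))])
    with pytest.raises(ValueError, match="empty cohort"):
        survival_rate(empty, "newly_generated")


def test_survival_matches_fate_recount(vpa_dataset):
    fates = classify_fates(vpa_dataset)
    gs = sum(f is FateLabel.GENERATED_SURVIVED for f in fates.values())
    gl = sum(f is FateLabel.GENERATED_LOST for f in fates.values())
    assert survival_rate(vpa_dataset, "newly_generated") == pytest.approx(
        100 * gs / (gs + gl)
    )


# ---------------------------------------------------------------------------
# volume quantification


def test_moving_average_constant_and_single_plane():
    const = np.full((11, 4, 4), 3.0)
    np.testing.assert_allclose(zstack_moving_average(const, 5), const)
    stack = np.zeros((11, 1, 1))
    stack[5] = 5.0
    out = zstack_moving_average(stack, 5)
    assert out[5, 0, 0] == pytest.approx(1.0)  # 5 / window of 5
    assert out[0, 0, 0] == 0.0


def test_moving_average_matches_brute_force():
    rng = np.random.default_rng(0)
    stack = rng.random((14, 3, 5))
    out = zstack_moving_average(stack, 5)
    for z in range(14):
        lo, hi = max(0, z - 2), min(13, z + 2)
        np.testing.assert_allclose(out[z], stack[lo:hi + 1].mean(axis=0))
    with pytest.raises(ValueError):
        zstack_moving_average(stack, 4)
    with pytest.raises(ValueError):
        zstack_moving_average(stack, 15)


def test_normalized_volume_ratio_and_scale_invariance():
    spine_roi = dict(z0=10, z1=20, y0=2, y1=14, x0=34, x1=50)
    shaft_roi = dict(z0=20, z1=31, y0=26, y1=38, x0=6, x1=26)
    def build(scale):
        return generate_zstack(
            [((7.5, 1.6, 8.4), 0.15 * scale, 0.6),    # spine blob, inside spine_roi
             ((12.5, 6.4, 3.2), 1.0 * scale, 0.6)],   # shaft blob, inside shaft_roi
            shaft_amplitude=0.0, shape=(51, 40, 64), voxel_um=(0.5, 0.2, 0.2),
        )
    v1 = normalized_spine_volume(build(1.0), spine_roi, shaft_roi)
    v2 = normalized_spine_volume(build(7.0), spine_roi, shaft_roi)
    assert v1 == pytest.approx(0.15, abs=0.02)  # PSF overlap tolerance
    assert v1 == pytest.approx(v2, rel=1e-9)    # scale invariant
    with pytest.raises(ValueError, match="degenerate shaft"):
        normalized_spine_volume(
            np.zeros((11, 8, 8)), dict(z0=0, z1=5, y0=0, y1=4, x0=0, x1=4),
            dict(z0=6, z1=11, y0=4, y1=8, x0=4, x1=8)
        )


def test_small_large_partition():
    small, large = small_large_partition([0.1, 0.2])
    assert small.tolist() == [0] and large.tolist() == [1]
    small, large = small_large_partition([])
    assert small.size == 0 and large.size == 0
    # tie at the threshold goes to the small group
    small, _ = small_large_partition([0.15])
    assert small.tolist() == [0]
    rng = np.random.default_rng(1)
    v = rng.lognormal(-1.2, 0.8, size=500)
    small, large = small_large_partition(v)
    assert small.size == int(np.sum(v <= 0.15))
    assert small.size + large.size == 500
    with pytest.raises(ValueError):
        small_large_partition([np.nan])
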