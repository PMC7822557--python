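import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nuclattice.fixtures import PlantedDip, dip_profile
from nuclattice.ndr import (
    LINE_STEP,
    NDR,
    NDR_CUTOFF,
    TARGET_MEAN,
    ReferenceTrack,
    annotate_ndrs,
    evaluate_prediction,
    rmsd,
    transform_occupancy,
    zero_ndrs_and_rescale,
)


class TestTransform:
    def test_constant_log_track_hits_target_at_gamma_cap(self):
        ref = transform_occupancy(np.zeros(1000), gamma_max=10.0)
        assert np.allclose(ref.y, TARGET_MEAN)
        assert ref.gamma == pytest.approx(10.0)

    def test_two_level_track_matches_bisection_oracle(self):
        ylog = np.concatenate([np.zeros(600), np.full(400, 0.7)])
        ref = transform_occupancy(ylog)
        assert ref.y.mean() == pytest.approx(TARGET_MEAN, abs=1e-6)
        assert ref.y.max() == pytest.approx(1.0, abs=1e-6)
        # independent oracle: scan gamma for the largest feasible value
        gammas = np.linspace(0, 10, 200_001)
        cs = TARGET_MEAN / np.array(
            [np.mean(np.exp(g * ylog)) for g in gammas[::1000]]
        )
        feasible = cs * np.exp(gammas[::1000] * ylog.max()) <= 1 + 1e-9
        g_star = gammas[::1000][feasible][-1]
        assert ref.gamma == pytest.approx(g_star, abs=0.1)

    def test_cutoff_is_two_sd_below_mean(self):
        assert TARGET_MEAN - 2 * LINE_STEP == pytest.approx(NDR_CUTOFF, abs=2e-4)


def literal_rule_oracle(y):
    """Independent, literal re-implementation of the three annotation rules."""
    accepted = []
    L = y.size
    i = 0
    while i < L:
        if y[i] >= 0.80:
            i += 1
            continue
        j = i
        while j < L and y[j] < 0.80:
            j += 1
        seg = y[i:j]
        lowest = seg.min()
        k = 1
        while 0.80 - (k + 1) * LINE_STEP > lowest:
            k += 1
        low_line = 0.80 - k * LINE_STEP
        if low_line > lowest:  # crossed the 73.2% line at least
            below1 = np.where(seg < 0.80 - LINE_STEP)[0]
            if below1.size and below1[-1] - below1[0] + 1 > 110:
                bl = np.where(seg < low_line)[0]
                dxl, dxr = bl[0], len(seg) - (bl[-1] + 1)
                if min(dxl, dxr) < 100:
                    accepted.append((i + bl[0], i + bl[-1] + 1))
        i = j
    # merge on centers < 125
    merged = []
    for a, b in accepted:
        if merged and (a + b - 1) / 2 - (merged[-1][0] + merged[-1][1] - 1) / 2 < 125:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


class TestAnnotate:
    def test_flat_track_has_no_ndrs(self):
        assert annotate_ndrs(np.full(1000, 0.80)) == []

    def test_single_smooth_dip_matches_literal_oracle(self):
        y = dip_profile(10_000, [PlantedDip(3000, 0.30, 100, 40)], 0.85)
        got = annotate_ndrs(y)
        expect = literal_rule_oracle(y)
        assert [(n.start, n.end) for n in got] == expect
        assert len(got) == 1
        assert abs(got[0].center - 3000) <= 10

    def test_narrow_dip_fails_width_rule(self):
        y = dip_profile(5000, [PlantedDip(2500, 0.30, 30, 15)], 0.85)
        assert annotate_ndrs(y) == []

    def test_shallow_dip_never_crossing_732_rejected(self):
        y = dip_profile(5000, [PlantedDip(2500, 0.75, 200, 40)], 0.85)
        assert annotate_ndrs(y) == []

    def test_gradual_dip_fails_steepness_rule(self):
        y = dip_profile(8000, [PlantedDip(4000, 0.30, 60, 250)], 0.85)
        assert annotate_ndrs(y) == []

    def test_close_centers_merge(self):
        dips = [PlantedDip(3000, 0.30, 56, 5), PlantedDip(3124, 0.30, 56, 5)]
        y = dip_profile(8000, dips, 0.85)
        got = annotate_ndrs(y)
        assert len(got) == 1
        assert got[0].start < 3000 < 3124 < got[0].end

    def test_distant_centers_stay_separate(self):
        dips = [PlantedDip(3000, 0.30, 56, 5), PlantedDip(3300, 0.30, 56, 5)]
        y = dip_profile(8000, dips, 0.85)
        assert len(annotate_ndrs(y)) == 2

    def test_random_multi_dip_tracks_match_literal_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(1, 5)
            centers = np.sort(rng.integers(600, 19_400, n))
            dips = [
                PlantedDip(
                    int(c),
                    float(rng.uniform(0.1, 0.7)),
                    int(rng.integers(20, 140)),
                    int(rng.integers(10, 160)),
                )
                for c in centers
            ]
            y = dip_profile(20_000, dips, 0.85)
            got = [(x.start, x.end) for x in annotate_ndrs(y)]
            assert got == literal_rule_oracle(y)

    def test_short_track_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert annotate_ndrs(np.full(100, 0.3)) == []


class TestZeroAndRescale:
    def test_empty_set_leaves_track_unchanged(self):
        ref = ReferenceTrack(np.full(1000, 0.81))
        out = zero_ndrs_and_rescale(ref, [])
        assert np.array_equal(out.y, ref.y)

    def test_mean_restored_and_interior_zeroed(self):
        y = dip_profile(10_000, [PlantedDip(3000, 0.30, 100, 40)], 0.85)
        ndrs = annotate_ndrs(y)
        out = zero_ndrs_and_rescale(ReferenceTrack(y), ndrs)
        assert out.y.mean() == pytest.approx(TARGET_MEAN, abs=1e-4)
        for n in ndrs:
            assert np.all(out.y[n.start : n.end] == 0.0)

    def test_reannotation_recovers_the_zeroed_intervals(self):
        y = dip_profile(
            20_000,
            [PlantedDip(4000, 0.30, 100, 40), PlantedDip(12_000, 0.2, 80, 30)],
            0.85,
        )
        ndrs = annotate_ndrs(y)
        out = zero_ndrs_and_rescale(ReferenceTrack(y), ndrs)
        again = annotate_ndrs(out)
        assert len(again) == len(ndrs)
        for a, b in zip(again, ndrs):
            assert abs(a.center - b.center) <= 10


class TestScoring:
    def test_rmsd_basic_identities(self, rng):
        y = rng.uniform(0, 1, 500)
        assert rmsd(y, y) == 0.0
        assert rmsd(y + 0.1, y) == pytest.approx(0.1)
        z = rng.uniform(0, 1, 500)
        assert rmsd(y, z) == pytest.approx(np.sqrt(np.mean((y - z) ** 2)))
        with pytest.raises(ValueError):
            rmsd(y, z[:-1])

    def test_perfect_prediction_scores_perfectly(self):
        # cliff-edged dip: the sub-cutoff region coincides with the NDR
        # interval, so a perfect prediction has no false-positive bp
        y = dip_profile(10_000, [PlantedDip(3000, 0.30, 100, 1)], 0.85)
        ndrs = annotate_ndrs(y)
        mod = zero_ndrs_and_rescale(ReferenceTrack(y), ndrs)
        rep = evaluate_prediction(mod.y, ndrs, ref=mod)
        assert rep.p_ndr == 1.0
        assert rep.fpr == 0.0
        assert rep.auc == 1.0
        assert rep.rmsd == 0.0

    def test_flat_prediction_finds_nothing(self):
        ndrs = [NDR(100, 300, 199.5, 200)]
        rep = evaluate_prediction(np.full(1000, 0.80), ndrs)
        assert rep.p_ndr == 0.0

    def test_half_of_planted_ndrs_hit(self):
        dips = [PlantedDip(1000 + 1500 * i, 0.30, 100, 40) for i in range(10)]
        y = dip_profile(17_000, dips, 0.85)
        ndrs = annotate_ndrs(y)
        assert len(ndrs) == 10
        pred = np.full(17_000, 0.85)
        for n in ndrs[:5]:
            pred[n.start : n.end] = 0.1
        rep = evaluate_prediction(pred, ndrs)
        assert rep.p_ndr == 0.5
        assert len(rep.missed) == 5

    def test_no_reference_ndrs_is_an_error(self):
        with pytest.raises(ValueError):
            evaluate_prediction(np.full(100, 0.8), [])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.uniform(0, 1, 2000)
        ndrs = [NDR(200, 400, 299.5, 200), NDR(1200, 1500, 1349.5, 300)]
        a = evaluate_prediction(pred, ndrs).auc
        b = evaluate_prediction(1 - (1 - pred) ** 3, ndrs).auc
        assert a == pytest.approx(b, abs=1e-12)
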