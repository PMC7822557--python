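import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nuclattice.energy import (
    NO_BIND,
    EnergyTrack,
    PositionWeightMatrix,
    SequenceRecord,
    build_polyA_factors,
    constant_nucleosome_track,
    load_nucleosome_energy,
    normalize_energy,
    scan_pwm,
)

LOG4 = np.log(4.0)


def uniform_pwm(l=3):
    return PositionWeightMatrix("uniform", np.full((l, 4), 0.25))


class TestScanPwm:
    def test_uniform_matrix_gives_constant_energy(self):
        track = scan_pwm(SequenceRecord("s", "ACGTACGT"), uniform_pwm(3), threshold=-np.inf)
        assert np.allclose(track.energies, 3 * LOG4)
        assert track.n_starts == 6

    def test_consensus_only_pwm_binds_only_its_site(self):
        w = np.zeros((3, 4))
        w[0, 0] = w[1, 1] = w[2, 2] = 1.0  # "ACG"
        pwm = PositionWeightMatrix("acg", w)
        track = scan_pwm(SequenceRecord("s", "TACGT"), pwm, both_strands=False, threshold=0.0)
        assert track.energies[1] == pytest.approx(0.0)
        assert np.isposinf(track.energies[[0, 2]]).all()

    def test_energy_is_negative_log_likelihood(self):
        # direct hand evaluation on a 2-bp window
        w = np.array([[0.7, 0.1, 0.1, 0.1], [0.2, 0.5, 0.2, 0.1]])
        pwm = PositionWeightMatrix("p", w)
        track = scan_pwm(SequenceRecord("s", "AC"), pwm, both_strands=False, threshold=-np.inf)
        assert track.energies[0] == pytest.approx(-np.log(0.7) - np.log(0.5))

    def test_windows_with_N_never_bind(self):
        track = scan_pwm(SequenceRecord("s", "ACNTACG"), uniform_pwm(3), threshold=-np.inf)
        assert np.isposinf(track.energies[:3]).all()
        assert np.isfinite(track.energies[3:]).all()

    def test_threshold_excludes_weak_windows(self):
        w = np.array([[0.97, 0.01, 0.01, 0.01]] * 4)
        pwm = PositionWeightMatrix("a4", w)
        track = scan_pwm(SequenceRecord("s", "AAAACCCC"), pwm)  # default 60% cutoff
        assert np.isfinite(track.energies[0])
        assert np.isposinf(track.energies[4])

    def test_strand_symmetry(self, rng):
        seq = SequenceRecord("s", "".join(rng.choice(list("ACGT"), 200)))
        w = rng.dirichlet(np.ones(4), size=5)
        pwm = PositionWeightMatrix("p", w)
        fwd = scan_pwm(seq, pwm, threshold=-np.inf)
        rev = scan_pwm(seq.reverse_complement(), pwm, threshold=-np.inf)
        assert np.allclose(fwd.energies, rev.energies[::-1])

    def test_pwm_wider_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_pwm(SequenceRecord("s", "AC"), uniform_pwm(3))


class TestNormalize:
    def test_constant_track_becomes_zero(self):
        t = normalize_energy(EnergyTrack("x", 2, np.full(10, 3.7)))
        assert np.allclose(t.energies, 0.0)

    def test_two_point_track_hand_computed(self):
        t = normalize_energy(EnergyTrack("x", 1, np.array([0.0, np.log(2)])))
        assert t.energies[0] == pytest.approx(np.log(0.75))
        assert t.energies[1] == pytest.approx(np.log(2) + np.log(0.75))
        assert np.mean(np.exp(-t.energies)) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=60))
    def test_mean_boltzmann_weight_is_one(self, values):
        t = normalize_energy(EnergyTrack("x", 1, np.array(values)))
        assert np.mean(np.exp(-t.energies)) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-20, 20), min_size=2, max_size=40),
        st.floats(-50, 50),
    )
    def test_constant_shift_before_normalization_is_absorbed(self, values, shift):
        raw = np.array(values)
        a = normalize_energy(EnergyTrack("x", 1, raw))
        b = normalize_energy(EnergyTrack("x", 1, raw + shift))
        assert np.allclose(a.energies, b.energies, atol=1e-8)

    def test_all_no_bind_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_energy(EnergyTrack("x", 1, np.full(5, NO_BIND)))

    def test_no_bind_positions_preserved(self):
        t = normalize_energy(EnergyTrack("x", 1, np.array([1.0, NO_BIND, 2.0])))
        assert np.isposinf(t.energies[1])
        finite = t.energies[np.isfinite(t.energies)]
        assert np.mean(np.exp(-finite)) == pytest.approx(1.0)


class TestPolyA:
    def test_single_exact_window(self):
        tracks = build_polyA_factors(SequenceRecord("s", "AAAAA"), [5])
        assert len(tracks) == 1
        assert np.isfinite(tracks[0].energies).sum() == 1

    def test_mixed_at_window_rejected(self):
        with pytest.warns(UserWarning):
            tracks = build_polyA_factors(SequenceRecord("s", "AATTT"), [5])
        assert tracks == []

    def test_counts_match_regex_oracle(self, rng):
        import re

        seq = "".join(rng.choice(list("ACGT"), 10_000, p=[0.31, 0.19, 0.19, 0.31]))
        tracks = build_polyA_factors(SequenceRecord("s", seq), [5, 6, 7, 8, 9])
        by_len = {t.footprint: t for t in tracks}
        for k in by_len:
            expected = sum(
                1
                for i in range(len(seq) - k + 1)
                if re.fullmatch(f"A{{{k}}}|T{{{k}}}", seq[i : i + k])
            )
            assert np.isfinite(by_len[k].energies).sum() == expected


class TestNucleosomeEnergy:
    def test_constant_probability_gives_zero_energy(self):
        t = load_nucleosome_energy(np.full(500, 0.4))
        assert np.allclose(t.energies, 0.0)

    def test_planted_energy_recovered_up_to_shift(self, rng):
        planted = rng.normal(0, 1, 400 - 146)
        p = np.exp(-planted)
        track = load_nucleosome_energy(
            np.concatenate([p, np.zeros(146) + p.mean()]), per_start=False
        )
        diff = track.energies - planted
        assert np.std(diff) == pytest.approx(0.0, abs=1e-10)

    def test_nonpositive_probability_is_no_bind(self):
        v = np.full(300, 0.5)
        v[10] = 0.0
        t = load_nucleosome_energy(v)
        assert np.isposinf(t.energies[10])

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            load_nucleosome_energy(np.full(100, 0.5))

    def test_surrogate_is_flat(self):
        t = constant_nucleosome_track(200)
        assert np.allclose(t.energies, 0.0)
        assert t.n_starts == 54
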