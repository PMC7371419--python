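import numpy as np
import pytest

import reactime as rt

FS = 300.0


def times_04():
    return np.arange(0, 121) / FS  # 0 .. 0.4 s inclusive


class TestEmd:
    def test_constant_input_has_no_imfs(self):
        s = rt.emd(np.full(50, 2.0))
        assert s.imfs == []
        np.testing.assert_array_equal(s.residual, np.full(50, 2.0))

    def test_monotone_input_has_no_imfs(self):
        s = rt.emd(np.linspace(0, 1, 64))
        assert s.imfs == []

    def test_pure_sinusoid_is_single_dominant_imf(self):
        t = times_04()
        sig = np.sin(2 * np.pi * 10 * t)
        s = rt.emd(sig, t)
        imf, _ = rt.select_imf(s, 8)
        assert np.corrcoef(imf, sig)[0, 1] > 0.99

    def test_two_tone_separation(self):
        t = times_04()
        fast = np.sin(2 * np.pi * 10 * t)
        slow = np.sin(2 * np.pi * 1 * t)
        s = rt.emd(fast + slow, t)
        assert np.corrcoef(s.imfs[0], fast)[0, 1] > 0.9

    def test_reconstruction_exact(self, rng):
        for sig in (rng.standard_normal(200),
                    np.sin(2 * np.pi * 7 * np.arange(200) / FS) + 0.3 * rng.standard_normal(200)):
            s = rt.emd(sig)
            err = np.linalg.norm(s.reconstruct() - sig) / np.linalg.norm(sig)
            assert err < 1e-6

    def test_imf_extrema_zero_crossing_balance(self, rng):
        sig = np.sin(2 * np.pi * 10 * times_04()) + 0.2 * rng.standard_normal(121)
        s = rt.emd(sig)
        for imf in s.imfs[:2]:
            ext = rt.recurrence._interior_extrema(imf).size
            zc = np.sum(np.diff(np.signbit(imf)) != 0)
            assert abs(ext - zc) <= 1


class TestSelectImf:
    def test_nearest_count_selected(self):
        t = times_04()
        imfs = [np.sin(2 * np.pi * f * t) for f in (15, 10, 2)]  # 12, 8, 2 extrema-ish
        s = rt.IMFSet(imfs, np.zeros_like(t), t)
        imf, ext = rt.select_imf(s, 8)
        assert imf is imfs[1]
        assert len(ext) == 8

    def test_tie_breaks_to_faster_imf(self):
        t = times_04()
        a = np.sin(2 * np.pi * 8.8 * t)   # 7 interior extrema
        b = np.sin(2 * np.pi * 11.3 * t)  # 9 interior extrema
        s = rt.IMFSet([b, a], np.zeros_like(t), t)
        imf, _ = rt.select_imf(s, 8)
        assert imf is b

    def test_empty_imf_list_rejected(self):
        s = rt.IMFSet([], np.zeros(10), np.arange(10.0))
        with pytest.raises(ValueError):
            rt.select_imf(s, 8)


class TestSegmentPhases:
    def test_ten_hz_sinusoid_yields_seven_interior_phases(self):
        t = times_04()
        sig = np.sin(2 * np.pi * 10 * t)
        s = rt.emd(sig, t)
        imf, ext = rt.select_imf(s, 8)
        phases = rt.segment_phases(imf, ext, t)
        assert len(phases) == 7

    def test_directions_alternate(self):
        t = times_04()
        sig = np.cos(2 * np.pi * 10 * t)
        ext = rt.recurrence._interior_extrema(sig)
        phases = rt.segment_phases(sig, t[ext], t)
        dirs = phases.directions()
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_too_few_extrema_rejected(self):
        with pytest.raises(ValueError):
            rt.segment_phases(np.zeros(10), np.array([0.5]), np.arange(10.0))


class TestFixedFreqPhases:
    def test_ten_hz_over_400ms_gives_eight_50ms_phases(self):
        phases = rt.fixed_freq_phases(10.0, (0.0, 0.4))
        assert len(phases) == 8
        for p in phases:
            assert np.isclose(p.t_end - p.t_start, 0.05)
        dirs = phases.directions()
        assert all(a != b for a, b in zip(dirs, dirs[1:]))

    def test_five_hz_gives_four_phases(self):
        assert len(rt.fixed_freq_phases(5.0, (0.0, 0.4))) == 4

    def test_exact_half_period_is_single_phase(self):
        assert len(rt.fixed_freq_phases(10.0, (0.0, 0.05))) == 1

    def test_integral_tiling_count(self):
        for f, w in [(3, 1.0), (25, 0.4), (10, 1.0)]:
            assert len(rt.fixed_freq_phases(f, (0.0, w))) == int(2 * f * w)


def synthetic_evidence(peak_fn, train_times, test_times, n_trials=5):
    """EvidenceTensor whose per-cell argmax lands at peak_fn(train_time, phase)."""
    vals = np.empty((n_trials, train_times.size, test_times.size))
    for j, tt in enumerate(train_times):
        centre = peak_fn(tt)
        vals[:, j, :] = -(test_times[None, :] - centre[None, :]) ** 2
    return rt.EvidenceTensor(vals, train_times, test_times, FS,
                             np.zeros(n_trials, int), np.zeros(n_trials, int))


class TestPhaseSlopes:
    def test_identity_peaks_give_positive_slopes(self):
        t = times_04()
        phases = rt.fixed_freq_phases(10.0, (0.0, 0.4))
        starts = np.array([p.t_start for p in phases])

        def peak_fn(tt):
            # the peak in every test phase sits at the training time's offset
            # within its own phase, mapped forward into that test phase
            offset = tt - starts[min(int(tt / 0.05), 7)]
            centre = np.empty(t.size)
            for i, p in enumerate(phases):
                sel = (t >= p.t_start - 1e-9) & (t <= p.t_end + 1e-9)
                centre[sel] = starts[i] + offset
            return centre

        ev = synthetic_evidence(peak_fn, t, t)
        slopes = rt.phase_slopes(ev, phases, phases)
        assert np.all(slopes.slopes[np.isfinite(slopes.slopes)] > 0)

    def test_checkerboard_construction_recovered(self):
        t = times_04()
        phases = rt.fixed_freq_phases(10.0, (0.0, 0.4))
        starts = np.array([p.t_start for p in phases])
        ends = np.array([p.t_end for p in phases])

        def peak_fn(tt):
            # within each test phase, map the training offset either forward
            # (same phase parity) or backward (opposite parity)
            j_phase = min(int(tt / 0.05), 7)
            offset = tt - starts[j_phase]
            centre = np.empty(t.size)
            for i in range(8):
                fwd = (i % 2) == (j_phase % 2)
                c = starts[i] + offset if fwd else ends[i] - offset
                centre[(t >= starts[i] - 1e-9) & (t <= ends[i] + 1e-9)] = c
            return centre

        ev = synthetic_evidence(peak_fn, t, t)
        slopes = rt.phase_slopes(ev, phases, phases)
        h = rt.hypothesis_matrix(phases, phases)
        finite = np.isfinite(slopes.slopes)
        assert np.all(np.sign(slopes.slopes[finite]) == h[finite])

    def test_constant_peaks_give_zero_slopes(self):
        t = times_04()
        phases = rt.fixed_freq_phases(10.0, (0.0, 0.4))
        ev = synthetic_evidence(lambda tt: np.full(t.size, 0.123), t, t)
        slopes = rt.phase_slopes(ev, phases, phases)
        np.testing.assert_allclose(slopes.slopes[np.isfinite(slopes.slopes)], 0.0,
                                   atol=1e-10)


class TestHypothesisMatrix:
    def test_same_direction_everywhere(self):
        p = rt.PhaseSet([rt.Phase(0, 0.1, "increasing"), rt.Phase(0.1, 0.2, "increasing")])
        np.testing.assert_array_equal(rt.hypothesis_matrix(p, p), np.ones((2, 2)))

    def test_alternating_checkerboard_with_positive_diagonal(self):
        p = rt.fixed_freq_phases(10.0, (0.0, 0.4))
        h = rt.hypothesis_matrix(p, p)
        assert np.all(np.diag(h) == 1.0)
        i, j = np.indices(h.shape)
        np.testing.assert_array_equal(h, np.where((i + j) % 2 == 0, 1.0, -1.0))

    def test_single_phase(self):
        p = rt.PhaseSet([rt.Phase(0, 0.05, "decreasing")])
        np.testing.assert_array_equal(rt.hypothesis_matrix(p, p), [[1.0]])


def slope_matrix(values, contrib=None):
    values = np.asarray(values, dtype=float)
    phases = rt.fixed_freq_phases(10.0, (0.0, 0.05 * values.shape[0]))
    return rt.SlopeMatrix(values, np.full(values.shape, 10), phases, phases, contrib)


class TestRecurrenceIndex:
    def test_zero_slopes_zero_ri(self):
        s = slope_matrix(np.zeros((4, 4)))
        assert rt.recurrence_index(s, np.ones((4, 4))).ri == 0.0

    def test_perfect_agreement_counts_cells(self):
        h = rt.hypothesis_matrix(rt.fixed_freq_phases(10, (0, 0.4)),
                                 rt.fixed_freq_phases(10, (0, 0.4)))
        s = slope_matrix(h.copy())
        assert rt.recurrence_index(s, h).ri == 64.0

    def test_hand_computed_two_by_two(self):
        s = slope_matrix(np.array([[0.5, -0.2], [-0.1, 0.3]]))
        h = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert np.isclose(rt.recurrence_index(s, h).ri, 1.1)

    def test_bilinearity(self, rng):
        s1 = rng.standard_normal((4, 4))
        s2 = rng.standard_normal((4, 4))
        h = np.where(rng.random((4, 4)) > 0.5, 1.0, -1.0)
        a, b = 2.5, -1.3
        ri = lambda m: rt.recurrence_index(slope_matrix(m), h).ri
        assert np.isclose(ri(a * s1 + b * s2), a * ri(s1) + b * ri(s2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rt.recurrence_index(slope_matrix(np.zeros((3, 3))), np.ones((4, 4)))

    def test_bootstrap_ci_brackets_ri_from_contributions(self, rng):
        contrib = 0.5 + 0.1 * rng.standard_normal((50, 4, 4))
        s = slope_matrix(contrib.mean(axis=0), contrib)
        h = np.ones((4, 4))
        res = rt.recurrence_index(s, h, n_boot=500, seed=3)
        assert res.bootstrap_ci[0] <= res.ri <= res.bootstrap_ci[1]
        assert res.bootstrap_ci[0] > 0.0


class TestNeighborRi:
    def test_diagonal_band_only(self):
        h = rt.hypothesis_matrix(rt.fixed_freq_phases(10, (0, 0.4)),
                                 rt.fixed_freq_phases(10, (0, 0.4)))
        vals = np.zeros((8, 8))
        i, j = np.indices(vals.shape)
        band = np.abs(i - j) <= 1
        vals[band] = h[band]
        near, far, _ = rt.neighbor_ri(slope_matrix(vals), h)
        assert near > 0 and far == 0.0

    def test_uniform_agreement_equalises_groups(self):
        h = rt.hypothesis_matrix(rt.fixed_freq_phases(10, (0, 0.4)),
                                 rt.fixed_freq_phases(10, (0, 0.4)))
        near, far, _ = rt.neighbor_ri(slope_matrix(h.copy()), h)
        assert np.isclose(near, far)

    def test_zero_slopes(self):
        h = np.ones((4, 4))
        near, far, _ = rt.neighbor_ri(slope_matrix(np.zeros((4, 4))), h)
        assert near == far == 0.0

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            rt.neighbor_ri(slope_matrix(np.zeros((2, 2))), np.ones((2, 2)))
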