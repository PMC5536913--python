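"""Generator contracts: profile shape, mitotic amplitude structure,
separability of noiseless kymographs, ensemble determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cicdyn as cd
from cicdyn.synthetic import (
    CYCLE_AMPLITUDE_FRACTIONS,
    _amplitude_and_mitoses,
    hill,
    make_spatial_profile,
)


def params(**kw):
    defaults = dict(plateau_amplitude=1.0, lambda_true=0.15,
                    hill_coeff_true=6.0, pole_floor=0.0)
    defaults.update(kw)
    return cd.GenotypeParams(**defaults)


class TestSpatialProfile:
    def test_central_plateau(self):
        prof = make_spatial_profile(params(), n_positions=101)
        x = np.linspace(0, 1, 101)
        assert 0.98 <= prof[x == 0.5][0] <= 1.0

    def test_half_max_at_lambda(self):
        p = params()
        prof = make_spatial_profile(p, n_positions=1001)
        x = np.linspace(0, 1, 1001)
        at_lambda = prof[np.isclose(x, 0.15)][0]
        # posterior factor is ~1 at x=0.15, so the value is ~half-plateau
        expected = 0.5 * hill(1 - 0.15, 0.15, 6.0)
        assert at_lambda == pytest.approx(expected, rel=1e-9)

    def test_sharper_boundary_is_higher_inside(self):
        x_probe = 0.20
        grid = np.linspace(0, 1, 1001)
        prof_a = make_spatial_profile(params(lambda_true=0.15), 1001)
        prof_b = make_spatial_profile(params(lambda_true=0.25), 1001)
        i = np.argmin(np.abs(grid - x_probe))
        assert prof_a[i] > prof_b[i]

    def test_midbody_within_two_percent_of_plateau(self, wt_params):
        prof = make_spatial_profile(wt_params, 200)
        x = np.linspace(0, 1, 200)
        mid = prof[(x >= 0.3) & (x <= 0.7)]
        assert abs(mid.mean() - wt_params.plateau_amplitude) <= 0.02 * wt_params.plateau_amplitude

    def test_mirror_symmetry(self):
        prof = make_spatial_profile(params(), 200)
        assert np.allclose(prof, prof[::-1], rtol=1e-12)

    def test_overlapping_boundaries_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_spatial_profile(params(lambda_true=0.3), 100, lambda_posterior=0.55)

    @given(lam=st.floats(0.05, 0.3), n=st.floats(2.0, 12.0))
    @settings(max_examples=25, deadline=None)
    def test_profile_bounded_by_floor_and_plateau(self, lam, n):
        p = params(lambda_true=lam, hill_coeff_true=n, pole_floor=0.05)
        prof = make_spatial_profile(p, 64)
        assert np.all(prof >= 0.05 - 1e-12)
        assert np.all(prof <= 1.0 + 1e-12)


class TestTemporalAmplitude:
    def test_exponential_recovery_identity(self, schedule):
        p = cd.GenotypeParams(recovery_tau=3.0)
        amp = cd.make_temporal_amplitude(schedule, p)
        times = schedule.frame_times()
        # 3 min into cycle-10 interphase (starts at t=0)
        i = np.argmin(np.abs(times - 3.0))
        target = p.plateau_amplitude * CYCLE_AMPLITUDE_FRACTIONS[0]
        assert amp[i] == pytest.approx(target * (1 - np.exp(-1)), rel=1e-9)

    def test_mitosis_midpoint_below_ten_percent_of_peak(self, schedule, wt_params):
        amp = cd.make_temporal_amplitude(schedule, wt_params)
        times = schedule.frame_times()
        for kind, _c, t0, t1 in schedule.segments():
            if kind != "mitosis":
                continue
            mid = np.argmin(np.abs(times - 0.5 * (t0 + t1)))
            prior_peak = amp[times < t0].max()
            assert amp[mid] < 0.1 * prior_peak

    def test_slower_tau_recovers_less(self, schedule):
        t_probe = 4.0
        times = schedule.frame_times()
        i = np.argmin(np.abs(times - t_probe))
        a3 = cd.make_temporal_amplitude(schedule, cd.GenotypeParams(recovery_tau=3.0))
        a6 = cd.make_temporal_amplitude(schedule, cd.GenotypeParams(recovery_tau=6.0))
        assert a6[i] < a3[i]

    def test_cycle14_reaches_plateau(self, schedule, wt_params):
        amp = cd.make_temporal_amplitude(schedule, wt_params)
        assert amp[-1] == pytest.approx(wt_params.plateau_amplitude, rel=1e-4)

    def test_mitosis_frames_are_window_minima(self, schedule, wt_params):
        amp, mitoses = _amplitude_and_mitoses(schedule, wt_params)
        times = schedule.frame_times()
        windows = [(t0, t1) for k, _c, t0, t1 in schedule.segments() if k == "mitosis"]
        assert len(mitoses) == len(windows)
        for mf, (t0, t1) in zip(mitoses, windows):
            sel = np.where((times >= t0 - 1e-9) & (times <= t1 + 1e-9))[0]
            assert mf == sel[np.argmin(amp[sel])]

    def test_amplitude_near_zero_at_divisions(self, wt_embryo):
        _, truth = wt_embryo
        amp = truth.amplitude_true
        for i, mf in enumerate(truth.mitosis_frames):
            nxt = (
                truth.mitosis_frames[i + 1]
                if i + 1 < len(truth.mitosis_frames)
                else len(amp)
            )
            assert amp[mf] < 0.1 * amp[mf:nxt].max()


class TestKymograph:
    def test_noiseless_is_rank_one(self, noiseless_embryo):
        stm, _ = noiseless_embryo
        s = np.linalg.svd(stm.values, compute_uv=False)
        assert s[1] / s[0] < 1e-10
        assert cd.accuracy_ratio(s) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_default_noise_keeps_separability(self, seed):
        stm, _ = cd.simulate_embryo(seed=seed)
        assert cd.decompose(stm).accuracy_ratio >= 0.96

    def test_bit_identical_given_seed(self):
        a, _ = cd.simulate_embryo(seed=7)
        b, _ = cd.simulate_embryo(seed=7)
        assert np.array_equal(a.values, b.values)

    def test_outer_product_structure(self):
        prof = np.array([1.0, 2.0, 3.0] * 6)
        amp = np.linspace(0, 5, 40)
        stm, truth = cd.make_kymograph(prof, amp, noise=None)
        assert np.allclose(stm.values, np.outer(prof, amp))
        assert np.array_equal(truth.spatial_profile_true, prof)


class TestEnsemble:
    def test_deterministic(self):
        e1 = cd.make_ensemble(n_embryos=5, base_seed=1)
        e2 = cd.make_ensemble(n_embryos=5, base_seed=1)
        for (s1, t1), (s2, t2) in zip(e1, e2):
            assert np.array_equal(s1.values, s2.values)
            assert np.array_equal(t1.mitosis_frames, t2.mitosis_frames)

    def test_phase_jitter_distinct(self):
        ens = cd.make_ensemble(n_embryos=5, base_seed=3)
        vecs = {tuple(tr.mitosis_frames) for _, tr in ens}
        assert len(vecs) >= 4  # start-phase jitter shifts the dip frames

    def test_wildtype_ensemble_separability(self):
        ens = cd.make_ensemble(cd.wild_type(), 10, base_seed=1)
        ratios = [cd.decompose(stm).accuracy_ratio for stm, _ in ens]
        assert min(ratios) >= 0.96


class TestValidation:
    def test_lambda_bounds(self):
        with pytest.raises(ValueError):
            cd.GenotypeParams(lambda_true=0.45)

    def test_plateau_above_floor(self):
        with pytest.raises(ValueError):
            cd.GenotypeParams(plateau_amplitude=1.0, pole_floor=2.0)

    def test_cycle14_must_be_longest(self):
        with pytest.raises(ValueError):
            cd.CycleSchedule(interphase_durations=(8, 10, 12, 50, 14))

    def test_schedule_fits_recording(self):
        with pytest.raises(ValueError, match="3 h"):
            cd.CycleSchedule(interphase_durations=(30, 35, 40, 45, 50))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            cd.NoiseParams(additive_sd=-1.0)
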