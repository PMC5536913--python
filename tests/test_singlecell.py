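"""Single-nucleus trace extraction and recovery-time estimation."""

import numpy as np
import pytest

import cicdyn as cd
from cicdyn.extraction import segment_embryo
from cicdyn.singlecell import ExponentialRecovery, RecoveryFitError, mean_trace


def exact_trace(tau=3.0, plateau=80.0, duration=50.0, nucleus_id=0):
    t = np.arange(0.0, duration, 0.5)
    return cd.NuclearTrace(nucleus_id, 0.5, t, plateau * (1.0 - np.exp(-t / tau)))


class TestRecoveryFit:
    def test_exact_exponential(self):
        est = cd.estimate_recovery(exact_trace(tau=3.0))
        assert est.tau == pytest.approx(3.0, abs=1e-3)
        assert est.t_half == pytest.approx(3.0 * np.log(2.0), abs=1e-3)
        assert est.plateau == pytest.approx(80.0, rel=1e-4)
        assert est.converged

    def test_all_zero_trace_rejected(self):
        t = np.arange(0.0, 30, 0.5)
        tr = cd.NuclearTrace(0, 0.5, t, np.zeros(t.size))
        with pytest.raises(RecoveryFitError):
            cd.estimate_recovery(tr)

    def test_too_few_frames_rejected(self):
        t = np.arange(0.0, 4, 0.5)
        tr = cd.NuclearTrace(0, 0.5, t, np.ones(t.size))
        with pytest.raises(ValueError, match="frames"):
            cd.estimate_recovery(tr)

    def test_tau_ratio_between_ensembles(self):
        from dataclasses import replace

        wt = cd.wild_type()
        taus = {}
        for label, tau in (("fast", 3.0), ("slow", 6.0)):
            gp = replace(wt, recovery_tau=tau)
            traces = cd.make_nuclear_traces(gp, n_nuclei=20, seed=11)
            taus[label] = np.mean([cd.estimate_recovery(tr).tau for tr in traces])
        assert taus["slow"] / taus["fast"] == pytest.approx(2.0, abs=0.2)

    def test_tau_scale_invariant(self):
        tr = exact_trace(tau=4.0)
        scaled = cd.NuclearTrace(0, 0.5, tr.times, 3.7 * tr.intensities)
        assert cd.estimate_recovery(scaled).tau == pytest.approx(
            cd.estimate_recovery(tr).tau, rel=1e-6
        )

    def test_larger_generator_tau_gives_larger_estimates(self):
        from dataclasses import replace

        wt = cd.wild_type()
        means = []
        for tau in (2.0, 4.0, 8.0):
            traces = cd.make_nuclear_traces(
                replace(wt, recovery_tau=tau), n_nuclei=15, seed=5
            )
            means.append(np.mean([cd.estimate_recovery(tr).tau for tr in traces]))
        assert np.all(np.diff(means) > 0)

    def test_estimator_api(self):
        tr = exact_trace()
        est = ExponentialRecovery().fit(tr.times, tr.intensities)
        assert est.tau_ == pytest.approx(3.0, abs=1e-3)
        assert np.allclose(est.predict(tr.times), tr.intensities, atol=1e-6)
        assert ExponentialRecovery().get_params() == {"min_frames": 10}


class TestMeanTrace:
    def test_identical_traces_zero_sd(self):
        traces = [exact_trace(nucleus_id=i) for i in range(3)]
        _, mean, sd = mean_trace(traces)
        assert np.allclose(sd[~np.isnan(sd)], 0.0)

    def test_constant_traces_average(self):
        t = np.arange(0.0, 20, 0.5)
        a = cd.NuclearTrace(0, 0.5, t, np.full(t.size, 4.0))
        b = cd.NuclearTrace(1, 0.5, t, np.full(t.size, 10.0))
        _, mean, _ = mean_trace([a, b])
        assert np.allclose(mean[~np.isnan(mean)], 7.0)

    def test_noisy_mean_tracks_true_curve(self):
        traces = cd.make_nuclear_traces(n_nuclei=20, seed=9)
        grid, mean, sd = mean_trace(traces)
        p = cd.wild_type()
        true = p.plateau_amplitude * (1.0 - np.exp(-np.clip(grid, 0, None) / p.recovery_tau))
        ok = ~np.isnan(mean) & ~np.isnan(sd)
        # the ensemble mean should stay within one ensemble SD of the
        # genotype-level curve nearly everywhere
        inside = np.abs(mean[ok] - true[ok]) <= np.maximum(sd[ok], 2.0)
        assert inside.mean() >= 0.95

    def test_single_trace_rejected(self):
        with pytest.raises(ValueError):
            mean_trace([exact_trace()])


@pytest.fixture(scope="module")
def movie_setup(wt_movie):
    movie, stm, truth = wt_movie
    kym = cd.build_space_time_matrix(movie)
    analysis = cd.analyze_embryo(kym)
    mid = movie.n_frames // 2
    geom = segment_embryo(movie.frames[mid - 10 : mid + 11].mean(axis=0))
    return movie, truth, geom, analysis


class TestMovieExtraction:

    def test_most_nuclei_recovered_accurately(self, movie_setup):
        movie, truth, geom, analysis = movie_setup
        traces = cd.extract_nuclear_traces(movie, geom, analysis.events)
        pos = np.array([t.position for t in traces])
        d_px = (
            np.abs(pos[:, None] - truth.nucleus_centers[None, :]).min(axis=0)
            * 2.0 * geom.semi_major
        )
        assert (d_px <= 2.0).sum() >= 18

    def test_traces_suppressed_during_mitosis(self, movie_setup):
        movie, truth, geom, analysis = movie_setup
        traces = cd.extract_nuclear_traces(movie, geom, analysis.events)
        mito = truth.mitosis_frames[-1]
        for tr in traces[:5]:
            plateau = tr.intensities[-20:].mean()
            assert tr.intensities[mito] < 0.25 * plateau

    def test_deterministic_given_seed(self, movie_setup):
        movie, truth, geom, analysis = movie_setup
        t1 = cd.extract_nuclear_traces(movie, geom, analysis.events)
        movie2, _, _ = cd.simulate_movie(seed=4)
        t2 = cd.extract_nuclear_traces(movie2, geom, analysis.events)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.intensities, b.intensities)

    def test_positions_in_midbody(self, movie_setup):
        movie, truth, geom, analysis = movie_setup
        traces = cd.extract_nuclear_traces(movie, geom, analysis.events)
        pos = np.array([t.position for t in traces])
        assert np.all((pos >= 0.25) & (pos <= 0.75))

    def test_recovery_fits_from_movie_traces(self, movie_setup):
        movie, truth, geom, analysis = movie_setup
        traces = cd.extract_nuclear_traces(movie, geom, analysis.events)
        taus = [cd.estimate_recovery(tr).tau for tr in traces]
        # movie traces mix tissue and per-nucleus kinetics; the fitted
        # values should still bracket the generating timescale
        assert np.mean(taus) == pytest.approx(truth.params.recovery_tau, rel=0.5)
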