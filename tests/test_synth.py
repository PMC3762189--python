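"""Synthetic-data generators: determinism, distributions, ground truth."""

import numpy as np
import pytest
from scipy import stats

from branchkin import Conditions
from branchkin.synth import (
    MovieGeneratorSpec,
    TraceGeneratorSpec,
    gen_dwell_times,
    gen_pyrene_ensemble,
    gen_tirf_movie,
)

SMALL_MOVIE = dict(field_size=(96, 96), n_filaments=5, filament_step_px=12,
                   filament_segments=6, n_frames=40)


@pytest.fixture(scope="module")
def fast_trace_spec():
    conds = (Conditions(actin_monomer=3.0, t_end=800.0),)
    return TraceGeneratorSpec(variant="spontaneous", conditions=conds,
                              noise_sd=0.01, seed=11)


class TestPyreneEnsemble:
    def test_zero_noise_matches_simulation(self, fast_trace_spec):
        from branchkin import build_network, simulate
        spec = TraceGeneratorSpec(variant="spontaneous",
                                  conditions=fast_trace_spec.conditions,
                                  noise_sd=0.0, seed=11)
        traces, truth = gen_pyrene_ensemble(spec)
        res = simulate(build_network("spontaneous"), spec.conditions[0])
        np.testing.assert_array_equal(traces[0].signal,
                                      res.polymerized_actin)
        assert truth["noise_sd"] == 0.0

    def test_seed_determinism(self, fast_trace_spec):
        t1, _ = gen_pyrene_ensemble(fast_trace_spec)
        t2, _ = gen_pyrene_ensemble(fast_trace_spec)
        np.testing.assert_array_equal(t1[0].signal, t2[0].signal)

    def test_noise_scale(self, fast_trace_spec):
        traces, _ = gen_pyrene_ensemble(fast_trace_spec)
        clean, _ = gen_pyrene_ensemble(
            TraceGeneratorSpec(variant="spontaneous",
                               conditions=fast_trace_spec.conditions,
                               noise_sd=0.0, seed=11))
        resid = traces[0].signal - clean[0].signal
        scale = 0.01 * clean[0].signal.max()
        assert 0.5 * scale < resid.std() < 1.5 * scale

    def test_fluorescence_mode_round_trips(self):
        from branchkin.traces import fluorescence_to_concentration
        conds = (Conditions(actin_monomer=3.0, t_end=2500.0),)
        spec = TraceGeneratorSpec(variant="spontaneous", conditions=conds,
                                  noise_sd=0.0, seed=3,
                                  fluorescence_mode=True)
        traces, truth = gen_pyrene_ensemble(spec)
        assert traces[0].mode == "fluorescence"
        assert len(truth["fluorescence_gains"]) == 1
        conv = fluorescence_to_concentration(traces[0])
        assert conv.signal[-1] == pytest.approx(2.9, rel=0.01)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TraceGeneratorSpec(noise_sd=-0.1)
        with pytest.raises(ValueError):
            TraceGeneratorSpec(conditions=())


class TestDwellTimes:
    def test_sample_mean_near_reciprocal_rate(self):
        """191 draws at 0.050 s^-1: sample mean within 3 s.e. of 20 s."""
        df = gen_dwell_times(0.050, 191, frame_interval=0.2,
                             movie_span=600.0, seed=5)
        se = 20.0 / np.sqrt(191)
        assert abs(df.true_lifetime_s.mean() - 20.0) <= 3 * se

    def test_quantization_error_vanishes_with_fine_frames(self):
        k, n = 0.05, 400
        coarse = gen_dwell_times(k, n, 1.0, 2000.0, seed=9)
        fine = gen_dwell_times(k, n, 1e-4, 2000.0, seed=9)
        # boundary-truncated events carry irreducible error; compare the rest
        ok_c = coarse[~coarse.censored_end]
        ok_f = fine[~fine.censored_end]
        err_coarse = np.abs(ok_c.lifetime_s - ok_c.true_lifetime_s).mean()
        err_fine = np.abs(ok_f.lifetime_s - ok_f.true_lifetime_s).mean()
        assert err_fine < 0.01 * err_coarse

    def test_censoring_flags_match_boundary_rule(self):
        df = gen_dwell_times(0.05, 500, frame_interval=0.5,
                             movie_span=100.0, seed=4)
        n_frames = 200
        first = np.floor(df.start_s / 0.5).astype(int)
        assert ((first == 0) == df.censored_start).all()
        # events overlapping the final frame are flagged
        assert df.censored_end.any()
        ends = df.start_s + df.true_lifetime_s
        assert (df.censored_end == (ends >= (n_frames - 1) * 0.5)).all()

    def test_exponentiality_across_seeds(self):
        """KS test against the target exponential passes at alpha = 0.01
        in >= 95% of seeds (n = 1000 draws each)."""
        passes = 0
        n_seeds = 60
        for seed in range(n_seeds):
            df = gen_dwell_times(0.05, 1000, 0.2, 5000.0, seed=seed)
            p = stats.kstest(df.true_lifetime_s, "expon",
                             args=(0, 20.0)).pvalue
            passes += p > 0.01
        assert passes >= 0.95 * n_seeds

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            gen_dwell_times(-1.0, 10, 0.2, 100.0)
        with pytest.raises(ValueError, match="span"):
            gen_dwell_times(0.05, 10, 10.0, 1.0)


@pytest.fixture(scope="module")
def small_movie():
    return gen_tirf_movie(MovieGeneratorSpec(seed=21, **SMALL_MOVIE))


class TestMovie:
    def test_seed_determinism(self, small_movie):
        again = gen_tirf_movie(MovieGeneratorSpec(seed=21, **SMALL_MOVIE))
        np.testing.assert_array_equal(small_movie.stack, again.stack)
        assert small_movie.tracks.equals(again.tracks)

    def test_shapes_and_truth(self, small_movie):
        assert small_movie.stack.shape == (40, 96, 96)
        assert small_movie.stack.dtype == np.uint16
        assert small_movie.filament_mask.shape == (96, 96)
        assert small_movie.side_sites > 0
        assert {"x", "y", "start_s", "duration_s",
                "binding_class"} <= set(small_movie.tracks.columns)

    def test_molecules_render_above_background(self, small_movie):
        row = small_movie.tracks.iloc[0]
        f = int(row.first_frame)
        x, y = int(round(row.x)), int(round(row.y))
        spot = small_movie.stack[f, y - 1:y + 2, x - 1:x + 2].mean()
        assert spot > small_movie.spec.background + 30

    def test_zero_molecule_movie(self):
        spec = MovieGeneratorSpec(seed=3, conc_nM=1e-7, **SMALL_MOVIE)
        mv = gen_tirf_movie(spec)
        assert len(mv.tracks) == 0
        # pure filament+noise movie: measurable detector false positives
        from branchkin.singlemol import detect_molecules, preprocess_frame
        fp = sum(len(detect_molecules(preprocess_frame(mv.stack[f])))
                 for f in range(mv.n_frames))
        assert fp <= 2

    def test_side_events_avoid_junction_footprint(self, small_movie):
        sides = small_movie.tracks.query(
            "binding_class == 'filament_side'")
        if len(sides) and len(small_movie.junctions):
            d = np.hypot(
                sides.x.to_numpy()[:, None] - small_movie.junctions[None, :, 0],
                sides.y.to_numpy()[:, None] - small_movie.junctions[None, :, 1])
            assert d.min() > 3.0

    def test_junctions_never_co_occupied(self):
        """A junction is one binding site: events at the same junction
        never overlap in time."""
        mv = gen_tirf_movie(MovieGeneratorSpec(seed=8, conc_nM=50.0,
                                               **SMALL_MOVIE))
        juncs = mv.tracks.query("binding_class == 'branch_junction'")
        for (_x, _y), grp in juncs.groupby(["x", "y"]):
            grp = grp.sort_values("start_s")
            ends = (grp.start_s + grp.duration_s).to_numpy()[:-1]
            starts = grp.start_s.to_numpy()[1:]
            assert (starts >= ends - 1e-9).all()

    def test_doubling_side_off_rate_halves_mean_dwell(self):
        spec1 = MovieGeneratorSpec(seed=2, n_frames=40, field_size=(96, 96),
                                   n_filaments=5, filament_step_px=12,
                                   filament_segments=6, conc_nM=20.0)
        spec2 = MovieGeneratorSpec(seed=2, n_frames=40, field_size=(96, 96),
                                   n_filaments=5, filament_step_px=12,
                                   filament_segments=6, conc_nM=20.0,
                                   k_off_side=2 * spec1.k_off_side)
        d1 = gen_tirf_movie(spec1).tracks.query(
            "binding_class == 'filament_side'").duration_s
        d2 = gen_tirf_movie(spec2).tracks.query(
            "binding_class == 'filament_side'").duration_s
        # Monte-Carlo: ratio of means within generous CI of 2
        assert 1.4 < d1.mean() / d2.mean() < 2.8

    def test_overcrowding_flagged(self):
        spec = MovieGeneratorSpec(seed=1, conc_nM=5e4, **SMALL_MOVIE)
        with pytest.raises(ValueError, match="overcrowded"):
            gen_tirf_movie(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MovieGeneratorSpec(k_off_side=-1.0)
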