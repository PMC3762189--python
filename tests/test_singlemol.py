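"""Single-molecule pipeline units: preprocessing, detection, linking,
filtering, dwell-time fits, census and affinity arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from branchkin.singlemol import (
    Detection,
    DwellTimeExponential,
    MoleculeTrack,
    classify_tracks,
    count_side_sites,
    detect_molecules,
    excess_ligand_check,
    filter_tracks,
    frame_interval_from_timestamps,
    kd_from_fraction_bound,
    link_tracks,
    off_rate_from_lifetimes,
    preprocess_frame,
)


def psf_frame(positions, shape=(64, 64), amp=1000.0, sigma=1.2,
              background=100.0, rng=None):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    img = np.full(shape, background, float)
    for x, y in positions:
        img += amp / (2 * np.pi * sigma**2) * np.exp(
            -((xx - x)**2 + (yy - y)**2) / (2 * sigma**2))
    if rng is not None:
        img = rng.poisson(img) + rng.normal(0, 2, size=shape)
    return img


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        out = preprocess_frame(np.full((40, 40), 57.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_spot_survives_sloping_background(self):
        yy, xx = np.mgrid[:64, :64]
        background = 50.0 + 0.8 * xx + 0.3 * yy
        spot = psf_frame([(30.0, 30.0)], background=0.0)
        out = preprocess_frame(background + spot)
        # background removed, spot preserved above threshold
        assert out[30, 30] > 0.5 * spot[30, 30]
        corner = np.abs(out[5:15, 45:60]).max()
        assert corner < 0.1 * out[30, 30]

    def test_not_idempotent(self):
        """A second pass erodes the spot - documented behavior."""
        frame = psf_frame([(30.0, 30.0)])
        once = preprocess_frame(frame)
        twice = preprocess_frame(once)
        assert twice[30, 30] < once[30, 30]

    def test_shrink_path_matches_full_opening_on_smooth_background(self):
        yy, xx = np.mgrid[:48, :48]
        img = 100.0 + 0.5 * xx
        full = preprocess_frame(img, shrink=1)
        fast = preprocess_frame(img)
        np.testing.assert_allclose(fast, full, atol=2.0)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            preprocess_frame(np.zeros((4, 4, 4)))


class TestDetect:
    def test_blank_noise_frames_yield_no_detections(self):
        """At a 5-sigma threshold, pure-noise frames produce < 1 false
        positive per 100 frames."""
        rng = np.random.default_rng(7)
        total = sum(
            len(detect_molecules(preprocess_frame(
                rng.normal(100, 3, size=(64, 64)))))
            for _ in range(100))
        assert total <= 1

    def test_single_spot_localized_within_half_pixel(self, rng):
        truth = (31.6, 28.3)
        frame = psf_frame([truth], rng=rng)
        dets = detect_molecules(preprocess_frame(frame))
        assert len(dets) == 1
        assert abs(dets[0].x - truth[0]) < 0.5
        assert abs(dets[0].y - truth[1]) < 0.5

    def test_resolvable_pair(self, rng):
        frame = psf_frame([(25.0, 25.0), (25.0, 31.0)], rng=rng)
        dets = detect_molecules(preprocess_frame(frame))
        assert len(dets) == 2

    def test_saturation_warning(self):
        frame = psf_frame([(30.0, 30.0)])
        with pytest.warns(UserWarning, match="saturated"):
            detect_molecules(frame, saturation_level=frame.max())


def static_detections(x, y, frames, intensity=100.0):
    return [Detection(frame=f, x=x, y=y, intensity=intensity)
            for f in frames]


class TestLinking:
    def test_static_spot_single_track(self):
        per_frame = [[Detection(f, 10.0, 12.0, 100.0)] for f in range(10)]
        tracks = link_tracks(per_frame, max_displacement=2.0)
        assert len(tracks) == 1
        assert tracks[0].lifetime_frames == 10

    def test_one_frame_gap_splits_track(self):
        """No gap closing: a single missed frame ends the track."""
        per_frame = [[Detection(f, 10.0, 12.0, 100.0)] for f in range(4)]
        per_frame += [[]]
        per_frame += [[Detection(f, 10.0, 12.0, 100.0)] for f in range(5, 9)]
        tracks = link_tracks(per_frame, max_displacement=2.0)
        assert len(tracks) == 2
        assert sorted(t.lifetime_frames for t in tracks) == [4, 4]

    def test_displacement_gate(self):
        per_frame = [[Detection(0, 10.0, 10.0, 100.0)],
                     [Detection(1, 20.0, 10.0, 100.0)]]
        tracks = link_tracks(per_frame, max_displacement=2.0)
        assert len(tracks) == 2

    def test_crowded_field_recovery(self, rng):
        """>= 95% of 20 simultaneous ground-truth molecules are recovered
        as single tracks without identity switches."""
        n_mol, n_frames = 20, 30
        pos = rng.uniform(5, 120, size=(n_mol, 2))
        spans = [(int(a), int(a) + int(b)) for a, b in
                 zip(rng.integers(0, 5, n_mol),
                     rng.integers(10, n_frames - 5, n_mol))]
        per_frame = []
        for f in range(n_frames):
            dets = []
            for i, (start, stop) in enumerate(spans):
                if start <= f <= stop:
                    jitter = rng.normal(0, 0.08, 2)
                    dets.append(Detection(f, pos[i, 0] + jitter[0],
                                          pos[i, 1] + jitter[1], 100.0))
            per_frame.append(dets)
        tracks = link_tracks(per_frame, max_displacement=2.0)
        recovered = 0
        for i, (start, stop) in enumerate(spans):
            match = [t for t in tracks
                     if t.start_frame == start and t.end_frame == stop
                     and np.hypot(t.centroid[0] - pos[i, 0],
                                  t.centroid[1] - pos[i, 1]) < 1.0]
            recovered += len(match) == 1
        assert recovered >= 0.95 * n_mol

    def test_empty_input(self):
        assert link_tracks([], max_displacement=2.0) == []

    def test_track_invariants(self):
        with pytest.raises(ValueError, match="consecutive"):
            MoleculeTrack([Detection(0, 1, 1, 5), Detection(2, 1, 1, 5)])
        track = MoleculeTrack(static_detections(1.0, 2.0, range(3)),
                              frame_interval=0.25)
        assert track.lifetime_frames == 3
        assert track.lifetime_s == pytest.approx(0.75)

    def test_frame_interval_from_timestamps(self):
        ts = 10.0 + 0.2 * np.arange(50)
        assert frame_interval_from_timestamps(ts) == pytest.approx(0.2)


class TestFilter:
    def make_tracks(self, n_frames=100):
        tracks = [
            MoleculeTrack(static_detections(5, 5, range(0, 4))),      # rule 1
            MoleculeTrack(static_detections(6, 5,
                                            range(n_frames - 3,
                                                  n_frames))),        # rule 1
            MoleculeTrack(static_detections(7, 5, [50])),             # rule 2
            MoleculeTrack(static_detections(8, 5, range(40, 50),
                                            intensity=10000.0)),      # rule 3
        ]
        clean = [MoleculeTrack(static_detections(10 + i, 5,
                                                 range(20, 35)))
                 for i in range(7)]
        return tracks[:3] + clean[:4] + tracks[3:] + clean[4:]

    def test_constructed_fixture_keeps_exactly_clean_tracks(self):
        """10 tracks, 3 violating one rule each (+1 intensity outlier),
        exactly the clean ones survive."""
        mask = np.zeros((20, 40), bool)
        mask[4:7, :] = True
        tracks = self.make_tracks()
        kept, counts = filter_tracks(tracks, n_frames=100,
                                     filament_mask=mask)
        assert len(kept) == 7
        assert counts == {"boundary": 2, "single_frame": 1, "intensity": 1,
                          "off_filament": 0}

    def test_off_filament_rejection(self):
        mask = np.zeros((20, 40), bool)
        mask[4:7, 5:15] = True
        far = MoleculeTrack(static_detections(35, 5, range(10, 20)))
        near = MoleculeTrack(static_detections(10, 5, range(10, 20)))
        kept, counts = filter_tracks([near, far], n_frames=100,
                                     filament_mask=mask,
                                     intensity_stats=(100.0, 50.0))
        assert kept == [near]
        assert counts["off_filament"] == 1

    def test_rules_toggleable(self):
        tracks = self.make_tracks()
        kept, _ = filter_tracks(tracks, n_frames=100,
                                enabled=(False, True, False, False))
        assert len(kept) == len(tracks) - 1  # only the 1-frame track drops

    def test_missing_mask_raises(self):
        with pytest.raises(ValueError, match="mask"):
            filter_tracks([], n_frames=10)


class TestClassify:
    def test_junction_side_and_nascent(self):
        junctions = [(10.0, 10.0), (30.0, 30.0)]
        births = [0, 25]
        at_junction = MoleculeTrack(static_detections(10.2, 9.9,
                                                      range(5, 9)))
        on_side = MoleculeTrack(static_detections(50.0, 50.0, range(5, 9)))
        nascent = MoleculeTrack(static_detections(30.0, 30.0, range(20, 28)))
        classify_tracks([at_junction, on_side, nascent], junctions,
                        junction_birth_frames=births)
        assert at_junction.binding_class == "branch_junction"
        assert on_side.binding_class == "filament_side"
        assert nascent.binding_class == "nascent_branch"


class TestDwellTimes:
    def test_recovery_at_large_n(self, rng):
        """n = 10^4 exponential draws at 0.050 s^-1 fit back within 5%."""
        lifetimes = rng.exponential(1 / 0.050, size=10_000)
        k, tau = off_rate_from_lifetimes(lifetimes)
        assert k == pytest.approx(0.050, rel=0.05)
        assert tau == pytest.approx(1 / k)

    def test_error_shrinks_with_n(self):
        """Estimator consistency: RMSE decreases from n=100 to n=10^4."""
        true_k = 0.050
        rmse = []
        for n in (100, 1000, 10_000):
            reps = []
            for seed in range(12):
                draw = np.random.default_rng(seed).exponential(1 / true_k, n)
                reps.append(off_rate_from_lifetimes(draw)[0])
            rmse.append(np.sqrt(np.mean((np.array(reps) - true_k) ** 2)))
        assert rmse[2] < rmse[1] < rmse[0]

    def test_scale_property(self, rng):
        """Scaling lifetimes and the bin width by s scales k by 1/s
        exactly."""
        lifetimes = rng.exponential(20.0, size=2000)
        k1, _ = off_rate_from_lifetimes(lifetimes, bin_width=5.0)
        k2, _ = off_rate_from_lifetimes(2 * lifetimes, bin_width=10.0)
        assert k2 == pytest.approx(k1 / 2, rel=1e-9)

    def test_estimator_interface_and_errors(self, rng):
        est = DwellTimeExponential()
        assert est.get_params()["bin_width"] == 5.0
        with pytest.raises(ValueError, match=">= 20"):
            est.fit([1.0, 2.0])
        with pytest.raises(ValueError, match="single bin"):
            DwellTimeExponential(bin_width=500.0).fit(
                rng.exponential(20.0, 100))
        est.fit(rng.exponential(20.0, 500))
        assert est.tau_ == pytest.approx(1 / est.k_off_)
        assert est.result_.n_events == 500


class TestCensus:
    def test_empty_mask(self):
        census = count_side_sites(np.zeros((10, 10), bool), 0)
        assert census.side_sites == 0
        assert census.junction_site_share == 0.0

    def test_methods_formula(self):
        """10,000 filament px and 10 junctions:
        floor(((10000-50)/3)*0.1067*370/6) sites."""
        mask = np.zeros((100, 100), bool)
        mask.ravel()[:10_000] = True
        census = count_side_sites(mask, 10)
        expected = int((10_000 - 50) / 3 * 0.1067 * 370 / 6)
        assert expected == 21_823
        assert census.side_sites == expected

    def test_junction_share_at_experimental_scale(self):
        """68 junctions against ~53,000 side sites: ~0.13% of all sites."""
        from branchkin.singlemol import BindingSiteCensus
        census = BindingSiteCensus(filament_pixels=0, n_junctions=68,
                                   side_sites=53_000)
        assert census.junction_site_share == pytest.approx(0.128, abs=0.005)

    @given(st.integers(min_value=1, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_linear_in_filament_pixels(self, blocks):
        """At fixed junction count, sites grow linearly with mask area."""
        base = 3000
        mask = np.zeros((400, 400), bool)
        mask.ravel()[:base * blocks] = True
        census = count_side_sites(mask, 0)
        per_block = base / 3 * 0.1067 * 370 / 6
        assert abs(census.side_sites - per_block * blocks) <= 1.0

    def test_junction_pixels_cannot_exceed_mask(self):
        mask = np.zeros((10, 10), bool)
        mask[0, :4] = True
        with pytest.raises(ValueError, match="exceed"):
            count_side_sites(mask, 1)


class TestAffinity:
    def test_half_occupancy_identity(self):
        assert kd_from_fraction_bound(0.5, 3.0) == pytest.approx(3.0)

    def test_junction_affinity_inversion(self):
        """1.5 nM ligand at fraction bound 1.5/18.5 inverts to K_D 17 nM."""
        fb = 1.5 / 18.5
        assert kd_from_fraction_bound(fb, 1.5) == pytest.approx(17.0)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_with_occupancy_formula(self, kd, conc):
        fb = conc / (kd + conc)
        assert kd_from_fraction_bound(fb, conc) == pytest.approx(kd,
                                                                 rel=1e-9)

    def test_closure_with_on_rate(self):
        """K_D from occupancy combined with k_on = k_off/K_D returns the
        generating off rate exactly."""
        from branchkin.fitting import k_on_from_kd
        k_off, kd_um = 0.034, 0.017
        fb = 0.0015 / (kd_um + 0.0015)
        kd_back = kd_from_fraction_bound(fb, 0.0015)
        assert k_on_from_kd(k_off, kd_back).per_uM_s * kd_back == \
            pytest.approx(k_off, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kd_from_fraction_bound(0.0, 1.0)
        with pytest.raises(ValueError):
            kd_from_fraction_bound(1.0, 1.0)


class TestExcessLigand:
    def test_experimental_numbers(self):
        """120 mm^2 chamber, 512^2 px at 106.7 nm, 20 bound/frame, 12 ul of
        1.5 nM: image share ~0.00248%, ~8.06e5 bound of ~1.08e10 total,
        ~0.0075% bound."""
        report = excess_ligand_check(avg_bound_per_frame=20.0)
        assert report["image_fraction_percent"] == pytest.approx(0.00248,
                                                                 rel=0.01)
        assert report["bound_per_chamber"] == pytest.approx(8.06e5, rel=0.01)
        assert report["total_molecules"] == pytest.approx(1.08e10, rel=0.01)
        assert report["percent_bound"] == pytest.approx(0.0075, rel=0.02)

    def test_zero_bound(self):
        assert excess_ligand_check(0.0)["percent_bound"] == 0.0

    def test_concentration_proportionality(self):
        r1 = excess_ligand_check(20.0, conc_nM=1.5)
        r2 = excess_ligand_check(20.0, conc_nM=3.0)
        assert r2["total_molecules"] == pytest.approx(2 * r1["total_molecules"])
        assert r2["percent_bound"] == pytest.approx(r1["percent_bound"] / 2)

    def test_bad_chamber(self):
        with pytest.raises(ValueError):
            excess_ligand_check(20.0, chamber_area_mm2=0.0)
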