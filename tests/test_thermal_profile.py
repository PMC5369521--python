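"""Cross-gel tracking, internal-standard normalization, melting fits,
shift scoring."""

import numpy as np
import pytest

from tsfitge.gel_image import Spot
from tsfitge.melting import logistic_melt
from tsfitge.synthetic import (
    generate_proteome,
    make_design,
    simulate_spot_tables,
    soluble_fraction,
)
from tsfitge.thermal_profile import (
    estimate_affine,
    fit_melting,
    match_spots,
    normalize_track,
    score_run,
)

TEMPS = np.array([37.0, 41.0, 45.0, 49.0, 53.0, 57.0, 61.0, 64.0])


def make_spot(i, x, y, cy2=1000.0, cy3=1000.0, cy5=1000.0):
    return Spot(
        spot_id=f"s{i:04d}", x=x, y=y, sigma_x=1.3, sigma_y=0.9, theta=0.0,
        intensity_cy2=cy2, intensity_cy3=cy3, intensity_cy5=cy5, fit_quality=1.0,
    )


class TestMatchSpots:
    def test_identical_tables_complete_tracks(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(20, 200, size=(30, 2))
        gels = {
            t: [make_spot(i, x, y) for i, (x, y) in enumerate(xy)]
            for t in (37.0, 45.0, 53.0)
        }
        tracks = match_spots(gels)
        assert len(tracks) == 30
        assert all(tr.complete for tr in tracks)

    def test_known_affine_recovered(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(20, 300, size=(60, 2))
        affine = ((1.003, 0.002, 1.8), (-0.001, 0.998, -2.4))
        (a, b, c), (d, e, f) = affine
        dst = np.column_stack([a * src[:, 0] + b * src[:, 1] + c,
                               d * src[:, 0] + e * src[:, 1] + f])
        est = estimate_affine(dst, src)  # mapping warped -> baseline
        back = np.column_stack([
            est[0][0] * dst[:, 0] + est[0][1] * dst[:, 1] + est[0][2],
            est[1][0] * dst[:, 0] + est[1][1] * dst[:, 1] + est[1][2],
        ])
        rms = np.sqrt(np.mean(np.sum((back - src) ** 2, axis=1)))
        assert rms <= 0.5

    def test_warped_simulation_matches(self):
        prot = generate_proteome(60, seed=8, min_separation_px=10.0)
        design = make_design(seed=8, warp_shift_px=2.0)
        tables = simulate_spot_tables(prot, design)
        tracks = match_spots(tables)
        n_complete = sum(tr.complete for tr in tracks)
        assert n_complete >= 0.95 * len(tracks)

    def test_baseline_only_spot_keeps_incomplete_track(self):
        gels = {
            37.0: [make_spot(0, 50, 50), make_spot(1, 120, 80)],
            53.0: [make_spot(0, 50, 50)],
        }
        tracks = match_spots(gels)
        assert len(tracks) == 2
        by_ref = {tr.reference_spot.x: tr for tr in tracks}
        assert by_ref[50].complete
        assert not by_ref[120].complete
        assert 53.0 not in by_ref[120].members

    def test_heated_only_spot_starts_no_track(self):
        gels = {
            37.0: [make_spot(0, 50, 50)],
            53.0: [make_spot(0, 50, 50), make_spot(1, 200, 200)],
        }
        tracks = match_spots(gels)
        assert len(tracks) == 1


class TestNormalizeTrack:
    def _track(self, gain_by_temp):
        prot = generate_proteome(1, seed=3)
        sp = prot[0]
        gels = {}
        for i, t in enumerate(TEMPS):
            g = gain_by_temp.get(t, 1.0)
            gels[float(t)] = [
                make_spot(
                    0, 50, 50,
                    cy2=g * sp.abundance,
                    cy3=g * sp.abundance * soluble_fraction(sp, t, "vehicle"),
                    cy5=g * sp.abundance * soluble_fraction(sp, t, "drug"),
                )
            ]
        (track,) = match_spots(gels)
        return sp, normalize_track(track)

    def test_baseline_is_exactly_one(self):
        _, track = self._track({})
        assert track.rel_vehicle[37.0] == 1.0
        assert track.rel_drug[37.0] == 1.0

    def test_gain_cancellation(self):
        _, a = self._track({})
        _, b = self._track({49.0: 2.7, 57.0: 0.4})
        for t in TEMPS:
            assert b.rel_vehicle[t] == pytest.approx(a.rel_vehicle[t], rel=1e-12)
            assert b.rel_drug[t] == pytest.approx(a.rel_drug[t], rel=1e-12)

    def test_noiseless_track_matches_forward_model(self):
        sp, track = self._track({})
        for t in TEMPS:
            expected = soluble_fraction(sp, t, "vehicle") / soluble_fraction(
                sp, 37.0, "vehicle"
            )
            assert track.rel_vehicle[t] == pytest.approx(expected, rel=0.02)

    def test_missing_cy2_point_left_missing(self):
        gels = {
            37.0: [make_spot(0, 50, 50, cy2=1000.0)],
            53.0: [make_spot(0, 50, 50, cy2=0.0)],
        }
        (track,) = match_spots(gels)
        normalize_track(track)
        assert 53.0 not in track.rel_vehicle
        assert 37.0 in track.rel_vehicle


class TestFitMelting:
    def test_exact_recovery(self):
        f = logistic_melt(TEMPS, 50.0, 1.0, 0.05)
        fit = fit_melting(TEMPS, f)
        assert fit.converged
        assert fit.tm == pytest.approx(50.0, abs=0.1)
        assert fit.slope_k == pytest.approx(1.0, rel=0.05)
        assert fit.plateau_p == pytest.approx(0.05, abs=0.05 * 0.05 + 0.01)

    def test_flat_input_not_converged(self):
        fit = fit_melting(TEMPS, np.ones_like(TEMPS))
        assert not fit.converged
        assert np.isnan(fit.tm)

    def test_too_few_points(self):
        assert not fit_melting([37, 49, 64], [1.0, 0.5, 0.1]).converged

    def test_noisy_median_error(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = logistic_melt(TEMPS, 50.0, 1.0, 0.05) * (
                1.0 + rng.normal(0, 0.03, len(TEMPS))
            )
            fit = fit_melting(TEMPS, f)
            if fit.converged:
                errs.append(abs(fit.tm - 50.0))
        assert len(errs) >= 95
        assert np.median(errs) <= 0.5

    def test_converged_fits_monotone(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            f = logistic_melt(TEMPS, 48.0, 0.8, 0.1) * (
                1.0 + rng.normal(0, 0.03, len(TEMPS))
            )
            fit = fit_melting(TEMPS, f)
            if fit.converged:
                curve = logistic_melt(np.linspace(37, 64, 100), fit.tm, fit.slope_k, fit.plateau_p)
                assert np.all(np.diff(curve) <= 1e-12)


class TestScoreShift:
    def _tracked(self, delta_tm, seed=0, noise_cv=0.0, n_inert=0):
        pr = {"delta_tm": (delta_tm, delta_tm)} if delta_tm else None
        prot = generate_proteome(
            1 + n_inert, 1 if delta_tm else 0, 0, seed=seed, param_ranges=pr,
            min_separation_px=10.0,
        )
        design = make_design(seed=seed)
        design.noise.proportional_cv = noise_cv
        design.noise.additive_sd = 0.0 if noise_cv == 0.0 else design.noise.additive_sd
        tables = simulate_spot_tables(prot, design, position_jitter_px=0.0 if noise_cv == 0 else 0.3)
        tracks = match_spots(tables)
        for tr in tracks:
            normalize_track(tr)
        return prot, tracks

    def test_identity_null(self):
        prot, tracks = self._tracked(0.0, n_inert=5)
        shifts = score_run(tracks)
        for sh in shifts:
            assert sh.y_dev_max == pytest.approx(0.0, abs=1e-9)
            assert sh.y_dev_area == pytest.approx(0.0, abs=1e-9)
            if np.isfinite(sh.delta_tm):
                assert abs(sh.delta_tm) < 0.1

    def test_stabilized_target_scores(self):
        prot, tracks = self._tracked(8.0, seed=21, noise_cv=0.03, n_inert=40)
        shifts = score_run(tracks)
        # track ids follow baseline spot order = species order here
        i_tgt = [i for i, s in enumerate(prot) if s.delta_tm != 0][0]
        sh = next(s for s in shifts if s.track_id == tracks[i_tgt].track_id)
        assert np.isfinite(sh.delta_tm)
        assert sh.delta_tm == pytest.approx(8.0, abs=1.0)
        assert sh.direction == "up"
        assert sh.y_dev_max == max(x.y_dev_max for x in shifts)
        assert sh.z_score == max(x.z_score for x in shifts)

    def test_destabilized_target_scores(self):
        prot, tracks = self._tracked(-5.0, seed=22, noise_cv=0.03, n_inert=40)
        shifts = score_run(tracks)
        i_tgt = [i for i, s in enumerate(prot) if s.delta_tm != 0][0]
        sh = next(s for s in shifts if s.track_id == tracks[i_tgt].track_id)
        assert sh.delta_tm < 0
        assert sh.direction == "down"
        assert sh.y_dev_max == max(x.y_dev_max for x in shifts)

    def test_delta_tm_recovery_100_seeds(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fv = logistic_melt(TEMPS, 50.0, 1.0, 0.05) * (1 + rng.normal(0, 0.03, 8))
            fd = logistic_melt(TEMPS, 58.0, 1.0, 0.05) * (1 + rng.normal(0, 0.03, 8))
            rv, rd = fit_melting(TEMPS, fv), fit_melting(TEMPS, fd)
            if rv.converged and rd.converged:
                errs.append(abs((rd.tm - rv.tm) - 8.0))
        assert len(errs) >= 95
        assert np.median(errs) <= 1.0
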