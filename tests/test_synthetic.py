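"""Forward-model tests: proteome generation, melting law, rendering,
mass conservation, PTM split, dose-response simulation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsfitge.melting import four_pl, logistic_melt
from tsfitge.synthetic import (
    ExperimentDesign,
    NoiseModel,
    ProteinSpecies,
    channel_amounts,
    generate_proteome,
    ground_truth_positions,
    make_design,
    ptm_fraction,
    render_gel,
    simulate_dose_response,
    simulate_spot_tables,
    soluble_fraction,
)


def species(**kw):
    base = dict(
        species_id="p0", pI=5.0, mass_kda=50.0, abundance=1e4,
        tm_vehicle=50.0, slope_k=1.0, plateau_p=0.1,
    )
    base.update(kw)
    return ProteinSpecies(**base)


class TestGenerateProteome:
    def test_empty(self):
        assert generate_proteome(0, seed=1) == []

    def test_determinism(self):
        a = generate_proteome(50, 2, 3, seed=42)
        b = generate_proteome(50, 2, 3, seed=42)
        assert [dataclasses.asdict(x) for x in a] == [dataclasses.asdict(x) for x in b]

    def test_target_and_ptm_counts(self):
        prot = generate_proteome(200, 1, 0, seed=7)
        n_shift = sum(1 for s in prot if s.delta_tm != 0)
        assert n_shift == 1
        assert sum(1 for s in prot if s.delta_tm == 0) == 199
        prot = generate_proteome(100, 3, 5, seed=7)
        assert sum(1 for s in prot if s.is_target) == 3
        assert sum(1 for s in prot if s.is_ptm_substrate) == 5
        # targets and PTM substrates are disjoint
        assert not any(s.is_target and s.is_ptm_substrate for s in prot)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError, match="invalid design"):
            generate_proteome(4, 3, 2, seed=0)

    def test_min_separation(self):
        from tsfitge.synthetic import pi_mass_to_pixel

        prot = generate_proteome(100, seed=3, min_separation_px=8.0, image_shape=(384, 384))
        xy = np.array(
            [pi_mass_to_pixel(s.pI, s.mass_kda, (384, 384)) for s in prot]
        )
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 8.0**2 - 1e-9


class TestSolubleFraction:
    def test_midpoint(self):
        sp = species(plateau_p=0.0)
        assert soluble_fraction(sp, 50.0, "vehicle") == pytest.approx(0.5)
        sp = species(plateau_p=0.2)
        assert soluble_fraction(sp, 50.0, "vehicle") == pytest.approx(0.6)

    def test_asymptotes(self):
        sp = species(plateau_p=0.1)
        assert soluble_fraction(sp, 20.0, "vehicle") == pytest.approx(1.0, abs=1e-6)
        assert soluble_fraction(sp, 90.0, "vehicle") == pytest.approx(0.1, abs=1e-6)

    def test_closed_form_value(self):
        # p + (1-p)/(1+e^2) at T = Tm + 2, k = 1
        sp = species(plateau_p=0.1, slope_k=1.0, tm_vehicle=50.0)
        expected = 0.1 + 0.9 / (1.0 + math.exp(2.0))
        assert soluble_fraction(sp, 52.0, "vehicle") == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2072, abs=5e-4)

    def test_drug_shift_and_inert_identity(self):
        tgt = species(delta_tm=8.0)
        assert soluble_fraction(tgt, 54.0, "drug") > soluble_fraction(tgt, 54.0, "vehicle")
        inert = species(delta_tm=0.0)
        for t in (40.0, 50.0, 60.0):
            assert soluble_fraction(inert, t, "drug") == soluble_fraction(inert, t, "vehicle")

    @given(
        tm=st.floats(40, 65), k=st.floats(0.1, 4), p=st.floats(0, 0.29),
        dtm=st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_and_bounded(self, tm, k, p, dtm):
        sp = species(tm_vehicle=tm, slope_k=k, plateau_p=p, delta_tm=dtm)
        temps = np.linspace(30, 80, 26)
        for cond in ("vehicle", "drug"):
            vals = np.array([soluble_fraction(sp, t, cond) for t in temps])
            assert np.all(np.diff(vals) <= 1e-12)
            assert np.all(vals >= p - 1e-12) and np.all(vals <= 1 + 1e-12)


class TestRenderGel:
    def test_symmetry_no_drug_effect(self):
        # far below Tm, no noise: all three channel amounts equal abundance
        sp = species(tm_vehicle=60.0, slope_k=2.0, plateau_p=0.0)
        design = ExperimentDesign(
            temperatures=(37.0,), noise=NoiseModel().off(), image_shape=(128, 128)
        )
        gel = render_gel([sp], design, 0)
        assert np.allclose(gel.cy3, gel.cy5)
        assert np.allclose(gel.cy2, gel.cy3, rtol=1e-3)

    def test_conservation_against_analytic_integral(self):
        sp = species()
        design = ExperimentDesign(
            temperatures=(37.0, 53.0), gel_gain=(1.0, 1.7),
            noise=NoiseModel().off(), image_shape=(128, 128),
        )
        for idx in (0, 1):
            gel = render_gel([sp], design, idx)
            t = design.temperatures[idx]
            g = design.gel_gain[idx]
            for chan, cond in ((gel.cy3, "vehicle"), (gel.cy5, "drug")):
                expected = g * sp.abundance * soluble_fraction(sp, t, cond)
                assert chan.sum() == pytest.approx(expected, rel=0.01)
            assert gel.cy2.sum() == pytest.approx(g * sp.abundance, rel=0.01)

    def test_determinism(self):
        prot = generate_proteome(20, 1, 1, seed=9)
        design = make_design(seed=9, image_shape=(128, 128))
        a, b = render_gel(prot, design, 2), render_gel(prot, design, 2)
        assert np.array_equal(a.cy2, b.cy2)
        assert np.array_equal(a.cy3, b.cy3)
        assert np.array_equal(a.cy5, b.cy5)

    def test_ptm_satellite_and_zero_treatment(self):
        sub = species(ptm_fraction_max=0.6, ptm_tau_min=10.0, ptm_delta_pi=0.3)
        on = ExperimentDesign(
            temperatures=(37.0,), treatment_minutes=20.0,
            noise=NoiseModel().off(), image_shape=(128, 128),
        )
        off = dataclasses.replace(on, treatment_minutes=0.0)
        assert ptm_fraction(sub, 0.0) == 0.0
        rows_on = ground_truth_positions([sub], on, 0)
        rows_off = ground_truth_positions([sub], off, 0)
        assert rows_on[0]["cy5_satellite"] > 0
        assert rows_off[0]["cy5_satellite"] == 0.0
        # mass balance: parent + satellite == no-PTM Cy5 amount, exactly
        total_on = rows_on[0]["cy5_parent"] + rows_on[0]["cy5_satellite"]
        assert total_on == pytest.approx(rows_off[0]["cy5_parent"], rel=1e-12)
        # satellite is horizontally displaced, not vertically
        gel_on = render_gel([sub], on, 0)
        gel_off = render_gel([sub], off, 0)
        assert gel_on.cy5.sum() == pytest.approx(gel_off.cy5.sum(), rel=0.01)
        assert not np.allclose(gel_on.cy5, gel_off.cy5)

    def test_misregistration_shifts_cy5_only(self):
        sp = species()
        base = ExperimentDesign(
            temperatures=(37.0,), noise=NoiseModel().off(), image_shape=(128, 128)
        )
        shifted = dataclasses.replace(base, misregistration_dy=(2.0,))
        a, b = render_gel([sp], base, 0), render_gel([sp], shifted, 0)
        assert np.array_equal(a.cy3, b.cy3)
        assert np.allclose(np.roll(a.cy5, 2, axis=0), b.cy5, atol=1e-6 * a.cy5.max())

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            render_gel([species()], ExperimentDesign(temperatures=(37.0,)), 1)


class TestSpotTableRoute:
    def test_determinism_and_structure(self):
        prot = generate_proteome(30, 1, 2, seed=4)
        design = make_design(seed=4)
        a = simulate_spot_tables(prot, design)
        b = simulate_spot_tables(prot, design)
        assert list(a) == list(design.temperatures)
        for t in a:
            assert [dataclasses.asdict(x) for x in a[t]] == [
                dataclasses.asdict(x) for x in b[t]
            ]
        # PTM satellites appear as extra spots at baseline
        n_ptm = sum(1 for s in prot if s.is_ptm_substrate)
        assert len(a[design.baseline_temperature]) == 30 + n_ptm


class TestDoseResponse:
    def test_midpoint_and_asymptotes(self):
        tab = simulate_dose_response(10.0, 1.0, 1.0, 0.0, [1e-4, 10.0, 1e6], 1, 0.0, 0)
        r = tab.set_index("dose_uM")["response"]
        assert r[10.0] == pytest.approx(0.5)
        assert r[1e-4] == pytest.approx(0.0, abs=1e-4)
        assert r[1e6] == pytest.approx(1.0, abs=1e-4)

    def test_direct_evaluation(self):
        assert four_pl(30.0, 10.0, 1.0, 1.0, 0.0) == pytest.approx(0.75)

    def test_nonpositive_dose_error(self):
        with pytest.raises(ValueError):
            simulate_dose_response(10.0, 1.0, 1.0, 0.0, [1.0, 0.0], 1, 0.0, 0)

    def test_noise_seeded(self):
        a = simulate_dose_response(7.6, 1.0, 1.0, 0.0, [1, 10], 3, 0.05, 5)
        b = simulate_dose_response(7.6, 1.0, 1.0, 0.0, [1, 10], 3, 0.05, 5)
        assert np.array_equal(a["response"], b["response"])
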