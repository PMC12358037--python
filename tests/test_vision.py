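"""Colour-vision models: catches, adaptation, loci, contrasts, thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from floravision.grid import DEFAULT_GRID
from floravision.spectra import Spectrum
from floravision.synthdata import foliage_background
from floravision.vision import (
    Illuminant,
    achromatic_contrast,
    adapt_von_kries,
    chromatic_contrast,
    excite_hyperbolic,
    flag_discriminable,
    fly_locus,
    hexagon_locus,
    make_receptor,
    quantum_catch,
    receptor_from_table,
    spectrum_contrast,
    spectrum_locus,
    visual_pigment_template,
    ViewingContext,
)

WL = DEFAULT_GRID.wavelengths


def narrowband(centre, peak=60.0, base=3.0, width=10.0, label="nb"):
    refl = base + peak * np.exp(-((WL - centre) ** 2) / (2 * width**2))
    return Spectrum(DEFAULT_GRID, refl, label)


class TestReceptors:
    def test_peak_normalised_at_lambda_max(self):
        r = make_receptor(544.0, name="green")
        assert r.curve[DEFAULT_GRID.index_of(544)] == pytest.approx(1.0)
        assert r.lambda_max == 544.0

    @pytest.mark.parametrize("lmax", [344.0, 436.0, 460.0, 544.0])
    def test_long_wavelength_flank_strictly_decreasing(self, lmax):
        # oracle: template evaluated on a 10x finer grid above the peak
        fine = np.arange(lmax, min(lmax + 80.0, 700.0) + 0.05, 0.1)
        vals = visual_pigment_template(fine, lmax)
        assert np.all(np.diff(vals) < 0)
        r = make_receptor(lmax)
        above = r.curve[(WL > lmax) & (WL <= lmax + 80)]
        assert np.all(np.diff(above) < 0)

    def test_lambda_max_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            make_receptor(250.0)

    def test_tabulated_curve_gives_identical_catches(self, tmp_path):
        templ = make_receptor(436.0, name="blue")
        p = tmp_path / "curve.csv"
        pd.DataFrame({"wavelength_nm": WL, "blue": templ.curve}).to_csv(p, index=False)
        tab = receptor_from_table(p, "blue")
        s = narrowband(450)
        i = Illuminant.d65()
        assert quantum_catch(s, tab, i) == pytest.approx(
            quantum_catch(s, templ, i), rel=1e-9
        )


class TestQuantumCatch:
    def test_null_spectrum_catches_nothing(self, flat_spectrum):
        r = make_receptor(500.0)
        assert quantum_catch(flat_spectrum(0.0), r, Illuminant.d65()) == 0.0

    def test_homogeneity(self):
        r = make_receptor(500.0)
        i = Illuminant.d65()
        s1 = narrowband(520, peak=30)
        s2 = Spectrum(DEFAULT_GRID, 2 * s1.reflectance, "double")
        assert quantum_catch(s2, r, i) == pytest.approx(
            2 * quantum_catch(s1, r, i), rel=1e-12
        )

    def test_grid_mismatch_rejected(self, flat_spectrum):
        from floravision.grid import WavelengthGrid

        g2 = WavelengthGrid(300, 700, 2.0)
        r = make_receptor(500.0, grid=g2)
        with pytest.raises(ValueError, match="grid"):
            quantum_catch(flat_spectrum(10.0), r, Illuminant.d65())


class TestTransduction:
    def test_von_kries_background_maps_to_one(self):
        assert adapt_von_kries(3.7, 3.7) == 1.0
        assert adapt_von_kries(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            adapt_von_kries(1.0, 0.0)

    @pytest.mark.parametrize("q,expected", [(1.0, 0.5), (0.0, 0.0), (3.0, 0.75)])
    def test_hyperbolic_values(self, q, expected):
        assert excite_hyperbolic(q) == pytest.approx(expected)

    def test_hyperbolic_monotone_and_bounded(self):
        q = np.linspace(0, 50, 200)
        e = excite_hyperbolic(q)
        assert np.all(np.diff(e) > 0)
        assert np.all((e >= 0) & (e < 1))


class TestHexagon:
    def test_achromatic_centre(self):
        loc = hexagon_locus(0.5, 0.5, 0.5)
        assert (loc.x, loc.y) == (0.0, 0.0)
        assert loc.sector == "achromatic"
        assert chromatic_contrast(loc) == 0.0

    def test_blue_corner(self):
        loc = hexagon_locus(0.0, 1.0 - 1e-12, 0.0)
        assert loc.x == pytest.approx(0.0)
        assert loc.y == pytest.approx(1.0)
        assert chromatic_contrast(loc) == pytest.approx(1.0)
        assert loc.sector == "blue"

    def test_green_corner(self):
        loc = hexagon_locus(0.0, 0.0, 1.0 - 1e-12)
        assert loc.x == pytest.approx(math.sqrt(3) / 2, abs=1e-9)
        assert loc.y == pytest.approx(-0.5)
        assert chromatic_contrast(loc) == pytest.approx(1.0)
        assert loc.sector == "green"

    @given(
        st.floats(0, 0.999), st.floats(0, 0.999), st.floats(0, 0.999)
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_loci_stay_inside_unit_hexagon(self, e_uv, e_b, e_g):
        loc = hexagon_locus(e_uv, e_b, e_g)
        # point-in-regular-hexagon (circumradius 1, pointy-top orientation:
        # corners at (0, +/-1) and (+/-sqrt(3)/2, +/-1/2))
        assert abs(loc.x) <= math.sqrt(3) / 2 + 1e-9
        assert abs(loc.x) / math.sqrt(3) + abs(loc.y) <= 1 + 1e-9

    def test_345_chromatic_distance(self):
        loc = hexagon_locus(0.5, 0.5, 0.5)
        loc.x, loc.y = 0.06, 0.08
        assert chromatic_contrast(loc) == pytest.approx(0.10)

    @pytest.mark.parametrize("eg,expected", [(0.5, 0.0), (0.822, 0.322), (0.1, 0.4)])
    def test_achromatic_contrast_values(self, eg, expected):
        assert achromatic_contrast(eg) == pytest.approx(expected)


class TestFlySpace:
    def test_background_is_achromatic_centre(self):
        loc = fly_locus(1.0, 1.0, 1.0, 1.0)
        assert (loc.x, loc.y) == (0.0, 0.0)
        assert loc.sector == "achromatic"

    def test_direct_difference_of_unit_sum_signals(self):
        loc = fly_locus(0.3, 0.25, 0.1, 0.35)
        assert loc.x == pytest.approx(0.2)
        assert loc.y == pytest.approx(-0.1)

    def test_swapping_pale_receptors_negates_x_only(self):
        a = fly_locus(0.4, 0.3, 0.2, 0.6)
        b = fly_locus(0.2, 0.3, 0.4, 0.6)
        assert b.x == pytest.approx(-a.x)
        assert b.y == pytest.approx(a.y)

    @given(st.lists(st.floats(0.01, 10), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_loci_bounded_in_unit_square(self, q):
        loc = fly_locus(*q)
        assert -1 <= loc.x <= 1 and -1 <= loc.y <= 1


class TestThresholds:
    @pytest.mark.parametrize(
        "contrast,model,expected",
        [
            (0.107, "hexagon", False),
            (0.11, "hexagon", True),
            (0.293, "hexagon", True),
            (0.096, "fly_categorical", True),
            (0.0959, "fly_categorical", False),
        ],
    )
    def test_default_thresholds_boundary_inclusive(self, contrast, model, expected):
        assert flag_discriminable(contrast, model) is expected

    def test_threshold_override(self):
        assert flag_discriminable(0.05, "hexagon", threshold=0.04)


class TestViewingContexts:
    def test_background_self_contrast_is_zero(self, bee_ctx, fly_ctx):
        bg = foliage_background()
        for ctx in (bee_ctx, fly_ctx):
            res = spectrum_contrast(bg, ctx)
            assert res.chromatic < 1e-10
            if res.achromatic is not None:
                assert res.achromatic < 1e-10

    def test_illuminant_intensity_invariance(self, bee_ctx):
        s = narrowband(560)
        base = spectrum_locus(s, bee_ctx)
        for k in (0.1, 10.0):
            ill = Illuminant("scaled", bee_ctx.illuminant.irradiance * k)
            ctx = ViewingContext(
                bee_ctx.receptors, ill, bee_ctx.background, "hexagon"
            )
            loc = spectrum_locus(s, ctx)
            assert abs(loc.x - base.x) < 1e-12
            assert abs(loc.y - base.y) < 1e-12

    def test_wrong_receptor_count_rejected(self, bee_ctx):
        with pytest.raises(ValueError, match="receptors"):
            ViewingContext(
                bee_ctx.receptors[:2],
                bee_ctx.illuminant,
                bee_ctx.background,
                "hexagon",
            )

    def test_monochromatic_sweep_moves_continuously(self, bee_ctx):
        centres = np.arange(320, 690, 10)
        pts = [spectrum_locus(narrowband(c), bee_ctx) for c in centres]
        steps = [
            math.hypot(b.x - a.x, b.y - a.y) for a, b in zip(pts, pts[1:])
        ]
        assert max(steps) < 0.35  # no jumps: sensitivity ordering is sane

    def test_long_wavelength_stimulus_lands_in_fly_yellow(self, fly_ctx):
        loc = spectrum_locus(narrowband(580), fly_ctx)
        assert loc.sector == "yellow"

    def test_analyse_set_row_schema(self, bee_ctx, fly_ctx):
        from floravision.spectra import SpectrumSet
        from floravision.vision import analyse_set

        ss = SpectrumSet([narrowband(450, label="a"), narrowband(600, label="b")],
                         {"a": "blue_violet", "b": "green"})
        df = analyse_set(ss, [bee_ctx, fly_ctx])
        assert len(df) == 4
        assert set(df.model) == {"hexagon", "fly_categorical"}
        assert df.loc[df.model == "fly_categorical", "achromatic_EU"].isna().all()
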