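"""Spectrum I/O, smoothing, negative correction and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from floravision.grid import DEFAULT_GRID, WavelengthGrid
from floravision.spectra import (
    Spectrum,
    SpectrumSet,
    aggregate_spectra,
    fix_negative,
    read_spectra,
    smooth_spectrum,
    write_spectra,
)

WL = DEFAULT_GRID.wavelengths


class TestGrid:
    def test_default_grid_is_401_points(self):
        assert len(DEFAULT_GRID) == 401
        assert WL[0] == 300.0 and WL[-1] == 700.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(start_nm=700, stop_nm=300),
            dict(step_nm=0.0),
            dict(step_nm=-1.0),
            dict(start_nm=300, stop_nm=700, step_nm=3.0),
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WavelengthGrid(**kwargs)


class TestReadSpectra:
    def test_flat_long_file_roundtrip(self, tmp_path):
        p = tmp_path / "flat.csv"
        pd.DataFrame({"wavelength_nm": WL, "reflectance": 10.0}).to_csv(p, index=False)
        ss = read_spectra(p, dialect="long")
        assert len(ss) == 1
        np.testing.assert_allclose(ss.spectra[0].reflectance, 10.0)
        assert len(ss.spectra[0].reflectance) == 401

    def test_fine_sampling_resampled_through_existing_points(self, tmp_path):
        wl = 299.8 + 0.4 * np.arange(1003)  # 0.4 nm instrument grid
        refl = 20.0 + 10.0 * np.sin(wl / 40.0)
        p = tmp_path / "fine.csv"
        pd.DataFrame({"wavelength_nm": wl, "reflectance": refl}).to_csv(p, index=False)
        ss = read_spectra(p, dialect="long")
        # instrument samples landing on integer nm are shared grid points
        shared = np.isclose(wl, np.round(wl), atol=1e-6) & (wl >= 300) & (wl <= 700)
        idx = np.round(wl[shared]).astype(int) - 300
        np.testing.assert_allclose(
            ss.spectra[0].reflectance[idx], refl[shared], atol=1e-6
        )
        assert shared.sum() > 100

    def test_wide_file_preserves_sample_columns(self, tmp_path):
        p = tmp_path / "wide.tsv"
        pd.DataFrame(
            {"wavelength_nm": WL, "sp_a": 10.0, "sp_b": 20.0, "sp_c": 30.0}
        ).to_csv(p, sep="\t", index=False)
        ss = read_spectra(p, dialect="wide")
        assert ss.labels == ["sp_a", "sp_b", "sp_c"]
        np.testing.assert_allclose(ss["sp_b"].reflectance, 20.0)

    def test_fractional_scale_autodetected(self, tmp_path):
        p = tmp_path / "frac.csv"
        pd.DataFrame({"wavelength_nm": WL, "s": 0.25}).to_csv(p, index=False)
        ss = read_spectra(p)
        np.testing.assert_allclose(ss.spectra[0].reflectance, 25.0)

    def test_non_numeric_cell_names_row(self, tmp_path):
        df = pd.DataFrame(
            {"wavelength_nm": WL, "s": np.full(len(WL), "10.0", dtype=object)}
        )
        df.loc[5, "s"] = "oops"
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="oops.*row 5"):
            read_spectra(p)

    def test_narrow_coverage_refused(self, tmp_path):
        p = tmp_path / "narrow.csv"
        pd.DataFrame({"wavelength_nm": np.arange(350, 701), "s": 10.0}).to_csv(
            p, index=False
        )
        with pytest.raises(ValueError, match="coverage"):
            read_spectra(p)

    def test_write_then_read_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        ss = SpectrumSet(
            [Spectrum(DEFAULT_GRID, rng.uniform(5, 60, 401), f"s{i}") for i in range(3)]
        )
        p = tmp_path / "out.tsv"
        write_spectra(ss, p)
        back = read_spectra(p)
        for a, b in zip(ss, back):
            np.testing.assert_allclose(a.reflectance, b.reflectance, atol=1e-12)


class TestSmoothing:
    def test_constant_preserved(self, flat_spectrum):
        out = smooth_spectrum(flat_spectrum(25.0))
        np.testing.assert_allclose(out.reflectance, 25.0, atol=1e-9)

    def test_linear_ramp_preserved_in_interior(self):
        ramp = np.linspace(0, 100, 401)
        out = smooth_spectrum(Spectrum(DEFAULT_GRID, ramp, "ramp"))
        np.testing.assert_allclose(out.reflectance[5:-5], ramp[5:-5], atol=1e-6)

    def test_noise_reduction_matches_local_regression_oracle(self):
        rng = np.random.default_rng(42)
        clean = 30.0 + 15.0 * np.sin(WL / 50.0)
        noisy = clean + rng.normal(0, 2.0, len(WL))
        out = smooth_spectrum(Spectrum(DEFAULT_GRID, noisy, "sin"), span=0.20)
        resid_sd = np.std(out.reflectance - clean)
        assert resid_sd < np.std(noisy - clean)

        # independent moving-window weighted least-squares oracle
        k = int(0.20 * len(WL))
        oracle = np.empty(len(WL))
        for i in range(len(WL)):
            d = np.abs(WL - WL[i])
            cutoff = np.sort(d)[k - 1]
            w = np.clip(1 - (d / max(cutoff, 1e-12)) ** 3, 0, None) ** 3
            A = np.vstack([np.ones(len(WL)), WL - WL[i]]).T
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(A * sw[:, None], noisy * sw, rcond=None)
            oracle[i] = coef[0]
        # same smoother family: agree closely in the interior
        assert np.max(np.abs(out.reflectance[20:-20] - oracle[20:-20])) < 0.5

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 50, 401)
        s = Spectrum(DEFAULT_GRID, base, "a")
        shifted = Spectrum(DEFAULT_GRID, base + 7.5, "b")
        np.testing.assert_allclose(
            smooth_spectrum(shifted).reflectance,
            smooth_spectrum(s).reflectance + 7.5,
            atol=1e-8,
        )

    @pytest.mark.parametrize("span", [0.0, -0.5, 1.2])
    def test_invalid_span_rejected(self, flat_spectrum, span):
        with pytest.raises(ValueError):
            smooth_spectrum(flat_spectrum(10.0), span=span)


class TestFixNegative:
    def test_shift_by_absolute_minimum(self):
        refl = np.full(401, 5.0)
        refl[100] = -2.0  # 400 nm
        out = fix_negative(Spectrum(DEFAULT_GRID, refl, "neg"))
        assert out.reflectance[100] == 0.0
        np.testing.assert_allclose(np.delete(out.reflectance, 100), 7.0)

    def test_positive_spectrum_unchanged(self, flat_spectrum):
        s = flat_spectrum(10.0)
        assert fix_negative(s) is s

    def test_all_zero_idempotent(self, flat_spectrum):
        out = fix_negative(flat_spectrum(0.0))
        np.testing.assert_array_equal(out.reflectance, 0.0)

    @given(
        st.lists(st.floats(-50, 100, allow_nan=False), min_size=401, max_size=401),
    )
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_idempotent_and_order_preserving(self, values):
        s = Spectrum(DEFAULT_GRID, np.array(values), "h")
        once = fix_negative(s)
        assert np.min(once.reflectance) >= 0.0
        np.testing.assert_array_equal(
            fix_negative(once).reflectance, once.reflectance
        )
        # rank order preserved (shifting can merge near-ties in float maths,
        # so check non-strict monotonicity along the original ordering)
        order = np.argsort(s.reflectance, kind="stable")
        assert np.all(np.diff(once.reflectance[order]) >= 0)


class TestAggregation:
    def test_identical_replicates_have_zero_sd(self, flat_spectrum):
        ss = SpectrumSet([flat_spectrum(12.0, "sp"), flat_spectrum(12.0, "sp")])
        agg = aggregate_spectra(ss)
        assert len(agg) == 1
        s = agg.spectra[0]
        np.testing.assert_allclose(s.reflectance, 12.0)
        np.testing.assert_allclose(s.sd, 0.0)
        assert s.n_aggregated == 2

    def test_mean_and_sample_sd(self, flat_spectrum):
        ss = SpectrumSet([flat_spectrum(10.0, "sp"), flat_spectrum(30.0, "sp")])
        s = aggregate_spectra(ss).spectra[0]
        np.testing.assert_allclose(s.reflectance, 20.0)
        np.testing.assert_allclose(s.sd, np.sqrt(200.0), rtol=1e-12)  # 14.142...

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        stack = rng.uniform(0, 80, (10, 401))
        ss = SpectrumSet(
            [Spectrum(DEFAULT_GRID, row, "sp") for row in stack]
        )
        s = aggregate_spectra(ss).spectra[0]
        mean = np.array([np.mean(stack[:, j]) for j in range(401)])
        sd = np.array(
            [np.sqrt(np.sum((stack[:, j] - mean[j]) ** 2) / 9) for j in range(401)]
        )
        np.testing.assert_allclose(s.reflectance, mean, atol=1e-12)
        np.testing.assert_allclose(s.sd, sd, atol=1e-12)

    def test_reaggregation_is_identity(self, flat_spectrum):
        ss = SpectrumSet(
            [flat_spectrum(10.0, "sp"), flat_spectrum(30.0, "sp"), flat_spectrum(5.0, "b")]
        )
        once = aggregate_spectra(ss)
        twice = aggregate_spectra(once)
        assert once.labels == twice.labels
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.reflectance, b.reflectance)
            np.testing.assert_array_equal(a.sd if a.sd is not None else [], b.sd if b.sd is not None else [])
            assert a.n_aggregated == b.n_aggregated

    def test_mismatched_grids_rejected(self):
        g2 = WavelengthGrid(300, 700, 2.0)
        with pytest.raises(ValueError, match="grid"):
            SpectrumSet(
                [
                    Spectrum(DEFAULT_GRID, np.full(401, 10.0), "a"),
                    Spectrum(g2, np.full(201, 10.0), "b"),
                ]
            )

    def test_group_labels_carried_through(self, flat_spectrum):
        ss = SpectrumSet(
            [flat_spectrum(10.0, "x1"), flat_spectrum(14.0, "x2")],
            {"x1": "green", "x2": "green"},
        )
        agg = aggregate_spectra(ss, by={"x1": "x", "x2": "x"})
        assert agg.group_labels == {"x": "green"}
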