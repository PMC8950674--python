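import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiobeat import dose_response as dr
from cardiobeat.synthetic_data import SyntheticPlateSpec, generate_plate, true_bmc


class TestSerialDilution:
    def test_5fu_range_displays_as_printed(self):
        series = dr.serial_dilution(3.0, 3.0, 6)
        assert series.display[0] == "3"
        assert series.display[-1] == "0.012"

    def test_peng_range_displays_as_printed(self):
        series = dr.serial_dilution(300.0, 3.0, 6)
        assert series.display[-1] == "1.2"

    def test_single_point_series(self):
        assert dr.serial_dilution(10.0, 2.0, 1).concentrations == (10.0,)

    def test_full_precision_kept(self):
        series = dr.serial_dilution(3.0, 3.0, 6)
        assert series.concentrations[-1] == 3.0 / 3**5  # exact, not rounded

    @settings(max_examples=50, derandomize=True)
    @given(
        top=st.floats(1e-3, 1e4),
        fold=st.floats(1.1, 10),
        n=st.integers(1, 10),
    )
    def test_strictly_decreasing_geometric(self, top, fold, n):
        conc = dr.serial_dilution(top, fold, n).concentrations
        assert all(a > b for a, b in zip(conc, conc[1:]))
        for a, b in zip(conc, conc[1:]):
            assert a / b == pytest.approx(fold)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            dr.serial_dilution(-1.0)
        with pytest.raises(ValueError):
            dr.serial_dilution(3.0, fold=1.0)


class TestPlateLayout:
    def test_24_treatment_wells_in_quadruplicate(self):
        layout = dr.build_plate_layout()
        counts = layout.table["role"].value_counts()
        assert sum(counts[f"C{i}"] for i in range(1, 7)) == 24
        assert all(counts[f"C{i}"] == 4 for i in range(1, 7))
        assert len(layout.table) == 48

    def test_sc_and_c1_have_exactly_one_edge_replicate(self):
        layout = dr.build_plate_layout()
        for role in ("SC", "C1"):
            wells = layout.table[layout.table["role"] == role]
            n_edge = sum(layout.is_edge(r.row, r.col) for r in wells.itertuples())
            assert n_edge == 1, role

    def test_water_border_and_controls_present(self):
        counts = dr.build_plate_layout().table["role"].value_counts()
        assert counts["WATER"] == 16
        assert counts["LC"] >= 1 and counts["BC"] >= 1

    def test_csv_round_trip(self, tmp_path):
        layout = dr.build_plate_layout()
        layout.to_csv(tmp_path / "layout.csv")
        back = dr.PlateLayout.from_csv(tmp_path / "layout.csv")
        pd.testing.assert_frame_equal(layout.table, back.table)


class TestNormalizeViability:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["role", "raw_value"])

    def test_sc_maps_to_100_bc_to_0(self):
        df = self._df([("SC", 1000), ("SC", 1000), ("BC", 100), ("C1", 1000), ("C2", 100)])
        out = dr.normalize_viability(df)
        assert out.loc[out["role"] == "C1", "value_pct"].iloc[0] == pytest.approx(100.0)
        assert out.loc[out["role"] == "C2", "value_pct"].iloc[0] == pytest.approx(0.0)

    def test_midpoint_is_50(self):
        df = self._df([("SC", 1000), ("BC", 100), ("C3", 550)])
        out = dr.normalize_viability(df)
        assert out.loc[out["role"] == "C3", "value_pct"].iloc[0] == pytest.approx(50.0)

    def test_sc_wells_mean_exactly_100(self, rng):
        raws = rng.normal(900, 80, 4)
        df = self._df([("SC", v) for v in raws] + [("BC", 100.0)])
        out = dr.normalize_viability(df)
        assert out.loc[out["role"] == "SC", "value_pct"].mean() == pytest.approx(100.0)

    def test_inverted_plate_rejected(self):
        with pytest.raises(dr.InvalidPlateError):
            dr.normalize_viability(self._df([("SC", 50), ("BC", 100)]))

    def test_missing_controls_rejected(self):
        with pytest.raises(dr.InvalidPlateError):
            dr.normalize_viability(self._df([("C1", 500)]))


class TestCovAndBMR:
    def test_constant_controls_have_zero_cov(self):
        assert dr.compute_cov([100, 100, 100]) == 0.0

    def test_two_point_example(self):
        assert dr.compute_cov([90, 110]) == pytest.approx(14.1421356, abs=1e-6)

    def test_scale_invariant(self, rng):
        vals = rng.normal(100, 10, 8)
        assert dr.compute_cov(vals) == pytest.approx(dr.compute_cov(2 * vals))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            dr.compute_cov([100])

    @pytest.mark.parametrize("cov, bmr", [(16, 20), (30, 30), (7, 20), (0, 20), (35, 40), (48, 50), (80, 50)])
    def test_cov_to_bmr_rule(self, cov, bmr):
        assert dr.select_bmr(cov) == bmr


def _noiseless_plate_arrays(spec=None):
    spec = spec or SyntheticPlateSpec(noise_cov=0.0, seed=0)
    df = generate_plate(spec).dropna(subset=["raw_value"])
    norm = dr.normalize_viability(df)
    sub = norm[norm["role"].isin([f"C{i}" for i in range(1, 7)] + ["SC"])]
    conc = np.where(sub["role"].eq("SC"), 0.0, sub["concentration_uM"].astype(float))
    return conc, sub["value_pct"].to_numpy(float), spec


class TestFitAndSelect:
    def test_pool_has_13_families(self):
        assert len(dr.MODEL_POOL) == 13
        assert len({m.name for m in dr.MODEL_POOL}) == 13

    def test_noiseless_4pl_recovered_with_tiny_residual(self):
        conc, y, _ = _noiseless_plate_arrays()
        fits = dr.fit_candidates(conc, y)
        ll = {f.family: f for f in fits}
        assert ll["log_logistic_4"].rss < 1e-6

    def test_flat_data_not_reached(self):
        conc = np.repeat([0.0, 0.1, 0.3, 1.0, 3.0], 4)
        y = np.full(conc.size, 100.0)
        fits = dr.fit_candidates(conc, y)
        best = dr.select_model(fits)
        res = dr.compute_bmc(best, 20, conc, y, n_boot=10, seed=0)
        assert res.not_reached
        assert res.bmc is None

    def test_hormetic_data_selects_nonmonotone_family(self):
        conc = np.repeat([0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0], 4)
        fam = next(m for m in dr.MODEL_POOL if m.name == "cedergreen_hormesis")
        y = fam.fn(conc, 3.0, 0.0, 100.0, 2.0, 200.0)  # rises well above 100, then falls
        fits = dr.fit_candidates(conc, y)
        best = dr.select_model(fits)
        assert best.family in ("cedergreen_hormesis", "lognormal_bell")

    def test_parsimony_breaks_equal_residual_tie(self):
        # equal-residual nested fits: the 3-parameter family must win
        mk = lambda fam, k: dr.FittedCurve(
            family=fam, params=np.ones(k), rss=1e-14, wrss=1e-14,
            n_obs=28, n_params=k, aicc=dr._aicc(1e-14, 28, k), _fn=lambda c: c,
        )
        best = dr.select_model([mk("log_logistic_4", 4), mk("log_logistic_3", 3)])
        assert best.family == "log_logistic_3"

    def test_aicc_bookkeeping_recomputable(self):
        conc, y, _ = _noiseless_plate_arrays(SyntheticPlateSpec(noise_cov=16.0, seed=2))
        for f in dr.fit_candidates(conc, y):
            n, k = f.n_obs, f.n_params + 1
            expect = (
                n * np.log(max(f.rss, 1e-12) / n)
                + 2 * k
                + 2 * k * (k + 1) / (n - k - 1)
            )
            assert f.aicc == pytest.approx(expect, abs=1e-9)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            dr.fit_candidates(np.array([0, 1, 1, 2.0]), np.array([100, 50, 55, 20.0]))


class TestComputeBMC:
    def test_bmr50_equals_ec50(self):
        conc, y, spec = _noiseless_plate_arrays()
        fits = dr.fit_candidates(conc, y)
        best = dr.select_model(fits)
        res = dr.compute_bmc(best, 50, conc, y, n_boot=10, seed=0)
        assert res.bmc == pytest.approx(spec.ec50, rel=1e-4)

    def test_noiseless_bmc20_matches_analytic_inverse(self):
        conc, y, spec = _noiseless_plate_arrays()
        fits = dr.fit_candidates(conc, y)
        best = dr.select_model(fits)
        res = dr.compute_bmc(best, 20, conc, y, n_boot=10, seed=0)
        assert res.bmc == pytest.approx(true_bmc(spec, 20), abs=1e-6)

    def test_bmc_ordering_on_monotone_curve(self):
        conc, y, _ = _noiseless_plate_arrays()
        fits = dr.fit_candidates(conc, y)
        best = dr.select_model(fits)
        bmcs = [dr.compute_bmc(best, b, conc, y, n_boot=5, seed=0).bmc for b in (20, 30, 50)]
        assert bmcs[0] <= bmcs[1] <= bmcs[2]

    def test_interval_brackets_estimate_and_is_reproducible(self):
        df = generate_plate(SyntheticPlateSpec(seed=11)).dropna(subset=["raw_value"])
        norm = dr.normalize_viability(df)
        res_a, _ = dr.analyze_endpoint(norm, bmr=20, n_boot=100, seed=4)
        res_b, _ = dr.analyze_endpoint(norm, bmr=20, n_boot=100, seed=4)
        assert res_a.bmcl <= res_a.bmc <= res_a.bmcu
        assert (res_a.bmcl, res_a.bmc, res_a.bmcu) == (res_b.bmcl, res_b.bmc, res_b.bmcu)

    def test_bmr_selected_from_control_cov(self):
        df = generate_plate(SyntheticPlateSpec(noise_cov=16.0, seed=21)).dropna(subset=["raw_value"])
        norm = dr.normalize_viability(df)
        res, _ = dr.analyze_endpoint(norm, n_boot=20, seed=0)
        assert res.bmr == dr.select_bmr(res.cov_controls)


def _bmc(l, u, endpoint="x", bmr=20):
    return dr.BMCResult(
        endpoint=endpoint, bmr=bmr, bmc=(l + u) / 2, bmcl=l, bmcu=u, model_family="log_logistic_4"
    )


class TestClassification:
    def test_disjoint_below_viability_is_specific(self):
        cls = dr.classify_endpoint(_bmc(0.5, 1.0), _bmc(0.1, 0.2))
        assert cls.label == "specific"
        assert cls.overlap_pct == 0.0
        assert cls.direction == "below"

    def test_disjoint_above_viability_is_unspecific(self):
        # beating-area CI entirely above the viability CI: the effect appears
        # only beyond cytotoxic concentrations, hence not a specific hit
        cls = dr.classify_endpoint(_bmc(0.37, 0.94), _bmc(1.02, 2.11))
        assert cls.label == "unspecific"
        assert cls.overlap_pct == 0.0
        assert cls.direction == "above"

    def test_four_percent_overlap_is_borderline(self):
        cls = dr.classify_endpoint(_bmc(0.37, 0.94), _bmc(0.90, 1.90))
        assert cls.overlap_pct == pytest.approx(4.0)
        assert cls.label == "borderline"

    def test_large_overlap_is_unspecific(self):
        cls = dr.classify_endpoint(_bmc(0.3, 1.0), _bmc(0.5, 1.2))
        assert cls.overlap_pct >= 10.0
        assert cls.label == "unspecific"

    def test_not_reached_propagates(self):
        nr = dr.BMCResult("x", 20, None, None, None, "none", not_reached=True)
        assert dr.classify_endpoint(_bmc(0.3, 1.0), nr).label == "not_reached"
        assert dr.classify_endpoint(nr, _bmc(0.3, 1.0)).label == "not_reached"

    def test_degenerate_width_zero_interval(self):
        inside = dr.classify_endpoint(_bmc(0.3, 1.0), _bmc(0.5, 0.5))
        outside = dr.classify_endpoint(_bmc(0.3, 1.0), _bmc(2.0, 2.0))
        assert inside.overlap_pct == 100.0 and inside.label == "unspecific"
        assert outside.overlap_pct == 0.0 and outside.label == "unspecific"

    @settings(max_examples=200, derandomize=True)
    @given(
        vals=st.tuples(*[st.floats(0.001, 100, allow_nan=False)] * 4),
    )
    def test_exactly_one_label_for_any_geometry(self, vals):
        lv, uv = sorted(vals[:2])
        le, ue = sorted(vals[2:])
        cls = dr.classify_endpoint(_bmc(lv, max(uv, lv)), _bmc(le, max(ue, le)))
        assert cls.label in ("specific", "unspecific", "borderline")
        again = dr.classify_endpoint(_bmc(lv, max(uv, lv)), _bmc(le, max(ue, le)))
        assert cls.label == again.label
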