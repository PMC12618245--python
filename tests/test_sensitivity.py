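import numpy as np
import pytest
from scipy import integrate

from ch4scale import (
    FluxTable,
    RegionalFlux,
    ResolutionSeries,
    SiteSuiteSpec,
    SyntheticConfig,
    auc_log_trapezoid,
    build_resolution_series,
    cross_site_summary,
    detect_sign_transition,
    deviation_curve,
    generate_site_suite,
    make_flux_table,
    rank_sites,
    regional_flux,
    run_experiment,
)
from ch4scale.sensitivity import DeviationCurve

from conftest import make_grid


def _rf(value, resolution_m, cls="fen"):
    return RegionalFlux(
        value=value,
        se=0.0,
        per_class_contribution={cls: (1.0, value)},
        resolution_m=resolution_m,
    )


class TestDeviationCurve:
    def test_constant_fluxes_give_zero_curve(self):
        fluxes = [_rf(3.0, r) for r in (2.5, 5, 10)]
        assert deviation_curve(fluxes).deviation_pct == [0.0, 0.0, 0.0]

    def test_sign_flip_counts_in_magnitude(self):
        fluxes = [_rf(10.0, 2.5), _rf(-2.0, 5.0)]
        assert deviation_curve(fluxes).deviation_pct[1] == pytest.approx(120.0)

    def test_printed_site_endpoints(self):
        # reference 21, coarsest 50 -> |21-50|/21 = 138.1%
        fluxes = [_rf(21.0, 2.5), _rf(50.0, 5000.0)]
        assert deviation_curve(fluxes).deviation_pct[1] == pytest.approx(138.1, abs=0.05)

    def test_negative_reference_stays_nonnegative(self):
        fluxes = [_rf(-2.0, 2.5), _rf(1.0, 5.0)]
        assert deviation_curve(fluxes).deviation_pct[1] == pytest.approx(150.0)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            deviation_curve([_rf(0.0, 2.5), _rf(1.0, 5.0)])

    def test_scaling_all_fluxes_leaves_curve_unchanged(self):
        rng = np.random.default_rng(1)
        g = make_grid(
            rng.integers(1, 4, (40, 40)),
            pixel_size_m=2.5,
            names={1: "fen", 2: "bog", 3: "upland"},
        )
        series = build_resolution_series(g, [5, 10, 25])
        base = {"fen": 4.0, "bog": 2.0, "upland": -0.4}
        for scale in (1.0, 3.5, -2.0):
            table = FluxTable(
                mean_flux={k: v * scale for k, v in base.items()},
                se_flux={k: 0.0 for k in base},
            )
            fluxes = [regional_flux(grid, table) for _, grid in series]
            curve = deviation_curve(fluxes)
            if scale == 1.0:
                reference_curve = curve.deviation_pct
            else:
                assert curve.deviation_pct == pytest.approx(reference_curve)


class TestAUC:
    def test_zero_curve_integrates_to_zero(self):
        assert auc_log_trapezoid(([2.5, 5, 10], [0, 0, 0])) == 0.0

    def test_single_segment_closed_form(self):
        assert auc_log_trapezoid(([2.5, 5.0], [0.0, 100.0])) == pytest.approx(
            50 * np.log(2)
        )

    def test_matches_quadrature_of_linear_interpolant(self):
        r = np.array([2.5, 10.0, 40.0])
        d = np.array([0.0, 30.0, 90.0])
        x = np.log(r)
        expected = sum(
            integrate.quad(lambda t: np.interp(t, x, d), x[i], x[i + 1])[0]
            for i in range(len(x) - 1)
        )
        assert auc_log_trapezoid((r, d)) == pytest.approx(expected, abs=1e-9)

    def test_additive_over_contiguous_segments(self):
        r = [2.5, 5, 25, 100, 1000]
        d = [0.0, 12.0, 31.0, 80.0, 140.0]
        total = auc_log_trapezoid((r, d))
        left = auc_log_trapezoid((r[:3], d[:3]))
        right = auc_log_trapezoid((r[2:], d[2:]))
        assert total == pytest.approx(left + right, abs=1e-12)

    def test_single_point_errors(self):
        with pytest.raises(ValueError, match="two"):
            auc_log_trapezoid(([2.5], [0.0]))

    def test_unsorted_resolutions_error(self):
        with pytest.raises(ValueError, match="increasing"):
            auc_log_trapezoid(([10, 5], [0, 1]))


class TestRanks:
    def test_single_site_gets_rank_one(self):
        assert rank_sites({"only": 4.2}) == {"only": 1}

    def test_descending_auc_order(self):
        ranks = rank_sites({"a": 5.0, "b": 2.0, "c": 9.0})
        assert ranks == {"c": 1, "a": 2, "b": 3}

    def test_ties_resolved_by_label(self):
        ranks = rank_sites({"z": 1.0, "a": 1.0})
        assert ranks == {"a": 1, "z": 2}

    def test_ranks_form_permutation(self):
        rng = np.random.default_rng(0)
        aucs = {f"s{i}": float(rng.random()) for i in range(7)}
        assert sorted(rank_sites(aucs).values()) == list(range(1, 8))


class TestSignTransition:
    def test_all_positive_is_none(self):
        assert detect_sign_transition([_rf(v, r) for v, r in [(2, 2.5), (1, 5)]]) is None

    def test_first_flip_reported(self):
        fluxes = [_rf(2, 2.5), _rf(1, 500), _rf(-0.5, 1000)]
        assert detect_sign_transition(fluxes) == 1000

    def test_sink_throughout_is_none(self):
        fluxes = [_rf(-1, 2.5), _rf(-2, 500), _rf(-0.1, 1000)]
        assert detect_sign_transition(fluxes) is None

    def test_exact_zero_is_not_a_flip(self):
        fluxes = [_rf(2, 2.5), _rf(0.0, 500)]
        assert detect_sign_transition(fluxes) is None


class TestCrossSiteSummary:
    def _series(self, grid):
        return ResolutionSeries(resolutions_m=[grid.pixel_size_m], grids=[grid])

    def test_two_site_mean_and_se(self):
        curves = {
            "a": DeviationCurve([2.5, 5.0], [0.0, 10.0], _rf(1.0, 2.5)),
            "b": DeviationCurve([2.5, 5.0], [0.0, 30.0], _rf(1.0, 2.5)),
        }
        g = make_grid([[1]], pixel_size_m=2.5, names={1: "fen"})
        table = FluxTable(mean_flux={"fen": 1.0}, se_flux={"fen": 0.0})
        out = cross_site_summary(
            curves, {k: self._series(g) for k in curves}, {k: table for k in curves}
        )
        row = out.per_resolution.set_index("resolution_m").loc[5.0]
        assert row["mean_deviation_pct"] == pytest.approx(20.0)
        assert row["se_deviation_pct"] == pytest.approx(10.0)  # sd 14.142 / sqrt(2)
        assert row["n_sites"] == 2

    def test_single_site_reports_zero_se_and_flag(self):
        curves = {"a": DeviationCurve([2.5, 5.0], [0.0, 10.0], _rf(1.0, 2.5))}
        g = make_grid([[1]], pixel_size_m=2.5, names={1: "fen"})
        table = FluxTable(mean_flux={"fen": 1.0}, se_flux={"fen": 0.0})
        out = cross_site_summary(curves, {"a": self._series(g)}, {"a": table})
        assert out.single_site
        assert (out.per_resolution["se_deviation_pct"] == 0).all()

    def test_symmetric_bog_fen_split_is_half_half(self):
        values = np.full((10, 10), 3)
        values[:2, :] = 1  # 20 bog px
        values[2:4, :] = 2  # 20 fen px
        g = make_grid(values, pixel_size_m=2.5, names={1: "bog", 2: "fen", 3: "upland"})
        table = FluxTable(
            mean_flux={"bog": 5.0, "fen": 5.0, "upland": -0.5},
            se_flux={"bog": 0.0, "fen": 0.0, "upland": 0.0},
        )
        flux = regional_flux(g, table)
        curves = {"a": deviation_curve([flux])}
        out = cross_site_summary(curves, {"a": self._series(g)}, {"a": table})
        row = out.per_resolution.iloc[0]
        assert row["bog_proportion"] == pytest.approx(0.5)
        assert row["fen_proportion"] == pytest.approx(0.5)
        assert row["bog_proportion"] + row["fen_proportion"] == pytest.approx(1.0)


class TestRunExperiment:
    @pytest.fixture
    def small_suite(self):
        spec = SiteSuiteSpec(
            n_sites=4,
            wetland_fraction_range=(0.1, 0.45),
            fragmentation_gradient=[2, 8],
            base_config=SyntheticConfig(
                grid_size=96, class_fractions={"upland": 1.0}, seed=0
            ),
        )
        grids = {f"site{i}": g for i, g in enumerate(generate_site_suite(spec))}
        return grids, make_flux_table(0)

    def test_report_has_permutation_ranks(self, small_suite):
        grids, table = small_suite
        report = run_experiment(grids, table, ladder_m=[5, 10, 25, 50, 100])
        ranks = sorted(r.score.rank for r in report.sites.values())
        assert ranks == [1, 2, 3, 4]
        for res in report.sites.values():
            assert res.curve.deviation_pct[0] == 0.0

    def test_homogeneous_site_has_flat_curve_and_no_transition(self):
        g = make_grid(np.ones((40, 40), dtype=int), pixel_size_m=2.5, names={1: "fen"})
        table = FluxTable(mean_flux={"fen": 4.0}, se_flux={"fen": 1.0})
        report = run_experiment(
            {"flat": g}, table, ladder_m=[5, 10, 25, 50], wetland_classes=("fen",)
        )
        res = report.sites["flat"]
        assert res.curve.deviation_pct == [0.0] * 5
        assert res.transition_m is None

    def test_rerun_writes_identical_tables(self, small_suite, tmp_path):
        grids, table = small_suite
        outs = []
        for name in ("one", "two"):
            outdir = tmp_path / name
            run_experiment(grids, table, ladder_m=[5, 10, 25, 50], output_dir=outdir)
            outs.append(
                {p.name: p.read_bytes() for p in sorted(outdir.iterdir())}
            )
        assert outs[0] == outs[1]

    def test_tables_written(self, small_suite, tmp_path):
        grids, table = small_suite
        run_experiment(grids, table, ladder_m=[5, 10], output_dir=tmp_path / "out")
        names = {p.name for p in (tmp_path / "out").iterdir()}
        assert names == {
            "deviation_curves.csv",
            "sensitivity_ranks.csv",
            "cross_site_summary.csv",
            "transitions.csv",
        }
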