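"""Dose-response fitting: exact-model identifiability, EC50 identities,
dose-scale equivariance, extraction of cut-time values and table exports."""

import numpy as np
import pandas as pd
import pytest

from platedrc import (
    CutTimeError,
    DRCRecord,
    FitError,
    LogLogistic4,
    PlateMap,
    calculate_drc_data,
    calculate_ec50,
    export_drc_table,
    export_ec50_table,
    fit_dose_response,
    fit_growth_curves_grouped,
    fit_growth_curves_individual,
    ll4,
    make_drc_set,
)

from conftest import compound_annotation, control_annotation, make_platedata

DOSES = 10.0 ** np.linspace(-3, 1, 8)


def random_params(rng):
    b = rng.uniform(0.5, 4.0)
    c = rng.uniform(0.0, 30.0)
    d = rng.uniform(60.0, 110.0)
    e = 10.0 ** rng.uniform(-2.5, 0.5)
    return b, c, d, e


class TestLogLogistic4:
    def test_half_effect_at_e(self):
        b, c, d, e = 2.0, 10.0, 90.0, 0.3
        assert ll4(e, b, c, d, e) == pytest.approx((c + d) / 2, abs=1e-12)

    def test_exact_recovery_canonical(self):
        y = ll4(DOSES, 1.0, 0.0, 100.0, 1.0)
        res = LogLogistic4(DOSES, y, "x").fit()
        assert res.converged
        for got, want in zip((res.b, res.c, res.d, res.e), (1.0, 0.0, 100.0, 1.0)):
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_recovery_random(self, seed):
        rng = np.random.default_rng(400 + seed)
        b, c, d, e = random_params(rng)
        res = LogLogistic4(DOSES, ll4(DOSES, b, c, d, e)).fit()
        assert res.converged
        np.testing.assert_allclose(
            [res.b, res.c, res.d, res.e], [b, c, d, e], rtol=1e-6, atol=1e-8
        )

    @pytest.mark.parametrize("k", [0.1, 10.0, 1000.0])
    def test_dose_scale_equivariance(self, k):
        """Scaling doses by k scales e (and EC50) by k, leaves b, c, d."""
        b, c, d, e = 1.7, 5.0, 95.0, 0.2
        y = ll4(DOSES, b, c, d, e)
        base = LogLogistic4(DOSES, y).fit()
        scaled = LogLogistic4(DOSES * k, y).fit()
        assert scaled.e == pytest.approx(base.e * k, rel=1e-6)
        np.testing.assert_allclose(
            [scaled.b, scaled.c, scaled.d], [base.b, base.c, base.d], rtol=1e-6
        )

    def test_replicate_permutation_invariance(self):
        rng = np.random.default_rng(3)
        dose = np.repeat(DOSES, 3)
        y = ll4(dose, 1.2, 10, 90, 0.5) + rng.normal(0, 2, dose.size)
        perm = rng.permutation(dose.size)
        a = LogLogistic4(dose, y).fit()
        b = LogLogistic4(dose[perm], y[perm]).fit()
        np.testing.assert_allclose([a.b, a.c, a.d, a.e], [b.b, b.c, b.d, b.e], rtol=1e-6)

    def test_constant_response_flagged_not_crashed(self):
        res = LogLogistic4(DOSES, np.full(8, 50.0)).fit()
        assert res.converged is False
        with pytest.raises(FitError):
            calculate_ec50(res)

    def test_too_few_concentrations(self):
        with pytest.raises(FitError, match="4 distinct"):
            LogLogistic4([1, 2, 3], [5, 6, 7])

    def test_zero_dose_rejected(self):
        with pytest.raises(FitError, match="positive"):
            LogLogistic4([0, 1, 2, 3], [1, 2, 3, 4])

    def test_from_dataframe(self):
        df = pd.DataFrame({"conc": DOSES, "value": ll4(DOSES, 1, 0, 100, 1)})
        res = LogLogistic4.from_dataframe(df, compound="z").fit()
        assert res.compound == "z" and res.converged

    def test_ec50_is_e_exact_model(self):
        y = ll4(DOSES, 2.0, 10.0, 90.0, 3.0)
        res = LogLogistic4(DOSES, y).fit()
        assert calculate_ec50(res) == pytest.approx(3.0, rel=1e-6)
        assert res.predict(res.ec50) == pytest.approx((res.c + res.d) / 2, abs=1e-9)

    def test_summary_mentions_parameters(self):
        res = LogLogistic4(DOSES, ll4(DOSES, 1, 0, 100, 1), "CmpdZ").fit()
        text = res.summary()
        assert "CmpdZ" in text and "EC50" in text and "converged" in text

    def test_standard_errors_on_noisy_fit(self):
        rng = np.random.default_rng(5)
        dose = np.repeat(DOSES, 3)
        y = ll4(dose, 1.0, 5.0, 95.0, 0.3) + rng.normal(0, 2, dose.size)
        se = LogLogistic4(dose, y).fit().bse
        assert all(np.isfinite(v) and v > 0 for v in se.values())


def linear_well_set(rates: dict[str, float], cut_time=10.0):
    """Wells growing linearly y = rate*t; compounds at log-spaced doses."""
    times = np.arange(0.0, 25.0, 2.0)
    wells, annots = {}, []
    for i, (label, rate) in enumerate(rates.items()):
        wells[label] = (lambda r: (lambda t: r * t))(rate)
    return wells, times


class TestCalculateDRCData:
    def build_set(self, n_compounds=2, n_conc=5, n_reps=3, noiseless=True):
        times = np.arange(0.0, 25.0, 2.0)
        annots = [control_annotation("A1"), control_annotation("A2")]
        wells = {"A1": lambda t: 2.0 * t, "A2": lambda t: 2.0 * t}
        row_letters = "BCDEFGH"
        for ci in range(n_compounds):
            for k in range(n_conc):
                conc = 10.0 ** (k - 2)
                for rep in range(n_reps):
                    label = f"{row_letters[ci * n_reps + rep]}{k + 1}"
                    annots.append(compound_annotation(label, f"cmp{ci}", conc))
                    slope = 2.0 / (1.0 + conc * (ci + 1))
                    wells[label] = (lambda s: (lambda t: s * t))(slope)
        pm = PlateMap("p", annots)
        return make_drc_set(pm, make_platedata(wells, times))

    def test_linear_wells_extracted_exactly(self):
        s = self.build_set()
        fit_growth_curves_individual(s)
        s.set_cut_time(10.0)
        calculate_drc_data(s)
        ctrl = [r for r in s.drc_records if r.concentration == 0.0][0]
        np.testing.assert_allclose(ctrl.values, 20.0, atol=1e-6)

    def test_record_shapes(self):
        s = self.build_set(n_compounds=2, n_conc=5, n_reps=3)
        fit_growth_curves_individual(s)
        s.set_cut_time(10.0)
        calculate_drc_data(s)
        cmp_records = [r for r in s.drc_records if r.concentration > 0]
        assert len(cmp_records) == 10
        assert all(len(r.values) == 3 for r in cmp_records)
        assert all(
            r.mean_value == pytest.approx(np.mean(r.values)) for r in cmp_records
        )

    def test_mean_decreasing_with_dose_noiseless(self):
        s = self.build_set()
        fit_growth_curves_individual(s)
        s.set_cut_time(10.0)
        calculate_drc_data(s)
        for name in ("cmp0", "cmp1"):
            recs = sorted(
                (r for r in s.drc_records if r.compound_name == name),
                key=lambda r: r.concentration,
            )
            means = [r.mean_value for r in recs]
            assert all(a > b for a, b in zip(means, means[1:]))

    def test_cut_time_unset_rejected(self):
        s = self.build_set()
        fit_growth_curves_individual(s)
        with pytest.raises(CutTimeError, match="unset"):
            calculate_drc_data(s)

    def test_cut_time_outside_domain_names_well(self):
        s = self.build_set()
        fit_growth_curves_individual(s)
        s.set_cut_time(100.0)
        with pytest.raises(CutTimeError, match="A1|B1"):
            calculate_drc_data(s)


class TestFitAndExport:
    def fitted_set(self):
        s = TestCalculateDRCData().build_set(n_compounds=2, n_conc=5, n_reps=2)
        fit_growth_curves_individual(s)
        s.set_cut_time(10.0)
        calculate_drc_data(s)
        fit_dose_response(s)
        return s

    def test_fit_requires_four_concentrations(self):
        s = TestCalculateDRCData().build_set(n_conc=3)
        fit_growth_curves_individual(s)
        s.set_cut_time(10.0)
        calculate_drc_data(s)
        with pytest.raises(FitError, match="4 distinct"):
            fit_dose_response(s)

    def test_long_layout_shape_and_round_trip(self, tmp_path):
        s = self.fitted_set()
        long = export_drc_table(s, "long")
        cmp_rows = long[long["conc"] > 0]
        assert len(cmp_rows) == 2 * 5 * 2
        f = tmp_path / "long.tsv"
        long.to_csv(f, sep="\t", index=False)
        back = pd.read_csv(f, sep="\t")
        regrouped = {
            (name, conc): sorted(g["value"])
            for (name, conc), g in back.groupby(["compound", "conc"])
        }
        for r in s.drc_records:
            assert regrouped[(r.compound_name, r.concentration)] == pytest.approx(
                sorted(r.values)
            )

    def test_prism_layout_shape(self):
        s = self.fitted_set()
        prism = export_drc_table(s, "prism")
        assert len(prism) == 5  # one row per concentration
        assert list(prism.columns)[0] == "conc"
        assert sum(c.startswith("cmp0_") for c in prism.columns) == 2

    def test_dotmatics_layout_blocks(self):
        s = self.fitted_set()
        dot = export_drc_table(s, "dotmatics")
        assert set(dot["sample_id"]) == {"cmp0", "cmp1"}
        assert {"conc", "value_1", "value_2"} <= set(dot.columns)

    def test_unknown_layout_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            export_drc_table(self.fitted_set(), "excel")

    def test_ec50_table_consistency(self):
        s = self.fitted_set()
        table = export_ec50_table(s)
        assert len(table) == 2
        for _, row in table.iterrows():
            res = s.dose_response_results[row["compound"]]
            assert row["ec50"] == pytest.approx(calculate_ec50(res))
            assert row["cut_time_h"] == 10.0
            assert row["n_points"] == res.n_points

    def test_unconverged_row_present_with_empty_ec50(self):
        s = self.fitted_set()
        flat = LogLogistic4(DOSES, np.full(8, 50.0), "flatline").fit()
        s.dose_response_results["flatline"] = flat
        table = export_ec50_table(s)
        row = table[table["compound"] == "flatline"].iloc[0]
        assert bool(row["converged"]) is False and np.isnan(row["ec50"])
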