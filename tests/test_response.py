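"""Viability, cytotoxicity, dose-response fitting, and correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spheroquant as sq
from spheroquant.errors import PlateError
from spheroquant.response import simulate_viability_plate


def make_plate(dose_lums: dict, control_lum=1000.0, n_controls=3, assay="viability"):
    rows = []
    for i in range(n_controls):
        rows.append(
            dict(
                well=f"V{i}", condition="vehicle", dose_nM=0.0, replicate=i,
                lum=control_lum, assay=assay,
            )
        )
    for dose, lums in dose_lums.items():
        for i, lum in enumerate(np.atleast_1d(lums)):
            rows.append(
                dict(
                    well=f"D{dose}R{i}", condition="drug", dose_nM=dose,
                    replicate=i, lum=float(lum), assay=assay,
                )
            )
    return pd.DataFrame(rows)


class TestRelativeViability:
    def test_wells_at_control_mean_are_one(self):
        plate = make_plate({10.0: [1000.0, 1000.0]})
        per_well, per_dose = sq.relative_viability(plate)
        treated = per_well[per_well["condition"] == "drug"]
        assert np.allclose(treated["rel_viability"], 1.0)
        assert per_dose["mean_viability"].iloc[0] == pytest.approx(1.0)

    def test_half_control_is_half(self):
        plate = make_plate({10.0: [500.0]})
        per_well, _ = sq.relative_viability(plate)
        assert per_well[per_well["condition"] == "drug"]["rel_viability"].iloc[
            0
        ] == pytest.approx(0.5)

    def test_scale_invariance(self):
        plate = make_plate({1.0: [800.0, 900.0], 10.0: [400.0, 300.0]})
        _, a = sq.relative_viability(plate)
        scaled = plate.assign(lum=plate["lum"] * 37.5)
        _, b = sq.relative_viability(scaled)
        np.testing.assert_allclose(a["mean_viability"], b["mean_viability"])

    def test_per_dose_estimates_track_truth(self):
        rng = np.random.default_rng(1)
        truth = {1.0: 0.9, 10.0: 0.6, 100.0: 0.3}
        n = 8
        plate = make_plate(
            {d: 1000.0 * v * (1 + 0.05 * rng.standard_normal(n)) for d, v in truth.items()}
        )
        _, per_dose = sq.relative_viability(plate)
        for _, row in per_dose.iterrows():
            se = row["sd_viability"] / np.sqrt(row["n"])
            assert abs(row["mean_viability"] - truth[row["dose_nM"]]) < 2 * se + 0.02

    def test_degenerate_control_rejected(self):
        plate = make_plate({10.0: [500.0]}, control_lum=0.0)
        with pytest.raises(PlateError, match="degenerate control"):
            sq.relative_viability(plate)


class TestCytotoxicityIndex:
    def plate(self, signal):
        rows = make_plate({10.0: signal}, control_lum=100.0, assay="cytotoxicity")
        lysis = pd.DataFrame(
            [
                dict(well=f"L{i}", condition="lysis", dose_nM=0.0, replicate=i,
                     lum=1100.0, assay="cytotoxicity")
                for i in range(3)
            ]
        )
        return pd.concat([rows, lysis], ignore_index=True)

    @pytest.mark.parametrize(
        "signal,expected", [(1100.0, 100.0), (100.0, 0.0), (600.0, 50.0)]
    )
    def test_anchor_points(self, signal, expected):
        _, per_dose = sq.cytotoxicity_index(self.plate([signal]))
        assert per_dose["mean_cytotoxicity"].iloc[0] == pytest.approx(expected)

    def test_affine_invariance(self):
        plate = self.plate([300.0, 700.0])
        _, a = sq.cytotoxicity_index(plate)
        transformed = plate.assign(lum=plate["lum"] * 2.5 + 40.0)
        _, b = sq.cytotoxicity_index(transformed)
        np.testing.assert_allclose(a["mean_cytotoxicity"], b["mean_cytotoxicity"])

    def test_sub_background_clipped_at_zero(self):
        _, per_dose = sq.cytotoxicity_index(self.plate([50.0]))
        assert per_dose["mean_cytotoxicity"].iloc[0] == 0.0

    def test_degenerate_lysis_rejected(self):
        plate = self.plate([500.0])
        plate.loc[plate["condition"] == "lysis", "lum"] = 50.0
        with pytest.raises(PlateError, match="degenerate lysis control"):
            sq.cytotoxicity_index(plate)


class TestDoseResponseFit:
    doses = np.logspace(0, 4, 8)  # 1 nM .. 10 µM

    def test_noise_free_4pl_recovers_ic50(self):
        y = sq.four_param_logistic(self.doses, 1.0, 0.0, np.log10(100.0), 1.0)
        fit = sq.fit_dose_response(self.doses, y)
        assert not fit.no_ic50
        assert fit.ic50 == pytest.approx(100.0, abs=5.0)
        assert fit.hill == pytest.approx(1.0, rel=0.05)

    def test_flat_response_yields_no_ic50(self):
        y = np.full_like(self.doses, 1.0)
        fit = sq.fit_dose_response(self.doses, y + 0.01 * np.sin(self.doses))
        assert fit.no_ic50
        assert fit.reason is not None
        assert fit.ic50 is None

    def test_out_of_range_ic50_rejected(self):
        # shallow monotone decline crossing 50% far beyond the tested range
        y = sq.four_param_logistic(self.doses, 1.0, 0.0, np.log10(1e6), 1.0)
        fit = sq.fit_dose_response(self.doses, y)
        assert fit.no_ic50
        assert "range" in fit.reason

    def test_too_few_doses_rejected(self):
        with pytest.raises(PlateError, match="insufficient doses"):
            sq.fit_dose_response([1.0, 10.0, 100.0], [1.0, 0.5, 0.1])

    @staticmethod
    def fit_wells(plate):
        per_well, _ = sq.relative_viability(plate)
        treated = per_well[per_well["condition"] == "drug"]
        return sq.fit_dose_response(treated["dose_nM"], treated["rel_viability"])

    def test_simulated_plate_round_trip(self):
        plate = simulate_viability_plate(self.doses, ic50=200.0, seed=3)
        fit = self.fit_wells(plate)
        assert not fit.no_ic50
        assert abs(np.log10(fit.ic50 / 200.0)) < 0.3

    def test_4pl_recovery_over_simulated_plates(self):
        errors = []
        for seed in range(40):
            plate = simulate_viability_plate(self.doses, ic50=100.0, hill=1.2, seed=seed)
            fit = self.fit_wells(plate)
            if not fit.no_ic50:
                errors.append(abs(np.log10(fit.ic50 / 100.0)))
        assert len(errors) >= 35
        assert np.median(errors) <= 0.1

    def test_flat_plates_fire_no_ic50_rule(self):
        fired = 0
        n = 40
        for seed in range(n):
            plate = simulate_viability_plate(
                self.doses, ic50=100.0, top=1.0, bottom=1.0, seed=seed
            )
            fired += self.fit_wells(plate).no_ic50
        assert fired / n >= 0.95


class TestCorrelation:
    def test_perfect_positive_line(self):
        d = np.array([300.0, 400.0, 500.0, 600.0])
        res = sq.diameter_viability_correlation(d, 0.002 * d - 0.1)
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_perfect_negative_line(self):
        d = np.array([300.0, 400.0, 500.0, 600.0])
        res = sq.diameter_viability_correlation(d, -0.001 * d + 1.0)
        assert res.r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(300, 1000, 20)
        v = rng.uniform(0, 1, 20)
        res = sq.diameter_viability_correlation(d, v)
        num = np.mean((d - d.mean()) * (v - v.mean()))
        oracle = num / (d.std() * v.std())
        assert res.r == pytest.approx(oracle, abs=1e-12)
        assert 0.0 <= res.p_value <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(PlateError, match="degenerate input"):
            sq.diameter_viability_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.tuples(
                st.floats(100, 1000, allow_nan=False),
                st.floats(0, 2, allow_nan=False),
            ),
            min_size=3,
            max_size=30,
        )
    )
    def test_correlation_bounded(self, pairs):
        d = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        if np.std(d) == 0 or np.std(v) == 0:
            return
        res = sq.diameter_viability_correlation(d, v)
        assert -1.0 <= res.r <= 1.0 or np.isnan(res.r)
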