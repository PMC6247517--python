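"""Tests for the Zwanzig estimator, schedule and leg aggregation."""

import math

import numpy as np
import pytest

from pipfep.constants import DEFAULT_TEMPERATURE, kT
from pipfep.fep import (
    DEFAULT_LAMBDAS,
    FreeEnergyResult,
    LambdaSchedule,
    accumulate,
    bootstrap_se,
    component_delta_g,
    default_schedule,
    estimate_leg,
    leg_report,
    load_leg_report,
    window_delta_g,
)
from pipfep.sampler import LegSamples, WindowSamples


def make_window(total, elec=None, vdw=None, run_id=0):
    total = np.asarray(total, dtype=float)
    elec = np.zeros_like(total) if elec is None else np.asarray(elec, dtype=float)
    vdw = np.zeros_like(total) if vdw is None else np.asarray(vdw, dtype=float)
    return WindowSamples(
        lam=0.0,
        lam_next=1.0,
        dV_total=total,
        dV_elec=elec,
        dV_vdw=vdw,
        dV_ext=total - elec - vdw,
        run_id=run_id,
    )


class TestSchedule:
    def test_default_has_21_windows(self):
        assert len(default_schedule()) == 21

    def test_default_endpoints(self):
        sched = default_schedule()
        assert sched.values[0] == 0.0
        assert sched.values[-1] == 0.999999

    def test_strictly_increasing(self):
        vals = default_schedule().values
        assert all(b > a for a, b in zip(vals[:-1], vals[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            LambdaSchedule((0.0,))
        with pytest.raises(ValueError):
            LambdaSchedule((0.1, 0.5))
        with pytest.raises(ValueError):
            LambdaSchedule((0.0, 0.5, 0.5))

    def test_pairs_cover_consecutive_windows(self):
        sched = default_schedule()
        pairs = sched.pairs()
        assert len(pairs) == 20
        assert pairs[0] == (0.0, 0.00001)
        assert pairs[-1] == (0.99999, 0.999999)


class TestWindowDeltaG:
    def test_null_perturbation(self):
        assert window_delta_g(make_window(np.zeros(100))) == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift(self):
        assert window_delta_g(make_window(np.full(50, 2.7))) == pytest.approx(2.7)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(12)
        mu, sigma, n = 0.5, 1.0, 50_000
        ws = make_window(mu + sigma * rng.standard_normal(n))
        expected = mu - sigma**2 / (2 * kT(DEFAULT_TEMPERATURE))
        se = bootstrap_se(ws, n_boot=100, seed=12)
        assert abs(window_delta_g(ws) - expected) < 3 * se

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            window_delta_g(make_window(np.array([])))
        with pytest.raises(ValueError):
            window_delta_g(make_window(np.array([1.0, np.inf])))

    def test_jensen_bound_on_random_windows(self):
        """Zwanzig estimate never exceeds the sample mean of dV."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            dv = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), size=500)
            ws = make_window(dv)
            assert window_delta_g(ws) <= dv.mean() + 1e-10

    def test_large_negative_samples_do_not_overflow(self):
        ws = make_window(np.array([-4000.0, -4000.5]))
        assert math.isfinite(window_delta_g(ws))


class TestComponents:
    def test_single_component_perturbation(self):
        rng = np.random.default_rng(5)
        dv = rng.normal(1.0, 0.5, 300)
        ws = make_window(dv, elec=dv, vdw=np.zeros_like(dv))
        elec, vdw = component_delta_g(ws)
        assert elec == pytest.approx(window_delta_g(ws))
        assert vdw == pytest.approx(0.0, abs=1e-12)

    def test_null_perturbation_components(self):
        ws = make_window(np.zeros(10))
        assert component_delta_g(ws) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_two_component_samples_match_independent_formula(self):
        rng = np.random.default_rng(6)
        elec = rng.normal(0.5, 0.3, 400)
        vdw = rng.normal(-0.2, 0.2, 400)
        ws = make_window(elec + vdw, elec=elec, vdw=vdw)
        kt = kT(DEFAULT_TEMPERATURE)
        # independent re-implementation of the exponential average
        expected_elec = -kt * math.log(np.mean(np.exp(-elec / kt)))
        expected_vdw = -kt * math.log(np.mean(np.exp(-vdw / kt)))
        got = component_delta_g(ws)
        assert got[0] == pytest.approx(expected_elec, rel=1e-10)
        assert got[1] == pytest.approx(expected_vdw, rel=1e-10)


class TestAccumulate:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accumulate([])

    def test_single_window(self):
        assert accumulate([1.3]) == pytest.approx(1.3)

    def test_sum_and_order_insensitivity(self):
        vals = [0.1, -0.4, 2.0, 0.3]
        assert accumulate(vals) == pytest.approx(accumulate(vals[::-1]), rel=1e-14)
        assert accumulate([0.0, 0.0]) == 0.0


class TestEstimateLeg:
    def test_identical_runs_zero_se(self):
        window = make_window(np.full(20, 1.5))
        leg = LegSamples(
            lambdas=[0.0, 1.0],
            by_run=[[make_window(np.full(20, 1.5), run_id=r)] for r in range(5)],
        )
        res = estimate_leg(leg)
        assert res.dG == pytest.approx(1.5)
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.n_runs == 5

    def test_textbook_se_over_runs(self):
        # constant-dV runs give per-run dG of exactly 1, 2, 3
        leg = LegSamples(
            lambdas=[0.0, 1.0],
            by_run=[[make_window(np.full(10, float(v)), run_id=v)] for v in (1, 2, 3)],
        )
        res = estimate_leg(leg)
        assert res.dG == pytest.approx(2.0)
        assert res.se == pytest.approx(1.0 / math.sqrt(3))

    def test_null_perturbation_all_zero(self):
        leg = LegSamples(
            lambdas=[0.0, 1.0],
            by_run=[[make_window(np.zeros(10), run_id=r)] for r in range(3)],
        )
        res = estimate_leg(leg)
        assert (res.dG, res.dG_elec, res.dG_vdw, res.dG_couple) == pytest.approx(
            (0.0, 0.0, 0.0, 0.0), abs=1e-12
        )
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_single_run_marks_se_unavailable(self):
        leg = LegSamples(lambdas=[0.0, 1.0], by_run=[[make_window(np.full(5, 1.0))]])
        res = estimate_leg(leg)
        assert res.dG == pytest.approx(1.0)
        assert math.isnan(res.se)

    def test_coupling_identity_exact(self):
        rng = np.random.default_rng(8)
        by_run = []
        for r in range(4):
            elec = rng.normal(0.3, 0.2, 50)
            vdw = rng.normal(-0.1, 0.1, 50)
            ext = rng.normal(0.05, 0.05, 50)
            by_run.append(
                [
                    WindowSamples(
                        lam=0.0,
                        lam_next=1.0,
                        dV_total=elec + vdw + ext,
                        dV_elec=elec,
                        dV_vdw=vdw,
                        dV_ext=ext,
                        run_id=r,
                    )
                ]
            )
        res = estimate_leg(LegSamples(lambdas=[0.0, 1.0], by_run=by_run))
        assert res.dG - res.dG_elec - res.dG_vdw - res.dG_couple == pytest.approx(
            0.0, abs=1e-10
        )

    def test_ragged_runs_rejected(self):
        leg = LegSamples(
            lambdas=[0.0, 0.5, 1.0],
            by_run=[
                [make_window(np.ones(5)), make_window(np.ones(5))],
                [make_window(np.ones(5))],
            ],
        )
        with pytest.raises(ValueError):
            estimate_leg(leg)


class TestLegReport:
    def test_json_round_trip(self, tmp_path):
        leg = LegSamples(
            lambdas=[0.0, 1.0],
            by_run=[[make_window(np.full(10, float(v)), run_id=v)] for v in (1, 2, 3)],
        )
        res = estimate_leg(leg, leg_label="bound")
        jpath, cpath = leg_report(res, tmp_path / "leg")
        back = load_leg_report(jpath)
        assert back.dG == pytest.approx(res.dG)
        assert back.leg_label == "bound"
        assert cpath.read_text().startswith("quantity,value,se")
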