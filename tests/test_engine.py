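"""Stock-flow engine: flows, occupancies, delays, stepping, trajectories."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from duotrack import (
    AnnualInputs,
    Delay3,
    ParameterError,
    ScalarParams,
    SimState,
    TaxPolicy,
    delay3_init,
    delay3_output,
    delay3_step,
    hi_level,
    occupancy_gap,
    occupancy_private,
    occupancy_public,
    simulate,
    split_admissions,
    step,
    tax_saving,
    write_trajectory,
)

NO_TAX = TaxPolicy(
    tax_inct=0.0, avg_prm_ratio=0.85, tax_rate=0.06, avg_tax=2876.0,
    start_date=dt.date(2999, 1, 1),
)


def flat_inputs(years=(2009, 2020), nonsurge=3800.0, ratio=1.196, los=7.5,
                pu_beds=24000.0, pr_beds=4000.0):
    yy = list(range(*years))
    return AnnualInputs(
        pd.DataFrame(
            {
                "year": yy,
                "inpt_surge": nonsurge * ratio,
                "inpt_nonsurge": nonsurge,
                "pu_los": los,
                "pu_beds": pu_beds,
                "pr_beds": pr_beds,
            }
        )
    )


def params(**overrides):
    base = dict(
        use_hi=0.57, selfpay=0.06, severity_ftr=0.39, occu_dmd=0.5,
        tax_dmd=0.138, baseline_hi=0.30, baseline_diff=0.055,
    )
    base.update(overrides)
    return ScalarParams(**base)


class TestSplitAdmissions:
    def test_worked_example(self):
        pu, pr = split_admissions(3945.0, 0.36, 0.57, 0.06)
        assert pu == pytest.approx(2984.0, abs=0.05)
        assert pr == pytest.approx(961.0, abs=0.05)

    def test_uninsured_no_selfpay_all_public(self):
        assert split_admissions(500.0, 0.0, 0.7, 0.0) == (500.0, 0.0)

    def test_all_insured_all_use_private(self):
        pu, pr = split_admissions(500.0, 1.0, 1.0, 0.3)
        assert (pu, pr) == (0.0, 500.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError, match="hi"):
            split_admissions(100.0, 1.5, 0.5, 0.1)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=1e5),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_conservation_and_nonnegativity(self, n, hi, use, sp):
        pu, pr = split_admissions(n, hi, use, sp)
        assert pu + pr == n  # exact, by construction
        assert pu >= 0.0 and pr >= 0.0


class TestOccupancy:
    def test_public_example(self):
        # 2984 * 7.5 / 25661 = 0.87214; quoted at 4 dp as 0.8722
        assert occupancy_public(2984.0, 7.5, 25661) == pytest.approx(0.8722, abs=1e-4)

    def test_private_example(self):
        assert occupancy_private(961.0, 7.5, 0.39, 5056) == pytest.approx(0.5560, abs=5e-5)

    def test_zero_admissions(self):
        assert occupancy_public(0.0, 7.5, 100) == 0.0
        assert occupancy_private(0.0, 7.5, 0.4, 100) == 0.0

    def test_beds_homogeneity(self):
        assert occupancy_public(100.0, 7.0, 2000) == pytest.approx(
            occupancy_public(100.0, 7.0, 1000) / 2
        )

    def test_severity_one_matches_public_form(self):
        assert occupancy_private(100.0, 7.0, 1.0, 900) == occupancy_public(100.0, 7.0, 900)

    def test_zero_beds_rejected(self):
        with pytest.raises(ParameterError):
            occupancy_public(1.0, 7.0, 0)

    def test_gap_orientation_antisymmetric(self):
        g = occupancy_gap(0.8722, 0.5560, "public_minus_private")
        assert g == pytest.approx(0.3162)
        assert occupancy_gap(0.8722, 0.5560, "private_minus_public") == pytest.approx(-g)
        assert occupancy_gap(0.5, 0.5, "public_minus_private") == 0.0


class TestDelay3:
    def test_constant_input_is_exact_fixed_point(self):
        d = delay3_init(2.5, 365.0)
        assert delay3_output(d) == 2.5
        for _ in range(500):
            d = delay3_step(d, 2.5, 1.0)
        assert delay3_output(d) == 2.5  # exact

    def test_zero_init_starts_at_zero(self):
        d = delay3_init(5.0, 365.0, zero_init=True)
        assert delay3_output(d) == 0.0

    def test_step_response_matches_erlang3(self):
        d = delay3_init(0.0, 365.0, zero_init=True)
        for _ in range(365):
            d = delay3_step(d, 1.0, 1.0)
        exact = 1 - np.exp(-3) * (1 + 3 + 4.5)  # Erlang-3 CDF at t = duration
        assert exact == pytest.approx(0.5768, abs=5e-5)
        assert delay3_output(d) == pytest.approx(exact, rel=5e-3)

    def test_euler_refinement_converges(self):
        vals = {}
        for dt_ in (1.0, 0.1):
            d = delay3_init(0.0, 365.0, zero_init=True)
            for _ in range(int(365 / dt_)):
                d = delay3_step(d, 1.0, dt_)
            vals[dt_] = delay3_output(d)
        assert abs(vals[1.0] - vals[0.1]) / vals[0.1] < 0.005

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ParameterError):
            delay3_init(1.0, 0.0)


class TestTaxSaving:
    def test_hk_policy(self):
        pol = TaxPolicy(tax_inct=8000, avg_prm_ratio=0.85, tax_rate=0.06, avg_tax=2876)
        assert tax_saving(pol) == pytest.approx(408.0)

    def test_zero_incentive(self):
        assert tax_saving(NO_TAX) == 0.0

    def test_full_premium_ratio(self):
        pol = TaxPolicy(tax_inct=8000, avg_prm_ratio=1.0, tax_rate=0.06, avg_tax=2876)
        assert tax_saving(pol) == pytest.approx(480.0)


class TestHiLevel:
    def test_plain_addition(self):
        assert hi_level(0.30, 0.02, 0.0) == pytest.approx(0.32)
        assert hi_level(0.30, 0.04, 0.0196) == pytest.approx(0.3596)

    def test_clamp_floors_negative_occupancy_effect(self):
        assert hi_level(0.30, -0.01, 0.0, clamp_effect_nonneg=True) == pytest.approx(0.30)
        assert hi_level(0.30, -0.01, 0.0, clamp_effect_nonneg=False) == pytest.approx(0.29)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=-2.0, max_value=2.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.booleans(),
    )
    def test_always_in_unit_interval(self, b, eo, et, clamp):
        assert 0.0 <= hi_level(b, eo, et, clamp) <= 1.0


class TestStep:
    def test_single_step_matches_hand_computation(self):
        inputs = flat_inputs()
        p = params()
        state = SimState(
            t=dt.date(2015, 7, 1),  # off-season: multiplier 1
            using_pu=20000.0,
            using_pr=2500.0,
            occu_delay=delay3_init(0.01, 365.0),
            tax_delay=delay3_init(0.0, 365.0),
            hi=0.35,
        )
        new = step(state, p, NO_TAX, inputs)
        # independent arithmetic oracle
        inpt = 3800.0
        pr_adm = inpt * (0.35 * 0.57 + 0.65 * 0.06)
        pu_adm = inpt - pr_adm
        pu_dis = 20000.0 / 7.5
        pr_dis = 2500.0 / (7.5 * 0.39)
        pu_occ = pu_adm * 7.5 / 24000.0
        pr_occ = pr_adm * 7.5 * 0.39 / 4000.0
        gap = pu_occ - pr_occ
        tau = 365.0 / 3.0
        u = (gap - 0.055) * 0.5
        s = 0.01 * tau  # matched stage level
        s1 = s + (u - 0.01)  # one Euler day
        expected_effect = s / tau  # s3 outflow fed by old stages: unchanged after 1 step
        assert new.t == dt.date(2015, 7, 2)
        assert new.using_pu == pytest.approx(20000.0 + pu_adm - pu_dis, abs=1e-9)
        assert new.using_pr == pytest.approx(2500.0 + pr_adm - pr_dis, abs=1e-9)
        assert new.occu_delay.s1 == pytest.approx(s1, abs=1e-9)
        assert new.occu_delay.output() == pytest.approx(expected_effect, abs=1e-9)
        assert new.hi == pytest.approx(0.30 + expected_effect, abs=1e-9)

    def test_zero_stocks_give_zero_discharges(self):
        inputs = flat_inputs()
        state = SimState(
            t=dt.date(2015, 7, 1), using_pu=0.0, using_pr=0.0,
            occu_delay=delay3_init(0.0, 365.0), tax_delay=delay3_init(0.0, 365.0),
            hi=0.3,
        )
        new = step(state, params(), NO_TAX, inputs)
        assert new.using_pu > 0.0 and new.using_pr > 0.0  # admissions only

    def test_stock_reaches_littles_law_equilibrium(self):
        """Held constant, the public stock converges to admissions x LoS."""
        p = params(occu_dmd=0.0)  # freeze the feedback so admissions are constant
        traj = simulate(
            p, NO_TAX, flat_inputs(), start=dt.date(2015, 4, 1), end=dt.date(2015, 11, 30)
        )
        pu_adm = traj["pu_admit"].iloc[-1]
        assert traj["using_pu"].iloc[-1] == pytest.approx(pu_adm * 7.5, rel=1e-3)
        assert traj["using_pr"].iloc[-1] == pytest.approx(
            traj["pr_admit"].iloc[-1] * 7.5 * 0.39, rel=1e-3
        )


class TestSimulate:
    def test_requires_baseline(self, hk):
        with pytest.raises(ParameterError, match="baseline_hi"):
            simulate(hk.scalar, hk.tax_policy, hk.annual)

    def test_one_day_horizon_is_initial_state(self):
        traj = simulate(
            params(), NO_TAX, flat_inputs(),
            start=dt.date(2015, 7, 1), end=dt.date(2015, 7, 1),
        )
        assert len(traj) == 1
        assert traj["hi"].iloc[0] == 0.30
        assert traj["using_pu"].iloc[0] == 0.0

    def test_matches_step_by_step_iteration(self):
        """The array fast path and the reference step() agree exactly."""
        inputs = flat_inputs()
        p = params()
        start = dt.date(2014, 12, 1)  # crosses the surge window
        traj = simulate(p, NO_TAX, inputs, start=start, end=start + dt.timedelta(days=59))
        first_gap = (
            occupancy_gap(
                occupancy_public(traj["pu_admit"].iloc[0], 7.5, 24000.0),
                occupancy_private(traj["pr_admit"].iloc[0], 7.5, 0.39, 4000.0),
            )
        )
        state = SimState(
            t=start, using_pu=0.0, using_pr=0.0,
            occu_delay=delay3_init((first_gap - 0.055) * 0.5, 365.0),
            tax_delay=delay3_init(0.0, 365.0, zero_init=True),
            hi=0.30,
        )
        for k in range(60):
            row = traj.iloc[k]
            assert row["hi"] == pytest.approx(state.hi, abs=1e-12)
            assert row["using_pu"] == pytest.approx(state.using_pu, abs=1e-9)
            assert row["effect_occu"] == pytest.approx(
                state.occu_delay.output(), abs=1e-12
            )
            state = step(state, p, NO_TAX, inputs)

    def test_effects_disabled_keeps_baseline_exactly(self):
        p = params(occu_dmd=0.0)
        traj = simulate(
            p, NO_TAX, flat_inputs(), start=dt.date(2010, 4, 1), end=dt.date(2013, 12, 31)
        )
        assert (traj["hi"] == 0.30).all()
        assert (traj["effect_occu"] == 0.0).all()
        assert (traj["effect_tax"] == 0.0).all()

    def test_tax_effect_zero_before_policy_then_converges(self):
        """The tax effect is exactly zero pre-policy and approaches
        (saving / avg_tax) * tax_dmd once the delay has passed."""
        pol = TaxPolicy(
            tax_inct=8000, avg_prm_ratio=0.85, tax_rate=0.06, avg_tax=2876,
            start_date=dt.date(2012, 4, 1),
        )
        p = params(occu_dmd=0.0)
        traj = simulate(
            p, pol, flat_inputs(), start=dt.date(2010, 4, 1), end=dt.date(2018, 12, 31)
        )
        pre = traj[traj["t"] < "2012-04-02"]
        assert (pre["effect_tax"] == 0.0).all()
        limit = 408.0 / 2876.0 * p.tax_dmd
        assert limit == pytest.approx(0.01958, abs=5e-6)
        assert traj["effect_tax"].iloc[-1] == pytest.approx(limit, rel=1e-3)
        assert traj["hi"].iloc[-1] == pytest.approx(0.30 + limit, rel=1e-3)

    def test_conservation_along_trajectory(self):
        traj = simulate(
            params(), NO_TAX, flat_inputs(), start=dt.date(2012, 4, 1), end=dt.date(2013, 3, 31)
        )
        assert (traj["pu_admit"] + traj["pr_admit"] == traj["inpt_num"]).all()

    def test_hk_occupancy_envelope(self, hk, hk_baseline):
        """Public occupancy stays in a plausible band after warm-up."""
        p = hk.scalar.model_copy(update={"baseline_hi": hk_baseline})
        traj = simulate(p, hk.tax_policy, hk.annual)
        after = traj[traj["t"] >= "2012-01-01"]
        # surge peaks may briefly exceed nominal capacity; the bulk of the
        # year sits inside the plausible band
        assert after["pu_occu"].between(0.7, 1.15).all()
        assert after["pu_occu"].between(0.7, 1.1).mean() > 0.97

    def test_doubling_private_beds_lowers_private_occupancy(self):
        inputs = flat_inputs()
        doubled = AnnualInputs(
            inputs.table.assign(pr_beds=inputs.table["pr_beds"] * 2).reset_index()
        )
        kw = dict(start=dt.date(2010, 4, 1), end=dt.date(2012, 3, 31))
        a = simulate(params(), NO_TAX, inputs, **kw)
        b = simulate(params(), NO_TAX, doubled, **kw)
        assert (b["pr_occu"].to_numpy() < a["pr_occu"].to_numpy()).all()

    def test_upward_hi_perturbation_closes_the_gap(self):
        """More insured patients load the private sector and relieve the
        public one, shrinking the public-minus-private gap (balancing loop)."""
        kw = dict(start=dt.date(2010, 4, 1), end=dt.date(2010, 4, 10))
        lo = simulate(params(baseline_hi=0.30), NO_TAX, flat_inputs(), **kw)
        hi = simulate(params(baseline_hi=0.35), NO_TAX, flat_inputs(), **kw)
        assert hi["pr_occu"].iloc[0] > lo["pr_occu"].iloc[0]
        assert hi["pu_occu"].iloc[0] < lo["pu_occu"].iloc[0]
        assert hi["diff_occu"].iloc[0] < lo["diff_occu"].iloc[0]

    def test_warmup_transient_exceeds_settled_variation(self, hk, hk_baseline):
        p = hk.scalar.model_copy(update={"baseline_hi": hk_baseline})
        traj = simulate(p, hk.tax_policy, hk.annual).set_index("t")
        jump = (traj.loc["2009":"2011", "hi"] - hk_baseline).abs().max()
        yoy = traj.loc["2015":"2019", "hi"].resample("YE").last().diff().abs().max()
        assert jump > yoy

    def test_stock_occupancy_basis_available(self):
        # horizon avoids the winter surge so the stocks actually equilibrate
        kw = dict(start=dt.date(2010, 4, 1), end=dt.date(2010, 11, 30))
        flow = simulate(params(occu_dmd=0.0), NO_TAX, flat_inputs(), **kw)
        stock = simulate(
            params(occu_dmd=0.0), NO_TAX, flat_inputs(), occupancy_basis="stock", **kw
        )
        # flow and stock forms agree once stocks equilibrate (Little's law)
        assert stock["pu_occu"].iloc[-1] == pytest.approx(
            flow["pu_occu"].iloc[-1], rel=1e-3
        )

    def test_substep_recording_contract(self):
        kw = dict(start=dt.date(2015, 7, 1), end=dt.date(2015, 7, 10))
        daily = simulate(params(), NO_TAX, flat_inputs(), **kw)
        halved = simulate(params(), NO_TAX, flat_inputs(), dt_days=0.5, **kw)
        sub = simulate(
            params(), NO_TAX, flat_inputs(), dt_days=0.5, emit_substeps=True, **kw
        )
        assert len(daily) == 10
        assert len(halved) == 10  # still one record per day
        assert len(sub) == 20

    def test_trajectory_writer_round_trip(self, tmp_path):
        traj = simulate(
            params(), NO_TAX, flat_inputs(),
            start=dt.date(2015, 7, 1), end=dt.date(2015, 7, 5),
        )
        path = tmp_path / "traj.csv"
        write_trajectory(traj, path, {"note": "test"})
        text = path.read_text()
        assert text.startswith("# note: test\n")
        back = pd.read_csv(path, comment="#", parse_dates=["t"])
        assert len(back) == len(traj)
        assert back["hi"].to_numpy() == pytest.approx(traj["hi"].to_numpy())
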