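"""Synthetic health-system scenarios for testing and parameter recovery.

A scenario has the same statistical structure the simulator assumes about
real systems: piecewise-annual inputs with smooth growth, a winter surge at
a fixed peak ratio, and sparse, noisy survey observations of the simulated
insurance penetration.  Survey noise is additive Gaussian on the penetration
fraction, clipped to [0, 1] -- the simplest observation model for a
self-reported survey quantity.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .engine import simulate
from .params import (
    AnnualInputs,
    ParameterError,
    ReferenceSeries,
    ScalarParams,
    TaxPolicy,
)
from .surge import SurgeCalendar

__all__ = ["ScenarioSpec", "generate_scenario"]

_FAR_FUTURE = dt.date(2999, 1, 1)


@dataclass
class ScenarioSpec:
    """Configuration of a synthetic dual-track health system."""

    true_params: ScalarParams
    n_years: int = 8
    start_year: int = 2009
    base_daily_admissions: float = 3500.0
    admission_growth: float = 0.015  # fraction/year
    beds_pu: float = 23000.0
    beds_pu_growth: float = 0.01
    beds_pr: float = 4000.0
    beds_pr_growth: float = 0.01
    pu_los: float = 7.4
    tax_policy: TaxPolicy | None = None
    survey_dates: tuple[dt.date, ...] = ()
    survey_noise_sd: float = 0.0  # fraction of population, e.g. 0.005 = 0.5 pp
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ParameterError("n_years must be >= 1")
        for name in ("base_daily_admissions", "beds_pu", "beds_pr", "pu_los"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.survey_noise_sd < 0:
            raise ParameterError("survey_noise_sd must be non-negative")
        if self.true_params.baseline_hi is None:
            raise ParameterError("true_params must carry a baseline_hi")
        lo, hi = self.horizon
        for d in self.survey_dates:
            if not lo <= d <= hi:
                raise ParameterError(f"survey date {d} outside horizon {lo}..{hi}")

    @property
    def horizon(self) -> tuple[dt.date, dt.date]:
        return (
            dt.date(self.start_year, 4, 1),
            dt.date(self.start_year + self.n_years - 1, 12, 31),
        )


def generate_scenario(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[AnnualInputs, ReferenceSeries, ScalarParams, TaxPolicy]:
    """Build a scenario and its noisy survey observations.

    The annual inputs grow geometrically; the surge level is exactly
    ``peak_ratio`` times the non-surge level.  The reference series is the
    simulated penetration at the survey dates plus Gaussian noise.
    Deterministic for a fixed ``spec.seed`` (or a supplied generator).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed) if rng is None else rng
    years = list(range(spec.start_year, spec.start_year + spec.n_years))
    k = np.arange(spec.n_years)
    nonsurge = spec.base_daily_admissions * (1.0 + spec.admission_growth) ** k
    table = pd.DataFrame(
        {
            "year": years,
            "inpt_surge": nonsurge * spec.true_params.surge_peak_ratio,
            "inpt_nonsurge": nonsurge,
            "pu_los": spec.pu_los,
            "pu_beds": spec.beds_pu * (1.0 + spec.beds_pu_growth) ** k,
            "pr_beds": spec.beds_pr * (1.0 + spec.beds_pr_growth) ** k,
        }
    )
    annual = AnnualInputs(table)
    policy = spec.tax_policy or TaxPolicy(
        tax_inct=0.0,
        avg_prm_ratio=0.85,
        tax_rate=0.06,
        avg_tax=2876.0,
        start_date=_FAR_FUTURE,
    )
    start, end = spec.horizon
    calendar = SurgeCalendar(peak_ratio=spec.true_params.surge_peak_ratio)
    traj = simulate(spec.true_params, policy, annual, calendar, start, end)
    reference = None
    if spec.survey_dates:
        t = pd.to_datetime(traj["t"]).dt.date
        lookup = dict(zip(t, traj["hi"]))
        obs = []
        for d in spec.survey_dates:
            noise = rng.normal(0.0, spec.survey_noise_sd)
            obs.append(float(np.clip(lookup[d] + noise, 0.0, 1.0)))
        reference = ReferenceSeries(list(spec.survey_dates), obs)
    else:
        last = end
        t = pd.to_datetime(traj["t"]).dt.date
        reference = ReferenceSeries([last], [float(traj["hi"].iloc[-1])])
    return annual, reference, spec.true_params, policy
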