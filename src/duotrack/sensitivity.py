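"""Multivariate Monte-Carlo sensitivity analysis.

Behavioural fractions bounded in [0, 1] (insurance usage, self-pay share,
tax-demand elasticity expressed as a fraction, severity adjustment) are
sampled from Beta distributions; the unbounded occupancy elasticity from a
Normal.  Each run draws one constant parameter set, simulates the full
horizon, and the pointwise 2.5/25/50/75/97.5 percentiles across runs form
the uncertainty envelope.

Beta shapes derive from a published mean and a symmetric range read as
mean +/- 2 standard deviations: with ``sd = (hi - lo) / 4`` and
``nu = m(1-m)/sd^2 - 1``, ``alpha = m * nu`` and ``beta = (1-m) * nu``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .engine import _simulate_arrays, build_exogenous
from .params import AnnualInputs, ParameterError, ScalarParams, TaxPolicy
from .surge import SurgeCalendar

__all__ = [
    "BetaDist",
    "NormalDist",
    "SensitivitySpec",
    "Envelope",
    "beta_params_from_range",
    "sample_parameter_set",
    "run_sensitivity",
    "PERCENTILES",
    "ENVELOPE_OUTPUTS",
]

PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)
ENVELOPE_OUTPUTS = ("hi", "pu_occu", "pr_occu", "pu_admit", "pr_admit")

#: ScalarParams fields that may be sampled.
_SAMPLABLE = ("use_hi", "selfpay", "tax_dmd", "severity_ftr", "occu_dmd")


@dataclass(frozen=True)
class BetaDist:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("Beta shape parameters must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class NormalDist:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.normal(self.mu, self.sigma))

    @property
    def mean(self) -> float:
        return self.mu


Distribution = Union[BetaDist, NormalDist]


def beta_params_from_range(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Beta (alpha, beta) matching a mean and a symmetric mean +/- 2 sd range."""
    if not (0.0 < lo < mean < hi < 1.0):
        raise ParameterError("need 0 < lo < mean < hi < 1")
    if abs((mean - lo) - (hi - mean)) > 1e-6 * (hi - lo):
        raise ParameterError("range must be symmetric around the mean")
    sd = (hi - lo) / 4.0
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ParameterError(f"sd {sd} too large for mean {mean}: no valid Beta")
    return mean * nu, (1.0 - mean) * nu


@dataclass
class SensitivitySpec:
    """Sampling design: one distribution per varied parameter."""

    distributions: dict[str, Distribution] = field(default_factory=dict)
    n_runs: int = 500
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ParameterError("n_runs must be >= 1")
        unknown = set(self.distributions) - set(_SAMPLABLE)
        if unknown:
            raise ParameterError(f"cannot sample parameters: {sorted(unknown)}")

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "SensitivitySpec":
        dists: dict[str, Distribution] = {}
        for name, kw in (doc.get("beta") or {}).items():
            dists[name] = BetaDist(float(kw["alpha"]), float(kw["beta"]))
        for name, kw in (doc.get("normal") or {}).items():
            dists[name] = NormalDist(float(kw["mu"]), float(kw["sigma"]))
        return cls(
            distributions=dists,
            n_runs=int(doc.get("n_runs", 500)),
            seed=int(doc.get("seed", 1234)),
        )


def sample_parameter_set(
    spec: SensitivitySpec, base: ScalarParams, rng: np.random.Generator
) -> ScalarParams:
    """One parameter draw; fields without a distribution keep base values."""
    update = {name: dist.sample(rng) for name, dist in spec.distributions.items()}
    return base.model_copy(update=update)


@dataclass
class Envelope:
    """Pointwise percentile curves per output, plus the per-run end states."""

    quantiles: dict[str, pd.DataFrame]  # index: dates; columns: p2.5 ... p97.5
    end_state: pd.DataFrame  # one row per run: draws + end-of-horizon outputs

    def to_csv(self, path) -> None:
        """Long-format CSV: date, output, p2.5, p25, p50, p75, p97.5."""
        frames = []
        for name, df in self.quantiles.items():
            block = df.copy()
            block.insert(0, "output", name)
            block.insert(0, "date", df.index)
            frames.append(block)
        pd.concat(frames).to_csv(path, index=False)


def run_sensitivity(
    spec: SensitivitySpec,
    base: ScalarParams,
    policy: TaxPolicy,
    inputs: AnnualInputs,
    calendar: SurgeCalendar | None = None,
    start: dt.date = dt.date(2009, 4, 1),
    end: dt.date = dt.date(2019, 12, 31),
    outputs: tuple[str, ...] = ENVELOPE_OUTPUTS,
    **sim_kwargs,
) -> Envelope:
    """Run ``spec.n_runs`` seeded simulations and assemble the envelope."""
    rng = np.random.default_rng(spec.seed)
    exog = build_exogenous(inputs, calendar, start, end, policy)
    dates = pd.DatetimeIndex(exog["days"])
    n = spec.n_runs
    store = {name: np.empty((n, len(dates))) for name in outputs}
    end_rows = []
    for i in range(n):
        draw = sample_parameter_set(spec, base, rng)
        try:
            arrays = _simulate_arrays(draw, policy, exog, **sim_kwargs)
        except Exception as exc:
            sampled = {k: getattr(draw, k) for k in spec.distributions}
            raise RuntimeError(f"run {i} failed with draw {sampled}: {exc}") from exc
        for name in outputs:
            store[name][i] = arrays[name]
        row = {name: getattr(draw, name) for name in spec.distributions}
        row.update({f"end_{name}": arrays[name][-1] for name in outputs})
        end_rows.append(row)
    cols = [f"p{q:g}" for q in PERCENTILES]
    quantiles = {
        name: pd.DataFrame(
            np.percentile(store[name], PERCENTILES, axis=0).T, index=dates, columns=cols
        )
        for name in outputs
    }
    return Envelope(quantiles=quantiles, end_state=pd.DataFrame(end_rows))
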