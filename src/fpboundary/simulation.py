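"""Monte Carlo evaluation of the boundary estimator on three scenario families.

Each scenario pairs a known boundary q(t) on [0, 1] with a family of random
trajectories observed on an equidistant grid with i.i.d. Gaussian noise:

* Scenario I   — linear trajectories X_i(t) = d_i t, d_i ~ U(0, 1), against the
  parabola q(t) = -4 (t - 1/2)^2 + 0.8.  The boundary dips below the
  trajectories' starting level, so first passages are detected as the first
  touch of the boundary and concentrate early in the domain.
* Scenario II  — logistic growth X_i(t) = a_i / (1 + exp{-b_i (t - c_i)}),
  a ~ U(0.8, 1.2), b ~ U(5, 10), c ~ U(0.3, 0.7), against the decreasing line
  q(t) = -0.8 t + 0.9; every trajectory crosses.
* Scenario III — concave parabolas X_i(t) = a_i (t - 1/2)^2 + b_i,
  a ~ U(-2, -0.5), b ~ U(0.2, 0.8), against a continuous piecewise-linear
  boundary with slopes (-1.2, -0.4), kink at t0 = 0.5 and intercept 1.0.

A replicate generates trajectories, collects crossing pairs, fits the
GCV-selected penalized cubic B-spline, and scores the fit by
MSE = (1/m) sum_j (Q_hat(t_j) - q(t_j))^2 on an equidistant evaluation grid.
Crossing levels are recorded with the "observed" convention (the measured
value at the detection grid node), so measurement noise propagates into the
pairs and the MSE responds to the noise level; the evaluation grid spans the
observed crossing-time range by default (``eval_range="support"``), i.e. the
estimator is scored where crossing data exist rather than on extrapolation.
Replicate seeds are spawned from the master seed so runs are reproducible
and independent of scheduling; generators draw standard normal noise scaled
by sigma, so runs at different noise levels with the same seed share their
underlying random draws (common random numbers).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import build_penalty, build_spline_spec
from .estimators import CrossingPairSet, default_lambda_grid, gcv_select
from .first_passage import ThresholdCurve, Trajectory, collect_crossings

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "ReplicateResult",
    "MCResult",
    "true_threshold",
    "generate_trajectories",
    "run_replicate",
    "run_monte_carlo",
    "summarize_tables",
    "censoring_rate",
]

SCENARIOS = ("I", "II", "III")

# Scenario III boundary pieces: slopes and the continuity-determined intercept
_S3_T0 = 0.5
_S3_BETA1, _S3_BETA2 = -1.2, -0.4
_S3_ALPHA1 = 1.0
_S3_ALPHA2 = _S3_ALPHA1 + (_S3_BETA1 - _S3_BETA2) * _S3_T0


@dataclass(frozen=True)
class ScenarioConfig:
    """One Monte Carlo configuration (scenario, sample size, noise level)."""

    scenario: str
    n: int = 100
    sigma: float = 0.05
    n_grid: int = 200
    R: int = 1000
    seed: int = 0
    K: int = 8
    order_p: int = 4
    penalty_flavor: str = "second_derivative_integral"
    lambda_grid: np.ndarray | None = None
    m_eval: int = 200
    eval_range: str = "support"
    level_convention: str = "observed"
    min_crossings: int = 10
    redraw_budget: int = 100

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n < 4:
            raise ValueError("need n >= 4 subjects")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n_grid < 10:
            raise ValueError("need n_grid >= 10")
        if self.R < 1:
            raise ValueError("need R >= 1 replications")
        if self.eval_range not in ("support", "domain"):
            raise ValueError("eval_range must be 'support' or 'domain'")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.lambda_grid is not None:
            d["lambda_grid"] = np.asarray(self.lambda_grid).tolist()
        return d


def true_threshold(scenario: str) -> ThresholdCurve:
    """The closed-form boundary q(t) of a scenario, on [0, 1]."""
    if scenario == "I":
        return ThresholdCurve(lambda t: -4.0 * (t - 0.5) ** 2 + 0.8, 0.0, 1.0,
                              form="closed_form_I")
    if scenario == "II":
        return ThresholdCurve(lambda t: -0.8 * t + 0.9, 0.0, 1.0, form="closed_form_II")
    if scenario == "III":
        def q3(t):
            t = np.asarray(t, float)
            return np.where(
                t <= _S3_T0, _S3_ALPHA1 + _S3_BETA1 * t, _S3_ALPHA2 + _S3_BETA2 * t
            )
        return ThresholdCurve(q3, 0.0, 1.0, form="closed_form_III")
    raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


def generate_trajectories(
    scenario: str, n: int, sigma: float, n_grid: int, rng: np.random.Generator
) -> list[Trajectory]:
    """Draw n noisy trajectories on the equidistant grid over [0, 1].

    Subject-specific parameters are drawn first and the noise is drawn as
    standard normals scaled by sigma, so two runs with equal seeds but
    different sigma share all underlying uniform and normal draws.
    """
    t = np.linspace(0.0, 1.0, n_grid)
    if scenario == "I":
        d = rng.uniform(0.0, 1.0, size=n)
        mean = d[:, None] * t[None, :]
    elif scenario == "II":
        a = rng.uniform(0.8, 1.2, size=n)
        b = rng.uniform(5.0, 10.0, size=n)
        c = rng.uniform(0.3, 0.7, size=n)
        mean = a[:, None] / (1.0 + np.exp(-b[:, None] * (t[None, :] - c[:, None])))
    elif scenario == "III":
        a = rng.uniform(-2.0, -0.5, size=n)
        b = rng.uniform(0.2, 0.8, size=n)
        mean = a[:, None] * (t[None, :] - 0.5) ** 2 + b[:, None]
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    X = mean + sigma * rng.standard_normal(size=(n, n_grid))
    return [Trajectory(i, t, X[i]) for i in range(n)]


@dataclass(frozen=True)
class ReplicateResult:
    mse: float
    n_crossed: int
    n_right_censored: int
    n_left_censored: int
    n_units: int

    @property
    def censored_share(self) -> float:
        """Share of units contributing no crossing pair (right- plus left-censored)."""
        return (self.n_right_censored + self.n_left_censored) / self.n_units


class ReplicateUnderdeterminedError(RuntimeError):
    """A replicate produced too few crossings for a minimally determined fit."""


def run_replicate(config: ScenarioConfig, rng: np.random.Generator,
                  fit_override=None) -> ReplicateResult:
    """Generate one sample, fit the boundary, and score it against the truth.

    ``fit_override`` (testing hook) replaces the fitted curve by a callable
    evaluated on the scoring grid.  Raises
    :class:`ReplicateUnderdeterminedError` when fewer than
    ``config.min_crossings`` pairs are available.
    """
    truth = true_threshold(config.scenario)
    trajs = generate_trajectories(config.scenario, config.n, config.sigma,
                                  config.n_grid, rng)
    records, summary = collect_crossings(trajs, truth, policy="first_touch",
                                         level_convention=config.level_convention)
    if fit_override is not None:
        t_eval = np.linspace(0.0, 1.0, config.m_eval)
        q_hat = np.asarray(fit_override(t_eval), float)
    else:
        if summary.n_crossed < config.min_crossings:
            raise ReplicateUnderdeterminedError(
                f"only {summary.n_crossed} crossings (< {config.min_crossings})"
            )
        pairs = CrossingPairSet.from_records(records)
        spec = build_spline_spec(0.0, 1.0, config.K, config.order_p)
        penalty = build_penalty(spec, config.penalty_flavor)
        grid = (default_lambda_grid() if config.lambda_grid is None
                else config.lambda_grid)
        _, fit = gcv_select(pairs, spec, penalty, grid)
        # score the reconstruction where the crossing data support it
        # (eval_range="support"); "domain" scores the whole of [0, 1],
        # extrapolation included
        if config.eval_range == "support":
            t_eval = np.linspace(pairs.times.min(), pairs.times.max(), config.m_eval)
        else:
            t_eval = np.linspace(0.0, 1.0, config.m_eval)
        q_hat = fit.predict(t_eval)
    mse = float(np.mean((q_hat - truth(t_eval)) ** 2))
    return ReplicateResult(
        mse=mse,
        n_crossed=summary.n_crossed,
        n_right_censored=summary.n_right_censored,
        n_left_censored=summary.n_left_censored,
        n_units=summary.n_units,
    )


@dataclass(frozen=True)
class MCResult:
    """Summary of R replicates of one configuration (one table row)."""

    config: ScenarioConfig
    avg_mse: float
    sd_mse: float
    censoring_proportion: float
    mse_values: np.ndarray = field(repr=False)
    n_redraws: int = 0

    def as_dict(self) -> dict:
        return {
            "config": self.config.as_dict(),
            "avg_mse": self.avg_mse,
            "sd_mse": self.sd_mse,
            "censoring_proportion": self.censoring_proportion,
            "n_redraws": self.n_redraws,
            "mse_values": np.asarray(self.mse_values).tolist(),
        }


def _replicate_rng(seed: int, rep: int, retry: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(rep), int(retry)]))


def run_monte_carlo(config: ScenarioConfig) -> MCResult:
    """Run R seeded replicates and summarize mean MSE, its SD and censoring.

    Each replicate gets its own seed stream spawned from ``config.seed``, so
    the result is deterministic and independent of execution order.
    Underdetermined replicates (too few crossings) are redrawn from a fresh
    substream within ``config.redraw_budget`` and counted, never dropped.
    """
    mses = np.empty(config.R)
    censored = np.empty(config.R)
    n_redraws = 0
    for rep in range(config.R):
        for retry in range(config.redraw_budget + 1):
            try:
                res = run_replicate(config, _replicate_rng(config.seed, rep, retry))
                break
            except ReplicateUnderdeterminedError:
                n_redraws += 1
        else:
            raise RuntimeError(
                f"replicate {rep} of {config.scenario} (n={config.n}, sigma={config.sigma}) "
                f"stayed underdetermined after {config.redraw_budget} redraws"
            )
        mses[rep] = res.mse
        censored[rep] = res.censored_share
    return MCResult(
        config=config,
        avg_mse=float(mses.mean()),
        sd_mse=float(mses.std(ddof=1)) if config.R > 1 else 0.0,
        censoring_proportion=float(censored.mean()),
        mse_values=mses,
        n_redraws=n_redraws,
    )


def censoring_rate(scenario: str, n: int, sigma: float, n_grid: int = 200,
                   R: int = 200, seed: int = 0) -> float:
    """Average share of non-crossing trajectories over R replicates.

    Generation and crossing detection only — no fitting — so the crossing
    calibration of a configuration can be checked cheaply.
    """
    truth = true_threshold(scenario)
    shares = np.empty(R)
    for rep in range(R):
        trajs = generate_trajectories(scenario, n, sigma, n_grid,
                                      _replicate_rng(seed, rep))
        _, summary = collect_crossings(trajs, truth, policy="first_touch")
        shares[rep] = (summary.n_right_censored + summary.n_left_censored) / summary.n_units
    return float(shares.mean())


def summarize_tables(results: list[MCResult]) -> pd.DataFrame:
    """Render MC results as one table: rows (n, sigma), columns MSE summaries."""
    if not results:
        raise ValueError("no results to summarize")
    scenarios = {r.config.scenario for r in results}
    if len(scenarios) > 1:
        raise ValueError(f"cannot mix scenarios in one table: {sorted(scenarios)}")
    rows = [
        {
            "n": r.config.n,
            "sigma": r.config.sigma,
            "avg_mse": r.avg_mse,
            "sd_mse": r.sd_mse,
            "censoring_proportion": r.censoring_proportion,
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(["n", "sigma"], kind="stable").reset_index(drop=True)
    return df
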