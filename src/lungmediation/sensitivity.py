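"""Unmeasured-confounder sensitivity simulation.

A deliberately simplified single-exposure / single-mediator / single-outcome
framework: one or two unmeasured confounders U ~ Normal(0, 0.001) act
simultaneously on the exposure (through the latent scale of a binary
exposure), the mediator and the outcome, with equal coefficients taken from
a grid (0, 1, 3, 5, 7, 9 by default). Each simulated dataset is analysed
twice -- once adjusting for the U's, once omitting them -- with a
product-of-coefficients mediation fit (natural direct effect = the
outcome-model exposure coefficient; natural indirect effect = mediator-model
exposure coefficient x outcome-model mediator coefficient) and quasi-Bayesian
Monte-Carlo percentile intervals. A run "matches" when the two analyses
agree on the significance of both the direct and the indirect effect; a
scenario reports the match proportion across runs and the absolute
difference of the run-averaged effect estimates.

Outcomes in this module are expressed in decilitres; the residual noise of
the mediator and outcome equations is unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .util import rng_from

DEFAULT_BETA_GRID = (0.0, 1.0, 3.0, 5.0, 7.0, 9.0)


class SensitivityError(ValueError):
    pass


@dataclass
class SensitivityScenario:
    """One simulation scenario.

    ``beta_u`` is applied equally to the exposure, mediator and outcome
    equations of every confounder. Base coefficients default to a
    paternal-line sons configuration: exposure prevalence 12%, a negative
    exposure-to-mediator path, and outcome-scale paths in decilitres
    (see :func:`scenario_from_paths` to derive them from a fitted model).
    """

    n_subjects: int = 197
    n_sim: int = 1000
    n_draws: int = 1000
    n_confounders: int = 1
    u_variance: float = 0.001
    beta_u: float = 0.0
    exposure_prevalence: float = 0.12
    exposure_link: str = "probit"        # or "logit"
    effect_e_on_m: float = -0.53
    effect_m_on_o: float = 2.7
    effect_e_on_o: float = -1.6
    seed: int = 0

    def validate(self) -> "SensitivityScenario":
        if self.n_confounders not in (1, 2):
            raise SensitivityError("1 or 2 unmeasured confounders supported")
        if self.u_variance < 0:
            raise SensitivityError("confounder variance must be >= 0")
        if not (0 < self.exposure_prevalence < 1):
            raise SensitivityError("exposure prevalence must lie in (0, 1)")
        if self.exposure_link not in ("probit", "logit"):
            raise SensitivityError(f"unknown link {self.exposure_link!r}")
        if min(self.n_subjects, self.n_sim, self.n_draws) < 1:
            raise SensitivityError("n_subjects, n_sim and n_draws must be >= 1")
        return self

    @property
    def exposure_intercept(self) -> float:
        if self.exposure_link == "probit":
            return float(stats.norm.ppf(self.exposure_prevalence))
        return float(np.log(self.exposure_prevalence / (1 - self.exposure_prevalence)))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_subjects", "n_sim", "n_draws", "n_confounders", "u_variance",
            "beta_u", "exposure_prevalence", "exposure_link", "effect_e_on_m",
            "effect_m_on_o", "effect_e_on_o", "seed")}


def scenario_from_paths(nde_ml: float, nie_path_a: float, nie_path_b: float,
                        exposure_prevalence: float,
                        **overrides) -> SensitivityScenario:
    """Build a scenario from fitted serial-model paths.

    ``nde_ml`` is the fitted direct effect in mL; ``nie_path_a`` /
    ``nie_path_b`` the exposure-to-mediator and mediator-to-outcome paths
    (the latter in mL per mediator unit). Outcome-scale quantities are
    converted to decilitres.
    """
    return SensitivityScenario(
        exposure_prevalence=exposure_prevalence,
        effect_e_on_m=nie_path_a,
        effect_m_on_o=nie_path_b / 100.0,
        effect_e_on_o=nde_ml / 100.0,
        **overrides,
    ).validate()


@dataclass
class SensitivityResult:
    """Aggregates of one scenario's simulation runs."""

    scenario: SensitivityScenario
    match_proportion: float
    avg_abs_diff_nde: float
    avg_abs_diff_nie: float
    n_runs: int
    n_skipped: int
    runs: pd.DataFrame | None = None

    @property
    def avg_abs_diff(self) -> float:
        """Mean of the NDE and NIE average absolute differences."""
        return 0.5 * (self.avg_abs_diff_nde + self.avg_abs_diff_nie)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.to_dict(),
            "match_proportion": self.match_proportion,
            "avg_abs_diff_nde": self.avg_abs_diff_nde,
            "avg_abs_diff_nie": self.avg_abs_diff_nie,
            "avg_abs_diff": self.avg_abs_diff,
            "n_runs": self.n_runs, "n_skipped": self.n_skipped,
            "match_definition": "significance agreement of NDE and NIE "
                                "between with-U and without-U fits",
        }


# ---------------------------------------------------------------------------
# simulation and fitting
# ---------------------------------------------------------------------------

def simulate_framework_dataset(scenario: SensitivityScenario, run_index: int):
    """One dataset of the single-mediator framework.

    Returns ``(e, m, o, u)`` with ``u`` of shape (n, n_confounders).
    Deterministic in ``(scenario.seed, run_index)``.
    """
    scenario.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=scenario.seed, spawn_key=(run_index,)))
    n = scenario.n_subjects
    u = np.sqrt(scenario.u_variance) * rng.standard_normal((n, scenario.n_confounders))
    eta = scenario.exposure_intercept + scenario.beta_u * u.sum(axis=1)
    p = stats.norm.cdf(eta) if scenario.exposure_link == "probit" \
        else 1.0 / (1.0 + np.exp(-eta))
    e = (rng.random(n) < p).astype(float)
    m = (scenario.effect_e_on_m * e + scenario.beta_u * u.sum(axis=1)
         + rng.standard_normal(n))
    o = (scenario.effect_e_on_o * e + scenario.effect_m_on_o * m
         + scenario.beta_u * u.sum(axis=1) + rng.standard_normal(n))
    return e, m, o, u


def _ols(x: np.ndarray, y: np.ndarray):
    """Coefficients and their covariance for one OLS fit."""
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = max(x.shape[0] - x.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(x.T @ x)
    return coef, cov


def fit_framework(dataset, include_u: bool, n_draws: int = 1000,
                  seed: int = 0, levels=(2.5, 97.5)) -> dict:
    """Product-of-coefficients mediation fit with Monte-Carlo intervals.

    Fits the mediator model (M ~ E [+U]) and outcome model (O ~ E + M [+U])
    by OLS; NDE is the outcome-model exposure coefficient, NIE the product
    of the mediator-model exposure coefficient and the outcome-model
    mediator coefficient. Intervals are percentile intervals of ``n_draws``
    quasi-Bayesian draws from the asymptotic normal of the coefficients.
    Raises if the exposure is degenerate (all exposed or all unexposed).
    """
    e, m, o, u = dataset
    if e.min() == e.max():
        raise SensitivityError("degenerate exposure in simulated dataset")
    n = e.size
    n_u = u.shape[1]
    ones = np.ones(n)
    cols = [ones, e] + ([u[:, j] for j in range(n_u)] if include_u else [])
    xm = np.column_stack(cols)
    coef_m, cov_m = _ols(xm, m)
    xo = np.column_stack([ones, e, m] + (
        [u[:, j] for j in range(n_u)] if include_u else []))
    coef_o, cov_o = _ols(xo, o)

    # common random numbers: the standard-normal panel is drawn at the full
    # (with-U) width whether or not U enters, so paired with/without analyses
    # run on identical randomness and significance flips reflect the
    # confounder adjustment, not Monte-Carlo noise
    rng = rng_from(seed)
    z_m = rng.standard_normal((n_draws, 2 + n_u))
    z_o = rng.standard_normal((n_draws, 3 + n_u))
    draws_m = coef_m + z_m[:, :coef_m.size] @ np.linalg.cholesky(cov_m).T
    draws_o = coef_o + z_o[:, :coef_o.size] @ np.linalg.cholesky(cov_o).T
    nde_draws = draws_o[:, 1]
    nie_draws = draws_m[:, 1] * draws_o[:, 2]

    def summarise(point, draws):
        lo, hi = np.percentile(draws, levels)
        return {"estimate": float(point), "lower": float(lo), "upper": float(hi),
                "significant": bool(lo > 0 or hi < 0)}

    return {"nde": summarise(coef_o[1], nde_draws),
            "nie": summarise(coef_m[1] * coef_o[2], nie_draws)}


def run_scenario(scenario: SensitivityScenario,
                 keep_runs: bool = False) -> SensitivityResult:
    """Simulate ``n_sim`` runs, each analysed with and without the U's.

    Errors out if more than 5% of runs are skipped for a degenerate
    exposure.
    """
    scenario.validate()
    records = []
    n_skipped = 0
    for run in range(scenario.n_sim):
        dataset = simulate_framework_dataset(scenario, run)
        draw_seed = (scenario.seed * 1_000_003 + run) % (2**31 - 1)
        try:
            with_u = fit_framework(dataset, True, scenario.n_draws,
                                   seed=draw_seed)
            without_u = fit_framework(dataset, False, scenario.n_draws,
                                      seed=draw_seed)
        except SensitivityError:
            n_skipped += 1
            continue
        records.append({
            "run": run,
            "nde_with": with_u["nde"]["estimate"],
            "nde_without": without_u["nde"]["estimate"],
            "nie_with": with_u["nie"]["estimate"],
            "nie_without": without_u["nie"]["estimate"],
            "match": (with_u["nde"]["significant"] == without_u["nde"]["significant"]
                      and with_u["nie"]["significant"] == without_u["nie"]["significant"]),
        })
    if n_skipped > 0.05 * scenario.n_sim:
        raise SensitivityError(
            f"{n_skipped}/{scenario.n_sim} runs skipped (degenerate exposure)")
    runs = pd.DataFrame(records)
    return SensitivityResult(
        scenario=scenario,
        match_proportion=float(runs["match"].mean()),
        avg_abs_diff_nde=abs(float(runs.nde_with.mean() - runs.nde_without.mean())),
        avg_abs_diff_nie=abs(float(runs.nie_with.mean() - runs.nie_without.mean())),
        n_runs=len(runs), n_skipped=n_skipped,
        runs=runs if keep_runs else None,
    )


def run_grid(base: SensitivityScenario, beta_grid=DEFAULT_BETA_GRID,
             confounder_counts=(1, 2)) -> list:
    """One :class:`SensitivityResult` per (beta, number of confounders)."""
    results = []
    for n_conf in confounder_counts:
        for beta in beta_grid:
            scenario = replace(base, beta_u=float(beta), n_confounders=n_conf)
            results.append(run_scenario(scenario))
    return results


def grid_frame(results) -> pd.DataFrame:
    """Tidy frame of grid results for reporting."""
    rows = []
    for res in results:
        row = res.scenario.to_dict()
        row.update(match_proportion=res.match_proportion,
                   avg_abs_diff_nde=res.avg_abs_diff_nde,
                   avg_abs_diff_nie=res.avg_abs_diff_nie,
                   avg_abs_diff=res.avg_abs_diff)
        rows.append(row)
    return pd.DataFrame(rows)
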