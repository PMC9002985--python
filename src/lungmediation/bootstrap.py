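"""Non-bias-corrected percentile bootstrap over parent clusters.

The family (parent) is the resampling unit: parents are drawn with
replacement to the original parent count and each drawn parent contributes
all of their offspring. Offspring-sex groups are re-formed within each
resample, the multi-group model is refitted (warm-started from the
full-sample estimates), and every natural-effect component and
sons-minus-daughters difference is recomputed. Confidence intervals are
plain empirical percentiles of the per-resample distributions -- no bias
correction, no acceleration -- with the sons-minus-daughters intervals taken
from the per-resample *differences*, not by differencing marginal
intervals. An effect is flagged significant when its interval excludes
zero (boundary inclusive: an interval touching zero is not significant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coefficients import CONTRASTS, ModelSpec
from .cohort import CohortTable
from .effects import EFFECT_NAMES, decompose_effects
from .model import FitError, GroupData, _fit_em, fit_multigroup_model
from .util import rng_from

logger = logging.getLogger(__name__)


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapConfig:
    """Resampling configuration.

    ``b`` resamples (shipped pipeline default 10,000); percentile levels in
    percent; refits that fail or do not converge are dropped and counted,
    with a hard error if the successful fraction falls below
    ``min_success``.
    """

    b: int = 10_000
    seed: int = 0
    levels: tuple = (2.5, 97.5)
    min_success: float = 0.95
    refit_tol: float = 1e-8
    refit_max_iter: int = 1500

    def validate(self) -> "BootstrapConfig":
        if self.b < 1:
            raise BootstrapError("resample count must be >= 1")
        lo, hi = self.levels
        if not (0 < lo < hi < 100) or abs((lo + hi) - 100.0) > 1e-9:
            raise BootstrapError("percentile levels must be symmetric within (0, 100)")
        if not (0 <= self.min_success <= 1):
            raise BootstrapError("min_success must lie in [0, 1]")
        return self


@dataclass
class BootstrapSummary:
    """Point estimates with percentile intervals per effect and per delta.

    ``table`` columns: contrast, group (son/daughter/delta), outcome,
    effect, estimate, lower, upper, significant. Percentile intervals need
    not contain the point estimate; ``lower <= upper`` always holds.
    """

    table: pd.DataFrame
    n_resamples: int
    n_successful: int
    levels: tuple
    coefficient_draws: dict = field(default_factory=dict)

    def get(self, contrast: str, group: str, outcome: str, effect: str):
        rows = self.table[(self.table.contrast == contrast) &
                          (self.table.group == group) &
                          (self.table.outcome == outcome) &
                          (self.table.effect == effect)]
        if rows.empty:
            raise KeyError((contrast, group, outcome, effect))
        return rows.iloc[0]


def percentile_ci(values, levels=(2.5, 97.5)):
    """Empirical-percentile interval, linear interpolation between order
    statistics (no bias correction)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise BootstrapError("cannot form a percentile interval from no values")
    lo, hi = np.percentile(values, levels, method="linear")
    return float(lo), float(hi)


def _interval_significant(lower: float, upper: float) -> bool:
    return lower > 0.0 or upper < 0.0


def significance_flags(summary: BootstrapSummary) -> pd.Series:
    """Recompute the CI-excludes-zero flag for every row of a summary."""
    return summary.table.apply(
        lambda row: _interval_significant(row.lower, row.upper), axis=1)


# ---------------------------------------------------------------------------
# resampling machinery
# ---------------------------------------------------------------------------

def _gather_rows(starts, counts, parent_draw):
    """Row indices of all offspring of the drawn parents (vectorised)."""
    lengths = counts[parent_draw]
    total = int(lengths.sum())
    first = np.repeat(starts[parent_draw], lengths)
    offsets = np.arange(total) - np.repeat(np.cumsum(lengths) - lengths, lengths)
    return first + offsets


def resample_clusters(table: CohortTable, seed, line: str | None = None) -> CohortTable:
    """One cluster resample of a cohort table.

    Parents are drawn with replacement to the original parent count; each
    drawn parent contributes all their offspring. Parents drawn more than
    once receive distinct synthetic cluster ids so downstream code never
    conflates independent resampled families.
    """
    sub = table.for_line(line) if line is not None else table
    if len(sub) == 0:
        raise BootstrapError("cannot resample an empty table")
    df = sub.df.sort_values("parent_id", kind="stable").reset_index(drop=True)
    codes, uniques = pd.factorize(df.parent_id, sort=True)
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    rng = rng_from(seed)
    draw = rng.integers(0, len(uniques), size=len(uniques))
    rows = _gather_rows(starts, counts, draw)
    out = df.iloc[rows].reset_index(drop=True)
    new_parent = np.repeat(
        [f"{uniques[p]}#{j}" for j, p in enumerate(draw)], counts[draw])
    out["parent_id"] = new_parent
    out["offspring_id"] = [f"r{i:06d}" for i in range(len(out))]
    return CohortTable(out, provenance=f"resample(seed={seed}) of {sub.provenance}")


class _ResamplePlan:
    """Pre-extracted arrays for fast repeated cluster resampling."""

    def __init__(self, table: CohortTable, spec: ModelSpec):
        df = table.for_line(spec.line).df
        src1, src2 = spec.source_columns()
        df = df[df[src1].notna() & df[src2].notna()]
        df = df.sort_values("parent_id", kind="stable").reset_index(drop=True)
        if df.empty:
            raise BootstrapError("no complete records to resample")
        codes, uniques = pd.factorize(df.parent_id, sort=True)
        self.n_parents = len(uniques)
        self.counts = np.bincount(codes)
        self.starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]])
        self.is_son = (df.sex == "son").to_numpy()
        ones = np.ones(len(df))
        e1 = (df.parent_exposure == "before_puberty").to_numpy(float)
        e2 = (df.parent_exposure == "at30_not_before").to_numpy(float)
        edu = df.parent_edu_low.to_numpy(float)
        self.xm = np.column_stack([ones, e1, e2, edu])
        self.xy = np.column_stack([ones, e1, e2, edu, df.age.to_numpy(float),
                                   df.ever_smoker.to_numpy(float)])
        self.m1 = df.m1_overweight_prepuberty.to_numpy(bool)
        self.m2 = df.height_cm.to_numpy(float)
        if spec.outcome_set == "fev1_fvc_pair":
            self.y = df[[src1, src2]].to_numpy(float)
        else:
            self.y = (100.0 * df[src1].to_numpy(float)
                      / df[src2].to_numpy(float))[:, None]
        self.ids = df.offspring_id.to_numpy()
        self.outcomes = spec.outcome_names()

    def group_data(self, rows, group: str) -> GroupData:
        mask = self.is_son[rows] if group == "son" else ~self.is_son[rows]
        sel = rows[mask]
        return GroupData(ids=self.ids[sel], xm=self.xm[sel], xy=self.xy[sel],
                         m1=self.m1[sel], m2=self.m2[sel], y=self.y[sel],
                         outcomes=self.outcomes)


def _effect_rows(spec: ModelSpec):
    rows = []
    for contrast in CONTRASTS:
        for outcome in spec.outcome_names():
            for group in spec.groups:
                for effect in EFFECT_NAMES:
                    rows.append((contrast, group, outcome, effect))
            for effect in EFFECT_NAMES:
                rows.append((contrast, "delta", outcome, effect))
    return rows


def _effect_vector(coefs_by_group, spec: ModelSpec, rows) -> np.ndarray:
    decomps = {}
    for group, cf in coefs_by_group.items():
        for contrast in CONTRASTS:
            for outcome in spec.outcome_names():
                decomps[(contrast, group, outcome)] = decompose_effects(
                    cf, contrast, group, outcome)
    out = np.empty(len(rows))
    for i, (contrast, group, outcome, effect) in enumerate(rows):
        if group == "delta":
            out[i] = (decomps[(contrast, "son", outcome)].value(effect)
                      - decomps[(contrast, "daughter", outcome)].value(effect))
        else:
            out[i] = decomps[(contrast, group, outcome)].value(effect)
    return out


def bootstrap_effects(table: CohortTable, spec: ModelSpec,
                      config: BootstrapConfig,
                      keep_coefficients: bool = False) -> BootstrapSummary:
    """Cluster-bootstrap intervals for every effect and group difference.

    The full-sample multi-group fit provides both the point estimates and
    the warm start for every refit. With ``keep_coefficients`` the
    per-resample coefficient vectors are retained (used for bootstrap
    standard errors in validation).
    """
    config.validate()
    full = fit_multigroup_model(table, spec)
    full_coefs = {g: r.coefficients for g, r in full.items()}
    plan = _ResamplePlan(table, spec)
    rows = _effect_rows(spec)
    point = _effect_vector(full_coefs, spec, rows)

    rng = rng_from(config.seed)
    draws = np.empty((config.b, len(rows)))
    coef_draws = {g: [] for g in spec.groups} if keep_coefficients else None
    n_ok = 0
    n_failed = 0
    for _ in range(config.b):
        parent_draw = rng.integers(0, plan.n_parents, size=plan.n_parents)
        sel = _gather_rows(plan.starts, plan.counts, parent_draw)
        try:
            coefs = {}
            for group in spec.groups:
                gd = plan.group_data(sel, group)
                if gd.n == 0 or gd.m1.min() == gd.m1.max():
                    raise FitError(f"degenerate resample for group {group}")
                cf, converged, _, _ = _fit_em(gd, full_coefs[group],
                                              config.refit_tol,
                                              config.refit_max_iter)
                if not converged:
                    raise FitError(f"refit not converged for group {group}")
                coefs[group] = cf
        except (FitError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.debug("dropped resample: %s", exc)
            continue
        draws[n_ok] = _effect_vector(coefs, spec, rows)
        if keep_coefficients:
            for g in spec.groups:
                coef_draws[g].append(coefs[g].to_vector())
        n_ok += 1

    if n_ok < config.min_success * config.b:
        raise BootstrapError(
            f"only {n_ok}/{config.b} resamples refitted successfully "
            f"({n_failed} dropped); threshold {config.min_success:.0%}")
    if n_failed:
        logger.info("dropped %d/%d bootstrap refits", n_failed, config.b)

    draws = draws[:n_ok]
    records = []
    for i, (contrast, group, outcome, effect) in enumerate(rows):
        lower, upper = percentile_ci(draws[:, i], config.levels)
        records.append({
            "contrast": contrast, "group": group, "outcome": outcome,
            "effect": effect, "estimate": point[i],
            "lower": lower, "upper": upper,
            "significant": _interval_significant(lower, upper),
        })
    return BootstrapSummary(
        table=pd.DataFrame(records), n_resamples=config.b, n_successful=n_ok,
        levels=tuple(config.levels),
        coefficient_draws={g: np.asarray(v) for g, v in (coef_draws or {}).items()},
    )
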