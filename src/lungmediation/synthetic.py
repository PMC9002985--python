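"""Synthetic two-generation cohort generator.

Generates parent-offspring data from exactly the structural model the
estimator assumes: a three-level parental prepubertal-overweight exposure,
a latent-probit offspring-overweight mediator (threshold at zero, unit
residual variance), a linear adult-height equation, and correlated
bivariate-normal FEV1/FVC outcomes. Offspring of the same parent share the
parent's exposure and education (the family cluster), while all offspring
residuals are independent.

Defaults emulate the marginal structure of a European two-generation
respiratory-health cohort: exposure prevalences, parental education, family
sizes, offspring sex ratio, age ranges, smoking, and sex-specific height
and lung-function means/sds. The structural path coefficients default to a
published set of paternal/maternal-line estimates; equation intercepts and
residual scales are then *solved in closed form* so that the implied
marginal means and standard deviations hit the cohort targets exactly
(everything is linear-Gaussian within discrete covariate cells, so the
implied moments are available analytically).

The generator also returns oracle columns -- the latent mediator value per
offspring and the true effect decomposition per group -- so estimators can
be validated against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coefficients import (EXPOSURE_LEVELS, GROUPS, LINES,
                           PathCoefficients)
from .cohort import CohortTable
from .effects import EffectDecomposition, decompose_all
from .util import rng_from

OUTCOMES = ("fev1_ml", "fvc_ml")


class GeneratorError(ValueError):
    """Invalid generator parameterisation."""


@dataclass
class GeneratorParams:
    """Full parameterisation of the synthetic cohort.

    ``exposure_probs`` are the parent-level exposure-category probabilities
    (must sum to 1); ``offspring_dist`` the family-size distribution on
    {1, 2, 3}; ``p_smoker`` offspring smoking probability per sex group;
    ``coefficients`` one :class:`PathCoefficients` per group.
    """

    line: str
    exposure_probs: dict
    p_edu_low: float
    offspring_dist: dict
    p_son: float
    age_range: tuple
    p_smoker: dict
    coefficients: dict
    post_bronchodilator: bool = True

    def validate(self) -> "GeneratorParams":
        if self.line not in LINES:
            raise GeneratorError(f"unknown line {self.line!r}")
        probs = [self.exposure_probs.get(lvl) for lvl in EXPOSURE_LEVELS]
        if any(p is None or not (0 <= p <= 1) for p in probs) or \
                abs(sum(probs) - 1.0) > 1e-9:
            raise GeneratorError("exposure probabilities must lie in [0,1] and sum to 1")
        if not (0 <= self.p_edu_low <= 1 and 0 <= self.p_son <= 1):
            raise GeneratorError("probabilities must lie in [0,1]")
        od = self.offspring_dist
        if set(od) - {1, 2, 3} or abs(sum(od.values()) - 1.0) > 1e-9 or \
                any(p < 0 for p in od.values()):
            raise GeneratorError("offspring-per-parent distribution must be on {1,2,3}")
        lo, hi = self.age_range
        if not (18 <= lo < hi):
            raise GeneratorError("age range must satisfy 18 <= lo < hi")
        for g in GROUPS:
            if g not in self.p_smoker or not (0 <= self.p_smoker[g] <= 1):
                raise GeneratorError(f"missing/invalid smoking probability for {g!r}")
            if g not in self.coefficients:
                raise GeneratorError(f"missing coefficients for group {g!r}")
            self.coefficients[g].validate()
        return self

    def to_dict(self) -> dict:
        return {
            "line": self.line, "exposure_probs": dict(self.exposure_probs),
            "p_edu_low": self.p_edu_low,
            "offspring_dist": {int(k): v for k, v in self.offspring_dist.items()},
            "p_son": self.p_son, "age_range": list(self.age_range),
            "p_smoker": dict(self.p_smoker),
            "coefficients": {g: c.to_dict() for g, c in self.coefficients.items()},
            "post_bronchodilator": self.post_bronchodilator,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GeneratorParams":
        payload = dict(payload)
        payload["offspring_dist"] = {int(k): v for k, v
                                     in payload["offspring_dist"].items()}
        payload["age_range"] = tuple(payload["age_range"])
        payload["coefficients"] = {g: PathCoefficients.from_dict(c)
                                   for g, c in payload["coefficients"].items()}
        return cls(**payload).validate()


@dataclass
class OracleColumns:
    """Ground truth carried alongside a generated table.

    ``m1_star`` is the latent mediator value per offspring row (the binary
    mediator equals ``m1_star > 0`` exactly); ``true_effects`` are the
    effect decompositions implied by the generating coefficients.
    """

    offspring_id: np.ndarray
    m1_star: np.ndarray
    true_effects: list

    def effect(self, contrast: str, group: str, outcome: str) -> EffectDecomposition:
        for e in self.true_effects:
            if (e.contrast, e.group, e.outcome) == (contrast, group, outcome):
                return e
        raise KeyError((contrast, group, outcome))


# ---------------------------------------------------------------------------
# default parameterisation and closed-form calibration
# ---------------------------------------------------------------------------

# marginal targets the defaults are calibrated to, per line
_TARGETS = {
    "paternal": {
        "exposure_probs": {"before_puberty": 0.120, "at30_not_before": 0.104,
                           "never": 0.776},
        "p_edu_low": 0.084,
        "p_son": 197 / 420,
        "age_range": (18.0, 51.0),
        "p_smoker": {"son": 0.284, "daughter": 0.224},
        "m1_prevalence": {"son": 0.127, "daughter": 0.296},
        "height": {"son": (181.0, 6.5), "daughter": (168.0, 6.3)},
        "fev1_ml": {"son": (4387.0, 629.0), "daughter": (3277.0, 405.0)},
        "fvc_ml": {"son": (5490.0, 727.0), "daughter": (3987.0, 492.0)},
    },
    "maternal": {
        "exposure_probs": {"before_puberty": 0.250, "at30_not_before": 0.229,
                           "never": 0.521},
        "p_edu_low": 0.101,
        "p_son": 232 / 510,
        "age_range": (18.0, 54.0),
        "p_smoker": {"son": 0.302, "daughter": 0.345},
        "m1_prevalence": {"son": 0.177, "daughter": 0.227},
        "height": {"son": (181.0, 6.4), "daughter": (168.0, 6.6)},
        "fev1_ml": {"son": (4430.0, 620.0), "daughter": (3238.0, 500.0)},
        "fvc_ml": {"son": (5537.0, 761.0), "daughter": (3957.0, 568.0)},
    },
}

# structural path defaults (probit paths unitless; height paths in cm;
# outcome paths in mL), per line x group:
#   a1, a2       exposure -> latent overweight
#   h1, h2       exposure -> height
#   d            latent overweight -> height
#   per outcome: c1, c2 (direct), b1 (latent overweight ->), b2 (height ->)
_STRUCTURAL = {
    ("paternal", "son"): {
        "a": (0.56, 0.07), "h": (-3.42, -0.17), "d": 0.37,
        "fev1_ml": {"c": (-164.0, -15.0), "b1": 36.0, "b2": 42.0},
        "fvc_ml": {"c": (-262.0, -43.0), "b1": 54.0, "b2": 61.0},
    },
    ("paternal", "daughter"): {
        "a": (0.83, -0.02), "h": (-2.11, -0.20), "d": -1.17,
        "fev1_ml": {"c": (26.0, 51.0), "b1": 32.0, "b2": 30.0},
        "fvc_ml": {"c": (78.0, 64.0), "b1": 48.0, "b2": 41.0},
    },
    ("maternal", "son"): {
        "a": (0.59, 0.54), "h": (0.10, 1.41), "d": 1.38,
        "fev1_ml": {"c": (115.0, 98.0), "b1": 114.0, "b2": 53.0},
        "fvc_ml": {"c": (124.0, 116.0), "b1": 35.0, "b2": 75.0},
    },
    ("maternal", "daughter"): {
        "a": (0.52, 0.30), "h": (-0.12, 1.10), "d": 0.57,
        "fev1_ml": {"c": (160.0, 186.0), "b1": 82.0, "b2": 42.0},
        "fvc_ml": {"c": (110.0, 180.0), "b1": 83.0, "b2": 53.0},
    },
}

# covariate adjustment defaults, common across lines and groups:
# education (low) on the latent mediator / height; and per outcome the
# education, age (per year) and smoking coefficients -- chosen once at
# physiologically plausible magnitudes (adult FEV1 declines on the order of
# tens of mL per year; smokers show a deficit)
_G1_EDU = 0.25
_G2_EDU = -1.0
_THETA = {"fev1_ml": (-40.0, -25.0, -80.0), "fvc_ml": (-50.0, -20.0, -60.0)}
_OUTCOME_RESIDUAL_CORR = 0.7
_OFFSPRING_DIST = {1: 0.70, 2: 0.25, 3: 0.05}


def _cells(exposure_probs: dict, p_edu: float, p_smoke: float):
    """Enumerate discrete covariate cells with probabilities.

    Yields (prob, e1, e2, edu, smoke); exposure, education and smoking are
    generated independently.
    """
    for lvl, pe in exposure_probs.items():
        e1 = 1.0 if lvl == "before_puberty" else 0.0
        e2 = 1.0 if lvl == "at30_not_before" else 0.0
        for edu, ped in ((1.0, p_edu), (0.0, 1 - p_edu)):
            for smoke, ps in ((1.0, p_smoke), (0.0, 1 - p_smoke)):
                yield pe * ped * ps, e1, e2, edu, smoke


def _calibrate_group(line: str, group: str, targets: dict) -> PathCoefficients:
    """Solve intercepts and residual scales for one group's coefficients."""
    struct = _STRUCTURAL[(line, group)]
    a1, a2 = struct["a"]
    h1, h2 = struct["h"]
    d = struct["d"]
    p_smoke = targets["p_smoker"][group]
    cells = list(_cells(targets["exposure_probs"], targets["p_edu_low"], p_smoke))
    probs = np.array([c[0] for c in cells])
    e1 = np.array([c[1] for c in cells])
    e2 = np.array([c[2] for c in cells])
    edu = np.array([c[3] for c in cells])
    smoke = np.array([c[4] for c in cells])

    # mediator threshold intercept from the target overweight prevalence
    target_prev = targets["m1_prevalence"][group]

    def prevalence(a0):
        return float(probs @ stats.norm.cdf(a0 + a1 * e1 + a2 * e2 + _G1_EDU * edu)) \
            - target_prev

    a0 = optimize.brentq(prevalence, -10.0, 10.0, xtol=1e-12)
    z_m = a0 + a1 * e1 + a2 * e2 + _G1_EDU * edu  # E[M1* | cell]

    # height intercept and residual sd from the target mean/sd
    mean_h, sd_h = targets["height"][group]
    mu2_no_int = h1 * e1 + h2 * e2 + _G2_EDU * edu + d * z_m
    h0 = mean_h - float(probs @ mu2_no_int)
    mu2 = h0 + mu2_no_int
    var_cells_h = float(probs @ mu2 ** 2 - (probs @ mu2) ** 2)
    resid_var_h = sd_h ** 2 - var_cells_h - d ** 2
    if resid_var_h <= 0.25:
        raise GeneratorError(
            f"height paths for {line}/{group} explain more variance than the "
            f"target sd {sd_h} allows")
    sigma_h = float(np.sqrt(resid_var_h))

    age_lo, age_hi = targets["age_range"]
    age_mean = 0.5 * (age_lo + age_hi)
    age_var = (age_hi - age_lo) ** 2 / 12.0

    c = np.zeros((2, 6))
    b1 = np.zeros(2)
    b2 = np.zeros(2)
    sds = np.zeros(2)
    for k, outcome in enumerate(OUTCOMES):
        blk = struct[outcome]
        th_edu, th_age, th_smoke = _THETA[outcome]
        b1[k], b2[k] = blk["b1"], blk["b2"]
        c1, c2 = blk["c"]
        mean_y, sd_y = targets[outcome][group]
        mu_no_int = (c1 * e1 + c2 * e2 + th_edu * edu + th_smoke * smoke
                     + b1[k] * z_m + b2[k] * mu2)
        c0 = mean_y - float(probs @ mu_no_int) - th_age * age_mean
        mu_y = c0 + mu_no_int
        var_cells_y = float(probs @ mu_y ** 2 - (probs @ mu_y) ** 2)
        explained = (var_cells_y + th_age ** 2 * age_var
                     + (b1[k] + b2[k] * d) ** 2 + b2[k] ** 2 * sigma_h ** 2)
        resid_var_y = sd_y ** 2 - explained
        if resid_var_y <= 100.0:  # demand a nontrivial residual (>= 10 mL sd)
            raise GeneratorError(
                f"outcome paths for {line}/{group}/{outcome} explain more "
                f"variance than the target sd {sd_y} allows")
        sds[k] = np.sqrt(resid_var_y)
        c[k] = (c0, c1, c2, th_edu, th_age, th_smoke)

    sigma = np.array([
        [sds[0] ** 2, _OUTCOME_RESIDUAL_CORR * sds[0] * sds[1]],
        [_OUTCOME_RESIDUAL_CORR * sds[0] * sds[1], sds[1] ** 2],
    ])
    return PathCoefficients(
        a=np.array([a0, a1, a2, _G1_EDU]),
        h=np.array([h0, h1, h2, _G2_EDU]),
        d=d, sigma_h=sigma_h, outcomes=OUTCOMES,
        c=c, b1=b1, b2=b2, sigma=sigma,
    ).validate()


def default_generator_params(line: str) -> GeneratorParams:
    """Default cohort conditions for one parental line.

    Prevalences, family sizes, sex ratio, ages, smoking, and the structural
    path coefficients are fixed study conditions; intercepts and residual
    scales are solved so that the implied marginal means and sds of the
    latent mediator, height, FEV1 and FVC match the per-sex targets exactly.
    """
    if line not in LINES:
        raise GeneratorError(f"unknown line {line!r}")
    t = _TARGETS[line]
    coefs = {g: _calibrate_group(line, g, t) for g in GROUPS}
    return GeneratorParams(
        line=line,
        exposure_probs=dict(t["exposure_probs"]),
        p_edu_low=t["p_edu_low"],
        offspring_dist=dict(_OFFSPRING_DIST),
        p_son=t["p_son"],
        age_range=t["age_range"],
        p_smoker=dict(t["p_smoker"]),
        coefficients=coefs,
    ).validate()


def implied_marginal_targets(line: str) -> dict:
    """The per-sex marginal means/sds the default parameters are solved to."""
    return _TARGETS[line]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

# bronchodilator response added on top of the pre-bronchodilator values
# (mean shift in mL, noise sd); present for 95% of offspring
_POST_SHIFT = {"fev1_ml": (130.0, 80.0), "fvc_ml": (-20.0, 80.0)}
_POST_AVAILABILITY = 0.95


def generate_cohort(params: GeneratorParams, n_parents: int, seed):
    """Sample a cohort of ``n_parents`` families.

    Returns ``(table, oracle)``; identical ``(params, n_parents, seed)``
    produce identical output.
    """
    params.validate()
    if n_parents < 1:
        raise GeneratorError("n_parents must be >= 1")
    rng = rng_from(seed)

    exp_levels = list(EXPOSURE_LEVELS)
    exp_p = np.array([params.exposure_probs[lvl] for lvl in exp_levels])
    exposure_parent = rng.choice(len(exp_levels), size=n_parents, p=exp_p)
    edu_parent = rng.random(n_parents) < params.p_edu_low
    sizes = np.array(sorted(params.offspring_dist))
    size_p = np.array([params.offspring_dist[int(s)] for s in sizes])
    n_off_parent = sizes[rng.choice(len(sizes), size=n_parents, p=size_p)]

    parent_idx = np.repeat(np.arange(n_parents), n_off_parent)
    n = parent_idx.size
    e_cat = exposure_parent[parent_idx]
    e1 = (e_cat == 0).astype(float)
    e2 = (e_cat == 1).astype(float)
    edu = edu_parent[parent_idx].astype(float)
    is_son = rng.random(n) < params.p_son
    age = rng.uniform(*params.age_range, size=n)
    p_smk = np.where(is_son, params.p_smoker["son"], params.p_smoker["daughter"])
    smoke = (rng.random(n) < p_smk).astype(float)

    m1_star = np.empty(n)
    m2 = np.empty(n)
    y = np.empty((n, 2))
    eps1 = rng.standard_normal(n)
    eps2 = rng.standard_normal(n)
    eta = rng.standard_normal((n, 2))
    for g, mask in (("son", is_son), ("daughter", ~is_son)):
        cf = params.coefficients[g]
        idx = np.where(mask)[0]
        z_m = cf.a[0] + cf.a[1] * e1[idx] + cf.a[2] * e2[idx] + cf.a[3] * edu[idx]
        m1_star[idx] = z_m + eps1[idx]
        lin_h = cf.h[0] + cf.h[1] * e1[idx] + cf.h[2] * e2[idx] + cf.h[3] * edu[idx]
        m2[idx] = lin_h + cf.d * m1_star[idx] + cf.sigma_h * eps2[idx]
        xw = np.column_stack([np.ones(idx.size), e1[idx], e2[idx],
                              edu[idx], age[idx], smoke[idx]])
        lin_y = xw @ cf.c.T
        chol = np.linalg.cholesky(cf.sigma)
        y[idx] = (lin_y + np.outer(m1_star[idx], cf.b1)
                  + np.outer(m2[idx], cf.b2) + eta[idx] @ chol.T)

    m1 = m1_star > 0

    df = pd.DataFrame({
        "offspring_id": [f"o{i:06d}" for i in range(n)],
        "parent_id": [f"p{i:05d}" for i in parent_idx],
        "line": params.line,
        "sex": np.where(is_son, "son", "daughter"),
        "age": age,
        "ever_smoker": smoke.astype(bool),
        "m1_overweight_prepuberty": m1,
        "height_cm": m2,
        "fev1_ml": y[:, 0],
        "fvc_ml": y[:, 1],
        "fev1_post_ml": np.nan,
        "fvc_post_ml": np.nan,
        "parent_edu_low": edu.astype(bool),
        "parent_exposure": [exp_levels[i] for i in e_cat],
    })
    if params.post_bronchodilator:
        have_post = rng.random(n) < _POST_AVAILABILITY
        for col, src in (("fev1_post_ml", "fev1_ml"), ("fvc_post_ml", "fvc_ml")):
            shift, noise = _POST_SHIFT[src]
            vals = df[src] + shift + noise * rng.standard_normal(n)
            df.loc[have_post, col] = vals[have_post]

    table = CohortTable(df, provenance=f"synthetic(line={params.line}, "
                                       f"n_parents={n_parents}, seed={seed})")
    oracle = OracleColumns(
        offspring_id=df["offspring_id"].to_numpy(),
        m1_star=m1_star,
        true_effects=decompose_all(params.coefficients),
    )
    return table, oracle


def attach_latent_oracle(table: CohortTable, oracle: OracleColumns) -> CohortTable:
    """Return the table extended with the latent ``m1_star`` column."""
    ids = table.df["offspring_id"].to_numpy()
    if ids.shape != oracle.offspring_id.shape or \
            not np.array_equal(ids, oracle.offspring_id):
        raise GeneratorError("oracle columns are not aligned with the table")
    out = table.with_column("m1_star", oracle.m1_star)
    observed = out.df["m1_overweight_prepuberty"].to_numpy()
    if not np.array_equal(observed, oracle.m1_star > 0):
        raise GeneratorError("latent oracle inconsistent with the binary mediator")
    return out
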