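"""Full-information maximum likelihood for the serial-mediation model.

Estimation targets the structural system documented in
:mod:`lungmediation.coefficients`: a latent-probit prepubertal-overweight
mediator (residual variance fixed at 1, threshold at 0), a linear height
equation that regresses on the *latent* mediator, and linear outcome
equations with correlated Gaussian residuals, fitted separately per
offspring-sex group (multi-group moderation) with no cross-group
constraints.

Likelihood
----------
Conditional on the covariates, the latent vector (M1*, M2, Y) is jointly
Gaussian, so the latent residual integrates out in closed form: with
V = (M2, Y) and eps1 the latent residual,

    f(M1, V | X) = N(V; mu_V, Omega) * Phi( q * (z_m + m) / tau ),

where z_m is the mediator-equation linear predictor, m and tau^2 are the
conditional mean and variance of eps1 given V, and q = +1/-1 encodes the
observed side of the threshold. The observed-data likelihood is therefore
evaluated exactly (no quadrature), and the same conditional-Gaussian
reduction yields the truncated-normal moments used by the EM algorithm.

Optimisation
------------
EM with closed-form M-steps: given the conditional first and second moments
of M1*, every M-step is a (multivariate) least-squares update. EM ascends
the observed-data log-likelihood monotonically; convergence is declared on
a relative log-likelihood change below ``tol``. Non-converged fits are
retried from jittered starting values, best likelihood wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .coefficients import (GROUPS, CoefficientError, ModelSpec,
                           PathCoefficients)
from .cohort import CohortTable
from .util import rng_from

logger = logging.getLogger(__name__)

_SQRT_2OPI = np.sqrt(2.0 / np.pi)
_LOG_2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    """Estimation could not proceed (degenerate data, invalid inputs)."""


@dataclass
class FitResult:
    """Outcome of one group's fit."""

    group: str
    coefficients: PathCoefficients
    converged: bool
    loglik: float
    n_iter: int
    n_obs: int

    def to_dict(self) -> dict:
        return {"schema_version": 1, "group": self.group,
                "coefficients": self.coefficients.to_dict(),
                "converged": self.converged, "loglik": self.loglik,
                "n_iter": self.n_iter, "n_obs": self.n_obs}

    @classmethod
    def from_dict(cls, payload: dict) -> "FitResult":
        payload = {k: v for k, v in payload.items() if k != "schema_version"}
        payload["coefficients"] = PathCoefficients.from_dict(payload["coefficients"])
        return cls(**payload)


@dataclass
class GroupData:
    """Numpy view of one group's complete-case analysis data."""

    ids: np.ndarray
    xm: np.ndarray   # (n, 4) mediator/height design
    xy: np.ndarray   # (n, 6) outcome design
    m1: np.ndarray   # (n,) bool
    m2: np.ndarray   # (n,) height, cm
    y: np.ndarray    # (n, K) outcomes
    outcomes: tuple

    @property
    def n(self) -> int:
        return self.m1.size


def build_group_data(table: CohortTable, spec: ModelSpec, group: str) -> GroupData:
    """Extract one group's arrays for the spec's outcome set.

    Post-bronchodilator specs keep only rows with a complete post pair
    (complete-case per analysis).
    """
    if group not in GROUPS:
        raise FitError(f"unknown group {group!r}")
    df = table.for_line(spec.line).df
    df = df[df.sex == group]
    src1, src2 = spec.source_columns()
    df = df[df[src1].notna() & df[src2].notna()]
    if df.empty:
        raise FitError(f"no complete records for group {group!r} "
                       f"({spec.line}, {spec.bronchodilator})")
    e1 = (df.parent_exposure == "before_puberty").to_numpy(float)
    e2 = (df.parent_exposure == "at30_not_before").to_numpy(float)
    edu = df.parent_edu_low.to_numpy(float)
    ones = np.ones(len(df))
    xm = np.column_stack([ones, e1, e2, edu])
    xy = np.column_stack([ones, e1, e2, edu,
                          df.age.to_numpy(float), df.ever_smoker.to_numpy(float)])
    if spec.outcome_set == "fev1_fvc_pair":
        y = df[[src1, src2]].to_numpy(float)
    else:
        y = (100.0 * df[src1].to_numpy(float) / df[src2].to_numpy(float))[:, None]
    return GroupData(ids=df.offspring_id.to_numpy(), xm=xm, xy=xy,
                     m1=df.m1_overweight_prepuberty.to_numpy(bool),
                     m2=df.height_cm.to_numpy(float), y=y,
                     outcomes=spec.outcome_names())


# ---------------------------------------------------------------------------
# exact observed-data likelihood and conditional (E-step) moments
# ---------------------------------------------------------------------------

def _estep(gd: GroupData, cf: PathCoefficients):
    """One pass over the data: log-likelihood and conditional moments.

    Returns ``(loglik, e1m, e2m, per_row_loglik)`` where ``e1m``/``e2m`` are
    the conditional first/second moments of the latent mediator M1* given
    all observed data.
    """
    n, k = gd.n, cf.n_outcomes
    z_m = gd.xm @ cf.a
    lin_h = gd.xm @ cf.h
    mu_m2 = lin_h + cf.d * z_m
    lin_y = gd.xy @ cf.c.T
    mu_y = lin_y + np.outer(z_m, cf.b1) + mu_m2[:, None] * cf.b2

    s = np.concatenate([[cf.d], cf.b1 + cf.b2 * cf.d])          # Cov(V, eps1)
    v = np.concatenate([[1.0], cf.b2])                           # eps2 loading
    omega = np.outer(s, s) + cf.sigma_h ** 2 * np.outer(v, v)
    omega[1:, 1:] += cf.sigma
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise FitError("residual covariance not positive definite")
    omega_inv = np.linalg.inv(omega)  # (1+K) x (1+K), K <= 2

    r = np.empty((n, 1 + k))
    r[:, 0] = gd.m2 - mu_m2
    r[:, 1:] = gd.y - mu_y

    # Gaussian part of the log-likelihood
    ri = r @ omega_inv
    ll_gauss = -0.5 * ((1 + k) * _LOG_2PI + logdet
                       + np.einsum("ij,ij->i", ri, r))

    # conditional distribution of eps1 | V
    w = omega_inv @ s
    tau2 = 1.0 - float(s @ w)
    tau2 = max(tau2, 1e-12)
    tau = np.sqrt(tau2)
    m = r @ w

    q = np.where(gd.m1, 1.0, -1.0)
    u = (z_m + m) / tau
    ll_probit = special.log_ndtr(q * u)
    row_ll = ll_gauss + ll_probit

    # truncated-normal moments of eps1 given V and the threshold side
    t = -z_m
    alpha = (t - m) / tau
    lam_low = _SQRT_2OPI / special.erfcx(alpha / np.sqrt(2.0))    # eps1 > t
    lam_up = _SQRT_2OPI / special.erfcx(-alpha / np.sqrt(2.0))    # eps1 < t
    e_eps = np.where(gd.m1, m + tau * lam_low, m - tau * lam_up)
    e_eps2 = np.where(gd.m1,
                      m ** 2 + tau2 + tau * lam_low * (t + m),
                      m ** 2 + tau2 - tau * lam_up * (t + m))
    e1m = z_m + e_eps
    e2m = z_m ** 2 + 2.0 * z_m * e_eps + e_eps2
    return float(row_ll.sum()), e1m, e2m, row_ll


def observed_loglik(table, spec: ModelSpec, group: str,
                    coefficients: PathCoefficients) -> float:
    """Exact observed-data log-likelihood of one group at given coefficients.

    The latent mediator residual is marginalised analytically (see module
    docstring); the result is deterministic. Raises if any row yields a
    non-finite density.
    """
    gd = table if isinstance(table, GroupData) else \
        build_group_data(table, spec, group)
    coefficients.validate()
    ll, _, _, row_ll = _estep(gd, coefficients)
    if not np.all(np.isfinite(row_ll)):
        bad = gd.ids[~np.isfinite(row_ll)][0]
        raise FitError(f"non-finite likelihood contribution at offspring {bad!r}")
    return ll


# ---------------------------------------------------------------------------
# EM fit
# ---------------------------------------------------------------------------

class _Precomputed:
    """Sufficient statistics that do not change across EM iterations."""

    def __init__(self, gd: GroupData):
        self.xtx_m = gd.xm.T @ gd.xm
        self.xt_m2 = gd.xm.T @ gd.m2
        self.m2m2 = float(gd.m2 @ gd.m2)
        self.xty_x = gd.xy.T @ gd.xy
        self.xy_m2 = gd.xy.T @ gd.m2
        self.xy_y = gd.xy.T @ gd.y
        self.m2_y = gd.m2 @ gd.y
        self.yty = gd.y.T @ gd.y


def _mstep(gd: GroupData, pc: _Precomputed, e1m, e2m,
           outcomes) -> PathCoefficients:
    n, k = gd.n, len(outcomes)
    sum_e2m = float(e2m.sum())

    a = np.linalg.solve(pc.xtx_m, gd.xm.T @ e1m)

    # height equation on [X, M1*]
    xt_e1 = gd.xm.T @ e1m
    g5 = np.empty((5, 5))
    g5[:4, :4] = pc.xtx_m
    g5[:4, 4] = g5[4, :4] = xt_e1
    g5[4, 4] = sum_e2m
    r5 = np.concatenate([pc.xt_m2, [float(e1m @ gd.m2)]])
    beta_h = np.linalg.solve(g5, r5)
    sigma_h2 = max((pc.m2m2 - float(beta_h @ r5)) / n, 1e-8)

    # outcome equations on [X, M2, M1*]
    xy_e1 = gd.xy.T @ e1m
    p = 8
    g8 = np.empty((p, p))
    g8[:6, :6] = pc.xty_x
    g8[:6, 6] = g8[6, :6] = pc.xy_m2
    g8[:6, 7] = g8[7, :6] = xy_e1
    g8[6, 6] = pc.m2m2
    g8[6, 7] = g8[7, 6] = float(e1m @ gd.m2)
    g8[7, 7] = sum_e2m
    r8 = np.empty((p, k))
    r8[:6] = pc.xy_y
    r8[6] = pc.m2_y
    r8[7] = e1m @ gd.y
    b = np.linalg.solve(g8, r8)
    sigma = (pc.yty - r8.T @ b) / n
    sigma = 0.5 * (sigma + sigma.T)
    # guard against a collapsing residual covariance in pathological resamples
    sigma += 1e-8 * np.eye(k) * max(np.trace(sigma) / k, 1.0)

    return PathCoefficients(
        a=a, h=beta_h[:4], d=float(beta_h[4]), sigma_h=float(np.sqrt(sigma_h2)),
        outcomes=outcomes, c=b[:6].T, b1=b[7], b2=b[6], sigma=sigma)


def _fit_em(gd: GroupData, init: PathCoefficients, tol: float,
            max_iter: int):
    """EM with squared-extrapolation acceleration.

    Each cycle takes two plain EM steps and then tries a SQUAREM-style
    extrapolated candidate; the candidate is kept only if it improves the
    log-likelihood, so the iteration remains monotone. ``max_iter`` counts
    likelihood evaluations; convergence is a relative log-likelihood change
    below ``tol`` across one EM step.
    """
    pc = _Precomputed(gd)
    cf = init
    ll, e1m, e2m, _ = _estep(gd, cf)
    if not np.isfinite(ll):
        raise FitError("non-finite log-likelihood at the starting values")
    it = 1
    while it < max_iter:
        cf1 = _mstep(gd, pc, e1m, e2m, gd.outcomes)
        ll1, e1m1, e2m1, _ = _estep(gd, cf1)
        it += 1
        if ll1 - ll < tol * (abs(ll1) + 1.0):
            return cf1, True, ll1, it
        cf2 = _mstep(gd, pc, e1m1, e2m1, gd.outcomes)
        ll2, e1m2, e2m2, _ = _estep(gd, cf2)
        it += 1
        if ll2 - ll1 < tol * (abs(ll2) + 1.0):
            return cf2, True, ll2, it

        # squared-extrapolation candidate in the unconstrained space
        t0 = cf.to_vector()
        r = cf1.to_vector() - t0
        v = (cf2.to_vector() - cf1.to_vector()) - r
        vnorm = float(np.linalg.norm(v))
        cf, ll, e1m, e2m = cf2, ll2, e1m2, e2m2
        if vnorm > 0:
            alpha = min(-float(np.linalg.norm(r)) / vnorm, -1.0)
            cand_vec = t0 - 2.0 * alpha * r + alpha ** 2 * v
            try:
                cand = PathCoefficients.from_vector(cand_vec, gd.outcomes)
                llc, e1mc, e2mc, _ = _estep(gd, cand)
                it += 1
                if np.isfinite(llc) and llc > ll2:
                    cf, ll, e1m, e2m = cand, llc, e1mc, e2mc
            except (FitError, CoefficientError, np.linalg.LinAlgError,
                    FloatingPointError, OverflowError):
                pass
    return cf, False, ll, max_iter


def initial_values(table, spec: ModelSpec, group: str) -> PathCoefficients:
    """Deterministic starting values.

    Probit fit of the binary mediator for the threshold equation, then
    plug-in least squares substituting the inverse-Mills conditional mean of
    the latent mediator for the unobserved M1*.
    """
    import statsmodels.api as sm

    gd = table if isinstance(table, GroupData) else \
        build_group_data(table, spec, group)
    m1 = gd.m1.astype(float)
    if m1.min() == m1.max():
        raise FitError(f"degenerate mediator in group {group!r}: "
                       "all records on one side of the threshold")
    probit = sm.Probit(m1, gd.xm).fit(disp=0, maxiter=200)
    a = np.asarray(probit.params, dtype=float)

    z_m = gd.xm @ a
    # E[M1* | M1] under the probit fit (inverse-Mills construction)
    mills_pos = _SQRT_2OPI / special.erfcx(-z_m / np.sqrt(2.0))
    mills_neg = _SQRT_2OPI / special.erfcx(z_m / np.sqrt(2.0))
    m1s_hat = np.where(gd.m1, z_m + mills_pos, z_m - mills_neg)

    wh = np.column_stack([gd.xm, m1s_hat])
    beta_h, *_ = np.linalg.lstsq(wh, gd.m2, rcond=None)
    res_h = gd.m2 - wh @ beta_h
    sigma_h = float(np.sqrt(max(res_h @ res_h / gd.n, 1e-6)))

    wy = np.column_stack([gd.xy, gd.m2, m1s_hat])
    b, *_ = np.linalg.lstsq(wy, gd.y, rcond=None)
    res_y = gd.y - wy @ b
    sigma = res_y.T @ res_y / gd.n
    k = gd.y.shape[1]
    sigma += 1e-6 * np.eye(k) * max(np.trace(sigma) / k, 1.0)

    return PathCoefficients(
        a=a, h=beta_h[:4], d=float(beta_h[4]), sigma_h=sigma_h,
        outcomes=gd.outcomes, c=b[:6].T, b1=b[7], b2=b[6], sigma=sigma)


def fit_group_model(table, spec: ModelSpec, group: str,
                    init: PathCoefficients | None = None, *,
                    tol: float = 1e-9, max_iter: int = 500,
                    restarts: int = 3, restart_seed: int = 0) -> FitResult:
    """Fit one group by EM from ``init`` (default: :func:`initial_values`).

    On non-convergence within the iteration cap, up to ``restarts`` jittered
    restarts are attempted; the best log-likelihood wins (ties broken by
    first). The returned ``converged`` flag reports the winning run.
    """
    gd = table if isinstance(table, GroupData) else \
        build_group_data(table, spec, group)
    if init is None:
        init = initial_values(gd, spec, group)
    init.validate()

    cf, converged, ll, n_iter = _fit_em(gd, init, tol, max_iter)
    if not converged and restarts > 0:
        rng = rng_from(restart_seed)
        vec0 = init.to_vector()
        scale = np.maximum(np.abs(vec0), 1.0)
        for _ in range(restarts):
            jitter = vec0 + 0.05 * scale * rng.standard_normal(vec0.size)
            try:
                start = PathCoefficients.from_vector(jitter, init.outcomes)
                cf_r, conv_r, ll_r, it_r = _fit_em(gd, start, tol, max_iter)
            except (FitError, np.linalg.LinAlgError):
                continue
            if (conv_r and not converged) or ll_r > ll + 1e-9:
                cf, converged, ll, n_iter = cf_r, conv_r, ll_r, it_r
        if not converged:
            logger.warning("group %s: EM not converged after %d restarts "
                           "(loglik %.6f)", group, restarts, ll)
    return FitResult(group=group, coefficients=cf, converged=converged,
                     loglik=ll, n_iter=n_iter, n_obs=gd.n)


def fit_multigroup_model(table: CohortTable, spec: ModelSpec,
                         init: dict | None = None, **kwargs) -> dict:
    """Independent per-group fits (sons, daughters); no pooling.

    Errors from a group's fit are re-raised labelled with the group.
    """
    results = {}
    for group in spec.groups:
        try:
            results[group] = fit_group_model(
                table, spec, group,
                init=None if init is None else init.get(group), **kwargs)
        except FitError as exc:
            raise FitError(f"group {group!r}: {exc}") from exc
    return results


def oracle_fit(table: CohortTable, spec: ModelSpec, group: str) -> PathCoefficients:
    """Least-squares fit treating the latent mediator column as observed.

    Requires an ``m1_star`` column (see
    :func:`lungmediation.synthetic.attach_latent_oracle`). Consistent for
    the same structural parameters as the FIML fit; used as an independent
    estimator in validation.
    """
    if "m1_star" not in table.df.columns:
        raise FitError("oracle fit requires the m1_star latent column")
    gd = build_group_data(table, spec, group)
    df = table.for_line(spec.line).df
    df = df[df.sex == group]
    src1, src2 = spec.source_columns()
    df = df[df[src1].notna() & df[src2].notna()]
    m1s = df.m1_star.to_numpy(float)

    a, *_ = np.linalg.lstsq(gd.xm, m1s, rcond=None)
    wh = np.column_stack([gd.xm, m1s])
    beta_h, *_ = np.linalg.lstsq(wh, gd.m2, rcond=None)
    res_h = gd.m2 - wh @ beta_h
    sigma_h = float(np.sqrt(res_h @ res_h / gd.n))
    wy = np.column_stack([gd.xy, gd.m2, m1s])
    b, *_ = np.linalg.lstsq(wy, gd.y, rcond=None)
    res_y = gd.y - wy @ b
    sigma = res_y.T @ res_y / gd.n
    return PathCoefficients(
        a=a, h=beta_h[:4], d=float(beta_h[4]), sigma_h=max(sigma_h, 1e-12),
        outcomes=gd.outcomes, c=b[:6].T, b1=b[7], b2=b[6],
        sigma=0.5 * (sigma + sigma.T))
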