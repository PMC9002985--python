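"""Structural path coefficients for the serial two-mediator model.

The structural system, per offspring-sex group, is

    M1* = a0 + a1*E1 + a2*E2 + g1*edu + eps1,          eps1 ~ N(0, 1)
    M1  = 1{M1* > 0}
    M2  = h0 + h1*E1 + h2*E2 + d*M1* + g2*edu + eps2,  eps2 ~ N(0, sigma_h^2)
    Yk  = c0k + c1k*E1 + c2k*E2 + b1k*M1* + b2k*M2
          + th_edu,k*edu + th_age,k*age + th_smk,k*smoke + eta_k,

with (eta_1, ..., eta_K) ~ N(0, Sigma), all residuals mutually independent.

E1/E2 are the dummies of the three-level parental-overweight exposure
(overweight before puberty, overweight at 30 but not before puberty; the
reference is never overweight); M1 is the offspring's own prepubertal
overweight, modelled through the latent response M1* with the residual
variance fixed at 1 (theta-style probit identification); M2 is adult height
in cm; the outcomes Yk are lung-function measures in mL (or the FEV1/FVC
ratio in percent points for the single-outcome variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GROUPS = ("son", "daughter")
CONTRASTS = ("before_puberty_vs_never", "at30_vs_never")
EXPOSURE_LEVELS = ("before_puberty", "at30_not_before", "never")
LINES = ("paternal", "maternal")

#: design-matrix term order of the mediator and height equations
XM_TERMS = ("const", "before_puberty", "at30_not_before", "parent_edu_low")
#: design-matrix term order of the outcome equations (excluding M1*, M2)
XY_TERMS = ("const", "before_puberty", "at30_not_before",
            "parent_edu_low", "age", "ever_smoker")


class CoefficientError(ValueError):
    """Raised for incomplete or invalid path-coefficient sets."""


@dataclass
class PathCoefficients:
    """Point values of every structural parameter of one group's model.

    Attributes
    ----------
    a : (4,) array
        Mediator (probit) equation: intercept, exposure dummies, education.
        The latent residual variance is fixed at 1 and is not a field.
    h : (4,) array
        Height equation: intercept, exposure dummies, education.
    d : float
        Height-equation coefficient of the latent mediator M1* (cm per
        latent unit) — the serial mediator-to-mediator path.
    sigma_h : float
        Residual standard deviation of height (cm).
    outcomes : tuple of str
        Outcome names, e.g. ``("fev1_ml", "fvc_ml")``.
    c : (K, 6) array
        Outcome equations over :data:`XY_TERMS` (direct-effect paths are
        columns 1 and 2).
    b1, b2 : (K,) arrays
        Outcome-equation coefficients of M1* and of M2.
    sigma : (K, K) array
        Residual covariance of the outcomes (symmetric positive definite).
    """

    a: np.ndarray
    h: np.ndarray
    d: float
    sigma_h: float
    outcomes: tuple
    c: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.c = np.atleast_2d(np.asarray(self.c, dtype=float))
        self.b1 = np.atleast_1d(np.asarray(self.b1, dtype=float))
        self.b2 = np.atleast_1d(np.asarray(self.b2, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        self.outcomes = tuple(self.outcomes)
        self.d = float(self.d)
        self.sigma_h = float(self.sigma_h)

    # -- shape / validity -------------------------------------------------

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    def validate(self) -> "PathCoefficients":
        k = self.n_outcomes
        if self.a.shape != (4,):
            raise CoefficientError(f"mediator equation must have 4 terms, got {self.a.shape}")
        if self.h.shape != (4,):
            raise CoefficientError(f"height equation must have 4 terms, got {self.h.shape}")
        if self.c.shape != (k, 6):
            raise CoefficientError(f"outcome equations must be ({k}, 6), got {self.c.shape}")
        if self.b1.shape != (k,) or self.b2.shape != (k,):
            raise CoefficientError("b1/b2 must have one entry per outcome")
        if self.sigma.shape != (k, k):
            raise CoefficientError(f"residual covariance must be ({k}, {k})")
        if not np.isfinite(self.sigma_h) or self.sigma_h <= 0:
            raise CoefficientError("sigma_h must be positive")
        if not np.allclose(self.sigma, self.sigma.T):
            raise CoefficientError("residual covariance must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise CoefficientError("residual covariance must be positive definite")
        for arr in (self.a, self.h, self.c, self.b1, self.b2):
            if not np.all(np.isfinite(arr)):
                raise CoefficientError("non-finite coefficient")
        return self

    def copy(self) -> "PathCoefficients":
        return replace(
            self, a=self.a.copy(), h=self.h.copy(), c=self.c.copy(),
            b1=self.b1.copy(), b2=self.b2.copy(), sigma=self.sigma.copy(),
        )

    # -- path accessors ---------------------------------------------------

    def exposure_paths(self, contrast: str, outcome: str):
        """Return (a, h, c) exposure paths for one contrast and outcome.

        ``a`` is the probit path onto the latent mediator, ``h`` the linear
        path onto height, ``c`` the direct path onto the outcome.
        """
        if contrast not in CONTRASTS:
            raise CoefficientError(f"unknown contrast {contrast!r}")
        if outcome not in self.outcomes:
            raise CoefficientError(
                f"missing coefficient block for outcome {outcome!r}; "
                f"have {self.outcomes}")
        j = CONTRASTS.index(contrast) + 1  # dummy column in the designs
        k = self.outcomes.index(outcome)
        return float(self.a[j]), float(self.h[j]), float(self.c[k, j])

    def outcome_index(self, outcome: str) -> int:
        if outcome not in self.outcomes:
            raise CoefficientError(f"missing coefficient block for outcome {outcome!r}")
        return self.outcomes.index(outcome)

    # -- flat-vector view (optimiser jitter, gradient checks) -------------

    def to_vector(self) -> np.ndarray:
        """Unconstrained flat parameterisation.

        Variance parameters are mapped through log / log-Cholesky so that any
        real vector maps back to a valid coefficient set.
        """
        chol = np.linalg.cholesky(self.sigma)
        k = self.n_outcomes
        tril = chol[np.tril_indices(k)]
        # log the diagonal entries in-place within the vech ordering
        diag_pos = np.cumsum(np.arange(1, k + 1)) - 1
        tril = tril.copy()
        tril[diag_pos] = np.log(tril[diag_pos])
        return np.concatenate([
            self.a, self.h, [self.d, np.log(self.sigma_h)],
            self.c.ravel(), self.b1, self.b2, tril,
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray, outcomes) -> "PathCoefficients":
        vec = np.asarray(vec, dtype=float)
        k = len(outcomes)
        n_expected = 4 + 4 + 2 + 6 * k + 2 * k + k * (k + 1) // 2
        if vec.size != n_expected:
            raise CoefficientError(f"expected {n_expected} parameters, got {vec.size}")
        pos = 0

        def take(n):
            nonlocal pos
            out = vec[pos:pos + n]
            pos += n
            return out

        a = take(4)
        h = take(4)
        d, log_sh = take(2)
        c = take(6 * k).reshape(k, 6)
        b1 = take(k)
        b2 = take(k)
        tril = take(k * (k + 1) // 2).copy()
        diag_pos = np.cumsum(np.arange(1, k + 1)) - 1
        tril[diag_pos] = np.exp(tril[diag_pos])
        chol = np.zeros((k, k))
        chol[np.tril_indices(k)] = tril
        return cls(a=a, h=h, d=float(d), sigma_h=float(np.exp(log_sh)),
                   outcomes=tuple(outcomes), c=c, b1=b1, b2=b2,
                   sigma=chol @ chol.T)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(), "h": self.h.tolist(), "d": self.d,
            "sigma_h": self.sigma_h, "outcomes": list(self.outcomes),
            "c": self.c.tolist(), "b1": self.b1.tolist(),
            "b2": self.b2.tolist(), "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PathCoefficients":
        return cls(**{**payload, "outcomes": tuple(payload["outcomes"])}).validate()


@dataclass
class ModelSpec:
    """What to fit: line, outcome block, bronchodilator state.

    ``outcome_set`` is ``"fev1_fvc_pair"`` for the two correlated lung-volume
    outcomes or ``"ratio"`` for the single FEV1/FVC outcome. The exposure
    contrasts, the mediator-equation covariate (parental education) and the
    outcome-equation covariates (education, age, smoking) are fixed by the
    model and not configurable.
    """

    line: str = "paternal"
    outcome_set: str = "fev1_fvc_pair"
    bronchodilator: str = "pre"
    groups: tuple = GROUPS

    RATIO_COLUMN = "fev1_fvc_ratio"

    def __post_init__(self):
        if self.line not in LINES:
            raise CoefficientError(f"unknown line {self.line!r}")
        if self.outcome_set not in ("fev1_fvc_pair", "ratio"):
            raise CoefficientError(f"unknown outcome set {self.outcome_set!r}")
        if self.bronchodilator not in ("pre", "post"):
            raise CoefficientError(f"unknown bronchodilator state {self.bronchodilator!r}")
        self.groups = tuple(self.groups)

    def source_columns(self):
        """FEV1/FVC columns in the input table for the bronchodilator state."""
        if self.bronchodilator == "pre":
            return ("fev1_ml", "fvc_ml")
        return ("fev1_post_ml", "fvc_post_ml")

    def outcome_names(self):
        if self.outcome_set == "fev1_fvc_pair":
            return self.source_columns()
        return (self.RATIO_COLUMN,)

    def to_dict(self) -> dict:
        return {"line": self.line, "outcome_set": self.outcome_set,
                "bronchodilator": self.bronchodilator, "groups": list(self.groups)}

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelSpec":
        payload = dict(payload)
        if "groups" in payload:
            payload["groups"] = tuple(payload["groups"])
        return cls(**payload)
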