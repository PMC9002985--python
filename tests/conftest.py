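"""Shared fixtures: generated cohorts and reference coefficient sets."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from lungmediation.coefficients import ModelSpec, PathCoefficients
from lungmediation.synthetic import (default_generator_params, generate_cohort)


def make_reference_coefficients() -> dict:
    """Published paternal-line structural estimates used as a worked example.

    Only the structural paths are published; intercepts, covariate
    coefficients and residual scales are filled with plausible values (they
    do not enter the effect decomposition).
    """
    sigma = np.array([[500.0 ** 2, 0.7 * 500.0 * 560.0],
                      [0.7 * 500.0 * 560.0, 560.0 ** 2]])
    son = PathCoefficients(
        a=[-1.26, 0.56, 0.07, 0.25],
        h=[182.0, -3.42, -0.17, -1.0], d=0.37, sigma_h=6.4,
        outcomes=("fev1_ml", "fvc_ml"),
        c=[[2000.0, -164.0, -15.0, -40.0, -25.0, -80.0],
           [2500.0, -262.0, -43.0, -50.0, -20.0, -60.0]],
        b1=[36.0, 54.0], b2=[42.0, 61.0], sigma=sigma)
    daughter = PathCoefficients(
        a=[-0.60, 0.83, -0.02, 0.25],
        h=[169.0, -2.11, -0.20, -1.0], d=-1.17, sigma_h=6.3,
        outcomes=("fev1_ml", "fvc_ml"),
        c=[[1800.0, 26.0, 51.0, -40.0, -25.0, -80.0],
           [2200.0, 78.0, 64.0, -50.0, -20.0, -60.0]],
        b1=[32.0, 48.0], b2=[30.0, 41.0], sigma=sigma)
    return {"son": son.validate(), "daughter": daughter.validate()}


def null_exposure_params(line: str = "paternal"):
    """Default generator parameters with every exposure path set to zero."""
    params = default_generator_params(line)
    out = dataclasses.replace(params, coefficients={})
    for g, cf in params.coefficients.items():
        cf = cf.copy()
        cf.a[1:3] = 0.0
        cf.h[1:3] = 0.0
        cf.c[:, 1:3] = 0.0
        out.coefficients[g] = cf
    return out.validate()


@pytest.fixture(scope="session")
def reference_coefficients():
    return make_reference_coefficients()


@pytest.fixture(scope="session")
def null_params():
    return null_exposure_params()


@pytest.fixture(scope="session")
def paternal_params():
    return default_generator_params("paternal")


@pytest.fixture(scope="session")
def paternal_spec():
    return ModelSpec(line="paternal")


@pytest.fixture(scope="session")
def small_cohort(paternal_params):
    """A cohort small enough for fast I/O and pipeline tests."""
    table, oracle = generate_cohort(paternal_params, 150, seed=11)
    return table, oracle


@pytest.fixture(scope="session")
def midsize_cohort(paternal_params):
    """A cohort large enough for meaningful estimation checks."""
    table, oracle = generate_cohort(paternal_params, 4000, seed=12)
    return table, oracle
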