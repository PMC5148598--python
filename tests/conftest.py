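"""Shared fixtures: small synthetic datasets and pre-fitted models.

Fits are session-scoped so the optimizer runs once per dataset, not once
per test.
"""

import numpy as np
import pandas as pd
import pytest

import gwreg
from gwreg.fit import _assemble, neg_loglik


def fit_at(design, beta, k, rho):
    """A FitResult pinned at given parameter values (no optimization).

    Used to evaluate prediction/partition/residual code at externally known
    estimates, and as a likelihood probe.
    """
    beta = np.asarray(beta, dtype=float)
    theta = np.concatenate([beta, [k, rho]])
    ll = -neg_loglik(theta, design, "natural")
    names = design.column_names + ["k", "rho"]
    return _assemble(design, beta, k, rho, None, None, None, "natural", names, ll, 0, "pinned", "", {})


@pytest.fixture(scope="session")
def badh_data():
    """Health-survey-shaped fixture: counts, binary indicator, bounded age."""
    return gwreg.fixtures("badhealth_like", n=1500, seed=42)


@pytest.fixture(scope="session")
def badh_design(badh_data):
    return gwreg.build_design(badh_data, "numvisit", ["badh"])


@pytest.fixture(scope="session")
def badh_fit(badh_design):
    return gwreg.fit_gw(badh_design)


@pytest.fixture(scope="session")
def badh_null_fit(badh_data):
    d0 = gwreg.build_design(badh_data, "numvisit", [])
    return gwreg.fit_gw(d0)


@pytest.fixture(scope="session")
def goals_data():
    return gwreg.fixtures("goals_like", n=1200, seed=7)


@pytest.fixture(scope="session")
def goals_fit(goals_data):
    d = gwreg.build_design(
        goals_data, "Goals", ["Position"], offset="Matches", offset_log=True,
        reference_levels={"Position": "defender"},
    )
    return gwreg.fit_gw(d)


@pytest.fixture(scope="session")
def small_fit():
    """A quick 300-row fit reused by the diagnostics tests."""
    df = gwreg.fixtures("badhealth_like", n=300, seed=11)
    d = gwreg.build_design(df, "numvisit", ["badh"])
    return gwreg.fit_gw(d)
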