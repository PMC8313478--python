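"""Shared fixtures: small synthetic datasets and prepared model objects."""

import numpy as np
import pandas as pd
import pytest

from miivkit import (build_moment_matrix, estimate_upsilon, find_miivs,
                     l2o_transform, parse_model, select_miivs)

EMPIRICAL_TYPES = {
    **{f"c{i}": "continuous" for i in (1, 2, 3)},
    **{f"a{i}": "continuous" for i in (1, 2, 3)},
    **{f"s{i}": "ordinal" for i in (1, 2, 3)},
    **{f"h{i}": "ordinal" for i in (1, 2, 3)},
}

EMPIRICAL_SYNTAX = """\
Contr =~ c1 + c2 + c3
Symp =~ s1 + s2 + s3
Anger =~ a1 + a2 + a3
Help =~ h1 + h2 + h3
Symp ~ Contr
Anger ~ Contr
Help ~ Symp + Anger
"""

EMPIRICAL_SYNTAX_CROSS = EMPIRICAL_SYNTAX.replace(
    "Help =~ h1 + h2 + h3", "Help =~ h1 + h2 + h3 + s3")


def one_factor_continuous_data(n=500, seed=3, loadings=(1.0, 0.8, 0.7, 0.6),
                               err_sd=0.6):
    """Sample from a one-factor model with four continuous indicators."""
    rng = np.random.default_rng(seed)
    eta = rng.normal(size=n)
    X = np.column_stack([l * eta + rng.normal(scale=err_sd, size=n)
                         for l in loadings])
    cols = [f"y{i + 1}" for i in range(len(loadings))]
    return pd.DataFrame(X, columns=cols), {c: "continuous" for c in cols}


def fitted_continuous_setup(n=500, seed=3):
    """One-factor continuous data with moments, normal-theory Upsilon, equations."""
    data, types = one_factor_continuous_data(n=n, seed=seed)
    model = parse_model("f =~ y1 + y2 + y3 + y4", types)
    eqs = l2o_transform(model)
    moments = build_moment_matrix(data, types)
    for eq in eqs:
        find_miivs(model, eq)
        select_miivs(eq, moments, strategy="all")
    upsilon = estimate_upsilon(data, moments, "normal")
    return data, types, model, eqs, moments, upsilon


@pytest.fixture(scope="session")
def cont_setup():
    return fitted_continuous_setup()


@pytest.fixture(scope="session")
def empirical_models():
    base = parse_model(EMPIRICAL_SYNTAX, EMPIRICAL_TYPES)
    cross = parse_model(EMPIRICAL_SYNTAX_CROSS, EMPIRICAL_TYPES)
    return base, cross
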