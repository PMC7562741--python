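"""Shared helpers for the test suite: small deterministic bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synopipe.exprio import ExpressionBundle


def make_bundle(
    values: np.ndarray,
    genes: list[str] | None = None,
    n_case: int | None = None,
    clinical: pd.DataFrame | None = None,
) -> ExpressionBundle:
    """Wrap a raw matrix into a bundle with default ids and labels."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    genes = genes or [f"g{i}" for i in range(p)]
    samples = [f"S{j}" for j in range(n)]
    n_case = n // 2 if n_case is None else n_case
    cohort = pd.Series([1] * n_case + [0] * (n - n_case), index=samples)
    return ExpressionBundle(
        values=pd.DataFrame(values, index=genes, columns=samples),
        cohort=cohort,
        clinical=clinical,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_bundle(rng):
    """30 genes x 8 samples of pure noise around a gene baseline."""
    base = rng.normal(6.0, 1.5, size=30)
    X = base[:, None] + rng.normal(0.0, 0.5, size=(30, 8))
    return make_bundle(X)
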