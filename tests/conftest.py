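import numpy as np
import pytest
from scipy import stats

from biasdyn import BiasParams


def chi2_pvalue(observed, expected, min_expected: float = 5.0) -> float:
    """Goodness-of-fit p-value with small expected bins pooled together."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    keep = expected >= min_expected
    if keep.sum() < 2:
        order = np.argsort(expected)[::-1]
        keep = np.zeros_like(keep)
        keep[order[:2]] = True
    obs = observed[keep]
    exp = expected[keep]
    if not np.all(keep):
        obs = np.append(obs, observed[~keep].sum())
        exp = np.append(exp, expected[~keep].sum())
    # chisquare requires matching totals; renormalise the expected side
    exp = exp * obs.sum() / exp.sum()
    return float(stats.chisquare(obs, exp).pvalue)


@pytest.fixture
def rng():
    return np.random.default_rng(20240710)


@pytest.fixture
def params():
    """Default bias function: b = J = 1, optimum at 1."""
    return BiasParams(b=1.0, J=1.0, a_hat=1.0)
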