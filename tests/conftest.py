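import numpy as np
import pytest

from scalecraft import CorrelationStructure, TrueScoreModel, fixture_table1


@pytest.fixture(scope="session")
def table1():
    return fixture_table1()


@pytest.fixture
def toy4():
    """Hand-sized 4-item structure with a criterion, for enumeration checks."""
    R = np.array(
        [
            [1.0, 0.5, 0.2, 0.1],
            [0.5, 1.0, 0.3, 0.2],
            [0.2, 0.3, 1.0, 0.4],
            [0.1, 0.2, 0.4, 1.0],
        ]
    )
    return CorrelationStructure(
        labels=(1, 2, 3, 4), R=R, r_crit=np.array([0.3, 0.1, 0.25, 0.2])
    )


def random_psd_structure(rng, p=None, with_criterion=False, with_sd=False):
    """Random correlation structure from a factor model (PSD by construction)."""
    p = p if p is not None else int(rng.integers(3, 9))
    m = int(rng.integers(1, 4))
    A = rng.normal(size=(p, m + 1))  # extra column keeps variances positive
    cov = A @ A.T + np.diag(rng.uniform(0.05, 1.0, p))
    d = np.sqrt(np.diag(cov))
    R = cov / np.outer(d, d)
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    sd = rng.uniform(0.3, 2.0, p) if with_sd else None
    r_crit = None
    if with_criterion:
        # criterion = weighted factors + noise, so r_crit is consistent with R
        w = rng.normal(size=m + 1)
        cy = A @ w
        vy = float(w @ w) + rng.uniform(0.1, 1.0)
        r_crit = np.clip(cy / (d * np.sqrt(vy)), -1, 1)
    return CorrelationStructure(labels=tuple(range(1, p + 1)), R=R, sd=sd, r_crit=r_crit)


def random_true_score_model(rng, p=None, with_criterion=False):
    p = p if p is not None else int(rng.integers(2, 8))
    A = rng.normal(size=(p, int(rng.integers(1, 4))))
    Sigma_T = A @ A.T
    model_kwargs = {}
    if with_criterion:
        model_kwargs["crit_weights"] = rng.normal(size=p)
        model_kwargs["crit_noise_var"] = float(rng.uniform(0.0, 2.0))
    return TrueScoreModel(
        Sigma_T=Sigma_T,
        error_var=rng.uniform(0.0, 2.0, p),
        **model_kwargs,
    )
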