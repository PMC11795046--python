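"""Shared fixtures: paired replicate runs and an independent GP oracle."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.linalg import cho_factor, cho_solve

from induceopt import RunConfig, run_closed_loop

N_REPLICATE_SEEDS = 20

warnings.filterwarnings("ignore", category=UserWarning)
try:  # sklearn warns when a length scale settles on its bound; harmless here
    from sklearn.exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


def gp_posterior_oracle(X, y, Xq, length_scales, signal_var, noise_var):
    """Textbook GP regression posterior by direct Cholesky solve.

    Anisotropic squared-exponential kernel with per-axis ``length_scales``
    and amplitude ``signal_var``; observation noise ``noise_var`` on the
    training diagonal.  The predictive variance includes the noise term
    (it is the distribution of a new *measurement*, matching a surrogate
    whose white-noise kernel is part of the fitted covariance).

    Independent of the package's surrogate module by construction: only
    numpy/scipy primitives.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    y = np.asarray(y, dtype=float)
    ls = np.asarray(length_scales, dtype=float)

    def kern(A, B):
        d = (A[:, None, :] - B[None, :, :]) / ls
        return signal_var * np.exp(-0.5 * np.sum(d**2, axis=2))

    K = kern(X, X) + (noise_var + 1e-10) * np.eye(len(X))
    Ks = kern(X, Xq)
    cf = cho_factor(K, lower=True)
    alpha = cho_solve(cf, y)
    mean = Ks.T @ alpha
    v = cho_solve(cf, Ks)
    var = signal_var + noise_var + 1e-10 - np.sum(Ks * v, axis=0)
    return mean, np.sqrt(np.clip(var, 0.0, None))


@pytest.fixture(scope="session")
def paired_runs():
    """Twenty paired-seed closed-loop runs per algorithm on the default twin.

    Expensive (about a minute and a half); shared by the algorithm-comparison
    and parameter-recovery tests.
    """
    out = {}
    for algo in ("gpr-ei", "gpr-ucb", "random"):
        out[algo] = [
            run_closed_loop(RunConfig(algorithm=algo, seed=s))
            for s in range(N_REPLICATE_SEEDS)
        ]
    return out
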