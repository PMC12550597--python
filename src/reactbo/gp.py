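"""Gaussian-process surrogate, expected improvement and Thompson sampling.

The surrogate is a Matérn-5/2 GP with automatic relevance determination
(one length-scale per input dimension, the encoded categorical coordinate
included) and a fitted white-noise term.  Hyperparameters maximize the
marginal likelihood with multi-start L-BFGS; targets are standardized
internally and predictions returned on the original scale.

Posterior draws for Thompson sampling use a spectral (random Fourier
feature) approximation: the Matérn-5/2 spectral density is a multivariate
Student-t with 5 degrees of freedom, so feature frequencies are sampled as
scaled t variates, and the posterior over feature weights is the standard
Bayesian linear model, giving a cheap, globally coherent, differentiable
sample path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = ["GPModel", "fit_gp", "expected_improvement", "ThompsonSample", "thompson_sample"]

_LS_BOUNDS = (np.exp(-3.0), np.exp(3.0))  # log length-scale in [-3, 3]
_JITTER = 1e-10


@dataclass
class GPModel:
    """Fitted GP surrogate over encoded inputs in [0, 1]^d."""

    gpr: GaussianProcessRegressor
    X: np.ndarray
    y: np.ndarray
    y_mean: float
    y_std: float

    # -- fitted hyperparameters (original-y scale where applicable) ------
    @property
    def length_scales(self) -> np.ndarray:
        return np.atleast_1d(self.gpr.kernel_.k1.k2.length_scale).astype(float)

    @property
    def signal_variance(self) -> float:
        """Signal variance on the standardized-target scale."""
        return float(self.gpr.kernel_.k1.k1.constant_value)

    @property
    def noise_variance(self) -> float:
        """Noise variance on the standardized-target scale."""
        return float(self.gpr.kernel_.k2.noise_level)

    def predict(self, X: np.ndarray, return_std: bool = True):
        X = np.atleast_2d(X)
        if return_std:
            mu, sd = self.gpr.predict(X, return_std=True)
            return mu * self.y_std + self.y_mean, sd * self.y_std
        return self.gpr.predict(X) * self.y_std + self.y_mean

    def log_marginal_likelihood(self) -> float:
        """Log marginal likelihood of the standardized targets at the
        fitted hyperparameters."""
        return float(self.gpr.log_marginal_likelihood_value_)

    def kernel_matrix(self, A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
        return self.gpr.kernel_(np.atleast_2d(A), None if B is None else np.atleast_2d(B))


def fit_gp(X: np.ndarray, y: np.ndarray, seed: int = 0, n_restarts: int = 5,
           noise_bounds: tuple[float, float] = (1e-8, 1e-1)) -> GPModel:
    """Fit the Matérn-5/2 ARD surrogate to encoded points.

    ``seed`` fixes the restart draws, making the fit deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 2:
        raise ValueError("need at least 2 points to fit a GP")
    if np.allclose(X, X[0][None, :]):
        raise ValueError("degenerate design: all input points identical")
    y_mean = float(np.mean(y))
    y_std = float(np.std(y))
    if y_std == 0.0:
        y_std = 1.0
    y_s = (y - y_mean) / y_std
    d = X.shape[1]
    kernel = (
        # targets are standardized, so the signal variance is O(1); tight
        # bounds keep the spectral (Thompson) approximation well conditioned
        ConstantKernel(1.0, (1e-2, 1e2))
        * Matern(length_scale=np.full(d, 0.5), length_scale_bounds=_LS_BOUNDS, nu=2.5)
        + WhiteKernel(noise_level=1e-6, noise_level_bounds=noise_bounds)
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=_JITTER,
        normalize_y=False,
        n_restarts_optimizer=n_restarts,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        # hyperparameters pinned at a bound are acceptable surrogates here
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        gpr.fit(X, y_s)
    return GPModel(gpr=gpr, X=X, y=y, y_mean=y_mean, y_std=y_std)


def expected_improvement(gp: GPModel, X: np.ndarray, best: float,
                         xi: float = 0.0) -> np.ndarray:
    """Closed-form EI for maximization: E[max(0, f(x) - best - xi)].

    Zero wherever the posterior standard deviation vanishes.
    """
    mu, sd = gp.predict(np.atleast_2d(X), return_std=True)
    ei = np.zeros_like(mu)
    ok = sd > 1e-12
    delta = mu[ok] - best - xi
    z = delta / sd[ok]
    ei[ok] = delta * norm.cdf(z) + sd[ok] * norm.pdf(z)
    return np.maximum(ei, 0.0)


@dataclass(frozen=True)
class ThompsonSample:
    """One deterministic posterior draw, f(x) = phi(x)^T w (original y scale)."""

    W: np.ndarray  # (m, d) spectral frequencies
    b: np.ndarray  # (m,) phases
    amplitude: float  # sqrt(2 * signal_var / m)
    w: np.ndarray  # (m,) sampled feature weights
    y_mean: float
    y_std: float

    def features(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return self.amplitude * np.cos(X @ self.W.T + self.b[None, :])

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.features(X) @ self.w * self.y_std + self.y_mean


def _rff_frequencies(rng: np.random.Generator, n_features: int,
                     length_scales: np.ndarray) -> np.ndarray:
    # Matérn-5/2 spectral density: omega ~ multivariate t, df = 2*nu = 5
    d = len(length_scales)
    df = 5.0
    z = rng.standard_normal((n_features, d))
    g = rng.chisquare(df, size=n_features)
    return z / np.sqrt(g / df)[:, None] / length_scales[None, :]


def thompson_sample(gp: GPModel, n_features: int = 500, seed: int = 0,
                    _return_posterior: bool = False):
    """Draw one approximate posterior sample path from the fitted GP.

    Deterministic given ``seed``; repeated calls with the same seed return
    identical functions.  ``n_features`` controls the fidelity of the
    spectral approximation (>= 100 recommended).
    """
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    rng = np.random.default_rng(seed)
    ls = gp.length_scales
    if ls.ndim != 1:
        raise ValueError("kernel without per-dimension length-scales")
    W = _rff_frequencies(rng, n_features, ls)
    b = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
    amplitude = np.sqrt(2.0 * gp.signal_variance / n_features)
    # Bayesian linear model over feature weights, standardized targets
    y_s = (gp.y - gp.y_mean) / gp.y_std
    Phi = amplitude * np.cos(gp.X @ W.T + b[None, :])
    noise = max(gp.noise_variance, 1e-8)
    A = Phi.T @ Phi / noise + np.eye(n_features)
    cf = cho_factor(A, lower=True)
    w_mean = cho_solve(cf, Phi.T @ y_s) / noise
    # sample w = w_mean + L^{-T} z with A = L L^T (cov = A^{-1})
    z = rng.standard_normal(n_features)
    L = np.tril(cf[0])
    w = w_mean + np.linalg.solve(L.T, z)
    ts = ThompsonSample(W=W, b=b, amplitude=amplitude, w=w,
                        y_mean=gp.y_mean, y_std=gp.y_std)
    if _return_posterior:
        mean_fn = ThompsonSample(W=W, b=b, amplitude=amplitude, w=w_mean,
                                 y_mean=gp.y_mean, y_std=gp.y_std)
        return ts, mean_fn, (cf, noise)
    return ts


def log_marginal_likelihood_oracle(gp: GPModel) -> float:
    """Direct Cholesky evaluation of the GP log marginal likelihood
    (independent of sklearn's internal value; standardized-target scale)."""
    y_s = (gp.y - gp.y_mean) / gp.y_std
    K = gp.kernel_matrix(gp.X) + _JITTER * np.eye(len(gp.X))
    L = cholesky(K, lower=True)
    alpha = cho_solve((L, True), y_s)
    n = len(y_s)
    return float(
        -0.5 * y_s @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2.0 * np.pi)
    )
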