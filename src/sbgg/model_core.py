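"""Core types and likelihood pieces for sparse Bayesian ordinal regression.

The model treats an ordinal response ``y_i in {1..k}`` as a discretization of
a continuous latent variable ``l_i = w_i' theta + e_i`` with logistic errors:
``y_i = j`` exactly when ``gamma_j <= l_i < gamma_{j+1}`` for a non-decreasing
threshold vector ``gamma`` with ``gamma_1 = -inf`` and ``gamma_{k+1} = +inf``.
Sparsity in ``theta`` is induced by a Generalized Double Pareto (GDP) prior,
a heavy-tailed density with a spike at zero that admits a
normal--exponential--gamma scale-mixture representation (see
:mod:`sbgg.gibbs_sampler`).

Threshold vectors are stored as length ``k+1`` arrays with sentinel
``-inf``/``+inf`` ends; index ``m`` of the array holds the boundary between
categories ``m`` and ``m+1`` (1-based categories). Because the latent linear
predictor carries no intercept, all ``k-1`` interior thresholds are
identified and sampled; this parameterization is equivalent to including an
intercept and pinning the first interior threshold at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


class InvariantViolation(RuntimeError):
    """A model-state invariant (threshold order, latent containment) failed."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class OrdinalDataset:
    """Expression matrix plus ordinal labels.

    Parameters
    ----------
    W : (n, p) float array
        ``W[i, j]`` is the expression level of gene ``j`` in sample ``i``.
    y : (n,) int array
        Ordinal category of each sample, values in ``{1, ..., k}``.
    sample_ids, feature_ids : lists of str
        Row / column identifiers.
    k : int
        Number of ordinal categories (``>= 2``).
    """

    W: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    k: int

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.W.ndim != 2:
            raise ValueError(f"W must be 2-d, got shape {self.W.shape}")
        n, p = self.W.shape
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match W rows")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match W columns")
        if self.k < 2:
            raise ValueError("need at least two ordinal categories")
        if np.any((self.y < 1) | (self.y > self.k)):
            raise ValueError(f"labels must lie in 1..{self.k}")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains missing or non-finite values")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[1]

    def subset(self, rows=None, cols=None) -> "OrdinalDataset":
        """Dataset restricted to the given sample rows / feature columns."""
        rows = np.arange(self.n) if rows is None else np.asarray(rows)
        cols = np.arange(self.p) if cols is None else np.asarray(cols)
        return OrdinalDataset(
            W=self.W[np.ix_(rows, cols)],
            y=self.y[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            feature_ids=[self.feature_ids[j] for j in cols],
            k=self.k,
        )


def make_threshold_vector(interior, k: int) -> np.ndarray:
    """Build a length ``k+1`` threshold vector from the ``k-1`` finite cuts."""
    interior = _as_1d_float(interior, "interior")
    if interior.shape != (k - 1,):
        raise ValueError(f"expected {k - 1} finite thresholds, got {interior.shape}")
    gamma = np.concatenate([[-np.inf], interior, [np.inf]])
    check_thresholds(gamma)
    return gamma


def check_thresholds(gamma: np.ndarray) -> None:
    """Validate sentinel ends and monotonicity of a threshold vector."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 1 or gamma.size < 3:
        raise InvariantViolation("threshold vector needs at least 3 entries")
    if not (np.isneginf(gamma[0]) and np.isposinf(gamma[-1])):
        raise InvariantViolation("threshold vector must start at -inf and end at +inf")
    if np.any(np.diff(gamma[1:-1]) < 0):
        raise InvariantViolation("thresholds must be non-decreasing")


@dataclass
class ModelState:
    """One full configuration of the sampler's unknowns.

    ``theta`` are the regression coefficients; ``tau`` their local prior
    variances; ``lam`` the per-coefficient exponential rates of the scale
    mixture; ``Lam`` the per-sample precisions of the Student-t
    approximation to the logistic error; ``latent`` the continuous latent
    responses; ``gamma`` the category thresholds; ``nu`` the t degrees of
    freedom; ``rho`` and ``delta`` the GDP shape and scale hyperparameters.
    """

    theta: np.ndarray
    tau: np.ndarray
    lam: np.ndarray
    Lam: np.ndarray
    latent: np.ndarray
    gamma: np.ndarray
    nu: float
    rho: float
    delta: float

    def validate(self, y: np.ndarray | None = None) -> None:
        check_thresholds(self.gamma)
        for name in ("tau", "lam", "Lam"):
            if np.any(getattr(self, name) <= 0):
                raise InvariantViolation(f"{name} must be strictly positive")
        if min(self.nu, self.rho, self.delta) <= 0:
            raise InvariantViolation("nu, rho, delta must be strictly positive")
        if y is not None:
            lo = self.gamma[y - 1]
            hi = self.gamma[y]
            if np.any(self.latent < lo) or np.any(self.latent >= hi):
                raise InvariantViolation("latent variable outside its category interval")


@dataclass
class SamplerConfig:
    """Hyperparameters, griddy grids and run lengths for the Gibbs sampler.

    ``c`` and ``c_prime`` are the scale hyperparameters of the generalized
    Pareto priors on ``rho`` and ``delta``. The griddy steps draw ``nu`` from
    ``nu_grid`` and the transformed hyperparameters ``u1 = 1/(1 + c*rho)``
    and ``u2 = 1/(1 + c_prime*delta)`` (uniform priors) from ``u_grid``.
    Defaults follow the reference analysis: 60k sweeps with a 20k burn-in
    and no thinning.
    """

    c: float = 1.0
    c_prime: float = 1.0
    nu_grid: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [np.arange(1.0, 31.0), [40.0, 50.0, 75.0, 100.0]]
        )
    )
    u_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.01, 0.99, 99))
    n_iter: int = 60_000
    burn_in: int = 20_000
    thin: int = 1
    seed: int = 0
    theta_floor: float = 1e-10  # |theta_j| floor in the inverse-Gaussian location

    def __post_init__(self) -> None:
        self.nu_grid = _as_1d_float(self.nu_grid, "nu_grid")
        self.u_grid = _as_1d_float(self.u_grid, "u_grid")
        if self.c <= 0 or self.c_prime <= 0:
            raise ValueError("c and c_prime must be positive")
        if self.nu_grid.size == 0 or np.any(self.nu_grid <= 0):
            raise ValueError("nu_grid must be non-empty and strictly positive")
        if self.u_grid.size == 0 or np.any((self.u_grid <= 0) | (self.u_grid >= 1)):
            raise ValueError("u_grid values must lie strictly inside (0, 1)")
        for g in (self.nu_grid, self.u_grid):
            if np.any(np.diff(g) <= 0):
                raise ValueError("grids must be sorted ascending without ties")
        if self.n_iter <= 0 or self.thin <= 0:
            raise ValueError("n_iter and thin must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")

    @property
    def n_kept(self) -> int:
        """Number of retained draws: floor((n_iter - burn_in) / thin)."""
        return (self.n_iter - self.burn_in) // self.thin

    def replace(self, **kwargs) -> "SamplerConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Densities and link


def gdp_log_density(theta_val: float, zeta: float, rho: float) -> float:
    """Log density of the Generalized Double Pareto distribution.

    ``f(theta | zeta, rho) = 1/(2*zeta) * (1 + |theta|/(rho*zeta))^-(1+rho)``.
    The density has a spike at zero and Student-t-like tails; as
    ``rho -> inf`` with ``zeta`` fixed it converges to the Laplace density
    ``(1/(2*zeta)) * exp(-|theta|/zeta)``.
    """
    if zeta <= 0 or rho <= 0:
        raise ValueError("zeta and rho must be strictly positive")
    theta_val = np.asarray(theta_val, dtype=float)
    return -np.log(2.0 * zeta) - (1.0 + rho) * np.log1p(np.abs(theta_val) / (rho * zeta))


def logistic_cdf(x):
    """Standard logistic CDF ``1 / (1 + exp(-x))``, overflow-safe."""
    return expit(x)


def class_probabilities(linear_predictor, gamma: np.ndarray, k: int) -> np.ndarray:
    """Category probabilities under the cumulative-logit link.

    ``pi_j = F(gamma_{j+1} - eta) - F(gamma_j - eta)`` where ``F`` is the
    logistic CDF and ``eta`` the linear predictor. Accepts a scalar ``eta``
    (returns shape ``(k,)``) or a vector (returns ``(n, k)``). Probabilities
    are non-negative and telescope to exactly one because ``F(-inf) = 0``
    and ``F(+inf) = 1``.
    """
    gamma = np.asarray(gamma, dtype=float)
    check_thresholds(gamma)
    if gamma.size != k + 1:
        raise ValueError(f"gamma must have length k+1={k + 1}, got {gamma.size}")
    eta = np.asarray(linear_predictor, dtype=float)
    cum = logistic_cdf(gamma[np.newaxis, :] - eta.reshape(-1, 1))
    probs = np.diff(cum, axis=1)
    probs = np.maximum(probs, 0.0)  # guard against tail cancellation
    if eta.ndim == 0:
        return probs[0]
    return probs


def classify(probs: np.ndarray) -> int | np.ndarray:
    """Most probable category (1-based); ties break toward the lowest index.

    This is the Bayes decision under 0-1 loss. Accepts a single probability
    vector or an ``(n, k)`` matrix of per-sample probabilities.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    if probs.ndim == 1:
        return int(np.argmax(probs)) + 1
    return np.argmax(probs, axis=1) + 1
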