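"""Gibbs sampler for the sparse Bayesian ordinal model with a GDP prior.

The scale-mixture hierarchy makes every conditional tractable or griddy:

* ``l_i | . ~ N(w_i' theta, 1/Lam_i)`` truncated to the interval of ``y_i``
  (the Student-t error, ``Lam_i ~ Gamma(nu/2, nu/2)``, approximates the
  logistic error law of the cumulative-logit link),
* ``theta | . ~ MVN([W' Lam W + T*]^-1 W' Lam l, [W' Lam W + T*]^-1)`` with
  ``T* = diag(1/tau_j)``,
* ``1/tau_j | . ~ Inverse-Gaussian(lam_j / |theta_j|, lam_j^2)``,
* ``lam_j | . ~ Gamma(rho + 1, |theta_j| + delta)`` (rate parameterization),
* ``Lam_r | . ~ Gamma((nu+1)/2, ((l_r - w_r' theta)^2 + nu)/2)``,
* ``nu`` and the transformed GDP hyperparameters ``u1 -> rho``,
  ``u2 -> delta`` by griddy Gibbs (evaluate the log conditional on a grid,
  normalize, draw),
* free thresholds ``gamma_s | . ~ Uniform(delta_1, delta_2)`` bounded by the
  neighbouring latents and thresholds.

A sweep visits the blocks in the fixed order latents, theta, tau, lam, Lam,
nu, u1/rho, u2/delta, thresholds. Any fixed scan order is a valid Gibbs
sampler; this one follows the hierarchy top-down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.special import gammaln

from .model_core import (
    InvariantViolation,
    ModelState,
    OrdinalDataset,
    SamplerConfig,
    check_thresholds,
    logistic_cdf,
    make_threshold_vector,
)

logger = logging.getLogger(__name__)

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


# ---------------------------------------------------------------------------
# Fully conditional draws


def sample_latents(
    state: ModelState, data: OrdinalDataset, rng: np.random.Generator
) -> np.ndarray:
    """Draw all latent responses from their doubly truncated normal conditionals.

    ``l_i ~ N(w_i' theta, 1/Lam_i)`` truncated to ``[gamma_{y_i}, gamma_{y_i+1})``.
    """
    mu = data.W @ state.theta
    sd = 1.0 / np.sqrt(state.Lam)
    lo = state.gamma[data.y - 1]
    hi = state.gamma[data.y]
    if np.any(lo >= hi):
        raise InvariantViolation("empty truncation interval for a latent draw")
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    # keep the half-open containment exact under floating-point rounding
    finite_hi = np.isfinite(hi)
    draws = np.where(
        finite_hi, np.minimum(draws, np.nextafter(hi, -np.inf)), draws
    )
    draws = np.maximum(draws, lo)
    return draws


def sample_theta(
    state: ModelState, data: OrdinalDataset, rng: np.random.Generator
) -> np.ndarray:
    """Joint draw of the coefficient vector from its multivariate normal conditional.

    Mean ``P^-1 W' Lam l`` and covariance ``P^-1`` with precision
    ``P = W' Lam W + diag(1/tau)``. The draw goes through a Cholesky
    factorization of ``P`` (never an explicit inverse), escalating a diagonal
    jitter if the factorization fails.
    """
    W = data.W
    WLam = W.T * state.Lam  # (p, n)
    P = WLam @ W
    P[np.diag_indices_from(P)] += 1.0 / state.tau
    b = WLam @ state.latent
    scale = np.mean(np.diag(P))
    for jit in _JITTERS:
        try:
            L = linalg.cholesky(P + jit * scale * np.eye(P.shape[0]), lower=True)
            break
        except linalg.LinAlgError:
            continue
    else:
        raise linalg.LinAlgError(
            f"theta precision factorization failed (p={P.shape[0]}, "
            f"cond~{np.linalg.cond(P):.2e}) even with jitter {_JITTERS[-1]}"
        )
    mean = linalg.cho_solve((L, True), b)
    z = rng.standard_normal(P.shape[0])
    return mean + linalg.solve_triangular(L.T, z, lower=False)


def sample_tau_inv(
    theta_j, lam_j, rng: np.random.Generator, theta_floor: float = 1e-10
):
    """Draw ``1/tau_j`` from an inverse-Gaussian with mean ``lam_j/|theta_j|``
    and shape ``lam_j^2``; ``|theta_j|`` is floored to keep the mean finite."""
    lam_j = np.asarray(lam_j, dtype=float)
    if np.any(lam_j <= 0):
        raise ValueError("lam_j must be strictly positive")
    abs_t = np.maximum(np.abs(np.asarray(theta_j, dtype=float)), theta_floor)
    mean = lam_j / abs_t
    shape = lam_j**2
    # scipy's invgauss(mu, scale) is IG(mean=mu*scale, shape=scale)
    return stats.invgauss.rvs(mean / shape, scale=shape, random_state=rng)


def sample_lambda(theta_j, rho: float, delta: float, rng: np.random.Generator):
    """Draw the exponential-rate mixing parameter:
    ``lam_j ~ Gamma(rho + 1, rate=|theta_j| + delta)``."""
    if rho <= 0 or delta <= 0:
        raise ValueError("rho and delta must be strictly positive")
    rate = np.abs(np.asarray(theta_j, dtype=float)) + delta
    return rng.gamma(shape=rho + 1.0, scale=1.0 / rate)


def sample_Lambda(residual, nu: float, rng: np.random.Generator):
    """Draw the t-mixture precision:
    ``Lam_r ~ Gamma((nu+1)/2, rate=((l_r - w_r' theta)^2 + nu)/2)``."""
    if nu <= 0:
        raise ValueError("nu must be strictly positive")
    rate = 0.5 * (np.asarray(residual, dtype=float) ** 2 + nu)
    return rng.gamma(shape=0.5 * (nu + 1.0), scale=1.0 / rate)


def griddy_draw(grid, log_weights, rng: np.random.Generator) -> float:
    """Sample one grid value with probability proportional to exp(log_weights).

    Normalization is done in log space (max subtraction) so widely spread
    conditionals cannot overflow.
    """
    grid = np.asarray(grid, dtype=float)
    lw = np.asarray(log_weights, dtype=float)
    if grid.shape != lw.shape or grid.size == 0:
        raise ValueError("grid and log_weights must be equal-length and non-empty")
    if np.all(np.isneginf(lw)):
        raise ValueError("all griddy weights are zero")
    if np.any(np.isnan(lw)) or np.any(np.isposinf(lw)):
        raise ValueError("griddy log-weights must be finite or -inf")
    w = np.exp(lw - np.max(lw))
    w /= w.sum()
    return float(rng.choice(grid, p=w))


def nu_log_weight(nu_candidate: float, Lam: np.ndarray) -> float:
    """Unnormalized log conditional of the t degrees of freedom ``nu``.

    ``sum_i [(nu/2 - 1) log Lam_i - nu Lam_i / 2]
    + n [ (nu/2) log(nu/2) - log Gamma(nu/2) ]``
    — one Gamma(nu/2, nu/2) factor per sample, in log space throughout.
    """
    Lam = np.asarray(Lam, dtype=float)
    h = 0.5 * nu_candidate
    term_data = np.sum((h - 1.0) * np.log(Lam) - h * Lam)
    return float(term_data + Lam.size * (h * np.log(h) - gammaln(h)))


def u1_log_weight(u1: float, theta: np.ndarray, delta: float, c: float) -> float:
    """Unnormalized log conditional of ``u1 = 1/(1 + c*rho)``.

    ``p log((1-u1)/(c u1)) - ((1-u1)/(c u1) + 1) sum_j log(1 + |theta_j|/delta)``;
    the implied GDP shape is ``rho = (1/c)(1/u1 - 1)``.
    """
    if not 0.0 < u1 < 1.0:
        raise ValueError("u1 must lie strictly inside (0, 1)")
    theta = np.asarray(theta, dtype=float)
    rho = (1.0 - u1) / (c * u1)
    s = np.sum(np.log1p(np.abs(theta) / delta))
    return float(theta.size * np.log(rho) - (rho + 1.0) * s)


def u2_log_weight(u2: float, theta: np.ndarray, rho: float, c_prime: float) -> float:
    """Unnormalized log conditional of ``u2 = 1/(1 + c'*delta)``.

    ``p log(c' u2/(1-u2)) - (1+rho) sum_j log(1 + c' u2 |theta_j|/(1-u2))``;
    the implied GDP scale is ``delta = (1/c')(1/u2 - 1)``.
    """
    if not 0.0 < u2 < 1.0:
        raise ValueError("u2 must lie strictly inside (0, 1)")
    theta = np.asarray(theta, dtype=float)
    inv_delta = c_prime * u2 / (1.0 - u2)
    s = np.sum(np.log1p(inv_delta * np.abs(theta)))
    return float(theta.size * np.log(inv_delta) - (1.0 + rho) * s)


def _nu_log_weights_grid(nu_grid: np.ndarray, Lam: np.ndarray) -> np.ndarray:
    """``nu_log_weight`` evaluated at every grid point at once."""
    Lam = np.asarray(Lam, dtype=float)
    h = 0.5 * np.asarray(nu_grid, dtype=float)
    s_log, s_lam = np.sum(np.log(Lam)), np.sum(Lam)
    return (h - 1.0) * s_log - h * s_lam + Lam.size * (h * np.log(h) - gammaln(h))


def _u1_log_weights_grid(
    u_grid: np.ndarray, theta: np.ndarray, delta: float, c: float
) -> np.ndarray:
    """``u1_log_weight`` evaluated at every grid point at once."""
    u = np.asarray(u_grid, dtype=float)
    rho = (1.0 - u) / (c * u)
    s = np.sum(np.log1p(np.abs(theta) / delta))
    return theta.size * np.log(rho) - (rho + 1.0) * s


def _u2_log_weights_grid(
    u_grid: np.ndarray, theta: np.ndarray, rho: float, c_prime: float
) -> np.ndarray:
    """``u2_log_weight`` evaluated at every grid point at once."""
    u = np.asarray(u_grid, dtype=float)
    inv_delta = c_prime * u / (1.0 - u)
    s = np.log1p(np.outer(inv_delta, np.abs(theta))).sum(axis=1)
    return theta.size * np.log(inv_delta) - (1.0 + rho) * s


def rho_from_u1(u1: float, c: float) -> float:
    return (1.0 / c) * (1.0 / u1 - 1.0)


def delta_from_u2(u2: float, c_prime: float) -> float:
    return (1.0 / c_prime) * (1.0 / u2 - 1.0)


def sample_thresholds(
    state: ModelState,
    data: OrdinalDataset,
    rng: np.random.Generator,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> np.ndarray:
    """Draw each free threshold from its uniform conditional.

    With ``gamma_1 = -inf`` and ``gamma_{k+1} = +inf`` fixed, every interior
    threshold ``gamma_s`` (s = 2..k) is drawn Uniform(d1, d2) with
    ``d1 = max(max{l_i : y_i = s-1}, gamma_{s-1})`` and
    ``d2 = min(min{l_i : y_i = s}, gamma_{s+1})``. Because the latent has no
    intercept, all k-1 thresholds are identified and sampled; this is the
    same model as an intercept plus a first threshold pinned at zero, in the
    parameterization that keeps the coefficient block free of location
    bookkeeping. Categories absent from the data contribute no latent bound,
    leaving the neighbouring thresholds; a threshold whose conditional is
    improper (an empty *edge* category next to an infinite sentinel) keeps
    its current value. ``lower``/``upper`` optionally bound every threshold
    (used by diagnostics that need a proper bounded-uniform prior).
    """
    gamma = state.gamma.copy()
    k = data.k
    for m in range(1, k):  # array slot m holds the paper's gamma_{m+1}
        below = state.latent[data.y == m]
        above = state.latent[data.y == m + 1]
        d1 = max(below.max(), gamma[m - 1]) if below.size else gamma[m - 1]
        d2 = min(above.min(), gamma[m + 1]) if above.size else gamma[m + 1]
        d1 = max(d1, lower)
        d2 = min(d2, upper)
        if not (np.isfinite(d1) and np.isfinite(d2)):
            continue  # improper conditional: keep the current threshold
        if d1 > d2:
            raise InvariantViolation(
                f"empty threshold interval at cut {m + 1}: ({d1}, {d2})"
            )
        gamma[m] = rng.uniform(d1, d2)
    check_thresholds(gamma)
    return gamma


# ---------------------------------------------------------------------------
# Chain orchestration


@dataclass
class ChainSummary:
    """Posterior summaries of one chain after burn-in and thinning."""

    theta_mean: np.ndarray
    theta_sd: np.ndarray
    gamma_mean: np.ndarray
    nu_mean: float
    rho_mean: float
    delta_mean: float
    n_kept: int
    rank_order: np.ndarray  # feature indices by decreasing |posterior mean|
    k: int
    feature_ids: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "theta_mean": self.theta_mean.tolist(),
            "theta_sd": self.theta_sd.tolist(),
            "gamma_mean": [
                "-inf" if np.isneginf(g) else "inf" if np.isposinf(g) else g
                for g in self.gamma_mean
            ],
            "nu_mean": self.nu_mean,
            "rho_mean": self.rho_mean,
            "delta_mean": self.delta_mean,
            "n_kept": self.n_kept,
            "rank_order": self.rank_order.tolist(),
            "k": self.k,
            "feature_ids": self.feature_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainSummary":
        gamma = np.array(
            [
                -np.inf if g == "-inf" else np.inf if g == "inf" else float(g)
                for g in d["gamma_mean"]
            ]
        )
        return cls(
            theta_mean=np.asarray(d["theta_mean"], dtype=float),
            theta_sd=np.asarray(d["theta_sd"], dtype=float),
            gamma_mean=gamma,
            nu_mean=float(d["nu_mean"]),
            rho_mean=float(d["rho_mean"]),
            delta_mean=float(d["delta_mean"]),
            n_kept=int(d["n_kept"]),
            rank_order=np.asarray(d["rank_order"], dtype=int),
            k=int(d["k"]),
            feature_ids=d.get("feature_ids"),
        )


def _rank_by_magnitude(theta_mean: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing |theta|, ties to the lower index."""
    # stable sort on -|theta| keeps the original order among ties
    return np.argsort(-np.abs(theta_mean), kind="stable")


def initial_state(
    data: OrdinalDataset, config: SamplerConfig, rng: np.random.Generator
) -> ModelState:
    """Deterministic-prior starting point.

    ``theta = 0``, unit scale parameters, ``nu = 7`` (a common t
    approximation to the logistic), ``rho = delta = 1``; thresholds at the
    logit of empirical cumulative label frequencies; latents from one
    truncated-normal draw.
    """
    n, p = data.n, data.p
    counts = np.bincount(data.y, minlength=data.k + 1)[1:]
    cum = np.cumsum(counts) / n
    cum = np.clip(cum, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    logits = np.log(cum[:-1] / (1.0 - cum[:-1]))
    interior = np.maximum.accumulate(logits)
    state = ModelState(
        theta=np.zeros(p),
        tau=np.ones(p),
        lam=np.ones(p),
        Lam=np.ones(n),
        latent=np.zeros(n),
        gamma=make_threshold_vector(interior, data.k),
        nu=7.0,
        rho=1.0,
        delta=1.0,
    )
    state.latent = sample_latents(state, data, rng)
    return state


def gibbs_sweep(
    state: ModelState,
    data: OrdinalDataset,
    config: SamplerConfig,
    rng: np.random.Generator,
    fixed: frozenset | set | tuple = (),
    threshold_lower: float = -np.inf,
    threshold_upper: float = np.inf,
) -> None:
    """One in-place scan of all fully conditional updates.

    ``fixed`` names blocks that are skipped; ``threshold_lower``/``upper``
    bound the free thresholds (finite only under a proper bounded-uniform
    threshold prior, as in the stationarity audit).
    """
    # The lambda conditional Gamma(rho+1, |theta|+delta) and the u1/u2
    # conditionals are *collapsed* (tau, lambda integrated out: they follow
    # from the double-exponential and GDP marginals of theta). A partially
    # collapsed Gibbs sampler is only valid if every marginalized draw comes
    # before the marginalized-out blocks are redrawn, so the scan order is
    # latents, theta, nu, rho, delta, lambda, tau, Lambda, thresholds.
    if "latent" not in fixed:
        state.latent = sample_latents(state, data, rng)
    if "theta" not in fixed:
        state.theta = sample_theta(state, data, rng)
    if "nu" not in fixed:
        lw = _nu_log_weights_grid(config.nu_grid, state.Lam)
        state.nu = griddy_draw(config.nu_grid, lw, rng)
    if "rho" not in fixed:
        lw = _u1_log_weights_grid(config.u_grid, state.theta, state.delta, config.c)
        state.rho = rho_from_u1(griddy_draw(config.u_grid, lw, rng), config.c)
    if "delta" not in fixed:
        lw = _u2_log_weights_grid(config.u_grid, state.theta, state.rho, config.c_prime)
        state.delta = delta_from_u2(griddy_draw(config.u_grid, lw, rng), config.c_prime)
    if "lam" not in fixed:
        state.lam = sample_lambda(state.theta, state.rho, state.delta, rng)
    if "tau" not in fixed:
        inv = sample_tau_inv(state.theta, state.lam, rng, theta_floor=config.theta_floor)
        state.tau = 1.0 / inv
    if "Lam" not in fixed:
        resid = state.latent - data.W @ state.theta
        state.Lam = sample_Lambda(resid, state.nu, rng)
    if "gamma" not in fixed:
        state.gamma = sample_thresholds(
            state, data, rng, lower=threshold_lower, upper=threshold_upper
        )


def run_chain(
    data: OrdinalDataset,
    config: SamplerConfig,
    fixed: dict | None = None,
    keep_draws: bool = False,
    validate_every: int = 0,
) -> ChainSummary:
    """Run the full Gibbs sampler and summarize the retained draws.

    Parameters
    ----------
    fixed
        Optional mapping of block name (``latent``, ``theta``, ``tau``,
        ``lam``, ``Lam``, ``gamma``, ``nu``, ``rho``, ``delta``) to a fixed
        value; fixed blocks are initialized to that value and never updated.
        Used by diagnostics (e.g. the conjugate-limit check with unit
        ``Lam`` and fixed latents/thresholds).
    keep_draws
        Attach the full retained draw arrays to the summary as ``.draws``
        (dict with keys theta, gamma, nu, rho, delta).
    validate_every
        If positive, re-check all state invariants every that many sweeps.

    Two runs with the same config (including seed) are bitwise identical.
    """
    fixed = fixed or {}
    rng = np.random.default_rng(config.seed)
    state = initial_state(data, config, rng)
    for name, value in fixed.items():
        if not hasattr(state, name):
            raise ValueError(f"unknown fixed block {name!r}")
        current = getattr(state, name)
        setattr(
            state,
            name,
            np.asarray(value, dtype=float) if np.ndim(current) else float(value),
        )
    if fixed and "latent" not in fixed:
        # overridden blocks may invalidate the initial latent draw
        state.latent = sample_latents(state, data, rng)
    state.validate(data.y if "latent" not in fixed else None)

    n_kept = config.n_kept
    kept_theta = np.empty((n_kept, data.p))
    kept_gamma = np.empty((n_kept, data.k + 1))
    kept_nu = np.empty(n_kept)
    kept_rho = np.empty(n_kept)
    kept_delta = np.empty(n_kept)

    log_every = max(1, config.n_iter // 10)
    fixed_names = frozenset(fixed)
    kept = 0
    for it in range(config.n_iter):
        try:
            gibbs_sweep(state, data, config, rng, fixed=fixed_names)
        except Exception as exc:
            raise type(exc)(f"sweep {it}: {exc}") from exc

        if validate_every and (it + 1) % validate_every == 0:
            state.validate(data.y if "latent" not in fixed else None)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if kept < n_kept:
                kept_theta[kept] = state.theta
                kept_gamma[kept] = state.gamma
                kept_nu[kept] = state.nu
                kept_rho[kept] = state.rho
                kept_delta[kept] = state.delta
                kept += 1
        if (it + 1) % log_every == 0:
            logger.info(
                "sweep %d/%d (kept %d) nu=%.1f rho=%.3f delta=%.3f",
                it + 1,
                config.n_iter,
                kept,
                state.nu,
                state.rho,
                state.delta,
            )

    theta_mean = kept_theta[:kept].mean(axis=0)
    summary = ChainSummary(
        theta_mean=theta_mean,
        theta_sd=kept_theta[:kept].std(axis=0, ddof=1) if kept > 1 else np.zeros(data.p),
        gamma_mean=np.concatenate(
            [[-np.inf], kept_gamma[:kept, 1:-1].mean(axis=0), [np.inf]]
        ),
        nu_mean=float(kept_nu[:kept].mean()),
        rho_mean=float(kept_rho[:kept].mean()),
        delta_mean=float(kept_delta[:kept].mean()),
        n_kept=kept,
        rank_order=_rank_by_magnitude(theta_mean),
        k=data.k,
        feature_ids=list(data.feature_ids),
    )
    if keep_draws:
        summary.draws = {
            "theta": kept_theta[:kept],
            "gamma": kept_gamma[:kept],
            "nu": kept_nu[:kept],
            "rho": kept_rho[:kept],
            "delta": kept_delta[:kept],
        }
    return summary


def rank_genes(summary: ChainSummary, top_m: int) -> np.ndarray:
    """Top ``top_m`` feature indices by decreasing |posterior mean theta|.

    Magnitude ranking keeps strong negative markers; ties break toward the
    lower feature index. Indices are 0-based positions into the summary's
    feature list.
    """
    p = summary.theta_mean.size
    if not 1 <= top_m <= p:
        raise ValueError(f"top_m must lie in 1..{p}, got {top_m}")
    return summary.rank_order[:top_m]
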