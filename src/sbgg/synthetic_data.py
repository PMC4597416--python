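"""Synthetic ordinal expression data with planted sparse ground truth.

The generator emits exactly the data-generating process the model assumes:
iid standard-normal covariates, a sparse coefficient vector with
alternating-sign planted effects, a latent linear predictor plus logistic
(or Student-t) noise, and thresholds placed at empirical latent quantiles so
the ordinal categories come out near-balanced. Alternating signs prevent
recovery via a marginal mean shift alone; balanced categories mirror the
balanced train/test design of the evaluation harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model_core import OrdinalDataset, class_probabilities, classify

_NOISE_LAWS = ("logistic", "student-t")


@dataclass
class SyntheticTruth:
    """Planted parameters behind a generated dataset."""

    theta_true: np.ndarray
    support: np.ndarray  # indices of nonzero coefficients (0-based, sorted)
    gamma_true: np.ndarray
    noise: str  # "logistic" or "student-t with nu=<df>"

    def __post_init__(self) -> None:
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        if self.support.size != np.count_nonzero(self.theta_true):
            raise ValueError("support size must equal the number of nonzero effects")

    def to_dict(self) -> dict:
        return {
            "theta_true": self.theta_true.tolist(),
            "support": self.support.tolist(),
            "gamma_true": [
                "-inf" if np.isneginf(g) else "inf" if np.isposinf(g) else g
                for g in self.gamma_true
            ],
            "noise": self.noise,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def generate(
    n: int,
    p: int,
    k: int,
    n_signal: int,
    effect: float,
    noise: str = "logistic",
    seed: int = 0,
    t_dof: float = 7.0,
) -> tuple[OrdinalDataset, SyntheticTruth]:
    """Generate an ordinal dataset from the latent-variable model.

    ``W`` is n x p iid standard normal; ``theta_true`` has ``n_signal``
    entries of magnitude ``effect`` with alternating signs at random
    positions; latents are ``W theta + e`` with ``e`` iid logistic or
    Student-t(``t_dof``); thresholds sit at the empirical ``j/k`` latent
    quantiles, so every category is occupied whenever ``n`` is a reasonable
    multiple of ``k``. Fully reproducible from ``seed``.
    """
    if k < 2:
        raise ValueError("need at least two categories")
    if n < k:
        raise ValueError(f"cannot balance {k} categories with only {n} samples")
    if not 0 <= n_signal <= p:
        raise ValueError("n_signal must lie in 0..p")
    if effect < 0:
        raise ValueError("effect magnitude must be non-negative")
    if noise not in _NOISE_LAWS:
        raise ValueError(f"noise must be one of {_NOISE_LAWS}")

    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, p))
    theta = np.zeros(p)
    support = np.sort(rng.choice(p, size=n_signal, replace=False))
    signs = np.where(np.arange(n_signal) % 2 == 0, 1.0, -1.0)
    theta[support] = signs * effect

    if noise == "logistic":
        e = rng.logistic(0.0, 1.0, size=n)
        label = "logistic"
    else:
        e = rng.standard_t(t_dof, size=n)
        label = f"student-t with nu={t_dof:g}"

    latent = W @ theta + e
    cuts = np.quantile(latent, np.arange(1, k) / k)
    cuts = np.maximum.accumulate(cuts)
    gamma = np.concatenate([[-np.inf], cuts, [np.inf]])
    y = np.searchsorted(cuts, latent, side="right") + 1

    # the construction must place every latent inside its category interval
    assert np.all(gamma[y - 1] <= latent) and np.all(latent < gamma[y])

    data = OrdinalDataset(
        W=W,
        y=y,
        sample_ids=[f"S{i + 1}" for i in range(n)],
        feature_ids=[f"G{j + 1}" for j in range(p)],
        k=k,
    )
    truth = SyntheticTruth(theta_true=theta, support=support, gamma_true=gamma, noise=label)
    return data, truth


def bayes_accuracy(truth: SyntheticTruth, data: OrdinalDataset) -> float:
    """Accuracy of the true-parameter classifier on the dataset.

    Plugs ``theta_true`` and ``gamma_true`` into the category probabilities
    and takes the most probable class. This is the performance ceiling any
    fitted model is benchmarked against on matched synthetic data.
    """
    eta = data.W @ truth.theta_true
    probs = class_probabilities(eta, truth.gamma_true, data.k)
    predicted = classify(probs)
    return float(np.mean(predicted == data.y))
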