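"""Balanced-resampling evaluation of the fitted classifier.

The harness mirrors the study design the model was built for: stratified
train/test splits with (near) equal class composition, a fit on all
screened genes, a refit restricted to the top-m genes ranked by
|posterior mean theta| on the training fit, and plug-in classification of
the held-out samples. Selecting the marker panel on the training fit only
keeps the test set untouched by the selection step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .gibbs_sampler import ChainSummary, rank_genes, run_chain
from .model_core import OrdinalDataset, SamplerConfig, class_probabilities, classify

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Accuracy bookkeeping across one or more resampling runs.

    ``confusion`` pools counts over runs (rows = true class, columns =
    predicted); per-class accuracy is the mean across runs of the per-run
    class recalls, matching the mean/sd reporting of resampling studies.
    """

    overall_accuracy: float
    overall_sd: float
    per_class_accuracy: np.ndarray
    per_class_sd: np.ndarray
    confusion: np.ndarray
    runs: int
    top_m: int
    per_run_accuracies: np.ndarray
    per_run_class_accuracies: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "overall_sd": self.overall_sd,
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "per_class_sd": self.per_class_sd.tolist(),
            "confusion": self.confusion.tolist(),
            "runs": self.runs,
            "top_m": self.top_m,
            "per_run_accuracies": self.per_run_accuracies.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def balanced_split(
    data: OrdinalDataset, train_frac: float = 0.5, seed: int = 0
) -> tuple[OrdinalDataset, OrdinalDataset]:
    """Stratified random train/test partition.

    Each class contributes ``round(train_frac * class size)`` samples to the
    training set (clipped so both halves keep at least one sample per
    class); the remainder goes to test. The two halves partition the data
    exactly and the split is a pure function of the seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in range(1, data.k + 1):
        members = np.flatnonzero(data.y == cls)
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_train = int(np.floor(train_frac * members.size + 0.5))
        n_train = min(max(n_train, 1), members.size - 1)
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))
    return data.subset(rows=train_idx), data.subset(rows=test_idx)


def predict(summary: ChainSummary, W: np.ndarray) -> np.ndarray:
    """Plug-in classification: posterior-mean theta and thresholds."""
    eta = np.asarray(W, dtype=float) @ summary.theta_mean
    probs = class_probabilities(eta, summary.gamma_mean, summary.k)
    return classify(probs)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> np.ndarray:
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (y_true - 1, y_pred - 1), 1)
    return conf


def _per_class_accuracy(conf: np.ndarray) -> np.ndarray:
    row = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.diag(conf) / row
    return np.where(row > 0, acc, np.nan)


def evaluate_once(
    data: OrdinalDataset,
    top_m: int,
    config: SamplerConfig,
    seed: int = 0,
    train_frac: float = 0.5,
    predictive_average: bool = False,
) -> EvaluationReport:
    """One split-fit-select-refit-predict cycle.

    Fits the full model on the training half, picks the ``top_m`` genes by
    |posterior mean theta|, refits on the training half restricted to those
    genes, and classifies the test half with posterior-mean parameters.
    With ``predictive_average=True`` the test-class probabilities are
    averaged over the retained posterior draws instead of plugging in the
    posterior means.
    """
    if top_m > data.p:
        raise ValueError("top_m exceeds the number of features")
    ss = np.random.SeedSequence(seed)
    split_seed, fit_seed, refit_seed = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)
    )
    train, test = balanced_split(data, train_frac=train_frac, seed=split_seed)

    full = run_chain(train, config.replace(seed=fit_seed))
    top = rank_genes(full, top_m)
    refit = run_chain(
        train.subset(cols=top),
        config.replace(seed=refit_seed),
        keep_draws=predictive_average,
    )

    W_test = test.W[:, top]
    if predictive_average:
        draws = refit.draws
        probs = np.zeros((test.n, test.k))
        for t in range(draws["theta"].shape[0]):
            probs += class_probabilities(
                W_test @ draws["theta"][t], draws["gamma"][t], test.k
            )
        probs /= draws["theta"].shape[0]
        y_pred = classify(probs)
    else:
        y_pred = predict(refit, W_test)

    conf = _confusion(test.y, y_pred, test.k)
    overall = float(np.trace(conf) / conf.sum())
    per_class = _per_class_accuracy(conf)
    return EvaluationReport(
        overall_accuracy=overall,
        overall_sd=0.0,
        per_class_accuracy=per_class,
        per_class_sd=np.zeros(test.k),
        confusion=conf,
        runs=1,
        top_m=top_m,
        per_run_accuracies=np.array([overall]),
        per_run_class_accuracies=per_class[np.newaxis, :],
    )


def resampling_experiment(
    data: OrdinalDataset,
    top_m: int,
    n_runs: int,
    config: SamplerConfig,
    seed: int = 0,
    train_frac: float = 0.5,
    predictive_average: bool = False,
) -> EvaluationReport:
    """Repeat ``evaluate_once`` over independent balanced resamplings.

    Run ``i`` uses master seed ``seed + i`` so any single run can be
    replayed in isolation. Reports the mean and standard deviation of the
    overall and per-class accuracies and the pooled confusion matrix.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    reports = []
    for i in range(n_runs):
        rep = evaluate_once(
            data,
            top_m,
            config,
            seed=seed + i,
            train_frac=train_frac,
            predictive_average=predictive_average,
        )
        logger.info("run %d/%d accuracy %.3f", i + 1, n_runs, rep.overall_accuracy)
        reports.append(rep)

    acc = np.array([r.overall_accuracy for r in reports])
    class_acc = np.vstack([r.per_class_accuracy for r in reports])
    conf = np.sum([r.confusion for r in reports], axis=0)
    return EvaluationReport(
        overall_accuracy=float(acc.mean()),
        overall_sd=float(acc.std(ddof=1)) if n_runs > 1 else 0.0,
        per_class_accuracy=np.nanmean(class_acc, axis=0),
        per_class_sd=np.nanstd(class_acc, axis=0, ddof=1)
        if n_runs > 1
        else np.zeros(data.k),
        confusion=conf,
        runs=n_runs,
        top_m=top_m,
        per_run_accuracies=acc,
        per_run_class_accuracies=class_acc,
    )
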