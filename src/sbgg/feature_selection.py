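"""Single-gene ordinal-logistic screening with Benjamini–Hochberg FDR.

Before the multivariate Bayesian fit, each gene is tested on its own in a
one-covariate cumulative-logit (proportional-odds) model; genes are ranked
by the p-value for H0: theta_j = 0 and kept when their BH-adjusted value
falls below the FDR threshold. The proportional-odds parameterization uses
the same latent/threshold convention as the Bayesian model (ascending
cutpoints, logistic errors), so slope signs agree between the screen and
the sampler.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .model_core import OrdinalDataset

logger = logging.getLogger(__name__)


@dataclass
class GeneFit:
    """MLE of the one-gene proportional-odds slope with a Wald test."""

    coef: float
    se: float
    pvalue: float
    converged: bool


@dataclass
class FeatureRanking:
    """Screening result across all genes."""

    pvalues: np.ndarray
    qvalues: np.ndarray
    selected: np.ndarray  # boolean, q <= fdr_threshold
    order: np.ndarray  # indices by ascending p-value, ties to lower index
    coefs: np.ndarray
    ses: np.ndarray
    fdr_threshold: float
    feature_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = self.feature_ids or [f"G{j + 1}" for j in range(self.pvalues.size)]
        return pd.DataFrame(
            {
                "feature_id": ids,
                "coef": self.coefs,
                "se": self.ses,
                "pvalue": self.pvalues,
                "qvalue": self.qvalues,
                "selected": self.selected,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_single_gene_ordinal(
    x: np.ndarray, y: np.ndarray, k: int, use_lr: bool = False, maxiter: int = 200
) -> GeneFit:
    """Fit the one-covariate cumulative-logit model and test H0: slope = 0.

    The likelihood is maximized by statsmodels' Newton-type optimizer for
    the proportional-odds model with ``k - 1`` free cutpoints. The returned
    p-value is the two-sided Wald test from the observed information; with
    ``use_lr=True`` a likelihood-ratio test against the intercepts-only
    multinomial fit is reported instead. Non-convergent fits come back
    flagged with ``pvalue = 1`` so a genome-wide screen never aborts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")
    if np.unique(y).size < k:
        raise ValueError("all k categories must be present in y")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(y, x[:, None], distr="logit")
            res = model.fit(method="bfgs", maxiter=maxiter, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
        coef = float(res.params[0])
        se = float(res.bse[0])
        pvalue = float(res.pvalues[0])
        if use_lr:
            counts = np.bincount(y, minlength=k + 1)[1:]
            ll0 = float(np.sum(counts * np.log(counts / y.size)))
            lr = 2.0 * (res.llf - ll0)
            pvalue = float(stats.chi2.sf(max(lr, 0.0), df=1))
        if not (converged and np.isfinite(coef) and np.isfinite(se) and se > 0):
            return GeneFit(coef=coef, se=se, pvalue=1.0, converged=False)
        return GeneFit(coef=coef, se=se, pvalue=pvalue, converged=True)
    except (np.linalg.LinAlgError, ValueError, FloatingPointError) as exc:
        logger.debug("single-gene fit failed: %s", exc)
        return GeneFit(coef=np.nan, se=np.nan, pvalue=1.0, converged=False)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sorted ascending, ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)``, mapped
    back to the input order; invariant under permutation of the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-d")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_features(
    data: OrdinalDataset,
    fdr_threshold: float = 0.05,
    standardize: bool = True,
    use_lr: bool = False,
) -> FeatureRanking:
    """Screen every gene with the single-gene ordinal fit and BH correction.

    Genes whose fit fails or does not converge enter the BH correction with
    ``pvalue = 1`` (conservative) and can never be selected. ``standardize``
    z-scores each gene before fitting; it changes the slope scale but not
    the Wald p-value ordering, and matches the default preprocessing of the
    Bayesian fit.
    """
    if not 0.0 < fdr_threshold < 1.0:
        raise ValueError("fdr_threshold must lie strictly inside (0, 1)")
    p = data.p
    coefs = np.full(p, np.nan)
    ses = np.full(p, np.nan)
    pvals = np.ones(p)
    for j in range(p):
        x = data.W[:, j]
        if np.ptp(x) == 0:
            logger.warning("feature %s has zero variance; excluded", data.feature_ids[j])
            continue
        if standardize:
            x = (x - x.mean()) / x.std()
        fit = fit_single_gene_ordinal(x, data.y, data.k, use_lr=use_lr)
        coefs[j], ses[j], pvals[j] = fit.coef, fit.se, fit.pvalue
    qvals = bh_adjust(pvals)
    selected = qvals <= fdr_threshold
    order = np.argsort(pvals, kind="stable")
    return FeatureRanking(
        pvalues=pvals,
        qvalues=qvals,
        selected=selected,
        order=order,
        coefs=coefs,
        ses=ses,
        fdr_threshold=fdr_threshold,
        feature_ids=list(data.feature_ids),
    )
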