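"""Competition-outcome statistics.

Winners are predicted from physical factors and rise counts with a
binomial GLM with logistic link, y ~ expit(c0 + sum_i c_i x_i).  Model
discrimination is summarized by the area under the ROC curve, with a
bootstrap SD; time-resolved AUC tracks how quickly cumulative rise counts
separate winners from losers.  Backward elimination prunes regression
models at alpha = 0.05, and a permutation test checks win-lose histories
for serial dependence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class GlmFit:
    """Coefficient table and discrimination summary of one logistic fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    predicted: np.ndarray
    auc: float
    auc_sd: float | None = None
    separation_flag: bool = False
    model: object = field(default=None, repr=False)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"lo": self.params - z * self.bse, "hi": self.params + z * self.bse}
        )


def fit_logistic_glm(features: pd.DataFrame, outcome) -> GlmFit:
    """Maximum-likelihood logistic GLM (IRLS) with Wald p-values.

    ``outcome`` is binary; a constant is added automatically.  Perfect
    separation is reported via ``separation_flag`` instead of silently
    diverging.
    """
    y = np.asarray(outcome).astype(float)
    if np.unique(y).size < 2:
        raise ValueError("degenerate outcome: all observations identical")
    X = sm.add_constant(features.astype(float), has_constant="add")
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
        for w in caught:
            if "separat" in str(w.message).lower():
                separated = True
    if not separated and np.abs(res.params).max() > 50:
        separated = True  # runaway coefficients: separation in disguise
    if separated:
        logger.warning("perfect separation detected; coefficients unreliable")
    pred = np.asarray(res.predict(X))
    return GlmFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        predicted=pred,
        auc=roc_auc(pred, y > 0.5),
        separation_flag=separated,
        model=res,
    )


def roc_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via midranks.

    Equivalent to the Mann-Whitney U statistic normalized by n1*n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_auc_sd(
    scores,
    labels,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """SD of the AUC over class-stratified bootstrap resamples."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    for k in range(n_boot):
        s = np.concatenate(
            [rng.choice(pos, pos.size, replace=True),
             rng.choice(neg, neg.size, replace=True)]
        )
        aucs[k] = roc_auc(s, lab)
    return float(aucs.std(ddof=1))


def cumulative_counts(times_list: list[np.ndarray], eval_times: np.ndarray) -> np.ndarray:
    """(n_series, n_eval) cumulative event counts at each evaluation time."""
    eval_times = np.asarray(eval_times, dtype=float)
    out = np.empty((len(times_list), eval_times.size))
    for i, t in enumerate(times_list):
        out[i] = np.searchsorted(np.sort(np.asarray(t, dtype=float)),
                                 eval_times, side="right")
    return out


def time_resolved_auc(
    loser_counts: np.ndarray,
    winner_counts: np.ndarray,
    eval_times: np.ndarray,
) -> np.ndarray:
    """AUC(t) for discriminating losers from winners by cumulative counts.

    ``loser_counts`` and ``winner_counts`` are (n_trials, n_times) and must
    be non-decreasing along time.  Losers are the positive class (they emit
    more rises).  All-tied times (e.g. t = 0) give AUC = 0.5.
    """
    lc = np.atleast_2d(np.asarray(loser_counts, dtype=float))
    wc = np.atleast_2d(np.asarray(winner_counts, dtype=float))
    eval_times = np.asarray(eval_times, dtype=float)
    if lc.shape != wc.shape or lc.shape[1] != eval_times.size:
        raise ValueError("count matrices must be (n_trials, n_eval_times)")
    for m in (lc, wc):
        if np.any(np.diff(m, axis=1) < 0):
            raise ValueError("cumulative counts must be non-decreasing")
    labels = np.concatenate([np.ones(lc.shape[0], bool), np.zeros(wc.shape[0], bool)])
    return np.array(
        [roc_auc(np.concatenate([lc[:, j], wc[:, j]]), labels)
         for j in range(eval_times.size)]
    )


@dataclass
class EliminationResult:
    final_features: list[str]
    eliminated: list[tuple[str, float]]  # (feature, p at removal)
    fit: object
    r_squared: float | None = None


def _fit_family(X: pd.DataFrame, y: np.ndarray, family: str):
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if family == "linear":
        return sm.OLS(y, Xc).fit()
    if family == "logistic":
        return sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
    raise ValueError("family must be 'linear' or 'logistic'")


def backward_eliminate(
    features: pd.DataFrame,
    response,
    alpha: float = 0.05,
    family: str = "linear",
) -> EliminationResult:
    """Backward elimination: drop the worst feature while its p > alpha.

    Perfectly collinear columns are removed (with a warning) before
    selection.  Returns the final fit, the surviving features, the ordered
    elimination log, and R^2 for linear models.
    """
    y = np.asarray(response, dtype=float)
    X = features.astype(float).copy()
    # drop exactly collinear columns, keeping the earliest
    keep: list[str] = []
    for col in X.columns:
        trial = X[keep + [col]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == len(keep) + 2:
            keep.append(col)
        else:
            warnings.warn(f"dropping collinear feature {col!r}", stacklevel=2)
    X = X[keep]
    eliminated: list[tuple[str, float]] = []
    while len(X.columns):
        res = _fit_family(X, y, family)
        pvals = res.pvalues.drop("const", errors="ignore")
        worst = pvals.idxmax()
        if pvals[worst] > alpha:
            eliminated.append((str(worst), float(pvals[worst])))
            X = X.drop(columns=[worst])
        else:
            break
    fit = _fit_family(X if len(X.columns) else X, y, family)
    r2 = float(fit.rsquared) if family == "linear" else None
    return EliminationResult(list(X.columns), eliminated, fit, r2)


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.std() == 0 or x[:-1].std() == 0 or x[1:].std() == 0:
        return np.nan
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def winlose_autocorrelation_test(
    sequences: list[np.ndarray],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation test for serial dependence of win-lose histories.

    Sequences are +/-1 coded per fish; the statistic is the mean lag-1
    autocorrelation across fish.  The null permutes each fish's outcomes
    within its own sequence.  Constant sequences carry no autocorrelation
    and are excluded (logged).  Returns (statistic, two-sided p), where the
    p-value is centered on the permutation mean.
    """
    seqs = []
    for s in sequences:
        s = np.asarray(s, dtype=float)
        if s.size < 3:
            raise ValueError("sequences must have length >= 3")
        if np.isnan(_lag1_autocorr(s)):
            logger.info("excluding constant win-lose sequence")
            continue
        seqs.append(s)
    if not seqs:
        raise ValueError("no usable (non-constant) sequences remain")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    obs = float(np.mean([_lag1_autocorr(s) for s in seqs]))
    null = np.empty(n_perm)
    for k in range(n_perm):
        vals = [_lag1_autocorr(rng.permutation(s)) for s in seqs]
        null[k] = np.nanmean(vals)
    center = null.mean()
    p = (1.0 + np.sum(np.abs(null - center) >= abs(obs - center))) / (n_perm + 1.0)
    return obs, float(min(p, 1.0))
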