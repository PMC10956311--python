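"""Discrimination metrics: ROC AUC, BCa bootstrap, Youden cutoff, PPV/NPV.

The AUC is the Mann-Whitney statistic with midrank tie handling (equal to
the trapezoidal area under the empirical ROC).  Bootstrap intervals are
bias-corrected and accelerated (BCa): percentile endpoints adjusted by the
bias term z0 (fraction of replicates below the original estimate) and the
acceleration a (jackknife skewness).  The operating cutoff maximises
Youden's J = sensitivity + specificity - 1, with predictive values
reported at that cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney formulation with midrank ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class BootstrapResult:
    """Bootstrap distribution summary for an AUC."""

    original_auc: float
    replicates: np.ndarray
    bias: float
    se: float
    bca_low: float
    bca_high: float
    level: float
    B: int
    seed: int
    n_redrawn: int = 0

    @property
    def z0(self) -> float:
        frac = np.mean(self.replicates < self.original_auc)
        return float(stats.norm.ppf(np.clip(frac, 1e-9, 1 - 1e-9)))


@dataclass
class CutoffMetrics:
    """Operating characteristics at one score cutoff (score >= cutoff is
    called positive).  ``ppv``/``npv`` are None with the matching flag set
    when their denominator is empty."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    ppv: float | None
    npv: float | None
    ppv_undefined: bool = False
    npv_undefined: bool = False


def _order_stat_quantile(sorted_reps: np.ndarray, alpha: float) -> float:
    """The ceil(alpha*B)-th order statistic (clamped), so percentile and
    BCa endpoints are always elements of the replicate vector."""
    B = len(sorted_reps)
    idx = int(np.ceil(alpha * B)) - 1
    return float(sorted_reps[min(max(idx, 0), B - 1)])


def bca_interval(replicates: np.ndarray, original: float,
                 jackknife: np.ndarray | None, level: float = 0.95
                 ) -> tuple[float, float]:
    """BCa endpoints from a replicate vector.

    ``jackknife`` holds the leave-one-out estimates used for the
    acceleration; ``None`` (or a degenerate vector) sets a = 0.  With
    z0 = 0 and a = 0 the endpoints coincide exactly with the percentile
    method's.
    """
    reps = np.sort(np.asarray(replicates, dtype=float))
    B = len(reps)
    frac = np.mean(reps < original)
    z0 = float(stats.norm.ppf(np.clip(frac, 1.0 / (2 * B), 1 - 1.0 / (2 * B))))
    a = 0.0
    if jackknife is not None:
        d = np.mean(jackknife) - np.asarray(jackknife, dtype=float)
        denom = (d ** 2).sum() ** 1.5
        if denom > 0:
            a = float((d ** 3).sum() / (6.0 * denom))
    z = stats.norm.ppf([(1 - level) / 2.0, (1 + level) / 2.0])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    return (_order_stat_quantile(reps, adj[0]),
            _order_stat_quantile(reps, adj[1]))


def bootstrap_auc(scores, labels, B: int = 1000, seed: int = 0,
                  level: float = 0.95) -> BootstrapResult:
    """BCa bootstrap of the AUC of a fixed score vector.

    Each replicate resamples subjects with replacement (unstratified) and
    recomputes the AUC of the same scores; replicates drawing a single
    outcome class are redrawn (the count is reported).  The acceleration
    uses the jackknife of leave-one-out AUCs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    original = roc_auc(s, y)
    rng = np.random.default_rng(seed)
    n = len(s)
    reps = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
            redrawn += 1
        reps[b] = roc_auc(s[idx], y[idx])
    jack = _jackknife_auc(s, y)
    lo, hi = bca_interval(reps, original, jack, level=level)
    return BootstrapResult(original_auc=original, replicates=reps,
                           bias=float(reps.mean() - original),
                           se=float(reps.std(ddof=1)), bca_low=lo,
                           bca_high=hi, level=level, B=B, seed=seed,
                           n_redrawn=redrawn)


def _jackknife_auc(s: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out AUCs (single-class leave-outs are skipped)."""
    n = len(s)
    out = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        yi = y[keep]
        if 0 < yi.sum() < n - 1:
            out[i] = roc_auc(s[keep], yi)
        else:
            out[i] = np.nan
        keep[i] = True
    valid = out[~np.isnan(out)]
    return valid


def bootstrap_model_auc(cohort: pd.DataFrame, outcome: str,
                        terms: list[str], B: int = 1000, seed: int = 0,
                        level: float = 0.95,
                        reference: dict[str, str] | None = None
                        ) -> tuple[BootstrapResult, "object"]:
    """BCa bootstrap of a logistic model's apparent AUC.

    The term set is FIXED: each replicate resamples rows with replacement,
    refits the same terms (no re-selection) and scores the replicate with
    its own fit (apparent AUC), so ``bias = mean(replicates) - original``
    reflects refitting variability.  Returns the bootstrap summary and the
    base fit on the full data.
    """
    from pdxms.models import fit_logistic

    data = cohort.dropna(subset=[outcome, *terms]).reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = fit_logistic(data, outcome, terms, reference)
    y = data[outcome].to_numpy(dtype=int)
    original = roc_auc(base.predict_proba(data), y)
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
            redrawn += 1
        boot = data.iloc[idx].reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_b = fit_logistic(boot, outcome, terms, reference,
                                 term_levels=base.term_levels)
        reps[b] = roc_auc(fit_b.predict_proba(boot), y[idx])
    jack = _jackknife_model_auc(data, outcome, terms, base, y)
    lo, hi = bca_interval(reps, original, jack, level=level)
    result = BootstrapResult(original_auc=original, replicates=reps,
                             bias=float(reps.mean() - original),
                             se=float(reps.std(ddof=1)), bca_low=lo,
                             bca_high=hi, level=level, B=B, seed=seed,
                             n_redrawn=redrawn)
    return result, base


def _jackknife_model_auc(data, outcome, terms, base, y) -> np.ndarray:
    from pdxms.models import fit_logistic

    out = []
    for i in range(len(data)):
        sub = data.drop(data.index[i]).reset_index(drop=True)
        yi = np.delete(y, i)
        if not 0 < yi.sum() < len(yi):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_i = fit_logistic(sub, outcome, terms,
                                 term_levels=base.term_levels)
        out.append(roc_auc(fit_i.predict_proba(sub), yi))
    return np.asarray(out)


def youden_cutoff(scores, labels) -> CutoffMetrics:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent sorted unique scores plus
    -inf and +inf; a score >= cutoff is called positive; ties on J break to
    the smallest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    candidates = np.concatenate(([-np.inf],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [np.inf]))
    best = None
    for cut in candidates:
        m = ppv_npv(s, y, cut)
        if best is None or m.youden_j > best.youden_j + 1e-12:
            best = m
    return best


def ppv_npv(scores, labels, cutoff: float) -> CutoffMetrics:
    """Operating characteristics at a given cutoff (score >= cutoff positive).

    An empty predicted-positive (or -negative) group leaves PPV (NPV)
    undefined and flagged, never silently zero.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s >= cutoff
    tp = int((pos & (y == 1)).sum())
    fp = int((pos & (y == 0)).sum())
    tn = int((~pos & (y == 0)).sum())
    fn = int((~pos & (y == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else None
    npv = tn / (tn + fn) if (tn + fn) else None
    return CutoffMetrics(cutoff=float(cutoff), sensitivity=sens,
                         specificity=spec, youden_j=sens + spec - 1.0,
                         ppv=ppv, npv=npv,
                         ppv_undefined=ppv is None, npv_undefined=npv is None)


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve points (FPR, TPR) over all cutoffs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    uniq = np.unique(s)
    cuts = np.concatenate(([np.inf], uniq[::-1], [-np.inf]))
    rows = []
    for cut in cuts:
        m = ppv_npv(s, y, cut)
        rows.append({"cutoff": cut, "fpr": 1.0 - m.specificity,
                     "tpr": m.sensitivity})
    return pd.DataFrame(rows)
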