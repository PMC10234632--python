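"""Evaluation metrics for association output.

* ``srmsd_p`` — signed root-mean-square deviation between the sorted null
  p-values and the uniform quantile grid (i - 0.5) / m0.  Zero means
  calibrated; positive means anti-conservative, negative conservative; the
  attainable range is +-1/sqrt(3) ~ +-0.577 (all p-values 0 or all 1).
* ``auc_pr`` — area under the precision-recall curve for ranking causal vs
  null loci, integrated with the Davis–Goadrich nonlinear interpolation
  between operating points (linear interpolation in TP/FP counts, which is
  nonlinear in precision).  A perfect ranking scores 1; a random ranking
  scores the causal proportion m1 / m in expectation.
* ``inflation_lambda`` — the genomic inflation factor: the median
  chi-square quantile of the p-values over the null chi-square median.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: median of the chi-square distribution with 1 degree of freedom
_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


def srmsd_p(null_pvalues: np.ndarray) -> float:
    """Signed RMSD of sorted null p-values against uniform quantiles.

    The sign is sgn(1/2 - median(p)), with sgn(0) taken as +1, so p-values
    stacked toward zero (anti-conservative) give a positive value.
    """
    p = np.asarray(null_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one null p-value")
    if np.any(~np.isfinite(p)) or np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    m0 = p.size
    p_sorted = np.sort(p)
    u = (np.arange(1, m0 + 1) - 0.5) / m0
    rmsd = float(np.sqrt(np.mean((u - p_sorted) ** 2)))
    sign = 1.0 if np.median(p) <= 0.5 else -1.0
    return sign * rmsd


def auc_pr(scores: np.ndarray, causal_mask: np.ndarray) -> float:
    """Davis–Goadrich area under the precision-recall curve.

    ``scores`` rank loci (higher = more significant, e.g. -log p);
    ``causal_mask`` marks the true causal loci.  Tied scores enter the curve
    together.  Between operating points (TP_a, FP_a) and (TP_b, FP_b) the
    interpolation takes precision(t) = t / (t + FP_a + s (t - TP_a)) with
    the local slope s = dFP/dTP, whose recall integral has the closed form
    used here; the curve is anchored at (TP=0, FP=0).
    """
    scores = np.asarray(scores, dtype=float)
    causal = np.asarray(causal_mask, dtype=bool)
    if scores.shape != causal.shape:
        raise ValueError("scores and causal_mask must align")
    n_pos = int(causal.sum())
    if n_pos == 0 or n_pos == causal.size:
        raise ValueError("need at least one causal and one non-causal locus")
    # NaN scores rank last (never detected)
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    c_sorted = causal[order]
    tp = np.cumsum(c_sorted)
    fp = np.cumsum(~c_sorted)
    # keep only the last index of each tied-score block
    last = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.concatenate([last, [scores.size - 1]])
    tp_pts = np.concatenate([[0], tp[idx]]).astype(float)
    fp_pts = np.concatenate([[0], fp[idx]]).astype(float)

    area = 0.0
    for (tp_a, fp_a), (tp_b, fp_b) in zip(
        zip(tp_pts[:-1], fp_pts[:-1]), zip(tp_pts[1:], fp_pts[1:])
    ):
        d_tp = tp_b - tp_a
        if d_tp == 0:
            continue
        s = (fp_b - fp_a) / d_tp
        b1 = 1.0 + s
        a1 = fp_a - s * tp_a
        if abs(a1) < 1e-12:
            area += d_tp / b1
        else:
            def F(t: float) -> float:
                return t / b1 - a1 / b1**2 * np.log(a1 + b1 * t)
            area += F(tp_b) - F(tp_a)
    return float(area / n_pos)


def inflation_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor from the median association chi-square."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    chisq = stats.chi2.isf(np.clip(p, tiny, 1.0), 1)
    return float(np.median(chisq) / _CHI2_MEDIAN_1DF)
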