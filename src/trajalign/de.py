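"""Likelihood-ratio testing of features against pseudotime.

For each feature (gene expression, or a precomputed motif deviation score)
the alternative model is a Gaussian fit of the (log-transformed) values on a
degree-4 B-spline basis of pseudotime; the null is a constant mean. Twice
the log-likelihood gap is compared to a chi-squared distribution whose
degrees of freedom equal the number of extra mean parameters. Selection uses
the raw p-value threshold plus a total-count cut-off (100 genes, 50 motifs);
a Benjamini-Hochberg FDR column is reported for reference but not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import chi2

__all__ = ["LrtResult", "spline_basis", "lrt_pseudotime", "select_significant"]

SPLINE_DEGREE = 4


@dataclass
class LrtResult:
    feature_id: str
    loglik_alt: float
    loglik_null: float
    lr_stat: float
    df: int
    p_value: float
    fdr: float = np.nan
    selected: bool = False


def spline_basis(t: np.ndarray, degree: int = SPLINE_DEGREE) -> np.ndarray:
    """Clamped B-spline basis of the given degree with no interior knots.

    Over [min t, max t] this yields degree+1 basis functions that sum to 1
    (the Bernstein basis), so the intercept is absorbed; the model has
    degree+1 mean parameters versus 1 for the constant null.
    """
    t = np.asarray(t, dtype=float)
    lo, hi = t.min(), t.max()
    if hi <= lo:
        raise ValueError("pseudotime is constant; spline basis undefined")
    knots = np.concatenate([np.full(degree + 1, lo), np.full(degree + 1, hi)])
    B = BSpline.design_matrix(t, knots, degree, extrapolate=True).toarray()
    return B


def _gaussian_loglik(rss: np.ndarray, n: int) -> np.ndarray:
    """Profile Gaussian log-likelihood at the MLE variance rss/n."""
    sigma2 = np.maximum(rss / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def lrt_pseudotime(X: np.ndarray, t: np.ndarray,
                   feature_ids: list[str] | None = None,
                   log_transform: bool = True,
                   degree: int = SPLINE_DEGREE) -> list[LrtResult]:
    """LRT of every feature (column of X) against pseudotime t.

    log_transform applies log1p to the values (genes); pass False for motif
    deviation scores that are already continuous. Zero-variance features get
    p = 1 rather than an error.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if X.shape[0] != t.shape[0]:
        raise ValueError("X rows must match pseudotime length")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite pseudotime")
    n, m = X.shape
    if feature_ids is None:
        feature_ids = [f"feature{j}" for j in range(m)]
    Y = np.log1p(X) if log_transform else X

    B = spline_basis(t, degree=degree)  # n x (degree+1)
    coef, _, _, _ = np.linalg.lstsq(B, Y, rcond=None)
    rss_alt = ((Y - B @ coef) ** 2).sum(axis=0)
    rss_null = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df = B.shape[1] - 1

    ll_alt = _gaussian_loglik(rss_alt, n)
    ll_null = _gaussian_loglik(rss_null, n)
    lr = 2.0 * (ll_alt - ll_null)
    lr = np.maximum(lr, 0.0)
    p = chi2.sf(lr, df)
    const = rss_null <= 1e-12
    p = np.where(const, 1.0, p)
    lr = np.where(const, 0.0, lr)

    # BH-FDR, reported only
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m)
    ranks[order] = np.arange(1, m + 1)
    fdr = np.minimum.accumulate((p * m / ranks)[order][::-1])[::-1]
    fdr_full = np.empty(m)
    fdr_full[order] = np.minimum(fdr, 1.0)

    return [LrtResult(feature_ids[j], float(ll_alt[j]), float(ll_null[j]),
                      float(lr[j]), int(df), float(p[j]), float(fdr_full[j]))
            for j in range(m)]


def select_significant(results: list[LrtResult], alpha: float = 0.05,
                       top_n: int = 100) -> list[LrtResult]:
    """Keep features with p < alpha, sorted ascending by p (ties by id),
    truncated to the top_n smallest."""
    ordered = sorted(results, key=lambda r: (r.p_value, r.feature_id))
    kept = [r for r in ordered if r.p_value < alpha][:top_n]
    chosen = {id(r) for r in kept}
    for r in results:
        r.selected = id(r) in chosen
    return kept
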