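"""Single-marker eQTL scan with permutation-based genome-wide thresholds.

Mirrors the classical marker-regression workflow used to pick covariates
for the conditional model: every gene is regressed on every marker
(intercept plus the 0/1 genotype), the association strength is the LOD
score ``(n/2) log10(RSS0 / RSS1)``, and each gene's genome-wide 5%
significance threshold is the 95th percentile of the max-over-markers LOD
under permutations of that gene's expression vector (genotypes fixed).
The covariates handed to the conditional covariance estimator are the
union, over genes, of markers whose LOD clears the gene's threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: LOD reported for numerically perfect fits (RSS1 ~ 0).
LOD_CAP = 50.0


@dataclass
class ScanResult:
    """LOD matrix, per-gene permutation thresholds and the selected markers."""

    lod: np.ndarray  # (p genes, q markers)
    perm_thresholds: np.ndarray  # (p,)
    selected: list  # marker ids (union over genes)


def _lod_from_groups(rss0, s1, n1, n0, total):
    """LOD for a binary regressor from group sums; vectorized over genes."""
    n = n1 + n0
    diff = s1 / n1 - (total - s1) / n0
    rss1 = rss0 - (n0 * n1 / n) * diff**2
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(rss0 / np.maximum(rss1, 0.0))
    lod = np.where(rss0 <= 0, 0.0, lod)
    lod = np.where(rss1 <= 1e-12 * np.maximum(rss0, 1e-300), LOD_CAP, lod)
    return np.minimum(lod, LOD_CAP)


def single_marker_scan(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LOD scores of every gene on every marker (marker regression).

    ``statistic[g, k] = (n/2) log10(RSS0_g / RSS1_{g,k})`` where RSS0 is
    the intercept-only residual sum of squares.  Monomorphic markers score
    0 with a warning; perfect fits are capped at 50.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = Y.shape
    q = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    if X.size and not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("markers must be backcross coded (0/1)")
    Yc = Y - Y.mean(axis=0)
    rss0 = (Yc**2).sum(axis=0)
    total = Y.sum(axis=0)
    lod = np.zeros((p, q))
    for k in range(q):
        x = X[:, k]
        n1 = int(x.sum())
        n0 = n - n1
        if n1 == 0 or n0 == 0:
            warnings.warn(f"marker column {k} is monomorphic; statistic set to 0",
                          stacklevel=2)
            continue
        lod[:, k] = _lod_from_groups(rss0, x @ Y, n1, n0, total)
    return lod


def permutation_threshold(y: np.ndarray, X: np.ndarray, n_perm: int = 1000,
                          alpha: float = 0.05, seed=None) -> float:
    """Genome-wide LOD threshold for one gene.

    The gene's expression vector is permuted ``n_perm`` times (marker
    matrix fixed); each permutation contributes its max-over-markers LOD,
    and the threshold is the empirical ``1 - alpha`` quantile (linear
    interpolation) of that max distribution.  LOD is invariant to affine
    rescaling of the trait, so the threshold is too.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20 for a stable quantile")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    perms = np.empty((n_perm, n), dtype=np.intp)
    for b in range(n_perm):
        perms[b] = rng.permutation(n)
    Yp = y[perms]  # (n_perm, n)
    rss0 = ((y - y.mean())**2).sum()
    total = y.sum()
    maxes = np.zeros(n_perm)
    for k in range(X.shape[1]):
        x = X[:, k]
        n1 = int(x.sum())
        n0 = n - n1
        if n1 == 0 or n0 == 0:
            continue
        lod = _lod_from_groups(rss0, Yp @ x, n1, n0, total)
        maxes = np.maximum(maxes, lod)
    # next-higher order statistic: the exact-level permutation convention
    # (linear interpolation between order statistics is slightly
    # anti-conservative for the max distribution)
    return float(np.quantile(maxes, 1.0 - alpha, method="higher"))


def select_covariates(panel, covariates, n_perm: int = 1000, alpha: float = 0.05,
                      seed=None) -> list:
    """Per-condition selected marker sets from the permutation scan.

    For each condition, each gene contributes the markers whose LOD
    exceeds that gene's genome-wide threshold; the condition's covariate
    set is the union over genes.  Returns a list of :class:`ScanResult`.
    An empty union means the downstream fit degenerates to the
    unconditional model.
    """
    X = covariates.X if hasattr(covariates, "X") else np.asarray(covariates, float)
    marker_ids = list(getattr(covariates, "marker_ids",
                              range(np.atleast_2d(X).shape[1])))
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) \
        else seed
    results = []
    for Y, child in zip(panel.Ys, ss.spawn(panel.T)):
        lod = single_marker_scan(Y, X)
        gene_seeds = child.spawn(Y.shape[1])
        thr = np.array([
            permutation_threshold(Y[:, g], X, n_perm=n_perm, alpha=alpha,
                                  seed=gene_seeds[g])
            for g in range(Y.shape[1])
        ])
        sel_idx = sorted({k for g in range(Y.shape[1])
                          for k in np.flatnonzero(lod[g] > thr[g])})
        results.append(ScanResult(lod=lod, perm_thresholds=thr,
                                  selected=[marker_ids[k] for k in sel_idx]))
    return results
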