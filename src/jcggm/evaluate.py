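"""Support-recovery and estimation-accuracy metrics against simulation truth.

Five criteria, each averaged over conditions where applicable:

* FP / FN - false positive and false negative edge rates at the selected
  model, per condition, averaged over the T conditions.
* FPC / FNC - the same notions computed jointly on "common zeros": pairs
  that are non-edges in every condition (FPC) or edges in at least one
  condition (FNC).
* RFL - relative Frobenius loss, mean over conditions of
  ``||Omega_t - Omega_hat_t||_F^2 / ||Omega_t||_F^2``.

Truth support is the generative adjacency, never a magnitude threshold on
the true precision; estimated support applies the edge-declaration
threshold to ``|omega_hat|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .joint import (EDGE_THRESHOLD, FitConfig, PenaltySpec,
                    default_lambda_grid, fit_jcggm)


def _est_adjacencies(est, threshold):
    if hasattr(est, "adjacency"):
        return est.adjacency(threshold)
    out = []
    for om in est:
        a = np.abs(np.asarray(om)) > threshold
        np.fill_diagonal(a, False)
        out.append(a)
    return out


def _truth_adjacencies(truth):
    out = []
    for adj in truth:
        a = np.asarray(adj)
        a = (np.abs(a) > 0) if a.dtype != bool else a.copy()
        np.fill_diagonal(a, False)
        out.append(a)
    return out


def fp_fn_rates(est, truth_adjacencies, threshold: float = EDGE_THRESHOLD):
    """Per-condition false positive / false negative edge rates, averaged.

    FP_t = wrongly declared edges / true non-edges; FN_t = missed edges /
    true edges; each rate is the mean of the per-condition rates.  A
    condition without any true zero (or any true edge) makes the
    corresponding rate undefined and raises.
    """
    est_adj = _est_adjacencies(est, threshold)
    tru_adj = _truth_adjacencies(truth_adjacencies)
    if len(est_adj) != len(tru_adj):
        raise ValueError("estimate and truth have different numbers of conditions")
    fps, fns = [], []
    for t, (e, a) in enumerate(zip(est_adj, tru_adj)):
        iu = np.triu_indices(a.shape[0], 1)
        e_u, a_u = e[iu], a[iu]
        n_zero = int((~a_u).sum())
        n_edge = int(a_u.sum())
        if n_zero == 0:
            raise ValueError(f"condition {t}: no true zeros, FP undefined")
        if n_edge == 0:
            raise ValueError(f"condition {t}: no true edges, FN undefined")
        fps.append((e_u & ~a_u).sum() / n_zero)
        fns.append((~e_u & a_u).sum() / n_edge)
    return float(np.mean(fps)), float(np.mean(fns))


def common_zero_rates(est, truth_adjacencies, threshold: float = EDGE_THRESHOLD):
    """FPC / FNC computed on the joint (across-condition) support.

    FPC: among pairs that are zero in every true condition, the fraction
    estimated nonzero in at least one condition.  FNC: among pairs that
    are an edge in at least one true condition, the fraction estimated
    zero in every condition.
    """
    est_adj = _est_adjacencies(est, threshold)
    tru_adj = _truth_adjacencies(truth_adjacencies)
    iu = np.triu_indices(tru_adj[0].shape[0], 1)
    tru_any = np.logical_or.reduce([a[iu] for a in tru_adj])
    est_any = np.logical_or.reduce([e[iu] for e in est_adj])
    common_zero = ~tru_any
    if not common_zero.any():
        raise ValueError("truth has no common zeros, FPC undefined")
    if not tru_any.any():
        raise ValueError("truth has no edges in any condition, FNC undefined")
    fpc = (est_any & common_zero).sum() / common_zero.sum()
    fnc = (~est_any & tru_any).sum() / tru_any.sum()
    return float(fpc), float(fnc)


def relative_frobenius_loss(est, truth_omegas) -> float:
    """Mean over conditions of ``||Omega_t - Omega_hat_t||_F^2 / ||Omega_t||_F^2``."""
    omegas = est.omegas if hasattr(est, "omegas") else list(est)
    losses = []
    for om_hat, om in zip(omegas, truth_omegas):
        om = np.asarray(om, dtype=float)
        losses.append(np.linalg.norm(om - np.asarray(om_hat)) ** 2
                      / np.linalg.norm(om) ** 2)
    return float(np.mean(losses))


@dataclass
class MetricReport:
    """All five criteria for one fitted model (optionally with an ROC path)."""

    fp: float
    fn: float
    fpc: float
    fnc: float
    rfl: float
    roc: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"fp": self.fp, "fn": self.fn, "fpc": self.fpc,
                "fnc": self.fnc, "rfl": self.rfl}


def evaluate_fit(est, truth_adjacencies, truth_omegas,
                 threshold: float = EDGE_THRESHOLD) -> MetricReport:
    fp, fn = fp_fn_rates(est, truth_adjacencies, threshold)
    fpc, fnc = common_zero_rates(est, truth_adjacencies, threshold)
    rfl = relative_frobenius_loss(est, truth_omegas)
    return MetricReport(fp=fp, fn=fn, fpc=fpc, fnc=fnc, rfl=rfl)


def roc_path(sigmas, n_ts, truth_adjacencies, lam_grid=None,
             penalty: PenaltySpec | None = None, cfg: FitConfig | None = None):
    """(FPR, TPR) along the lambda path (no BIC selection), sorted by FPR.

    TPR = 1 - FN and FPR = FP, each the mean over conditions, at every
    lambda of the grid.  Averaging across replicates is done pointwise at
    matched grid indices by :func:`aggregate_roc`.
    """
    penalty = penalty or PenaltySpec()
    cfg = cfg or FitConfig()
    if lam_grid is None:
        lam_grid = default_lambda_grid(sigmas, n_ts, penalty, cfg)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise ValueError("lambda grid is empty")
    lam_grid = np.sort(lam_grid)[::-1]
    pts = []
    warm = None
    for lam in lam_grid:
        fit = fit_jcggm(sigmas, n_ts, PenaltySpec(penalty.epsilon, float(lam)),
                        cfg, omegas0=warm)
        warm = fit.omegas
        fp, fn = fp_fn_rates(fit, truth_adjacencies)
        pts.append((fp, 1.0 - fn))
    return pts


def aggregate_roc(roc_lists):
    """Average ROC points across replicates at matched lambda indices."""
    arr = np.asarray(roc_lists, dtype=float)  # (reps, n_lam, 2)
    mean = arr.mean(axis=0)
    order = np.argsort(mean[:, 0])
    return [tuple(xy) for xy in mean[order]]


def summarize(values) -> tuple:
    """Mean and standard error (sd / sqrt(n_reps)) of replicate values."""
    v = np.asarray(values, dtype=float)
    se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return float(v.mean()), float(se)
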