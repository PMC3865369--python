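"""The four-method comparison harness used throughout the simulation study.

Methods, as evaluated on generated replicates:

* ``ggm``   - per-condition truncated-log fit (T = 1) on the marginal
              sample covariance (covariates ignored), per-condition BIC.
* ``cggm``  - the same separate fit, but on the linear-kernel conditional
              covariance (marker effects conditioned out).
* ``jggm``  - joint truncated-log fit on the marginal covariances.
* ``jcggm`` - joint truncated-log fit on the conditional covariances
              (the full two-stage method).

The separate baselines are the T = 1 special case of the same estimator,
so the comparison isolates exactly the two design axes: conditioning on
markers, and joint estimation across conditions.  A plain scalar-penalty
graphical lasso path (:func:`scalar_glasso_path`) is also provided for
reference.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from .cond_cov import linear_cond_cov
from .evaluate import MetricReport, evaluate_fit
from .joint import (EDGE_THRESHOLD, FitConfig, PenaltySpec, PrecisionSet,
                    bic_score, select_lambda)
from .simulate import SimScenario, run_scenario
from .wglasso import WGlassoProblem, solve_wglasso

METHODS = ("ggm", "cggm", "jggm", "jcggm")


def scalar_glasso_path(S: np.ndarray, n: int, *, n_lambdas: int = 30,
                       lam_ratio: float = 1e-3, tol: float = 1e-5,
                       max_iter: int = 500):
    """Scalar-penalty graphical lasso path with BIC selection (one condition).

    The grid runs from ``lam_max = max off-diagonal |S|`` (which empties
    the graph) down by ``lam_ratio``, descending with warm starts.  BIC is
    ``-log det + tr(S Omega) + log(n) df / n`` with df counting nonzero
    upper-triangle entries including the diagonal.  Non-converged interior
    solutions are kept (flagged), matching how a practitioner would treat
    a near-singular input.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    lam_max = float(np.max(np.abs(S[off]))) or 1.0
    grid = np.geomspace(lam_max, lam_max * lam_ratio, n_lambdas)
    W = np.ones((p, p)) - np.eye(p)
    warm = None
    best = None
    path = []
    for lam in grid:
        prob = WGlassoProblem(S, W, float(lam), tol=tol, max_iter=max_iter)
        omega, info = solve_wglasso(prob, Omega0=warm, raise_on_fail=False)
        warm = omega
        fit = PrecisionSet([omega], lam=float(lam), converged=info["converged"])
        sign, logdet = np.linalg.slogdet(omega)
        if sign <= 0:
            path.append({"lam": float(lam), "bic": np.inf})
            continue
        bic = bic_score(fit, [S], [n])
        path.append({"lam": float(lam), "bic": bic})
        if best is None or bic < best[1]:
            best = (float(lam), bic, omega)
    if best is None:
        raise RuntimeError("no lambda produced a positive definite estimate")
    return best[0], best[2], path


def _separate_fit(sigmas, n_ts, penalty=None, cfg=None) -> PrecisionSet:
    omegas, lams = [], []
    for s, n in zip(sigmas, n_ts):
        lam, fit, _ = select_lambda([s], [n], penalty or PenaltySpec(), cfg)
        omegas.append(fit.omegas[0])
        lams.append(lam)
    return PrecisionSet(omegas, lam=float(np.mean(lams)))


def _joint_fit(sigmas, n_ts, penalty=None, cfg=None) -> PrecisionSet:
    _, fit, _ = select_lambda(sigmas, n_ts, penalty or PenaltySpec(), cfg)
    return fit


def fit_method(method: str, scn: SimScenario, penalty: PenaltySpec | None = None,
               cfg: FitConfig | None = None) -> PrecisionSet:
    """Fit one of the four benchmark methods to a generated replicate."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    n_ts = [Y.shape[0] for Y in scn.Ys]
    if method in ("cggm", "jcggm"):
        sigmas = [linear_cond_cov(Y, scn.X) for Y in scn.Ys]
    else:
        sigmas = [linear_cond_cov(Y, None) for Y in scn.Ys]
    if method in ("ggm", "cggm"):
        return _separate_fit(sigmas, n_ts, penalty, cfg)
    return _joint_fit(sigmas, n_ts, penalty, cfg)


def evaluate_method(method: str, scn: SimScenario, **kw) -> MetricReport:
    fit = fit_method(method, scn, **kw)
    return evaluate_fit(fit, scn.true_adjacencies, scn.true_omegas)


def run_benchmark(case: str, n: int, n_reps: int, seed=None,
                  methods=METHODS, progress: bool = False) -> pd.DataFrame:
    """Replicate-level metric table for the requested methods.

    Returns a tidy DataFrame with columns ``rep, method, fp, fn, fpc,
    fnc, rfl``; summarize with :func:`summarize_benchmark`.
    """
    rows = []
    for rep, scn in enumerate(run_scenario(case, n, n_reps, seed)):
        for method in methods:
            report = evaluate_method(method, scn)
            rows.append({"rep": rep, "method": method, **report.as_dict()})
        if progress:
            print(f"  replicate {rep + 1}/{n_reps} done", flush=True)
    return pd.DataFrame(rows)


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error per method, in the usual table layout."""
    out = {}
    for metric in ("fp", "fn", "fpc", "fnc", "rfl"):
        g = df.groupby("method")[metric]
        out[metric] = g.mean()
        out[f"{metric}_se"] = g.std(ddof=1) / np.sqrt(g.count())
    return pd.DataFrame(out)
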