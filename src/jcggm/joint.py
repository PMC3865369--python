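"""Joint estimation of condition-specific precision matrices.

The T condition-specific precision matrices are estimated jointly by
minimizing the penalized profiled likelihood

    PPL({Omega_t}) = sum_t n_t ( -log det(Omega_t) + tr(Sigma_t Omega_t) )
                     + lam * P({Omega_t}),

where ``Sigma_t`` is the (conditional) covariance estimate for condition t
and ``P`` is the truncated-log joint-sparsity penalty on the per-pair
cross-condition magnitudes ``a_jk = sum_t |omega_t[j,k]|``:

    P = sum_{j != k} [ (log a_jk - log eps + 1)  if a_jk > eps
                       a_jk / eps                if a_jk <= eps ].

Both branches equal 1 at ``a = eps``, so the penalty is continuous; the
logarithmic branch makes an additional condition sharing an already
detected edge almost free, which is what couples the conditions.

The nonconvex problem is attacked by local linear approximation (LLA):
each iteration linearizes P at the current estimate, giving a weighted
graphical lasso per condition with weights

    zeta_jk = 1 / max(sum_t |omega_t[j,k]|, eps),

a majorize-minimize scheme, so the PPL objective is non-increasing across
iterations when each subproblem is solved accurately.  The tuning
parameter ``lam`` is selected by BIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cond_cov import CondCovEstimate
from .wglasso import WGlassoConvergenceError, WGlassoProblem, solve_wglasso

log = logging.getLogger(__name__)

#: |omega| above this counts as an edge (solver zeros are exact, but LLA
#: re-weighting can leave tiny values; far below any genuine signal).
EDGE_THRESHOLD = 1e-6


@dataclass
class PenaltySpec:
    """Truncated-log penalty parameters: truncation ``epsilon`` and level ``lam``."""

    epsilon: float = 1e-3
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass
class FitConfig:
    """Algorithmic knobs for the joint fit.

    ``delta_ridge`` is added (repeatedly) to the diagonal of an
    ill-conditioned covariance before inversion at initialization;
    ``cond_threshold`` is the eigenvalue-ratio trigger for that ridge.
    ``lla_tol`` is the relative Frobenius change stopping rule of the LLA
    loop.  ``n_lambdas``/``lam_ratio`` shape the default lambda grid.
    """

    delta_ridge: float = 1e-3
    cond_threshold: float = 1e3
    lla_tol: float = 1e-4
    lla_max_iter: int = 50
    lla_fail_streak: int = 3
    wglasso_tol: float = 1e-5
    wglasso_max_iter: int = 100
    n_lambdas: int = 32
    lam_ratio: float = 1e-4
    lam_grid: np.ndarray | None = None
    bic_patience: int | None = 6


@dataclass
class PrecisionSet:
    """Jointly fitted precision matrices for one lambda."""

    omegas: list
    lam: float
    n_iters: int = 0
    converged: bool = True
    objective_path: list = field(default_factory=list)

    @property
    def T(self) -> int:
        return len(self.omegas)

    def adjacency(self, threshold: float = EDGE_THRESHOLD) -> list:
        """Per-condition boolean edge indicators (off-diagonal support)."""
        out = []
        for om in self.omegas:
            a = np.abs(om) > threshold
            np.fill_diagonal(a, False)
            out.append(a)
        return out


def _as_sigma_arrays(sigmas) -> list:
    out = []
    for s in sigmas:
        if isinstance(s, CondCovEstimate):
            s = s.sigma
        out.append(np.asarray(s, dtype=float))
    return out


def truncated_log_penalty(omega_sums: np.ndarray, epsilon: float) -> float:
    """Evaluate the truncated-log penalty on the matrix of ``a_jk`` sums.

    ``omega_sums`` holds ``a_jk = sum_t |omega_t[j,k]|``; the diagonal is
    ignored.  Both branches equal 1 at ``a = eps``.
    """
    a = np.asarray(omega_sums, dtype=float)
    if np.any(a < 0):
        raise ValueError("omega_sums must be nonnegative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    off = ~np.eye(a.shape[0], dtype=bool)
    vals = a[off]
    big = vals > epsilon
    total = np.sum(np.log(vals[big]) - np.log(epsilon) + 1.0)
    total += np.sum(vals[~big] / epsilon)
    return float(total)


def lla_weights(omegas_prev, epsilon: float) -> np.ndarray:
    """LLA penalty weights ``zeta_jk = 1 / max(sum_t |omega_t[j,k]|, eps)``.

    The diagonal is set to zero (unpenalized).  All-zero previous estimates
    hit the cap ``1/eps``.
    """
    oms = [np.asarray(o, dtype=float) for o in omegas_prev]
    a = np.sum([np.abs(o) for o in oms], axis=0)
    zeta = 1.0 / np.maximum(a, epsilon)
    np.fill_diagonal(zeta, 0.0)
    return zeta


def initialize_omegas(sigmas, delta_ridge: float = 1e-3,
                      cond_threshold: float = 1e3) -> list:
    """Initial precision estimates ``(Sigma_t + k*delta*I)^{-1}``.

    ``delta`` is added to the diagonal as many times as needed for the
    eigenvalue ratio of the ridged covariance to fall to ``cond_threshold``
    (and for the smallest eigenvalue to be positive), then the inverse is
    returned.  The loop always terminates: the ratio tends to 1 as the
    ridge grows.
    """
    out = []
    for s in _as_sigma_arrays(sigmas):
        s = (s + s.T) / 2.0
        w = np.linalg.eigvalsh(s)
        ridge = 0.0
        while w[0] + ridge <= 0 or (w[-1] + ridge) / (w[0] + ridge) > cond_threshold:
            ridge += delta_ridge
        out.append(np.linalg.inv(s + ridge * np.eye(s.shape[0])))
    return out


def _ppl_objective(sigmas, n_ts, omegas, lam, epsilon) -> float:
    total = 0.0
    for s, n_t, om in zip(sigmas, n_ts, omegas):
        sign, logdet = np.linalg.slogdet(om)
        if sign <= 0:
            return np.inf
        total += n_t * (np.sum(s * om) - logdet)
    a = np.sum([np.abs(o) for o in omegas], axis=0)
    np.fill_diagonal(a, 0.0)
    return float(total + lam * truncated_log_penalty(a, epsilon))


def fit_jcggm(sigmas, n_ts, penalty: PenaltySpec, cfg: FitConfig | None = None,
              omegas0=None) -> PrecisionSet:
    """LLA fit of the joint model at a single ``lam``.

    Parameters
    ----------
    sigmas : sequence of T (p, p) arrays or CondCovEstimate
        Conditional covariance inputs.
    n_ts : sequence of T ints
        Per-condition sample sizes (likelihood weights).
    penalty : PenaltySpec
    cfg : FitConfig, optional
    omegas0 : optional warm start (e.g. the previous lambda's solution);
        defaults to :func:`initialize_omegas`.

    Notes
    -----
    The per-condition inner problem handed to the weighted graphical lasso
    is normalized by ``n_t``:  tr(Sigma Omega) - log det Omega +
    (lam/n_t) * sum zeta_jk |omega_jk|, which is the LLA subproblem divided
    by ``n_t``.
    """
    cfg = cfg or FitConfig()
    sigmas = _as_sigma_arrays(sigmas)
    n_ts = [int(n) for n in n_ts]
    if len(sigmas) != len(n_ts):
        raise ValueError("sigmas and n_ts must have the same length")
    if penalty.lam <= 0:
        raise ValueError("fit_jcggm requires lam > 0 (use initialize_omegas for the MLE)")

    if omegas0 is None:
        omegas = initialize_omegas(sigmas, cfg.delta_ridge, cfg.cond_threshold)
    else:
        omegas = [np.asarray(o, dtype=float).copy() for o in omegas0]

    obj_path = [_ppl_objective(sigmas, n_ts, omegas, penalty.lam, penalty.epsilon)]
    converged = False
    all_inner_ok = True
    inner_fail_streak = 0
    k = 0
    for k in range(1, cfg.lla_max_iter + 1):
        zeta = lla_weights(omegas, penalty.epsilon)
        new_omegas = []
        iter_inner_ok = True
        for s, n_t, om_prev in zip(sigmas, n_ts, omegas):
            prob = WGlassoProblem(s, zeta, penalty.lam / n_t,
                                  tol=cfg.wglasso_tol, max_iter=cfg.wglasso_max_iter)
            try:
                om, info = solve_wglasso(prob, Omega0=om_prev, raise_on_fail=False)
            except np.linalg.LinAlgError as exc:  # warm start unusable
                om, info = solve_wglasso(prob, raise_on_fail=False)
            if not info["converged"]:
                iter_inner_ok = False
            new_omegas.append(om)
        if not iter_inner_ok:
            all_inner_ok = False
            inner_fail_streak += 1
        else:
            inner_fail_streak = 0
        rel = max(
            np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-12)
            for a, b in zip(new_omegas, omegas)
        )
        omegas = new_omegas
        obj_path.append(_ppl_objective(sigmas, n_ts, omegas, penalty.lam, penalty.epsilon))
        if rel < cfg.lla_tol:
            converged = True
            break
        if inner_fail_streak >= cfg.lla_fail_streak:
            # degenerate regime (e.g. singular covariance at small lambda):
            # the inner solver cannot certify its iterates, so majorization
            # no longer holds and further LLA passes only compound the cost
            log.debug("LLA stopped after %d iterations: inner solver kept "
                      "failing on a degenerate subproblem", k)
            break
    return PrecisionSet(omegas=omegas, lam=penalty.lam, n_iters=k,
                        converged=converged and all_inner_ok,
                        objective_path=obj_path)


def bic_score(precisions: PrecisionSet, sigmas, n_ts,
              edge_threshold: float = EDGE_THRESHOLD) -> float:
    """BIC of a fitted precision set:

    ``sum_t { -log det(Omega_t) + tr(Sigma_t Omega_t) + log(n_t) df_t / n_t }``

    with ``df_t`` the number of upper-triangular entries (diagonal
    included) whose magnitude exceeds ``edge_threshold``.
    """
    sigmas = _as_sigma_arrays(sigmas)
    total = 0.0
    for om, s, n_t in zip(precisions.omegas, sigmas, n_ts):
        sign, logdet = np.linalg.slogdet(om)
        if sign <= 0:
            raise np.linalg.LinAlgError("precision matrix is not positive definite")
        iu = np.triu_indices(om.shape[0])
        df = int(np.sum(np.abs(om[iu]) > edge_threshold))
        total += -logdet + float(np.sum(s * om)) + np.log(n_t) * df / n_t
    return float(total)


def default_lambda_grid(sigmas, n_ts, penalty: PenaltySpec,
                        cfg: FitConfig | None = None) -> np.ndarray:
    """Descending log-spaced lambda grid.

    ``lam_max = max_t n_t * max_t max_{j != k} |Sigma_t[j,k]|`` empties the
    graph: at that level the per-element LLA penalty ``(lam/n) zeta_jk``
    exceeds every off-diagonal of the input even for pairs whose
    initialization weight is mildest.  The grid descends to
    ``lam_max * lam_ratio``.
    """
    cfg = cfg or FitConfig()
    sigmas = _as_sigma_arrays(sigmas)
    off_max = 0.0
    for s in sigmas:
        off = np.abs(s - np.diag(np.diag(s)))
        off_max = max(off_max, float(off.max()))
    if off_max <= 0:
        off_max = 1.0
    lam_max = max(n_ts) * off_max
    return np.geomspace(lam_max, lam_max * cfg.lam_ratio, cfg.n_lambdas)


def select_lambda(sigmas, n_ts, penalty: PenaltySpec | None = None,
                  cfg: FitConfig | None = None):
    """Fit the whole lambda path and return the BIC-best model.

    The grid is traversed in descending order; every lambda is fitted from
    the same dense initialization ``(Sigma_t + delta I)^{-1}`` rather than
    warm-started from its neighbour (with the nonconvex penalty an empty
    warm start is an absorbing state: fully capped weights keep every edge
    out, so warm starts destroy the informative part of the path).  Ties
    in BIC go to the larger (sparser) lambda.  When ``cfg.bic_patience``
    is set, the descent stops early once BIC has worsened for that many
    consecutive lambdas past the incumbent (the dense tail is the
    expensive part of the path and cannot win).

    Returns
    -------
    (best_lam, best_fit, path) where ``path`` is a list of
    ``{"lam", "bic", "fit"}`` records in grid order.
    """
    penalty = penalty or PenaltySpec()
    cfg = cfg or FitConfig()
    grid = cfg.lam_grid
    if grid is None:
        grid = default_lambda_grid(sigmas, n_ts, penalty, cfg)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(grid <= 0):
        raise ValueError("lambda grid must be strictly positive")
    grid = np.sort(grid)[::-1]

    omegas0 = initialize_omegas(_as_sigma_arrays(sigmas),
                                cfg.delta_ridge, cfg.cond_threshold)
    path = []
    failures = []
    best_bic = np.inf
    since_best = 0
    invalid_streak = 0
    for lam in grid:
        spec = PenaltySpec(epsilon=penalty.epsilon, lam=float(lam))
        try:
            fit = fit_jcggm(sigmas, n_ts, spec, cfg, omegas0=omegas0)
            bic = bic_score(fit, sigmas, n_ts)
            if not np.isfinite(bic):
                raise np.linalg.LinAlgError("non-finite BIC")
        except (np.linalg.LinAlgError, WGlassoConvergenceError) as exc:
            failures.append((float(lam), str(exc)))
            path.append({"lam": float(lam), "bic": np.inf, "fit": None})
            invalid_streak += 1
            if invalid_streak >= 3 and any(r["fit"] is not None for r in path):
                # numerically degenerate tail of the path; nothing further
                # down can be certified, stop descending
                break
            continue
        invalid_streak = 0
        path.append({"lam": float(lam), "bic": bic, "fit": fit})
        if bic < best_bic:
            best_bic = bic
            since_best = 0
        elif bic > best_bic:
            # ties (e.g. the empty-graph plateau at the top of the grid)
            # neither reset nor advance the patience counter
            since_best += 1
            if cfg.bic_patience is not None and since_best >= cfg.bic_patience:
                break
    finite = [rec for rec in path if rec["fit"] is not None and np.isfinite(rec["bic"])]
    if not finite:
        raise RuntimeError(f"all lambda fits failed: {failures}")
    # grid is descending, min() takes the first (largest-lambda) minimizer
    best = min(finite, key=lambda rec: rec["bic"])
    return best["lam"], best["fit"], path
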