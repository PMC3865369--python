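"""Weighted graphical lasso with element-wise off-diagonal penalties.

Solves

    minimize_{Omega > 0}  tr(S Omega) - log det(Omega)
                          + lam * sum_{j != k} W_jk |omega_jk|

for a symmetric input matrix ``S`` and a symmetric nonnegative weight
matrix ``W`` with zero diagonal (the diagonal of ``Omega`` is never
penalized).  Element-wise weights are what the local linear approximation
of a nonconvex joint penalty produces, and they rule out off-the-shelf
scalar-penalty solvers, so the solver is built here: Friedman-style block
coordinate descent over columns, each column's lasso subproblem solved by
coordinate descent with a per-element penalty vector.

The hot loops are compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass
class WGlassoProblem:
    """One weighted graphical-lasso subproblem.

    ``S`` is the (conditional) covariance input, ``W`` the symmetric
    nonnegative penalty-weight matrix with zero diagonal, ``lam`` the
    overall penalty level.  Convergence is declared when the mean absolute
    change of the entries of ``Omega`` over one full sweep drops below
    ``tol`` times the mean absolute off-diagonal of ``S`` and the KKT
    residual is below the same scaled tolerance.
    """

    S: np.ndarray
    W: np.ndarray
    lam: float
    tol: float = 1e-5
    max_iter: int = 500

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        W = np.asarray(self.W, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if W.shape != S.shape:
            raise ValueError("W must have the same shape as S")
        scale = 1.0 + np.max(np.abs(S))
        if np.max(np.abs(S - S.T)) > 1e-8 * scale:
            raise ValueError("S must be symmetric")
        if np.max(np.abs(W - W.T)) > 1e-8 * (1.0 + np.max(np.abs(W))):
            raise ValueError("W must be symmetric")
        if np.any(W < 0):
            raise ValueError("W must be nonnegative")
        if np.max(np.abs(np.diag(W))) > 0:
            raise ValueError("W must have a zero diagonal (diagonal is unpenalized)")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if np.any(np.diag(S) < 0):
            raise ValueError("S has a negative diagonal entry")
        self.S = (S + S.T) / 2.0
        self.W = (W + W.T) / 2.0


class WGlassoConvergenceError(RuntimeError):
    """Raised when the solver exhausts ``max_iter`` sweeps.

    Carries the last iterate (``omega``) and its KKT residual
    (``residual``) so callers may inspect or reuse it.
    """

    def __init__(self, message: str, omega: np.ndarray, residual: float):
        super().__init__(message)
        self.omega = omega
        self.residual = residual


@njit(cache=True, fastmath=True)
def _lasso_cd(V, s, lamvec, beta, tol, max_iter):  # pragma: no cover - jit
    """Coordinate descent for 0.5 b'Vb - s'b + sum_k lamvec_k |b_k| (in place)."""
    m = beta.shape[0]
    Vb = V @ beta
    for _ in range(max_iter):
        maxd = 0.0
        for k in range(m):
            vkk = V[k, k]
            if vkk <= 1e-300:
                continue
            old = beta[k]
            g = s[k] - (Vb[k] - vkk * old)
            lk = lamvec[k]
            if g > lk:
                new = (g - lk) / vkk
            elif g < -lk:
                new = (g + lk) / vkk
            else:
                new = 0.0
            if new != old:
                d = new - old
                for i in range(m):
                    Vb[i] += V[i, k] * d
                beta[k] = new
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
        if maxd < tol:
            break


@njit(cache=True, fastmath=True)
def _sweep(S, L, W, B, inner_tol, inner_max_iter):  # pragma: no cover - jit
    """One full block-coordinate sweep over all columns; updates W and B."""
    p = S.shape[0]
    m = p - 1
    V = np.empty((m, m))
    s = np.empty(m)
    lamvec = np.empty(m)
    beta = np.empty(m)
    for j in range(p):
        r = 0
        for a in range(p):
            if a == j:
                continue
            c = 0
            for b in range(p):
                if b == j:
                    continue
                V[r, c] = W[a, b]
                c += 1
            s[r] = S[a, j]
            lamvec[r] = L[a, j]
            beta[r] = B[a, j]
            r += 1
        _lasso_cd(V, s, lamvec, beta, inner_tol, inner_max_iter)
        w12 = V @ beta
        r = 0
        for a in range(p):
            if a == j:
                continue
            W[a, j] = w12[r]
            W[j, a] = w12[r]
            B[a, j] = beta[r]
            r += 1


@njit(cache=True, fastmath=True)
def _assemble(W, B):  # pragma: no cover - jit
    """Recover Omega from the working covariance W and regression betas B."""
    p = W.shape[0]
    Omega = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for a in range(p):
            if a != j:
                dot += W[a, j] * B[a, j]
        denom = W[j, j] - dot
        if denom < 1e-12:
            denom = 1e-12
        ojj = 1.0 / denom
        Omega[j, j] = ojj
        for a in range(p):
            if a != j:
                Omega[a, j] = -B[a, j] * ojj
    # symmetrize (columns are solved one at a time)
    for a in range(p):
        for b in range(a + 1, p):
            v = 0.5 * (Omega[a, b] + Omega[b, a])
            Omega[a, b] = v
            Omega[b, a] = v
    return Omega


def _objective(S: np.ndarray, W: np.ndarray, lam: float, Omega: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        return np.inf
    pen = lam * np.sum(W * np.abs(Omega))
    return float(np.sum(S * Omega) - logdet + pen)


def kkt_residual(S: np.ndarray, W: np.ndarray, lam: float, Omega: np.ndarray) -> float:
    """Max-norm violation of the stationarity conditions at ``Omega``.

    On nonzero entries the subgradient is ``sign(omega)``; on zero entries
    the best subgradient in [-1, 1] is used, so the violation there is
    ``max(0, |S - Omega^{-1}| - lam W)``.  The diagonal (unpenalized)
    contributes ``|S_jj - (Omega^{-1})_jj|``.
    """
    Omega = np.asarray(Omega, dtype=float)
    sign, _ = np.linalg.slogdet(Omega)
    if sign <= 0:
        raise np.linalg.LinAlgError("Omega is singular or not positive definite")
    R = S - np.linalg.inv(Omega)
    off = ~np.eye(Omega.shape[0], dtype=bool)
    nz = (Omega != 0.0) & off
    z = (Omega == 0.0) & off
    res = np.abs(np.diag(R)).max() if Omega.shape[0] else 0.0
    if nz.any():
        res = max(res, np.max(np.abs(R[nz] + lam * W[nz] * np.sign(Omega[nz]))))
    if z.any():
        res = max(res, np.max(np.maximum(0.0, np.abs(R[z]) - lam * W[z])))
    return float(res)


def solve_wglasso(prob: WGlassoProblem, Omega0: np.ndarray | None = None,
                  *, raise_on_fail: bool = True):
    """Solve the weighted graphical lasso.

    Parameters
    ----------
    prob : WGlassoProblem
    Omega0 : optional warm-start precision matrix (symmetric PD).  The
        working covariance is initialized from its inverse; cold start uses
        ``diag(1/(S_jj + lam))``.
    raise_on_fail : raise :class:`WGlassoConvergenceError` when ``max_iter``
        sweeps do not reach tolerance.  When False the last iterate is
        returned with ``info['converged'] = False``.

    Returns
    -------
    Omega : (p, p) ndarray, symmetric positive definite
    info : dict with keys ``n_sweeps``, ``converged``, ``objective_path``
        (primal objective after each sweep, non-increasing up to solver
        tolerance), ``kkt``.
    """
    S, Wts, lam = prob.S, prob.W, prob.lam
    p = S.shape[0]
    L = lam * Wts
    np.fill_diagonal(L, 0.0)

    diag_floor = np.maximum(np.diag(S), 1e-12)
    if Omega0 is not None:
        Omega0 = np.asarray(Omega0, dtype=float)
        W = np.linalg.inv((Omega0 + Omega0.T) / 2.0)
        W = (W + W.T) / 2.0
        # keep the working diagonal consistent with the unpenalized
        # stationarity condition (Omega^{-1})_jj = S_jj
        np.fill_diagonal(W, diag_floor)
        B = np.zeros((p, p))
        for j in range(p):
            ojj = max(Omega0[j, j], 1e-12)
            B[:, j] = -Omega0[:, j] / ojj
            B[j, j] = 0.0
    else:
        W = np.diag(diag_floor).copy()
        W[~np.eye(p, dtype=bool)] = 0.0
        B = np.zeros((p, p))

    off = ~np.eye(p, dtype=bool)
    scale = float(np.mean(np.abs(S[off]))) if p > 1 else 0.0
    if scale <= 0:
        scale = float(np.mean(np.abs(np.diag(S)))) or 1.0
    tol_change = prob.tol * scale
    tol_kkt = prob.tol * (1.0 + float(np.max(np.abs(S))))
    inner_tol = 0.1 * tol_change
    if p == 1:
        Omega = np.array([[1.0 / max(S[0, 0], 1e-12)]])
        return Omega, {"n_sweeps": 0, "converged": True,
                       "objective_path": [_objective(S, Wts, lam, Omega)], "kkt": 0.0}

    Omega_prev = _assemble(W, B)
    path = []
    converged = False
    kkt = np.inf
    n_sweeps = 0
    change_prev = np.inf
    for n_sweeps in range(1, prob.max_iter + 1):
        _sweep(S, L, W, B, inner_tol, 50)
        Omega = _assemble(W, B)
        path.append(_objective(S, Wts, lam, Omega))
        change = float(np.mean(np.abs(Omega - Omega_prev)))
        Omega_prev = Omega
        omega_scale = float(np.mean(np.abs(Omega)))
        # crawl detection: entries far larger than S shrinking by <10% per
        # sweep after a warm-up — the signature of a near-unbounded
        # (degenerate) problem, where finishing is hopeless anyway
        stalled = change < prob.tol * omega_scale or (
            n_sweeps >= 30 and change > 0.9 * change_prev
            and change < 1e-3 * omega_scale)
        change_prev = change
        if change < tol_change or stalled:
            try:
                kkt = kkt_residual(S, Wts, lam, Omega)
            except np.linalg.LinAlgError:
                kkt = np.inf
            if kkt <= tol_kkt:
                converged = True
                break
            if stalled:
                # stagnation relative to the iterate itself without an
                # optimality certificate: near-singular inputs produce
                # iterates whose entries dwarf S and coordinate descent
                # crawls, so further sweeps are pointless — stop and report
                # the iterate as unconverged
                break
    Omega = Omega_prev
    info = {"n_sweeps": n_sweeps, "converged": converged,
            "objective_path": path, "kkt": kkt}
    if not converged and raise_on_fail:
        if not np.isfinite(kkt):
            try:
                kkt = kkt_residual(S, Wts, lam, Omega)
            except np.linalg.LinAlgError:
                kkt = np.inf
        raise WGlassoConvergenceError(
            f"weighted glasso did not converge in {prob.max_iter} sweeps "
            f"(KKT residual {kkt:.3g}, tolerance {tol_kkt:.3g})", Omega, kkt)
    return Omega, info
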