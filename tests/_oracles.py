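"""Independent reference solvers used only by the tests.

The weighted graphical-lasso oracle is a FISTA proximal-gradient method on
the primal objective with a positive-definiteness-preserving backtracking
line search.  It shares no code with the package's block-coordinate
solver, so agreement between the two is a meaningful cross-check.
"""

from __future__ import annotations

import numpy as np


def wglasso_objective(S, W, lam, Omega) -> float:
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        return np.inf
    return float(np.sum(S * Omega) - logdet + lam * np.sum(W * np.abs(Omega)))


def _soft(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def wglasso_fista(S, W, lam, max_iter=20000, tol=1e-12):
    """High-precision proximal-gradient solution of the weighted glasso."""
    S = np.asarray(S, float)
    p = S.shape[0]
    L = lam * np.asarray(W, float)
    Omega = np.diag(1.0 / np.maximum(np.diag(S), 1e-12)).copy()
    Y = Omega.copy()
    t_mom = 1.0
    step = 1.0 / max(np.linalg.eigvalsh(S).max() ** 2, 1.0)
    f_prev = wglasso_objective(S, W, lam, Omega)
    for _ in range(max_iter):
        try:
            Yinv = np.linalg.inv(Y)
        except np.linalg.LinAlgError:
            Y = Omega.copy()
            Yinv = np.linalg.inv(Y)
        grad = S - Yinv
        st = step
        while True:
            cand = _soft(Y - st * grad, st * L)
            cand = (cand + cand.T) / 2.0
            # PD check + sufficient-decrease of the smooth part
            try:
                np.linalg.cholesky(cand)
            except np.linalg.LinAlgError:
                st *= 0.5
                if st < 1e-14:
                    cand = Omega
                    break
                continue
            diff = cand - Y
            smooth_y = np.sum(S * Y) - np.linalg.slogdet(Y)[1]
            smooth_c = np.sum(S * cand) - np.linalg.slogdet(cand)[1]
            quad = smooth_y + np.sum(grad * diff) + np.sum(diff**2) / (2 * st)
            if smooth_c <= quad + 1e-12:
                break
            st *= 0.5
            if st < 1e-14:
                cand = Omega
                break
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        Y = cand + ((t_mom - 1.0) / t_new) * (cand - Omega)
        Y = (Y + Y.T) / 2.0
        f_new = wglasso_objective(S, W, lam, cand)
        if f_new > f_prev:  # FISTA restart
            Y = cand.copy()
            t_new = 1.0
        if abs(f_prev - f_new) < tol * (1.0 + abs(f_new)):
            Omega = cand
            break
        Omega = cand
        f_prev = min(f_prev, f_new)
        t_mom = t_new
    return Omega
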