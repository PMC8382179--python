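"""Constrained elastic-net solver for sparse sensor recovery.

Solves

    min_s  lam * ||s||_1 + (1 - lam) * ||s||_2      (Euclidean, not squared)

subject to either the exact reconstruction constraint  Psi^T s = w  (two
classes) or the elementwise relaxation  |Psi^T s - w| <= eps  (multi-class,
s and w may have several columns).

The solver is ADMM with the splitting  f(s) = indicator(constraint set),
g(z) = objective:  the projection onto {s : Psi^T s = w} is closed-form when
Psi has orthonormal columns, and prox of lam*L1 + (1-lam)*L2 is
soft-thresholding followed by block shrinkage (the two proximal maps
compose in that order).
"""

from __future__ import annotations

import numpy as np

__all__ = ["solve_constrained_elastic_net"]


def _prox_elastic(v: np.ndarray, lam: float, mu: float, t: float) -> np.ndarray:
    """prox_{t (lam ||.||_1 + mu ||.||_2)}(v)."""
    z = np.sign(v) * np.maximum(np.abs(v) - t * lam, 0.0)
    nz = np.linalg.norm(z)
    if nz <= t * mu:
        return np.zeros_like(z)
    return (1.0 - t * mu / nz) * z


def solve_constrained_elastic_net(Psi: np.ndarray, w: np.ndarray,
                                  lam: float = 0.9, eps: float = 0.0,
                                  rho: float = 1.0, max_iter: int = 20000,
                                  tol: float = 3e-9,
                                  squared_l2: bool = False):
    """Return ``(s, info)`` minimizing the elastic-net objective subject to
    ``Psi.T @ s = w`` (``eps == 0``) or ``|Psi.T @ s - w| <= eps`` elementwise.

    ``Psi`` is (n, m) with orthonormal columns; ``w`` is (m,) or (m, d); the
    returned ``s`` matches ``w``'s trailing shape.  ``info`` carries the
    solver iteration count and final residuals.
    """
    Psi = np.asarray(Psi, float)
    w = np.asarray(w, float)
    single = w.ndim == 1
    W = w[:, None] if single else w
    n, m = Psi.shape
    if W.shape[0] != m:
        raise ValueError("w length must equal the subspace dimension")
    gram = Psi.T @ Psi
    if not np.allclose(gram, np.eye(m), atol=1e-8):
        # orthonormalize and transform w accordingly: Psi = Q R, Psi^T s = w
        # <=> Q^T s = R^{-T} w
        Q, R = np.linalg.qr(Psi)
        return solve_constrained_elastic_net(
            Q, np.linalg.solve(R.T, W[:, 0] if single else W), lam=lam,
            eps=eps, rho=rho, max_iter=max_iter, tol=tol,
            squared_l2=squared_l2)

    mu = 1.0 - lam

    def project(S):
        A = Psi.T @ S
        if eps > 0.0:
            A_target = np.clip(A, W - eps, W + eps)
        else:
            A_target = W
        return S + Psi @ (A_target - A)

    S = project(np.zeros((n, W.shape[1])))
    Z = S.copy()
    U = np.zeros_like(S)
    t = 1.0 / rho
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        S = project(Z - U)
        V = (S + U).ravel()
        if squared_l2:
            z = np.sign(V) * np.maximum(np.abs(V) - t * lam, 0.0)
            Z_new = (z / (1.0 + 2.0 * t * mu)).reshape(S.shape)
        else:
            Z_new = _prox_elastic(V, lam, mu, t).reshape(S.shape)
        r_primal = np.linalg.norm(S - Z_new)
        r_dual = rho * np.linalg.norm(Z_new - Z)
        Z = Z_new
        U = U + S - Z
        if max(r_primal, r_dual) < tol * max(1.0, np.linalg.norm(Z)):
            break

    # report the feasible iterate
    S_out = project(Z)
    resid = Psi.T @ S_out - W
    if eps > 0.0:
        constraint_violation = float(np.max(np.maximum(np.abs(resid) - eps, 0.0)))
    else:
        constraint_violation = float(np.max(np.abs(resid))) if resid.size else 0.0
    info = {"iterations": n_iter, "constraint_violation": constraint_violation,
            "primal_residual": float(np.linalg.norm(S_out - Z))}
    s = S_out[:, 0] if single else S_out
    return s, info
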