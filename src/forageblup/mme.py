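"""Henderson's mixed-model equations: assembly and solution.

For the animal model y = Xb + Zu (+ Wp) + e with u ~ N(0, A s2A),
p ~ N(0, I s2pe) and e ~ N(0, R) (R diagonal, possibly heterogeneous),
the coefficient system is

    [ X'R-1X   X'R-1Z          X'R-1W        ] [b]   [X'R-1y]
    [ Z'R-1X   Z'R-1Z + A-1/s2A  Z'R-1W      ] [u] = [Z'R-1y]
    [ W'R-1X   W'R-1Z   W'R-1W + I/s2pe      ] [p]   [W'R-1y]

Its solution gives BLUEs of the fixed effects and BLUPs of the random
effects simultaneously.  Systems are assembled sparse and factorized by
a dense Cholesky at the desk scales this package targets, which keeps
solutions deterministic and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp


class InvalidVarianceError(ValueError):
    """A variance parameter required to be positive is not."""


class SingularSystemError(np.linalg.LinAlgError):
    """MME coefficient matrix singular after constraints."""


@dataclass
class MMESystem:
    """Assembled Henderson system plus (after solving) its solution."""

    C: sp.csr_matrix
    rhs: np.ndarray
    y: np.ndarray
    X: np.ndarray
    Z: sp.csr_matrix
    W: sp.csr_matrix | None
    resid_weight: np.ndarray  # per-record 1/sigma2_e
    n_fixed: int
    n_genetic: int
    n_pe: int
    beta: np.ndarray | None = None
    u: np.ndarray | None = None
    p: np.ndarray | None = None
    e: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.C.shape[0]


def assemble_mme(
    X: np.ndarray,
    Z: sp.csr_matrix,
    W: sp.csr_matrix | None,
    A_inv: sp.spmatrix,
    y: np.ndarray,
    sigma2_A: float,
    sigma2_e,
    sigma2_pe: float | None = None,
) -> MMESystem:
    """Assemble the Henderson coefficient matrix and right-hand side.

    ``sigma2_e`` may be a scalar or a per-record vector (heterogeneous
    diagonal R, e.g. cut-specific residual variances).
    """
    n = len(y)
    sigma2_e = np.broadcast_to(np.asarray(sigma2_e, dtype=float), (n,)).copy()
    if np.any(sigma2_e <= 0):
        raise InvalidVarianceError("residual variance must be strictly positive")
    if sigma2_A <= 0:
        raise InvalidVarianceError("additive genetic variance must be strictly positive")
    if W is not None and (sigma2_pe is None or sigma2_pe <= 0):
        raise InvalidVarianceError(
            "permanent-environment variance must be strictly positive when W is present"
        )

    w = 1.0 / sigma2_e
    Xs = sp.csr_matrix(X)
    parts = [Xs, Z] + ([W] if W is not None else [])
    Wfull = sp.hstack(parts).tocsr()
    Ri = sp.diags(w)
    C = (Wfull.T @ Ri @ Wfull).tolil()

    p_fix = X.shape[1]
    q = Z.shape[1]
    C[p_fix : p_fix + q, p_fix : p_fix + q] += A_inv / sigma2_A
    if W is not None:
        m = W.shape[1]
        C[p_fix + q : p_fix + q + m, p_fix + q : p_fix + q + m] += (
            sp.eye(m) / sigma2_pe
        )
    rhs = Wfull.T @ (w * y)
    return MMESystem(
        C=C.tocsr(),
        rhs=np.asarray(rhs).ravel(),
        y=np.asarray(y, dtype=float),
        X=X,
        Z=Z,
        W=W,
        resid_weight=w,
        n_fixed=p_fix,
        n_genetic=q,
        n_pe=W.shape[1] if W is not None else 0,
    )


def solve_mme(system: MMESystem) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
    """Solve the assembled system; returns (BLUE, BLUP, pe-BLUP, residuals).

    Raises :class:`SingularSystemError` naming aliased equations if the
    coefficient matrix is not positive definite.
    """
    Cd = system.C.toarray()
    try:
        cho = la.cho_factor(Cd, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        diag = np.abs(np.diag(Cd))
        suspects = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
        raise SingularSystemError(
            f"MME coefficient matrix singular; aliased equations at indices {suspects.tolist()}"
        ) from exc
    sol = la.cho_solve(cho, system.rhs, check_finite=False)

    p_fix, q, m = system.n_fixed, system.n_genetic, system.n_pe
    beta = sol[:p_fix]
    u = sol[p_fix : p_fix + q]
    p = sol[p_fix + q : p_fix + q + m] if m else None
    fitted = system.X @ beta + system.Z @ u
    if p is not None:
        fitted = fitted + system.W @ p
    e = system.y - fitted
    system.beta, system.u, system.p, system.e = beta, u, p, e
    return beta, u, p, e
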