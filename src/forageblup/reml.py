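"""Average-information REML for pedigree animal models.

Variance components are estimated by maximizing the restricted
log-likelihood

    logL = -1/2 ( log|V| + log|X'V^-1 X| + y'Py ),   P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1,

computed through Henderson's mixed-model equations: with C the full MME
coefficient matrix, log|V| + log|X'V^-1X| = log|C| + log|R| + sum_k log|G_k|
and y'Py = y'R^-1 e_hat.  Updates use the average-information (AI)
algorithm -- Newton steps with the averaged observed/expected
information 1/2 y'P V_i P V_j P y -- with step halving and an EM
fallback whenever an AI step would leave the parameter space or reduce
the likelihood.  This mirrors the DMUAI-style estimation customarily
used for this class of models.

The engine supports:

* scalar random terms u_k ~ N(0, s2_k K_k), K_k the pedigree A matrix
  (through its sparse inverse) or the identity (permanent environment);
* unstructured multi-dimension terms u ~ N(0, G (x) K), used for
  cut-wise genetic covariances and bivariate-trait fits;
* residuals that are heterogeneous-diagonal (per-cut variances) or
  block-diagonal by observation unit (2x2 trait covariance per record).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .design import ModelSpec, build_design_matrices
from .pedigree import OrderedPedigree, relationship_inverse

DEFAULT_SEED = 20170101

MAX_ITER = 200
REL_TOL = 1e-8
LOGL_TOL = 1e-9
FLOOR_FRACTION = 1e-8


# --------------------------------------------------------------------------
# model pieces
# --------------------------------------------------------------------------


@dataclass
class RandomTerm:
    """One random term: incidence Z (n x t*q, dim-major columns),
    covariance G (x) K with K given by its (sparse) inverse."""

    name: str
    Z: sp.csr_matrix
    q: int
    t: int = 1
    K_inv: sp.spmatrix | None = None  # None = identity
    K_logdet: float = 0.0


@dataclass
class GroupedResidual:
    """Diagonal R with one variance per record group (e.g. per cut)."""

    groups: np.ndarray
    labels: list

    @property
    def n_params(self) -> int:
        return len(self.labels)


@dataclass
class UnitResidual:
    """Block-diagonal R: a shared t x t matrix per observation unit.

    Units must be complete (all t dimensions observed)."""

    unit: np.ndarray  # int unit id per row
    dim: np.ndarray  # int dimension per row
    t: int
    pos: list[np.ndarray] = field(default_factory=list)  # row of (unit, dim a)

    def __post_init__(self):
        if not self.pos:
            units = np.unique(self.unit)
            lookup = {u: i for i, u in enumerate(units)}
            uidx = np.array([lookup[u] for u in self.unit])
            self.pos = []
            for a in range(self.t):
                rows_a = np.flatnonzero(self.dim == a)
                order = np.argsort(uidx[rows_a], kind="stable")
                rows_a = rows_a[order]
                if len(rows_a) != len(units):
                    raise ValueError(
                        "unit residual requires complete units (every dimension observed)"
                    )
                self.pos.append(rows_a)

    @property
    def n_units(self) -> int:
        return len(self.pos[0])

    @property
    def n_params(self) -> int:
        return self.t * (self.t + 1) // 2


def _vech_pairs(t: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(t) for b in range(a, t)]


def _basis(t: int, a: int, b: int) -> np.ndarray:
    E = np.zeros((t, t))
    E[a, b] = 1.0
    E[b, a] = 1.0
    return E


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Estimated variance components of one fit (trait units squared)."""

    sigma2_A: float | None = None
    sigma2_pe: float | None = None
    sigma2_e: float | dict | None = None
    G_mat: np.ndarray | None = None
    R_mat: np.ndarray | None = None

    @property
    def sigma2_e_mean(self) -> float | None:
        if self.sigma2_e is None:
            return None
        if isinstance(self.sigma2_e, dict):
            return float(np.mean(list(self.sigma2_e.values())))
        return float(self.sigma2_e)

    @property
    def sigma2_P(self) -> float | None:
        """Phenotypic variance: sum of the fitted components, with
        cut-specific residuals entering through their mean."""
        total = 0.0
        seen = False
        for v in (self.sigma2_A, self.sigma2_pe, self.sigma2_e_mean):
            if v is not None:
                total += v
                seen = True
        return total if seen else None


@dataclass
class REMLResult:
    vc: VarianceComponents
    logL: float
    n_iter: int
    converged: bool
    AI_matrix: np.ndarray
    theta: np.ndarray
    param_names: list[str]
    beta: np.ndarray | None = None
    fixed_names: list[str] | None = None
    u_genetic: np.ndarray | None = None
    u_pe: np.ndarray | None = None
    ped_ids: list[str] | None = None
    boundary: bool = False
    n_records: int = 0
    meta: dict = field(default_factory=dict)

    def theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of the parameter estimates (inverse AI)."""
        return np.linalg.inv(self.AI_matrix)

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.theta_cov()[i, i]))


# --------------------------------------------------------------------------
# engine
# --------------------------------------------------------------------------


class _Eval:
    __slots__ = (
        "logL", "grad", "AI", "s", "e", "Cinv",
        "em_terms", "em_resid", "theta",
    )


class REMLProblem:
    """Restricted-likelihood machinery for one data/model combination.

    Parameters are packed as: for each random term its variance (scalar)
    or the vech of its G matrix, followed by the residual parameters.
    """

    def __init__(self, y, X, terms: list[RandomTerm], residual):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n = len(self.y)
        self.p = self.X.shape[1]
        self.terms = terms
        self.residual = residual
        self.W = sp.hstack([sp.csr_matrix(self.X)] + [t.Z for t in terms]).tocsr()
        self.offsets = []
        off = self.p
        for t in terms:
            self.offsets.append(off)
            off += t.t * t.q
        self.m = off
        self.param_names = []
        for t in terms:
            if t.t == 1:
                self.param_names.append(f"sigma2_{t.name}")
            else:
                for a, b in _vech_pairs(t.t):
                    self.param_names.append(f"{t.name}[{a},{b}]")
        if isinstance(residual, GroupedResidual):
            for lab in residual.labels:
                self.param_names.append(f"sigma2_e[{lab}]")
            self._group_rows = [
                np.flatnonzero(residual.groups == g)
                for g in range(len(residual.labels))
            ]
            # per-group normal-equation blocks W_c' W_c are constant
            self._group_WtW = [
                (self.W[rows].T @ self.W[rows]).tocsr() for rows in self._group_rows
            ]
        else:
            for a, b in _vech_pairs(residual.t):
                self.param_names.append(f"R[{a},{b}]")
        self.n_params = len(self.param_names)
        self.floor = FLOOR_FRACTION * float(np.var(self.y))

    # -- parameter packing -------------------------------------------------

    def pack(self, term_values: list, resid_value) -> np.ndarray:
        out = []
        for trm, val in zip(self.terms, term_values):
            if trm.t == 1:
                out.append([float(val)])
            else:
                val = np.asarray(val)
                out.append([val[a, b] for a, b in _vech_pairs(trm.t)])
        if isinstance(self.residual, GroupedResidual):
            out.append(np.asarray(resid_value, dtype=float).ravel())
        else:
            rv = np.asarray(resid_value)
            out.append([rv[a, b] for a, b in _vech_pairs(self.residual.t)])
        return np.concatenate(out)

    def unpack(self, theta: np.ndarray) -> tuple[list, object]:
        terms = []
        i = 0
        for trm in self.terms:
            if trm.t == 1:
                terms.append(float(theta[i]))
                i += 1
            else:
                G = np.zeros((trm.t, trm.t))
                for a, b in _vech_pairs(trm.t):
                    G[a, b] = G[b, a] = theta[i]
                    i += 1
                terms.append(G)
        if isinstance(self.residual, GroupedResidual):
            g = self.residual.n_params
            resid = theta[i : i + g].copy()
        else:
            t = self.residual.t
            resid = np.zeros((t, t))
            for a, b in _vech_pairs(t):
                resid[a, b] = resid[b, a] = theta[i]
                i += 1
        return terms, resid

    def is_valid(self, theta: np.ndarray) -> bool:
        terms, resid = self.unpack(theta)
        for val in terms:
            if np.isscalar(val):
                if val < self.floor:
                    return False
            else:
                if np.any(np.diag(val) < self.floor):
                    return False
                if np.linalg.eigvalsh(val)[0] <= 0:
                    return False
        if isinstance(self.residual, GroupedResidual):
            if np.any(resid < self.floor):
                return False
        else:
            if np.linalg.eigvalsh(resid)[0] <= self.floor:
                return False
        return True

    # -- residual helpers --------------------------------------------------

    def _resid_apply(self, resid_par):
        """Return (Rinv as sparse/diag operator, log|R|)."""
        if isinstance(self.residual, GroupedResidual):
            w = 1.0 / resid_par[self.residual.groups]
            logdet = float(np.sum(np.log(resid_par[self.residual.groups])))
            return sp.diags(w), logdet
        Rmat = resid_par
        Rinv_mat = np.linalg.inv(Rmat)
        logdet = self.residual.n_units * float(np.linalg.slogdet(Rmat)[1])
        return self._unit_block_matrix(Rinv_mat), logdet

    def _unit_block_matrix(self, M: np.ndarray) -> sp.csr_matrix:
        """Sparse block-diagonal matrix with block M per unit."""
        res = self.residual
        rows, cols, vals = [], [], []
        for a in range(res.t):
            for b in range(res.t):
                if M[a, b] != 0.0:
                    rows.append(res.pos[a])
                    cols.append(res.pos[b])
                    vals.append(np.full(res.n_units, M[a, b]))
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )

    # -- likelihood, gradient, average information -------------------------

    def evaluate(self, theta: np.ndarray, derivs: bool = True) -> _Eval:
        term_vals, resid_par = self.unpack(theta)
        Rinv, logdetR = self._resid_apply(resid_par)

        WtRi = (self.W.T @ Rinv).tocsr()
        C = (WtRi @ self.W).tolil()
        logdetG = 0.0
        for trm, val, off in zip(self.terms, term_vals, self.offsets):
            sl = slice(off, off + trm.t * trm.q)
            if trm.t == 1:
                Ki = trm.K_inv if trm.K_inv is not None else sp.eye(trm.q)
                C[sl, sl] += Ki / val
                logdetG += trm.q * np.log(val) + trm.K_logdet
            else:
                Ginv = np.linalg.inv(val)
                Ki = trm.K_inv if trm.K_inv is not None else sp.eye(trm.q)
                C[sl, sl] += sp.kron(sp.csr_matrix(Ginv), Ki)
                sign, ld = np.linalg.slogdet(val)
                logdetG += trm.q * ld + trm.t * trm.K_logdet

        Cd = C.toarray()
        cho = la.cho_factor(Cd, lower=True, check_finite=False)
        rhs = WtRi @ self.y
        s = la.cho_solve(cho, rhs, check_finite=False)
        e = self.y - self.W @ s
        yRiy = float(self.y @ (Rinv @ self.y))
        yPy = yRiy - float(s @ rhs)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        logL = -0.5 * (logdetC + logdetR + logdetG + yPy)

        out = _Eval()
        out.theta = theta.copy()
        out.logL = logL
        out.s = s
        out.e = e
        if not derivs:
            out.grad = out.AI = out.Cinv = None
            out.em_terms = out.em_resid = None
            return out

        Cinv = la.cho_solve(cho, np.eye(self.m), check_finite=False)
        Py = Rinv @ e

        grad = np.zeros(self.n_params)
        Fcols = np.zeros((self.n, self.n_params))
        em_terms = []
        ip = 0
        for trm, val, off in zip(self.terms, term_vals, self.offsets):
            if trm.t == 1:
                u = s[off : off + trm.q]
                Cb = Cinv[off : off + trm.q, off : off + trm.q]
                if trm.K_inv is not None:
                    T = float(trm.K_inv.multiply(Cb).sum())
                    Q = float(u @ (trm.K_inv @ u))
                else:
                    T = float(np.trace(Cb))
                    Q = float(u @ u)
                grad[ip] = -0.5 * (trm.q / val - T / val**2 - Q / val**2)
                Fcols[:, ip] = trm.Z @ u / val
                em_terms.append((Q + T) / trm.q)
                ip += 1
            else:
                t, q = trm.t, trm.q
                U = s[off : off + t * q].reshape(t, q)
                Tm = np.zeros((t, t))
                Qm = np.zeros((t, t))
                for a in range(t):
                    for b in range(a, t):
                        Cab = Cinv[off + a * q : off + (a + 1) * q,
                                   off + b * q : off + (b + 1) * q]
                        if trm.K_inv is not None:
                            Tm[a, b] = Tm[b, a] = float(trm.K_inv.multiply(Cab.T).sum())
                            Qm[a, b] = Qm[b, a] = float(U[a] @ (trm.K_inv @ U[b]))
                        else:
                            Tm[a, b] = Tm[b, a] = float(np.trace(Cab))
                            Qm[a, b] = Qm[b, a] = float(U[a] @ U[b])
                Ginv = np.linalg.inv(val)
                for a, b in _vech_pairs(t):
                    E = _basis(t, a, b)
                    M = Ginv @ E @ Ginv
                    trPV = q * float(np.trace(Ginv @ E)) - float((M * Tm).sum())
                    quad = float((M * Qm).sum())
                    grad[ip] = -0.5 * (trPV - quad)
                    Fcols[:, ip] = trm.Z @ ((E @ Ginv @ U).reshape(-1))
                    ip += 1
                em_terms.append((Qm + Tm) / q)

        if isinstance(self.residual, GroupedResidual):
            em_resid = np.zeros(self.residual.n_params)
            for g, (rows, WtW) in enumerate(zip(self._group_rows, self._group_WtW)):
                s2 = resid_par[g]
                n_g = len(rows)
                tc = float(WtW.multiply(Cinv).sum())
                ss = float(e[rows] @ e[rows])
                grad[ip] = -0.5 * (n_g / s2 - tc / s2**2 - ss / s2**2)
                col = np.zeros(self.n)
                col[rows] = e[rows] / s2
                Fcols[:, ip] = col
                em_resid[g] = (ss + tc) / n_g
                ip += 1
        else:
            res = self.residual
            t = res.t
            Rinv_mat = np.linalg.inv(resid_par)
            v = np.asarray(Py).ravel()
            Vm = np.zeros((t, t))
            Em = np.zeros((t, t))
            for a in range(t):
                for b in range(t):
                    Vm[a, b] = float(v[res.pos[a]] @ v[res.pos[b]])
                    Em[a, b] = float(e[res.pos[a]] @ e[res.pos[b]])
            # conditional residual covariance contribution, per unit: W_u Cinv W_u'
            Wm = np.zeros((t, t))
            Wrows = [self.W[res.pos[a]] for a in range(t)]
            Wc = [np.asarray((Wr @ Cinv)) for Wr in Wrows]
            for a in range(t):
                for b in range(t):
                    Wm[a, b] = float(Wrows[b].multiply(Wc[a]).sum())
            for a, b in _vech_pairs(t):
                E = _basis(t, a, b)
                S = Rinv_mat @ E @ Rinv_mat
                Ssp = self._unit_block_matrix(S)
                Msp = (self.W.T @ (Ssp @ self.W)).tocsr()
                t2 = float(Msp.multiply(Cinv).sum())
                trR = res.n_units * float(np.trace(Rinv_mat @ E))
                quad = float((E * Vm).sum())
                grad[ip] = -0.5 * (trR - t2 - quad)
                col = np.zeros(self.n)
                for aa in range(t):
                    acc = np.zeros(res.n_units)
                    for bb in range(t):
                        if E[aa, bb] != 0.0:
                            acc += E[aa, bb] * v[res.pos[bb]]
                    col[res.pos[aa]] = acc
                Fcols[:, ip] = col
                ip += 1
            em_resid = (Em + Wm) / res.n_units

        # average information: AI_ij = 1/2 f_i' P f_j
        RiF = Rinv @ Fcols
        tmp = la.cho_solve(cho, self.W.T @ RiF, check_finite=False)
        PF = RiF - Rinv @ (self.W @ tmp)
        AI = 0.5 * (Fcols.T @ PF)
        AI = 0.5 * (AI + AI.T)

        out.grad = grad
        out.AI = AI
        out.Cinv = Cinv
        out.em_terms = em_terms
        out.em_resid = em_resid
        return out

    def restricted_loglik(self, theta: np.ndarray) -> float:
        """REML log-likelihood at ``theta`` (additive constant
        -n*/2 log(2*pi) omitted consistently everywhere)."""
        return self.evaluate(np.asarray(theta, dtype=float), derivs=False).logL

    # -- optimization ------------------------------------------------------

    def _em_theta(self, ev: _Eval) -> np.ndarray:
        return self.pack(ev.em_terms, ev.em_resid)

    def _clip(self, theta: np.ndarray) -> np.ndarray:
        """Clamp scalar variances at the floor (leaves matrices alone)."""
        out = theta.copy()
        i = 0
        for trm in self.terms:
            if trm.t == 1:
                out[i] = max(out[i], self.floor)
                i += 1
            else:
                i += trm.t * (trm.t + 1) // 2
        if isinstance(self.residual, GroupedResidual):
            g = self.residual.n_params
            out[i : i + g] = np.maximum(out[i : i + g], self.floor)
        return out

    def fit(self, theta0: np.ndarray, max_iter: int = MAX_ITER) -> _FitState:
        theta = self._clip(np.asarray(theta0, dtype=float))
        if not self.is_valid(theta):
            raise ValueError("invalid starting values for REML")
        ev = self.evaluate(theta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            step = None
            try:
                step = np.linalg.solve(
                    ev.AI + 1e-12 * np.eye(self.n_params) * np.trace(ev.AI), ev.grad
                )
            except np.linalg.LinAlgError:
                step = None

            new_ev = None
            if step is not None:
                frac = 1.0
                for _ in range(10):
                    cand = self._clip(theta + frac * step)
                    if self.is_valid(cand):
                        try:
                            trial = self.evaluate(cand)
                        except np.linalg.LinAlgError:
                            trial = None
                        if trial is not None and np.isfinite(trial.logL) and (
                            trial.logL >= ev.logL - 1e-10
                        ):
                            new_ev = trial
                            break
                    frac *= 0.5
            if new_ev is None:
                # EM fallback: guaranteed uphill, always in the space
                cand = self._clip(self._em_theta(ev))
                if not self.is_valid(cand):
                    break
                new_ev = self.evaluate(cand)

            d_logl = new_ev.logL - ev.logL
            rel = np.max(np.abs(new_ev.theta - theta) / (np.abs(theta) + self.floor + 1e-30))
            theta = new_ev.theta
            ev = new_ev
            if rel < REL_TOL or abs(d_logl) < LOGL_TOL:
                converged = True
                break
        return _FitState(problem=self, ev=ev, n_iter=it, converged=converged)


@dataclass
class _FitState:
    problem: REMLProblem
    ev: _Eval
    n_iter: int
    converged: bool

    @property
    def at_boundary(self) -> bool:
        pb = self.problem
        theta = self.ev.theta
        i = 0
        for trm in pb.terms:
            if trm.t == 1:
                if theta[i] <= 2.0 * pb.floor:
                    return True
                i += 1
            else:
                i += trm.t * (trm.t + 1) // 2
        return False


# --------------------------------------------------------------------------
# public fits
# --------------------------------------------------------------------------


def _pedigree_term(name: str, Z: sp.csr_matrix, ped: OrderedPedigree, t: int = 1) -> RandomTerm:
    A_inv = relationship_inverse(ped)
    # log|A| = sum log d_i of the mendelian-sampling variances
    F = ped.inbreeding()
    d = np.ones(ped.n)
    for i in range(ped.n):
        for par in (ped.sire[i], ped.dam[i]):
            if par >= 0:
                d[i] -= 0.25 * (1.0 + F[par])
    K_logdet = float(np.sum(np.log(d)))
    return RandomTerm(name=name, Z=Z, q=ped.n, t=t, K_inv=A_inv, K_logdet=K_logdet)


def fit_single_harvest(
    pheno: pd.DataFrame,
    ped: OrderedPedigree,
    trait: str,
    harvest: str,
    max_iter: int = MAX_ITER,
) -> REMLResult:
    """Single-cut animal model: trait = mean + year + additive + residual.

    Estimates (sigma2_A, sigma2_e) by AI-REML and returns BLUPs at the
    optimum.
    """
    sub = pheno.loc[pheno["harvest"] == harvest]
    if sub["year"].nunique() < 2:
        raise ValueError("single-harvest fit needs records from >= 2 years")
    dm = build_design_matrices(sub, ModelSpec(response=trait, fixed=("year",)), ped)
    term = _pedigree_term("A", dm.Z, ped)
    resid = GroupedResidual(groups=np.zeros(len(dm.y), dtype=int), labels=[harvest])
    prob = REMLProblem(dm.y, dm.X, [term], resid)
    vy = float(np.var(dm.y))
    theta0 = prob.pack([0.4 * vy], [0.6 * vy])
    st = prob.fit(theta0, max_iter=max_iter)
    (s2A,), (s2e,) = st.ev.theta[:1], st.ev.theta[1:]
    vc = VarianceComponents(sigma2_A=float(s2A), sigma2_e=float(s2e))
    return _wrap_result(st, vc, dm, ped, prob, meta={"model": "single", "harvest": harvest, "trait": trait})


def fit_multi_harvest(
    pheno: pd.DataFrame,
    ped: OrderedPedigree,
    trait: str,
    structure: str = "repeatability",
    max_iter: int = MAX_ITER,
) -> REMLResult:
    """Multi-cut repeated-measures animal model.

    ``repeatability`` (default): one additive variance shared across
    cuts, a plant-level permanent-environment variance, and cut-specific
    residual variances.  ``unstructured``: a full cut x cut genetic
    covariance matrix G (x) A instead of the shared additive variance.
    With a single observed cut the model collapses to the single-cut
    form (no permanent environment), so the fit coincides with
    :func:`fit_single_harvest`.
    """
    sub = pheno.loc[pheno[trait].notna()]
    cuts = sorted(sub["harvest"].unique())
    if len(cuts) < 2:
        return fit_single_harvest(pheno, ped, trait, cuts[0], max_iter=max_iter)

    dm = build_design_matrices(
        sub, ModelSpec(response=trait, fixed=("harvest", "year"), permanent_env=True), ped
    )
    rows = dm.rows
    cut_idx = rows["harvest"].map({c: i for i, c in enumerate(cuts)}).to_numpy()
    resid = GroupedResidual(groups=cut_idx, labels=list(cuts))
    vy = float(np.var(dm.y))

    if structure == "repeatability":
        gen = _pedigree_term("A", dm.Z, ped)
        pe = RandomTerm("pe", dm.W.tocsr(), q=dm.W.shape[1])
        prob = REMLProblem(dm.y, dm.X, [gen, pe], resid)
        theta0 = prob.pack([0.3 * vy, 0.2 * vy], np.full(len(cuts), 0.5 * vy))
        st = prob.fit(theta0, max_iter=max_iter)
        terms, resid_par = prob.unpack(st.ev.theta)
        vc = VarianceComponents(
            sigma2_A=float(terms[0]),
            sigma2_pe=float(terms[1]),
            sigma2_e={c: float(v) for c, v in zip(cuts, resid_par)},
        )
    elif structure == "unstructured":
        t = len(cuts)
        n = len(dm.y)
        gidx = dm.Z.nonzero()[1]
        Zg = sp.csr_matrix(
            (np.ones(n), (np.arange(n), cut_idx * ped.n + gidx)),
            shape=(n, t * ped.n),
        )
        gen = _pedigree_term("G", Zg, ped, t=t)
        pe = RandomTerm("pe", dm.W.tocsr(), q=dm.W.shape[1])
        prob = REMLProblem(dm.y, dm.X, [gen, pe], resid)
        G0 = 0.3 * vy * (0.6 * np.eye(t) + 0.4 * np.ones((t, t)))
        theta0 = prob.pack([G0, 0.2 * vy], np.full(t, 0.5 * vy))
        st = prob.fit(theta0, max_iter=max_iter)
        terms, resid_par = prob.unpack(st.ev.theta)
        vc = VarianceComponents(
            G_mat=terms[0],
            sigma2_A=float(np.mean(np.diag(terms[0]))),
            sigma2_pe=float(terms[1]),
            sigma2_e={c: float(v) for c, v in zip(cuts, resid_par)},
        )
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return _wrap_result(
        st, vc, dm, ped, prob, meta={"model": "multi", "structure": structure, "trait": trait, "cuts": cuts}
    )


def fit_bivariate(
    pheno: pd.DataFrame,
    ped: OrderedPedigree,
    trait_x: str,
    trait_y: str,
    include_pe: bool | str = "auto",
    max_iter: int = MAX_ITER,
) -> REMLResult:
    """Bivariate animal model for a trait pair.

    Complete-case records (both traits observed) are stacked two rows
    per record; the additive term has covariance G (x) A with G an
    unstructured 2x2 matrix, the residual a shared 2x2 matrix per
    record.  A 2x2 plant-level permanent-environment term is added when
    plants carry repeated records across cuts (or on request).
    Starting values come from the univariate fits.
    """
    sub = pheno.loc[pheno[trait_x].notna() & pheno[trait_y].notna()].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no records with both traits observed")
    cuts = sorted(sub["harvest"].unique())
    if include_pe == "auto":
        # permanent environment is identifiable (and needed) whenever the
        # same physical plant carries repeated records, across cuts or years
        include_pe = bool(
            sub.groupby(["genotype", "replicate"]).size().max() > 1
        )

    n = len(sub)
    fixed = ("harvest", "year") if len(cuts) > 1 else ("year",)
    dm = build_design_matrices(
        sub.assign(_resp=0.0), ModelSpec(response="_resp", fixed=fixed, permanent_env=True), ped
    )
    # stacked system: rows [trait_x block; trait_y block]
    y = np.concatenate([sub[trait_x].to_numpy(float), sub[trait_y].to_numpy(float)])
    X = la.block_diag(dm.X, dm.X)
    fixed_names = [f"{trait_x}:{c}" for c in dm.fixed_names] + [
        f"{trait_y}:{c}" for c in dm.fixed_names
    ]
    gidx = dm.Z.nonzero()[1]
    rows2 = np.arange(2 * n)
    dim = np.repeat([0, 1], n)
    Zg = sp.csr_matrix(
        (np.ones(2 * n), (rows2, dim * ped.n + np.tile(gidx, 2))),
        shape=(2 * n, 2 * ped.n),
    )
    terms = [_pedigree_term("G", Zg, ped, t=2)]
    if include_pe:
        npl = dm.W.shape[1]
        pidx = dm.W.nonzero()[1]
        Zpe = sp.csr_matrix(
            (np.ones(2 * n), (rows2, dim * npl + np.tile(pidx, 2))),
            shape=(2 * n, 2 * npl),
        )
        terms.append(RandomTerm("P", Zpe, q=npl, t=2))
    resid = UnitResidual(unit=np.tile(np.arange(n), 2), dim=dim, t=2)
    prob = REMLProblem(y, X, terms, resid)

    # univariate starts
    uni = {}
    for tr in (trait_x, trait_y):
        if len(cuts) > 1:
            uni[tr] = fit_multi_harvest(sub, ped, tr, max_iter=50)
        else:
            uni[tr] = fit_single_harvest(sub, ped, tr, cuts[0], max_iter=50)
    r_ph = float(np.corrcoef(sub[trait_x], sub[trait_y])[0, 1])
    r0 = float(np.clip(r_ph, -0.7, 0.7))
    ax, ay = uni[trait_x].vc.sigma2_A, uni[trait_y].vc.sigma2_A
    ax = max(ax, prob.floor * 10)
    ay = max(ay, prob.floor * 10)
    G0 = np.array([[ax, r0 * np.sqrt(ax * ay)], [r0 * np.sqrt(ax * ay), ay]])
    start_terms = [G0]
    if include_pe:
        px = uni[trait_x].vc.sigma2_pe or 0.1 * uni[trait_x].vc.sigma2_P
        py = uni[trait_y].vc.sigma2_pe or 0.1 * uni[trait_y].vc.sigma2_P
        start_terms.append(np.array([[px, 0.0], [0.0, py]]))
    ex = uni[trait_x].vc.sigma2_e_mean
    ey = uni[trait_y].vc.sigma2_e_mean
    R0 = np.array([[ex, r0 * np.sqrt(ex * ey)], [r0 * np.sqrt(ex * ey), ey]])
    theta0 = prob.pack(start_terms, R0)
    st = prob.fit(theta0, max_iter=max_iter)
    term_vals, resid_par = prob.unpack(st.ev.theta)
    vc = VarianceComponents(
        G_mat=term_vals[0],
        R_mat=resid_par,
        sigma2_pe=None if not include_pe else float(np.trace(term_vals[1]) / 2.0),
    )
    res = _wrap_result(
        st, vc, dm, ped, prob,
        meta={"model": "bivariate", "traits": (trait_x, trait_y), "include_pe": include_pe},
    )
    res.fixed_names = fixed_names
    # project a runaway genetic correlation back into [-1, 1]
    G = term_vals[0]
    rg = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
    if abs(rg) > 1.0:
        warnings.warn("genetic correlation estimate outside [-1, 1]; projected", UserWarning)
        G[0, 1] = G[1, 0] = np.sign(rg) * np.sqrt(G[0, 0] * G[1, 1]) * (1 - 1e-10)
    return res


def _wrap_result(st: _FitState, vc, dm, ped, prob, meta) -> REMLResult:
    s = st.ev.s
    p = prob.p
    beta = s[:p]
    first = prob.terms[0]
    u_gen = s[prob.offsets[0] : prob.offsets[0] + first.t * first.q]
    u_pe = None
    for trm, off in zip(prob.terms, prob.offsets):
        if trm.name in ("pe", "P"):
            u_pe = s[off : off + trm.t * trm.q]
    return REMLResult(
        vc=vc,
        logL=st.ev.logL,
        n_iter=st.n_iter,
        converged=st.converged,
        AI_matrix=st.ev.AI,
        theta=st.ev.theta,
        param_names=prob.param_names,
        beta=beta,
        fixed_names=dm.fixed_names,
        u_genetic=u_gen,
        u_pe=u_pe,
        ped_ids=list(ped.ids),
        boundary=st.at_boundary,
        n_records=prob.n,
        meta=meta,
    )
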