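"""Average-information REML engine.

Fits Gaussian mixed models y = Xb + e, e ~ MVN(0, sum_k theta_k K_k) by
maximizing the restricted (or full) likelihood.  Three interchangeable
linear-algebra backends provide the per-iteration quantities:

* ``DenseKernel`` — generic dense matrices, O(n^3) per iteration;
* ``EigenKernel`` — one non-identity component plus the identity; a single
  eigendecomposition makes every iteration O(n p^2) (the natural choice for
  GRM fits);
* ``BlockedKernel`` — all components share a block-diagonal structure
  (families, twin pairs); per-iteration work is batched over blocks.

All backends return the same quantities so they can be cross-checked:
restricted/full log-likelihood, the score for each variance parameter,
the average-information (AI) matrix, and the expected-information traces
tr(P K_i), tr(P K_i P K_j) used for Fisher information matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import DesignError, NumericalError


@dataclass
class KernelState:
    """Quantities at one parameter value theta."""

    ok: bool
    theta: np.ndarray
    ll: float = np.nan
    grad: np.ndarray | None = None
    ai: np.ndarray | None = None
    beta: np.ndarray | None = None
    tr_pk: np.ndarray | None = None  # tr(P K_k) (REML) or tr(V^-1 K_k) (ML)
    quad: np.ndarray | None = None  # y' P K_k P y
    ypy: float = np.nan


def _solve_psd(C: np.ndarray, rhs: np.ndarray):
    try:
        cf = sla.cho_factor(C)
    except sla.LinAlgError as exc:
        raise DesignError(f"singular X'V^-1X matrix ({exc})") from exc
    return sla.cho_solve(cf, rhs), 2.0 * np.log(np.diag(cf[0])).sum()


class _KernelBase:
    n: int
    p: int
    k: int

    def var_y(self) -> float:
        raise NotImplementedError

    def quantities(self, theta, method="REML") -> KernelState:
        raise NotImplementedError

    def expected_info(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """(t, G) with t_i = tr(P K_i), G_ij = tr(P K_i P K_j)."""
        raise NotImplementedError


# ---------------------------------------------------------------------------


class DenseKernel(_KernelBase):
    def __init__(self, K_list, X, y):
        self.K = [k.toarray() if sp.issparse(k) else np.asarray(k, float) for k in K_list]
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.n, self.p = self.X.shape
        self.k = len(self.K)
        if np.linalg.matrix_rank(self.X) < self.p:
            raise DesignError("fixed-effect design is rank deficient")

    def var_y(self) -> float:
        resid = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        return float(resid @ resid / max(self.n - self.p, 1))

    def _decompose(self, theta):
        V = sum(t * K for t, K in zip(theta, self.K))
        try:
            cf = sla.cho_factor(V, lower=True)
        except sla.LinAlgError:
            return None
        logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
        Vinv = sla.cho_solve(cf, np.eye(self.n))
        ViX = Vinv @ self.X
        C = self.X.T @ ViX
        return V, logdetV, Vinv, ViX, C

    def quantities(self, theta, method="REML") -> KernelState:
        theta = np.asarray(theta, float)
        dec = self._decompose(theta)
        if dec is None:
            return KernelState(ok=False, theta=theta)
        _, logdetV, Vinv, ViX, C = dec
        Viy = Vinv @ self.y
        beta, logdetC = _solve_psd(C, self.X.T @ Viy)
        Cinv = _solve_psd(C, np.eye(self.p))[0]
        Py = Viy - ViX @ beta
        ypy = float(self.y @ Py)
        W = np.column_stack([K @ Py for K in self.K])
        quad = Py @ W
        tr_vik = np.array([np.sum(Vinv * K) for K in self.K])
        if method == "REML":
            M = [ViX.T @ K @ ViX for K in self.K]
            tr_pk = tr_vik - np.array([np.sum(Cinv * m.T) for m in M])
            ll = -0.5 * (logdetV + logdetC + ypy)
            PW = Vinv @ W - ViX @ (Cinv @ (ViX.T @ W))
        else:
            tr_pk = tr_vik
            ll = -0.5 * (logdetV + ypy)
            PW = Vinv @ W
        grad = -0.5 * (tr_pk - quad)
        ai = 0.5 * W.T @ PW
        ai = 0.5 * (ai + ai.T)
        return KernelState(True, theta, ll, grad, ai, beta, tr_pk, quad, ypy)

    def expected_info(self, theta):
        dec = self._decompose(np.asarray(theta, float))
        if dec is None:
            raise NumericalError("covariance matrix not positive definite")
        _, _, Vinv, ViX, C = dec
        Cinv = _solve_psd(C, np.eye(self.p))[0]
        P = Vinv - ViX @ Cinv @ ViX.T
        PK = [P @ K for K in self.K]
        t = np.array([np.trace(pk) for pk in PK])
        G = np.empty((self.k, self.k))
        for i in range(self.k):
            for j in range(i + 1):
                G[i, j] = G[j, i] = np.sum(PK[i] * PK[j].T)
        return t, G


# ---------------------------------------------------------------------------


class EigenKernel(_KernelBase):
    """One dense component K plus the identity: V = theta0*K + theta1*I."""

    def __init__(self, K, X, y):
        K = K.toarray() if sp.issparse(K) else np.asarray(K, float)
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.n, self.p = self.X.shape
        self.k = 2
        if np.linalg.matrix_rank(self.X) < self.p:
            raise DesignError("fixed-effect design is rank deficient")
        self.d, U = np.linalg.eigh(K)
        self.Xr = U.T @ self.X
        self.yr = U.T @ self.y

    def var_y(self) -> float:
        resid = self.yr - self.Xr @ np.linalg.lstsq(self.Xr, self.yr, rcond=None)[0]
        return float(resid @ resid / max(self.n - self.p, 1))

    def _eigvals(self, theta):
        return theta[0] * self.d + theta[1]

    def quantities(self, theta, method="REML") -> KernelState:
        theta = np.asarray(theta, float)
        lam = self._eigvals(theta)
        if (lam <= 0).any():
            return KernelState(ok=False, theta=theta)
        w = 1.0 / lam
        logdetV = np.log(lam).sum()
        ViX = self.Xr * w[:, None]
        C = self.Xr.T @ ViX
        Viy = self.yr * w
        beta, logdetC = _solve_psd(C, self.Xr.T @ Viy)
        Cinv = _solve_psd(C, np.eye(self.p))[0]
        Py = Viy - ViX @ beta
        ypy = float(self.yr @ Py)
        kdiag = (self.d, np.ones(self.n))
        W = np.column_stack([kd * Py for kd in kdiag])
        quad = Py @ W
        tr_vik = np.array([(kd * w).sum() for kd in kdiag])
        if method == "REML":
            tr_pk = tr_vik - np.array(
                [np.sum(Cinv * (self.Xr.T @ (self.Xr * (kd * w * w)[:, None])).T) for kd in kdiag]
            )
            ll = -0.5 * (logdetV + logdetC + ypy)
            PW = W * w[:, None] - ViX @ (Cinv @ (ViX.T @ W))
        else:
            tr_pk = tr_vik
            ll = -0.5 * (logdetV + ypy)
            PW = W * w[:, None]
        grad = -0.5 * (tr_pk - quad)
        ai = 0.5 * W.T @ PW
        ai = 0.5 * (ai + ai.T)
        return KernelState(True, theta, ll, grad, ai, beta, tr_pk, quad, ypy)

    def expected_info(self, theta):
        lam = self._eigvals(np.asarray(theta, float))
        if (lam <= 0).any():
            raise NumericalError("covariance matrix not positive definite")
        w = 1.0 / lam
        ViX = self.Xr * w[:, None]
        C = self.Xr.T @ ViX
        Cinv = _solve_psd(C, np.eye(self.p))[0]
        kdiag = (self.d, np.ones(self.n))
        M = [self.Xr.T @ (self.Xr * (kd * w * w)[:, None]) for kd in kdiag]
        t = np.array(
            [(kd * w).sum() - np.sum(Cinv * m.T) for kd, m in zip(kdiag, M)]
        )
        G = np.empty((2, 2))
        for i in range(2):
            for j in range(i + 1):
                N = self.Xr.T @ (self.Xr * (kdiag[i] * kdiag[j] * w**3)[:, None])
                G[i, j] = G[j, i] = (
                    (kdiag[i] * kdiag[j] * w * w).sum()
                    - 2.0 * np.sum(Cinv * N.T)
                    + np.sum((Cinv @ M[i]) * (Cinv @ M[j]).T)
                )
        return t, G


# ---------------------------------------------------------------------------


class BlockedKernel(_KernelBase):
    """All components share one block-diagonal partition (families, pairs).

    Blocks are grouped by size and processed with batched dense linear
    algebra, making per-iteration cost linear in the number of blocks.
    """

    def __init__(self, K_list, X, y, max_block: int = 200):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.n, self.p = self.X.shape
        self.k = len(K_list)
        if np.linalg.matrix_rank(self.X) < self.p:
            raise DesignError("fixed-effect design is rank deficient")
        union = sp.eye(self.n, format="coo")
        mats = []
        for K in K_list:
            Ks = sp.coo_matrix(K) if not sp.issparse(K) else K.tocoo()
            mats.append(Ks)
            union = union + abs(Ks)
        _, labels = connected_components(union.tocsr(), directed=False)
        sizes_all = np.bincount(labels)
        if sizes_all.max() > max_block:
            raise NumericalError(
                f"largest block has {sizes_all.max()} members (> {max_block}); "
                "use the dense backend"
            )
        order = np.argsort(labels, kind="stable")
        starts = np.concatenate([[0], np.cumsum(sizes_all)])
        pos = np.empty(self.n, dtype=np.int64)
        pos[order] = np.arange(self.n) - starts[labels[order]]
        self._labels, self._pos = labels, pos
        # group blocks by size
        self.groups: list[dict] = []
        rowmap = np.full(len(sizes_all), -1, dtype=np.int64)
        for s in np.unique(sizes_all):
            bids = np.flatnonzero(sizes_all == s)
            rowmap[bids] = np.arange(len(bids))
            idx = np.stack([order[starts[b] : starts[b] + s] for b in bids])
            self.groups.append(
                {
                    "size": int(s),
                    "bids": bids,
                    "idx": idx,  # (nb, s)
                    "X": self.X[idx],  # (nb, s, p)
                    "y": self.y[idx],  # (nb, s)
                    "K": [np.zeros((len(bids), s, s)) for _ in range(self.k)],
                }
            )
        group_of = {int(s["size"]): gi for gi, s in enumerate(self.groups)}
        for ki, Ks in enumerate(mats):
            i, j, v = Ks.row, Ks.col, Ks.data
            bi = labels[i]
            if (bi != labels[j]).any():
                raise NumericalError("component entry crosses the block partition")
            bs = sizes_all[bi]
            for s in np.unique(bs):
                m = bs == s
                g = self.groups[group_of[int(s)]]
                g["K"][ki][rowmap[bi[m]], pos[i[m]], pos[j[m]]] = v[m]

    def var_y(self) -> float:
        resid = self.y - self.X @ np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        return float(resid @ resid / max(self.n - self.p, 1))

    def _decompose(self, theta):
        logdetV = 0.0
        per = []
        for g in self.groups:
            Vb = sum(t * Kb for t, Kb in zip(theta, g["K"]))
            sign, ld = np.linalg.slogdet(Vb)
            if (sign <= 0).any():
                return None
            logdetV += ld.sum()
            Vinv = np.linalg.inv(Vb)
            ViX = Vinv @ g["X"]
            Viy = np.einsum("bst,bt->bs", Vinv, g["y"])
            per.append({"Vinv": Vinv, "ViX": ViX, "Viy": Viy})
        C = np.zeros((self.p, self.p))
        XtViy = np.zeros(self.p)
        for g, d in zip(self.groups, per):
            C += np.einsum("bsp,bsq->pq", g["X"], d["ViX"])
            XtViy += np.einsum("bsp,bs->p", g["X"], d["Viy"])
        return logdetV, per, C, XtViy

    def quantities(self, theta, method="REML") -> KernelState:
        theta = np.asarray(theta, float)
        dec = self._decompose(theta)
        if dec is None:
            return KernelState(ok=False, theta=theta)
        logdetV, per, C, XtViy = dec
        beta, logdetC = _solve_psd(C, XtViy)
        Cinv = _solve_psd(C, np.eye(self.p))[0]
        ypy = 0.0
        for g, d in zip(self.groups, per):
            d["Py"] = d["Viy"] - d["ViX"] @ beta
            ypy += float(np.einsum("bs,bs->", g["y"], d["Py"]))
        quad = np.zeros(self.k)
        tr_vik = np.zeros(self.k)
        M = np.zeros((self.k, self.p, self.p))
        u = np.zeros((self.k, self.p))
        for g, d in zip(self.groups, per):
            d["W"] = [np.einsum("bst,bt->bs", Kb, d["Py"]) for Kb in g["K"]]
            for ki in range(self.k):
                quad[ki] += float(np.einsum("bs,bs->", d["Py"], d["W"][ki]))
                tr_vik[ki] += float(np.einsum("bst,bst->", d["Vinv"], g["K"][ki]))
                M[ki] += np.einsum("bsp,bst,btq->pq", d["ViX"], g["K"][ki], d["ViX"])
                u[ki] += np.einsum("bsp,bs->p", d["ViX"], d["W"][ki])
        if method == "REML":
            tr_pk = tr_vik - np.array([np.sum(Cinv * M[ki].T) for ki in range(self.k)])
            ll = -0.5 * (logdetV + logdetC + ypy)
        else:
            tr_pk = tr_vik
            ll = -0.5 * (logdetV + ypy)
        grad = -0.5 * (tr_pk - quad)
        ai = np.zeros((self.k, self.k))
        corr = u @ Cinv @ u.T if method == "REML" else 0.0
        for g, d in zip(self.groups, per):
            Wstack = np.stack(d["W"], axis=-1)  # (nb, s, k)
            VinvW = np.einsum("bst,btk->bsk", d["Vinv"], Wstack)
            ai += np.einsum("bsi,bsj->ij", Wstack, VinvW)
        ai = 0.5 * (ai - corr)
        ai = 0.5 * (ai + ai.T)
        return KernelState(True, theta, ll, grad, ai, beta, tr_pk, quad, ypy)

    def expected_info(self, theta):
        theta = np.asarray(theta, float)
        dec = self._decompose(theta)
        if dec is None:
            raise NumericalError("covariance matrix not positive definite")
        _, per, C, _ = dec
        Cinv = _solve_psd(C, np.eye(self.p))[0]
        t_raw = np.zeros(self.k)
        M = np.zeros((self.k, self.p, self.p))
        trvv = np.zeros((self.k, self.k))
        N = np.zeros((self.k, self.k, self.p, self.p))
        for g, d in zip(self.groups, per):
            ViK = [d["Vinv"] @ Kb for Kb in g["K"]]
            T = [np.einsum("bst,btp->bsp", Kb, d["ViX"]) for Kb in g["K"]]
            for i in range(self.k):
                t_raw[i] += float(np.einsum("bss->", ViK[i]))
                M[i] += np.einsum("bsp,bsq->pq", d["ViX"], T[i])
                for j in range(i + 1):
                    trvv[i, j] += float(np.einsum("bst,bts->", ViK[i], ViK[j]))
                    nij = np.einsum("bsp,bst,btq->pq", T[i], d["Vinv"], T[j])
                    N[i, j] += nij
                    if i != j:
                        N[j, i] += nij.T
        trvv = trvv + np.tril(trvv, -1).T
        t = t_raw - np.array([np.sum(Cinv * M[i].T) for i in range(self.k)])
        G = np.empty((self.k, self.k))
        for i in range(self.k):
            for j in range(self.k):
                G[i, j] = (
                    trvv[i, j]
                    - 2.0 * np.sum(Cinv * N[i, j].T)
                    + np.sum((Cinv @ M[i]) * (Cinv @ M[j]).T)
                )
        G = 0.5 * (G + G.T)
        return t, G


# ---------------------------------------------------------------------------
# AI-REML driver


@dataclass
class AIREMLResult:
    theta: np.ndarray
    beta: np.ndarray
    loglik: float
    info: np.ndarray  # AI matrix at the optimum
    grad: np.ndarray
    se: np.ndarray
    n_iter: int
    converged: bool
    boundary: np.ndarray
    trace: list = field(default_factory=list)
    method: str = "REML"


def _safe_se(info: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(info)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(info.shape[0], np.nan)


def ai_reml(
    kern: _KernelBase,
    theta0=None,
    method: str = "REML",
    nonneg=None,
    max_iter: int = 200,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
    floor_frac: float = 1e-6,
) -> AIREMLResult:
    """Maximize the (restricted) likelihood by average-information updates.

    One EM-style first step, then AI (quasi-Newton) steps with step-halving
    whenever a proposal decreases the likelihood or leaves the positive
    definite region.  Components marked non-negative are projected onto a
    small positive floor; a parameter resting on the floor at convergence is
    flagged as a boundary estimate.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"unknown method {method!r}")
    k = kern.k
    nonneg = np.ones(k, dtype=bool) if nonneg is None else np.asarray(nonneg, bool)
    vary = kern.var_y()
    floor = floor_frac * vary
    if theta0 is None:
        theta0 = np.full(k, vary / k)
    theta = np.asarray(theta0, float).copy()
    st = kern.quantities(theta, method)
    if not st.ok:
        raise NumericalError("starting covariance matrix is not positive definite")
    trace = [{"iter": 0, "ll": st.ll, "theta": theta.copy(), "grad_norm": float(np.abs(st.grad).max())}]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if it == 1:
            delta = theta**2 * (st.quad - st.tr_pk) / kern.n
        else:
            ai = st.ai + 1e-10 * np.eye(k) * max(1.0, np.abs(st.ai).max())
            try:
                delta = np.linalg.solve(ai, st.grad)
            except np.linalg.LinAlgError:
                delta = st.grad / np.maximum(np.abs(np.diag(st.ai)), 1e-8)
        accepted = None
        lam = 1.0
        for _ in range(60):
            prop = theta + lam * delta
            prop[nonneg] = np.maximum(prop[nonneg], floor)
            st_new = kern.quantities(prop, method)
            if st_new.ok and np.isfinite(st_new.ll) and st_new.ll >= st.ll - 1e-12:
                accepted = (prop, st_new)
                break
            lam *= 0.5
        if accepted is None:
            break  # no uphill step found: treat as converged at current theta
        prop, st_new = accepted
        d_ll = st_new.ll - st.ll
        d_par = np.max(np.abs(prop - theta) / (np.abs(theta) + 1.0))
        theta, st = prop, st_new
        trace.append(
            {"iter": it, "ll": st.ll, "theta": theta.copy(), "grad_norm": float(np.abs(st.grad).max())}
        )
        if abs(d_ll) < tol_ll and d_par < tol_par:
            converged = True
            break
    if not np.isfinite(st.ll):
        raise NumericalError("non-finite likelihood during fitting", trace=trace)
    boundary = nonneg & (theta <= floor * 1.01 + 1e-300)
    return AIREMLResult(
        theta=theta,
        beta=st.beta,
        loglik=st.ll,
        info=st.ai,
        grad=st.grad,
        se=_safe_se(st.ai),
        n_iter=it,
        converged=converged or bool(np.abs(st.grad).max() < 1e-4 * max(1.0, abs(st.ll))),
        boundary=boundary,
        trace=trace,
        method=method,
    )
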