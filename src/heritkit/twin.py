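"""MZ/DZ twin model for the common-environment lower bound.

Twin pairs share a within-pair phenotypic correlation r_MZ (monozygotic) or
r_DZ (dizygotic), so the phenotypic covariance is ``sigma_Y^2 * V`` with
``V = I + r_MZ A + r_DZ B`` where A and B indicate MZ and DZ co-twin pairs.
Under an additive model with a shared-environment variance sigma_c^2 and
dominance variance sigma_d^2,

    rho_c = 2 r_DZ - r_MZ = (sigma_c^2 - 0.5 sigma_d^2) / sigma_Y^2,

which equals the common-environment share sigma_c^2 / sigma_Y^2 when
sigma_d^2 = 0 and is a lower bound for it otherwise (epistasis ignored).
The parameters are estimated by average-information REML on transformed
coordinates (log sigma_Y^2, atanh r) so the correlations stay inside
(-1, 1); the Fisher information Psi over (sigma_Y^2, r_MZ, r_DZ) is
evaluated on the natural scale and gives the delta-method variance of
rho_c as (0, -1, 2) Psi^-1 (0, -1, 2)^t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._core import BlockedKernel, DenseKernel
from .errors import DataError, NumericalError, PedigreeError
from .pedigree import Pedigree
from .reml import TraitModel

_R_CAP = np.arctanh(1.0 - 1e-6)


@dataclass
class TwinDesign:
    """MZ/DZ co-membership indicators over one sample order."""

    sample_ids: np.ndarray
    A: sp.csr_matrix  # MZ co-twin indicator, zero diagonal
    B: sp.csr_matrix  # DZ analogue
    n_mz_pairs: int
    n_dz_pairs: int
    n_singletons: int

    def __post_init__(self):
        n = len(self.sample_ids)
        for name, mat in (("A", self.A), ("B", self.B)):
            if mat.shape != (n, n):
                raise DataError(f"{name} must be {n}x{n}")
            if abs(mat - mat.T).nnz:
                raise DataError(f"{name} must be symmetric")
            if mat.diagonal().any():
                raise DataError(f"{name} must have a zero diagonal")
        if self.A.multiply(self.B).nnz:
            raise DataError("a pair cannot be both MZ and DZ")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class TwinFit:
    sigma_Y2: float
    r_mz: float
    r_dz: float
    psi: np.ndarray  # Fisher information over (sigma_Y2, r_mz, r_dz)
    rho_c: float
    rho_c_var: float
    rho_c_se: float
    rho_c_ci: tuple
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    counts: dict
    boundary: bool
    dropped: list = field(default_factory=list)  # parameters absent from the design
    trace: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma_Y2": self.sigma_Y2,
                "r_mz": self.r_mz,
                "r_dz": self.r_dz,
                "rho_c": self.rho_c,
                "rho_c_se": self.rho_c_se,
                "rho_c_ci": list(self.rho_c_ci),
                "psi": [[float(x) for x in row] for row in self.psi],
                "fixed_effects": [float(b) for b in self.beta],
                "loglik": self.loglik,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "counts": self.counts,
                "boundary": self.boundary,
                "dropped": self.dropped,
            },
            indent=2,
        )


def build_twin_design(ped: Pedigree, X: np.ndarray | None = None) -> TwinDesign:
    """Indicator matrices from zygosity-tagged pairs in a pedigree.

    Each (family, zygosity-tag) group must have exactly two members; tagged
    singletons and untagged individuals contribute only to the identity
    part of the covariance.
    """
    ids = ped.ids
    pos = {s: i for i, s in enumerate(ids)}
    rows_a, cols_a, rows_b, cols_b = [], [], [], []
    n_mz = n_dz = n_single = 0
    for (fid, tag), members in ped.twin_groups().items():
        if len(members) > 2:
            raise PedigreeError(
                f"zygosity group ({fid!r}, {tag!r}) has {len(members)} members; "
                "twin groups must be pairs"
            )
        if len(members) == 1:
            n_single += 1
            continue
        i, j = (pos[m] for m in members)
        up = tag.upper()
        if up.startswith("MZ"):
            rows_a += [i, j]
            cols_a += [j, i]
            n_mz += 1
        elif up.startswith("DZ"):
            rows_b += [i, j]
            cols_b += [j, i]
            n_dz += 1
        else:
            raise PedigreeError(f"unrecognized zygosity tag {tag!r}")
    n = len(ids)
    tagged = {m for g in ped.twin_groups().values() for m in g}
    n_single += sum(1 for s in ids if s not in tagged)
    A = sp.coo_matrix((np.ones(len(rows_a)), (rows_a, cols_a)), shape=(n, n)).tocsr()
    B = sp.coo_matrix((np.ones(len(rows_b)), (rows_b, cols_b)), shape=(n, n)).tocsr()
    return TwinDesign(ids, A, B, n_mz, n_dz, n_single)


def _twin_kernel(model: TraitModel, design: TwinDesign, use_dense=False):
    mats = [sp.eye(design.n, format="csr"), design.A, design.B]
    cls = DenseKernel if use_dense else BlockedKernel
    return cls(mats, model.X, model.y)


def _start_values(model: TraitModel, design: TwinDesign):
    resid = model.y - model.X @ np.linalg.lstsq(model.X, model.y, rcond=None)[0]
    s2 = float(resid @ resid / max(model.n - model.X.shape[1], 1))

    def pair_corr(mat):
        co = sp.triu(mat, k=1).tocoo()
        if co.nnz < 2:
            return 0.0
        a, b = resid[co.row], resid[co.col]
        both = np.concatenate([a, b]), np.concatenate([b, a])
        c = np.corrcoef(both[0], both[1])[0, 1]
        return float(np.clip(np.nan_to_num(c), -0.9, 0.9))

    return s2, pair_corr(design.A), pair_corr(design.B)


def fit_twin_reml(
    model: TraitModel,
    design: TwinDesign,
    max_iter: int = 100,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
) -> TwinFit:
    """REML fit of (sigma_Y^2, r_MZ, r_DZ) by average-information updates.

    Optimization runs on (log sigma_Y^2, atanh r_MZ, atanh r_DZ) with
    step-halving whenever a proposal fails to increase the restricted
    likelihood; a correlation whose pair type is absent from the design is
    dropped from the parameter vector and reported in ``dropped``.
    """
    if len(model.sample_ids) != design.n or (model.sample_ids != design.sample_ids).any():
        raise DataError("trait model and twin design sample orders differ")
    kern = _twin_kernel(model, design)
    n, p = model.n, model.X.shape[1]
    have = [True, design.n_mz_pairs > 0, design.n_dz_pairs > 0]
    dropped = [name for name, h in zip(["sigma_Y2", "r_mz", "r_dz"], have) if not h]
    act = np.flatnonzero(have)  # indices into (sigma, r_mz, r_dz)
    s2_0, rmz_0, rdz_0 = _start_values(model, design)
    eta = np.array([np.log(s2_0), np.arctanh(rmz_0), np.arctanh(rdz_0)])

    def natural(e):
        return np.array([np.exp(e[0]), np.tanh(e[1]), np.tanh(e[2])])

    def theta_lin(pi):
        return np.array([pi[0], pi[0] * pi[1], pi[0] * pi[2]])

    def state(e):
        pi = natural(e)
        st = kern.quantities(theta_lin(pi), method="REML")
        return pi, st

    pi, st = state(eta)
    if not st.ok:
        raise NumericalError("starting twin covariance is not positive definite")
    trace = [{"iter": 0, "ll": st.ll, "eta": eta.copy()}]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # chain rule: linear coefficients -> natural params -> transformed
        J_theta = np.array(
            [[1.0, 0.0, 0.0], [pi[1], pi[0], 0.0], [pi[2], 0.0, pi[0]]]
        )
        g_pi = J_theta.T @ st.grad
        ai_pi = J_theta.T @ st.ai @ J_theta
        J_eta = np.diag([pi[0], 1.0 - pi[1] ** 2, 1.0 - pi[2] ** 2])
        g = (J_eta @ g_pi)[act]
        ai = (J_eta @ ai_pi @ J_eta)[np.ix_(act, act)]
        ai = ai + 1e-10 * max(1.0, np.abs(ai).max()) * np.eye(len(act))
        try:
            delta_act = np.linalg.solve(ai, g)
        except np.linalg.LinAlgError:
            delta_act = g / np.maximum(np.abs(np.diag(ai)), 1e-8)
        delta = np.zeros(3)
        delta[act] = delta_act
        accepted = None
        lam = 1.0
        for _ in range(60):
            prop = eta + lam * delta
            prop[1:] = np.clip(prop[1:], -_R_CAP, _R_CAP)
            prop[0] = np.clip(prop[0], -50.0, 50.0)
            pi_new, st_new = state(prop)
            if st_new.ok and np.isfinite(st_new.ll) and st_new.ll >= st.ll - 1e-12:
                accepted = (prop, pi_new, st_new)
                break
            lam *= 0.5
        if accepted is None:
            break
        prop, pi_new, st_new = accepted
        d_ll = st_new.ll - st.ll
        d_par = np.max(np.abs(prop - eta) / (np.abs(eta) + 1.0))
        eta, pi, st = prop, pi_new, st_new
        trace.append({"iter": it, "ll": st.ll, "eta": eta.copy()})
        if abs(d_ll) < tol_ll and d_par < tol_par:
            converged = True
            break
    boundary = bool((np.abs(eta[1:]) >= _R_CAP - 1e-9).any())
    sigma_Y2, r_mz, r_dz = pi
    psi = twin_fisher_information(model.X, sigma_Y2, r_mz, r_dz, design.A, design.B)
    if len(dropped) == 0:
        rho_c, var, ci = _rho_c_from(psi, r_mz, r_dz)
    else:
        rho_c = var = np.nan
        ci = (np.nan, np.nan)
    return TwinFit(
        sigma_Y2=float(sigma_Y2),
        r_mz=float(r_mz) if have[1] else np.nan,
        r_dz=float(r_dz) if have[2] else np.nan,
        psi=psi,
        rho_c=rho_c,
        rho_c_var=var,
        rho_c_se=np.sqrt(var) if np.isfinite(var) else np.nan,
        rho_c_ci=ci,
        beta=st.beta,
        loglik=st.ll,
        converged=converged or boundary,
        n_iter=it,
        counts={
            "n": n,
            "p": p,
            "mz_pairs": design.n_mz_pairs,
            "dz_pairs": design.n_dz_pairs,
            "singletons": design.n_singletons,
        },
        boundary=boundary,
        dropped=dropped,
        trace=trace,
    )


def twin_fisher_information(X, sigma2, r_mz, r_dz, A, B) -> np.ndarray:
    """Expected (Fisher) information over (sigma_Y^2, r_MZ, r_DZ).

    With V = I + r_MZ A + r_DZ B and P the REML projection built from V,
    the entries are [(n-p)/(2 sigma^4), tr(PA)/(2 sigma^2),
    tr(PB)/(2 sigma^2); ., tr(PAPA)/2, tr(PAPB)/2; ., ., tr(PBPB)/2].
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    mats = [sp.eye(n, format="csr"), sp.csr_matrix(A), sp.csr_matrix(B)]
    y_dummy = np.zeros(n)
    try:
        kern = BlockedKernel(mats, X, y_dummy)
    except NumericalError:
        kern = DenseKernel(mats, X, y_dummy)
    theta_v = np.array([1.0, r_mz, r_dz])
    t, G = kern.expected_info(theta_v)
    tr_pa, tr_pb = t[1], t[2]
    psi = np.array(
        [
            [(n - p) / (2.0 * sigma2**2), tr_pa / (2.0 * sigma2), tr_pb / (2.0 * sigma2)],
            [tr_pa / (2.0 * sigma2), G[1, 1] / 2.0, G[1, 2] / 2.0],
            [tr_pb / (2.0 * sigma2), G[1, 2] / 2.0, G[2, 2] / 2.0],
        ]
    )
    return psi


def restricted_loglik(model: TraitModel, design: TwinDesign, sigma2, r_mz, r_dz) -> float:
    """Restricted log-likelihood at the given parameter values (constants dropped)."""
    kern = _twin_kernel(model, design)
    st = kern.quantities(np.array([sigma2, sigma2 * r_mz, sigma2 * r_dz]), method="REML")
    if not st.ok:
        raise NumericalError("covariance not positive definite at the requested point")
    return float(st.ll)


def rho_c_lower_bound(r_mz: float, r_dz: float) -> float:
    """Common-environment share lower bound 2 r_DZ - r_MZ."""
    return 2.0 * r_dz - r_mz


def _rho_c_from(psi, r_mz, r_dz):
    rho = rho_c_lower_bound(r_mz, r_dz)
    v = np.array([0.0, -1.0, 2.0])
    try:
        var = float(v @ np.linalg.solve(psi, v))
    except np.linalg.LinAlgError:
        raise NumericalError("singular Fisher information matrix") from None
    se = np.sqrt(max(var, 0.0))
    return float(rho), var, (float(rho - 1.96 * se), float(rho + 1.96 * se))


@dataclass
class CommonEnvEstimate:
    rho_c: float
    variance: float
    ci: tuple


def common_env_proportion(fit: TwinFit) -> CommonEnvEstimate:
    """rho_c = 2 r_DZ - r_MZ with delta-method variance (0,-1,2) Psi^-1 (0,-1,2)^t.

    Equals the common-environment share of variance when dominance variance
    is zero; otherwise (sigma_c^2 - 0.5 sigma_d^2)/sigma_Y^2, a lower bound.
    """
    if fit.dropped:
        raise DataError(
            f"rho_c requires both twin correlations; missing: {fit.dropped}"
        )
    rho, var, ci = _rho_c_from(fit.psi, fit.r_mz, fit.r_dz)
    return CommonEnvEstimate(rho_c=rho, variance=var, ci=ci)
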