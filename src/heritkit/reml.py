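"""Variance-component model fitting and heritability.

The model is ``y = X beta + e`` with ``e ~ MVN(0, sum_k sigma_k^2 K_k +
sigma^2 I)`` over named relationship components (GRM, FRM, sibship, marital,
...).  Parameters are estimated by average-information REML (ML optional);
narrow-sense heritability is the additive genetic share of the total
variance, with a delta-method standard error from the inverse information
matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._core import BlockedKernel, DenseKernel, EigenKernel, ai_reml
from .errors import ConfigError, DataError, DesignError, NumericalError
from .pedigree import Pedigree
from .relatedness import CovarianceComponent

GENETIC_NAMES = ("grm", "frm", "additive", "polygenic", "genetic")
RESIDUAL_NAMES = ("residual", "identity", "error")


@dataclass
class TraitModel:
    """Aligned trait vector and fixed-effect design.

    ``X`` must include the intercept; rows of ``y``, ``X`` and every
    component matrix share the order of ``sample_ids``.
    """

    y: np.ndarray
    X: np.ndarray
    sample_ids: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, float)
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.sample_ids) != n:
            raise DesignError("y, X, and sample_ids must have matching lengths")
        if not (np.isfinite(self.y).all() and np.isfinite(self.X).all()):
            raise DataError("y/X contain missing values; apply complete-case filtering first")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("fixed-effect design is rank deficient")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class VarianceFit:
    component_names: list[str]
    variances: np.ndarray
    beta: np.ndarray
    loglik: float
    info: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    boundary: np.ndarray
    method: str
    trace: list = field(default_factory=list)

    @property
    def total_variance(self) -> float:
        return float(self.variances.sum())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
            "components": {
                name: {"variance": float(v), "se": float(s), "boundary": bool(b)}
                for name, v, s, b in zip(
                    self.component_names, self.variances, self.se, self.boundary
                )
            },
            "fixed_effects": [float(b) for b in self.beta],
            "information": [[float(x) for x in row] for row in self.info],
            "trace": [
                {"iter": t["iter"], "loglik": t["ll"], "grad_norm": t["grad_norm"]}
                for t in self.trace
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [f"method\t{self.method}", f"converged\t{self.converged}", f"loglik\t{self.loglik:.6f}"]
        for name, v, s in zip(self.component_names, self.variances, self.se):
            lines.append(f"var({name})\t{v:.6g}\t(se {s:.3g})")
        return "\n".join(lines)


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    shares: dict  # component name -> share of total variance

    def to_dict(self) -> dict:
        return {"h2": self.h2, "se": self.se, "shares": self.shares}


def _pick_backend(components, n):
    non_id = [c for c in components if not c.is_identity()]
    if len(non_id) == 1 and n > 150:
        return "eigen"
    try_blocked = all(sp.issparse(c.matrix) or c.n <= 2000 for c in components)
    if try_blocked and n > 500:
        return "blocked"
    return "dense"


def fit_variance_components(
    model: TraitModel,
    components: list[CovarianceComponent],
    method: str = "REML",
    backend: str = "auto",
    max_iter: int = 200,
    theta0=None,
) -> VarianceFit:
    """Fit the mixed model by AI-REML (or ML) over the listed components.

    The component list must include the identity (residual) component.
    Components are re-aligned to the trait's sample order before fitting, so
    the result is invariant to the order individuals are stored in.
    """
    comps = [c.reorder(model.sample_ids) for c in components]
    if not any(c.is_identity() for c in comps):
        raise ConfigError("the identity (residual) component must be included")
    if backend == "auto":
        backend = _pick_backend(comps, model.n)
    mats = [c.matrix for c in comps]
    if backend == "eigen":
        id_pos = next(i for i, c in enumerate(comps) if c.is_identity())
        other = [i for i in range(len(comps)) if i != id_pos]
        if len(other) != 1:
            raise ConfigError("eigen backend requires exactly one non-identity component")
        kern = EigenKernel(mats[other[0]], model.X, model.y)
        perm = [other[0], id_pos]
    elif backend == "blocked":
        kern = BlockedKernel(mats, model.X, model.y)
        perm = list(range(len(comps)))
    elif backend == "dense":
        kern = DenseKernel(mats, model.X, model.y)
        perm = list(range(len(comps)))
    else:
        raise ConfigError(f"unknown backend {backend!r}")
    theta0p = None if theta0 is None else np.asarray(theta0, float)[perm]
    res = ai_reml(kern, theta0=theta0p, method=method, max_iter=max_iter)
    inv = np.argsort(perm)
    return VarianceFit(
        component_names=[c.name for c in comps],
        variances=res.theta[inv],
        beta=res.beta,
        loglik=res.loglik,
        info=res.info[np.ix_(inv, inv)],
        se=res.se[inv],
        converged=res.converged,
        n_iter=res.n_iter,
        boundary=res.boundary[inv],
        method=method,
        trace=res.trace,
    )


def heritability_from_fit(
    fit: VarianceFit, genetic: str | None = None
) -> HeritabilityEstimate:
    """Narrow-sense heritability: genetic variance / total variance.

    The genetic component is located by name (``genetic=`` overrides the
    default search over GRM/FRM-style names).  The standard error follows
    from the delta method applied to the inverse information matrix.
    """
    if not fit.converged:
        raise NumericalError("cannot derive heritability from a non-converged fit")
    names = [n.lower() for n in fit.component_names]
    if genetic is None:
        hits = [i for i, n in enumerate(names) if n in GENETIC_NAMES]
        if not hits:
            non_res = [i for i, n in enumerate(names) if n not in RESIDUAL_NAMES]
            if len(non_res) != 1:
                raise ConfigError(
                    "could not identify the genetic component; pass genetic=<name>"
                )
            hits = non_res
        gi = hits[0]
    else:
        try:
            gi = names.index(genetic.lower())
        except ValueError:
            raise ConfigError(f"no component named {genetic!r} in fit") from None
    total = fit.total_variance
    if total <= 0:
        raise NumericalError("total variance is not positive")
    k = len(names)
    h2 = float(fit.variances[gi] / total)
    grad = np.full(k, -fit.variances[gi] / total**2)
    grad[gi] += 1.0 / total
    try:
        cov = np.linalg.inv(fit.info)
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
    shares = {n: float(v / total) for n, v in zip(fit.component_names, fit.variances)}
    return HeritabilityEstimate(h2=h2, se=se, shares=shares)


def design_matrix(table, covariates) -> tuple[np.ndarray, list[str]]:
    """Intercept + named covariate columns from a phenotype table.

    'age2' is derived as age squared when requested by name but absent from
    the table, so inputs only need the raw age column.
    """
    import pandas as pd

    table = pd.DataFrame(table)
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for cov in covariates:
        if cov in table.columns:
            col = pd.to_numeric(table[cov], errors="coerce").to_numpy(float)
        elif cov == "age2" and "age" in table.columns:
            col = pd.to_numeric(table["age"], errors="coerce").to_numpy(float) ** 2
        else:
            raise DataError(f"covariate {cov!r} not found in phenotype table")
        cols.append(col)
        names.append(cov)
    return np.column_stack(cols), names


def household_components(
    ped: Pedigree,
) -> tuple[CovarianceComponent, CovarianceComponent]:
    """Common-sibship and marital grouping components.

    Both are outer products of group-membership indicators (hence positive
    semidefinite): the sibship matrix is 1 for pairs — and on the diagonal —
    of individuals sharing both parents, and the marital matrix is 1 on
    spouse pairs and on the diagonal of married individuals.
    """
    ids = ped.ids
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)

    def grouping(groups):
        rows, cols = [], []
        for g in groups:
            gi = [pos[m] for m in g]
            for a in gi:
                for b in gi:
                    rows.append(a)
                    cols.append(b)
        mat = sp.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        ).tocsr()
        mat.data = np.minimum(mat.data, 1.0)
        return mat

    sib = grouping(ped.sibships())
    mar = grouping([list(pair) for pair in ped.spouse_pairs()])
    return (
        CovarianceComponent("sibship", ids, sib),
        CovarianceComponent("marital", ids, mar),
    )
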