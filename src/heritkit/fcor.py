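"""Familial pair-type correlations of covariate-adjusted residuals.

Traits are first residualized on the fixed covariates (age, age squared,
sex) by ordinary least squares; correlations are then estimated per pair
type: mother-father and parent-offspring as interclass Pearson correlations
over ordered pairs, and sibling as the intraclass convention that includes
both orderings of every pair.  Confidence intervals use the Fisher
z-transform with the number of distinct pairs as the effective sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .pedigree import Pedigree
from .reml import TraitModel

PAIR_TYPES = ("mother-father", "parent-offspring", "sibling")


def residualize(model: TraitModel) -> np.ndarray:
    """OLS residuals of the trait on the fixed-effect design."""
    beta, _, rank, _ = np.linalg.lstsq(model.X, model.y, rcond=None)
    if rank < model.X.shape[1]:
        raise ConfigError("fixed-effect design is rank deficient")
    return model.y - model.X @ beta


def _weighted_pearson(x, y, w):
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx, vy = w @ (x - mx) ** 2, w @ (y - my) ** 2
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def _enumerate_pairs(ped: Pedigree, pair_type: str):
    """(id_a, id_b, family) triples; sibling pairs are unordered distinct pairs."""
    fam_of = dict(zip(ped.table["iid"], ped.table["fid"]))
    if pair_type == "mother-father":
        sex_pairs = [(m, f) for f, m in ped.spouse_pairs()]
        return [(a, b, fam_of[a]) for a, b in sex_pairs]
    if pair_type == "parent-offspring":
        return [(a, b, fam_of[b]) for a, b in ped.parent_offspring_pairs()]
    if pair_type == "sibling":
        out = []
        for sibs in ped.sibships():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    out.append((sibs[i], sibs[j], fam_of[sibs[i]]))
        return out
    raise ConfigError(f"unknown pair type {pair_type!r}")


def pair_correlations(
    residuals: np.ndarray,
    ped: Pedigree,
    types=PAIR_TYPES,
    weighting: str = "pair",
) -> pd.DataFrame:
    """Familial correlations per pair type with Fisher-z 95% intervals.

    ``weighting='pair'`` gives every pair equal weight; ``'family'`` divides
    each pair's weight by the number of pairs its family contributes.  A
    pair type with fewer than 3 pairs is reported with NaN estimates rather
    than raising.
    """
    residuals = np.asarray(residuals, float)
    if len(residuals) != len(ped.table):
        raise DataError("residuals are not aligned to the pedigree individuals")
    if weighting not in ("pair", "family"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    pos = {s: i for i, s in enumerate(ped.ids)}
    rows = []
    for pt in types:
        pairs = _enumerate_pairs(ped, pt)
        n_pairs = len(pairs)
        if n_pairs < 3:
            rows.append((pt, n_pairs, np.nan, np.nan, np.nan))
            continue
        a = np.array([pos[x] for x, _, _ in pairs])
        b = np.array([pos[y] for _, y, _ in pairs])
        fams = pd.Series([f for _, _, f in pairs])
        w = np.ones(n_pairs) if weighting == "pair" else (1.0 / fams.map(fams.value_counts())).to_numpy()
        xa, xb = residuals[a], residuals[b]
        if pt == "sibling":  # intraclass: both orderings
            xa, xb = np.concatenate([xa, xb]), np.concatenate([xb, xa])
            w = np.concatenate([w, w])
        corr = _weighted_pearson(xa, xb, w)
        if np.isnan(corr) or abs(corr) >= 1.0 or n_pairs <= 3:
            lo = hi = np.nan
        else:
            z = np.arctanh(corr)
            half = 1.96 / np.sqrt(n_pairs - 3)
            lo, hi = np.tanh(z - half), np.tanh(z + half)
        rows.append((pt, n_pairs, corr, lo, hi))
    return pd.DataFrame(
        rows, columns=["pair_type", "n_pairs", "correlation", "ci_low", "ci_high"]
    )
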