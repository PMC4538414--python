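"""Synthetic cohorts: related genotype pairs, twin pairs, nuclear families.

The genotype-pair generator draws biallelic SNPs in Hardy-Weinberg
equilibrium and linkage equilibrium.  Within a pair, each of the second
member's two allele slots is an identical-by-descent copy of the first
member's matching slot with probability r, independently per slot and SNP.
This yields an expected genotype correlation of r and a kinship coefficient
of r/2 between pair members, so r = 1/2 emulates full sibs or
parent-offspring pairs and r = 0 unrelated individuals.

Causal architectures assign each of n_causal causal SNPs an equal share of
the genetic variance: with allele frequency p_l the per-allele effect is

    beta_l = sqrt( h2 * sigma2 / (2 * n_causal * p_l (1 - p_l) * (1 - h2)) )

so that sum_l 2 beta_l^2 p_l (1 - p_l) = h2 * sigma2 / (1 - h2), i.e. the
polygenic variance is the fraction h2 of the total phenotypic variance when
the residual variance is sigma2.

Twin cohorts are drawn phenotype-only from the bivariate normal implied by
the additive/common-environment/dominance decomposition; nuclear-family
cohorts add common-sibship and marital variance components on top of the
polygenic covariance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genio import GenotypeMatrix
from .pedigree import NO_ZYGOSITY, Pedigree

_LAW_RE = re.compile(r"^U\(\s*([0-9.]+)\s*,\s*([0-9.]+)\s*\)$")


def _parse_law(law: str) -> tuple[float, float]:
    m = _LAW_RE.match(law.strip())
    if not m:
        raise ConfigError(f"unknown MAF law tag {law!r}; expected 'U(a,b)'")
    a, b = float(m.group(1)), float(m.group(2))
    if not (0.0 <= a < b <= 0.5):
        raise ConfigError(f"MAF law {law!r} must satisfy 0 <= a < b <= 0.5")
    return a, b


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_mafs(n: int, law: str = "U(0,0.4)", seed=None) -> np.ndarray:
    """Draw n minor allele frequencies strictly inside the uniform law's support."""
    if n < 1:
        raise ConfigError(f"cannot draw {n} allele frequencies")
    a, b = _parse_law(law)
    rng = _as_rng(seed)
    p = rng.uniform(a, b, size=n)
    # uniform() includes the lower endpoint; redraw the measure-zero hits
    bad = (p <= a) | (p >= b)
    while bad.any():
        p[bad] = rng.uniform(a, b, size=int(bad.sum()))
        bad = (p <= a) | (p >= b)
    return p


@dataclass
class SimConfig:
    """Generation settings for one related-pairs cohort."""

    n_pairs: int = 500
    n_snps: int = 5000
    r: float = 0.5
    maf_law: str = "U(0,0.4)"
    causal_maf_law: str = "U(0,0.1)"
    n_causal: int = 100
    causal_genotyped_fraction: float = 1.0
    h2: float = 0.5
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1 or self.n_snps < 1:
            raise ConfigError("n_pairs and n_snps must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ConfigError(f"r={self.r} must lie in [0, 1]")
        if not 0.0 <= self.h2 < 1.0:
            raise ConfigError(f"h2={self.h2} must lie in [0, 1)")
        if self.sigma2 <= 0:
            raise ConfigError(f"sigma2={self.sigma2} must be positive")
        if not 0.0 < self.causal_genotyped_fraction <= 1.0:
            raise ConfigError("causal_genotyped_fraction must lie in (0, 1]")
        if self.causal_genotyped_fraction == 1.0 and self.n_causal > self.n_snps:
            raise ConfigError("n_causal exceeds n_snps with full causal coverage")
        _parse_law(self.maf_law)
        _parse_law(self.causal_maf_law)


@dataclass
class CausalModel:
    """Equal-variance additive architecture over causal SNPs."""

    causal_indices: np.ndarray
    p_l: np.ndarray
    beta_l: np.ndarray
    h2: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self):
        self.causal_indices = np.asarray(self.causal_indices, dtype=np.int64)
        self.p_l = np.asarray(self.p_l, float)
        self.beta_l = np.asarray(self.beta_l, float)
        var_l = 2.0 * self.beta_l**2 * self.p_l * (1.0 - self.p_l)
        total = var_l.sum()
        expected = self.h2 * self.sigma2 / (1.0 - self.h2)
        if total > 0 and (var_l.max() - var_l.min()) > 1e-10 * var_l.max():
            raise ConfigError("per-SNP genetic variances are not equal")
        if abs(total - expected) > 1e-10 * max(expected, 1.0):
            raise ConfigError(
                f"genetic variance {total} does not match h2*sigma2/(1-h2) = {expected}"
            )


def causal_effects(
    p_l: np.ndarray,
    h2: float,
    sigma2: float,
    indices: np.ndarray | None = None,
    random_signs: bool = False,
    seed=None,
) -> CausalModel:
    """Per-allele effects giving each causal SNP an equal variance share.

    All effects are positive by default (the sign is irrelevant for
    independent Hardy-Weinberg genotypes); ``random_signs`` flips each with
    probability 1/2.
    """
    p_l = np.asarray(p_l, float)
    if ((p_l <= 0) | (p_l >= 1)).any():
        raise DataError("causal allele frequencies must lie strictly in (0, 1)")
    if not 0.0 <= h2 <= 1.0:
        raise ConfigError(f"h2={h2} must lie in [0, 1)")
    if h2 == 1.0:
        raise ConfigError(
            "h2 = 1 makes the effect-size denominator 2*n_causal*p(1-p)*(1-h2) zero"
        )
    if sigma2 <= 0:
        raise ConfigError(f"sigma2={sigma2} must be positive")
    n_causal = len(p_l)
    beta = np.sqrt(h2 * sigma2 / (2.0 * n_causal * p_l * (1.0 - p_l) * (1.0 - h2)))
    if random_signs:
        beta = beta * _as_rng(seed).choice([-1.0, 1.0], size=n_causal)
    if indices is None:
        indices = np.arange(n_causal)
    return CausalModel(indices, p_l, beta, h2=h2, sigma2=sigma2)


def simulate_related_pairs(
    cfg: SimConfig,
    mafs: np.ndarray | None = None,
    seed=None,
    drop_monomorphic: bool = True,
) -> GenotypeMatrix:
    """Genotypes for n_pairs pairs with within-pair genotype correlation r.

    SNPs that come out monomorphic in the realized sample are removed (they
    carry no information for a relationship matrix); the dropped count and
    ids are recorded in ``meta``.
    """
    rng = _as_rng(cfg.seed if seed is None else seed)
    p = draw_mafs(cfg.n_snps, cfg.maf_law, rng) if mafs is None else np.asarray(mafs, float)
    if p.shape != (cfg.n_snps,):
        raise ConfigError("mafs length must equal n_snps")
    shape = (cfg.n_pairs, cfg.n_snps)
    a1 = rng.random(shape) < p
    a2 = rng.random(shape) < p
    fresh1 = rng.random(shape) < p
    fresh2 = rng.random(shape) < p
    copy1 = rng.random(shape) < cfg.r
    copy2 = rng.random(shape) < cfg.r
    b1 = np.where(copy1, a1, fresh1)
    b2 = np.where(copy2, a2, fresh2)
    codes = np.empty((2 * cfg.n_pairs, cfg.n_snps), dtype=np.int8)
    codes[0::2] = (a1.astype(np.int8) + a2.astype(np.int8))
    codes[1::2] = (b1.astype(np.int8) + b2.astype(np.int8))
    sample_ids = np.array(
        [f"p{i}_{m}" for i in range(cfg.n_pairs) for m in (1, 2)], dtype=object
    )
    snp_ids = np.array([f"snp{j}" for j in range(cfg.n_snps)], dtype=object)
    meta = {"r": cfg.r, "monomorphic_dropped": 0, "dropped_snp_ids": []}
    if drop_monomorphic:
        poly = ~(codes == codes[0]).all(axis=0)
        meta["monomorphic_dropped"] = int((~poly).sum())
        meta["dropped_snp_ids"] = snp_ids[~poly].tolist()
        codes = codes[:, poly]
        snp_ids = snp_ids[poly]
        p = p[poly]
    return GenotypeMatrix(sample_ids, snp_ids, codes, freqs=None, meta=meta)


def simulate_traits(
    G: GenotypeMatrix,
    model: CausalModel,
    sigma2: float,
    seed=None,
    causal_codes: np.ndarray | None = None,
) -> np.ndarray:
    """Trait = polygenic score over causal SNPs + N(0, sigma2) noise.

    ``causal_codes`` supplies an unobserved causal panel when some causal
    SNPs are not among the genotyped columns of ``G``.
    """
    if sigma2 <= 0:
        raise ConfigError(f"sigma2={sigma2} must be positive")
    if causal_codes is None:
        if len(model.causal_indices) and (
            model.causal_indices.min() < 0 or model.causal_indices.max() >= G.n_snps
        ):
            raise DataError("causal index out of range for the genotype matrix")
        causal_codes = G.codes[:, model.causal_indices]
    if (np.asarray(causal_codes) < 0).any():
        raise DataError("causal genotypes contain missing calls")
    rng = _as_rng(seed)
    g = np.asarray(causal_codes, float) @ model.beta_l
    return g + rng.normal(0.0, np.sqrt(sigma2), size=len(g))


# ---------------------------------------------------------------------------
# phenotype-only family designs


def simulate_twin_cohort(
    n_mz: int,
    n_dz: int,
    sigma_a2: float,
    sigma_c2: float,
    sigma_d2: float,
    sigma2: float,
    seed=None,
) -> tuple[np.ndarray, Pedigree]:
    """MZ/DZ twin phenotypes with the additive/common-env/dominance covariance.

    Within-pair covariance is sigma_c2 + sigma_a2 + sigma_d2 for MZ pairs and
    sigma_c2 + 0.5 sigma_a2 + 0.25 sigma_d2 for DZ pairs; pairs independent.
    """
    for name, v in (
        ("sigma_a2", sigma_a2),
        ("sigma_c2", sigma_c2),
        ("sigma_d2", sigma_d2),
        ("sigma2", sigma2),
    ):
        if v < 0:
            raise ConfigError(f"{name}={v} must be non-negative")
    sigma_y2 = sigma_a2 + sigma_c2 + sigma_d2 + sigma2
    if sigma_y2 <= 0:
        raise ConfigError("total variance is zero")
    r_mz = (sigma_c2 + sigma_a2 + sigma_d2) / sigma_y2
    r_dz = (sigma_c2 + 0.5 * sigma_a2 + 0.25 * sigma_d2) / sigma_y2
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 < r < 1.0:
            raise ConfigError(f"implied correlation {name}={r} outside (-1, 1)")
    rng = _as_rng(seed)

    def draw(npairs, rho):
        shared = rng.normal(size=npairs)
        ind = rng.normal(size=(npairs, 2))
        y = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * ind
        return (np.sqrt(sigma_y2) * y).ravel()

    y = np.concatenate([draw(n_mz, r_mz), draw(n_dz, r_dz)])
    rows = []
    for i in range(n_mz):
        for m in (1, 2):
            rows.append((f"mz{i}", f"mz{i}_{m}", "0", "0", "0", "MZ"))
    for i in range(n_dz):
        for m in (1, 2):
            rows.append((f"dz{i}", f"dz{i}_{m}", "0", "0", "0", "DZ"))
    ped = Pedigree(
        pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "zygosity"])
    )
    return y, ped


def simulate_family_cohort(
    n_families: int,
    sibs_per_family: int,
    sigma_a2: float,
    sigma_s2: float,
    sigma_m2: float,
    sigma2: float,
    seed=None,
) -> tuple[np.ndarray, Pedigree]:
    """Nuclear families (two parents + sibs) with polygenic, sibship, marital effects.

    Trait covariance is sigma_a2 * FRM + sigma_s2 * (same sibship)
    + sigma_m2 * (spouse pair) + sigma2 * I, so e.g. the spouse covariance
    is sigma_m2 and the sib-sib covariance 0.5 sigma_a2 + sigma_s2.
    """
    for name, v in (
        ("sigma_a2", sigma_a2),
        ("sigma_s2", sigma_s2),
        ("sigma_m2", sigma_m2),
        ("sigma2", sigma2),
    ):
        if v < 0:
            raise ConfigError(f"{name}={v} must be non-negative")
    if n_families < 1 or sibs_per_family < 1:
        raise ConfigError("need at least one family with at least one sib")
    s = 2 + sibs_per_family
    frm = np.eye(s)
    frm[2:, 0] = frm[0, 2:] = 0.5  # father-offspring
    frm[2:, 1] = frm[1, 2:] = 0.5  # mother-offspring
    frm[2:, 2:] = 0.5 + 0.5 * np.eye(sibs_per_family)  # full sibs
    sib = np.zeros((s, s))
    sib[2:, 2:] = 1.0
    mar = np.zeros((s, s))
    mar[:2, :2] = 1.0
    cov = sigma_a2 * frm + sigma_s2 * sib + sigma_m2 * mar + sigma2 * np.eye(s)
    L = np.linalg.cholesky(cov)
    rng = _as_rng(seed)
    z = rng.normal(size=(n_families, s))
    y = (z @ L.T).ravel()
    rows = []
    for i in range(n_families):
        fid = f"fam{i}"
        rows.append((fid, f"{fid}_f", "0", "0", "1", NO_ZYGOSITY))
        rows.append((fid, f"{fid}_m", "0", "0", "2", NO_ZYGOSITY))
        for j in range(sibs_per_family):
            rows.append((fid, f"{fid}_s{j}", f"{fid}_f", f"{fid}_m", "0", NO_ZYGOSITY))
    ped = Pedigree(
        pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "zygosity"])
    )
    return y, ped
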