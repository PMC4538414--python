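"""Relationship matrices: genotype-based GRM and pedigree-based FRM.

The GRM entry for individuals j, k is the average over SNPs of
``(x_j - 2p)(x_k - 2p) / (2p(1-p))`` with p the coded-allele frequency,
averaged over SNPs where both genotypes are observed.  Two diagonal dialects
are carried: "simple" (the same formula with j = k, i.e. the mean squared
standardized genotype) and "gcta" (``1 + [x^2 - (1+2p)x + 2p^2]/(2p(1-p))``
averaged over SNPs), which differ only in how the self-relationship is
estimated.  The FRM is twice the pedigree kinship coefficient.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, DataError
from .genio import MISSING, GenotypeMatrix
from .pedigree import Pedigree


@dataclass
class CovarianceComponent:
    """A named symmetric matrix over an ordered individual index.

    ``matrix`` may be a dense ndarray or a scipy sparse matrix; sparse
    storage is the natural choice for block-diagonal pedigree components.
    """

    name: str
    sample_ids: np.ndarray
    matrix: object
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise DataError(
                f"component {self.name!r}: matrix shape {self.matrix.shape} "
                f"does not match {n} sample ids"
            )
        if sp.issparse(self.matrix):
            self.matrix = self.matrix.tocsr()
            asym = abs(self.matrix - self.matrix.T)
            if asym.nnz and asym.max() > 1e-12:
                raise DataError(f"component {self.name!r} is not symmetric")
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
                raise DataError(f"component {self.name!r} is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def dense(self) -> np.ndarray:
        return self.matrix.toarray() if sp.issparse(self.matrix) else self.matrix

    def is_identity(self) -> bool:
        if sp.issparse(self.matrix):
            return (abs(self.matrix - sp.eye(self.n, format="csr")).max() if self.n else 0) <= 1e-12
        return bool(np.allclose(self.matrix, np.eye(self.n), atol=1e-12))

    def reorder(self, ids: np.ndarray) -> "CovarianceComponent":
        """Align to a new sample order (ids must be a subset permutation)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            take = np.array([pos[s] for s in ids])
        except KeyError as exc:
            raise DataError(f"component {self.name!r} lacks sample {exc.args[0]!r}") from None
        mat = self.matrix[take][:, take] if sp.issparse(self.matrix) else self.matrix[np.ix_(take, take)]
        return CovarianceComponent(self.name, np.asarray(ids, dtype=object), mat, dict(self.meta))


def identity_component(sample_ids) -> CovarianceComponent:
    n = len(sample_ids)
    return CovarianceComponent("residual", np.asarray(sample_ids, dtype=object), sp.eye(n, format="csr"))


# ---------------------------------------------------------------------------
# allele frequencies and GRM


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP coded-allele frequency over non-missing calls of all individuals."""
    if G.n_snps == 0 or G.n_samples == 0:
        raise DataError("empty genotype matrix")
    obs = G.codes != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise DataError(f"SNP {G.snp_ids[j]!r} has no non-missing calls")
    totals = np.where(obs, G.codes, 0).sum(axis=0)
    return totals / (2.0 * n_obs)


def compute_grm(
    G: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    diagonal: str = "simple",
) -> CovarianceComponent:
    """Genetic relationship matrix from standardized genotypes.

    Missing genotypes are handled by pairwise-complete averaging: each entry
    averages over the SNPs jointly observed for that pair, and the count of
    jointly observed SNPs is stored in ``meta['pair_counts']``.
    """
    if diagonal not in ("simple", "gcta"):
        raise ConfigError(f"unknown GRM diagonal dialect {diagonal!r}")
    p = allele_frequencies(G) if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (G.n_snps,):
        raise DataError("frequency vector length does not match SNP count")
    fixed = (p <= 0.0) | (p >= 1.0)
    if fixed.any():
        j = int(np.argmax(fixed))
        raise DataError(
            f"SNP {G.snp_ids[j]!r} has allele frequency {p[j]}; monomorphic "
            "SNPs must be removed before GRM construction"
        )
    obs = G.codes != MISSING
    complete = bool(obs.all())
    x = G.codes.astype(float)
    x[~obs] = 0.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = np.where(obs, (x - 2.0 * p) / denom, 0.0)
    num = z @ z.T
    if complete:  # pairwise counts are constant; skip the indicator matmul
        counts = np.full((G.n_samples, G.n_samples), float(G.n_snps))
    else:
        counts = obs.astype(float) @ obs.T.astype(float)
        if (counts == 0).any():
            raise DataError("a sample pair shares no jointly observed SNPs")
    grm = num / counts
    if diagonal == "gcta":
        xx = np.where(obs, (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (denom * denom), 0.0)
        np.fill_diagonal(grm, 1.0 + xx.sum(axis=1) / obs.sum(axis=1))
    return CovarianceComponent(
        "grm",
        G.sample_ids,
        grm,
        meta={"diagonal": diagonal, "n_snps": G.n_snps, "pair_counts": counts.astype(np.int64)},
    )


# ---------------------------------------------------------------------------
# pedigree FRM


def pedigree_frm(ped: Pedigree, sparse: bool | None = None) -> CovarianceComponent:
    """Familial relationship matrix: twice the kinship coefficient.

    Block-diagonal by family; the diagonal is 1 + inbreeding coefficient.
    Stored sparsely when the pedigree is large (or on request).
    """
    blocks = ped.kinship_blocks()
    n = len(ped.table)
    if sparse is None:
        sparse = n > 500
    if sparse:
        rows, cols, vals = [], [], []
        for idx, phi in blocks:
            r = np.repeat(idx, len(idx))
            c = np.tile(idx, len(idx))
            v = 2.0 * phi.ravel()
            keep = v != 0.0
            rows.append(r[keep])
            cols.append(c[keep])
            vals.append(v[keep])
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:
        mat = np.zeros((n, n))
        for idx, phi in blocks:
            mat[np.ix_(idx, idx)] = 2.0 * phi
    return CovarianceComponent("frm", ped.ids, mat)


def select_mz_representatives(ped: Pedigree, seed: int = 0) -> np.ndarray:
    """Keep one randomly selected member of each MZ twin pair.

    Returns the ids retained for analyses whose relationship matrix cannot
    represent genetically identical individuals (FRM and GRM fits).
    """
    rng = np.random.default_rng(seed)
    drop = set()
    for (fid, tag), members in sorted(ped.twin_groups().items()):
        if tag.upper().startswith("MZ") and len(members) > 1:
            keep = rng.integers(len(members))
            drop.update(m for i, m in enumerate(members) if i != keep)
    return np.array([i for i in ped.ids if i not in drop], dtype=object)


# ---------------------------------------------------------------------------
# relatedness cutoff


def grm_cutoff_filter(
    K: CovarianceComponent,
    cutoff: float = 0.025,
    call_rates: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy selection of individuals with no pairwise relatedness above cutoff.

    Repeatedly removes the individual participating in the most above-cutoff
    pairs; ties are broken by lower call rate (when provided), then by later
    sample order.  The retained set satisfies
    ``max off-diagonal among retained <= cutoff`` by construction.
    """
    if cutoff < 0:
        raise ConfigError(f"cutoff must be non-negative, got {cutoff}")
    mat = K.dense().copy()
    np.fill_diagonal(mat, 0.0)
    adj = mat > cutoff
    active = np.ones(K.n, dtype=bool)
    degree = adj.sum(axis=1).astype(float)
    if call_rates is not None:
        call_rates = np.asarray(call_rates, dtype=float)
        if call_rates.shape != (K.n,):
            raise ConfigError("call_rates length must match sample count")
    while True:
        deg = np.where(active, degree, -1.0)
        dmax = deg.max()
        if dmax <= 0:
            break
        cand = np.flatnonzero(deg == dmax)
        if call_rates is not None:
            cand = cand[call_rates[cand] == call_rates[cand].min()]
        victim = cand[-1]  # later sample order
        active[victim] = False
        degree[adj[victim]] -= 1
        degree[victim] = 0.0
    return K.sample_ids[active]


# ---------------------------------------------------------------------------
# GRM file formats (GCTA binary triplet and TSV triplets)


def write_grm_tsv(K: CovarianceComponent, path: str | os.PathLike) -> None:
    """Lower-triangle (id1, id2, value) triplets, diagonal included."""
    mat = K.dense()
    with open(path, "w") as fh:
        fh.write("id1\tid2\tvalue\n")
        for i in range(K.n):
            for j in range(i + 1):
                fh.write(f"{K.sample_ids[i]}\t{K.sample_ids[j]}\t{mat[i, j]:.10g}\n")


def read_grm_tsv(path: str | os.PathLike) -> CovarianceComponent:
    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    ids = list(dict.fromkeys(df["id1"]))
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    mat = np.zeros((n, n))
    for a, b, v in df.itertuples(index=False):
        i, j = pos[a], pos[b]
        mat[i, j] = mat[j, i] = v
    return CovarianceComponent("grm", np.array(ids, dtype=object), mat)


def write_grm_gcta(K: CovarianceComponent, prefix: str | os.PathLike) -> None:
    """GCTA binary triplet: .grm.bin / .grm.N.bin (float32 lower triangle) + .grm.id."""
    prefix = str(prefix)
    mat = K.dense()
    tri = np.tril_indices(K.n)
    mat[tri].astype("<f4").tofile(prefix + ".grm.bin")
    counts = K.meta.get("pair_counts")
    if counts is None:
        counts = np.full((K.n, K.n), K.meta.get("n_snps", 0))
    np.asarray(counts)[tri].astype("<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in K.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_gcta(prefix: str | os.PathLike) -> CovarianceComponent:
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None, dtype=str)[1].to_numpy(dtype=object)
    n = len(ids)
    vals = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if vals.size != n * (n + 1) // 2:
        raise DataError(
            f"{prefix}.grm.bin holds {vals.size} values, expected {n * (n + 1) // 2}"
        )
    mat = np.zeros((n, n))
    tri = np.tril_indices(n)
    mat[tri] = vals
    mat = mat + np.tril(mat, -1).T
    meta = {}
    npath = prefix + ".grm.N.bin"
    if os.path.exists(npath):
        counts = np.zeros((n, n))
        counts[tri] = np.fromfile(npath, dtype="<f4")
        meta["pair_counts"] = (counts + np.tril(counts, -1).T).astype(np.int64)
    return CovarianceComponent("grm", ids, mat, meta)
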