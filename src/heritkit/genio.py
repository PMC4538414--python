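"""Genotype containers and file IO.

Genotypes are additive codes counting copies of the A1 allele: 0, 1, 2, with
-1 for missing.  Two on-disk dialects are supported:

* a plain TSV with one row per individual, one column per SNP, values
  ``0/1/2/NA`` and a leading ``sample_id`` column;
* PLINK 1 binary triplets (``.bed`` SNP-major + ``.bim`` + ``.fam``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes -> additive count of A1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive genotype codes.

    Parameters
    ----------
    sample_ids : array of str, one per row of ``codes``.
    snp_ids : array of str, one per column of ``codes``.
    codes : int8 array with values in {-1, 0, 1, 2}; -1 denotes missing.
    freqs : optional per-SNP frequency of the coded (A1) allele in [0, 1].
    meta : free-form provenance (allele coding convention, drop counts, ...).
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray
    freqs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise DataError("genotype codes must be a 2-D array")
        if self.codes.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise DataError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"invalid genotype code {int(self.codes[i, j])} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, dtype=float)
            if self.freqs.shape != (len(self.snp_ids),):
                raise DataError("freqs must have one entry per SNP")
            if ((self.freqs < 0) | (self.freqs > 1)).any():
                raise DataError("allele frequencies must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def call_rates(self, axis: str = "sample") -> np.ndarray:
        """Fraction of non-missing calls per sample (axis='sample') or SNP."""
        obs = self.codes != MISSING
        return obs.mean(axis=1) if axis == "sample" else obs.mean(axis=0)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        """Positional subset; keeps metadata, slices freqs alongside snps."""
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        vi = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[si],
            snp_ids=self.snp_ids[vi],
            codes=self.codes[np.ix_(si, vi)],
            freqs=None if self.freqs is None else self.freqs[vi],
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# TSV dialect


def write_genotypes_tsv(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    codes = G.codes.astype(object)
    codes[G.codes == MISSING] = "NA"
    df = pd.DataFrame(codes, columns=G.snp_ids)
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: malformed genotype TSV ({exc})") from exc
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise FormatError(f"{path}: expected a leading 'sample_id' column")
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    codes = np.empty(raw.shape, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": -1}
    flat = raw.ravel()
    out = codes.ravel()
    for k, v in enumerate(flat):
        try:
            out[k] = valid[v]
        except KeyError:
            i, j = divmod(k, raw.shape[1])
            raise FormatError(
                f"{path}: invalid genotype value {v!r} for sample "
                f"{df.iloc[i, 0]!r}, SNP {df.columns[j + 1]!r}"
            ) from None
    return GenotypeMatrix(
        sample_ids=df.iloc[:, 0].to_numpy(dtype=object),
        snp_ids=df.columns[1:].to_numpy(dtype=object),
        codes=codes,
        meta={"source": str(path), "coded_allele": "A1"},
    )


def write_phenotype_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Trait/covariate table keyed by family and individual id."""
    if not {"fid", "iid"}.issubset(df.columns):
        raise FormatError("phenotype table must contain 'fid' and 'iid' columns")
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str})
    if not {"fid", "iid"}.issubset(df.columns):
        raise FormatError(f"{path}: phenotype table must contain 'fid' and 'iid' columns")
    return df


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed/.bim/.fam)


def write_plink(G: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write SNP-major PLINK 1 binary files (synthetic .bim/.fam columns)."""
    prefix = str(prefix)
    n, m = G.n_samples, G.n_snps
    with open(prefix + ".fam", "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    with open(prefix + ".bim", "w") as fh:
        for j, vid in enumerate(G.snp_ids):
            fh.write(f"1\t{vid}\t0\t{j + 1}\tA\tB\n")
    # two bits per sample, packed 4 samples/byte, little end first
    lut = np.zeros(256, dtype=np.uint8)  # maps int8 code (viewed as uint8) -> 2-bit
    for code, bits in _BED_ENCODE.items():
        lut[code % 256] = bits
    nbytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        two_bit = lut[G.codes.view(np.uint8)]  # (n, m)
        padded = np.zeros((nbytes * 4, m), dtype=np.uint8)  # pad bits 00
        padded[:n] = two_bit
        packed = (
            padded[0::4]
            | (padded[1::4] << 2)
            | (padded[2::4] << 4)
            | (padded[3::4] << 6)
        )
        fh.write(packed.T.tobytes())  # SNP-major


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(
                f"{prefix}.bed: bad magic bytes {magic.hex()} "
                f"(expected SNP-major PLINK 1 bed {_BED_MAGIC.hex()})"
            )
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    nbytes = (n + 3) // 4
    if data.size != nbytes * m:
        raise FormatError(
            f"{prefix}.bed: {data.size} payload bytes, expected {nbytes * m} "
            f"for {n} samples x {m} SNPs"
        )
    data = data.reshape(m, nbytes)
    shifts = np.arange(4, dtype=np.uint8) * 2
    unpacked = (data[:, :, None] >> shifts[None, None, :]) & 0b11  # (m, nbytes, 4)
    codes = _BED_DECODE[unpacked.reshape(m, nbytes * 4)[:, :n]].T
    return GenotypeMatrix(
        sample_ids=fam.iloc[:, 1].to_numpy(dtype=object),
        snp_ids=bim.iloc[:, 1].to_numpy(dtype=object),
        codes=codes,
        meta={"source": prefix, "coded_allele": "A1"},
    )


def read_genotypes(path: str | os.PathLike, fmt: str = "auto") -> GenotypeMatrix:
    """Dispatch on format tag: 'tsv', 'plink', or 'auto' (by extension)."""
    p = str(path)
    if fmt == "auto":
        fmt = "plink" if os.path.exists(p + ".bed") or p.endswith(".bed") else "tsv"
    if fmt == "plink":
        return read_plink(p[:-4] if p.endswith(".bed") else p)
    if fmt == "tsv":
        return read_genotypes_tsv(p)
    raise FormatError(f"unknown genotype format tag {fmt!r}")
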