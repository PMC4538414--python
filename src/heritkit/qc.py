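"""SNP- and sample-level genotype quality control.

Default thresholds follow common GWAS practice: SNPs are dropped when the
Hardy-Weinberg exact test p-value falls below 1e-5, the genotype call rate
below 95%, or the minor allele frequency below 0.01; samples are dropped for
call rate below 95% or heterozygosity above 30%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import ConfigError, DataError
from .genio import MISSING, GenotypeMatrix


@dataclass
class QCReport:
    """Per-rule removal counts plus the thresholds that produced them."""

    snps_removed_hwe: int = 0
    snps_removed_callrate: int = 0
    snps_removed_maf: int = 0
    samples_removed_callrate: int = 0
    samples_removed_heterozygosity: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def snps_removed(self) -> int:
        return self.snps_removed_hwe + self.snps_removed_callrate + self.snps_removed_maf

    @property
    def samples_removed(self) -> int:
        return self.samples_removed_callrate + self.samples_removed_heterozygosity

    def to_json(self) -> str:
        return json.dumps(
            {
                "snps_removed": {
                    "hwe": self.snps_removed_hwe,
                    "callrate": self.snps_removed_callrate,
                    "maf": self.snps_removed_maf,
                },
                "samples_removed": {
                    "callrate": self.samples_removed_callrate,
                    "heterozygosity": self.samples_removed_heterozygosity,
                },
                "thresholds": self.thresholds,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"snps_removed_hwe\t{self.snps_removed_hwe}",
            f"snps_removed_callrate\t{self.snps_removed_callrate}",
            f"snps_removed_maf\t{self.snps_removed_maf}",
            f"samples_removed_callrate\t{self.samples_removed_callrate}",
            f"samples_removed_heterozygosity\t{self.samples_removed_heterozygosity}",
        ]
        lines += [f"threshold_{k}\t{v}" for k, v in self.thresholds.items()]
        return "\n".join(lines)


def hwe_exact_pvalue(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional test for departure from Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one (two-sided exact rule).  Symmetric in the two homozygote
    classes.

    Returns a p-value in (0, 1].
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 for c in counts):
        raise DataError(f"negative genotype count in {counts}")
    if sum(counts) == 0:
        raise DataError("all genotype counts are zero")
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het  # count of the first allele
    nb = 2 * n - na
    if na == 0 or nb == 0:
        return 1.0  # monomorphic: a single possible table
    # heterozygote count h shares the parity of na and satisfies
    # h <= min(na, nb), (na - h) even
    h_min = na % 2
    h_max = min(na, nb)
    h = np.arange(h_min, h_max + 1, 2)
    # log P(h | n, na) up to a constant: ln n! - ln h1! - ln h! - ln h2! + h ln 2
    h1 = (na - h) // 2
    h2 = (nb - h) // 2
    logp = h * np.log(2.0) - gammaln(h1 + 1) - gammaln(h + 1) - gammaln(h2 + 1)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[(h == n_het).argmax()]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _check_threshold(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ConfigError(f"{name}={value} must lie in [0, 1]")


def snp_qc(
    G: GenotypeMatrix,
    hwe_min: float = 1e-5,
    maf_min: float = 0.01,
    call_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs failing HWE, call-rate, or MAF rules.

    A SNP failing several rules is attributed to the first failing rule in
    the fixed order HWE, call rate, MAF, and counted once.
    """
    for name, v in (("hwe_min", hwe_min), ("maf_min", maf_min), ("call_min", call_min)):
        _check_threshold(name, v)
    if G.n_snps == 0 or G.n_samples == 0:
        raise DataError("empty genotype matrix")
    obs = G.codes != MISSING
    n_obs = obs.sum(axis=0)
    call = n_obs / G.n_samples
    codes = G.codes
    n_het = ((codes == 1) & obs).sum(axis=0)
    n_hom1 = (codes == 2).sum(axis=0)
    n_hom2 = (codes == 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, (2.0 * n_hom1 + n_het) / (2.0 * n_obs), np.nan)
    maf = np.minimum(freq, 1 - freq)

    fail_hwe = np.array(
        [
            n_obs[j] > 0 and hwe_exact_pvalue(int(n_hom1[j]), int(n_het[j]), int(n_hom2[j])) < hwe_min
            for j in range(G.n_snps)
        ]
    )
    fail_call = call < call_min
    fail_maf = ~np.isnan(maf) & (maf < maf_min)

    reason = np.full(G.n_snps, 0)  # 0 keep, 1 hwe, 2 call, 3 maf
    reason[fail_maf] = 3
    reason[fail_call] = 2
    reason[fail_hwe] = 1
    keep = reason == 0
    report = QCReport(
        snps_removed_hwe=int((reason == 1).sum()),
        snps_removed_callrate=int((reason == 2).sum()),
        snps_removed_maf=int((reason == 3).sum()),
        thresholds={"hwe_min": hwe_min, "maf_min": maf_min, "call_min": call_min},
    )
    return G.subset(snps=np.flatnonzero(keep)), report


def sample_qc(
    G: GenotypeMatrix,
    call_min: float = 0.95,
    het_max: float = 0.30,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove individuals with call rate < call_min or heterozygosity > het_max.

    Heterozygosity is the fraction of heterozygous calls among non-missing
    calls; attribution order is call rate first, then heterozygosity.
    """
    for name, v in (("call_min", call_min), ("het_max", het_max)):
        _check_threshold(name, v)
    if G.n_snps == 0 or G.n_samples == 0:
        raise DataError("empty genotype matrix")
    obs = G.codes != MISSING
    n_obs = obs.sum(axis=1)
    call = n_obs / G.n_snps
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_obs > 0, (G.codes == 1).sum(axis=1) / n_obs, 0.0)
    fail_call = call < call_min
    fail_het = ~fail_call & (het > het_max)
    keep = ~(fail_call | fail_het)
    report = QCReport(
        samples_removed_callrate=int(fail_call.sum()),
        samples_removed_heterozygosity=int(fail_het.sum()),
        thresholds={"call_min": call_min, "het_max": het_max},
    )
    return G.subset(samples=np.flatnonzero(keep)), report
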