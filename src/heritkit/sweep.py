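"""Relatedness sweep: heritability estimates versus within-pair correlation.

For each grid cell (r, h2, causal coverage, causal MAF law) the sweep
simulates pairs of individuals with genotype correlation r, generates traits
from an equal-variance causal architecture, builds the GRM from the
genotyped SNPs (all of them by default — no relatedness cutoff), fits
single-component REML, and records the heritability estimate per replicate.

The reference line for a cell is the proportion of the phenotypic variance
explained by the genotyped SNPs,

    coverage * h2 * sigma2/(1-h2) / (h2 * sigma2/(1-h2) + sigma2),

which reduces to h2 at full coverage.  When only half the causal SNPs are
genotyped, estimates exceed this line once pair members are appreciably
correlated: the untagged genetic variance is picked up through relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, NumericalError
from .relatedness import compute_grm, identity_component
from .reml import TraitModel, fit_variance_components, heritability_from_fit
from .simulate import SimConfig, causal_effects, draw_mafs, simulate_related_pairs, simulate_traits


@dataclass
class SweepGrid:
    r_values: tuple = (0.5, 0.25, 0.125, 0.0)
    h2_values: tuple = (0.5,)
    coverages: tuple = (1.0, 0.5)
    causal_maf_laws: tuple = ("U(0,0.1)",)
    noncausal_maf_law: str = "U(0,0.4)"
    n_pairs: int = 500
    n_snps: int = 5000
    n_causal: int = 100
    sigma2: float = 1.0
    include_noncausal: bool = True

    def __post_init__(self):
        if self.n_causal > self.n_snps:
            raise ConfigError("n_causal exceeds n_snps")

    def cells(self):
        cells = []
        for law in self.causal_maf_laws:
            for h2 in self.h2_values:
                for cov in self.coverages:
                    for r in self.r_values:
                        cells.append({"r": r, "h2": h2, "coverage": cov, "causal_maf_law": law})
        return cells

    @classmethod
    def paper_scale(cls, **kw) -> "SweepGrid":
        """Grid at the full study scale (5000 pairs, 100k SNPs)."""
        kw.setdefault("n_pairs", 5000)
        kw.setdefault("n_snps", 100_000)
        kw.setdefault("r_values", (1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32, 1 / 64, 1 / 128, 0.0))
        return cls(**kw)


@dataclass
class SweepResult:
    grid: SweepGrid
    replicates: pd.DataFrame
    summary: pd.DataFrame = field(default=None)


def reference_line(coverage: float, h2: float, sigma2: float = 1.0) -> float:
    """Share of phenotypic variance explained by the genotyped causal SNPs."""
    if h2 >= 1.0:
        raise ConfigError("h2 must be below 1")
    vg = h2 * sigma2 / (1.0 - h2)
    return coverage * vg / (vg + sigma2)


def _run_replicate(grid: SweepGrid, cell: dict, rng: np.random.Generator) -> dict:
    n_non = grid.n_snps - grid.n_causal
    p_non = draw_mafs(n_non, grid.noncausal_maf_law, rng) if n_non else np.empty(0)
    p_causal = draw_mafs(grid.n_causal, cell["causal_maf_law"], rng)
    cfg = SimConfig(
        n_pairs=grid.n_pairs,
        n_snps=grid.n_snps,
        r=cell["r"],
        maf_law=grid.noncausal_maf_law,
        causal_maf_law=cell["causal_maf_law"],
        n_causal=grid.n_causal,
        h2=cell["h2"],
        sigma2=grid.sigma2,
    )
    G = simulate_related_pairs(
        cfg, mafs=np.concatenate([p_non, p_causal]), seed=rng, drop_monomorphic=False
    )
    causal_cols = n_non + np.arange(grid.n_causal)
    model = causal_effects(p_causal, cell["h2"], grid.sigma2, indices=causal_cols)
    y = simulate_traits(G, model, grid.sigma2, seed=rng)
    n_geno_causal = int(round(cell["coverage"] * grid.n_causal))
    chosen = np.sort(rng.choice(grid.n_causal, size=n_geno_causal, replace=False))
    keep = np.concatenate(
        [np.arange(n_non) if grid.include_noncausal else np.empty(0, int), causal_cols[chosen]]
    ).astype(int)
    Gg = G.subset(snps=keep)
    poly = ~(Gg.codes == Gg.codes[0]).all(axis=0)
    n_dropped = int((~poly).sum())
    Gg = Gg.subset(snps=np.flatnonzero(poly))
    out = {
        "n_monomorphic_dropped": n_dropped,
        "n_genotyped_snps": Gg.n_snps,
        "h2_hat": np.nan,
        "converged": False,
        "boundary": False,
    }
    try:
        grm = compute_grm(Gg)
        tm = TraitModel(y=y, X=np.ones((len(y), 1)), sample_ids=G.sample_ids)
        fit = fit_variance_components(
            tm, [grm, identity_component(G.sample_ids)], method="REML", backend="eigen"
        )
        out["converged"] = bool(fit.converged)
        out["boundary"] = bool(fit.boundary.any())
        if fit.converged:
            out["h2_hat"] = heritability_from_fit(fit, genetic="grm").h2
    except NumericalError:
        pass
    return out


def run_sweep(grid: SweepGrid, replicates: int = 20, seed: int = 0) -> SweepResult:
    """Run every grid cell for the requested replicate count.

    Replicate seeds derive deterministically from (seed, cell index,
    replicate index), so the whole sweep is reproducible bit-identically
    from the master seed and any cell can be recomputed in isolation.
    """
    rows = []
    for ci, cell in enumerate(grid.cells()):
        for rep in range(replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, rep]))
            rec = dict(cell, replicate=rep, **_run_replicate(grid, cell, rng))
            rows.append(rec)
    reps = pd.DataFrame(rows)
    res = SweepResult(grid=grid, replicates=reps)
    res.summary = summarize_sweep(res)
    return res


def summarize_sweep(res: SweepResult) -> pd.DataFrame:
    """Per-cell summary: mean, sd, quartiles, reference line, failure count."""
    if res.replicates.empty:
        raise ConfigError("empty sweep result")
    rows = []
    keys = ["causal_maf_law", "h2", "coverage", "r"]
    for key, g in res.replicates.groupby(keys, sort=True):
        law, h2, cov, r = key
        est = g.loc[g["converged"], "h2_hat"].dropna()
        n_fail = len(g) - len(est)
        q1, med, q3 = (
            est.quantile([0.25, 0.5, 0.75]) if len(est) else (np.nan, np.nan, np.nan)
        )
        rows.append(
            {
                "causal_maf_law": law,
                "h2": h2,
                "coverage": cov,
                "r": r,
                "n_replicates": len(g),
                "n_failed": n_fail,
                "cell_ok": n_fail <= 0.2 * len(g),
                "mean": est.mean() if len(est) else np.nan,
                "sd": est.std(ddof=1) if len(est) > 1 else np.nan,
                "q1": q1,
                "median": med,
                "q3": q3,
                "iqr": q3 - q1,
                "reference": reference_line(cov, h2, res.grid.sigma2),
            }
        )
    return pd.DataFrame(rows)


def load_grid_yaml(path) -> tuple[SweepGrid, int, int]:
    """Read (grid, replicates, seed) from a YAML sweep configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    replicates = int(raw.pop("replicates", 20))
    seed = int(raw.pop("seed", 0))
    paper = bool(raw.pop("paper_scale", False))
    for key in ("r_values", "h2_values", "coverages", "causal_maf_laws"):
        if key in raw:
            raw[key] = tuple(raw[key])
    grid = SweepGrid.paper_scale(**raw) if paper else SweepGrid(**raw)
    return grid, replicates, seed
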