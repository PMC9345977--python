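"""GWAS support computations.

Multiple-testing thresholds (plain Bonferroni and an LD-considerate
Bonferroni over the LD-pruned effective SNP count), the per-SNP percent
variance explained (PVE) of a single marker, per-group allele-frequency
profiles against group trait means, and a single-locus OLS association scan
used to exercise these pieces end-to-end on synthetic data. The scan is an
ordinary least-squares stand-in (optionally with principal-component
covariates via Frisch–Waugh residualisation); mixed-model association is
deliberately out of scope.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, allele_freqs
from .ld import ld_prune

__all__ = [
    "bonferroni_threshold",
    "ld_considerate_threshold",
    "pve",
    "group_allele_freqs",
    "simple_assoc_scan",
]


def bonferroni_threshold(alpha: float, n_snps: int, digits: int | None = 2) -> float:
    """-log10(alpha / n_snps); rounded to ``digits`` (None for raw)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    value = -math.log10(alpha / n_snps)
    return value if digits is None else round(value, digits)


def ld_considerate_threshold(
    g: GenotypeMatrix,
    alpha: float = 0.05,
    window_bp: int = 50_000,
    r2_max: float = 0.95,
    digits: int | None = 2,
) -> tuple[int, float]:
    """(effective SNP count after LD pruning, Bonferroni -log10 threshold)."""
    kept = ld_prune(g, window_bp=window_bp, r2_max=r2_max)
    return len(kept), bonferroni_threshold(alpha, len(kept), digits=digits)


def pve(beta: float, se_beta: float, maf: float, n: int) -> float:
    """Fraction of phenotypic variance explained by one SNP.

    PVE = 2 beta^2 MAF (1-MAF) / (2 beta^2 MAF (1-MAF) + se_beta^2 2 N MAF (1-MAF)).
    """
    if not 0 < maf < 1:
        raise ValueError("maf must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    num = 2.0 * beta**2 * maf * (1.0 - maf)
    den = num + se_beta**2 * 2.0 * n * maf * (1.0 - maf)
    return 0.0 if num == 0.0 else num / den


def group_allele_freqs(
    g: GenotypeMatrix,
    metadata: pd.DataFrame,
    snp: tuple[str, int],
    trait: str = "gill_raker_count",
    grouping: str = "ecomorph",
) -> pd.DataFrame:
    """Per-group alt-allele frequency at one SNP, with group trait means.

    ``grouping`` is 'ecomorph' or 'ecomorph_lake' (ecomorph within lake).
    Only samples present in both the genotype matrix and metadata are used.
    """
    chrom, pos = snp
    hit = g.loci[(g.loci["chrom"] == chrom) & (g.loci["pos"] == pos)]
    if hit.empty:
        raise KeyError(f"SNP {chrom}:{pos} not found")
    j = int(hit.index[0])
    meta = metadata[metadata["sample"].isin(g.sample_ids)].copy()
    if grouping == "ecomorph":
        meta["group"] = meta["ecomorph"]
    elif grouping == "ecomorph_lake":
        meta["group"] = meta["ecomorph"] + ":" + meta["lake"]
    else:
        raise ValueError("grouping must be 'ecomorph' or 'ecomorph_lake'")
    groups = {
        label: sub["sample"].tolist() for label, sub in meta.groupby("group")
    }
    freqs = allele_freqs(g.take_snps(np.array([j])), groups)
    rows = []
    for label, ids in groups.items():
        rows.append(
            {
                "group": label,
                "n": len(ids),
                "alt_freq": float(freqs.at[0, label]),
                "trait_mean": float(
                    meta.loc[meta["group"] == label, trait].mean()
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def simple_assoc_scan(
    g: GenotypeMatrix,
    trait: pd.Series | np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of trait on dosage with Wald p-values.

    ``trait`` is aligned to ``g.sample_ids`` (a Series indexed by sample id,
    or an array in row order) and must be complete. Optional covariate
    columns (e.g. principal components) are projected out of both trait and
    dosages before the per-SNP fit, which is the exact multiple-OLS slope.
    Monomorphic SNPs are skipped. Binary traits are scanned by the same
    linear scoring. Records are independent of sample order.
    """
    if isinstance(trait, pd.Series):
        y = trait.reindex(g.sample_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if y.shape[0] != g.n_samples:
        raise ValueError("trait length does not match sample count")
    if np.any(np.isnan(y)):
        raise ValueError("trait vector must be complete")
    n = g.n_samples
    x = g.dosages.astype(np.float64)
    design = np.ones((n, 1))
    if covariates is not None:
        design = np.hstack([design, np.asarray(covariates, dtype=float)])
    # project out intercept + covariates (Frisch-Waugh-Lovell)
    q, _ = np.linalg.qr(design)
    y_r = y - q @ (q.T @ y)
    x_r = x - q @ (q.T @ x)
    df = n - design.shape[1] - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    sxx = np.einsum("ij,ij->j", x_r, x_r)
    poly = ~np.isclose(sxx, 0.0)
    sxy = x_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = np.dot(y_r, y_r) - beta * sxy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    alt = x.sum(axis=0) / (2 * n)
    maf = np.minimum(alt, 1 - alt)
    out = pd.DataFrame(
        {
            "chrom": g.loci["chrom"],
            "pos": g.loci["pos"],
            "beta": beta,
            "se_beta": se,
            "p": p,
            "neg_log10_p": -np.log10(np.clip(p, 1e-300, None)),
            "maf": maf,
            "n": n,
        }
    )
    return out[poly].reset_index(drop=True)
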