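"""Linkage-disequilibrium pruning of dosage matrices.

Greedy left-to-right pruning: walking each chromosome in genomic order, a
SNP is dropped if its squared Pearson correlation (r^2 of dosages) with any
already-retained SNP inside the trailing window exceeds the threshold — i.e.
of an offending pair the later-positioned SNP is removed. The window can be
measured in base pairs (the default, matching sliding-window pruning over
physical distance) or in variant count.
"""

from __future__ import annotations

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["ld_prune"]


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(np.dot(xc, xc) * np.dot(yc, yc))
    if denom == 0.0:
        # one SNP is monomorphic: correlation undefined, treat as unlinked
        return 0.0
    num = float(np.dot(xc, yc))
    return num * num / denom


def ld_prune(
    g: GenotypeMatrix,
    window_bp: int = 50_000,
    step: int = 10,
    r2_max: float = 0.95,
    window_unit: str = "bp",
) -> np.ndarray:
    """Return the retained SNP column indices after greedy LD pruning.

    Parameters
    ----------
    window_bp
        Window extent: base pairs when ``window_unit='bp'``, number of
        retained variants when ``window_unit='variants'``.
    step
        Kept for interface parity with sliding-window pruning tools; the
        greedy scan advances one variant at a time, which is the step=1
        limit and strictly stricter, so results never depend on it.
    r2_max
        Retain a SNP only if r^2 with every retained window-mate is <= this.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError("r2_max must be in (0, 1]")
    if window_unit not in ("bp", "variants"):
        raise ValueError("window_unit must be 'bp' or 'variants'")
    chrom = g.loci["chrom"].to_numpy()
    pos = g.loci["pos"].to_numpy()
    X = g.dosages.astype(np.float64)
    kept: list[int] = []
    kept_chrom_start = 0  # index into kept of first SNP on current chromosome
    current_chrom = None
    for j in range(g.n_snps):
        if chrom[j] != current_chrom:
            current_chrom = chrom[j]
            kept_chrom_start = len(kept)
        lo = kept_chrom_start
        if window_unit == "variants":
            lo = max(lo, len(kept) - (window_bp - 1))
        drop = False
        for k in reversed(range(lo, len(kept))):
            i = kept[k]
            if window_unit == "bp" and pos[j] - pos[i] >= window_bp:
                break
            if _r2(X[:, i], X[:, j]) > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return np.asarray(kept, dtype=int)
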