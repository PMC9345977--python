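"""Weir–Cockerham F_ST scans and cross-lake outlier overlap.

Per-SNP variance components a (between populations), b (between individuals
within populations) and c (within individuals) follow the Weir & Cockerham
(1984) two-level estimator computed from genotype counts, including the
observed-heterozygosity term; theta = a / (a + b + c) and may be negative.
Windowed estimates report both the ratio-of-sums ("weighted") form
sum(a) / sum(a + b + c) and the mean of per-SNP theta; outlier ranking uses
the weighted estimate. The expected number of outlier windows shared by k of
L independent per-lake scans at outlier fraction q is q^k * W * C(L, k).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .windows import WindowSet

__all__ = [
    "wc_fst_snp",
    "windowed_fst",
    "top_percentile_outliers",
    "expected_overlap",
    "shared_outlier_windows",
]


def _pop_summaries(dosages: np.ndarray):
    """(n, p, h) per SNP for one population's dosage sub-matrix."""
    n = dosages.shape[0]
    p = dosages.sum(axis=0, dtype=np.float64) / (2 * n)
    h = np.count_nonzero(dosages == 1, axis=0) / n
    return n, p, h


def wc_fst_snp(
    dosages_pop1: np.ndarray, dosages_pop2: np.ndarray
) -> pd.DataFrame:
    """Weir–Cockerham variance components and theta per SNP (two populations).

    Input arrays are (individuals, SNPs) dosage sub-matrices; each
    population needs at least two diploids. Returns columns a, b, c, theta;
    theta is NaN where a + b + c == 0 (a SNP with no variance at all), and
    such SNPs are skipped by the windowed accumulator.
    """
    d1 = np.atleast_2d(np.asarray(dosages_pop1))
    d2 = np.atleast_2d(np.asarray(dosages_pop2))
    if d1.shape[0] < 2 or d2.shape[0] < 2:
        raise ValueError("each population needs >= 2 diploid individuals")
    r = 2
    n1, p1, h1 = _pop_summaries(d1)
    n2, p2, h2 = _pop_summaries(d2)
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0.0, a / denom, np.nan)
    return pd.DataFrame({"a": a, "b": b, "c": c, "theta": theta})


def windowed_fst(
    g: GenotypeMatrix,
    windows: WindowSet,
    pop1: list[str],
    pop2: list[str],
    min_snps: int = 10,
) -> pd.DataFrame:
    """Windowed Weir–Cockerham F_ST between two sample groups.

    Windows with fewer than ``min_snps`` usable SNPs are removed. Returns
    FstRecord rows: window coordinates, SNP count, fst_weighted
    (ratio-of-sums), fst_mean (mean per-SNP theta).
    """
    rows1 = g.sample_indices(list(pop1))
    rows2 = g.sample_indices(list(pop2))
    comp = wc_fst_snp(g.dosages[rows1], g.dosages[rows2])
    a = comp["a"].to_numpy()
    abc = a + comp["b"].to_numpy() + comp["c"].to_numpy()
    usable = abc != 0.0
    out = []
    for _, w in windows.table.iterrows():
        sl = slice(int(w["snp_start"]), int(w["snp_stop"]))
        use = usable[sl]
        n_use = int(np.count_nonzero(use))
        if n_use < min_snps:
            continue
        a_w = a[sl][use]
        abc_w = abc[sl][use]
        out.append(
            {
                "chrom": w["chrom"],
                "start": int(w["start"]),
                "end": int(w["end"]),
                "n_snps": n_use,
                "fst_weighted": float(a_w.sum() / abc_w.sum()),
                "fst_mean": float(np.mean(a_w / abc_w)),
            }
        )
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_snps", "fst_weighted", "fst_mean"],
    )


def top_percentile_outliers(
    records: pd.DataFrame, fraction: float = 0.01, by: str = "fst_weighted"
) -> pd.DataFrame:
    """The ceil(fraction * W) most-differentiated windows.

    Ties are broken by genomic order (the earlier window is kept), so the
    outlier count is exactly ceil(fraction * W) and the analytic
    expected-overlap arithmetic applies by construction.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(records))
    ranked = records.reset_index(drop=True)
    # stable sort on descending statistic keeps genomic order within ties
    order = np.argsort(-ranked[by].to_numpy(), kind="stable")
    return ranked.iloc[order[:k]].sort_index()


def expected_overlap(q: float, w: int, n_lakes: int, k: int) -> float:
    """Expected count of outlier windows shared by k of n_lakes scans by chance.

    Independent per-lake outlier draws of fraction q over W common windows:
    q^k * W * C(n_lakes, k).
    """
    if not 2 <= k <= n_lakes:
        raise ValueError("require 2 <= k <= number of lakes")
    return q**k * w * math.comb(n_lakes, k)


def shared_outlier_windows(
    outlier_sets: dict[str, pd.DataFrame],
    n_windows: int,
    fraction: float = 0.01,
) -> pd.DataFrame:
    """Observed vs expected counts of outlier windows shared across lakes.

    ``outlier_sets`` maps lake label -> outlier table over a common window
    grid. For each k in 2..L, reports how many windows appear in exactly k
    and in at least k of the per-lake sets, with the analytic expectation
    for at-least-pairwise sharing of independent draws.
    """
    lakes = list(outlier_sets)
    L = len(lakes)
    keys = [
        set(zip(t["chrom"], t["start"], t["end"])) for t in outlier_sets.values()
    ]
    grids = {len(k) for k in keys}
    counts: dict[tuple, int] = {}
    for kset in keys:
        for key in kset:
            counts[key] = counts.get(key, 0) + 1
    rows = []
    for k in range(2, L + 1):
        exact = sum(1 for v in counts.values() if v == k)
        at_least = sum(1 for v in counts.values() if v >= k)
        rows.append(
            {
                "k": k,
                "observed_exact": exact,
                "observed_at_least": at_least,
                "expected": expected_overlap(fraction, n_windows, L, k),
            }
        )
    out = pd.DataFrame(rows, columns=["k", "observed_exact", "observed_at_least", "expected"])
    out.attrs["outlier_set_sizes"] = dict(zip(lakes, (len(s) for s in keys)))
    out.attrs["grid_sizes"] = grids
    return out
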