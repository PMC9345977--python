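"""Cluster separation score (CSS) genome scan.

CSS quantifies, per genomic window, how far apart two groups of individuals
(here: ecomorphs pooled across lakes) sit in genotype space relative to the
variation inside each group. Pairwise individual distances are Euclidean
distances between dosage vectors scaled by the window's SNP count, embedded
by classical multidimensional scaling (all positive-eigenvalue axes kept,
which preserves this metric), and

    CSS = mean(between-group d) - (m * mean(within-1 d) + n * mean(within-2 d)) / (m + n)

with m, n the group sizes and within-group means over the k(k-1)/2 unordered
pairs. Significance comes from a stratified permutation null: group labels
are reshuffled within each lake, so lake-level population structure is
preserved while the ecomorph contrast is broken. Exact enumeration of the
stratified label assignments replaces sampling when the assignment count is
small. Windows with fewer than ``min_snps`` SNPs are removed before testing,
and outliers are called at an FDR-adjusted p-value cut-off.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genotypes import GenotypeMatrix
from .windows import WindowSet
from .ld import ld_prune

__all__ = [
    "ContrastDesign",
    "css_window",
    "stratified_permutation_test",
    "fdr_adjust",
    "outlier_pca",
    "trait_regression",
    "n_stratified_assignments",
]

EXACT_ENUMERATION_LIMIT = 200_000


@dataclass
class ContrastDesign:
    """Two-group contrast with lake strata for the permutation null."""

    group1: list[str]
    group2: list[str]
    strata: dict[str, list[str]]
    n_permutations: int = 100_000
    min_snps: int = 24
    fdr_level: float = 0.01
    seed: int = 0
    samples: list[str] = field(init=False)

    def __post_init__(self) -> None:
        overlap = set(self.group1) & set(self.group2)
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")
        self.samples = list(self.group1) + list(self.group2)
        pooled = set(self.samples)
        strat_union: set[str] = set()
        for lake, ids in self.strata.items():
            ids_set = set(ids)
            if ids_set & strat_union:
                raise ValueError(f"stratum {lake!r} overlaps another stratum")
            strat_union |= ids_set
            in1 = ids_set & set(self.group1)
            in2 = ids_set & set(self.group2)
            if not in1 or not in2:
                raise ValueError(
                    f"stratum {lake!r} must contain members of both groups"
                )
        if strat_union != pooled:
            raise ValueError("strata must partition the union of the groups")


def _mds_embed_distances(d: np.ndarray) -> np.ndarray:
    """Distance matrix after classical MDS keeping positive-eigenvalue axes.

    For Euclidean input this is distance-preserving up to floating point;
    it is applied anyway so the statistic is well-defined for any metric.
    """
    n = d.shape[0]
    d2 = d * d
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    keep = vals > 1e-12
    if not np.any(keep):
        return np.zeros_like(d)
    x = vecs[:, keep] * np.sqrt(vals[keep])
    return squareform(pdist(x))


def _window_distance_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean dosage distance divided by the SNP count."""
    n_snps = dosages.shape[1]
    d = squareform(pdist(dosages.astype(np.float64))) / n_snps
    return _mds_embed_distances(d)


def _css_from_assignments(d: np.ndarray, a: np.ndarray) -> np.ndarray:
    """CSS for each boolean group-1 assignment row in ``a`` over distances ``d``."""
    a = a.astype(np.float64)
    b = 1.0 - a
    m = a.sum(axis=1)
    n = b.sum(axis=1)
    ad = a @ d
    s1 = np.einsum("pi,pi->p", ad, a)  # 2 * sum of within-group-1 pair d
    cross = np.einsum("pi,pi->p", ad, b)
    bd = b @ d
    s2 = np.einsum("pi,pi->p", bd, b)
    between = cross / (m * n)
    within1 = s1 / (m * (m - 1))  # s1 double-counts pairs: 2/(m(m-1)) * s1/2
    within2 = s2 / (n * (n - 1))
    return between - (m * within1 + n * within2) / (m + n)


def css_window(
    dosages: np.ndarray, group1_idx: np.ndarray, group2_idx: np.ndarray
) -> float:
    """CSS for one window given row indices of the two groups."""
    group1_idx = np.asarray(group1_idx, dtype=int)
    group2_idx = np.asarray(group2_idx, dtype=int)
    if len(group1_idx) < 2 or len(group2_idx) < 2:
        raise ValueError("each group needs at least 2 individuals")
    if dosages.shape[1] < 1:
        raise ValueError("window contains no SNPs")
    rows = np.concatenate([group1_idx, group2_idx])
    d = _window_distance_matrix(dosages[rows])
    a = np.zeros((1, len(rows)), dtype=bool)
    a[0, : len(group1_idx)] = True
    return float(_css_from_assignments(d, a)[0])


def n_stratified_assignments(design: ContrastDesign) -> int:
    """Number of distinct stratified group-label assignments."""
    total = 1
    g1 = set(design.group1)
    for ids in design.strata.values():
        k = sum(1 for s in ids if s in g1)
        total *= math.comb(len(ids), k)
    return total


def _assignment_matrix(design: ContrastDesign, rng: np.random.Generator | None):
    """Boolean (P, n_samples) matrix of permuted group-1 assignments.

    With ``rng`` None, enumerate every stratified assignment exactly;
    otherwise draw ``design.n_permutations`` uniform stratified reshuffles
    (the identity may occur; the add-one p-value estimator accounts for it).
    """
    sample_pos = {s: i for i, s in enumerate(design.samples)}
    g1 = set(design.group1)
    strata = []
    for ids in design.strata.values():
        pos = np.array([sample_pos[s] for s in ids], dtype=int)
        k = sum(1 for s in ids if s in g1)
        strata.append((pos, k))
    n = len(design.samples)
    if rng is None:
        per_stratum = [
            [np.array(c, dtype=int) for c in itertools.combinations(range(len(pos)), k)]
            for pos, k in strata
        ]
        total = int(np.prod([len(c) for c in per_stratum]))
        a = np.zeros((total, n), dtype=bool)
        for p, combo in enumerate(itertools.product(*per_stratum)):
            for (pos, _k), chosen in zip(strata, combo):
                a[p, pos[chosen]] = True
        return a
    a = np.zeros((design.n_permutations, n), dtype=bool)
    for pos, k in strata:
        for p in range(design.n_permutations):
            chosen = rng.choice(len(pos), size=k, replace=False)
            a[p, pos[chosen]] = True
    return a


def stratified_permutation_test(
    design: ContrastDesign,
    g: GenotypeMatrix,
    windows: WindowSet,
    exact: bool | None = None,
) -> pd.DataFrame:
    """Windowed CSS scan with a lake-stratified permutation null.

    One shared permutation set is evaluated against every window (a single
    genome-wide null). Returns a table of CssRecord rows: window coordinates,
    SNP count, observed CSS, permutation p (add-one rule in sampled mode,
    exact tail fraction in enumeration mode), BH q-value, and the outlier
    flag at ``design.fdr_level``.
    """
    sub = g.take_samples(design.samples)
    n1 = len(design.group1)
    obs_assignment = np.zeros((1, len(design.samples)), dtype=bool)
    obs_assignment[0, :n1] = True

    if exact is None:
        exact = n_stratified_assignments(design) <= EXACT_ENUMERATION_LIMIT
    rng = None if exact else np.random.default_rng(design.seed)
    perms = _assignment_matrix(design, rng)

    rows = []
    for _, w in windows.table.iterrows():
        if w["n_snps"] < design.min_snps:
            continue
        dos = sub.dosages[:, int(w["snp_start"]) : int(w["snp_stop"])]
        d = _window_distance_matrix(dos)
        obs = float(_css_from_assignments(d, obs_assignment)[0])
        perm_css = _css_from_assignments(d, perms)
        # tolerance keeps the identity assignment in the exact tail despite
        # rounding differences between the 1-row and batched evaluations
        tol = 1e-9 * max(1.0, abs(obs))
        n_ge = int(np.count_nonzero(perm_css >= obs - tol))
        if exact:
            p = n_ge / len(perm_css)
        else:
            p = (1 + n_ge) / (1 + len(perm_css))
        rows.append(
            {
                "chrom": w["chrom"],
                "start": int(w["start"]),
                "end": int(w["end"]),
                "n_snps": int(w["n_snps"]),
                "css": obs,
                "p_perm": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "css", "p_perm"]
    )
    if len(out):
        out["q_value"] = fdr_adjust(out["p_perm"].to_numpy())
        out["outlier"] = out["q_value"] <= design.fdr_level
    else:
        out["q_value"] = []
        out["outlier"] = []
    return out


def fdr_adjust(
    p_values: np.ndarray, method: str = "bh", pi0: float | None = None
) -> np.ndarray:
    """FDR adjustment: Benjamini–Hochberg (default) or Storey q-values.

    The Storey estimate of the null proportion pi0 uses the lambda grid
    0.05..0.95 with cubic-spline smoothing evaluated at the largest lambda;
    forcing ``pi0=1`` recovers BH exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        pi0_hat = 1.0
    elif method == "storey":
        if pi0 is not None:
            pi0_hat = pi0
        else:
            lam = np.arange(0.05, 0.951, 0.05)
            pi0_lam = np.array([np.mean(p > l) / (1 - l) for l in lam])
            from scipy.interpolate import CubicSpline

            spline = CubicSpline(lam, pi0_lam)
            pi0_hat = float(np.clip(spline(lam[-1]), 0.0, 1.0))
            if pi0_hat <= 0:
                pi0_hat = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0_hat * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def outlier_pca(
    g: GenotypeMatrix,
    windows: WindowSet,
    outlier_table: pd.DataFrame,
    ld_window_bp: int = 50_000,
    ld_r2_max: float = 0.1,
    n_components: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on LD-pruned SNPs inside CSS outlier windows.

    ``outlier_table`` is a scan result (or any table with chrom/start/end)
    whose rows select windows. Dosages are mean-centred and decomposed by
    SVD; each PC's sign is fixed so its loading sum is non-negative. Returns
    (scores DataFrame indexed by sample, explained-variance fractions).
    """
    wanted = set(
        zip(outlier_table["chrom"], outlier_table["start"], outlier_table["end"])
    )
    if not wanted:
        raise ValueError("no outlier windows supplied")
    snp_idx: list[np.ndarray] = []
    for i, w in windows.table.iterrows():
        if (w["chrom"], w["start"], w["end"]) in wanted:
            snp_idx.append(windows.snp_indices(i))
    idx = np.concatenate(snp_idx) if snp_idx else np.array([], dtype=int)
    sub = g.take_snps(idx)
    kept = ld_prune(sub, window_bp=ld_window_bp, r2_max=ld_r2_max)
    sub = sub.take_snps(kept)
    if sub.n_snps < 2:
        raise ValueError("fewer than 2 SNPs available for PCA")
    x = sub.dosages.astype(np.float64)
    x -= x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    flip = np.where(vt[:k].sum(axis=1) < 0, -1.0, 1.0)
    scores = u[:, :k] * s[:k] * flip
    total_var = float((s**2).sum())
    var_frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(scores, index=g.sample_ids, columns=cols), var_frac


def trait_regression(
    pc_scores: pd.Series | np.ndarray,
    trait: pd.Series | np.ndarray,
    by: pd.Series | None = None,
) -> pd.DataFrame:
    """OLS of trait on a principal component, overall and optionally per lake.

    Returns a table with slope, intercept, R^2 and F-test p-value; when
    ``by`` is given, one extra row per stratum (lake / lake system).
    """
    import statsmodels.api as sm

    x = np.asarray(pc_scores, dtype=float)
    y = np.asarray(trait, dtype=float)
    if len(x) != len(y):
        raise ValueError("predictor and trait lengths differ")

    def fit_one(xs, ys, label):
        mask = ~(np.isnan(xs) | np.isnan(ys))
        xs, ys = xs[mask], ys[mask]
        if len(xs) < 3:
            raise ValueError(f"fewer than 3 complete pairs in {label!r}")
        if np.ptp(xs) == 0:
            raise ValueError(f"zero variance in predictor in {label!r}")
        res = sm.OLS(ys, sm.add_constant(xs)).fit()
        return {
            "group": label,
            "n": int(len(xs)),
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "r_squared": float(res.rsquared),
            "p_value": float(res.f_pvalue),
        }

    rows = [fit_one(x, y, "all")]
    if by is not None:
        by = np.asarray(by)
        for lev in pd.unique(by):
            sel = by == lev
            rows.append(fit_one(x[sel], y[sel], str(lev)))
    return pd.DataFrame(rows)
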