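"""Four-taxon statistics and tree-guided excess allele-sharing.

Implements, from per-population allele-frequency tables:

* the F4 statistic, mean over SNPs of (p_A - p_B)(p_C - p_D), and the
  two-arrangement topology contrast used to ask whether sympatric ecomorph
  pairs evolved independently within lakes (support for within-lake origin
  when |F4 of the sympatric-pair arrangement| < |F4 of the ecomorph-pair
  arrangement|);
* Patterson's D and the f4-admixture ratio f(A, B; C, O) with the
  donor-into-itself denominator;
* the f-branch statistic f_b(C): for a branch b with sister clade a,
  the median over recipients B below b of the minimum over references A
  below a of f(A, B; C, O), negatives floored at zero, with combinations
  that violate the tree topology marked untestable;
* block-jackknife Z-scores (equal-SNP contiguous blocks) and the one-sided
  Bonferroni Z threshold used to flag significant cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy
from scipy.stats import norm

__all__ = [
    "GroupTree",
    "f4_stat",
    "topology_contrast",
    "d_and_f4ratio",
    "fbranch",
    "FBranchResult",
    "jackknife_z",
    "bonferroni_z_threshold",
]


class GroupTree:
    """Rooted binary tree over population labels with a designated outgroup.

    After construction the outgroup tip is a direct child of the root; the
    remaining (ingroup) topology drives f-branch enumeration.
    """

    def __init__(self, tree: dendropy.Tree, outgroup: str):
        self.tree = tree
        self.outgroup = outgroup
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        if outgroup not in labels:
            raise ValueError(f"outgroup {outgroup!r} is not a tip")
        og = [
            leaf
            for leaf in tree.leaf_node_iter()
            if leaf.taxon.label == outgroup
        ][0]
        if og.parent_node is not tree.seed_node:
            tree.to_outgroup_position(og, update_bipartitions=False)
        self._og_node = og
        for node in tree.preorder_node_iter():
            n_children = len(node.child_nodes())
            if n_children not in (0, 2):
                raise ValueError(
                    "tree must be strictly binary (resolve polytomies first)"
                )

    @classmethod
    def from_newick(cls, newick: str, outgroup: str) -> "GroupTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree, outgroup)

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def ingroup_tips(self) -> list[str]:
        return [t for t in self.tips if t != self.outgroup]

    @staticmethod
    def clade_tips(node) -> list[str]:
        return [leaf.taxon.label for leaf in node.leaf_iter()]

    def branches(self) -> list[tuple[str, list[str], list[str]]]:
        """Testable branches as (label, tips below b, tips below sister a).

        Every node except the root, the outgroup tip and the ingroup root
        (whose sister is the outgroup) is a testable branch; internal
        branches are labelled by their descendant tips joined with '+'.
        """
        out = []
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None or parent is self.tree.seed_node:
                continue
            sibling = [c for c in parent.child_nodes() if c is not node][0]
            b_tips = self.clade_tips(node)
            a_tips = self.clade_tips(sibling)
            if self.outgroup in b_tips or self.outgroup in a_tips:
                continue
            label = b_tips[0] if node.is_leaf() else "+".join(b_tips)
            out.append((label, b_tips, a_tips))
        return out


def f4_stat(
    p_a: np.ndarray, p_b: np.ndarray, p_c: np.ndarray, p_d: np.ndarray
) -> float:
    """F4(A,B;C,D) = mean over SNPs of (p_A - p_B)(p_C - p_D)."""
    p_a, p_b, p_c, p_d = (np.asarray(x, float) for x in (p_a, p_b, p_c, p_d))
    if p_a.size == 0:
        raise ValueError("no usable SNPs")
    return float(np.mean((p_a - p_b) * (p_c - p_d)))


def topology_contrast(
    balchen1: np.ndarray,
    albeli1: np.ndarray,
    balchen2: np.ndarray,
    albeli2: np.ndarray,
) -> dict:
    """F4 under the two four-taxon arrangements and the supported scenario.

    F4_1 places the sympatric pairs together, ((Balchen1, Albeli1),
    (Balchen2, Albeli2)); F4_2 pairs by ecomorph, ((Balchen1, Balchen2),
    (Albeli1, Albeli2)). A smaller |F4| indicates the more tree-like
    arrangement, so |F4_1| < |F4_2| supports independent within-lake origin
    of the ecomorph pair; the signed values are also reported.
    """
    f4_1 = f4_stat(balchen1, albeli1, balchen2, albeli2)
    f4_2 = f4_stat(balchen1, balchen2, albeli1, albeli2)
    if abs(f4_1) < abs(f4_2):
        verdict = "parallel within-lake origin"
    elif abs(f4_1) > abs(f4_2):
        verdict = "single ecomorph origin"
    else:
        verdict = "indeterminate"
    return {"F4_1": f4_1, "F4_2": f4_2, "verdict": verdict}


def _abba_baba(p_a, p_b, p_c, p_o):
    abba = (1 - p_a) * p_b * p_c * (1 - p_o)
    baba = p_a * (1 - p_b) * p_c * (1 - p_o)
    return abba, baba


def _f_denominator(p_a, p_c, p_o, n_c_alleles: int | None):
    """Per-site donor-into-itself denominator (1-pO)(pC^2 - pA pC).

    The pC^2 term is a squared sample frequency and overshoots the parametric
    value by Var(pC_hat) = pC(1-pC)/(n-1)-ish; with few sampled alleles this
    inflates the denominator and biases f toward zero, so when the donor's
    allele count ``n_c_alleles`` is known, pC^2 is replaced by its unbiased
    estimator pC^2 - pC(1-pC)/(n_c_alleles - 1).
    """
    pc2 = p_c * p_c
    if n_c_alleles is not None and n_c_alleles > 1:
        pc2 = pc2 - p_c * (1 - p_c) / (n_c_alleles - 1)
    return (1 - p_o) * (pc2 - p_a * p_c)


def d_and_f4ratio(
    p_a: np.ndarray,
    p_b: np.ndarray,
    p_c: np.ndarray,
    p_o: np.ndarray,
    n_c_alleles: int | None = None,
) -> tuple[float, float]:
    """Patterson's D and the f4-admixture ratio f(A, B; C, O).

    D = sum(ABBA - BABA) / sum(ABBA + BABA); f divides the same numerator by
    the donor-into-itself denominator (C's frequencies substituted for B's).
    When ``n_c_alleles`` (the number of alleles sampled in the donor C) is
    given, the denominator's pC^2 term uses its unbiased estimator, removing
    the small-sample attenuation of f. Returns NaN for a statistic whose
    denominator is zero.
    """
    p_a, p_b, p_c, p_o = (np.asarray(x, float) for x in (p_a, p_b, p_c, p_o))
    abba, baba = _abba_baba(p_a, p_b, p_c, p_o)
    num = float(np.sum(abba - baba))
    d_den = float(np.sum(abba + baba))
    f_den = float(np.sum(_f_denominator(p_a, p_c, p_o, n_c_alleles)))
    d = num / d_den if d_den != 0 else float("nan")
    f = num / f_den if f_den != 0 else float("nan")
    return d, f


def _block_bounds(n_snps: int, n_blocks: int) -> np.ndarray:
    """Boundaries of ``n_blocks`` contiguous, equal-SNP-count blocks."""
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n_snps < n_blocks:
        raise ValueError("fewer SNPs than jackknife blocks")
    return np.linspace(0, n_snps, n_blocks + 1).astype(int)


def jackknife_z(
    numerator: np.ndarray, denominator: np.ndarray, n_blocks: int = 20
) -> tuple[float, float, float]:
    """Delete-one-block jackknife of a ratio statistic.

    ``numerator`` and ``denominator`` are per-SNP streams in genome order;
    the statistic is sum(num) / sum(den). Returns (estimate, SE, Z). A
    degenerate zero-variance case yields Z = +/-inf with a warning.
    """
    num = np.asarray(numerator, float)
    den = np.asarray(denominator, float)
    bounds = _block_bounds(num.size, n_blocks)
    tot_num, tot_den = num.sum(), den.sum()
    est = tot_num / tot_den
    reps = np.empty(n_blocks)
    for j in range(n_blocks):
        s, e = bounds[j], bounds[j + 1]
        reps[j] = (tot_num - num[s:e].sum()) / (tot_den - den[s:e].sum())
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((reps - reps.mean()) ** 2)))
    if se == 0.0:
        warnings.warn("zero jackknife variance; Z reported as infinite")
        z = float(np.sign(est) * np.inf) if est != 0 else 0.0
    else:
        z = float(est / se)
    return float(est), se, z


def bonferroni_z_threshold(alpha: float, n_tests: int) -> float:
    """Upper-tail standard-normal quantile of alpha / n_tests, to 2 dp."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return round(float(norm.isf(alpha / n_tests)), 2)


@dataclass
class FBranchResult:
    """f-branch matrix with jackknife Z-scores.

    ``fb``: branches x donor tips, negatives floored at 0, NaN where the
    (branch, donor) combination is untestable under the tree. ``z``: the
    jackknife Z of the unfloored estimate. ``significant``: Z above the
    Bonferroni threshold. ``n_testable``: number of testable cells.
    """

    fb: pd.DataFrame
    z: pd.DataFrame
    significant: pd.DataFrame
    z_threshold: float
    n_testable: int

    def long_format(self) -> pd.DataFrame:
        rows = []
        for b in self.fb.index:
            for c in self.fb.columns:
                rows.append(
                    {
                        "branch": b,
                        "donor": c,
                        "fb": self.fb.at[b, c],
                        "z": self.z.at[b, c],
                        "significant": bool(self.significant.at[b, c]),
                    }
                )
        return pd.DataFrame(rows)


def fbranch(
    tree: GroupTree,
    freqs: pd.DataFrame,
    n_blocks: int = 20,
    alpha: float = 0.01,
    exclude_tips: list[str] | None = None,
    n_alleles: dict[str, int] | None = None,
) -> FBranchResult:
    """Compute the f-branch matrix f_b(C) over ``tree``.

    ``freqs`` holds per-SNP allele frequencies, one column per tree tip
    (including the outgroup), rows in genome order. ``exclude_tips`` drops
    tips (e.g. putative F1 hybrids) from both branches and donors. The
    Z threshold is the one-sided Bonferroni quantile of ``alpha`` over the
    number of testable cells. ``n_alleles`` optionally maps tip label to the
    number of sampled alleles (2x diploids) behind its frequency column and
    switches the f4-ratio denominators to their unbiased-pC^2 form.
    """
    excluded = set(exclude_tips or ())
    missing = set(tree.tips) - excluded - set(freqs.columns)
    if missing:
        raise ValueError(f"no frequencies for tip(s): {sorted(missing)}")
    p_o = freqs[tree.outgroup].to_numpy()
    n_snps = len(freqs)
    bounds = _block_bounds(n_snps, n_blocks)

    cache: dict[tuple[str, str, str], tuple[float, np.ndarray]] = {}

    def f_ratio_with_blocks(a: str, b: str, c: str):
        """(full f, per-delete-one-block f) for f(A,B;C,O), cached."""
        key = (a, b, c)
        if key in cache:
            return cache[key]
        p_a = freqs[a].to_numpy()
        p_b = freqs[b].to_numpy()
        p_c = freqs[c].to_numpy()
        abba, baba = _abba_baba(p_a, p_b, p_c, p_o)
        num = abba - baba
        n_c = n_alleles.get(c) if n_alleles else None
        den = _f_denominator(p_a, p_c, p_o, n_c)
        tot_num, tot_den = num.sum(), den.sum()
        full = tot_num / tot_den if tot_den != 0 else np.nan
        reps = np.empty(n_blocks)
        for j in range(n_blocks):
            s, e = bounds[j], bounds[j + 1]
            dn = tot_den - den[s:e].sum()
            reps[j] = (tot_num - num[s:e].sum()) / dn if dn != 0 else np.nan
        cache[key] = (full, reps)
        return cache[key]

    branches = [
        (label, [t for t in b_tips if t not in excluded],
         [t for t in a_tips if t not in excluded])
        for label, b_tips, a_tips in tree.branches()
    ]
    branches = [br for br in branches if br[1] and br[2]]
    donors = [t for t in tree.ingroup_tips if t not in excluded]

    fb = pd.DataFrame(np.nan, index=[b[0] for b in branches], columns=donors)
    zm = pd.DataFrame(np.nan, index=fb.index, columns=donors)
    n_testable = 0
    raw_cells = []
    for label, b_tips, a_tips in branches:
        clade = set(b_tips) | set(a_tips)
        for c in donors:
            if c in clade:
                continue  # topology violation: C must sit outside ((A,B),·)
            n_testable += 1
            full_vals = np.empty(len(b_tips))
            rep_vals = np.empty((len(b_tips), n_blocks))
            for bi, b_tip in enumerate(b_tips):
                per_a = [f_ratio_with_blocks(a, b_tip, c) for a in a_tips]
                fulls = np.array([v[0] for v in per_a])
                ai = int(np.nanargmin(fulls))
                full_vals[bi] = fulls[ai]
                rep_vals[bi] = per_a[ai][1]
            est = float(np.nanmedian(full_vals))
            reps = np.nanmedian(rep_vals, axis=0)
            se = float(
                np.sqrt(
                    (n_blocks - 1) / n_blocks * np.nansum((reps - np.nanmean(reps)) ** 2)
                )
            )
            z = est / se if se > 0 else (np.inf if est > 0 else 0.0)
            raw_cells.append((label, c, est, z))
    z_threshold = bonferroni_z_threshold(alpha, max(n_testable, 1))
    for label, c, est, z in raw_cells:
        fb.at[label, c] = max(est, 0.0)
        zm.at[label, c] = z
    sig = (zm > z_threshold) & (fb > 0)
    return FBranchResult(
        fb=fb, z=zm, significant=sig.fillna(False).astype(bool),
        z_threshold=z_threshold, n_testable=n_testable,
    )
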