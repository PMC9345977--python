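"""Genomic window tiling and interval overlap.

Windows tile each chromosome from coordinate 0 in fixed-size 0-based
half-open bins, so a SNP at 1-based VCF position ``p`` falls in window
``(p - 1) // size``. Interval overlap uses the standard half-open >= 1 bp
test; GFF intervals (1-based closed) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "WindowSet",
    "make_windows",
    "read_bed",
    "read_gff3",
    "interval_overlap",
]


@dataclass
class WindowSet:
    """Tiled, non-overlapping windows with per-window SNP index ranges.

    ``table`` has columns ``chrom, start, end`` (0-based half-open),
    ``snp_start, snp_stop`` (column range into the source GenotypeMatrix,
    half-open) and ``n_snps``. Only windows containing at least one SNP are
    emitted; every SNP belongs to exactly one window.
    """

    table: pd.DataFrame
    window_size_bp: int

    def __len__(self) -> int:
        return len(self.table)

    def snp_indices(self, i: int) -> np.ndarray:
        row = self.table.iloc[i]
        return np.arange(row["snp_start"], row["snp_stop"], dtype=int)


def make_windows(g: GenotypeMatrix, size_bp: int) -> WindowSet:
    """Tile ``g``'s loci into fixed-size windows of ``size_bp``."""
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    chrom = g.loci["chrom"].to_numpy()
    pos = g.loci["pos"].to_numpy()
    win_of_snp = (pos - 1) // size_bp
    rows = []
    j = 0
    n = len(chrom)
    while j < n:
        c, w = chrom[j], win_of_snp[j]
        k = j
        while k < n and chrom[k] == c and win_of_snp[k] == w:
            k += 1
        rows.append(
            {
                "chrom": c,
                "start": int(w) * size_bp,
                "end": (int(w) + 1) * size_bp,
                "snp_start": j,
                "snp_stop": k,
                "n_snps": k - j,
            }
        )
        j = k
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "snp_start", "snp_stop", "n_snps"]
    )
    return WindowSet(table, size_bp)


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end/name."""
    feats = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    names = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    feats["name"] = names[3] if names.shape[1] > 3 else [
        f"feature_{i}" for i in range(len(feats))
    ]
    _validate_intervals(feats)
    return feats


def read_gff3(path, feature_types: list[str] | None = None) -> pd.DataFrame:
    """Read GFF3 intervals, converting 1-based closed to 0-based half-open."""
    gff = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str},
    )
    if feature_types is not None:
        gff = gff[gff["type"].isin(feature_types)]
    feats = pd.DataFrame(
        {
            "chrom": gff["chrom"],
            "start": gff["start"].astype(int) - 1,
            "end": gff["end"].astype(int),
            "name": gff["attributes"].str.extract(r"ID=([^;]+)", expand=False)
            .fillna("feature"),
        }
    ).reset_index(drop=True)
    _validate_intervals(feats)
    return feats


def _validate_intervals(feats: pd.DataFrame) -> None:
    bad = feats[(feats["end"] <= feats["start"]) | (feats["start"] < 0)]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"malformed interval {r['chrom']}:{r['start']}-{r['end']}"
        )


def interval_overlap(
    windows: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """All (window, feature) pairs overlapping by at least 1 bp.

    Both inputs are 0-based half-open tables with chrom/start/end columns
    (``windows`` may be a :class:`WindowSet` table or an outlier subset).
    Returns one row per overlapping pair with both coordinate sets and the
    overlap length.
    """
    if isinstance(windows, WindowSet):
        windows = windows.table
    out = []
    for c, wsub in windows.groupby("chrom", sort=False):
        fsub = features[features["chrom"] == c]
        if fsub.empty:
            continue
        ws = wsub["start"].to_numpy()
        we = wsub["end"].to_numpy()
        order = np.argsort(ws, kind="stable")
        ws, we = ws[order], we[order]
        widx = wsub.index.to_numpy()[order]
        # tiled windows are sorted & non-overlapping: binary search bounds
        for fi, fs, fe in zip(fsub.index, fsub["start"], fsub["end"]):
            lo = np.searchsorted(we, fs, side="right")
            hi = np.searchsorted(ws, fe, side="left")
            for k in range(lo, hi):
                ov = min(we[k], fe) - max(ws[k], fs)
                if ov >= 1:
                    out.append(
                        {
                            "chrom": c,
                            "window_start": int(ws[k]),
                            "window_end": int(we[k]),
                            "window_index": int(widx[k]),
                            "feature_start": int(fs),
                            "feature_end": int(fe),
                            "feature_name": features.at[fi, "name"]
                            if "name" in features.columns
                            else str(fi),
                            "overlap_bp": int(ov),
                        }
                    )
    return pd.DataFrame(
        out,
        columns=["chrom", "window_start", "window_end", "window_index",
                 "feature_start", "feature_end", "feature_name", "overlap_bp"],
    )
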