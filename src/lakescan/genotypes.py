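"""Genotype data model and I/O.

The central container is :class:`GenotypeMatrix`, a dense samples x SNPs
dosage matrix (count of alternate alleles, values in {0, 1, 2}) with locus
coordinates, backed by plain numpy. Genotypes are loaded from biallelic-SNP
VCFs with complete GT fields; missing genotypes are rejected at load time
because every downstream statistic in this package assumes a zero-missingness
call set.

Coordinate conventions: VCF positions stay 1-based in ``loci``; all internal
window and tract arithmetic elsewhere in the package is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "filter_mac",
    "allele_freqs",
    "METADATA_COLUMNS",
]

#: Required columns of the sample metadata table, in canonical order.
METADATA_COLUMNS = [
    "sample",
    "lake",
    "lake_system",
    "species",
    "ecomorph",
    "sex",
    "standard_length_mm",
    "gill_raker_count",
]


@dataclass
class GenotypeMatrix:
    """Dense diploid dosage matrix with locus coordinates.

    Attributes
    ----------
    dosages
        ``(n_samples, n_snps)`` int8 array of alternate-allele counts.
    loci
        DataFrame with columns ``chrom, pos, ref, alt``; ``pos`` is 1-based
        as in the source VCF, sorted by (chrom, pos), unique per chromosome.
    sample_ids
        Sample labels in dosage row order.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if self.dosages.size and (
            self.dosages.min() < 0 or self.dosages.max() > 2
        ):
            raise ValueError("dosages must lie in {0, 1, 2}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.loci = self.loci.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self) -> None:
        chrom = self.loci["chrom"].to_numpy()
        pos = self.loci["pos"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(
                    f"loci on chromosome {c} are unsorted or duplicated"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.loci)

    def sample_indices(self, ids: list[str]) -> np.ndarray:
        """Row indices for the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to SNP columns ``idx`` (kept in order)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx], self.loci.iloc[idx], list(self.sample_ids)
        )

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        rows = self.sample_indices(ids)
        return GenotypeMatrix(self.dosages[rows], self.loci, list(ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.loci.equals(other.loci)
            and np.array_equal(self.dosages, other.dosages)
        )


def read_vcf(path) -> GenotypeMatrix:
    """Load a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Rejects multiallelic records, non-SNP alleles, missing genotypes and
    unsorted input, each with a diagnostic naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS} "
                f"(ALT={','.join(v.ALT) or '.'}); split or drop it first"
            )
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise ValueError(f"non-SNP record at {v.CHROM}:{v.POS}")
        # with gts012=True, 3 encodes an unknown genotype
        gt = v.gt_types.astype(np.int8)
        if np.any(gt == 3):
            raise ValueError(
                f"missing genotype at {v.CHROM}:{v.POS}; this pipeline "
                "requires complete genotypes (max-missing 1)"
            )
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(gt)
    vcf.close()
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    dosages = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), np.int8)
    )
    return GenotypeMatrix(dosages, loci, samples)


def write_vcf(g: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCFv4.2 file (GT field only).

    Output is deterministic: identical matrices produce byte-identical files.
    """
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    chrom = g.loci["chrom"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lakescan\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        for c in pd.unique(chrom):
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        pos = g.loci["pos"].to_numpy()
        ref = g.loci["ref"].to_numpy()
        alt = g.loci["alt"].to_numpy()
        for j in range(g.n_snps):
            gts = "\t".join(gt_strings[g.dosages[:, j]])
            fh.write(
                f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate its schema."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample id(s) in metadata: {dup}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


def filter_mac(
    g: GenotypeMatrix, subset: list[str] | None = None, min_mac: int = 1
) -> GenotypeMatrix:
    """Drop loci whose minor allele count within ``subset`` is below ``min_mac``.

    With ``min_mac=1`` this removes loci monomorphic in the subset, matching
    the conventional ``--mac 1`` site filter applied before F_ST scans.
    """
    if min_mac <= 0:
        return g
    rows = (
        np.arange(g.n_samples)
        if subset is None
        else g.sample_indices(list(subset))
    )
    if len(rows) == 0:
        raise ValueError("subset must be nonempty")
    sub = g.dosages[rows]
    alt = sub.sum(axis=0, dtype=np.int64)
    total = 2 * len(rows)
    mac = np.minimum(alt, total - alt)
    return g.take_snps(np.flatnonzero(mac >= min_mac))


def allele_freqs(
    g: GenotypeMatrix, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-group alternate-allele frequencies, one column per group.

    freq = sum of alt dosages / (2 * group size). Groups may overlap; each
    must be nonempty.
    """
    out = {}
    for label, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"group {label!r} is empty")
        rows = g.sample_indices(list(ids))
        out[label] = g.dosages[rows].sum(axis=0, dtype=np.float64) / (
            2 * len(rows)
        )
    return pd.DataFrame(out, index=g.loci.index)
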