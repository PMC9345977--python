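"""Synthetic lake-radiation genotype generator.

Emulates a replicated adaptive radiation: several lakes each holding species
assigned to ecomorph classes, with genome-wide lake-level drift under the
Balding–Nichols model, a small fraction of loci carrying parallel
ecomorph-associated allele-frequency shifts repeated across lakes, loci
divergent in a single lake only, one large-effect locus for gill-raker
count, polygenic control of standard length, and optional introgression of
donor-lake alleles into designated hybrid species. Every draw flows from a
single seeded generator in a fixed order, so a seed fully determines the
output (including the emitted VCF bytes).

Two origin modes set which split is deep:

* ``parallel`` (default) — lakes diverge first (drift parameter
  ``fst_lake``), ecomorphs within each lake then differ only through the
  selected-locus frequency shifts plus optional within-lake species drift.
* ``single`` — ecomorphs diverge first (one origin of each ecomorph, drift
  ``fst_lake`` between ecomorphs) and then sort into lakes with drift
  ``fst_species``.

The generator is frequency-level by design: no coalescent, recombination or
sequence realism. Ground truth (locus classes, shift signs, causal effects,
introgressed tracts, latent trait values) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_radiation",
    "write_truth",
    "read_truth",
    "GILL_RAKER_BASELINE",
    "STANDARD_LENGTH_BASELINE",
]

#: Mean gill-raker counts per ecomorph; ordered Balchen < Felchen < Albeli,
#: matching the benthic-to-zooplanktivorous feeding axis.
GILL_RAKER_BASELINE = {
    "Balchen": 24.0,
    "Felchen": 32.0,
    "Albeli": 40.0,
    "large-pelagic": 36.0,
    "benthic-profundal": 20.0,
    "pelagic-profundal": 38.0,
}

#: Mean standard length (mm) per ecomorph; Balchen largest, Albeli smallest.
STANDARD_LENGTH_BASELINE = {
    "Balchen": 420.0,
    "Felchen": 330.0,
    "Albeli": 250.0,
    "large-pelagic": 450.0,
    "benthic-profundal": 280.0,
    "pelagic-profundal": 300.0,
}

GILL_RAKER_MIN = 12
ECOMORPHS = list(GILL_RAKER_BASELINE)


def _default_lakes() -> list[str]:
    return ["Brienz", "Lucerne", "Walen", "Neuchatel"]


def _default_ecomorphs(lakes: list[str]) -> dict[str, list[str]]:
    return {lake: ["Balchen", "Albeli"] for lake in lakes}


@dataclass
class SimConfig:
    """Parameters of one simulated radiation. Defaults give the study-like
    four-lake, two-ecomorph, 24-fish contrast panel."""

    lakes: list[str] = field(default_factory=_default_lakes)
    ecomorphs_per_lake: dict[str, list[str]] | None = None
    n_per_species: int = 3
    n_chromosomes: int = 4
    snps_per_chromosome: int = 5_000
    chrom_length_bp: int = 2_500_000
    fst_lake: float = 0.10
    fst_species: float = 0.0
    prop_parallel_loci: float = 0.01
    parallel_shift: float = 0.8
    prop_lake_specific_loci: float = 0.01
    lake_specific_shift: float = 0.8
    # selected loci come in contiguous runs of this many SNPs, emulating the
    # linked haplotype blocks that divergence hitchhiking produces
    selected_cluster_snps: int = 25
    # contrast ecomorphs get opposite frequency shifts at parallel loci
    ecomorph_shift_direction: dict[str, float] | None = None
    large_effect_locus: tuple[str, int, float] | None = ("chr1", 1_250_000, 4.0)
    large_effect_freq_shift: float = 0.8
    polygenic_trait_params: tuple[int, float, float] = (100, 3.0, 15.0)
    # fraction of the ecomorph gill-raker baseline difference NOT mediated by
    # the large-effect locus; most of the divergence runs through the locus,
    # which is what lets a single-SNP scan find it on top of ecomorph structure
    gill_raker_ecomorph_scale: float = 0.25
    introgression_events: list[tuple[str, str, float, int]] = field(
        default_factory=list
    )
    origin: str = "parallel"
    n_outgroup: int = 4
    fst_outgroup: float = 0.35
    gill_raker_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ecomorphs_per_lake is None:
            self.ecomorphs_per_lake = _default_ecomorphs(self.lakes)
        if self.ecomorph_shift_direction is None:
            self.ecomorph_shift_direction = {"Balchen": -1.0, "Albeli": 1.0}
        if self.prop_parallel_loci + self.prop_lake_specific_loci > 1:
            raise ValueError("locus-class fractions exceed 1")
        if self.origin not in ("parallel", "single"):
            raise ValueError("origin must be 'parallel' or 'single'")
        if not 0 <= self.fst_lake < 1:
            raise ValueError("fst_lake must lie in [0, 1)")
        for eco_list in self.ecomorphs_per_lake.values():
            unknown = set(eco_list) - set(ECOMORPHS)
            if unknown:
                raise ValueError(f"unknown ecomorph(s): {sorted(unknown)}")
        if self.large_effect_locus is not None:
            chrom, pos, _eff = self.large_effect_locus
            if not 1 <= pos <= self.chrom_length_bp:
                raise ValueError("large-effect locus position outside chromosome")
        for donor, _recipient, frac, tract_len in self.introgression_events:
            if donor not in self.lakes:
                raise ValueError(f"unknown donor lake {donor!r}")
            if not 0 < frac <= 1:
                raise ValueError("tract fraction must lie in (0, 1]")
            if tract_len > self.chrom_length_bp:
                raise ValueError("tract length exceeds chromosome length")

    @property
    def species(self) -> list[str]:
        return [
            f"{lake}_{eco}"
            for lake in self.lakes
            for eco in self.ecomorphs_per_lake[lake]
        ]

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimTruth:
    """Ground truth of one simulated radiation.

    ``loci``: per-SNP chrom, pos, locus_class in {neutral, parallel,
    lake_specific, large_effect, polygenic}, shift_sign (the global per-locus
    sign of the ecomorph contrast shift) and lake (for lake-specific loci).
    ``tracts``: per recipient sample, 0-based half-open introgressed
    intervals with their donor lake. ``traits``: latent (noise-free is not
    stored; these are the realized values) per-sample trait values and the
    polygenic score.
    """

    loci: pd.DataFrame
    tracts: pd.DataFrame
    traits: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimTruth):
            return NotImplemented
        return (
            self.loci.equals(other.loci)
            and self.tracts.equals(other.tracts)
            and self.traits.equals(other.traits)
        )


def _truncated_beta(rng, a, b, lo, hi, size):
    """Beta(a, b) truncated (by rejection) to [lo, hi]."""
    out = rng.beta(a, b, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _clustered_runs(
    rng, n_snps: int, snps_per_chrom: int, sizes: tuple[int, ...], run_len: int
) -> list[np.ndarray]:
    """Disjoint sets of SNP indices drawn as contiguous within-chromosome runs.

    Selected loci are not scattered singletons: divergence hitchhiking makes
    them arrive in linked blocks, so each class is laid down as runs of
    ``run_len`` consecutive SNPs (never crossing a chromosome boundary).
    """
    taken = np.zeros(n_snps, dtype=bool)
    out: list[np.ndarray] = []
    for size in sizes:
        picked: list[int] = []
        attempts = 0
        while len(picked) < size:
            attempts += 1
            if attempts > 10_000 * max(size, 1):
                raise ValueError("cannot place selected-locus runs; too dense")
            want = min(run_len, size - len(picked))
            start = int(rng.integers(0, n_snps))
            chrom_start = (start // snps_per_chrom) * snps_per_chrom
            end = min(start + want, chrom_start + snps_per_chrom)
            if np.any(taken[start:end]):
                continue
            taken[start:end] = True
            picked.extend(range(start, end))
        out.append(np.sort(np.array(picked, dtype=int)))
    return out


def _balding_nichols(rng, p0: np.ndarray, f: float) -> np.ndarray:
    """Draw descendant frequencies around p0 with drift parameter f."""
    if f <= 0:
        return p0.copy()
    a = p0 * (1 - f) / f
    b = (1 - p0) * (1 - f) / f
    return rng.beta(a, b)


def simulate_radiation(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Generate (genotypes, sample metadata, ground truth) for one radiation."""
    rng = np.random.default_rng(config.seed)
    chroms = config.chromosomes
    s_per = config.snps_per_chromosome
    n_snps = s_per * config.n_chromosomes

    # -- loci ---------------------------------------------------------------
    chrom_col = np.repeat(chroms, s_per)
    pos_col = np.concatenate(
        [
            np.sort(
                rng.choice(config.chrom_length_bp, size=s_per, replace=False)
            )
            + 1
            for _ in chroms
        ]
    )
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_snps)]
    alt_offset = rng.integers(1, 4, size=n_snps)
    alt = bases[(np.searchsorted(bases, ref) + alt_offset) % 4]

    # -- locus classes ------------------------------------------------------
    locus_class = np.full(n_snps, "neutral", dtype=object)
    shift_sign = np.zeros(n_snps)
    lake_of_locus = np.full(n_snps, "", dtype=object)

    n_parallel = int(round(config.prop_parallel_loci * n_snps))
    n_lake_specific = int(round(config.prop_lake_specific_loci * n_snps))
    parallel_idx, lake_specific_idx = _clustered_runs(
        rng, n_snps, s_per, (n_parallel, n_lake_specific),
        config.selected_cluster_snps,
    )
    locus_class[parallel_idx] = "parallel"
    locus_class[lake_specific_idx] = "lake_specific"
    shift_sign[parallel_idx] = rng.choice([-1.0, 1.0], size=n_parallel)
    shift_sign[lake_specific_idx] = rng.choice([-1.0, 1.0], size=n_lake_specific)
    lake_of_locus[lake_specific_idx] = rng.choice(
        config.lakes, size=n_lake_specific
    )

    large_idx = -1
    if config.large_effect_locus is not None:
        le_chrom, le_pos, le_effect = config.large_effect_locus
        on_chrom = np.flatnonzero(chrom_col == le_chrom)
        if len(on_chrom) == 0:
            raise ValueError(f"large-effect chromosome {le_chrom!r} has no SNPs")
        large_idx = int(on_chrom[np.argmin(np.abs(pos_col[on_chrom] - le_pos))])
        locus_class[large_idx] = "large_effect"
        shift_sign[large_idx] = 1.0
        lake_of_locus[large_idx] = ""

    n_causal, poly_effect_sd, poly_resid_sd = config.polygenic_trait_params
    neutral_pool = np.flatnonzero(locus_class == "neutral")
    causal_idx = np.sort(
        rng.choice(neutral_pool, size=min(n_causal, len(neutral_pool)), replace=False)
    )
    locus_class[causal_idx] = "polygenic"
    poly_effects = rng.normal(0.0, poly_effect_sd, size=len(causal_idx))

    # -- population frequencies --------------------------------------------
    p0 = _truncated_beta(rng, 0.8, 0.8, 0.05, 0.95, n_snps)
    species = config.species
    sp_lake = {sp: sp.rsplit("_", 1)[0] for sp in species}
    sp_eco = {sp: sp.rsplit("_", 1)[1] for sp in species}

    if config.origin == "parallel":
        lake_freq = {
            lake: _balding_nichols(rng, p0, config.fst_lake)
            for lake in config.lakes
        }
        species_freq = {
            sp: _balding_nichols(rng, lake_freq[sp_lake[sp]], config.fst_species)
            for sp in species
        }
    else:  # single origin: ecomorph split is the deep one
        all_ecos = sorted({e for sp in species for e in [sp_eco[sp]]})
        eco_freq = {
            eco: _balding_nichols(rng, p0, config.fst_lake) for eco in all_ecos
        }
        lake_freq = {
            lake: _balding_nichols(rng, p0, config.fst_lake)
            for lake in config.lakes
        }  # drawn (and consumed from the stream) but only used for donors
        species_freq = {
            sp: _balding_nichols(rng, eco_freq[sp_eco[sp]], config.fst_species)
            for sp in species
        }
    outgroup_freq = _balding_nichols(rng, p0, config.fst_outgroup)

    # ecomorph-contrast shifts at selected loci
    direction = config.ecomorph_shift_direction
    gr_vals = np.array([GILL_RAKER_BASELINE[e] for e in ECOMORPHS])
    gr_mid = float(np.median(gr_vals))
    for sp in species:
        eco = sp_eco[sp]
        d_eco = direction.get(eco, 0.0)
        f = species_freq[sp]
        if d_eco != 0.0:
            at = parallel_idx
            f[at] = np.clip(
                f[at] + shift_sign[at] * d_eco * config.parallel_shift / 2, 0, 1
            )
            mine = lake_specific_idx[
                lake_of_locus[lake_specific_idx] == sp_lake[sp]
            ]
            f[mine] = np.clip(
                f[mine]
                + shift_sign[mine] * d_eco * config.lake_specific_shift / 2,
                0,
                1,
            )
        if large_idx >= 0:
            # alt allele raises gill-raker count: push it up in high-raker
            # ecomorphs, down in low-raker ones (Fig-style frequency ladder)
            d_gr = np.sign(GILL_RAKER_BASELINE[eco] - gr_mid) or 0.5
            f[large_idx] = np.clip(
                f[large_idx] + d_gr * config.large_effect_freq_shift / 2, 0, 1
            )
        species_freq[sp] = f

    # -- samples and genotypes ----------------------------------------------
    sample_ids: list[str] = []
    meta_rows = []
    dosage_rows = []
    for sp in species:
        for i in range(config.n_per_species):
            sid = f"{sp}_{i + 1}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "lake": sp_lake[sp],
                    "lake_system": sp_lake[sp],
                    "species": sp,
                    "ecomorph": sp_eco[sp],
                }
            )
            dosage_rows.append(
                rng.binomial(2, species_freq[sp]).astype(np.int8)
            )
    for i in range(config.n_outgroup):
        sid = f"outgroup_{i + 1}"
        sample_ids.append(sid)
        meta_rows.append(
            {
                "sample": sid,
                "lake": "outgroup",
                "lake_system": "outgroup",
                "species": "outgroup",
                "ecomorph": "outgroup",
            }
        )
        dosage_rows.append(rng.binomial(2, outgroup_freq).astype(np.int8))
    dosages = np.stack(dosage_rows)

    # -- introgression: tract-level allele replacement ----------------------
    pos_per_chrom = {c: pos_col[chrom_col == c] for c in chroms}
    tract_rows = []
    for donor, recipient, frac, tract_len in config.introgression_events:
        if recipient not in species:
            raise ValueError(f"unknown recipient species {recipient!r}")
        genome_len = config.n_chromosomes * config.chrom_length_bp
        n_tracts = max(1, int(round(frac * genome_len / tract_len)))
        slots_per_chrom = config.chrom_length_bp // tract_len
        all_slots = config.n_chromosomes * slots_per_chrom
        if n_tracts > all_slots:
            raise ValueError("tract fraction/length combination does not fit")
        slots = np.sort(rng.choice(all_slots, size=n_tracts, replace=False))
        donor_p = (
            lake_freq[donor] if config.origin == "parallel" else lake_freq[donor]
        )
        rec_rows = [
            k for k, m in enumerate(meta_rows) if m["species"] == recipient
        ]
        snp_mask = np.zeros(n_snps, dtype=bool)
        for slot in slots:
            ci = int(slot // slots_per_chrom)
            c = chroms[ci]
            start = int(slot % slots_per_chrom) * tract_len
            end = start + tract_len
            base = ci * s_per
            p = pos_per_chrom[c]
            lo = base + int(np.searchsorted(p, start + 1, side="left"))
            hi = base + int(np.searchsorted(p, end, side="right"))
            snp_mask[lo:hi] = True
            for k in rec_rows:
                tract_rows.append(
                    {
                        "sample": sample_ids[k],
                        "chrom": c,
                        "start": start,
                        "end": end,
                        "donor_lake": donor,
                    }
                )
        in_tract = np.flatnonzero(snp_mask)
        for k in rec_rows:
            dosages[k, in_tract] = rng.binomial(
                2, donor_p[in_tract]
            ).astype(np.int8)

    # -- phenotypes ----------------------------------------------------------
    meta = pd.DataFrame(meta_rows)
    n_samples = len(sample_ids)
    sex = rng.choice(["M", "F"], size=n_samples)
    poly_dos = dosages[:, causal_idx].astype(np.float64)
    poly_score = (poly_dos - 2 * p0[causal_idx]) @ poly_effects
    length = np.array(
        [
            STANDARD_LENGTH_BASELINE.get(e, 300.0)
            for e in meta["ecomorph"]
        ]
    )
    length = length + poly_score + rng.normal(0.0, poly_resid_sd, size=n_samples)
    gr_base = np.array(
        [GILL_RAKER_BASELINE.get(e, 30.0) for e in meta["ecomorph"]]
    )
    gr = gr_mid + config.gill_raker_ecomorph_scale * (gr_base - gr_mid)
    if large_idx >= 0:
        _, _, le_effect = config.large_effect_locus
        gr = gr + le_effect * (dosages[:, large_idx].astype(float) - 1.0)
    gr = gr + rng.normal(0.0, config.gill_raker_noise_sd, size=n_samples)
    gill_rakers = np.maximum(np.rint(gr), GILL_RAKER_MIN).astype(int)

    meta["sex"] = sex
    meta["standard_length_mm"] = np.round(length, 1)
    meta["gill_raker_count"] = gill_rakers

    loci = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col, "ref": ref, "alt": alt}
    )
    g = GenotypeMatrix(dosages, loci, sample_ids)

    truth_loci = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos_col,
            "locus_class": locus_class,
            "shift_sign": shift_sign,
            "lake": lake_of_locus,
        }
    )
    tracts = pd.DataFrame(
        tract_rows, columns=["sample", "chrom", "start", "end", "donor_lake"]
    )
    traits = pd.DataFrame(
        {
            "sample": sample_ids,
            "polygenic_score": np.round(poly_score, 4),
            "standard_length_mm": meta["standard_length_mm"],
            "gill_raker_count": gill_rakers,
        }
    )
    truth = SimTruth(loci=truth_loci, tracts=tracts, traits=traits)
    return g, meta, truth


def write_truth(truth: SimTruth, prefix) -> list[str]:
    """Write truth tables as TSVs ``<prefix>.loci/tracts/traits.tsv``."""
    paths = []
    for name, df in (
        ("loci", truth.loci),
        ("tracts", truth.tracts),
        ("traits", truth.traits),
    ):
        path = f"{prefix}.{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_truth(prefix) -> SimTruth:
    """Read truth tables written by :func:`write_truth` (lossless round-trip)."""
    loci = pd.read_csv(
        f"{prefix}.loci.tsv", sep="\t",
        dtype={"chrom": str, "locus_class": str},
        keep_default_na=False,
    )
    tracts = pd.read_csv(
        f"{prefix}.tracts.tsv", sep="\t",
        dtype={"sample": str, "chrom": str, "donor_lake": str},
    )
    traits = pd.read_csv(f"{prefix}.traits.tsv", sep="\t", dtype={"sample": str})
    return SimTruth(loci=loci, tracts=tracts, traits=traits)
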