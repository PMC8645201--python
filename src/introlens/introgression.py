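"""Allele-frequency Patterson's D per species triad.

The test takes a four-taxon pectinate arrangement ((P1, P2), P3), O and asks
whether derived alleles are shared between P2 and P3 (ABBA) more or less
often than between P1 and P3 (BABA).  With derived-allele frequencies
p1, p2, p3, p4 per site, sites contribute frequency-weighted pattern counts

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)

and D = (sum(abba) - sum(baba)) / (sum(abba) + sum(baba)).  D is 0 in
expectation under incomplete lineage sorting alone and is pushed positive
(negative) by P3<->P2 (P3<->P1) introgression.  Significance comes from a
locus bootstrap: loci are resampled with replacement, D recomputed, and the
observed D divided by the bootstrap standard deviation to give a Z-score
whose two-sided normal tail is the p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlleleFreqMatrix",
    "DResult",
    "InsufficientSitesError",
    "polarize_to_derived",
    "read_freq_tsv",
    "read_triad_vcf",
    "site_pattern_weights",
    "informative_mask",
    "select_informative_sites",
    "d_statistic",
    "bootstrap_z",
    "analyze_triad",
]

TAXON_COLUMNS = ("p1", "p2", "p3", "out")


class InsufficientSitesError(ValueError):
    """Requested subsample exceeds the number of informative sites."""


@dataclass
class AlleleFreqMatrix:
    """Sites x 4 derived-allele frequencies with locus bookkeeping.

    ``freqs`` has columns (p1, p2, p3, outgroup) in [0, 1]; ``locus_ids``
    and ``positions`` give each site's locus and 0-based offset.
    """

    freqs: np.ndarray
    locus_ids: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.locus_ids = np.asarray(self.locus_ids)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("freqs must be an (n_sites, 4) array")
        if len(self.locus_ids) != len(self.freqs) or len(self.positions) != len(self.freqs):
            raise ValueError("locus_ids/positions must match the number of sites")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freqs, initial=0.0) < 0 or np.nanmax(self.freqs, initial=0.0) > 1:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.freqs)

    @property
    def n_loci(self) -> int:
        return len(np.unique(self.locus_ids))

    def subset(self, index: np.ndarray) -> "AlleleFreqMatrix":
        return AlleleFreqMatrix(
            self.freqs[index], self.locus_ids[index], self.positions[index]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, columns=list(TAXON_COLUMNS))
        df.insert(0, "locus_id", self.locus_ids)
        df.insert(1, "site", self.positions)
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_freq_tsv(path: str) -> AlleleFreqMatrix:
    """Read a frequency table with columns locus_id, site, p1, p2, p3, out."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("locus_id", "site", *TAXON_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return AlleleFreqMatrix(
        df[list(TAXON_COLUMNS)].to_numpy(float),
        df["locus_id"].to_numpy(),
        df["site"].to_numpy(int),
    )


def polarize_to_derived(
    alt_counts: np.ndarray,
    called_alleles: np.ndarray,
    locus_ids: np.ndarray,
    positions: np.ndarray,
) -> tuple[AlleleFreqMatrix, dict[str, int]]:
    """Polarize biallelic calls into derived-allele frequencies.

    ``alt_counts`` and ``called_alleles`` are (n_sites, 4) integer arrays of
    alternate-allele counts and total called alleles per taxon, columns
    ordered (p1, p2, p3, outgroup).  The ancestral allele at each site is
    the outgroup's major allele; sites where the outgroup is at exactly 50/50
    (polarization undefined) or where any taxon has no called allele are
    excluded.  Returns the matrix and a counter of exclusions.
    """
    alt_counts = np.asarray(alt_counts, float)
    called = np.asarray(called_alleles, float)
    if alt_counts.shape != called.shape or alt_counts.shape[1] != 4:
        raise ValueError("alt_counts and called_alleles must be (n_sites, 4)")
    n = len(alt_counts)
    any_missing = (called == 0).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(called > 0, alt_counts / np.maximum(called, 1), np.nan)
    out_freq = alt_freq[:, 3]
    tie = ~any_missing & (out_freq == 0.5)
    keep = ~any_missing & ~tie
    counters = {
        "n_input": n,
        "n_missing_taxon": int(any_missing.sum()),
        "n_outgroup_tie": int(tie.sum()),
        "n_used": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError("all sites excluded during polarization")
    alt_is_derived = out_freq[keep] < 0.5
    freqs = np.where(alt_is_derived[:, None], alt_freq[keep], 1.0 - alt_freq[keep])
    m = AlleleFreqMatrix(
        freqs, np.asarray(locus_ids)[keep], np.asarray(positions)[keep]
    )
    return m, counters


def read_triad_vcf(
    path: str, sample_map: dict[str, str]
) -> tuple[AlleleFreqMatrix, dict[str, int]]:
    """Read one diploid individual per taxon from a VCF and polarize.

    ``sample_map`` maps the roles ``p1, p2, p3, out`` to VCF sample names.
    Only biallelic SNPs are used; indels and multiallelic records are
    skipped and counted.  The VCF CHROM field is taken as the locus id.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    order = [vcf.samples.index(sample_map[role]) for role in TAXON_COLUMNS]
    alt_rows, called_rows, loci, pos = [], [], [], []
    skipped = {"n_not_snp": 0, "n_multiallelic": 0}
    for var in vcf:
        if not var.is_snp:
            skipped["n_not_snp"] += 1
            continue
        if len(var.ALT) != 1:
            skipped["n_multiallelic"] += 1
            continue
        alts, calleds = [], []
        for i in order:
            gt = var.genotypes[i]
            alleles = [a for a in gt[:2] if a >= 0]
            alts.append(sum(1 for a in alleles if a == 1))
            calleds.append(len(alleles))
        alt_rows.append(alts)
        called_rows.append(calleds)
        loci.append(var.CHROM)
        pos.append(var.POS - 1)
    if not alt_rows:
        raise ValueError(f"{path}: no usable biallelic SNPs")
    m, counters = polarize_to_derived(
        np.array(alt_rows), np.array(called_rows), np.array(loci), np.array(pos)
    )
    counters.update(skipped)
    return m, counters


def site_pattern_weights(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted ABBA and BABA contributions per site."""
    freqs = np.atleast_2d(np.asarray(freqs, float))
    p1, p2, p3, p4 = freqs.T
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def informative_mask(m: AlleleFreqMatrix) -> np.ndarray:
    """Sites carrying any ABBA/BABA weight (abba + baba > 0)."""
    abba, baba = site_pattern_weights(m.freqs)
    return (abba + baba) > 0


def select_informative_sites(
    m: AlleleFreqMatrix, n: int | None, seed: int | np.random.Generator | None = None
) -> AlleleFreqMatrix:
    """Restrict to informative sites; optionally subsample *n* of them.

    Subsampling is uniform without replacement with the given seed.  ``n``
    of ``None`` keeps all informative sites.  Raises
    :class:`InsufficientSitesError` when fewer than *n* are available;
    pipeline callers record the triad as dropped rather than aborting.
    """
    idx = np.flatnonzero(informative_mask(m))
    if n is not None:
        if n > len(idx):
            raise InsufficientSitesError(
                f"requested {n} informative sites, only {len(idx)} available"
            )
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        idx = np.sort(rng.choice(idx, size=n, replace=False))
    return m.subset(idx)


def d_statistic(m: AlleleFreqMatrix) -> float:
    """Patterson's D over all sites; NaN if no site carries weight."""
    abba, baba = site_pattern_weights(m.freqs)
    denom = abba.sum() + baba.sum()
    if denom == 0:
        return math.nan
    return float((abba.sum() - baba.sum()) / denom)


@dataclass(frozen=True)
class DResult:
    """Per-triad D-statistic with locus-bootstrap significance."""

    triad_id: str
    d: float
    sd_boot: float
    z: float
    p: float
    n_sites_used: int
    n_loci_used: int
    subsample_size: int | None  # None means "all informative sites"
    seed: int | None
    alpha: float = 0.05
    counters: dict = field(default_factory=dict, compare=False)

    @property
    def significant(self) -> bool:
        return (not math.isnan(self.p)) and self.p < self.alpha

    @staticmethod
    def tsv_header() -> str:
        return (
            "triad_id\tsubsample_size\td\tsd_boot\tz\tp"
            "\tn_sites_used\tn_loci_used\tseed\tsignificant"
        )

    def tsv_row(self) -> str:
        size = "all" if self.subsample_size is None else str(self.subsample_size)
        return (
            f"{self.triad_id}\t{size}\t{self.d:.6g}\t{self.sd_boot:.6g}"
            f"\t{self.z:.6g}\t{self.p:.6g}\t{self.n_sites_used}"
            f"\t{self.n_loci_used}\t{self.seed}\t{int(self.significant)}"
        )


def z_to_pvalue(z: float) -> float:
    """Two-sided standard-normal tail probability of a Z-score."""
    if math.isnan(z):
        return math.nan
    return float(2.0 * stats.norm.sf(abs(z)))


def bootstrap_z(
    m: AlleleFreqMatrix,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    triad_id: str = "",
    subsample_size: int | None = None,
    record_seed: int | None = None,
) -> DResult:
    """D with locus-bootstrap SD, Z-score and two-sided normal p-value.

    The resampling unit is the locus: each replicate draws ``n_loci`` loci
    with replacement (multiplicity respected) and recomputes D from their
    per-locus ABBA/BABA sums.  If all replicates agree exactly the Z and p
    are NaN (flagged undefined); a single locus cannot be bootstrapped.
    """
    abba, baba = site_pattern_weights(m.freqs)
    loci, inverse = np.unique(m.locus_ids, return_inverse=True)
    if len(loci) < 2:
        raise ValueError("cannot bootstrap one locus")
    locus_abba = np.bincount(inverse, weights=abba, minlength=len(loci))
    locus_baba = np.bincount(inverse, weights=baba, minlength=len(loci))
    d = d_statistic(m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.integers(0, len(loci), size=(n_boot, len(loci)))
    rep_abba = locus_abba[draws].sum(axis=1)
    rep_baba = locus_baba[draws].sum(axis=1)
    denom = rep_abba + rep_baba
    with np.errstate(invalid="ignore", divide="ignore"):
        reps = np.where(denom > 0, (rep_abba - rep_baba) / np.maximum(denom, 1e-300), np.nan)
    sd = float(np.nanstd(reps, ddof=1))
    if sd > 0 and not math.isnan(d):
        z = d / sd
        p = z_to_pvalue(z)
    else:
        z = p = math.nan
    return DResult(
        triad_id=triad_id,
        d=d,
        sd_boot=sd,
        z=z,
        p=p,
        n_sites_used=m.n_sites,
        n_loci_used=len(loci),
        subsample_size=subsample_size,
        seed=record_seed,
        alpha=alpha,
    )


def analyze_triad(
    triad_id: str,
    m: AlleleFreqMatrix,
    subsample_size: int | None = None,
    seed: int | None = None,
    n_boot: int = 100,
    alpha: float = 0.05,
) -> DResult:
    """Full per-triad pipeline: informative-site selection, subsampling, D, bootstrap.

    ``m`` must already be polarized (derived-allele frequencies).  Positive
    D indicates excess P2-P3 allele sharing (ABBA), negative excess P1-P3
    sharing (BABA).  Raises :class:`InsufficientSitesError` when the triad
    has too few informative sites for the requested subsample.
    """
    rng = np.random.default_rng(seed)
    selected = select_informative_sites(m, subsample_size, rng)
    return bootstrap_z(
        selected,
        n_boot=n_boot,
        seed=rng,
        alpha=alpha,
        triad_id=triad_id,
        subsample_size=subsample_size,
        record_seed=seed,
    )
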