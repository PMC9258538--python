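"""Genotype containers, QC filters, LD utilities and genomic relationship matrices.

SNP genotypes are held in additive coding (0/1/2 copies of the alternate
allele, ``nan`` for missing) together with a marker map.  All quality-control
steps used upstream of association — minor-allele-frequency filtering, greedy
LD pruning — and the additive/dominance genomic relationship matrices
(VanRaden form) live here, as does the LD-decay distance estimate that sets
the half-width of QTL intervals.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "filter_maf",
    "prune_ld",
    "kinship_additive",
    "kinship_dominance",
    "ld_decay_distance",
]

#: distance returned by :func:`ld_decay_distance` when decay never crosses
#: the target r-squared (bp)
DEFAULT_LD_DECAY_FALLBACK = 50_000


@dataclasses.dataclass
class GenotypeMatrix:
    """N x P additive-coded SNP genotypes with a marker map.

    Parameters
    ----------
    values
        ``(n_samples, n_snps)`` float array of alternate-allele counts in
        {0, 1, 2}; ``nan`` marks a missing call.
    sample_ids
        Sample identifiers, length ``n_samples``.
    markers
        Per-SNP table with columns ``id``, ``chrom``, ``pos`` (1-based bp),
        ``ref``, ``alt``.  Positions must be strictly increasing within a
        chromosome.
    """

    values: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (samples x SNPs) array")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match values rows")
        if self.values.shape[1] != len(self.markers):
            raise ValueError("markers length does not match values columns")
        self.markers = self.markers.reset_index(drop=True)
        for _, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP (in [0, 0.5])."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Copy of ``values`` with missing calls replaced by the SNP mean."""
        out = self.values.copy()
        if np.isnan(out).any():
            col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(out))
            out[idx] = col_mean[idx[1]]
        return out

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset SNP columns, preserving order."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[:, index],
            list(self.sample_ids),
            self.markers.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[index, :],
            [self.sample_ids[i] for i in index],
            self.markers.copy(),
        )


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into additive coding.

    Multi-allelic and non-SNP records are skipped (a count is logged);
    ``./.`` genotypes become ``nan``.  Raises ``ValueError`` on malformed
    input.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports the offending position itself
        raise ValueError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.array([g[:2] for g in var.genotypes], dtype=float)
        dose = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1))
        rows.append(dose)
        meta.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    markers = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    values = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    gm = GenotypeMatrix(values, samples, markers)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a minimal unphased VCF 4.2 (GT field only)."""
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for j, m in geno.markers.iterrows():
            calls = [
                "./." if np.isnan(v) else gt_code[float(v)]
                for v in geno.values[:, j]
            ]
            fh.write(f"{m['chrom']}\t{m['pos']}\t{m['id']}\t{m['ref']}\t{m['alt']}"
                     "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_maf(geno: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor-allele frequency >= ``threshold``.

    The boundary is inclusive: a SNP with MAF exactly at the threshold is
    retained (only frequencies strictly below the threshold are discarded).
    """
    maf = geno.maf()
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= threshold)[0]
    return geno.take_snps(keep)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype vectors (composite LD)."""
    va, vb = a - a.mean(), b - b.mean()
    denom = np.sqrt((va @ va) * (vb @ vb))
    if denom == 0:
        return 0.0
    return float((va @ vb) / denom) ** 2


def prune_ld(
    geno: GenotypeMatrix,
    r2_threshold: float = 0.9,
    window: int = 500_000,
) -> GenotypeMatrix:
    """Greedy positional LD pruning.

    Scanning left to right within each chromosome, a SNP is dropped when its
    r-squared with any *kept* SNP at most ``window`` bp upstream exceeds
    ``r2_threshold`` (keep-first convention).  Idempotent: pruning an already
    pruned set removes nothing.
    """
    vals = geno.imputed()
    chrom = geno.markers["chrom"].to_numpy()
    pos = geno.markers["pos"].to_numpy()
    keep: list[int] = []
    kept_by_chrom: dict = {}
    for j in range(geno.n_snps):
        kept = kept_by_chrom.setdefault(chrom[j], [])
        drop = False
        for i in reversed(kept):
            if pos[j] - pos[i] > window:
                break
            if _pairwise_r2(vals[:, i], vals[:, j]) > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(j)
            keep.append(j)
    return geno.take_snps(np.array(sorted(keep), dtype=int))


# ---------------------------------------------------------------------------
# Genomic relationship matrices
# ---------------------------------------------------------------------------

def kinship_additive(geno: GenotypeMatrix, ld_prune_r2: float | None = None) -> np.ndarray:
    """Additive genomic relationship matrix (VanRaden).

    ``A = W W' / (2 sum_k p_k (1 - p_k))`` with ``W`` the genotype matrix
    centered by twice the allele frequency.  Missing calls are mean-imputed
    per SNP.  ``ld_prune_r2`` optionally prunes the SNP set first (the
    estimator assumes linkage equilibrium; a 0.5 threshold is conventional
    here).
    """
    if ld_prune_r2 is not None:
        geno = prune_ld(geno, r2_threshold=ld_prune_r2)
    m = geno.imputed()
    p = m.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: additive relationship undefined")
    w = m - 2.0 * p
    return (w @ w.T) / denom


def kinship_dominance(geno: GenotypeMatrix, ld_prune_r2: float | None = None) -> np.ndarray:
    """Dominance genomic relationship matrix (classical parameterization).

    Genotype counts {0, 1, 2} are recoded per SNP to {-2p^2, 2pq, -2q^2}
    and the cross-product is scaled by ``sum_k (2 p_k q_k)^2``; under
    Hardy-Weinberg proportions the diagonal averages 1.
    """
    if ld_prune_r2 is not None:
        geno = prune_ld(geno, r2_threshold=ld_prune_r2)
    m = geno.imputed()
    p = m.mean(axis=0) / 2.0
    q = 1.0 - p
    denom = np.sum((2.0 * p * q) ** 2)
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: dominance relationship undefined")
    # piecewise recode; fractional dosages from mean imputation are
    # interpolated linearly between the adjacent genotype codes
    low = -2.0 * p**2
    mid = 2.0 * p * q
    high = -2.0 * q**2
    frac = np.clip(m, 0.0, 2.0)
    h = np.where(
        frac <= 1.0,
        low + (mid - low) * frac,
        mid + (high - mid) * (frac - 1.0),
    )
    return (h @ h.T) / denom


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay_distance(
    geno: GenotypeMatrix,
    r2_target: float = 0.2,
    n_pairs: int = 20_000,
    seed: int | None = None,
    n_bins: int = 20,
    max_distance: int = 1_000_000,
    fallback: int = DEFAULT_LD_DECAY_FALLBACK,
    exclude_chroms: tuple[str, ...] = ("Un", "unknown", "chrUn"),
) -> float:
    """Distance (bp) at which the smoothed median pair r-squared drops below
    ``r2_target``.

    Random intra-chromosomal SNP pairs up to ``max_distance`` bp apart are
    sampled, their composite-LD r-squared values binned by distance, bin
    medians smoothed with a 3-bin rolling mean, and the representative
    distance (bin center) of the first bin whose smoothed median falls
    below the target is returned.  If the decay never crosses the target,
    ``fallback`` is returned with a warning.  Unplaced contigs
    (``exclude_chroms``) are ignored.
    """
    rng = np.random.default_rng(seed)
    chrom = geno.markers["chrom"].to_numpy()
    pos = geno.markers["pos"].to_numpy()
    usable = ~np.isin(chrom, list(exclude_chroms))
    pairs_i: list[np.ndarray] = []
    pairs_j: list[np.ndarray] = []
    chroms, counts = np.unique(chrom[usable], return_counts=True)
    multi = chroms[counts >= 2]
    if len(multi) == 0:
        warnings.warn("no chromosome with >=2 SNPs; returning fallback LD-decay distance")
        return float(fallback)
    per_chrom = max(1, n_pairs // len(multi))
    for c in multi:
        idx = np.where((chrom == c) & usable)[0]
        cpos = pos[idx]
        i = rng.integers(0, len(idx) - 1, size=per_chrom)
        # partner sampled among SNPs within max_distance downstream
        hi = np.searchsorted(cpos, cpos[i] + max_distance, side="right")
        lo = i + 1
        ok = hi > lo
        i = i[ok]
        j = (lo[ok] + (rng.random(ok.sum()) * (hi[ok] - lo[ok])).astype(int))
        pairs_i.append(idx[i])
        pairs_j.append(idx[j])
    pi = np.concatenate(pairs_i)
    pj = np.concatenate(pairs_j)
    if len(pi) == 0:
        warnings.warn("no usable SNP pairs; returning fallback LD-decay distance")
        return float(fallback)
    vals = geno.imputed()
    vc = vals - vals.mean(axis=0)
    ss = (vc**2).sum(axis=0)
    num = np.einsum("ij,ij->j", vc[:, pi], vc[:, pj])
    denom = np.sqrt(ss[pi] * ss[pj])
    good = denom > 0
    r2 = np.zeros(len(pi))
    r2[good] = (num[good] / denom[good]) ** 2
    dist = np.abs(pos[pj] - pos[pi]).astype(float)

    edges = np.linspace(0.0, float(max_distance), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    medians = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.sum() >= 5:
            medians[b] = np.median(r2[sel])
    if np.all(np.isnan(medians)):
        warnings.warn("too few pairs per bin; returning fallback LD-decay distance")
        return float(fallback)
    med = pd.Series(medians).interpolate(limit_direction="both").to_numpy()
    smooth = pd.Series(med).rolling(3, center=True, min_periods=1).mean().to_numpy()
    below = np.where(smooth < r2_target)[0]
    if len(below) == 0:
        warnings.warn(
            f"LD never decays below r2={r2_target}; returning fallback {fallback} bp"
        )
        return float(fallback)
    return float(centers[below[0]])
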