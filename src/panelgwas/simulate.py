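"""Synthetic genotype panels and multi-environment trial phenotypes.

The generator emulates the statistical structure the pipeline assumes: an
outbred diversity panel of unrelated genotypes with weak population structure
(a few groups with drifted allele frequencies), tens of thousands of SNPs
whose linkage disequilibrium decays rapidly with distance, and a randomized
complete-block trial repeated over years with genotype-year interaction,
plot-level covariates and a field grid for spatial diagnostics.  Every draw
is deterministic given the configured seed, and a :class:`SimulationTruth`
record carries the causal loci and variance components for
parameter-recovery tests.

LD is produced by a block-copying scheme: within an LD block each gamete
carries one block-level latent allele that every SNP copies, after which a
per-SNP "mutation" resamples the allele from its population frequency.
Because the mutation resamples from the same Bernoulli marginal, allele
frequencies are preserved exactly while the within-block correlation is
tunable through the mutation rate; SNPs in different blocks are independent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pheno import PlotPhenotypes

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_trial",
    "inject_spatial_field",
    "plot_variance_components",
    "write_truth_tsv",
]


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic panel and trial.

    Defaults mirror the emulated field experiment: ~280 unrelated genotypes
    weakly structured in 3 groups, 5 complete blocks observed in 2 years,
    and a SNP panel with LD negligible beyond ~100 kb.
    """

    n_genotypes: int = 280
    n_snps: int = 20_000
    n_chromosomes: int = 19
    chrom_length_bp: int = 20_000_000
    ld_block_length: int = 100_000
    mutation_rate: float = 0.15       # per-SNP within-block resampling prob
    freq_jitter: float = 0.05         # per-SNP deviation from the block base frequency
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_groups: int = 3
    fst: float = 0.05                 # drift of group frequencies (weak structure)
    n_blocks: int = 5
    n_years: int = 2
    architecture: str = "sparse"      # {"sparse", "dense"}
    n_causal: int = 3
    h2_additive: float = 0.35         # plot-level proportion of variance
    prop_gxy: float = 0.20            # plot-level genotype-year proportion
    covariate_effects: dict = dataclasses.field(default_factory=dict)
    missing_rate: float = 0.0
    block_effect_sd: float = 0.3      # free parameters of the trial conduct
    year_effect_sd: float = 0.3
    block_year_effect_sd: float = 0.15
    intercept: float = 10.0
    total_variance: float = 1.0       # plot-level var(g) + var(g:y) + var(e)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h2_additive", "prop_gxy", "missing_rate", "mutation_rate", "fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.h2_additive + self.prop_gxy > 1.0:
            raise ValueError("h2_additive + prop_gxy must not exceed 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        if self.architecture not in {"sparse", "dense"}:
            raise ValueError("architecture must be 'sparse' or 'dense'")

    @property
    def variances(self) -> tuple[float, float, float]:
        """(sigma2_g, sigma2_gy, sigma2_e) at the plot level."""
        tot = self.total_variance
        s2g = self.h2_additive * tot
        s2gy = self.prop_gxy * tot
        return s2g, s2gy, tot - s2g - s2gy


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth of one simulated trial."""

    causal_snp_ids: list[str]
    causal_effects: np.ndarray
    true_sigma2_g: float
    true_sigma2_gy: float
    true_sigma2_e: float
    true_h2: float
    group_assignment: pd.Series

    def recompute_h2(self, n_y: float, n_r: float) -> float:
        """Broad-sense heritability under the balanced-design formula."""
        if self.true_sigma2_g <= 0:
            return 0.0
        return self.true_sigma2_g / (
            self.true_sigma2_g
            + self.true_sigma2_gy / n_y
            + self.true_sigma2_e / (n_y * n_r)
        )


def plot_variance_components(h2_target: float, n_years: int, n_blocks: int,
                             gxy_ratio: float = 0.6) -> tuple[float, float]:
    """Plot-level (h2_additive, prop_gxy) proportions yielding a target
    broad-sense heritability for a balanced ``n_blocks`` x ``n_years`` trial.

    ``gxy_ratio`` fixes sigma2_gy / sigma2_g.  Solves the balanced-design
    formula for the error variance and renormalizes to unit total variance.
    """
    if not 0.0 < h2_target < 1.0:
        raise ValueError("h2_target must be in (0, 1)")
    s2g = 1.0
    s2gy = gxy_ratio * s2g
    # H2 = s2g / (s2g + s2gy/n_y + s2e/(n_y*n_r))
    s2e = (s2g / h2_target - s2g - s2gy / n_years) * n_years * n_blocks
    if s2e <= 0:
        raise ValueError("target heritability unattainable with this gxy_ratio")
    tot = s2g + s2gy + s2e
    return s2g / tot, s2gy / tot


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate an additive-coded SNP panel with block LD and group structure.

    Group structure arises from group-specific allele frequencies drifted
    from a common ancestral frequency (Balding-Nichols Beta model with the
    configured Fst).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, P, C = config.n_genotypes, config.n_snps, config.n_chromosomes

    # marker map: strictly increasing positions per chromosome
    per_chrom = np.full(C, P // C)
    per_chrom[: P % C] += 1
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for c in range(C):
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1), size=per_chrom[c], replace=False
        ))
        positions.append(pos)
        chroms.extend([f"chr{c + 1}"] * per_chrom[c])
    pos_all = np.concatenate(positions)
    chrom_all = np.asarray(chroms)

    # LD blocks: block id per SNP (across-chromosome ids are distinct)
    if config.ld_block_length <= 1:
        block_id = np.arange(P)
    else:
        block_id = np.zeros(P, dtype=int)
        nxt = 0
        for c in range(C):
            sel = chrom_all == f"chr{c + 1}"
            ids = pos_all[sel] // config.ld_block_length
            _, local = np.unique(ids, return_inverse=True)
            block_id[sel] = local + nxt
            nxt = block_id[sel].max() + 1
    n_blocks_ld = block_id.max() + 1

    # ancestral frequencies: a block-level base frequency with per-SNP jitter,
    # so SNPs sharing a block latent are strongly correlated (similar
    # thresholds on the same latent), then group-level drift
    p_block = rng.uniform(config.maf_low, config.maf_high, size=n_blocks_ld)
    p0 = np.clip(
        p_block[block_id] + rng.normal(0.0, config.freq_jitter, size=P),
        config.maf_low, config.maf_high,
    )
    if config.n_groups > 1 and config.fst > 0:
        a = p0 * (1.0 - config.fst) / config.fst
        b = (1.0 - p0) * (1.0 - config.fst) / config.fst
        pg = rng.beta(a, b, size=(config.n_groups, P))
        # recentre on the ancestral frequency so the panel-wide marginal
        # frequency stays at p0 (drift differentiates groups, not the mean)
        pg = np.clip(pg - pg.mean(axis=0, keepdims=True) + p0, 0.005, 0.995)
    else:
        pg = np.tile(p0, (max(config.n_groups, 1), 1))
    groups = np.arange(n) % max(config.n_groups, 1)

    # gametes: 2 per individual; block-level latent copied, per-SNP mutation
    p_gam = pg[groups]                       # (n, P) frequency per individual
    p_gam = np.repeat(p_gam, 2, axis=0)      # (2n, P)
    u = rng.random((2 * n, n_blocks_ld))     # block latent per gamete
    alleles = u[:, block_id] < p_gam
    mut = rng.random((2 * n, P)) < config.mutation_rate
    fresh = rng.random((2 * n, P)) < p_gam
    alleles = np.where(mut, fresh, alleles)
    dosage = alleles[0::2].astype(float) + alleles[1::2].astype(float)

    markers = pd.DataFrame({
        "id": [f"{c}_{p}" for c, p in zip(chrom_all, pos_all)],
        "chrom": chrom_all,
        "pos": pos_all.astype(int),
        "ref": "A",
        "alt": "T",
    })
    gm = GenotypeMatrix(dosage, [f"G{i + 1:04d}" for i in range(n)], markers)
    gm.group_assignment = pd.Series(groups, index=gm.sample_ids, name="group")  # type: ignore[attr-defined]
    return gm


# ---------------------------------------------------------------------------
# Trial phenotypes
# ---------------------------------------------------------------------------

def simulate_trial(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[PlotPhenotypes, SimulationTruth]:
    """Simulate plot-level phenotypes for a blocks-by-years trial.

    Plot value = intercept + block + year + block:year + covariates + g_i +
    (g:y)_iy + e.  Genetic values are built from causal SNP effects (a few
    Normal effects under the sparse architecture, all SNPs under the dense
    one) and rescaled so the realized genotypic variance matches the
    configured component; interaction and error draws match theirs exactly
    in distribution.
    """
    if geno.n_samples != config.n_genotypes:
        raise ValueError("genotype matrix inconsistent with config (n_genotypes)")
    s2g, s2gy, s2e = config.variances
    if config.h2_additive >= 1.0 and config.prop_gxy > 0:
        raise ValueError("variance targets unattainable: h2_additive=1 with prop_gxy>0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    n, P = geno.n_samples, geno.n_snps

    W = geno.imputed()
    W = W - W.mean(axis=0)
    if config.architecture == "sparse":
        causal_idx = np.sort(rng.choice(P, size=config.n_causal, replace=False))
    else:
        causal_idx = np.arange(P)
    effects = rng.normal(0.0, 1.0, size=len(causal_idx))
    g_raw = W[:, causal_idx] @ effects
    v = g_raw.var()
    if s2g > 0 and v > 0:
        scale = np.sqrt(s2g / v)
    else:
        scale = 0.0
    g = g_raw * scale
    effects = effects * scale

    blocks = [f"B{b + 1}" for b in range(config.n_blocks)]
    years = [f"Y{t + 1}" for t in range(config.n_years)]
    block_eff = dict(zip(blocks, rng.normal(0.0, config.block_effect_sd, config.n_blocks)))
    year_eff = dict(zip(years, rng.normal(0.0, config.year_effect_sd, config.n_years)))
    by_eff = {
        (b, t): e
        for (b, t), e in zip(
            [(b, t) for b in blocks for t in years],
            rng.normal(0.0, config.block_year_effect_sd, config.n_blocks * config.n_years),
        )
    }
    gy = rng.normal(0.0, np.sqrt(s2gy), size=(n, config.n_years)) if s2gy > 0 else np.zeros((n, config.n_years))

    # field layout: one location per (genotype, block), constant across years
    n_rank = int(np.ceil(np.sqrt(n)))
    rows_per_block = int(np.ceil(n / n_rank))
    loc: dict[tuple[str, str], tuple[int, int]] = {}
    for bi, b in enumerate(blocks):
        order = rng.permutation(n)
        for k, gi in enumerate(order):
            loc[(geno.sample_ids[gi], b)] = (
                bi * rows_per_block + k // n_rank + 1,
                k % n_rank + 1,
            )

    covar_names = list(config.covariate_effects)
    records: list[dict] = []
    for gi, gid in enumerate(geno.sample_ids):
        for b in blocks:
            for ti, t in enumerate(years):
                val = (
                    config.intercept + block_eff[b] + year_eff[t] + by_eff[(b, t)]
                    + g[gi] + gy[gi, ti]
                )
                rec = {
                    "genotype": gid, "block": b, "year": t, "treatment": "none",
                    "row": loc[(gid, b)][0], "rank": loc[(gid, b)][1],
                }
                for cname in covar_names:
                    if "virus" in cname.lower():
                        cval = float(rng.random() < 0.3)
                    else:
                        cval = rng.normal()
                    rec[cname] = cval
                    val += config.covariate_effects[cname] * cval
                rec["value"] = val + rng.normal(0.0, np.sqrt(s2e))
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    if config.missing_rate > 0:
        miss = rng.random(len(df)) < config.missing_rate
        df.loc[miss, "value"] = np.nan

    truth = SimulationTruth(
        causal_snp_ids=geno.markers["id"].iloc[causal_idx].tolist(),
        causal_effects=effects,
        true_sigma2_g=s2g,
        true_sigma2_gy=s2gy,
        true_sigma2_e=s2e,
        true_h2=_h2_of(s2g, s2gy, s2e, config.n_years, config.n_blocks),
        group_assignment=getattr(
            geno, "group_assignment",
            pd.Series(0, index=geno.sample_ids, name="group"),
        ),
    )
    return PlotPhenotypes(df, covariates=covar_names, response="value"), truth


def _h2_of(s2g: float, s2gy: float, s2e: float, n_y: int, n_r: int) -> float:
    if s2g <= 0:
        return 0.0
    return s2g / (s2g + s2gy / n_y + s2e / (n_y * n_r))


def inject_spatial_field(
    pheno: PlotPhenotypes, range_param: float, sill: float, seed: int | None = None
) -> PlotPhenotypes:
    """Add a zero-mean Gaussian field with exponential covariance over the
    (row, rank) grid; used to exercise the variogram/kriging diagnostics.

    cov(d) = sill * exp(-d / range).  ``range_param`` -> 0 degenerates to iid
    noise of variance ``sill``; ``sill = 0`` returns the input unchanged.
    """
    if sill < 0 or range_param < 0:
        raise ValueError("sill and range must be non-negative")
    df = pheno.data.copy()
    if {"row", "rank"} - set(df.columns):
        raise ValueError("phenotypes lack row/rank coordinates")
    if sill == 0:
        return PlotPhenotypes(df, list(pheno.covariates), pheno.response)
    rng = np.random.default_rng(seed)
    coords = df[["row", "rank"]].to_numpy(dtype=float)
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    m = len(uniq)
    if range_param == 0:
        field = rng.normal(0.0, np.sqrt(sill), size=m)
    else:
        d = np.linalg.norm(uniq[:, None, :] - uniq[None, :, :], axis=-1)
        cov = sill * np.exp(-d / range_param) + 1e-10 * sill * np.eye(m)
        field = np.linalg.cholesky(cov) @ rng.standard_normal(m)
    df[pheno.response] = df[pheno.response].to_numpy(dtype=float) + field[inv]
    return PlotPhenotypes(df, list(pheno.covariates), pheno.response)


def write_truth_tsv(truth: SimulationTruth, path) -> None:
    """Persist causal SNPs and variance components as TSV."""
    head = pd.DataFrame({
        "key": ["sigma2_g", "sigma2_gy", "sigma2_e", "h2"],
        "value": [truth.true_sigma2_g, truth.true_sigma2_gy,
                  truth.true_sigma2_e, truth.true_h2],
    })
    body = pd.DataFrame({
        "key": ["causal:" + s for s in truth.causal_snp_ids],
        "value": truth.causal_effects,
    })
    pd.concat([head, body]).to_csv(path, sep="\t", index=False)
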