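"""Synthetic genotype-phenotype cohorts with family structure and regional QTLs.

The generator emulates the statistical structure that the regional
heritability scan assumes: several cohorts of related individuals (nuclear
families plus unrelated singletons), SNP panels with a configurable allele
frequency spectrum and first-order linkage disequilibrium, a polygenic
background, one or more regional QTLs contributing fixed fractions of the
trait variance, sex/age/age² covariate effects, genotype missingness and a
handful of Hardy-Weinberg-violating SNPs.

Linkage disequilibrium uses latent-uniform copying: each haplotype carries a
latent uniform variable along the chromosome that is copied from the previous
SNP with probability ``ld_decay`` and redrawn otherwise; the allele at SNP k
is the indicator ``u < p_k``.  This preserves the marginal allele frequencies
exactly (so Hardy-Weinberg holds per SNP) while giving adjacent markers
positive, geometrically decaying correlation.  Non-founders are produced by
gene dropping: each gamete copies one parental haplotype and switches between
the two with probability ``recomb_rate`` at each adjacent-SNP interval.

All randomness flows from ``numpy.random.default_rng`` seeded from the
config, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, write_plink

__all__ = ["QTLSpec", "SimulationConfig", "SimulatedCohort",
           "simulate_genotypes", "simulate_phenotypes", "simulate_cohort",
           "write_cohort"]


@dataclass(frozen=True)
class QTLSpec:
    """One regional QTL: a window of SNP indices on one chromosome.

    ``start``/``end`` index SNPs within the chromosome (half-open);
    ``h2_region`` is the target fraction of (adjusted) trait variance;
    ``n_causal`` SNPs are drawn from the window, restricted to the requested
    frequency class (``common``: MAF >= 0.05, ``rare``: MAF < 0.05, ``any``).
    """

    chromosome: int
    start: int
    end: int
    h2_region: float
    n_causal: int = 5
    causal_maf_class: str = "any"


@dataclass
class SimulationConfig:
    n_samples: int = 600
    n_cohorts: int = 3
    n_families: int = 100
    sibship_size: int = 3
    n_chromosomes: int = 2
    snps_per_chromosome: int = 500
    maf_low: float = 0.01
    maf_high: float = 0.5
    rare_tail_frac: float = 0.0   # fraction of SNPs with MAF in [rare_low, maf_low)
    rare_low: float = 0.001
    ld_decay: float = 0.9         # latent-copying probability per adjacent marker
    recomb_rate: float = 0.01     # per-interval crossover probability in meiosis
    qtl_spec: tuple[QTLSpec, ...] = ()
    h2_poly: float = 0.45
    covariate_effects: dict = field(
        default_factory=lambda: {"sex": 0.5, "age": 0.02, "age2": -0.0002}
    )
    age_range: tuple[float, float] = (18.0, 90.0)
    missing_rate: float = 0.005
    n_hwe_violators: int = 0
    drop_causal_snps: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.qtl_spec, list):
            self.qtl_spec = tuple(
                q if isinstance(q, QTLSpec) else QTLSpec(**q) for q in self.qtl_spec
            )
        h2_sum = self.h2_poly + sum(q.h2_region for q in self.qtl_spec)
        if not 0.0 <= h2_sum < 1.0:
            raise ValueError(f"h2_poly + sum(h2_region) = {h2_sum} must be in [0, 1)")
        for frac in (self.h2_poly, self.missing_rate, self.ld_decay, self.recomb_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for count in (self.n_samples, self.n_cohorts, self.n_chromosomes,
                      self.snps_per_chromosome):
            if count <= 0:
                raise ValueError("counts must be positive")
        if self.n_families < 0 or self.sibship_size < 0 or self.n_hwe_violators < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        fam_size = 2 + self.sibship_size
        if self.n_families * fam_size > self.n_samples:
            raise ValueError(
                f"{self.n_families} families of {fam_size} exceed n_samples={self.n_samples}"
            )
        for q in self.qtl_spec:
            if not (1 <= q.chromosome <= self.n_chromosomes
                    and 0 <= q.start < q.end <= self.snps_per_chromosome):
                raise ValueError(f"QTL window {q} outside the simulated map")
            if not 0.0 <= q.h2_region <= 1.0 or q.n_causal <= 0:
                raise ValueError(f"invalid QTL spec {q}")
            if q.n_causal > q.end - q.start:
                raise ValueError(f"QTL {q}: n_causal exceeds window size")


@dataclass
class SimulatedCohort:
    """Genotypes, registry, phenotype and the realized ground truth."""

    genotypes: GenotypeMatrix
    samples: pd.DataFrame  # sample_id, family_id, cohort, sex, age
    phenotype: np.ndarray  # trait values aligned to the registry
    truth: dict

    def trait_table(self, trait_name: str = "trait") -> pd.DataFrame:
        t = self.samples[["sample_id", "cohort", "sex", "age"]].copy()
        t[trait_name] = self.phenotype
        return t


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _draw_mafs(config: SimulationConfig, m: int, rng: np.random.Generator) -> np.ndarray:
    """Allele frequencies along a chromosome.

    Adjacent SNPs in strong LD necessarily have similar allele frequencies
    (r² between two loci is capped by their frequency mismatch), so the
    frequency sequence is drawn as a slowly drifting walk that resets to a
    fresh uniform draw with probability 1 − ld_decay per step — the same
    parameter that governs haplotype copying.  With ld_decay = 0 this is an
    i.i.d. uniform spectrum on [maf_low, maf_high].
    """
    lo, hi = config.maf_low, config.maf_high
    p = np.empty(m)
    p[0] = rng.uniform(lo, hi)
    fresh = rng.uniform(lo, hi, size=m)
    reset = rng.random(m) < (1.0 - config.ld_decay)
    steps = rng.normal(0.0, 0.05 * (hi - lo), size=m)
    for k in range(1, m):
        if reset[k]:
            p[k] = fresh[k]
        else:
            q = p[k - 1] + steps[k]
            # reflect into [lo, hi]
            if q < lo:
                q = 2 * lo - q
            if q > hi:
                q = 2 * hi - q
            p[k] = min(max(q, lo), hi)
    if config.rare_tail_frac > 0:
        rare = rng.random(m) < config.rare_tail_frac
        p[rare] = rng.uniform(config.rare_low, lo, size=int(rare.sum()))
    return p


def _founder_haplotypes(n_hap: int, p: np.ndarray, ld_decay: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Latent-uniform copying haplotypes: marginals exact, adjacent-marker LD."""
    m = p.size
    u = np.empty((n_hap, m))
    u[:, 0] = rng.random(n_hap)
    fresh = rng.random((n_hap, m))
    copy = rng.random((n_hap, m - 1)) < ld_decay
    for k in range(1, m):
        u[:, k] = np.where(copy[:, k - 1], u[:, k - 1], fresh[:, k])
    return (u < p).astype(np.int8)


def _meiosis(h0: np.ndarray, h1: np.ndarray, recomb_rate: float,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete: copy along one parental haplotype, crossing over between
    adjacent SNPs with probability ``recomb_rate``."""
    m = h0.size
    switches = rng.random(m - 1) < recomb_rate
    state = np.empty(m, dtype=np.int8)
    state[0] = rng.integers(0, 2)
    state[1:] = switches
    state = np.cumsum(state) % 2
    return np.where(state == 0, h0, h1)


def sample_registry(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic family/cohort layout: families first (each kept within a
    single cohort, assigned round-robin), then unrelated singletons."""
    rows = []
    fam_size = 2 + config.sibship_size
    for f in range(config.n_families):
        cohort = f % config.n_cohorts
        for j in range(fam_size):
            role = "founder" if j < 2 else "sib"
            rows.append((f"F{f:04d}_I{j}", f"F{f:04d}", f"cohort{cohort}", role))
    n_single = config.n_samples - config.n_families * fam_size
    for s in range(n_single):
        cohort = (config.n_families + s) % config.n_cohorts
        rows.append((f"S{s:04d}", f"S{s:04d}", f"cohort{cohort}", "singleton"))
    return pd.DataFrame(rows, columns=["sample_id", "family_id", "cohort", "role"])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Generate the dosage matrix: founder haplotypes with copying LD, gene
    dropping within families, missingness, and injected HWE violators.

    HWE-violating SNPs are overwritten with fully homozygous genotypes drawn
    at the SNP's allele frequency (inbreeding coefficient 1): allele
    frequency is preserved but heterozygotes are absent, a violation the
    exact test detects decisively at cohort sample sizes.  Violators are
    marked in ``variants['hwe_violator']``.
    """
    rng = np.random.default_rng(config.seed)
    registry = sample_registry(config)
    n = len(registry)
    fam_size = 2 + config.sibship_size

    chrom_blocks, variant_rows = [], []
    snp_counter = 0
    for c in range(1, config.n_chromosomes + 1):
        m = config.snps_per_chromosome
        p = _draw_mafs(config, m, rng)
        positions = np.cumsum(rng.integers(2_000, 20_000, size=m))
        n_founder_ind = 2 * config.n_families + (n - config.n_families * fam_size)
        H = _founder_haplotypes(2 * n_founder_ind, p, config.ld_decay, rng)

        hap_pairs = np.empty((n, 2, m), dtype=np.int8)
        founder_cursor = 0
        row = 0
        for f in range(config.n_families):
            parents = []
            for _ in range(2):
                hp = H[2 * founder_cursor: 2 * founder_cursor + 2]
                founder_cursor += 1
                parents.append(hp)
                hap_pairs[row] = hp
                row += 1
            for _ in range(config.sibship_size):
                for par in (0, 1):
                    hap_pairs[row, par] = _meiosis(
                        parents[par][0], parents[par][1], config.recomb_rate, rng
                    )
                row += 1
        while row < n:
            hap_pairs[row] = H[2 * founder_cursor: 2 * founder_cursor + 2]
            founder_cursor += 1
            row += 1

        dosage = hap_pairs.sum(axis=1) / 2.0  # {0, 0.5, 1}
        chrom_blocks.append(dosage)
        for k in range(m):
            variant_rows.append(
                (f"snp{snp_counter + k:06d}", c, int(positions[k]), "A", "B")
            )
        snp_counter += m

    values = np.concatenate(chrom_blocks, axis=1).astype(float)
    variants = pd.DataFrame(variant_rows, columns=["snp_id", "chromosome", "position",
                                                   "allele_a", "allele_b"])
    variants["hwe_violator"] = False

    # HWE violators: keep clear of QTL windows so causal structure is untouched
    if config.n_hwe_violators > 0:
        qtl_cols = set()
        for q in config.qtl_spec:
            base = (q.chromosome - 1) * config.snps_per_chromosome
            qtl_cols.update(range(base + q.start, base + q.end))
        candidates = np.array(sorted(set(range(values.shape[1])) - qtl_cols))
        if candidates.size < config.n_hwe_violators:
            raise ValueError("not enough non-QTL SNPs to host HWE violators")
        chosen = rng.choice(candidates, size=config.n_hwe_violators, replace=False)
        for j in chosen:
            p_j = values[:, j].mean()
            p_j = min(max(p_j, 0.1), 0.9)  # keep violators comfortably polymorphic
            values[:, j] = rng.binomial(1, p_j, size=n).astype(float)
        variants.loc[np.sort(chosen), "hwe_violator"] = True

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    return GenotypeMatrix(values=values, variants=variants,
                          samples=list(registry["sample_id"]))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _standardized(dosages: np.ndarray) -> np.ndarray:
    """Column-standardize, mean-imputing missing entries first."""
    g = dosages.copy()
    mu = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = np.take(mu, idx[1])
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return (g - g.mean(axis=0)) / sd


def _scale_to_variance(x: np.ndarray, target: float) -> np.ndarray:
    v = float(np.var(x))
    if v == 0:
        raise ValueError("component has zero variance; cannot scale")
    return x * np.sqrt(target / v)


def simulate_phenotypes(genotypes: GenotypeMatrix, samples: pd.DataFrame,
                        config: SimulationConfig) -> SimulatedCohort:
    """Build the trait from covariate, regional-QTL, polygenic and residual parts.

    The genetic-plus-residual part is scaled to unit variance, within which
    each QTL component has empirical variance exactly ``h2_region`` and the
    polygenic component exactly ``h2_poly``; covariate effects (per-cohort
    coefficients allowed) are added on top.  ``truth`` records the realized
    variance fractions — component variance over the variance of the total
    genetic-plus-residual sum, which differs from the nominal target only
    through sampling covariance between components.
    """
    if genotypes.n_samples != len(samples):
        raise ValueError("genotypes and sample registry not aligned")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = genotypes.n_samples

    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(*config.age_range, size=n)
    registry = samples.copy()
    registry["sex"] = sex
    registry["age"] = age

    # covariate part, per-cohort coefficients if a dict of dicts is given
    ce = config.covariate_effects
    per_cohort = all(isinstance(v, dict) for v in ce.values()) if ce else False
    cov_part = np.zeros(n)
    coeff_record: dict[str, dict[str, float]] = {}
    for cohort, idx in registry.groupby("cohort", sort=False).groups.items():
        coeffs = ce[cohort] if per_cohort else ce
        ii = np.asarray(idx)
        cov_part[ii] = (
            coeffs.get("sex", 0.0) * sex[ii]
            + coeffs.get("age", 0.0) * age[ii]
            + coeffs.get("age2", 0.0) * age[ii] ** 2
        )
        coeff_record[str(cohort)] = {k: float(v) for k, v in coeffs.items()}

    chrom = genotypes.variants["chromosome"].to_numpy()
    causal_ids: list[str] = []
    qtl_components: list[np.ndarray] = []
    qtl_meta = []
    causal_cols: list[int] = []
    with np.errstate(invalid="ignore"):
        p_all = np.nanmean(genotypes.values, axis=0)
    maf = np.minimum(p_all, 1.0 - p_all)

    for q in config.qtl_spec:
        offs = np.flatnonzero(chrom == q.chromosome)
        cols = offs[q.start:q.end]
        poly_mask = (maf[cols] > 0) & np.isfinite(maf[cols])
        if q.causal_maf_class == "common":
            cls = poly_mask & (maf[cols] >= 0.05)
        elif q.causal_maf_class == "rare":
            cls = poly_mask & (maf[cols] < 0.05)
        else:
            cls = poly_mask
        if not poly_mask.any():
            raise ValueError(
                f"QTL window chr{q.chromosome}:[{q.start},{q.end}) contains no polymorphic SNP"
            )
        pool = cols[cls] if cls.any() else cols[poly_mask]
        take = min(q.n_causal, pool.size)
        chosen = np.sort(rng.choice(pool, size=take, replace=False))
        causal_cols.extend(chosen)
        causal_ids.extend(genotypes.variants["snp_id"].iloc[chosen])
        Z = _standardized(genotypes.values[:, chosen])
        comp = Z.sum(axis=1)
        comp = _scale_to_variance(comp, q.h2_region) if q.h2_region > 0 else np.zeros(n)
        qtl_components.append(comp)
        qtl_meta.append(q)

    poly_cols = np.array(sorted(set(range(genotypes.m_snps)) - set(causal_cols)))
    hwe_mask = genotypes.variants.get("hwe_violator")
    if hwe_mask is not None:
        poly_cols = poly_cols[~hwe_mask.to_numpy()[poly_cols]]
    poly_cols = poly_cols[(maf[poly_cols] > 0) & np.isfinite(maf[poly_cols])]
    if config.h2_poly > 0:
        Zp = _standardized(genotypes.values[:, poly_cols])
        poly_part = _scale_to_variance(Zp @ rng.normal(size=poly_cols.size), config.h2_poly)
    else:
        poly_part = np.zeros(n)

    h2_resid = 1.0 - config.h2_poly - sum(q.h2_region for q in config.qtl_spec)
    resid = rng.normal(size=n) * np.sqrt(h2_resid)

    genetic_sum = poly_part + resid
    for comp in qtl_components:
        genetic_sum = genetic_sum + comp
    y = cov_part + genetic_sum

    var_total = float(np.var(genetic_sum))
    truth = {
        "seed": config.seed,
        "h2_poly_nominal": config.h2_poly,
        "h2_poly_realized": float(np.var(poly_part)) / var_total,
        "qtls": [
            {
                "chromosome": q.chromosome,
                "start": q.start,
                "end": q.end,
                "h2_region_nominal": q.h2_region,
                "h2_region_realized": float(np.var(comp)) / var_total,
                "causal_snp_ids": [
                    str(s) for s in genotypes.variants["snp_id"].iloc[
                        [c for c in causal_cols
                         if c in set(np.flatnonzero(chrom == q.chromosome)[q.start:q.end])]
                    ]
                ],
            }
            for q, comp in zip(qtl_meta, qtl_components)
        ],
        "causal_snp_ids": causal_ids,
        "covariate_coefficients": coeff_record,
        "dropped_causal_snps": bool(config.drop_causal_snps),
    }

    out_genotypes = genotypes
    if config.drop_causal_snps and causal_cols:
        keep = np.array(sorted(set(range(genotypes.m_snps)) - set(causal_cols)))
        out_genotypes = genotypes.subset(snp_idx=keep)

    return SimulatedCohort(
        genotypes=out_genotypes,
        samples=registry[["sample_id", "family_id", "cohort", "sex", "age"]],
        phenotype=y,
        truth=truth,
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Convenience: genotypes + phenotypes in one call."""
    genotypes = simulate_genotypes(config)
    return simulate_phenotypes(genotypes, sample_registry(config), config)


def write_cohort(cohort: SimulatedCohort, prefix: str | Path,
                 trait_name: str = "trait") -> None:
    """Write PLINK trio, phenotype TSV (sample_id, cohort, sex, age, trait)
    and the truth JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_plink(cohort.genotypes, prefix,
                family_ids=list(cohort.samples["family_id"]))
    cohort.trait_table(trait_name).to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False)
    Path(f"{prefix}.truth.json").write_text(json.dumps(cohort.truth, indent=2))
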