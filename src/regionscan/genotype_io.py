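"""Genotype containers, PLINK binary I/O and per-SNP / per-sample quality control.

Dosages are coded on the allele-fraction scale {0, 0.5, 1} for the AA, AB and
BB genotypes of the counted ("B") allele, with ``numpy.nan`` for missing calls.
This coding makes the mean dosage over samples equal to the B-allele frequency
directly, and is the scale assumed by :mod:`regionscan.kinship`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "read_plink",
    "write_plink",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "allele_frequency",
    "minor_allele_frequency",
    "hwe_exact_test",
    "apply_qc",
]

VARIANT_COLUMNS = ["snp_id", "chromosome", "position", "allele_a", "allele_b"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK v1.00, SNP-major


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam triplet is malformed."""


@dataclass
class GenotypeMatrix:
    """Samples-by-SNPs dosage matrix with variant and sample registries.

    Attributes
    ----------
    values
        ``(n_samples, m_snps)`` float array with entries in {0, 0.5, 1, nan}.
    variants
        DataFrame with columns snp_id, chromosome, position, allele_a,
        allele_b (one row per SNP, in column order of ``values``).
    samples
        Sample identifiers, in row order of ``values``.
    """

    values: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x SNPs)")
        n, m = self.values.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} columns")
        ok = np.isnan(self.values) | np.isin(self.values, (0.0, 0.5, 1.0))
        if not ok.all():
            bad = np.unique(self.values[~ok])
            raise ValueError(f"dosages must be in {{0, 0.5, 1, nan}}; found {bad[:5]}")
        if self.variants["snp_id"].duplicated().any():
            dup = self.variants.loc[self.variants["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate snp ids: {list(dup[:5])}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def m_snps(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/SNP positional indices."""
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.m_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            values=self.values[np.ix_(sample_idx, snp_idx)].copy(),
            variants=self.variants.iloc[snp_idx].reset_index(drop=True),
            samples=[self.samples[i] for i in sample_idx],
        )

    def sort_by_position(self) -> "GenotypeMatrix":
        """Return a copy with SNPs ordered by (chromosome, position)."""
        order = np.lexsort(
            (self.variants["position"].to_numpy(), self.variants["chromosome"].to_numpy())
        )
        if np.array_equal(order, np.arange(self.m_snps)):
            return self
        return self.subset(snp_idx=order)


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------
# 2-bit codes in SNP-major .bed, least-significant pair first within a byte:
#   00 -> homozygous allele-1  (allele_b, the counted allele) -> dosage 1
#   10 -> heterozygous                                        -> dosage 0.5
#   11 -> homozygous allele-2  (allele_a)                     -> dosage 0
#   01 -> missing                                             -> nan
_CODE_TO_DOSAGE = np.array([1.0, np.nan, 0.5, 0.0])


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet into a :class:`GenotypeMatrix`.

    Allele 1 of the .bim file is taken as the counted B allele, so a
    homozygote for allele 1 maps to dosage 1.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position", "allele1", "allele2"],
        dtype={"chromosome": int, "snp_id": str, "position": int,
               "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"bad .bed magic at byte 0: {raw[:3].hex()} (expected {_BED_MAGIC.hex()})"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f".bed length {len(raw)} at byte {min(len(raw), expected)}: "
            f"expected {expected} for {n} samples x {m} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    values = _CODE_TO_DOSAGE[codes].T  # (n, m)
    variants = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chromosome": bim["chromosome"],
            "position": bim["position"],
            "allele_a": bim["allele2"],
            "allele_b": bim["allele1"],
        }
    )
    return GenotypeMatrix(values=values, variants=variants, samples=list(fam["iid"]))


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path,
                family_ids: list[str] | None = None) -> None:
    """Write a .bed/.bim/.fam triplet (SNP-major v1.00 .bed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.values.shape
    v = genotypes.variants
    bim = pd.DataFrame(
        {
            "chromosome": v["chromosome"],
            "snp_id": v["snp_id"],
            "cm": 0,
            "position": v["position"],
            "allele1": v["allele_b"],
            "allele2": v["allele_a"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fids = family_ids if family_ids is not None else genotypes.samples
    fam = pd.DataFrame(
        {"fid": fids, "iid": genotypes.samples, "father": 0, "mother": 0,
         "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    dosage_to_code = {1.0: 0, 0.5: 2, 0.0: 3}
    codes = np.full((m, n), 1, dtype=np.uint8)  # default = missing (01)
    vals = genotypes.values.T
    for dose, code in dosage_to_code.items():
        codes[vals == dose] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(m, -1, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text dialect: header ``sample_id`` + snp ids, cells in {0, 0.5, 1, NA}."""
    df = pd.DataFrame(
        genotypes.values, columns=genotypes.variants["snp_id"], index=genotypes.samples
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path: str | Path,
                    variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read the plain-text dosage dialect written by :func:`write_dosage_tsv`.

    If no variant table is supplied, placeholder coordinates are synthesized
    (chromosome 1, positions in column order).
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
    if variants is None:
        variants = pd.DataFrame(
            {
                "snp_id": df.columns,
                "chromosome": 1,
                "position": np.arange(1, df.shape[1] + 1),
                "allele_a": "A",
                "allele_b": "B",
            }
        )
    return GenotypeMatrix(values=df.to_numpy(float), variants=variants,
                          samples=[str(s) for s in df.index])


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------

def allele_frequency(genotypes: GenotypeMatrix | np.ndarray, snp: int | None = None) -> float | np.ndarray:
    """B-allele frequency: mean dosage over non-missing samples.

    With the 0/0.5/1 coding the mean dosage *is* the allele fraction.  Pass a
    SNP index for a single frequency, or omit it for the full vector.
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    if snp is not None:
        col = values[:, snp]
        good = ~np.isnan(col)
        if not good.any():
            raise ValueError(f"SNP index {snp}: all calls missing")
        return float(col[good].mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns -> nan
        return np.nanmean(values, axis=0)


def minor_allele_frequency(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    p = np.atleast_1d(allele_frequency(genotypes))
    return np.minimum(p, 1.0 - p)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value, conditional on allele counts.

    Sums the probabilities of all heterozygote counts whose conditional
    probability (hypergeometric-type, given the minor-allele count) does not
    exceed that of the observed table.  Monomorphic SNPs return 1 by
    convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype calls")
    n_b = 2 * n_bb + n_ab  # B-allele count
    n_minor = min(n_b, 2 * n - n_b)
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed_het = n_ab
    p_obs = prob[hets == observed_het]
    if p_obs.size == 0:  # parity mismatch: impossible table
        raise ValueError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


def _genotype_counts(values: np.ndarray) -> np.ndarray:
    """Per-SNP (n_AA, n_AB, n_BB) counts, shape (m, 3)."""
    counts = np.empty((values.shape[1], 3), dtype=int)
    counts[:, 0] = (values == 0.0).sum(axis=0)
    counts[:, 1] = (values == 0.5).sum(axis=0)
    counts[:, 2] = (values == 1.0).sum(axis=0)
    return counts


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Per-SNP and per-individual filters.

    SNPs with MAF strictly below ``maf_min``, exact-HWE p strictly below
    ``hwe_p_floor`` or call rate strictly below ``snp_call_rate_min`` are
    discarded; individuals with call rate strictly below
    ``sample_call_rate_min`` are then removed.
    """

    maf_min: float = 0.001
    hwe_p_floor: float = 1e-8
    snp_call_rate_min: float = 0.98
    sample_call_rate_min: float = 0.98

    def __post_init__(self) -> None:
        for name in ("maf_min", "hwe_p_floor", "snp_call_rate_min", "sample_call_rate_min"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name}={x} outside [0, 1]")


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed_snps: dict[str, list[str]] = field(default_factory=dict)
    removed_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed_per_criterion(self) -> dict[str, int]:
        out = {f"snp_{k}": len(v) for k, v in self.removed_snps.items()}
        out.update({f"sample_{k}": len(v) for k, v in self.removed_samples.items()})
        return out


class EmptyAfterQCError(ValueError):
    """All SNPs or all samples were removed by the requested filters."""


def apply_qc(genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None,
             iterate: bool = False) -> tuple[GenotypeMatrix, QCReport]:
    """Apply SNP filters (call rate, then MAF, then exact HWE) and then the
    individual call-rate filter, in a single deterministic pass.

    With ``iterate=True`` the pass is repeated until no further removal occurs
    (sample removal can change per-SNP statistics and vice versa).
    """
    thresholds = thresholds or QCThresholds()
    if genotypes.m_snps == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")

    current = genotypes
    removed_snps: dict[str, list[str]] = {"call_rate": [], "maf": [], "hwe": []}
    removed_samples: dict[str, list[str]] = {"call_rate": []}
    while True:
        values = current.values
        n, m = values.shape
        missing = np.isnan(values)
        snp_ids = current.variants["snp_id"].to_numpy()

        keep = np.ones(m, dtype=bool)
        call_rate = 1.0 - missing.mean(axis=0)
        bad = call_rate < thresholds.snp_call_rate_min
        removed_snps["call_rate"].extend(snp_ids[bad])
        keep &= ~bad

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(values, axis=0)
        maf = np.minimum(p, 1.0 - p)
        all_missing = missing.all(axis=0)
        bad = keep & (all_missing | (maf < thresholds.maf_min))
        removed_snps["maf"].extend(snp_ids[bad])
        keep &= ~bad

        if thresholds.hwe_p_floor > 0.0:
            counts = _genotype_counts(values)
            for j in np.flatnonzero(keep):
                if hwe_exact_test(*counts[j]) < thresholds.hwe_p_floor:
                    removed_snps["hwe"].append(snp_ids[j])
                    keep[j] = False

        snp_kept = current.subset(snp_idx=np.flatnonzero(keep))
        if snp_kept.m_snps == 0:
            raise EmptyAfterQCError("all SNPs removed: empty after QC")

        sample_call = 1.0 - np.isnan(snp_kept.values).mean(axis=1)
        keep_s = sample_call >= thresholds.sample_call_rate_min
        removed_samples["call_rate"].extend(
            s for s, k in zip(snp_kept.samples, keep_s) if not k
        )
        if not keep_s.any():
            raise EmptyAfterQCError("all samples removed: empty after QC")
        result = snp_kept.subset(sample_idx=np.flatnonzero(keep_s))

        changed = result.m_snps < current.m_snps or result.n_samples < current.n_samples
        current = result
        if not (iterate and changed):
            break

    report = QCReport(
        n_snps_in=genotypes.m_snps,
        n_snps_out=current.m_snps,
        n_samples_in=genotypes.n_samples,
        n_samples_out=current.n_samples,
        removed_snps={k: v for k, v in removed_snps.items()},
        removed_samples={k: v for k, v in removed_samples.items()},
    )
    return current, report
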