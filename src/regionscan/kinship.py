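"""Marker-derived genomic relationship matrices (whole-genome and regional).

The relationship between individuals *i* and *j* is the frequency-weighted
cross-product of centred dosages,

    f_ij = (2 / m_ij) * sum_k (g_ik - p_k)(g_jk - p_k) / (p_k (1 - p_k)),

summed over SNPs non-missing in both individuals (m_ij of them), with dosages
g on the {0, 0.5, 1} allele-fraction scale and p_k the B-allele frequency
estimated from the analysis sample.  The factor 2 puts the self-relationship
of a non-inbred individual at 1, so variance components attached to this
matrix read directly as additive genetic variances.  Diagonals use the
homozygosity-based estimator

    f_ii = 1 + (Obs(#hom)_i - E(#hom)_i) / (m_i - E(#hom)_i),

where E(#hom)_i = sum_k (1 - 2 p_k (1 - p_k)) over the SNPs non-missing in
individual *i* — the expected homozygote count under Hardy-Weinberg
equilibrium.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "genomic_relationship",
    "bend_psd",
    "write_gcta_grm",
    "read_gcta_grm",
]


@dataclass
class RelationshipMatrix:
    """n-by-n symmetric marker-derived relatedness.

    ``role`` distinguishes the whole-genome matrix (covariance of the
    polygenic effect) from a regional matrix (covariance of one window's
    effect).  ``m`` is the number of polymorphic SNPs that entered the
    estimate.
    """

    values: np.ndarray
    role: str  # "whole_genome" | "regional"
    m: int
    snp_ids: list[str]
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n1, n2 = self.values.shape
        if n1 != n2:
            raise ValueError("relationship matrix must be square")
        if not np.isfinite(self.values).all():
            raise ValueError("relationship matrix has non-finite entries")
        asym = np.abs(self.values - self.values.T).max()
        if asym > 1e-12:
            raise ValueError(f"relationship matrix asymmetric by {asym:.2e}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def genomic_relationship(genotypes: GenotypeMatrix,
                         snp_subset: np.ndarray | list[int] | None = None,
                         role: str = "whole_genome") -> RelationshipMatrix:
    """Build the frequency-weighted relationship matrix from a SNP subset.

    Missingness is handled pairwise-complete: each pair (i, j) is averaged
    over the SNPs non-missing in both, which is unbiased under missingness
    at random.  Monomorphic SNPs in the subset carry no information about
    relatedness and are skipped with a warning.
    """
    idx = np.arange(genotypes.m_snps) if snp_subset is None else np.asarray(snp_subset)
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    G = genotypes.values[:, idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(G, axis=0)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("SNP subset entirely monomorphic: relationship undefined")
    if not poly.all():
        warnings.warn(f"skipping {int((~poly).sum())} monomorphic SNPs in subset")
        idx, G, p = idx[poly], G[:, poly], p[poly]

    het = p * (1.0 - p)
    obs = ~np.isnan(G)
    W = np.where(obs, (G - p) / np.sqrt(het), 0.0)
    num = 2.0 * (W @ W.T)
    m_pair = obs.astype(float) @ obs.T.astype(float)
    if (m_pair == 0).any():
        raise ValueError("some sample pairs share no non-missing SNP")
    F = num / m_pair

    # homozygosity-corrected diagonal
    hom = obs & ((G == 0.0) | (G == 1.0))
    obs_hom = hom.sum(axis=1).astype(float)
    e_hom = (obs * (1.0 - 2.0 * het)).sum(axis=1)
    m_i = obs.sum(axis=1).astype(float)
    denom = m_i - e_hom
    degenerate = denom <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} individuals with m_i == E(#hom): "
            "diagonal falls back to the cross-product formula"
        )
    diag = np.where(degenerate, np.diag(F), 1.0 + (obs_hom - e_hom) / np.where(denom > 0, denom, 1.0))
    np.fill_diagonal(F, diag)
    F = (F + F.T) / 2.0

    return RelationshipMatrix(
        values=F,
        role=role,
        m=int(idx.size),
        snp_ids=list(genotypes.variants["snp_id"].iloc[idx]),
        allele_freqs=p,
    )


def bend_psd(matrix: RelationshipMatrix | np.ndarray,
             floor: float = 1e-8) -> RelationshipMatrix | np.ndarray:
    """Raise eigenvalues below ``floor`` to ``floor`` ("bending").

    Returns the input object unchanged (same array) when it is already
    positive semi-definite at the floor, so a PSD matrix round-trips
    bit-identically.
    """
    A = matrix.values if isinstance(matrix, RelationshipMatrix) else np.asarray(matrix)
    # cheap sufficient check first: A - floor*I positive definite => no bending
    try:
        np.linalg.cholesky(A - floor * np.eye(A.shape[0]))
        return matrix
    except np.linalg.LinAlgError:
        pass
    w, U = np.linalg.eigh(A)
    if w.min() >= floor:
        return matrix
    w = np.maximum(w, floor)
    bent = (U * w) @ U.T
    bent = (bent + bent.T) / 2.0
    if isinstance(matrix, RelationshipMatrix):
        return RelationshipMatrix(
            values=bent, role=matrix.role, m=matrix.m,
            snp_ids=matrix.snp_ids, allele_freqs=matrix.allele_freqs,
        )
    return bent


# ---------------------------------------------------------------------------
# GCTA text GRM interchange
# ---------------------------------------------------------------------------

def write_gcta_grm(matrix: RelationshipMatrix, sample_ids: list[str],
                   prefix: str | Path, compress: bool = True) -> None:
    """Write the lower triangle as GCTA text (.grm.gz or .grm, plus .grm.id).

    Columns: i, j (1-based), number of SNPs, relationship.  Pairwise SNP
    counts are not retained in :class:`RelationshipMatrix`; the subset size
    ``m`` is written for every pair.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = matrix.n
    rows = []
    for i in range(n):
        for j in range(i + 1):
            rows.append(f"{i + 1}\t{j + 1}\t{matrix.m}\t{matrix.values[i, j]:.8g}\n")
    text = "".join(rows)
    if compress:
        with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
            fh.write(text)
    else:
        Path(f"{prefix}.grm").write_text(text)
    pd.DataFrame({"fid": sample_ids, "iid": sample_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_gcta_grm(prefix: str | Path, role: str = "whole_genome") -> tuple[RelationshipMatrix, list[str]]:
    """Read a GCTA text GRM written by :func:`write_gcta_grm`."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None, names=["fid", "iid"])
    n = len(ids)
    gz = Path(f"{prefix}.grm.gz")
    opener = (lambda: gzip.open(gz, "rt")) if gz.exists() else (lambda: open(f"{prefix}.grm"))
    A = np.zeros((n, n))
    m = 1
    with opener() as fh:
        for line in fh:
            i, j, m_ij, f = line.split()
            A[int(i) - 1, int(j) - 1] = A[int(j) - 1, int(i) - 1] = float(f)
            m = int(float(m_ij))
    mat = RelationshipMatrix(values=A, role=role, m=m, snp_ids=[],
                             allele_freqs=np.array([]))
    return mat, list(ids["iid"].astype(str))
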