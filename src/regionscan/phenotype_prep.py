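"""Analysis-phenotype construction: per-cohort covariate adjustment followed by
rank inverse-normal transformation.

Each cohort's trait is regressed on sex, age and age squared by ordinary least
squares; the residuals are then mapped onto standard-normal quantiles within
the cohort, and cohorts are concatenated.  The resulting scores are the
phenotype used by both the regional-heritability scan and the single-SNP scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "AdjustedPhenotype",
    "adjust_covariates",
    "rank_inverse_normal",
    "prepare_phenotype",
]

TRAIT_TABLE_COLUMNS = ["sample_id", "cohort", "sex", "age"]


@dataclass
class AdjustedPhenotype:
    """Standard-normal phenotype scores aligned to a sample registry."""

    sample_ids: list[str]
    values: np.ndarray
    provenance: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "y": self.values})


def _design(sub: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(sub)), sub["sex"].to_numpy(float),
            sub["age"].to_numpy(float), sub["age"].to_numpy(float) ** 2]
    names = ["intercept", "sex", "age", "age2"]
    return np.column_stack(cols), names


def adjust_covariates(table: pd.DataFrame, trait: str = "trait",
                      min_cohort_size: int = 5) -> pd.DataFrame:
    """OLS-adjust the trait for sex, age and age² within each cohort.

    Parameters
    ----------
    table
        One row per sample with columns sample_id, cohort, sex, age and the
        trait column.  Rows with a missing trait or covariate are dropped
        (and recorded in the returned frame's ``attrs['dropped']``).
    trait
        Name of the trait column to adjust.

    Returns
    -------
    DataFrame with columns sample_id, cohort, residual; per-cohort fit
    summaries in ``attrs['fits']``.

    Notes
    -----
    A rank-deficient design column (e.g. sex in a single-sex cohort) is
    dropped with a warning rather than failing the cohort.
    """
    required = {"sample_id", "cohort", "sex", "age", trait}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"trait table missing columns: {sorted(missing_cols)}")

    complete = table[["sample_id", "cohort", "sex", "age", trait]].dropna()
    dropped = sorted(set(table["sample_id"]) - set(complete["sample_id"]))

    pieces = []
    fits: dict[str, dict] = {}
    for cohort, sub in complete.groupby("cohort", sort=False):
        if len(sub) < min_cohort_size:
            raise ValueError(
                f"cohort {cohort!r}: only {len(sub)} complete samples (need >= {min_cohort_size})"
            )
        X, names = _design(sub)
        y = sub[trait].to_numpy(float)
        # drop collinear columns (keep intercept), e.g. single-sex cohorts
        keep = [0]
        for j in range(1, X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                warnings.warn(
                    f"cohort {cohort!r}: dropping collinear covariate {names[j]!r}"
                )
        Xk = X[:, keep]
        beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        resid = y - Xk @ beta
        fits[str(cohort)] = {
            "n": int(len(sub)),
            "coefficients": {names[j]: float(b) for j, b in zip(keep, beta)},
        }
        pieces.append(
            pd.DataFrame({"sample_id": sub["sample_id"], "cohort": cohort, "residual": resid})
        )

    out = pd.concat(pieces, ignore_index=True)
    out.attrs["fits"] = fits
    out.attrs["dropped"] = dropped
    return out


def rank_inverse_normal(values: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Map values to standard-normal quantiles by rank.

    ``value_i = Phi^-1((rank_i - offset) / (n - 2*offset + 1))`` with average
    ranks for ties.  The default offset 0.5 gives the (rank−½)/n rule; Blom's
    variant uses ``offset=3/8``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to rank-transform")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: no ordering information")
    ranks = rankdata(x, method="average")
    return norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))


def prepare_phenotype(table: pd.DataFrame, trait: str = "trait",
                      offset: float = 0.5) -> AdjustedPhenotype:
    """Full pipeline: per-cohort covariate adjustment, then per-cohort rank
    inverse-normal transform, cohorts concatenated in input order."""
    adjusted = adjust_covariates(table, trait=trait)
    values = np.empty(len(adjusted))
    for _, idx in adjusted.groupby("cohort", sort=False).groups.items():
        values[np.asarray(idx)] = rank_inverse_normal(
            adjusted.loc[idx, "residual"].to_numpy(), offset=offset
        )
    return AdjustedPhenotype(
        sample_ids=list(adjusted["sample_id"]),
        values=values,
        provenance=adjusted.attrs["fits"],
    )
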