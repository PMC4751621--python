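"""Quality control and phenotype preparation for the reference cohort.

Applies the per-SNP filters (call rate >= 0.98, MAF >= 0.001, exact-HWE
p >= 1e-8) and the per-individual call-rate filter, then adjusts the trait
for sex, age and age^2 within each cohort and maps the residual ranks onto
standard-normal quantiles.  The injected HWE-violating SNPs should fall to
the HWE filter.

Writes results/cohort_qc.{bed,bim,fam} and results/phenotype.tsv.
"""

from pathlib import Path

import pandas as pd

from regionscan import genotype_io, phenotype_prep

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    genotypes = genotype_io.read_plink(OUT / "cohort")
    clean, report = genotype_io.apply_qc(genotypes)
    genotype_io.write_plink(clean, OUT / "cohort_qc")
    print(f"QC: SNPs {report.n_snps_in} -> {report.n_snps_out} "
          f"({report.n_removed_per_criterion}); "
          f"samples {report.n_samples_in} -> {report.n_samples_out}")

    table = pd.read_csv(OUT / "cohort.pheno.tsv", sep="\t")
    table = table[table["sample_id"].isin(clean.samples)]
    adjusted = phenotype_prep.prepare_phenotype(table)
    frame = adjusted.to_frame().set_index("sample_id").loc[clean.samples]
    frame.to_csv(OUT / "phenotype.tsv", sep="\t")
    for cohort, fit in adjusted.provenance.items():
        print(f"{cohort}: n={fit['n']}, coefficients="
              f"{ {k: round(v, 4) for k, v in fit['coefficients'].items()} }")


if __name__ == "__main__":
    main()
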