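"""Single-SNP mixed-model scan of the reference cohort, for comparison.

Fits the polygenic null (whole-genome kinship as random effect) once, then
score-tests every SNP against it.  Compare the per-SNP -log10 p values with
the windows flagged by the regional scan (script 03).

Writes results/ssgwas.tsv.
"""

from pathlib import Path

import pandas as pd

from regionscan import genotype_io, kinship, ssgwas
from regionscan.scan_pipeline import threshold_set

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gm = genotype_io.read_plink(OUT / "cohort_qc").sort_by_position()
    y = (pd.read_csv(OUT / "phenotype.tsv", sep="\t")
         .set_index("sample_id").loc[gm.samples, "y"].to_numpy())
    G_w = kinship.bend_psd(kinship.genomic_relationship(gm))
    null_fit = ssgwas.fit_polygenic_null(y, G_w)
    scan = ssgwas.scan_snps(null_fit, gm)
    ssgwas.associations_to_frame(scan).to_csv(OUT / "ssgwas.tsv", sep="\t",
                                              index=False, float_format="%.6g")
    thr = threshold_set("ssgwas", gm.m_snps)
    tested = [a for a in scan if a.stat is not None]
    top = max(tested, key=lambda a: a.stat)
    n_gw = sum(a.neg_log10_p >= thr.genomewide_neg_log10_p for a in tested)
    print(f"null model: h2 = {null_fit.heritability:.3f}")
    print(f"lambda_GC = {ssgwas.genomic_control_lambda(scan):.3f}")
    print(f"top SNP {top.snp_id} (chr{top.chromosome}:{top.position}): "
          f"-log10 p = {top.neg_log10_p:.2f}; "
          f"{n_gw} SNPs past the genome-wide threshold {thr.genomewide_neg_log10_p:.2f}")


if __name__ == "__main__":
    main()
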