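"""Map cis sQTLs, eeQTLs and geQTLs in every tissue.

For each tissue, scans all SNPs within +/-1 Mb of each feature against the
four phenotype kinds (breed fitted as a covariate in milk), calls sQTLs by
the exon-inclusion AND adjacent-intron-excision conjunction (FDR < 0.1 each
side), calls eeQTLs/geQTLs at FDR < 0.01, classifies SNPs by QTL type, and
annotates significant SNPs with their TSS distance. Writes everything under
results/cisqtl/.
"""

from pathlib import Path

import pandas as pd

from spliceqtl import cis_qtl, io_core as io
from spliceqtl.phenotypes import read_phenotypes
from spliceqtl.synthetic_data import SimConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "cisqtl"
TISSUES = ("blood", "milk", "liver", "muscle")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = io.read_genotypes(ROOT / "sim" / "genotypes.tsv")
    feats = io.read_features(ROOT / "sim" / "features.gff3")
    genes = {f.feature_id: f for f in feats if f.kind == "gene"}
    snp_by_id = {s.snp_id: s for s in gm.snps}
    breed = SimConfig().individuals().set_index("individual")[["breed"]]
    truth = pd.read_csv(ROOT / "sim" / "truth.tsv", sep="\t")

    summary = []
    for tissue in TISSUES:
        cov = breed if tissue == "milk" else None
        scans = {}
        for kind in ("inclusion", "excision", "exon_expr", "gene_expr"):
            pm = read_phenotypes(ROOT / "phenotypes" / f"{tissue}_{kind}.tsv", feats)
            scans[kind] = cis_qtl.scan_cis(pm, gm, feats, covariates=cov)
            scans[kind].to_csv(OUT / f"{tissue}_{kind}_assoc.tsv", sep="\t",
                               index=False)
        sqtls = cis_qtl.call_sqtls(scans["inclusion"], scans["excision"], feats,
                                   fdr=0.1)
        sqtls.to_csv(OUT / f"{tissue}_sqtls.tsv", sep="\t", index=False)
        types = cis_qtl.classify_qtl_types(
            sqtls, scans["exon_expr"], scans["gene_expr"], fdr=0.01
        )
        types.to_csv(OUT / f"{tissue}_qtl_types.tsv", sep="\t", index=False)

        # TSS distance of sQTL SNPs to their gene
        rows = []
        for r in sqtls.itertuples():
            rows.append(
                (r.snp_id, r.gene_id,
                 io.tss_distance(snp_by_id[r.snp_id], genes[r.gene_id]))
            )
        pd.DataFrame(rows, columns=["snp_id", "gene_id", "tss_distance"]).to_csv(
            OUT / f"{tissue}_sqtl_tss_distance.tsv", sep="\t", index=False
        )

        planted = set(truth.loc[truth.effect_type == "sQTL", "gene_id"])
        found = set(sqtls.gene_id)
        summary.append(
            (tissue, len(sqtls), sqtls.gene_id.nunique(),
             int(types.eeQTL.sum()), int(types.geQTL.sum()),
             len(planted & found), len(planted))
        )
        print(
            f"{tissue}: {len(sqtls)} sQTL calls over {sqtls.gene_id.nunique()} genes; "
            f"{int(types.eeQTL.sum())} eeQTL SNPs, {int(types.geQTL.sum())} geQTL SNPs; "
            f"planted sQTL genes recovered {len(planted & found)}/{len(planted)}"
        )
    pd.DataFrame(
        summary,
        columns=["tissue", "n_sqtl", "n_sqtl_genes", "n_eeqtl", "n_geqtl",
                 "recovered_sqtl_genes", "planted_sqtl_genes"],
    ).to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
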