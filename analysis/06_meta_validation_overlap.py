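"""Multi-transcriptome meta-analysis, holdout validation, and overlap tests.

Combines blood, milk and muscle gene-expression signed t values per
(SNP, gene) pair into the chi-square(1) meta statistic, validates against
the held-out liver transcriptome (meta p < 1e-05 vs liver p < 0.05), then
simulates two-cohort (bull/cow) GWAS summaries, forms inverse-variance
weighted t values and the multi-trait chi-square, and tests QTL/pleiotropy
overlap enrichment with Fisher's exact test. Writes results/meta/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spliceqtl import io_core as io, meta_overlap as mo
from spliceqtl import synthetic_data as sd
from spliceqtl.fdr import qvalues

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "meta"

COMBINED = ("blood", "milk", "muscle")
HOLDOUT = "liver"


def main(seed: int = 20260901) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    assoc = {
        t: pd.read_csv(ROOT / "cisqtl" / f"{t}_gene_expr_assoc.tsv", sep="\t")
        for t in COMBINED + (HOLDOUT,)
    }
    tab, overlap = mo.run_validation(
        {t: assoc[t] for t in COMBINED}, assoc[HOLDOUT],
        p_single=0.05, p_meta=1e-05, p_holdout=0.05,
    )
    tab.to_csv(OUT / "validation_pairs.tsv", sep="\t", index=False)
    both = int((tab.meta_sig & tab.holdout_sig).sum())
    print(
        f"validation: {len(tab)} candidate pairs (p<0.05 in all of "
        f"{', '.join(COMBINED)}); {int(tab.meta_sig.sum())} meta-significant "
        f"(p<1e-05), {int(tab.holdout_sig.sum())} liver-significant, {both} both; "
        f"overlap Fisher p = {overlap.p:.3g}, OR = {overlap.odds_ratio:.2f}"
    )

    # two-cohort GWAS: weighted t, multi-trait chi-square, pleiotropic SNPs
    cfg = sd.SimConfig(seed=seed, breed_fst=0.1)
    gm = io.read_genotypes(ROOT / "sim" / "genotypes.tsv")
    summaries, _ = sd.simulate_gwas_summaries(cfg, gm, n_traits=6)
    weighted = mo.weighted_t_table(summaries["bull"], summaries["cow"])
    weighted.to_csv(OUT / "gwas_weighted_t.tsv", sep="\t", index=False)
    v = mo.estimate_t_correlation(weighted)
    wide = weighted.pivot(index="snp_id", columns="trait", values="t_w")
    vinv = np.linalg.inv(v)
    stat = np.einsum("ij,jk,ik->i", wide.to_numpy(), vinv, wide.to_numpy())
    from scipy import stats as sps

    pleio = pd.DataFrame(
        {"snp_id": wide.index, "chi2": stat,
         "p": sps.chi2.sf(stat, wide.shape[1])}
    )
    pleio["q"] = qvalues(pleio["p"].to_numpy())
    pleio.to_csv(OUT / "gwas_multitrait.tsv", sep="\t", index=False)
    pleio_snps = set(pleio.loc[pleio.q < 0.01, "snp_id"])

    background = {s.snp_id for s in gm.snps}
    results = []
    for tissue in COMBINED + (HOLDOUT,):
        types = pd.read_csv(ROOT / "cisqtl" / f"{tissue}_qtl_types.tsv", sep="\t")
        for qtl_type in ("sQTL", "eeQTL", "geQTL"):
            qtl_snps = set(types.loc[types[qtl_type], "snp_id"])
            if not qtl_snps or not pleio_snps:
                continue
            res = mo.fisher_overlap(
                qtl_snps, pleio_snps, background,
                label_a=f"{tissue} {qtl_type}", label_b="pleiotropic",
            )
            results.append(
                (tissue, qtl_type, res.both, len(qtl_snps), len(pleio_snps),
                 res.odds_ratio, res.p)
            )
    enr = pd.DataFrame(
        results,
        columns=["tissue", "qtl_type", "overlap", "n_qtl", "n_pleio",
                 "odds_ratio", "fisher_p"],
    )
    enr.to_csv(OUT / "pleiotropy_enrichment.tsv", sep="\t", index=False)
    if len(enr):
        top = enr.sort_values("fisher_p").iloc[0]
        print(
            f"pleiotropy enrichment: strongest overlap {top.tissue} {top.qtl_type} "
            f"({top.overlap}/{top.n_qtl} SNPs, Fisher p = {top.fisher_p:.3g})"
        )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
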