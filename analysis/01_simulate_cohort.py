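"""Simulate the multi-tissue cattle-like study cohort.

Two dairy-breed cell types (blood, milk) share 131 individuals; liver (35)
and muscle (41) come from disjoint beef cohorts. Each of 20 genes carries a
+/-1 Mb cis window of 60 SNPs in LD; a quarter of genes get a geQTL, a
quarter an sQTL. Writes genotypes (TSV + VCF), annotation (GFF3), per-tissue
gene/exon/intron count tables, and the truth table under results/sim/.
"""

from pathlib import Path

from spliceqtl import io_core as io, synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main(seed: int = 20260901) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SimConfig(seed=seed, breed_fst=0.1, breed_splice_shift=0.25,
                       breed_splice_genes=2)
    gm = sd.simulate_genotypes(cfg)
    feats = sd.simulate_annotation(cfg)
    counts, truth = sd.simulate_counts(cfg, gm)

    io.write_genotypes_tsv(gm, OUT / "genotypes.tsv")
    io.write_genotypes_vcf(gm, OUT / "genotypes.vcf")
    io.write_features_gff3(feats, OUT / "features.gff3")
    for tissue, kinds in counts.items():
        for kind, cm in kinds.items():
            io.write_counts(cm, OUT / f"counts_{tissue}_{kind}.tsv")
    truth.table.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    (OUT / "config.txt").write_text(repr(cfg) + "\n")

    n_planted = (truth.table.effect_type != "none").sum()
    print(f"cohort: {gm.n_samples} individuals, {gm.n_snps} SNPs, "
          f"{cfg.n_genes} genes ({n_planted} with planted cis effects)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
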