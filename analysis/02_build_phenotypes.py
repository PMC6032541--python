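"""Turn the simulated counts into regression-ready phenotypes.

For every tissue: CPM expression filtering, exon-inclusion and
intron-excision ratios, then the log2 / per-feature inverse-normal quantile
/ per-individual z-score chain. Writes one phenotype TSV per (tissue, kind)
under results/phenotypes/.
"""

from pathlib import Path

from spliceqtl import io_core as io, phenotypes as ph

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"
OUT = ROOT / "phenotypes"

TISSUES = ("blood", "milk", "liver", "muscle")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    feats = io.read_features(SIM / "features.gff3")
    for tissue in TISSUES:
        gene_c = io.read_counts(SIM / f"counts_{tissue}_gene.tsv", feats)
        exon_c = io.read_counts(SIM / f"counts_{tissue}_exon.tsv", feats)
        intron_c = io.read_counts(SIM / f"counts_{tissue}_intron.tsv", feats)
        gene_c = ph.filter_expressed(gene_c)
        exon_c = ph.filter_expressed(exon_c)

        made = {
            "inclusion": ph.normalize_ratios(
                ph.inclusion_ratio(exon_c, gene_c), kind="inclusion"
            ),
            "excision": ph.normalize_ratios(
                ph.excision_ratio(intron_c), kind="excision"
            ),
            "exon_expr": ph.normalize_expression(exon_c, kind="exon_expr"),
            "gene_expr": ph.normalize_expression(gene_c, kind="gene_expr"),
        }
        for kind, pm in made.items():
            pm.write_tsv(OUT / f"{tissue}_{kind}.tsv")
        print(
            f"{tissue}: "
            + ", ".join(f"{k} {len(v.features)}x{len(v.samples)}" for k, v in made.items())
        )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
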