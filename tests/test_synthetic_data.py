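import numpy as np
import pandas as pd
import pytest

from spliceqtl import synthetic_data as sd
from spliceqtl.phenotypes import cpm


def _cfg(**kw):
    base = dict(n_genes=1, seed=0, tissues=[sd.TissueSpec("t", "c", 100)])
    base.update(kw)
    return sd.SimConfig(**base)


class TestGenotypes:
    def test_determinism(self):
        a = sd.simulate_genotypes(_cfg(seed=5))
        b = sd.simulate_genotypes(_cfg(seed=5))
        assert np.array_equal(a.dosages, b.dosages)
        assert [s.snp_id for s in a.snps] == [s.snp_id for s in b.snps]

    def test_ld_decay_zero_gives_independent_snps(self):
        gm = sd.simulate_genotypes(
            _cfg(ld_decay=0.0, n_snps_per_window=30,
                 tissues=[sd.TissueSpec("t", "c", 500)], seed=2)
        )
        d = gm.dosages.astype(float)
        cors = [
            abs(np.corrcoef(d[:, j], d[:, j + 1])[0, 1])
            for j in range(d.shape[1] - 1)
        ]
        assert np.mean(cors) < 0.1

    def test_ld_decay_target_hit_with_equal_frequencies(self):
        # equal per-SNP frequencies make the adjacent-SNP correlation = rho
        gm = sd.simulate_genotypes(
            _cfg(ld_decay=0.9, n_snps_per_window=30, maf_range=(0.3, 0.3),
                 tissues=[sd.TissueSpec("t", "c", 2000)], seed=4)
        )
        d = gm.dosages.astype(float)
        cors = [
            np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(d.shape[1] - 1)
        ]
        assert np.mean(cors) == pytest.approx(0.9, abs=0.05)

    def test_maf_bounds(self, genotypes):
        mafs = np.array([s.maf for s in genotypes.snps])
        assert (mafs > 0.0).all() and (mafs <= 0.5).all()

    def test_breed_differentiated_frequencies(self):
        cfg = _cfg(
            breed_fst=0.3, breed_fraction=0.5, seed=9,
            tissues=[sd.TissueSpec("t", "dairy", 400)],
        )
        gm = sd.simulate_genotypes(cfg)
        ind = cfg.individuals()
        is_b = (ind.breed == "B").to_numpy()
        fa = gm.dosages[~is_b].mean(axis=0) / 2
        fb = gm.dosages[is_b].mean(axis=0) / 2
        # Fst=0.3 should produce visible frequency differences at many SNPs
        assert np.mean(np.abs(fa - fb) > 0.1) > 0.3


class TestCounts:
    def test_determinism(self, small_config, genotypes):
        c1, t1 = sd.simulate_counts(small_config, genotypes)
        c2, t2 = sd.simulate_counts(small_config, genotypes)
        for tissue in c1:
            for kind in c1[tissue]:
                assert np.array_equal(c1[tissue][kind].counts, c2[tissue][kind].counts)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_null_genes_show_no_dosage_effect(self):
        cfg = _cfg(n_genes=8, frac_geqtl=0.0, frac_sqtl=0.0, seed=21,
                   tissues=[sd.TissueSpec("t", "c", 200)])
        gm = sd.simulate_genotypes(cfg)
        counts, truth = sd.simulate_counts(cfg, gm)
        logc = np.log2(counts["t"]["gene"].counts + 0.5)
        tstats = []
        for g in range(cfg.n_genes):
            x = gm.dosages[:, g * cfg.n_snps_per_window + 30].astype(float)
            y = logc[g]
            xc = x - x.mean()
            beta = xc @ y / (xc @ xc)
            resid = y - y.mean() - beta * xc
            se = np.sqrt(resid @ resid / (len(y) - 2) / (xc @ xc))
            tstats.append(beta / se)
        assert np.mean(np.abs(tstats) < 3) >= 0.85

    def test_geqtl_effect_recovered_by_ols(self):
        cfg = _cfg(n_genes=4, frac_geqtl=1.0, frac_sqtl=0.0, effect_size=1.0,
                   seed=31, tissues=[sd.TissueSpec("t", "c", 200)])
        gm = sd.simulate_genotypes(cfg)
        counts, truth = sd.simulate_counts(cfg, gm)
        # raw log2 counts: the planted scale (CPM would couple the strong
        # planted effects through the library size)
        logc = np.log2(counts["t"]["gene"].counts + 0.5)
        sigma_resid = np.hypot(cfg.polygenic_sd, cfg.noise_sd)
        snp_ids = [s.snp_id for s in gm.snps]
        for _, row in truth.table.iterrows():
            g = int(row.gene_id.replace("gene", ""))
            x = gm.dosages[:, snp_ids.index(row.causal_snp)].astype(float)
            y = logc[g]
            xc = x - x.mean()
            beta = xc @ y / (xc @ xc)
            resid = y - y.mean() - beta * xc
            se = np.sqrt(resid @ resid / (len(y) - 2) / (xc @ xc))
            # planted effect is effect_size residual-SDs per alt allele
            assert abs(beta / sigma_resid - 1.0) < 2 * se / sigma_resid + 0.15

    def test_sqtl_usage_shift_matches_plant(self):
        cfg = _cfg(n_genes=2, frac_geqtl=0.0, frac_sqtl=1.0, usage_shift=0.3,
                   seed=41, tissues=[sd.TissueSpec("t", "c", 500)])
        gm = sd.simulate_genotypes(cfg)
        counts, truth = sd.simulate_counts(cfg, gm)
        # exon-to-gene count ratio per sample checks the generator's own
        # calibration without CPM library factors
        ec = counts["t"]["exon"].counts
        gc = counts["t"]["gene"].counts.astype(float)
        snp_ids = [s.snp_id for s in gm.snps]
        exon_ids = [f.feature_id for f in counts["t"]["exon"].features]
        gene_ids = [f.feature_id for f in counts["t"]["gene"].features]
        diffs = []
        for _, row in truth.table.iterrows():
            dose = gm.dosages[:, snp_ids.index(row.causal_snp)]
            g = gc[gene_ids.index(row.gene_id)]
            ratio = np.where(g > 0, ec[exon_ids.index(row.target_exon)] / g, np.nan)
            diffs.append(np.nanmean(ratio[dose == 2]) - np.nanmean(ratio[dose == 0]))
        assert np.mean(diffs) == pytest.approx(0.3, abs=0.05)

    def test_cross_tissue_expression_correlation_tracks_rg(self):
        # strong polygenic signal, weak noise: log-expression correlation
        # between shared-cohort tissues approaches the planted rg
        cfg = sd.SimConfig(
            n_genes=6, frac_geqtl=0.0, frac_sqtl=0.0, cross_tissue_rg=0.9,
            polygenic_sd=1.0, noise_sd=0.1, dispersion=0.01, depth=5000,
            seed=51,
            tissues=[sd.TissueSpec("a", "c", 500), sd.TissueSpec("b", "c", 500)],
        )
        gm = sd.simulate_genotypes(cfg)
        counts, _ = sd.simulate_counts(cfg, gm)
        la = np.log2(counts["a"]["gene"].counts + 0.5)
        lb = np.log2(counts["b"]["gene"].counts + 0.5)
        cors = [np.corrcoef(la[g], lb[g])[0, 1] for g in range(cfg.n_genes)]
        assert np.mean(cors) == pytest.approx(
            0.9 * cfg.polygenic_sd**2 / (cfg.polygenic_sd**2 + cfg.noise_sd**2),
            abs=0.1,
        )


class TestGwasSummaries:
    def test_null_calibration(self):
        cfg = sd.SimConfig(n_genes=50, n_snps_per_window=40, seed=61,
                           tissues=[sd.TissueSpec("t", "c", 20)])
        gm = sd.simulate_genotypes(cfg)
        tabs, truth = sd.simulate_gwas_summaries(
            cfg, gm, n_traits=5, frac_causal=0.0
        )
        z = (tabs["bull"]["B"] / tabs["bull"]["se"]).to_numpy()
        assert len(z) == 10_000
        assert abs(z.mean()) < 0.03
        assert z.var() == pytest.approx(1.0, abs=0.05)

    def test_inverse_variance_weight_favors_precise_cohort(self):
        from spliceqtl.meta_overlap import weighted_t_table

        cfg = sd.SimConfig(n_genes=10, seed=71,
                           tissues=[sd.TissueSpec("t", "c", 20)])
        gm = sd.simulate_genotypes(cfg)
        tabs, _ = sd.simulate_gwas_summaries(
            cfg, gm, n_traits=1, frac_causal=1.0, effect_sd=0.5,
            se_bull=1.0, se_cow=2.0,
        )
        merged = weighted_t_table(tabs["bull"], tabs["cow"]).merge(
            tabs["bull"], on=["snp_id", "trait"]
        ).merge(tabs["cow"], on=["snp_id", "trait"], suffixes=("_bull", "_cow"))
        d_bull = (merged.B_w - merged.B_bull).abs()
        d_cow = (merged.B_w - merged.B_cow).abs()
        assert (d_bull < d_cow).mean() > 0.9

    def test_determinism(self):
        cfg = _cfg(seed=81, tissues=[sd.TissueSpec("t", "c", 30)])
        gm = sd.simulate_genotypes(cfg)
        a, _ = sd.simulate_gwas_summaries(cfg, gm, n_traits=2)
        b, _ = sd.simulate_gwas_summaries(cfg, gm, n_traits=2)
        pd.testing.assert_frame_equal(a["bull"], b["bull"])
        pd.testing.assert_frame_equal(a["cow"], b["cow"])


class TestTruthClosure:
    def test_planted_causal_snps_lie_in_cis_windows(self, small_config, genotypes,
                                                    counts_truth, annotation):
        _, truth = counts_truth
        snp_by_id = {s.snp_id: s for s in genotypes.snps}
        genes = {f.feature_id: f for f in annotation if f.kind == "gene"}
        planted = truth.table.dropna(subset=["causal_snp"])
        assert len(planted) > 0
        for _, row in planted.iterrows():
            snp = snp_by_id[row.causal_snp]
            gene = genes[row.gene_id]
            assert gene.start - small_config.window <= snp.pos <= gene.end + small_config.window

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sd.SimConfig(ld_decay=1.0)
        with pytest.raises(ValueError):
            sd.SimConfig(cross_tissue_rg=1.5)
        with pytest.raises(ValueError):
            sd.SimConfig(frac_geqtl=0.7, frac_sqtl=0.7)
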