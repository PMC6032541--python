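import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceqtl import cis_qtl, synthetic_data as sd
from spliceqtl import phenotypes as ph
from spliceqtl.io_core import FeatureRecord, GenotypeMatrix, SnpRecord, folded_maf
from spliceqtl.phenotypes import PhenotypeMatrix


def _gm(dosages, positions, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.int16)
    snps = [
        SnpRecord(f"snp{j}", chrom, int(p), "A", "C", folded_maf(dosages[:, j]))
        for j, p in enumerate(positions)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(dosages.shape[0])], snps=snps, dosages=dosages
    )


def _pheno(values, samples, feature=None):
    feature = feature or FeatureRecord("f0", "exon", "1", 5000, 5200, "+", "g")
    return PhenotypeMatrix([feature], list(samples), np.atleast_2d(values), "inclusion")


class TestScanCis:
    def test_perfect_signal(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(50, 1))
        gm = _gm(dos, [5100])
        y = 0.5 * dos[:, 0].astype(float)
        res = cis_qtl.scan_cis(_pheno(y, gm.samples), gm)
        assert res.beta.iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert res.p.iloc[0] < 1e-30

    def test_orthogonalized_phenotype_gives_null(self):
        # phenotype residualized against the dosage: the scan must report a
        # numerically zero slope
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(80, 1))
        gm = _gm(dos, [5100])
        x = dos[:, 0].astype(float)
        xc = x - x.mean()
        y = rng.normal(size=80)
        y_orth = y - xc * ((y @ xc) / (xc @ xc))
        res = cis_qtl.scan_cis(_pheno(y_orth, gm.samples), gm)
        assert abs(res.beta.iloc[0]) < 1e-10
        assert abs(res.t.iloc[0]) < 1e-6

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for rep in range(20):
            n = rng.integers(30, 80)
            dos = rng.integers(0, 3, size=(n, 3))
            if any(len(np.unique(dos[:, j])) < 2 for j in range(3)):
                continue
            gm = _gm(dos, [5000, 5100, 5300])
            cov = pd.DataFrame(
                {"c1": rng.normal(size=n), "c2": rng.normal(size=n)},
                index=gm.samples,
            )
            y = rng.normal(size=n)
            res = cis_qtl.scan_cis(_pheno(y, gm.samples), gm, covariates=cov)
            for j in range(3):
                x_full = np.column_stack(
                    [np.ones(n), cov.c1, cov.c2, dos[:, j].astype(float)]
                )
                coef, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
                resid = y - x_full @ coef
                df = n - 4
                sigma2 = resid @ resid / df
                vcov = sigma2 * np.linalg.inv(x_full.T @ x_full)
                se = np.sqrt(vcov[3, 3])
                t = coef[3] / se
                p = 2 * stats.t.sf(abs(t), df)
                row = res[res.snp_id == f"snp{j}"].iloc[0]
                assert row.beta == pytest.approx(coef[3], abs=1e-8)
                assert row.se == pytest.approx(se, abs=1e-8)
                assert row.p == pytest.approx(p, abs=1e-8)

    def test_window_symmetry(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(40, 2))
        # one SNP 900 kb upstream of feature start, one 900 kb downstream of end
        feature = FeatureRecord("f0", "exon", "1", 2_000_000, 2_000_200, "+", "g")
        gm = _gm(dos, [2_000_000 - 900_000, 2_000_200 + 900_000])
        y = rng.normal(size=40)
        res = cis_qtl.scan_cis(_pheno(y, gm.samples, feature), gm)
        assert set(res.snp_id) == {"snp0", "snp1"}
        gm_far = _gm(dos, [2_000_000 - 1_100_000, 2_000_200 + 1_100_000])
        res_far = cis_qtl.scan_cis(_pheno(y, gm_far.samples, feature), gm_far)
        assert len(res_far) == 0

    def test_breed_covariate_removes_confounding(self):
        # breed shifts the target exon's usage and allele frequencies differ
        # by breed, but no SNP has a real effect
        cfg = sd.SimConfig(
            n_genes=2, frac_geqtl=0.0, frac_sqtl=0.0, breed_fst=0.3,
            breed_fraction=0.5, breed_splice_shift=0.25, breed_splice_genes=2,
            seed=17, tissues=[sd.TissueSpec("milk", "dairy", 300)],
        )
        gm = sd.simulate_genotypes(cfg)
        counts, truth = sd.simulate_counts(cfg, gm)
        feats = sd.simulate_annotation(cfg)
        incl = ph.normalize_ratios(
            ph.inclusion_ratio(counts["milk"]["exon"], counts["milk"]["gene"]),
            kind="inclusion",
        )
        breed = cfg.individuals().set_index("individual")["breed"]
        naked = cis_qtl.scan_cis(incl, gm, feats)
        adjusted = cis_qtl.scan_cis(
            incl, gm, feats, covariates=breed.to_frame("breed")
        )
        target = set(truth.table.breed_exon.dropna())
        t_naked = naked[naked.feature_id.isin(target)].t.abs()
        t_adj = adjusted[adjusted.feature_id.isin(target)].t.abs()
        assert t_adj.median() < 2.0
        assert t_naked.median() > t_adj.median()


def _assoc(rows):
    return pd.DataFrame(rows, columns=["snp_id", "feature_id", "q"]).assign(
        kind="exon", gene_id="g", beta=0.1, se=0.1, t=1.0, p=lambda d: d.q
    )


def _features():
    return [
        FeatureRecord("g", "gene", "1", 1000, 2000, "+", "g"),
        FeatureRecord("ex1", "exon", "1", 1000, 1200, "+", "g"),
        FeatureRecord("in1", "intron", "1", 1201, 1400, "+", "g"),
    ]


class TestCallSqtls:
    def test_conjunction_requires_both(self):
        exon = _assoc([("rs1", "ex1", 0.05)])
        intron_ns = _assoc([("rs1", "in1", 0.5)])
        assert len(cis_qtl.call_sqtls(exon, intron_ns, _features())) == 0
        intron_sig = _assoc([("rs1", "in1", 0.02)])
        calls = cis_qtl.call_sqtls(exon, intron_sig, _features())
        assert len(calls) == 1
        assert calls.intron_ids.iloc[0] == "in1"
        assert calls.combined_threshold.iloc[0] == pytest.approx(0.01)

    def test_same_snp_required(self):
        exon = _assoc([("rs1", "ex1", 0.05)])
        intron = _assoc([("rs2", "in1", 0.02)])  # different SNP
        assert len(cis_qtl.call_sqtls(exon, intron, _features())) == 0

    def test_planted_sqtl_recovered_with_ld_proxy(self):
        recovered = 0
        n_reps = 10
        for rep in range(n_reps):
            cfg = sd.SimConfig(
                n_genes=2, frac_sqtl=0.5, frac_geqtl=0.0, usage_shift=0.3,
                n_snps_per_window=40, ld_decay=0.7, seed=100 + rep,
                tissues=[sd.TissueSpec("t", "c", 200)],
            )
            gm = sd.simulate_genotypes(cfg)
            counts, truth = sd.simulate_counts(cfg, gm)
            feats = sd.simulate_annotation(cfg)
            incl = ph.normalize_ratios(
                ph.inclusion_ratio(counts["t"]["exon"], counts["t"]["gene"]),
                kind="inclusion",
            )
            exc = ph.normalize_ratios(
                ph.excision_ratio(counts["t"]["intron"]), kind="excision"
            )
            calls = cis_qtl.call_sqtls(
                cis_qtl.scan_cis(incl, gm, feats),
                cis_qtl.scan_cis(exc, gm, feats),
                feats,
                fdr=0.1,
            )
            causal = truth.table.query("effect_type=='sQTL'").causal_snp.iloc[0]
            snp_ids = [s.snp_id for s in gm.snps]
            r2 = np.corrcoef(gm.dosages.astype(float).T)[snp_ids.index(causal)] ** 2
            proxies = {snp_ids[j] for j in np.flatnonzero(r2 > 0.8)}
            recovered += bool(set(calls.snp_id) & proxies)
        assert recovered >= 8


class TestClassifyQtlTypes:
    def test_membership_counts_consistent(self):
        ee = _assoc([("rs1", "e", 0.005), ("rs2", "e", 0.5)])
        ge = _assoc([("rs1", "g", 0.002), ("rs3", "g", 0.9)])
        sq = pd.DataFrame({"snp_id": ["rs2"]})
        tab = cis_qtl.classify_qtl_types(sq, ee, ge, fdr=0.01)
        assert tab.set_index("snp_id").loc["rs1"].tolist() == [False, True, True]
        assert tab.sQTL.sum() == 1
        assert tab.eeQTL.sum() == 1
        assert tab.geQTL.sum() == 1

    def test_unseen_snp_all_false(self):
        ee = _assoc([("rs1", "e", 0.5)])
        ge = _assoc([("rs1", "g", 0.5)])
        tab = cis_qtl.classify_qtl_types(pd.DataFrame({"snp_id": []}), ee, ge)
        assert not tab[["sQTL", "eeQTL", "geQTL"]].to_numpy().any()

    def test_geqtl_gene_is_ee_and_ge_but_not_sqtl(self):
        cfg = sd.SimConfig(
            n_genes=2, frac_geqtl=0.5, frac_sqtl=0.0, effect_size=1.0,
            seed=23, tissues=[sd.TissueSpec("t", "c", 500)],
        )
        gm = sd.simulate_genotypes(cfg)
        counts, truth = sd.simulate_counts(cfg, gm)
        feats = sd.simulate_annotation(cfg)
        gexp = ph.normalize_expression(counts["t"]["gene"], kind="gene_expr")
        eexp = ph.normalize_expression(counts["t"]["exon"], kind="exon_expr")
        incl = ph.normalize_ratios(
            ph.inclusion_ratio(counts["t"]["exon"], counts["t"]["gene"]),
            kind="inclusion",
        )
        exc = ph.normalize_ratios(
            ph.excision_ratio(counts["t"]["intron"]), kind="excision"
        )
        sq = cis_qtl.call_sqtls(
            cis_qtl.scan_cis(incl, gm, feats),
            cis_qtl.scan_cis(exc, gm, feats),
            feats,
        )
        tab = cis_qtl.classify_qtl_types(
            sq,
            cis_qtl.scan_cis(eexp, gm, feats),
            cis_qtl.scan_cis(gexp, gm, feats),
            fdr=0.01,
        ).set_index("snp_id")
        causal = truth.table.query("effect_type=='geQTL'").causal_snp.iloc[0]
        row = tab.loc[causal]
        assert row.geQTL and row.eeQTL
        assert not row.sQTL
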