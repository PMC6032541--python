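import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceqtl import splicing_diff as sdf
from spliceqtl.fdr import qvalues
from spliceqtl.io_core import FeatureRecord
from spliceqtl.phenotypes import PhenotypeMatrix


def _repeated_design(n_animals, tissues=("A", "B", "C"), n_exp=2):
    samples = [f"s{i}_{t}" for i in range(n_animals) for t in tissues]
    design = pd.DataFrame(
        {
            "animal": [f"an{i}" for i in range(n_animals) for _ in tissues],
            "experiment": [
                f"e{i * n_exp // n_animals}" for i in range(n_animals) for _ in tissues
            ],
            "tissue": [t for _ in range(n_animals) for t in tissues],
        },
        index=samples,
    )
    return samples, design


def _pheno(values, samples, n=None):
    values = np.atleast_2d(values)
    feats = [
        FeatureRecord(f"f{k}", "exon", "1", 1, 2, "+", "g")
        for k in range(values.shape[0])
    ]
    return PhenotypeMatrix(feats, list(samples), values, "inclusion")


class TestTissueMixedModel:
    def test_ols_limit_each_animal_observed_once(self):
        # one observation per animal: the mixed-model F must equal OLS ANOVA F
        rng = np.random.default_rng(0)
        n = 60
        samples = [f"u{i}" for i in range(n)]
        design = pd.DataFrame(
            {
                "animal": [f"an{i}" for i in range(n)],
                "experiment": ["e1"] * 30 + ["e2"] * 30,
                "tissue": ["A", "B", "C"] * 20,
            },
            index=samples,
        )
        y = rng.normal(size=n)
        res = sdf.tissue_mixed_model(_pheno(y, samples), design)

        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = design.copy()
        df["y"] = y
        ols = smf.ols("y ~ C(experiment) + C(tissue)", df).fit()
        aov = anova_lm(ols, typ=3)
        assert res.stat.iloc[0] == pytest.approx(aov.loc["C(tissue)", "F"], abs=1e-6)
        assert res.p.iloc[0] == pytest.approx(aov.loc["C(tissue)", "PR(>F)"], abs=1e-6)

    def test_planted_tissue_shift_detected(self):
        rng = np.random.default_rng(1)
        samples, design = _repeated_design(30, tissues=("A", "B"))
        shift = np.tile([0.0, 2.0], 30)  # 2 SD tissue effect
        y = np.repeat(rng.normal(0, 0.5, 30), 2) + rng.normal(0, 1, 60) + shift
        res = sdf.tissue_mixed_model(_pheno(y, samples), design)
        assert res.p.iloc[0] < 1e-6

    def test_matches_lmertest_oracle(self, tmp_path):
        """Independent cross-check against R's lmerTest on one feature."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lmerTest oracle")
        rng = np.random.default_rng(42)
        samples, design = _repeated_design(15)
        an_eff = rng.normal(0, 0.8, 15)
        y = np.repeat(an_eff, 3) + rng.normal(0, 1, 45) + np.tile([0, 0.5, 0.2], 15)
        res = sdf.tissue_mixed_model(_pheno(y, samples), design)
        df = design.copy()
        df["y"] = y
        df.to_csv(tmp_path / "d.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(lmerTest))\n'
            f'd <- read.delim("{tmp_path}/d.tsv")\n'
            'm <- lmer(y ~ experiment + tissue + (1|animal), data=d)\n'
            'a <- anova(m)\n'
            'cat(a["tissue","F value"], a["tissue","DenDF"], a["tissue","Pr(>F)"], "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        f_r, ddf_r, p_r = map(float, out.stdout.split())
        assert res.stat.iloc[0] == pytest.approx(f_r, rel=1e-3)
        assert res.ddf.iloc[0] == pytest.approx(ddf_r, rel=0.01)
        assert res.p.iloc[0] == pytest.approx(p_r, abs=1e-3)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        samples, design = _repeated_design(25)
        vals = [
            np.repeat(rng.normal(0, 0.8, 25), 3) + rng.normal(0, 1, 75)
            for _ in range(400)
        ]
        res = sdf.tissue_mixed_model(_pheno(np.array(vals), samples), design)
        rate = (res.p < 0.05).mean()
        ci = 1.96 * np.sqrt(0.05 * 0.95 / len(res))
        assert abs(rate - 0.05) < ci + 0.01


class TestBreedModel:
    def test_equal_means_give_zero_t(self):
        samples = [f"s{i}" for i in range(8)]
        y = np.array([1.0, 2.0, 3.0, 4.0, 4.0, 3.0, 2.0, 1.0])
        breed = pd.Series(["H"] * 4 + ["J"] * 4, index=samples)
        res = sdf.breed_model(_pheno(y, samples), breed)
        assert res.stat.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_equivalent_to_two_sample_t_test(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(40)]
        y = rng.normal(size=40)
        breed = pd.Series(["H"] * 25 + ["J"] * 15, index=samples)
        res = sdf.breed_model(_pheno(y, samples), breed)
        t, p = stats.ttest_ind(y[25:], y[:25])  # J vs H, equal variance
        assert res.stat.iloc[0] == pytest.approx(t, abs=1e-12)
        assert res.p.iloc[0] == pytest.approx(p, abs=1e-12)

    def test_single_breed_is_error(self):
        samples = [f"s{i}" for i in range(6)]
        breed = pd.Series(["H"] * 6, index=samples)
        with pytest.raises(ValueError, match="2 levels"):
            sdf.breed_model(_pheno(np.zeros(6), samples), breed)


def _result_frame(ids, qs, kind, gene="g"):
    return pd.DataFrame(
        {"feature_id": ids, "kind": kind, "term": "tissue", "stat": 1.0,
         "p": qs, "q": qs, "gene_id": gene}
    )


def _gene_features():
    return [
        FeatureRecord("g", "gene", "1", 1000, 2000, "+", "g"),
        FeatureRecord("ex1", "exon", "1", 1000, 1200, "+", "g"),
        FeatureRecord("in1", "intron", "1", 1201, 1400, "+", "g"),
        FeatureRecord("ex2", "exon", "1", 1401, 1600, "+", "g"),
    ]


class TestConjunctionCall:
    def test_exon_without_intron_not_called(self):
        exon = _result_frame(["ex1"], [0.01], "exon")
        intron = _result_frame(["in1"], [0.5], "intron")
        calls = sdf.call_differential_splicing(exon, intron, _gene_features())
        assert not calls.called.iloc[0]

    def test_exon_with_adjacent_intron_called(self):
        exon = _result_frame(["ex1"], [0.01], "exon")
        intron = _result_frame(["in1"], [0.05], "intron")
        calls = sdf.call_differential_splicing(exon, intron, _gene_features())
        assert calls.called.iloc[0]
        assert calls.best_intron.iloc[0] == "in1"

    def test_combined_threshold_is_product(self):
        exon = _result_frame(["ex1"], [0.01], "exon")
        intron = _result_frame(["in1"], [0.05], "intron")
        calls = sdf.call_differential_splicing(
            exon, intron, _gene_features(), fdr=0.1
        )
        assert calls.combined_threshold.iloc[0] == pytest.approx(0.01)

    def test_call_count_bounded_by_marginal_sets(self):
        rng = np.random.default_rng(5)
        feats, exon_rows, intron_rows = [], [], []
        for g in range(30):
            gid = f"g{g}"
            feats += [
                FeatureRecord(gid, "gene", "1", 1000 * g + 1, 1000 * g + 500, "+", gid),
                FeatureRecord(f"ex{g}", "exon", "1", 1000 * g + 1, 1000 * g + 100, "+", gid),
                FeatureRecord(f"in{g}", "intron", "1", 1000 * g + 101, 1000 * g + 200, "+", gid),
            ]
            exon_rows.append((f"ex{g}", rng.uniform(), gid))
            intron_rows.append((f"in{g}", rng.uniform(), gid))
        exon = pd.DataFrame(exon_rows, columns=["feature_id", "q", "gene_id"])
        exon["p"] = exon["q"]
        intron = pd.DataFrame(intron_rows, columns=["feature_id", "q", "gene_id"])
        intron["p"] = intron["q"]
        calls = sdf.call_differential_splicing(exon, intron, feats, fdr=0.3)
        n_sig_exon_genes = (exon.q < 0.3).sum()
        n_sig_intron_genes = (intron.q < 0.3).sum()
        assert calls.called.sum() <= min(n_sig_exon_genes, n_sig_intron_genes)


class TestAdjacency:
    def test_boundary_sharing_preferred(self):
        feats = _gene_features()
        exon = feats[1]
        adj = sdf.adjacent_introns(exon, [feats[2]])
        assert [i.feature_id for i in adj] == ["in1"]

    def test_nearest_fallback_within_10kb(self):
        exon = FeatureRecord("ex", "exon", "1", 1000, 1200, "+", "g")
        far = FeatureRecord("in_far", "intron", "1", 5000, 5500, "+", "g")
        assert [i.feature_id for i in sdf.adjacent_introns(exon, [far])] == ["in_far"]
        too_far = FeatureRecord("in_toofar", "intron", "1", 50_000, 50_500, "+", "g")
        assert sdf.adjacent_introns(exon, [too_far]) == []


class TestQvalues:
    def test_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_q_at_least_bh_floor_times_pi0(self):
        rng = np.random.default_rng(10)
        p = np.concatenate([rng.uniform(0, 0.001, 20), rng.uniform(size=480)])
        q_storey = qvalues(p, method="storey")
        q_bh = qvalues(p, method="bh")
        # Storey rescales BH by pi0 <= 1
        assert (q_storey <= q_bh + 1e-12).all()
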