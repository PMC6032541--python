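"""End-to-end study drivers over the synthetic cohorts.

Each function runs one self-contained experiment — simulate, build
phenotypes, run the mapping or estimation stage, measure the outcome —
and returns plain numbers. The analysis scripts and the acceptance
checks are thin wrappers around these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import cis_qtl, lgrm_greml as lg, meta_overlap as mo, phenotypes as ph
from . import synthetic_data as sd
from .io_core import FeatureRecord


# ---------------------------------------------------------------------------
# sQTL conjunction mapping


def _sqtl_replicate(seed: int, planted: bool, n: int = 200, usage_shift: float = 0.3):
    cfg = sd.SimConfig(
        n_genes=2,
        frac_sqtl=0.5 if planted else 0.0,
        frac_geqtl=0.0,
        usage_shift=usage_shift,
        n_snps_per_window=40,
        ld_decay=0.7,
        seed=seed,
        tissues=[sd.TissueSpec("t", "c", n)],
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
    return gm, truth, calls


def sqtl_recovery_rate(
    n_reps: int = 50, seed: int = 0, n: int = 200, usage_shift: float = 0.3,
    ld_r2: float = 0.8,
) -> float:
    """Fraction of replicates in which the planted causal SNP, or a proxy in
    LD at r^2 > ``ld_r2`` with it, appears among the conjunction sQTL calls."""
    hits = 0
    for rep in range(n_reps):
        gm, truth, calls = _sqtl_replicate(seed * 100_000 + rep, planted=True,
                                           n=n, usage_shift=usage_shift)
        causal = truth.table.query("effect_type=='sQTL'").causal_snp.iloc[0]
        snp_ids = [s.snp_id for s in gm.snps]
        r2 = np.corrcoef(gm.dosages.astype(float).T)[snp_ids.index(causal)] ** 2
        proxies = {snp_ids[j] for j in np.flatnonzero(r2 > ld_r2)}
        hits += bool(set(calls.snp_id) & proxies)
    return hits / n_reps


def sqtl_null_fdp(n_reps: int = 50, seed: int = 0, n: int = 200) -> float:
    """Mean false-discovery proportion V/max(R,1) of the conjunction calls
    under a global null; with no planted effects every call is false, so this
    is the fraction of replicates with at least one call."""
    fdp = []
    for rep in range(n_reps):
        _, _, calls = _sqtl_replicate(seed * 100_000 + 50_000 + rep, planted=False,
                                      n=n)
        fdp.append(1.0 if len(calls) else 0.0)
    return float(np.mean(fdp))


# ---------------------------------------------------------------------------
# local genetic correlation


def _rg_cohort(seed: int, n: int = 300, m: int = 100):
    cfg = sd.SimConfig(
        n_genes=1, n_snps_per_window=m, seed=seed,
        tissues=[sd.TissueSpec("t1", "c", n)],
    )
    gm = sd.simulate_genotypes(cfg)
    gene = FeatureRecord("gene000", "gene", "1", 2_000_000, 2_002_199, "+", "gene000")
    grm = lg.build_lgrm(gm, gene, method="gcta")
    return gm, grm


def rg_recovery(
    true_rg: float, n_reps: int = 50, seed: int = 0, n: int = 300,
    h2: float = 0.5, with_lrt: bool = False,
) -> tuple[float, list[float]]:
    """Mean bivariate-REML genetic correlation over replicates with
    phenotype pairs planted at ``true_rg``; optionally also the per-replicate
    likelihood-ratio p-values against r = 0."""
    gm, grm = _rg_cohort(seed + 17, n=n)
    rng = np.random.default_rng([seed, 23, int(round(true_rg * 100))])
    ests, pvals = [], []
    for _ in range(n_reps):
        y1, y2 = sd.simulate_phenotype_pair(gm, h2=h2, rg=true_rg, rng=rng)
        fit = lg.bivariate_reml(
            pd.Series(y1, index=gm.samples), pd.Series(y2, index=gm.samples),
            grm, compute_tests=False,
        )
        ests.append(fit.r_lg)
        if with_lrt:
            pvals.append(lg.test_rg(fit, 0))
    return float(np.nanmean(ests)), pvals


# ---------------------------------------------------------------------------
# differential-splicing mixed model


def mixed_model_type1(
    n_features: int = 1000, n_animals: int = 25, seed: int = 0, alpha: float = 0.05,
) -> float:
    """Type-I error of the tissue F test over null repeated-measures features."""
    from .phenotypes import PhenotypeMatrix
    from .splicing_diff import tissue_mixed_model

    rng = np.random.default_rng([seed, 31])
    tissues = ("A", "B", "C")
    samples = [f"s{i}_{t}" for i in range(n_animals) for t in tissues]
    design = pd.DataFrame(
        {
            "animal": [f"an{i}" for i in range(n_animals) for _ in tissues],
            "experiment": [
                "e1" if i < n_animals // 2 else "e2"
                for i in range(n_animals)
                for _ in tissues
            ],
            "tissue": [t for _ in range(n_animals) for t in tissues],
        },
        index=samples,
    )
    vals = np.array(
        [
            np.repeat(rng.normal(0, 0.8, n_animals), len(tissues))
            + rng.normal(0, 1, n_animals * len(tissues))
            for _ in range(n_features)
        ]
    )
    feats = [FeatureRecord(f"f{k}", "exon", "1", 1, 2, "+", "g")
             for k in range(n_features)]
    res = tissue_mixed_model(PhenotypeMatrix(feats, samples, vals, "inclusion"), design)
    return float((res.p < alpha).mean())


# ---------------------------------------------------------------------------
# meta-analysis calibration


def meta_null_rejection_rate(
    n_pairs: int = 10_000, n_tissues: int = 3, seed: int = 0, alpha: float = 0.05,
) -> float:
    """Rejection rate of the multi-tissue chi-square(1) meta-analysis on
    independent standard-normal t values (its null model)."""
    rng = np.random.default_rng([seed, 41])
    tab = pd.DataFrame(
        rng.standard_normal((n_pairs, n_tissues)),
        columns=[f"t{k}" for k in range(n_tissues)],
    )
    tab["snp_id"] = [f"s{i}" for i in range(n_pairs)]
    tab["feature_id"] = "f"
    out = mo.meta_combine(tab)
    return float((out.p < alpha).mean())


def multitrait_null_ks(n_draws: int = 10_000, seed: int = 0) -> float:
    """KS p-value of the multi-trait statistic against chi-square(df) under a
    correlated-t null."""
    rng = np.random.default_rng([seed, 43])
    v = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
    t = rng.standard_normal((n_draws, 3)) @ np.linalg.cholesky(v).T
    vinv = np.linalg.inv(v)
    statvals = np.einsum("ij,jk,ik->i", t, vinv, t)
    return float(stats.kstest(statvals, lambda x: stats.chi2.cdf(x, 3)).pvalue)
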