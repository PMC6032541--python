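"""Per-SNP cis scans and the conjunction rule defining splicing QTLs.

Every SNP within [feature start - window, feature end + window] on the
feature's chromosome is regressed against the phenotype (OLS, additive
dosage coding, optional covariates such as breed). An sQTL call requires the
same SNP to pass the stage FDR in both the exon-inclusion scan and the scan
of at least one adjacent intron's excision ratio; the combined threshold is
the product of the two cutoffs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .fdr import qvalues
from .io_core import FeatureRecord, GenotypeMatrix
from .phenotypes import PhenotypeMatrix
from .splicing_diff import adjacent_introns

log = logging.getLogger(__name__)


def _covariate_matrix(
    covariates: pd.DataFrame | None, samples: list[str]
) -> np.ndarray:
    """Intercept plus numeric-coded covariates aligned to the sample order."""
    if covariates is None:
        return np.ones((len(samples), 1))
    cov = covariates.loc[samples]
    num = pd.get_dummies(cov, drop_first=True).to_numpy(float)
    return np.column_stack([np.ones(len(samples)), num])


def scan_cis(
    pheno: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    features: list[FeatureRecord] | None = None,
    window: int = 1_000_000,
    covariates: pd.DataFrame | None = None,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """OLS scan of every (feature, cis SNP) pair.

    Returns a table with snp_id, feature_id, kind, gene_id, beta, se, t, p
    and q (FDR within this scan). Pairs with fewer than (#covariate columns
    + 3) complete observations, or with no dosage variation among the
    scanned samples, are skipped.
    """
    feats = features if features is not None else pheno.features
    by_id = {f.feature_id: f for f in feats}
    gt_samples = {s: i for i, s in enumerate(genotypes.samples)}
    missing = [s for s in pheno.samples if s not in gt_samples]
    if missing:
        raise ValueError(f"samples without genotypes: {missing[:5]}")
    row_idx = np.array([gt_samples[s] for s in pheno.samples])
    dosages = genotypes.dosages[row_idx].astype(float)
    snp_chrom = np.array([s.chrom for s in genotypes.snps])
    snp_pos = np.array([s.pos for s in genotypes.snps])
    snp_ids = np.array([s.snp_id for s in genotypes.snps])
    cmat = _covariate_matrix(covariates, pheno.samples)
    min_obs = cmat.shape[1] + 3

    rows = []
    n_skipped = 0
    for f, y in zip(pheno.features, pheno.values):
        feat = by_id.get(f.feature_id, f)
        in_win = (snp_chrom == feat.chrom) & (
            (snp_pos >= feat.start - window) & (snp_pos <= feat.end + window)
        )
        cols = np.flatnonzero(in_win)
        if cols.size == 0:
            continue
        obs = ~np.isnan(y)
        n = int(obs.sum())
        if n < min_obs:
            n_skipped += cols.size
            continue
        yy = y[obs]
        c = cmat[obs]
        q_c, _ = np.linalg.qr(c)
        y_r = yy - q_c @ (q_c.T @ yy)
        x = dosages[np.ix_(obs, cols)]
        x_r = x - q_c @ (q_c.T @ x)
        sxx = (x_r**2).sum(axis=0)
        ok = sxx > 1e-12
        n_skipped += int((~ok).sum())
        sxy = x_r.T @ y_r
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        rss = float(y_r @ y_r) - beta**2 * sxx
        df = n - c.shape[1] - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
            t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df)
        for k in np.flatnonzero(ok):
            rows.append(
                (
                    snp_ids[cols[k]],
                    f.feature_id,
                    feat.kind,
                    feat.gene_id,
                    beta[k],
                    se[k],
                    t[k],
                    p[k],
                )
            )
    out = pd.DataFrame(
        rows,
        columns=["snp_id", "feature_id", "kind", "gene_id", "beta", "se", "t", "p"],
    )
    if n_skipped:
        log.info("scan_cis: skipped %d (SNP, feature) pairs", n_skipped)
    if len(out):
        out["q"] = qvalues(out["p"].to_numpy(), method=fdr_method)
    return out


def call_sqtls(
    exon_assoc: pd.DataFrame,
    intron_assoc: pd.DataFrame,
    features: list[FeatureRecord],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Conjunction sQTL calls from exon-inclusion and intron-excision scans.

    One call per (snp, exon) where the exon association has q < fdr and the
    same SNP's association with at least one adjacent intron has q < fdr.
    """
    by_id = {f.feature_id: f for f in features}
    introns = [f for f in features if f.kind == "intron"]
    sig_exon = exon_assoc[exon_assoc["q"] < fdr]
    sig_intron = intron_assoc[intron_assoc["q"] < fdr]
    intron_lookup = {
        (r.snp_id, r.feature_id): r.q for r in sig_intron.itertuples()
    }
    rows = []
    for r in sig_exon.itertuples():
        exon = by_id.get(r.feature_id)
        if exon is None:
            continue
        support = []
        for i in adjacent_introns(exon, introns):
            qi = intron_lookup.get((r.snp_id, i.feature_id))
            if qi is not None:
                support.append((i.feature_id, qi))
        if support:
            support.sort(key=lambda s: s[1])
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "exon_id": r.feature_id,
                    "gene_id": exon.gene_id,
                    "exon_q": r.q,
                    "best_intron_q": support[0][1],
                    "intron_ids": ",".join(s[0] for s in support),
                    "combined_threshold": fdr * fdr,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "exon_id", "gene_id", "exon_q", "best_intron_q",
            "intron_ids", "combined_threshold",
        ],
    )


def classify_qtl_types(
    sqtl_calls: pd.DataFrame,
    exon_expr_assoc: pd.DataFrame,
    gene_expr_assoc: pd.DataFrame,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP boolean membership in {sQTL, eeQTL, geQTL} for one tissue.

    eeQTL / geQTL membership is q < fdr in the respective expression scan;
    sQTL membership comes from the conjunction calls.
    """
    sqtl_snps = set(sqtl_calls["snp_id"]) if len(sqtl_calls) else set()
    ee_snps = set(exon_expr_assoc.loc[exon_expr_assoc["q"] < fdr, "snp_id"])
    ge_snps = set(gene_expr_assoc.loc[gene_expr_assoc["q"] < fdr, "snp_id"])
    universe = sorted(
        set(exon_expr_assoc["snp_id"])
        | set(gene_expr_assoc["snp_id"])
        | sqtl_snps
    )
    return pd.DataFrame(
        {
            "snp_id": universe,
            "sQTL": [s in sqtl_snps for s in universe],
            "eeQTL": [s in ee_snps for s in universe],
            "geQTL": [s in ge_snps for s in universe],
        }
    )
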