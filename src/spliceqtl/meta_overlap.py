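"""Summary-statistic combination across cohorts/traits/tissues and
Fisher's-exact overlap testing.

Three combiners:
  * two-cohort inverse-variance weighting of per-SNP effects (bull vs cow),
    t_w = B_w / se_w;
  * a multi-trait chi-square t' V^-1 t with V the empirical correlation of
    t-values across SNPs (estimated from |t| < 2 SNPs to avoid signal
    contamination);
  * a multi-tissue chi-square(1), (sum_n t_n / sqrt(N))^2, which gains power
    when a QTL acts in the same direction in every tissue.

The cross-tissue validation design cross-tabulates meta-significance against
a held-out tissue's significance, and enrichment between SNP sets is tested
one-sided by the hypergeometric (Fisher's exact) distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class WeightedEffect:
    b_w: float
    se_w: float
    t_w: float


def weighted_t(b1: float, se1: float, b2: float, se2: float) -> WeightedEffect:
    """Inverse-variance weighted two-cohort effect and its signed t value."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    b_w = (b1 * w1 + b2 * w2) / (w1 + w2)
    se_w = 1.0 / np.sqrt(w1 + w2)
    return WeightedEffect(b_w=b_w, se_w=se_w, t_w=b_w / se_w)


def weighted_t_table(
    bull: pd.DataFrame, cow: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized two-cohort weighting over (snp_id, trait) tables with
    columns B and se."""
    merged = bull.merge(cow, on=["snp_id", "trait"], suffixes=("_bull", "_cow"))
    w1 = 1.0 / merged["se_bull"] ** 2
    w2 = 1.0 / merged["se_cow"] ** 2
    merged["B_w"] = (merged["B_bull"] * w1 + merged["B_cow"] * w2) / (w1 + w2)
    merged["se_w"] = 1.0 / np.sqrt(w1 + w2)
    merged["t_w"] = merged["B_w"] / merged["se_w"]
    return merged[["snp_id", "trait", "B_w", "se_w", "t_w"]]


def estimate_t_correlation(t_table: pd.DataFrame, t_max: float = 2.0) -> np.ndarray:
    """Trait-trait correlation of t values over null-ish SNPs (all |t| < t_max)."""
    wide = t_table.pivot(index="snp_id", columns="trait", values="t_w")
    nullish = wide[(wide.abs() < t_max).all(axis=1)]
    if len(nullish) < 10:
        raise ValueError("too few null SNPs to estimate the t correlation")
    return np.corrcoef(nullish.to_numpy(), rowvar=False)


def multitrait_chisq(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Multi-trait statistic t' V^-1 t with df = len(t); returns (stat, p)."""
    t = np.atleast_1d(np.asarray(t, float))
    v = np.atleast_2d(np.asarray(v, float))
    df = t.size
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0 or np.linalg.cond(v) > 1e12:
        raise ValueError("singular trait correlation; prune traits or add ridge")
    stat = float(t @ np.linalg.solve(v, t))
    return stat, float(stats.chi2.sf(stat, df))


def meta_combine(
    t_by_tissue: pd.DataFrame, effective_n: bool = False
) -> pd.DataFrame:
    """Multi-tissue chi-square(1) meta-analysis of signed t values.

    ``t_by_tissue``: rows = (snp_id, feature_id) pairs, one column of t per
    tissue. Pairs with any missing tissue are excluded (counted in the log).
    Returns snp_id, feature_id, n_tissues, chi2, p.

    The statistic assumes the per-tissue t are independent under the null;
    shared-animal tissue pairs violate this. ``effective_n=True`` divides by
    1'R1 instead of N, with R the cross-tissue t correlation estimated from
    null-ish rows (all |t| < 2). Default off, matching standard usage.
    """
    key_cols = [c for c in ("snp_id", "feature_id") if c in t_by_tissue.columns]
    tcols = [c for c in t_by_tissue.columns if c not in key_cols]
    if not tcols:
        raise ValueError("no tissue t-value columns")
    tvals = t_by_tissue[tcols].to_numpy(float)
    complete = ~np.isnan(tvals).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("meta_combine: excluded %d pairs with missing tissues", n_dropped)
    n = len(tcols)
    denom = float(n)
    if effective_n and n > 1:
        nullish = tvals[complete][(np.abs(tvals[complete]) < 2.0).all(axis=1)]
        if len(nullish) < 10:
            raise ValueError("too few null rows to estimate the t correlation")
        r = np.corrcoef(nullish, rowvar=False)
        denom = float(r.sum())
    chi2 = tvals[complete].sum(axis=1) ** 2 / denom
    out = t_by_tissue.loc[complete, key_cols].copy()
    out["n_tissues"] = n
    out["chi2"] = chi2
    out["p"] = stats.chi2.sf(chi2, 1)
    return out.reset_index(drop=True)


@dataclass
class OverlapResult:
    label_a: str
    label_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    background: int
    odds_ratio: float
    p: float


def fisher_overlap(
    set_a: set, set_b: set, background: set,
    label_a: str = "A", label_b: str = "B",
) -> OverlapResult:
    """One-sided (enrichment) Fisher's exact test of the overlap of two SNP
    sets against a background universe."""
    if not set_a <= background or not set_b <= background:
        raise ValueError("sets must be subsets of the background")
    both = len(set_a & set_b)
    a_only = len(set_a) - both
    b_only = len(set_b) - both
    neither = len(background) - both - a_only - b_only
    odds, p = stats.fisher_exact(
        [[both, a_only], [b_only, neither]], alternative="greater"
    )
    return OverlapResult(
        label_a=label_a, label_b=label_b, both=both, a_only=a_only,
        b_only=b_only, neither=neither, background=len(background),
        odds_ratio=float(odds), p=float(p),
    )


def run_validation(
    tissues_combined: dict[str, pd.DataFrame],
    holdout: pd.DataFrame,
    p_single: float = 0.05,
    p_meta: float = 1e-05,
    p_holdout: float = 0.05,
) -> tuple[pd.DataFrame, OverlapResult]:
    """Cross-tissue validation of the meta-analysis against a held-out tissue.

    ``tissues_combined`` maps tissue name to an association table (snp_id,
    feature_id, t, p); candidate pairs must have p < ``p_single`` in every
    combined tissue. Their t values are meta-combined and cross-tabulated
    (meta p < ``p_meta`` vs holdout p < ``p_holdout``), with a Fisher test of
    the overlap. Returns (candidate table with flags, OverlapResult).
    """
    keys = ["snp_id", "feature_id"]
    merged = None
    for name, tab in tissues_combined.items():
        sub = tab.loc[tab["p"] < p_single, keys + ["t"]].rename(
            columns={"t": f"t_{name}"}
        )
        merged = sub if merged is None else merged.merge(sub, on=keys)
    if merged is None or merged.empty:
        raise ValueError("no candidate pairs significant in every combined tissue")
    meta = meta_combine(merged)
    meta = meta.rename(columns={"p": "p_meta", "chi2": "chi2_meta"})
    hold = holdout[keys + ["p"]].rename(columns={"p": "p_holdout"})
    tab = meta.merge(hold, on=keys, how="inner")
    if tab.empty:
        raise ValueError("no candidate pair was tested in the holdout tissue")
    tab["meta_sig"] = tab["p_meta"] < p_meta
    tab["holdout_sig"] = tab["p_holdout"] < p_holdout
    universe = set(map(tuple, tab[keys].to_numpy()))
    set_meta = set(map(tuple, tab.loc[tab.meta_sig, keys].to_numpy()))
    set_hold = set(map(tuple, tab.loc[tab.holdout_sig, keys].to_numpy()))
    overlap = fisher_overlap(
        set_meta, set_hold, universe, label_a="meta", label_b="holdout"
    )
    return tab, overlap


def greedy_lead_loci(
    assoc: pd.DataFrame, positions: pd.DataFrame, radius: int = 1_000_000
) -> pd.DataFrame:
    """Utility: greedy lead-SNP clumping — repeatedly take the most
    significant remaining SNP and absorb everything within ``radius`` bp.

    ``positions``: snp_id, chrom, pos. Not validated against any external
    locus catalogue.
    """
    df = assoc.merge(positions, on="snp_id").sort_values("p")
    leads = []
    taken = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for i in range(len(df)):
        if taken[i]:
            continue
        leads.append(df.iloc[i])
        taken |= (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= radius)
    return pd.DataFrame(leads).reset_index(drop=True)
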