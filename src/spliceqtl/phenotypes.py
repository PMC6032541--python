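"""Count matrices -> regression-ready splicing and expression phenotypes.

The chain mirrors standard eQTL practice: expression filtering on CPM,
exon-inclusion ratios (exon CPM / parent-gene CPM), intron-excision ratios
(junction count / cluster total), removal of ratios below 0.001, log2,
per-feature rank-based inverse-normal ("quantile") normalization, and
per-individual z-score standardization. Missing values propagate (never
imputed) and are excluded pairwise downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io_core import CountMatrix, FeatureRecord

log = logging.getLogger(__name__)


@dataclass
class RatioMatrix:
    """Exon-inclusion or intron-excision ratios, features x samples."""

    features: list[FeatureRecord]
    samples: list[str]
    values: np.ndarray  # nonneg, NaN where denominator was zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[f.feature_id for f in self.features],
            columns=self.samples,
        )


@dataclass
class PhenotypeMatrix:
    """Normalized phenotype values with a provenance tag.

    ``kind`` is one of inclusion / excision / exon_expr / gene_expr.
    """

    features: list[FeatureRecord]
    samples: list[str]
    values: np.ndarray
    kind: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[f.feature_id for f in self.features],
            columns=self.samples,
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# phenotype kind: {self.kind}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="feature_id")


def read_phenotypes(path, features: list[FeatureRecord]) -> PhenotypeMatrix:
    """Read a PhenotypeMatrix TSV written by ``write_tsv``."""
    with open(path) as fh:
        header = fh.readline()
        kind = header.split(":", 1)[1].strip() if ":" in header else "unknown"
        df = pd.read_csv(fh, sep="\t", index_col=0)
    by_id = {f.feature_id: f for f in features}
    missing = [fid for fid in df.index if fid not in by_id]
    if missing:
        raise ValueError(f"phenotype rows without annotation: {missing[:5]}")
    return PhenotypeMatrix(
        features=[by_id[fid] for fid in df.index],
        samples=list(df.columns),
        values=df.to_numpy(float),
        kind=kind,
    )


def cpm(counts: np.ndarray) -> np.ndarray:
    """Counts per million; library size = per-sample column total."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = int(np.flatnonzero(lib == 0)[0])
        raise ValueError(f"sample column {bad} has zero library size")
    return counts * 1e6 / lib


def filter_expressed(
    counts: CountMatrix, cpm_min: float = 0.0, frac_min: float = 0.40
) -> CountMatrix:
    """Keep features with CPM > cpm_min in strictly more than frac_min of samples."""
    c = cpm(counts.counts)
    frac = (c > cpm_min).mean(axis=1)
    keep = frac > frac_min
    log.info("filter_expressed: kept %d of %d features", int(keep.sum()), keep.size)
    return CountMatrix(
        features=[f for f, k in zip(counts.features, keep) if k],
        samples=list(counts.samples),
        counts=counts.counts[keep],
    )


def inclusion_ratio(
    exon_counts: CountMatrix, gene_counts: CountMatrix
) -> RatioMatrix:
    """Exon-to-gene expression ratio on the CPM scale, per sample.

    Missing (NaN) where the parent gene's count is zero.
    """
    if exon_counts.samples != gene_counts.samples:
        raise ValueError("exon and gene matrices must share sample order")
    gene_ids = [f.feature_id for f in gene_counts.features]
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for f in exon_counts.features:
        if f.gene_id not in gene_row:
            raise ValueError(f"exon {f.feature_id}: parent gene {f.gene_id} not found")
    exon_cpm = cpm(exon_counts.counts)
    gene_cpm = cpm(gene_counts.counts)
    parent = np.array([gene_row[f.gene_id] for f in exon_counts.features])
    denom = gene_cpm[parent]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, exon_cpm / np.where(denom > 0, denom, 1.0), np.nan)
    return RatioMatrix(
        features=list(exon_counts.features),
        samples=list(exon_counts.samples),
        values=vals,
    )


def excision_ratio(intron_counts: CountMatrix) -> RatioMatrix:
    """Each intron's junction count over its cluster total (cluster = gene).

    Ratios sum to 1 over the cluster in each sample; missing where the
    cluster total is zero.
    """
    if not intron_counts.features:
        raise ValueError("empty intron cluster set")
    gene_of = np.array([f.gene_id for f in intron_counts.features])
    vals = np.full(intron_counts.counts.shape, np.nan)
    for gid in pd.unique(gene_of):
        rows = np.flatnonzero(gene_of == gid)
        block = intron_counts.counts[rows].astype(float)
        tot = block.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals[rows] = np.where(tot > 0, block / np.where(tot > 0, tot, 1.0), np.nan)
    return RatioMatrix(
        features=list(intron_counts.features),
        samples=list(intron_counts.samples),
        values=vals,
    )


def _rank_inverse_normal(row: np.ndarray) -> np.ndarray:
    """Map non-missing entries onto standard-normal quantiles at (rank-0.5)/m."""
    out = np.full_like(row, np.nan, dtype=float)
    obs = ~np.isnan(row)
    m = int(obs.sum())
    if m == 0:
        return out
    ranks = rankdata(row[obs], method="average")
    out[obs] = norm.ppf((ranks - 0.5) / m)
    return out


def _zscore_columns(values: np.ndarray) -> np.ndarray:
    """Per-sample z-score over non-missing entries (sample SD, ddof=1)."""
    out = values.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            continue
        mu = col[obs].mean()
        sd = col[obs].std(ddof=1)
        if sd == 0:
            out[obs, j] = 0.0
        else:
            out[obs, j] = (col[obs] - mu) / sd
    return out


def _rank_common(row: np.ndarray, pooled: np.ndarray) -> np.ndarray:
    """Map non-missing entries onto the pooled empirical distribution's
    quantiles at (rank-0.5)/m — the all-features-to-common-distribution
    alternative to the inverse-normal transform."""
    out = np.full_like(row, np.nan, dtype=float)
    obs = ~np.isnan(row)
    m = int(obs.sum())
    if m == 0:
        return out
    ranks = rankdata(row[obs], method="average")
    out[obs] = np.quantile(pooled, (ranks - 0.5) / m)
    return out


def _quantile_zscore_chain(
    features: list[FeatureRecord],
    samples: list[str],
    values: np.ndarray,
    kind: str,
    mode: str = "inverse_normal",
) -> PhenotypeMatrix:
    if mode == "inverse_normal":
        normed = np.apply_along_axis(_rank_inverse_normal, 1, values)
    elif mode == "common":
        pooled = np.sort(values[~np.isnan(values)])
        normed = np.apply_along_axis(_rank_common, 1, values, pooled)
    else:
        raise ValueError(f"unknown quantile mode {mode!r}")
    n_obs = (~np.isnan(normed)).sum(axis=1)
    spread = np.nanmax(normed, axis=1, initial=0) - np.nanmin(normed, axis=1, initial=0)
    keep = (n_obs >= 3) & (spread > 0)
    dropped = int((~keep).sum())
    if dropped:
        log.warning(
            "%s normalization: dropped %d feature(s) with <3 values or no variation",
            kind, dropped,
        )
    return PhenotypeMatrix(
        features=[f for f, k in zip(features, keep) if k],
        samples=list(samples),
        values=_zscore_columns(normed[keep]),
        kind=kind,
    )


def normalize_ratios(
    ratios: RatioMatrix,
    ratio_min: float = 0.001,
    kind: str = "inclusion",
    mode: str = "inverse_normal",
) -> PhenotypeMatrix:
    """Ratio phenotypes: drop entries < ratio_min, log2, per-feature quantile
    normalization (inverse-normal by default, ``mode='common'`` for the
    all-features-to-common-distribution variant), then per-individual
    z-score."""
    vals = ratios.values.astype(float).copy()
    vals[vals < ratio_min] = np.nan
    with np.errstate(divide="ignore"):
        vals = np.log2(vals)
    return _quantile_zscore_chain(ratios.features, ratios.samples, vals, kind, mode)


def log2_cpm(counts: np.ndarray) -> np.ndarray:
    """log2((count + 0.5) * 1e6 / (library + 1)), the standard log-CPM."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    return np.log2((counts + 0.5) * 1e6 / (lib + 1.0))


def normalize_expression(
    counts: CountMatrix, kind: str = "gene_expr", mode: str = "inverse_normal"
) -> PhenotypeMatrix:
    """Expression phenotypes: log2-CPM with 0.5 pseudocount, then the same
    quantile-normalization and individual z-score chain as the ratios.

    All observations are weighted equally; no mean-variance precision weights
    are computed.
    """
    vals = log2_cpm(counts.counts)
    return _quantile_zscore_chain(counts.features, counts.samples, vals, kind, mode)
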