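"""Synthetic multi-tissue genotype + count data with planted, recoverable truth.

The generator emulates the structure of a multi-tissue cattle RNA-seq study:
a dairy cohort of two breeds measured in two cell types (blood, milk) plus two
smaller disjoint cohorts (liver, muscle); whole-genome-sequence-like dosages
with AR(1) linkage disequilibrium in each gene's cis window; gene/exon/intron
counts with negative-binomial noise; cis genetic effects on gene expression
(geQTL) or on the usage of one target exon with opposite movement of the
adjacent introns (sQTL); a SNP-mediated local polygenic term whose effects are
correlated across tissues with a specified genetic correlation; and two-cohort
(bull/cow) GWAS summary statistics with different standard errors.

Every output is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_core import CountMatrix, FeatureRecord, GenotypeMatrix, SnpRecord, folded_maf

# stage tags for independent, reproducible random substreams
_STREAM_GENO = 1
_STREAM_COUNTS = 2
_STREAM_GWAS = 3


@dataclass
class TissueSpec:
    """A tissue and the cohort of individuals it samples.

    Tissues sharing a ``cohort`` label are measured on the same individuals
    (the blood/milk design); distinct cohorts are disjoint animals.
    """

    name: str
    cohort: str
    n_individuals: int


@dataclass
class SimConfig:
    tissues: list[TissueSpec] = field(
        default_factory=lambda: [
            TissueSpec("blood", "dairy", 131),
            TissueSpec("milk", "dairy", 131),
            TissueSpec("liver", "beef_liver", 35),
            TissueSpec("muscle", "beef_muscle", 41),
        ]
    )
    n_genes: int = 20
    exons_per_gene: int = 5
    n_snps_per_window: int = 60
    ld_decay: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_geqtl: float = 0.25
    frac_sqtl: float = 0.25
    effect_size: float = 1.0  # geQTL shift per alt allele, residual-SD units (log2 scale)
    usage_shift: float = 0.3  # sQTL inclusion-ratio difference between dose 2 and dose 0
    cross_tissue_rg: float = 0.8
    breed_fraction: float = 0.8  # proportion of the dairy cohort in breed A
    breed_fst: float = 0.0  # >0 turns on breed-differentiated allele frequencies
    breed_splice_shift: float = 0.0  # usage shift of the target exon in breed B
    breed_splice_genes: int = 0  # number of genes carrying the breed splice shift
    tissue_usage_sd: float = 0.08  # SD of per-(gene, tissue) usage offsets
    polygenic_sd: float = 0.3  # SD of the local polygenic term, log2 scale
    noise_sd: float = 0.4  # residual SD, log2 scale
    depth: float = 500.0  # expected gene-level count
    intron_depth_frac: float = 0.5  # cluster depth relative to gene depth
    dispersion: float = 0.1  # negative-binomial dispersion
    window: int = 1_000_000
    gene_spacing: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if not -1.0 <= self.cross_tissue_rg <= 1.0:
            raise ValueError("cross_tissue_rg must be in [-1, 1]")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= lo <= hi <= 0.5")
        for frac in (self.frac_geqtl, self.frac_sqtl, self.breed_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("proportions must be in [0, 1]")
        if self.frac_geqtl + self.frac_sqtl > 1.0:
            raise ValueError("frac_geqtl + frac_sqtl must not exceed 1")

    # -- cohort bookkeeping -------------------------------------------------

    def cohorts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.tissues:
            if t.cohort in out and out[t.cohort] != t.n_individuals:
                raise ValueError(f"cohort {t.cohort!r} with inconsistent sizes")
            out[t.cohort] = t.n_individuals
        return out

    def individuals(self) -> pd.DataFrame:
        """One row per individual: id, cohort, breed (A/B within the dairy cohort)."""
        rows = []
        for cohort, n in self.cohorts().items():
            n_a = int(round(self.breed_fraction * n)) if cohort == "dairy" else n
            for i in range(n):
                breed = "A" if (cohort != "dairy" or i < n_a) else "B"
                rows.append((f"{cohort}_{i:04d}", cohort, breed))
        return pd.DataFrame(rows, columns=["individual", "cohort", "breed"])

    def tissue_samples(self, tissue: str) -> list[str]:
        spec = next(t for t in self.tissues if t.name == tissue)
        ind = self.individuals()
        return list(ind.loc[ind.cohort == spec.cohort, "individual"])


@dataclass
class TruthTable:
    """Planted per-gene ground truth for downstream recovery tests."""

    table: pd.DataFrame  # gene_id, effect_type, causal_snp, target_exon,
    # effect_size, usage_shift, breed_shift, true_rg

    def causal_snp(self, gene_id: str) -> str | None:
        row = self.table.set_index("gene_id").loc[gene_id]
        snp = row["causal_snp"]
        return None if pd.isna(snp) else str(snp)


# ---------------------------------------------------------------------------
# annotation layout


def simulate_annotation(config: SimConfig) -> list[FeatureRecord]:
    """Deterministic gene/exon/intron layout: equally spaced genes on chr 1.

    Each gene has ``exons_per_gene`` 200-bp exons separated by 300-bp introns,
    alternating strand so both TSS conventions are exercised.
    """
    feats: list[FeatureRecord] = []
    exon_len, intron_len = 200, 300
    for g in range(config.n_genes):
        gid = f"gene{g:03d}"
        gstart = 2_000_000 + g * config.gene_spacing
        gene_len = config.exons_per_gene * exon_len + (
            config.exons_per_gene - 1
        ) * intron_len
        strand = "+" if g % 2 == 0 else "-"
        feats.append(
            FeatureRecord(gid, "gene", "1", gstart, gstart + gene_len - 1, strand, gid)
        )
        pos = gstart
        for e in range(config.exons_per_gene):
            feats.append(
                FeatureRecord(
                    f"{gid}_exon{e}", "exon", "1", pos, pos + exon_len - 1, strand, gid
                )
            )
            if e < config.exons_per_gene - 1:
                feats.append(
                    FeatureRecord(
                        f"{gid}_intron{e}",
                        "intron",
                        "1",
                        pos + exon_len,
                        pos + exon_len + intron_len - 1,
                        strand,
                        gid,
                    )
                )
            pos += exon_len + intron_len
    return feats


# ---------------------------------------------------------------------------
# genotypes


def _window_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, rho: float
) -> np.ndarray:
    """AR(1) haplotypes: allele j copies allele j-1 with probability rho."""
    m = freqs.size
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        fresh = (rng.random(n_hap) < freqs[j]).astype(np.int8)
        copy = rng.random(n_hap) < rho
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def _breed_freqs(
    rng: np.random.Generator, base: np.ndarray, fst: float
) -> np.ndarray:
    """Balding-Nichols breed-specific frequencies around the base frequency."""
    if fst <= 0:
        return base.copy()
    a = base * (1.0 - fst) / fst
    b = (1.0 - base) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 0.01, 0.99)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Dosages for every individual at every gene's cis window.

    SNP positions span gene +/- window; within-window LD follows r^|i-j| with
    r = ``ld_decay`` via haplotype copying; Hardy-Weinberg holds within breed;
    ``breed_fst`` > 0 differentiates dairy-breed allele frequencies.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENO])
    ind = config.individuals()
    n = len(ind)
    is_b = (ind.breed == "B").to_numpy()
    lo, hi = config.maf_range
    snps: list[tuple[str, int]] = []
    cols: list[np.ndarray] = []
    alleles = np.array(list("ACGT"))
    for g in range(config.n_genes):
        gstart = 2_000_000 + g * config.gene_spacing
        m = config.n_snps_per_window
        positions = np.linspace(
            gstart - config.window + 1, gstart + config.window, m
        ).astype(int)
        base = rng.uniform(lo, hi, size=m)
        flip = rng.random(m) < 0.5  # alt allele may be the major one
        base = np.where(flip, 1.0 - base, base)
        freq_a = _breed_freqs(rng, base, config.breed_fst)
        freq_b = _breed_freqs(rng, base, config.breed_fst)
        hap_a = _window_haplotypes(rng, 2 * n, freq_a, config.ld_decay)
        if config.breed_fst > 0 and is_b.any():
            hap_b = _window_haplotypes(rng, 2 * n, freq_b, config.ld_decay)
            hap = hap_a.reshape(n, 2, m)
            hap[is_b] = hap_b.reshape(n, 2, m)[is_b]
            dos = hap.sum(axis=1)
        else:
            dos = hap_a.reshape(n, 2, m).sum(axis=1)
        for j in range(m):
            snps.append((f"snp_g{g:03d}_{j:03d}", int(positions[j])))
        cols.append(dos)
    dosages = np.concatenate(cols, axis=1).astype(np.int16)
    records = []
    for j, (sid, pos) in enumerate(snps):
        ref, alt = rng.choice(alleles, size=2, replace=False)
        records.append(
            SnpRecord(sid, "1", pos, str(ref), str(alt), folded_maf(dosages[:, j]))
        )
    return GenotypeMatrix(
        samples=list(ind.individual), snps=records, dosages=dosages
    )


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + disp * mean^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-8)
    if disp <= 0:
        return rng.poisson(mean)
    size = 1.0 / disp
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _assign_effects(config: SimConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_genes
    n_ge = int(round(config.frac_geqtl * n))
    n_sq = int(round(config.frac_sqtl * n))
    types = ["geQTL"] * n_ge + ["sQTL"] * n_sq + ["none"] * (n - n_ge - n_sq)
    rng.shuffle(types)
    return types


def _usage_slope(pi0: float, shift: float) -> float:
    """Logistic slope so that usage(dose 2) - usage(dose 0) equals ``shift``."""
    target = np.clip(pi0 + shift, 0.02, 0.98)
    return float(logit(target) - logit(pi0)) / 2.0


def simulate_counts(
    config: SimConfig, genotypes: GenotypeMatrix
) -> tuple[dict[str, dict[str, CountMatrix]], TruthTable]:
    """Per-tissue gene/exon/intron counts with planted cis effects.

    Returns ``(counts, truth)`` where ``counts[tissue]`` maps
    ``{"gene","exon","intron"}`` to a CountMatrix, and ``truth`` records each
    gene's effect type, causal SNP, target exon, and the planted rg.

    Gene-level log2 expression is baseline + dosage*beta + local polygenic
    term + noise; the polygenic term is SNP-mediated with per-SNP effects
    drawn bivariate-normal across tissues at correlation ``cross_tissue_rg``,
    so the local-GRM genetic correlation estimand equals that value. sQTL
    genes shift the target exon's usage by a logistic function of dosage
    calibrated to ``usage_shift``, with the adjacent introns moving oppositely.
    """
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    feats = simulate_annotation(config)
    ind = config.individuals().set_index("individual")
    snp_frame = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in genotypes.snps],
            "pos": [s.pos for s in genotypes.snps],
        }
    )
    effect_types = _assign_effects(config, rng)
    tissue_names = [t.name for t in config.tissues]
    n_t = len(tissue_names)
    # equicorrelated cross-tissue effect correlation
    r_mat = np.full((n_t, n_t), config.cross_tissue_rg)
    np.fill_diagonal(r_mat, 1.0)
    # nearest-PD guard for negative rg with >2 tissues
    w, v = np.linalg.eigh(r_mat)
    r_mat = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
    chol = np.linalg.cholesky(r_mat)

    genes = [f for f in feats if f.kind == "gene"]
    truth_rows = []
    # per-tissue accumulators
    out: dict[str, dict[str, list]] = {
        t: {"gene": [], "exon": [], "intron": []} for t in tissue_names
    }
    feat_lists: dict[str, dict[str, list[FeatureRecord]]] = {
        t: {"gene": [], "exon": [], "intron": []} for t in tissue_names
    }
    sample_lists = {t: config.tissue_samples(t) for t in tissue_names}
    sample_idx = {
        t: [genotypes.samples.index(s) for s in sample_lists[t]] for t in tissue_names
    }

    for g_i, gene in enumerate(genes):
        gid = gene.feature_id
        etype = effect_types[g_i]
        exons = [f for f in feats if f.kind == "exon" and f.gene_id == gid]
        introns = [f for f in feats if f.kind == "intron" and f.gene_id == gid]
        # window SNPs and standardized dosage for the polygenic term
        in_win = snp_frame.snp_id.str.startswith(f"snp_g{g_i:03d}_")
        snp_cols = np.flatnonzero(in_win.to_numpy())
        dos = genotypes.dosages[:, snp_cols].astype(float)
        p_hat = dos.mean(axis=0) / 2.0
        sd = np.sqrt(np.maximum(2 * p_hat * (1 - p_hat), 1e-8))
        z_std = (dos - 2 * p_hat) / sd
        m = len(snp_cols)
        # per-SNP effects, bivariate-normal across tissues at cross_tissue_rg
        u_raw = rng.standard_normal((m, n_t)) @ chol.T
        u = u_raw * (config.polygenic_sd / np.sqrt(m))
        poly = z_std @ u  # individuals x tissues

        causal_snp, target_exon = None, None
        beta = 0.0
        if etype != "none":
            # pick a common-ish SNP near the gene for power
            near = np.argsort(
                np.abs(snp_frame.pos.to_numpy()[snp_cols] - gene.start)
            )
            mafs = np.array([genotypes.snps[snp_cols[k]].maf for k in near])
            pick = near[np.flatnonzero(mafs >= 0.1)[0]] if (mafs >= 0.1).any() else near[0]
            causal_snp = genotypes.snps[snp_cols[pick]].snp_id
            causal_dose = dos[:, pick]
        if etype == "geQTL":
            beta = config.effect_size * np.hypot(config.polygenic_sd, config.noise_sd)
        if etype == "sQTL":
            target_exon = exons[len(exons) // 2].feature_id

        base_usage = rng.dirichlet(np.full(len(exons), 5.0))
        base_usage = np.clip(base_usage, 0.05, 0.6)
        # tissue-differential splicing: a per-(gene, tissue) offset on the
        # middle exon's usage, constant within tissue so cis contrasts and
        # dosage effects are untouched
        tissue_offsets = rng.normal(0.0, config.tissue_usage_sd, size=n_t)
        intron_w = rng.dirichlet(np.full(max(len(introns), 1), 5.0))
        breed_gene = g_i < config.breed_splice_genes and config.breed_splice_shift != 0
        breed_exon = exons[len(exons) // 2].feature_id if breed_gene else None

        for t_i, tissue in enumerate(tissue_names):
            idx = sample_idx[tissue]
            n_s = len(idx)
            log2_mu = (
                np.log2(config.depth)
                + poly[idx, t_i]
                + rng.normal(0.0, config.noise_sd, size=n_s)
            )
            if etype == "geQTL":
                log2_mu = log2_mu + beta * causal_dose[idx]
            mu = np.power(2.0, log2_mu)
            gene_counts = _nb_draw(rng, mu, config.dispersion)
            # exon usage per sample
            usage = np.tile(base_usage, (n_s, 1))
            tgt = len(exons) // 2
            if etype == "sQTL":
                s = _usage_slope(base_usage[tgt], config.usage_shift)
                usage[:, tgt] = expit(
                    logit(base_usage[tgt]) + s * causal_dose[idx]
                )
            if breed_gene:
                is_b_t = (ind.loc[sample_lists[tissue], "breed"] == "B").to_numpy()
                shifted = np.clip(
                    usage[is_b_t, tgt] + config.breed_splice_shift, 0.02, 0.98
                )
                usage[is_b_t, tgt] = shifted
            if config.tissue_usage_sd > 0:
                usage[:, tgt] = np.clip(usage[:, tgt] + tissue_offsets[t_i],
                                        0.02, 0.98)
            exon_counts = _nb_draw(rng, mu[:, None] * usage, config.dispersion)
            # introns: adjacent introns move opposite to the included exon
            w_mat = np.tile(intron_w, (n_s, 1))
            has_tissue = config.tissue_usage_sd > 0 and abs(tissue_offsets[t_i]) > 0
            if len(introns) and (etype == "sQTL" or breed_gene or has_tissue):
                adj = [k for k in (tgt - 1, tgt) if 0 <= k < len(introns)]
                drive = np.zeros(n_s)
                if etype == "sQTL":
                    s = _usage_slope(base_usage[tgt], config.usage_shift)
                    drive = drive + s * causal_dose[idx]
                if breed_gene:
                    is_b_t = (ind.loc[sample_lists[tissue], "breed"] == "B").to_numpy()
                    drive = drive + 2.0 * config.breed_splice_shift * is_b_t
                if has_tissue:
                    drive = drive + 2.0 * tissue_offsets[t_i]
                for k in adj:
                    w_mat[:, k] = w_mat[:, k] * np.exp(-drive)
                w_mat = w_mat / w_mat.sum(axis=1, keepdims=True)
            if len(introns):
                mu_i = mu[:, None] * config.intron_depth_frac * w_mat
                intron_counts = _nb_draw(rng, mu_i, config.dispersion)
            else:
                intron_counts = np.zeros((n_s, 0), dtype=int)

            out[tissue]["gene"].append(gene_counts[None, :])
            feat_lists[tissue]["gene"].append(gene)
            out[tissue]["exon"].append(exon_counts.T)
            feat_lists[tissue]["exon"].extend(exons)
            if len(introns):
                out[tissue]["intron"].append(intron_counts.T)
                feat_lists[tissue]["intron"].extend(introns)

        truth_rows.append(
            {
                "gene_id": gid,
                "effect_type": etype,
                "causal_snp": causal_snp,
                "target_exon": target_exon,
                "effect_size": beta if etype == "geQTL" else (
                    config.usage_shift if etype == "sQTL" else 0.0
                ),
                "usage_shift": config.usage_shift if etype == "sQTL" else 0.0,
                "breed_shift": config.breed_splice_shift if breed_gene else 0.0,
                "breed_exon": breed_exon,
                "true_rg": config.cross_tissue_rg,
            }
        )

    counts: dict[str, dict[str, CountMatrix]] = {}
    for tissue in tissue_names:
        counts[tissue] = {}
        for kind in ("gene", "exon", "intron"):
            blocks = out[tissue][kind]
            mat = (
                np.concatenate(blocks, axis=0)
                if blocks
                else np.zeros((0, len(sample_lists[tissue])), dtype=int)
            )
            counts[tissue][kind] = CountMatrix(
                features=feat_lists[tissue][kind],
                samples=sample_lists[tissue],
                counts=mat,
            )
    return counts, TruthTable(pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# GWAS summary statistics


def simulate_gwas_summaries(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    n_traits: int,
    frac_causal: float = 0.01,
    effect_sd: float = 0.5,
    se_bull: float = 1.0,
    se_cow: float = 2.0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Two-cohort (bull/cow) per-SNP effects and SEs for ``n_traits`` traits.

    Returns ``(summaries, truth)``: ``summaries['bull']`` / ``['cow']`` are
    long tables (snp_id, trait, B, se); truth holds the planted effects. Bulls
    have smaller SEs than cows, mimicking the phenotypic error difference
    between progeny-tested bulls and cows.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GWAS])
    snp_ids = [s.snp_id for s in genotypes.snps]
    m = len(snp_ids)
    truth_rows, tabs = [], {"bull": [], "cow": []}
    for t in range(n_traits):
        trait = f"trait{t}"
        causal = rng.random(m) < frac_causal
        b_true = np.where(causal, rng.normal(0.0, effect_sd, size=m), 0.0)
        for cohort, se in (("bull", se_bull), ("cow", se_cow)):
            b_hat = b_true + rng.normal(0.0, se, size=m)
            tabs[cohort].append(
                pd.DataFrame(
                    {"snp_id": snp_ids, "trait": trait, "B": b_hat, "se": se}
                )
            )
        truth_rows.append(
            pd.DataFrame({"snp_id": snp_ids, "trait": trait, "b_true": b_true})
        )
    summaries = {c: pd.concat(tabs[c], ignore_index=True) for c in tabs}
    return summaries, pd.concat(truth_rows, ignore_index=True)


# ---------------------------------------------------------------------------
# direct phenotype pairs for genetic-correlation studies


def simulate_phenotype_pair(
    genotypes: GenotypeMatrix,
    h2: float,
    rg: float,
    rng: np.random.Generator,
    snp_cols: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One feature's phenotype in two tissues with local heritability ``h2``
    and genetic correlation ``rg``, SNP-mediated so the GRM-REML estimand is
    exactly ``rg``. Returns (y1, y2) over ``genotypes.samples``.
    """
    dos = genotypes.dosages.astype(float)
    if snp_cols is not None:
        dos = dos[:, snp_cols]
    p_hat = dos.mean(axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    dos = dos[:, keep]
    p_hat = p_hat[keep]
    z = (dos - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    n, m = z.shape
    chol = np.linalg.cholesky(np.array([[1.0, rg], [rg, 1.0]]) + 1e-12 * np.eye(2))
    u = (rng.standard_normal((m, 2)) @ chol.T) * np.sqrt(h2 / m)
    g = z @ u
    e = rng.standard_normal((n, 2)) * np.sqrt(1.0 - h2)
    y = g + e
    return y[:, 0], y[:, 1]
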