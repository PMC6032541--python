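"""Differential splicing across tissues and between breeds.

Per feature (exon inclusion or intron excision phenotype) the tissue test is
a linear mixed model

    y = animal (random) + experiment (fixed) + tissue (fixed) + e

fit by REML with a single animal variance component; the tissue term is a
Wald F test with Satterthwaite denominator degrees of freedom obtained by the
delta method from the REML information matrix. The breed test is the
ordinary two-group linear model. A gene is called differentially spliced when
at least one exon and one intron adjacent to it are both significant at the
stage FDR; the combined threshold is reported as the product of the two
stage cutoffs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .fdr import qvalues
from .io_core import FeatureRecord
from .phenotypes import PhenotypeMatrix

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-10


def _design_matrix(df: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, dict]:
    """Intercept + treatment-coded dummies; aliased columns dropped by rank."""
    blocks = [np.ones((len(df), 1))]
    spans: dict[str, slice] = {}
    for col in columns:
        d = pd.get_dummies(df[col].astype(str), drop_first=True).to_numpy(float)
        start = sum(b.shape[1] for b in blocks)
        blocks.append(d)
        spans[col] = slice(start, start + d.shape[1])
    x = np.concatenate(blocks, axis=1)
    # drop aliased columns, keeping track of surviving indices
    keep: list[int] = []
    r = 0
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > r:
            keep.append(j)
            r += 1
    remap = {old: new for new, old in enumerate(keep)}
    spans = {
        c: [remap[j] for j in range(s.start, s.stop) if j in remap]
        for c, s in spans.items()
    }
    return x[:, keep], spans


class _RemlFit:
    """REML of y = X b + Z u + e with u ~ N(0, s2a I), in the rotated basis."""

    def __init__(self, y, x, d, u):
        # d, u: eigenvalues/vectors of ZZ'
        self.ys = u.T @ y
        self.xs = u.T @ x
        self.d = d
        self.n, self.p = x.shape

    def _profile_neg2ll(self, lam: float) -> float:
        w = 1.0 + lam * self.d
        xw = self.xs / w[:, None]
        xtx = self.xs.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ self.ys)
        resid = self.ys - self.xs @ beta
        rss = float(resid @ (resid / w))
        s2e = rss / (self.n - self.p)
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        return (
            (self.n - self.p) * np.log(s2e) + np.log(w).sum() + logdet_xtx
        )

    def fit(self) -> None:
        res = minimize_scalar(
            lambda t: self._profile_neg2ll(np.exp(t)),
            bounds=(-14.0, 14.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        if self._profile_neg2ll(0.0) <= res.fun:  # boundary: no animal variance
            lam = 0.0
        self.lam = lam
        w = 1.0 + lam * self.d
        xw = self.xs / w[:, None]
        self.xtx = self.xs.T @ xw
        self.beta = np.linalg.solve(self.xtx, xw.T @ self.ys)
        resid = self.ys - self.xs @ self.beta
        self.s2e = float(resid @ (resid / w)) / (self.n - self.p)
        self.s2a = lam * self.s2e
        self.vcov_beta = self.s2e * np.linalg.inv(self.xtx)

    # -- two-parameter restricted loglik for the Satterthwaite delta method --

    def _neg2ll_theta(self, s2a: float, s2e: float) -> float:
        w = s2e + s2a * self.d
        xw = self.xs / w[:, None]
        xtx = self.xs.T @ xw
        beta = np.linalg.solve(xtx, xw.T @ self.ys)
        resid = self.ys - self.xs @ beta
        rss = float(resid @ (resid / w))
        _, logdet = np.linalg.slogdet(xtx)
        return np.log(w).sum() + logdet + rss

    def theta_vcov(self) -> np.ndarray:
        theta = np.array([self.s2a, self.s2e])
        h = np.maximum(1e-4 * np.maximum(theta, self.s2e), 1e-7)
        hess = np.zeros((2, 2))

        def f(t):
            return 0.5 * self._neg2ll_theta(max(t[0], 0.0), max(t[1], _VAR_FLOOR))

        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                val = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
                hess[i, j] = hess[j, i] = val
        return np.linalg.pinv(hess)

    def _vcov_beta_at(self, s2a: float, s2e: float) -> np.ndarray:
        w = s2e + s2a * self.d
        xw = self.xs / w[:, None]
        return np.linalg.inv(self.xs.T @ xw)

    def ftest(self, cols: list[int]) -> tuple[float, float, float]:
        """Wald F for the listed coefficients with Satterthwaite ddf."""
        q = len(cols)
        lb = self.beta[cols]
        m = self.vcov_beta[np.ix_(cols, cols)]
        lam_m, qmat = np.linalg.eigh(m)
        lam_m = np.maximum(lam_m, 1e-300)
        t2 = (qmat.T @ lb) ** 2 / lam_m
        fstat = float(t2.sum() / q)
        vtheta = self.theta_vcov()
        theta = np.array([self.s2a, self.s2e])
        h = np.maximum(1e-4 * np.maximum(theta, self.s2e), 1e-7)
        # numerical gradient of each eigen-contrast variance wrt theta
        nus = []
        for k in range(q):
            lk = qmat[:, k]
            grad = np.zeros(2)
            for i in range(2):
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] = max(tm[i] - h[i], 0.0 if i == 0 else _VAR_FLOOR)
                cp = self._vcov_beta_at(tp[0], tp[1])[np.ix_(cols, cols)]
                cm = self._vcov_beta_at(tm[0], tm[1])[np.ix_(cols, cols)]
                grad[i] = (lk @ cp @ lk - lk @ cm @ lk) / (tp[i] - tm[i])
            var_f = float(grad @ vtheta @ grad)
            fk = float(lk @ m @ lk)
            nu = 2.0 * fk**2 / var_f if var_f > 0 else self.n - self.p
            nus.append(nu)
        good = [nu for nu in nus if nu > 2.0]
        if good:
            e_sum = sum(nu / (nu - 2.0) for nu in good)
            ddf = 2.0 * e_sum / (e_sum - q) if e_sum > q else self.n - self.p
        else:
            ddf = self.n - self.p
        p = float(stats.f.sf(fstat, q, ddf))
        return fstat, ddf, p


def tissue_mixed_model(
    pheno: PhenotypeMatrix,
    design: pd.DataFrame,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """Per-feature mixed-model F test of the tissue term.

    ``design`` is indexed by sample id with columns animal, experiment,
    tissue. Returns a table with feature_id, kind, term, stat, ddf, p, q,
    gene_id. Rank-deficient features are skipped with a warning.
    """
    design = design.loc[pheno.samples]
    if design["tissue"].nunique() < 2:
        raise ValueError("need at least 2 tissues")
    animals = design["animal"].astype(str).to_numpy()
    rows = []
    eig_cache: dict[bytes, tuple] = {}
    for f, y in zip(pheno.features, pheno.values):
        obs = ~np.isnan(y)
        key = obs.tobytes()
        sub = design.loc[obs]
        try:
            x, spans = _design_matrix(sub, ["experiment", "tissue"])
        except Exception:
            log.warning("skipping %s: design construction failed", f.feature_id)
            continue
        if not spans["tissue"]:
            log.warning("skipping %s: tissue term aliased", f.feature_id)
            continue
        if key in eig_cache:
            d, u = eig_cache[key]
        else:
            a = animals[obs]
            z = pd.get_dummies(a).to_numpy(float)
            d, u = np.linalg.eigh(z @ z.T)
            eig_cache[key] = (d, u)
        fit = _RemlFit(y[obs], x, d, u)
        try:
            fit.fit()
            fstat, ddf, p = fit.ftest(spans["tissue"])
        except np.linalg.LinAlgError:
            log.warning("skipping %s: singular fit", f.feature_id)
            continue
        rows.append(
            {
                "feature_id": f.feature_id,
                "kind": f.kind,
                "term": "tissue",
                "stat": fstat,
                "ddf": ddf,
                "p": p,
                "gene_id": f.gene_id,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = qvalues(out["p"].to_numpy(), method=fdr_method)
    return out


def breed_model(
    pheno: PhenotypeMatrix, breed: pd.Series, fdr_method: str = "storey"
) -> pd.DataFrame:
    """Per-feature OLS of phenotype on a two-level breed indicator.

    Equivalent to the equal-variance two-sample t-test.
    """
    breed = breed.loc[pheno.samples]
    levels = sorted(breed.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"breed must have exactly 2 levels, got {levels}")
    ind = (breed.astype(str) == levels[1]).to_numpy(float)
    rows = []
    for f, y in zip(pheno.features, pheno.values):
        obs = ~np.isnan(y)
        yy, xx = y[obs], ind[obs]
        n = yy.size
        if n < 3 or len(np.unique(xx)) < 2:
            continue
        xc = xx - xx.mean()
        beta = float(xc @ yy / (xc @ xc))
        resid = yy - yy.mean() - beta * xc
        s2 = float(resid @ resid) / (n - 2)
        se = float(np.sqrt(s2 / (xc @ xc)))
        t = beta / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), n - 2))
        rows.append(
            {
                "feature_id": f.feature_id,
                "kind": f.kind,
                "term": "breed",
                "stat": t,
                "p": p,
                "gene_id": f.gene_id,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = qvalues(out["p"].to_numpy(), method=fdr_method)
    return out


# ---------------------------------------------------------------------------
# exon/intron adjacency and the gene-level conjunction call


def adjacent_introns(
    exon: FeatureRecord,
    introns: list[FeatureRecord],
    max_gap: int = 10_000,
) -> list[FeatureRecord]:
    """Introns sharing a boundary with the exon; failing that, the nearest
    same-gene intron within ``max_gap`` bp."""
    same_gene = [i for i in introns if i.gene_id == exon.gene_id]
    adj = [
        i
        for i in same_gene
        if i.start == exon.end + 1 or i.end == exon.start - 1
    ]
    if adj:
        return adj
    best, best_d = None, max_gap + 1
    for i in same_gene:
        d = max(i.start - exon.end, exon.start - i.end, 0)
        if d < best_d:
            best, best_d = i, d
    return [best] if best is not None else []


def call_differential_splicing(
    exon_results: pd.DataFrame,
    intron_results: pd.DataFrame,
    features: list[FeatureRecord],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Gene-level conjunction: >=1 exon with q < fdr AND >=1 adjacent intron
    with q < fdr. Returns per-gene calls with the combined threshold fdr^2
    and the per-gene combined score min(exon q x intron q) used for ranking.
    """
    by_id = {f.feature_id: f for f in features}
    introns = [f for f in features if f.kind == "intron"]
    exon_q = exon_results.set_index("feature_id")["q"]
    intron_q = intron_results.set_index("feature_id")["q"]
    rows = []
    for gid, grp in exon_results.groupby("gene_id"):
        called = False
        best_combo = np.inf
        best_exon = best_intron = None
        rule = ""
        for fid in grp["feature_id"]:
            exon = by_id.get(fid)
            if exon is None:
                continue
            adj = adjacent_introns(exon, introns)
            shares = any(
                i.start == exon.end + 1 or i.end == exon.start - 1 for i in adj
            )
            for i in adj:
                if i.feature_id not in intron_q.index:
                    continue
                qe, qi = float(exon_q[fid]), float(intron_q[i.feature_id])
                if qe * qi < best_combo:
                    best_combo = qe * qi
                    best_exon, best_intron = fid, i.feature_id
                    rule = "boundary" if shares else "nearest"
                if qe < fdr and qi < fdr:
                    called = True
        rows.append(
            {
                "gene_id": gid,
                "called": called,
                "best_exon": best_exon,
                "best_intron": best_intron,
                "combined_q": best_combo if np.isfinite(best_combo) else np.nan,
                "adjacency_rule": rule,
                "combined_threshold": fdr * fdr,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        log.info(
            "differential splicing: %d of %d genes called (combined threshold %g)",
            int(out.called.sum()), len(out), fdr * fdr,
        )
    return out


def top_gene_ranking(calls: pd.DataFrame, top_frac: float = 0.10) -> pd.DataFrame:
    """Top genes among the called set, ranked by the combined exon x intron q."""
    called = calls[calls.called].sort_values("combined_q")
    k = max(1, int(np.ceil(top_frac * len(called)))) if len(called) else 0
    return called.head(k)
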