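"""Local genomic relationship matrices and bivariate REML genetic correlations.

For a feature of interest, SNPs within the cis window form a local GRM; a
feature's phenotype measured in two tissues is then modelled as a two-trait
mixed model with genetic covariance structured by that GRM. The genetic
correlation is

    r_lg = cov_g(tr1, tr2) / sqrt(var_g(tr1) * var_g(tr2))

and is tested against 0 (regular chi-square(1) likelihood-ratio test) and
against 1 (boundary null: 50:50 mixture of chi-square(0) and chi-square(1)).

The covariance model is linear in its parameters
(vg1, cov_g, vg2, ve1, ve2[, cov_e]), so the unconstrained and r=0 fits use
average-information (AI) REML with step-halving and a gradient-ascent
fallback; accepted iterations never decrease the restricted likelihood. The
r=1 fit is nonlinear in the parameters and uses a derivative-free simplex
search on log-variance coordinates. When the two traits are measured on the
same individuals, an eigenrotation of the GRM reduces the model to
independent 2x2 blocks (an exact, fast path); overlapping or disjoint
designs use dense matrices. A residual covariance is estimated only when the
sample sets overlap — it is structurally absent for disjoint designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import FeatureRecord, GenotypeMatrix

log = logging.getLogger(__name__)

_M1 = np.array([[1.0, 0.0], [0.0, 0.0]])
_M2 = np.array([[0.0, 0.0], [0.0, 1.0]])
_M12 = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass
class LocalGRM:
    samples: list[str]
    matrix: np.ndarray
    n_snps: int


def build_lgrm(
    genotypes: GenotypeMatrix,
    feature: FeatureRecord,
    window: int = 1_000_000,
    method: str = "vanraden1",
    ridge: float = 1e-6,
) -> LocalGRM:
    """GRM from SNPs within ``window`` bp of the feature.

    ``vanraden1``: centered crossproduct scaled by sum(2 p (1-p));
    ``gcta``: per-SNP standardized crossproduct scaled by the SNP count.
    Monomorphic SNPs are excluded; fewer than 10 usable SNPs is an error.
    A small ridge keeps small local windows invertible.
    """
    pos = np.array([s.pos for s in genotypes.snps])
    chrom = np.array([s.chrom for s in genotypes.snps])
    in_win = (chrom == feature.chrom) & (
        (pos >= feature.start - window) & (pos <= feature.end + window)
    )
    dos = genotypes.dosages[:, in_win].astype(float)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    dos, p = dos[:, poly], p[poly]
    m = dos.shape[1]
    if m < 10:
        raise ValueError(
            f"only {m} polymorphic SNPs within {window} bp of "
            f"{feature.feature_id}; widen the window"
        )
    w = dos - 2 * p
    if method == "vanraden1":
        g = (w @ w.T) / float((2 * p * (1 - p)).sum())
    elif method == "gcta":
        z = w / np.sqrt(2 * p * (1 - p))
        g = (z @ z.T) / m
    else:
        raise ValueError(f"unknown GRM method {method!r}")
    g = g + ridge * np.eye(g.shape[0])
    return LocalGRM(samples=list(genotypes.samples), matrix=g, n_snps=m)


# ---------------------------------------------------------------------------
# REML engines: restricted loglik, score, and average-information matrix
# for a covariance model V(theta) = sum_k theta_k V_k.


class _BlockEngine:
    """Shared-sample fast path: rotate by the GRM eigenbasis so the two-trait
    model becomes n independent 2x2 blocks."""

    def __init__(self, y1: np.ndarray, y2: np.ndarray, g: np.ndarray, names):
        d, u = np.linalg.eigh(g)
        self.d = np.maximum(d, 0.0)
        self.y = np.column_stack([u.T @ y1, u.T @ y2])  # (n, 2)
        self.x = u.T @ np.ones(len(y1))  # intercept per trait, rotated
        self.names = list(names)
        ones = np.ones_like(self.d)
        spec = {
            "vg1": (self.d, _M1), "cg": (self.d, _M12), "vg2": (self.d, _M2),
            "ve1": (ones, _M1), "ve2": (ones, _M2), "ce": (ones, _M12),
        }
        self.comp = [spec[n] for n in self.names]

    def _sigma(self, theta: np.ndarray) -> np.ndarray:
        n = self.d.size
        sig = np.zeros((n, 2, 2))
        for t, (a, m) in zip(theta, self.comp):
            sig += t * a[:, None, None] * m
        return sig

    @staticmethod
    def _inv2(sig: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        det = sig[:, 0, 0] * sig[:, 1, 1] - sig[:, 0, 1] * sig[:, 1, 0]
        inv = np.empty_like(sig)
        inv[:, 0, 0] = sig[:, 1, 1]
        inv[:, 1, 1] = sig[:, 0, 0]
        inv[:, 0, 1] = -sig[:, 0, 1]
        inv[:, 1, 0] = -sig[:, 1, 0]
        return inv / det[:, None, None], det

    def _core(self, theta):
        sig = self._sigma(theta)
        inv, det = self._inv2(sig)
        if np.any(det <= 0) or not np.all(np.isfinite(inv)):
            return None
        w = np.einsum("i,ijk->jk", self.x**2, inv)
        rhs = np.einsum("i,ijk,ik->j", self.x, inv, self.y)
        try:
            beta = np.linalg.solve(w, rhs)
        except np.linalg.LinAlgError:
            return None
        r = self.y - self.x[:, None] * beta
        py = np.einsum("ijk,ik->ij", inv, r)
        quad = float(np.einsum("ij,ij->", r, py))
        sign, logdet_w = np.linalg.slogdet(w)
        ll = -0.5 * (np.log(det).sum() + logdet_w + quad)
        return sig, inv, w, beta, r, py, ll

    def loglik(self, theta: np.ndarray) -> float:
        core = self._core(theta)
        return -np.inf if core is None else core[-1]

    def derivs(self, theta: np.ndarray):
        core = self._core(theta)
        if core is None:
            return -np.inf, None, None
        sig, inv, w, beta, r, py, ll = core
        w_inv = np.linalg.inv(w)
        k = len(self.comp)
        score = np.zeros(k)
        wk_list = []
        for ki, (a, m) in enumerate(self.comp):
            # tr(P V_k)
            tr_vinv = float(np.einsum("i,ijk,kj->", a, inv, m))
            mid = np.einsum("i,ijk,kl,ilm->jm", self.x**2 * a, inv, m, inv)
            tr_p = tr_vinv - float(np.trace(w_inv @ mid))
            ypvpy = float(np.einsum("i,ij,jk,ik->", a, py, m, py))
            score[ki] = -0.5 * (tr_p - ypvpy)
            wk_list.append(a[:, None] * (py @ m.T))
        ai = np.zeros((k, k))
        pw = []
        for wk in wk_list:
            rhs = np.einsum("i,ijk,ik->j", self.x, inv, wk)
            bw = w_inv @ rhs
            rw = wk - self.x[:, None] * bw
            pw.append(np.einsum("ijk,ik->ij", inv, rw))
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(
                    np.einsum("ij,ij->", wk_list[i], pw[j])
                )
        return ll, score, ai


class _DenseEngine:
    """General path for overlapping or disjoint sample sets."""

    def __init__(self, y: np.ndarray, x: np.ndarray, v_parts: list[np.ndarray], names):
        self.y, self.x = y, x
        self.v_parts = v_parts
        self.names = list(names)

    def _core(self, theta):
        v = sum(t * vk for t, vk in zip(theta, self.v_parts))
        try:
            c = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        try:
            vinv = np.linalg.inv(v)
            xtvx = self.x.T @ vinv @ self.x
            beta = np.linalg.solve(xtvx, self.x.T @ (vinv @ self.y))
        except np.linalg.LinAlgError:
            return None
        r = self.y - self.x @ beta
        py = vinv @ r
        quad = float(r @ py)
        _, logdet_w = np.linalg.slogdet(xtvx)
        ll = -0.5 * (logdet_v + logdet_w + quad)
        p = vinv - vinv @ self.x @ np.linalg.solve(xtvx, self.x.T @ vinv)
        return p, py, ll

    def loglik(self, theta: np.ndarray) -> float:
        core = self._core(theta)
        return -np.inf if core is None else core[-1]

    def derivs(self, theta: np.ndarray):
        core = self._core(theta)
        if core is None:
            return -np.inf, None, None
        p, py, ll = core
        k = len(self.v_parts)
        score = np.zeros(k)
        vk_py = [vk @ py for vk in self.v_parts]
        for i, vk in enumerate(self.v_parts):
            score[i] = -0.5 * (float(np.einsum("ij,ji->", p, vk)) - float(py @ vk_py[i]))
        ai = np.zeros((k, k))
        p_vk_py = [p @ w for w in vk_py]
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(vk_py[i] @ p_vk_py[j])
        return ll, score, ai


# Search coordinates: log variances and atanh correlations keep every
# iterate interior (positive variances, |correlation| < 1).

_PHI_CLIP = 30.0
_Z_CLIP = 12.0  # |r| saturates at ~1 - 1e-10 while the 2x2 blocks stay invertible


def _theta_from_phi(phi: np.ndarray, names: list[str]) -> np.ndarray:
    ph = dict(zip(_phi_names(names), phi))
    t = {"vg1": np.exp(ph["lvg1"]), "vg2": np.exp(ph["lvg2"]),
         "ve1": np.exp(ph["lve1"]), "ve2": np.exp(ph["lve2"])}
    if "zg" in ph:
        t["cg"] = np.tanh(ph["zg"]) * np.sqrt(t["vg1"] * t["vg2"])
    if "ze" in ph:
        t["ce"] = np.tanh(ph["ze"]) * np.sqrt(t["ve1"] * t["ve2"])
    return np.array([t[n] for n in names])


def _phi_names(names: list[str]) -> list[str]:
    m = {"vg1": "lvg1", "cg": "zg", "vg2": "lvg2",
         "ve1": "lve1", "ve2": "lve2", "ce": "ze"}
    return [m[n] for n in names]


def _jacobian(phi: np.ndarray, names: list[str]) -> np.ndarray:
    """d theta / d phi for the log/atanh transform."""
    pnames = _phi_names(names)
    ph = dict(zip(pnames, phi))
    theta = dict(zip(names, _theta_from_phi(phi, names)))
    j = np.zeros((len(names), len(pnames)))
    for i, nm in enumerate(names):
        if nm in ("vg1", "vg2", "ve1", "ve2"):
            j[i, pnames.index({"vg1": "lvg1", "vg2": "lvg2",
                               "ve1": "lve1", "ve2": "lve2"}[nm])] = theta[nm]
        elif nm == "cg":
            s = np.sqrt(theta["vg1"] * theta["vg2"])
            j[i, pnames.index("lvg1")] = theta["cg"] / 2.0
            j[i, pnames.index("lvg2")] = theta["cg"] / 2.0
            j[i, pnames.index("zg")] = (1.0 - np.tanh(ph["zg"]) ** 2) * s
        elif nm == "ce":
            s = np.sqrt(theta["ve1"] * theta["ve2"])
            j[i, pnames.index("lve1")] = theta["ce"] / 2.0
            j[i, pnames.index("lve2")] = theta["ce"] / 2.0
            j[i, pnames.index("ze")] = (1.0 - np.tanh(ph["ze"]) ** 2) * s
    return j


def _clip_phi(phi: np.ndarray, names: list[str]) -> np.ndarray:
    out = np.clip(phi, -_PHI_CLIP, _PHI_CLIP)
    for k, pn in enumerate(_phi_names(names)):
        if pn in ("zg", "ze"):
            out[k] = np.clip(out[k], -_Z_CLIP, _Z_CLIP)
    return out


def _ai_reml(engine, theta0: np.ndarray, names, max_iter: int, tol: float):
    """AI-REML Newton steps in the transformed coordinates, with step-halving
    and a gradient-ascent fallback; accepted iterations are monotone in the
    restricted likelihood."""
    t0 = dict(zip(names, np.asarray(theta0, float)))
    phi = []
    for pn in _phi_names(names):
        if pn.startswith("l"):
            key = {"lvg1": "vg1", "lvg2": "vg2", "lve1": "ve1", "lve2": "ve2"}[pn]
            phi.append(np.log(max(t0[key], 1e-12)))
        elif pn == "zg":
            r0 = t0["cg"] / max(np.sqrt(t0["vg1"] * t0["vg2"]), 1e-12)
            phi.append(np.arctanh(np.clip(r0, -0.99, 0.99)))
        else:
            r0 = t0["ce"] / max(np.sqrt(t0["ve1"] * t0["ve2"]), 1e-12)
            phi.append(np.arctanh(np.clip(r0, -0.99, 0.99)))
    phi = _clip_phi(np.array(phi), names)
    ll, score, ai = engine.derivs(_theta_from_phi(phi, names))
    path = [ll]
    converged = False
    k = len(names)
    for _ in range(max_iter):
        if score is None:
            break
        j = _jacobian(phi, names)
        score_p = j.T @ score
        ai_p = j.T @ ai @ j
        try:
            step = np.linalg.solve(ai_p + 1e-8 * np.eye(k), score_p)
        except np.linalg.LinAlgError:
            step = score_p
        # cap step length in the transformed space for stability
        norm = np.abs(step).max()
        if norm > 4.0:
            step = step * (4.0 / norm)
        accepted = False
        for trial in (step, score_p / (np.abs(score_p).max() + 1e-30)):
            alpha = 1.0
            for _ in range(30):
                cand = _clip_phi(phi + alpha * trial, names)
                ll_new = engine.loglik(_theta_from_phi(cand, names))
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                break
        if not accepted:
            converged = True
            break
        delta = ll_new - ll
        phi, ll = cand, ll_new
        path.append(ll)
        if abs(delta) < tol * (1.0 + abs(ll)):
            converged = True
            break
        _, score, ai = engine.derivs(_theta_from_phi(phi, names))
    theta = _theta_from_phi(phi, names)
    _, _, ai = engine.derivs(theta)
    return theta, ll, ai, path, converged


@dataclass
class BivarFit:
    """Variance components and the genetic correlation from a bivariate fit."""

    var_g1: float
    var_g2: float
    cov_g: float
    var_e1: float
    var_e2: float
    cov_e: float | None
    r_lg: float
    se_r: float
    loglik: float
    converged: bool
    p_vs_0: float | None = None
    p_vs_1: float | None = None
    loglik_path: list[float] = field(default_factory=list)
    _engine: object | None = field(default=None, repr=False)
    _names: list[str] = field(default_factory=list, repr=False)


def _align(y: pd.Series, grm_samples: list[str]) -> pd.Series:
    y = y.dropna()
    keep = [s for s in grm_samples if s in y.index]
    return y.loc[keep]


def _delta_se_r(theta: dict[str, float], vcov: np.ndarray, names: list[str]) -> float:
    vg1, vg2, cg = theta["vg1"], theta["vg2"], theta["cg"]
    if vg1 <= 0 or vg2 <= 0:
        return np.nan
    r = cg / np.sqrt(vg1 * vg2)
    grad = np.zeros(len(names))
    grad[names.index("vg1")] = -r / (2 * vg1)
    grad[names.index("vg2")] = -r / (2 * vg2)
    grad[names.index("cg")] = 1.0 / np.sqrt(vg1 * vg2)
    var = float(grad @ vcov @ grad)
    return float(np.sqrt(var)) if var > 0 else np.nan


def bivariate_reml(
    y1: pd.Series,
    y2: pd.Series,
    grm: LocalGRM,
    max_iter: int = 200,
    tol: float = 1e-8,
    fit_res_cov: bool | None = None,
    compute_tests: bool = True,
) -> BivarFit:
    """REML fit of the two-trait local-GRM model; see the module docstring.

    ``y1``/``y2`` are one feature's phenotype in two tissues, indexed by
    sample id; sample sets may overlap fully, partially, or not at all.
    ``fit_res_cov`` defaults to True when any sample appears in both traits.
    """
    y1 = _align(y1, grm.samples)
    y2 = _align(y2, grm.samples)
    shared = [s for s in y1.index if s in set(y2.index)]
    if fit_res_cov is None:
        fit_res_cov = len(shared) > 0
    if fit_res_cov and not shared:
        raise ValueError("cannot fit a residual covariance with disjoint samples")
    names = ["vg1", "cg", "vg2", "ve1", "ve2"] + (["ce"] if fit_res_cov else [])
    pos = {s: i for i, s in enumerate(grm.samples)}

    if list(y1.index) == list(y2.index):
        idx = [pos[s] for s in y1.index]
        g = grm.matrix[np.ix_(idx, idx)]
        engine = _BlockEngine(y1.to_numpy(), y2.to_numpy(), g, names)
    else:
        i1 = [pos[s] for s in y1.index]
        i2 = [pos[s] for s in y2.index]
        n1, n2 = len(i1), len(i2)
        n = n1 + n2
        g11 = grm.matrix[np.ix_(i1, i1)]
        g22 = grm.matrix[np.ix_(i2, i2)]
        g12 = grm.matrix[np.ix_(i1, i2)]
        zero11, zero22 = np.zeros((n1, n1)), np.zeros((n2, n2))
        a1 = np.block([[g11, np.zeros((n1, n2))], [np.zeros((n2, n1)), zero22]])
        a2 = np.block([[zero11, np.zeros((n1, n2))], [np.zeros((n2, n1)), g22]])
        a12 = np.block([[zero11, g12], [g12.T, zero22]])
        e1 = np.diag(np.r_[np.ones(n1), np.zeros(n2)])
        e2 = np.diag(np.r_[np.zeros(n1), np.ones(n2)])
        parts = {"vg1": a1, "cg": a12, "vg2": a2, "ve1": e1, "ve2": e2}
        if fit_res_cov:
            e12 = np.zeros((n, n))
            pos2 = {s: j for j, s in enumerate(y2.index)}
            for i, s in enumerate(y1.index):
                if s in pos2:
                    e12[i, n1 + pos2[s]] = e12[n1 + pos2[s], i] = 1.0
            parts["ce"] = e12
        y = np.r_[y1.to_numpy(), y2.to_numpy()]
        x = np.zeros((n, 2))
        x[:n1, 0] = 1.0
        x[n1:, 1] = 1.0
        engine = _DenseEngine(y, x, [parts[nm] for nm in names], names)

    v1, v2 = float(np.var(y1)), float(np.var(y2))
    scale = 0.5 * (v1 + v2)
    start = {"vg1": 0.5 * v1, "cg": 0.0, "vg2": 0.5 * v2,
             "ve1": 0.5 * v1, "ve2": 0.5 * v2, "ce": 0.0}
    theta0 = np.array([start[nm] for nm in names])
    theta, ll, ai, path, converged = _ai_reml(engine, theta0, names, max_iter, tol)
    t = dict(zip(names, theta))
    # a genetic variance collapsing to the boundary leaves r_lg undefined
    at_boundary = t["vg1"] <= 1e-7 * scale or t["vg2"] <= 1e-7 * scale
    if at_boundary:
        r_lg, se_r = np.nan, np.nan
    else:
        r_lg = float(t["cg"] / np.sqrt(t["vg1"] * t["vg2"]))
        se_r = np.nan
        if ai is not None:
            try:
                vcov = np.linalg.inv(ai + 1e-12 * np.eye(len(names)))
                se_r = _delta_se_r(t, vcov, names)
            except np.linalg.LinAlgError:
                pass
    fit = BivarFit(
        var_g1=t["vg1"], var_g2=t["vg2"], cov_g=t["cg"],
        var_e1=t["ve1"], var_e2=t["ve2"], cov_e=t.get("ce"),
        r_lg=r_lg, se_r=se_r, loglik=ll, converged=converged,
        loglik_path=path, _engine=engine, _names=names,
    )
    if compute_tests and converged and not at_boundary:
        fit.p_vs_0 = test_rg(fit, 0)
        fit.p_vs_1 = test_rg(fit, 1)
    return fit


def _constrained_loglik_max(fit: BivarFit, null_value: float) -> float:
    engine, names = fit._engine, fit._names
    if null_value == 0:
        sub = [nm for nm in names if nm != "cg"]
        theta0 = np.array(
            [getattr(fit, {"vg1": "var_g1", "vg2": "var_g2", "ve1": "var_e1",
                           "ve2": "var_e2", "ce": "cov_e"}[nm]) for nm in sub]
        )

        class _Wrap:
            def __init__(self, eng):
                self.eng = eng

            def _full(self, th):
                t = dict(zip(sub, th))
                t["cg"] = 0.0
                return np.array([t[nm] for nm in names])

            def loglik(self, th):
                return self.eng.loglik(self._full(th))

            def derivs(self, th):
                ll, score, ai = self.eng.derivs(self._full(th))
                if score is None:
                    return ll, None, None
                keep = [names.index(nm) for nm in sub]
                return ll, score[keep], ai[np.ix_(keep, keep)]

        theta, ll, _, _, conv = _ai_reml(_Wrap(engine), theta0, sub, 200, 1e-8)
        if not conv:
            log.warning("constrained (r=0) fit did not converge; p reported missing")
            return np.nan
        return ll
    if null_value == 1:
        free = ["vg1", "vg2", "ve1", "ve2"]
        has_ce = "ce" in names

        def assemble(x):
            vg1, vg2, ve1, ve2 = np.exp(np.clip(x[:4], -_PHI_CLIP, _PHI_CLIP))
            t = {"vg1": vg1, "vg2": vg2, "ve1": ve1, "ve2": ve2,
                 "cg": np.sqrt(vg1 * vg2)}
            if has_ce:
                # same saturation as the unconstrained search coordinates
                t["ce"] = np.tanh(np.clip(x[4], -_Z_CLIP, _Z_CLIP)) * np.sqrt(ve1 * ve2)
            return np.array([t[nm] for nm in names])

        x0 = np.log(np.maximum(
            [fit.var_g1, fit.var_g2, fit.var_e1, fit.var_e2], 1e-8
        ))
        if has_ce:
            ce0 = fit.cov_e or 0.0
            lim = np.sqrt(fit.var_e1 * fit.var_e2)
            x0 = np.r_[x0, np.arctanh(np.clip(ce0 / max(lim, 1e-12), -0.999, 0.999))]
        res = optimize.minimize(
            lambda x: -engine.loglik(assemble(x)), x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-9, "fatol": 1e-10},
        )
        if not np.isfinite(res.fun):
            log.warning("constrained (r=1) fit did not converge; p reported missing")
            return np.nan
        return -res.fun
    raise ValueError("null_value must be 0 or 1")


def test_rg(fit: BivarFit, null_value: int) -> float:
    """Likelihood-ratio p-value against r_lg = 0 or r_lg = 1.

    Against 0 the statistic is referred to chi-square(1); against 1 the null
    sits on the parameter boundary and the 50:50 chi-square(0)/chi-square(1)
    mixture is used. A statistic of exactly zero returns p = 1.
    """
    if fit._engine is None:
        raise ValueError("fit carries no model state; refit with bivariate_reml")
    ll0 = _constrained_loglik_max(fit, null_value)
    if not np.isfinite(ll0):
        return float('nan')
    stat = max(2.0 * (fit.loglik - ll0), 0.0)
    if stat <= 1e-12:
        return 1.0
    if null_value == 0:
        return float(stats.chi2.sf(stat, 1))
    return float(min(1.0, 0.5 * stats.chi2.sf(stat, 1)))


# ---------------------------------------------------------------------------
# univariate oracle used by tests and for local-h2 reporting


def univariate_reml(y: pd.Series, grm: LocalGRM) -> tuple[float, float]:
    """Single-trait GRM REML; returns (var_g, var_e) via a 1-D profile search."""
    y = _align(y, grm.samples)
    pos = {s: i for i, s in enumerate(grm.samples)}
    idx = [pos[s] for s in y.index]
    g = grm.matrix[np.ix_(idx, idx)]
    d, u = np.linalg.eigh(g)
    d = np.maximum(d, 0.0)
    ys = u.T @ y.to_numpy()
    xs = u.T @ np.ones(len(ys))
    n = len(ys)

    def neg2ll(log_lam):
        lam = np.exp(log_lam)
        w = 1.0 + lam * d
        xtx = float((xs**2 / w).sum())
        beta = float((xs * ys / w).sum()) / xtx
        r = ys - xs * beta
        s2e = float((r**2 / w).sum()) / (n - 1)
        return (n - 1) * np.log(s2e) + np.log(w).sum() + np.log(xtx)

    res = optimize.minimize_scalar(
        neg2ll, bounds=(-14, 14), method="bounded", options={"xatol": 1e-10}
    )
    lam = float(np.exp(res.x))
    if neg2ll(-30) <= res.fun:
        lam = 0.0
    w = 1.0 + lam * d
    xtx = float((xs**2 / w).sum())
    beta = float((xs * ys / w).sum()) / xtx
    r = ys - xs * beta
    s2e = float((r**2 / w).sum()) / (n - 1)
    return lam * s2e, s2e
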