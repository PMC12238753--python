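"""Random-intercept linear mixed models with Satterthwaite inference.

The crossover designs analyzed here need exactly one random effect (a
participant intercept), for which the marginal covariance is block
compound-symmetric: ``V_i = sigma2 * I + tau2 * 11'`` per participant.  The
model is estimated by REML with closed-form per-block algebra and a 2-D
variance-parameter optimization; fixed-effect contrasts are tested with
t/F statistics whose denominator degrees of freedom come from the
Satterthwaite approximation (numerical gradient of the contrast variance in
the variance parameters against the observed REML information).

Savings-style models with one record per participant omit the random effect
and reduce to ordinary least squares with classical residual df; both paths
expose the same result surface (Type III term tests, contrast tests, EMMs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import FactorDesign

__all__ = ["LinearModelFit", "fit_lmm", "fit_ols", "type3_anova"]

_SINGULAR_TOL = 1e-8


@dataclass
class LinearModelFit:
    """Unified fitted-model surface for the LMM and OLS paths."""

    design: FactorDesign
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float | None          # None for OLS
    df_resid: float
    data: pd.DataFrame
    outcome: str
    kind: str                   # "lmm" | "ols"
    group_col: str | None = None
    reml: float | None = None
    singular: bool = False
    diagnostics: dict = field(default_factory=dict)
    _satt: dict = field(default_factory=dict, repr=False)

    def contrast(self, L: np.ndarray) -> dict:
        """Estimate, SE, df, t and p for a single contrast row L."""
        L = np.asarray(L, dtype=float)
        est = float(L @ self.beta)
        var = float(L @ self.cov_beta @ L)
        se = float(np.sqrt(max(var, 0.0)))
        df = self._contrast_df(L, var)
        t = est / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        return {"estimate": est, "se": se, "df": df, "t": t, "p": p}

    def _contrast_df(self, L: np.ndarray, var: float) -> float:
        if self.kind == "ols" or self.tau2 is None or self.singular:
            return self.df_resid
        grad = _contrast_var_grad(self._satt["blocks"], L,
                                  (self.sigma2, self.tau2))
        A = self._satt["vcov_theta"]
        denom = float(grad @ A @ grad)
        if denom <= 0:
            return self.df_resid
        df = 2.0 * var ** 2 / denom
        return float(np.clip(df, 1.0, self.df_resid))


# ---------------------------------------------------------------------------
# REML machinery


def _blocks(X: np.ndarray, y: np.ndarray, ids: np.ndarray):
    out = []
    for g in pd.unique(ids):
        m = ids == g
        out.append((X[m], y[m]))
    return out


def _reml_pieces(blocks, theta):
    """Accumulate A = X'V^-1 X, b = X'V^-1 y, q = y'V^-1 y, log|V|."""
    sigma2, tau2 = theta
    p = blocks[0][0].shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    q = 0.0
    logdet = 0.0
    for Xi, yi in blocks:
        ni = len(yi)
        k = tau2 / (sigma2 + ni * tau2)
        Xs, ys = Xi.sum(axis=0), yi.sum()
        A += (Xi.T @ Xi - k * np.outer(Xs, Xs)) / sigma2
        b += (Xi.T @ yi - k * Xs * ys) / sigma2
        q += (yi @ yi - k * ys * ys) / sigma2
        logdet += ni * np.log(sigma2) + np.log1p(ni * tau2 / sigma2)
    return A, b, q, logdet


def _neg_reml(blocks, theta, n, p):
    sigma2, tau2 = theta
    if sigma2 <= 0 or tau2 < 0:
        return np.inf
    A, b, q, logdet = _reml_pieces(blocks, theta)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    rss = q - b @ np.linalg.solve(A, b)
    return 0.5 * (logdet + logdetA + rss)


def _contrast_var_grad(blocks, L, theta, rel_step=1e-5):
    """Numerical gradient of g(theta) = L C(theta) L' (central differences)."""
    def g(th):
        A, *_ = _reml_pieces(blocks, th)
        return float(L @ np.linalg.solve(A, L))

    grad = np.zeros(2)
    for j in range(2):
        h = rel_step * max(abs(theta[j]), 1e-10)
        tp, tm = list(theta), list(theta)
        tp[j] += h
        tm[j] = max(tm[j] - h, 0.0 if j == 1 else 1e-12)
        grad[j] = (g(tp) - g(tm)) / (tp[j] - tm[j])
    return grad


def _reml_information(blocks, theta, n, p, rel_step=1e-4):
    """Observed information of the REML criterion in (sigma2, tau2)."""
    def f(th):
        return _neg_reml(blocks, th, n, p)

    H = np.zeros((2, 2))
    h = [rel_step * max(abs(theta[j]), 1e-8) for j in range(2)]
    f0 = f(theta)
    for j in range(2):
        for k in range(j, 2):
            if j == k:
                tp = list(theta); tp[j] += h[j]
                tm = list(theta); tm[j] = max(tm[j] - h[j], 1e-12)
                hj = (tp[j] - theta[j] + theta[j] - tm[j]) / 2
                H[j, j] = (f(tp) - 2 * f0 + f(tm)) / hj ** 2
            else:
                tpp = list(theta); tpp[j] += h[j]; tpp[k] += h[k]
                tpm = list(theta); tpm[j] += h[j]; tpm[k] = max(tpm[k] - h[k], 1e-12)
                tmp = list(theta); tmp[j] = max(tmp[j] - h[j], 1e-12); tmp[k] += h[k]
                tmm = list(theta); tmm[j] = max(tmm[j] - h[j], 1e-12); tmm[k] = max(tmm[k] - h[k], 1e-12)
                H[j, k] = H[k, j] = ((f(tpp) - f(tpm) - f(tmp) + f(tmm))
                                     / ((tpp[j] - tmm[j]) * (tpp[k] - tmm[k])))
    return H


def _residual_diagnostics(resid: np.ndarray) -> dict:
    out = {"resid_mean": float(np.mean(resid)), "resid_sd": float(np.std(resid))}
    if 3 <= resid.size <= 5000:
        try:
            w, p = stats.shapiro(resid)
            out["shapiro_w"], out["shapiro_p"] = float(w), float(p)
        except Exception:
            pass
    return out


def fit_lmm(df: pd.DataFrame, outcome: str, factors: list[str],
            group_col: str = "participant",
            max_order: int | None = None) -> LinearModelFit:
    """REML random-intercept LMM with sum-coded factorial fixed effects.

    Falls back to OLS (with a warning and ``singular=True``) when the
    random-intercept variance estimate collapses to the boundary.
    """
    levels = {f: sorted(df[f].unique()) for f in factors}
    design = FactorDesign(levels, max_order=max_order)
    X = design.matrix(df)
    y = df[outcome].to_numpy(dtype=float)
    ids = df[group_col].to_numpy()
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    blocks = _blocks(X, y, ids)
    if max(len(bi[1]) for bi in blocks) == 1:
        # one record per participant: the random-intercept variance is
        # confounded with the residual, so the model degenerates to OLS
        warnings.warn("random-intercept variance is not identifiable with one "
                      "record per group; refitting as a fixed-effects (OLS) "
                      "model", UserWarning, stacklevel=2)
        fit = fit_ols(df, outcome, factors, max_order=max_order)
        fit.singular = True
        fit.kind = "lmm"
        fit.tau2 = 0.0
        return fit

    # moment-based start values
    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ ols_beta
    s2 = float(resid @ resid) / max(n - p, 1)
    res = optimize.minimize(
        lambda lt: _neg_reml(blocks, np.exp(lt), n, p),
        x0=np.log([s2 * 0.6 + 1e-12, s2 * 0.4 + 1e-12]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    sigma2, tau2 = (float(v) for v in np.exp(res.x))

    if tau2 < _SINGULAR_TOL * sigma2:
        warnings.warn("random-intercept variance is ~0; refitting as a "
                      "fixed-effects (OLS) model", UserWarning, stacklevel=2)
        fit = fit_ols(df, outcome, factors, max_order=max_order)
        fit.singular = True
        fit.kind = "lmm"
        fit.tau2 = 0.0
        return fit

    A, b, q, _ = _reml_pieces(blocks, (sigma2, tau2))
    C = np.linalg.inv(A)
    beta = C @ b
    marg_resid = y - X @ beta
    fit = LinearModelFit(
        design=design, beta=beta, cov_beta=C, sigma2=sigma2, tau2=tau2,
        df_resid=float(n - p), data=df.reset_index(drop=True), outcome=outcome,
        kind="lmm", group_col=group_col, reml=float(-res.fun),
        diagnostics=_residual_diagnostics(marg_resid))
    H = _reml_information(blocks, (sigma2, tau2), n, p)
    try:
        vcov_theta = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_theta = np.linalg.pinv(H)
    fit._satt = {"blocks": blocks, "vcov_theta": vcov_theta}
    return fit


def fit_ols(df: pd.DataFrame, outcome: str, factors: list[str],
            max_order: int | None = None) -> LinearModelFit:
    """Sum-coded factorial OLS (used when only one record per participant)."""
    levels = {f: sorted(df[f].unique()) for f in factors}
    design = FactorDesign(levels, max_order=max_order)
    X = design.matrix(df)
    y = df[outcome].to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError(f"saturated model: {n} observations for {p} "
                         "parameters leaves no residual df")
    sigma2 = float(resid @ resid) / df_resid
    C = sigma2 * np.linalg.inv(X.T @ X)
    return LinearModelFit(
        design=design, beta=beta, cov_beta=C, sigma2=sigma2, tau2=None,
        df_resid=float(df_resid), data=df.reset_index(drop=True),
        outcome=outcome, kind="ols",
        diagnostics=_residual_diagnostics(resid))


def type3_anova(fit: LinearModelFit) -> pd.DataFrame:
    """Type III F tests per model term (Satterthwaite denominator df).

    Multi-df terms combine per-eigencontrast Satterthwaite dfs via the
    standard harmonic (2q/df -> E[F]) construction; for the 2-level factors
    of the crossover design every term has 1 numerator df, where F = t^2.
    """
    rows = []
    for term in fit.design.terms:
        sl = fit.design.term_slices[term]
        idx = np.arange(sl.start, sl.stop)
        q = idx.size
        if q == 1:
            L = np.zeros(fit.beta.size)
            L[idx[0]] = 1.0
            c = fit.contrast(L)
            rows.append({"term": ":".join(term), "F": c["t"] ** 2,
                         "df1": 1, "df2": c["df"], "p": c["p"]})
            continue
        Lmat = np.zeros((q, fit.beta.size))
        for r, j in enumerate(idx):
            Lmat[r, j] = 1.0
        V = Lmat @ fit.cov_beta @ Lmat.T
        est = Lmat @ fit.beta
        Fval = float(est @ np.linalg.solve(V, est)) / q
        # eigencontrast-wise Satterthwaite, combined as in lmerTest
        w, U = np.linalg.eigh(V)
        dfs = []
        for k in range(q):
            Lk = U[:, k] @ Lmat
            dfs.append(fit._contrast_df(Lk, float(w[k])))
        dfs = np.asarray(dfs)
        ratio = np.sum(dfs / np.maximum(dfs - 2, 1e-8))
        df2 = 2 * ratio / max(ratio - q, 1e-8) if ratio > q else fit.df_resid
        p = float(stats.f.sf(Fval, q, df2))
        rows.append({"term": ":".join(term), "F": Fval, "df1": q,
                     "df2": float(df2), "p": p})
    return pd.DataFrame(rows)
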