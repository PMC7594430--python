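"""Differential-expression battery.

Six in-house statistics spanning five families of analysis, each emitting a
per-transcript raw and Benjamini-Hochberg-adjusted p-value plus a signed log2
fold change (affected over unaffected):

==============  ===================  =====================================
method_id       normalization        test
==============  ===================  =====================================
exact-tmm       TMM                  conditional NB exact test
glm-lrt-tmm     TMM                  NB GLM likelihood-ratio test
exact-deges     DEGES (iterated TMM) conditional NB exact test
wald-mor        median of ratios     NB GLM Wald test
mod-t           log-CPM              trend-weighted moderated t
clr-mc          CLR                  Dirichlet Monte-Carlo Welch t
==============  ===================  =====================================

All NB tests share a dispersion model (variance = mu + phi * mu^2) estimated by
a Cox-Reid adjusted profile likelihood: a common dispersion pooled over
transcripts plus tagwise values shrunk toward it with a configurable prior
degrees of freedom.  The consensus layer downstream is method-agnostic, so the
battery is a registry and the number of methods M is configuration, not a
constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io_model import CohortConfig, CountMatrix, DesignError
from .expression import NormFactors, fold_change, median_of_ratios_factors, tmm_factors

_LN2 = np.log(2.0)
_EXACT_ENUM_MAX = 20_000  # above this total, the conditional tail is normal-approximated


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# likelihoods and designs


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float | np.ndarray) -> np.ndarray:
    """Elementwise NB log-likelihood; phi -> 0 degenerates to Poisson."""
    mu = np.maximum(mu, 1e-12)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0 and phi <= 0:
        return y * np.log(mu) - mu - special.gammaln(y + 1)
    phi_b = np.broadcast_to(phi if phi.ndim else phi[None], np.broadcast_shapes(y.shape, mu.shape))
    out = np.empty(np.broadcast_shapes(y.shape, mu.shape))
    y_b = np.broadcast_to(y, out.shape)
    mu_b = np.broadcast_to(mu, out.shape)
    pois = phi_b <= 0
    if pois.any():
        out[pois] = y_b[pois] * np.log(mu_b[pois]) - mu_b[pois] - special.gammaln(y_b[pois] + 1)
    nb = ~pois
    if nb.any():
        r = 1.0 / phi_b[nb]
        out[nb] = (
            special.gammaln(y_b[nb] + r)
            - special.gammaln(r)
            - special.gammaln(y_b[nb] + 1)
            + r * np.log(r / (r + mu_b[nb]))
            + y_b[nb] * np.log(mu_b[nb] / (r + mu_b[nb]))
        )
    return out


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-transcript NB deviance (row sums)."""
    mu = np.maximum(mu, 1e-12)
    phi = np.asarray(phi, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        r = np.where(phi > 0, 1.0 / np.maximum(phi, 1e-300), np.inf)
        term2 = np.where(
            phi > 0,
            (y + r) * np.log((y + r) / (mu + r)),
            y - mu,
        )
    return 2.0 * np.sum(term1 - term2, axis=1)


def design_matrix(affected: np.ndarray, pairs: list[tuple[int, int]] | None) -> tuple[np.ndarray, int]:
    """Design matrix and the index of the group column.

    Unpaired: intercept + group.  Paired: one indicator per pair (acting as
    pair-specific intercepts) + group.
    """
    affected = np.asarray(affected, dtype=bool)
    n = affected.shape[0]
    if pairs is None:
        X = np.column_stack([np.ones(n), affected.astype(float)])
        return X, 1
    npairs = len(pairs)
    X = np.zeros((n, npairs + 1))
    for j, (a, u) in enumerate(pairs):
        X[a, j] = 1.0
        X[u, j] = 1.0
    X[:, npairs] = affected.astype(float)
    covered = {i for p in pairs for i in p}
    if len(covered) != n:
        raise DesignError("paired design: some samples are not in any pair")
    return X, npairs


def _batched_wls(X: np.ndarray, W: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve (X'WX) beta = X'Wz per transcript; returns (beta, XtWX)."""
    O = X[:, :, None] * X[:, None, :]  # (n, p, p)
    XtWX = np.tensordot(W, O, axes=([1], [0]))  # (G, p, p)
    XtWz = (W * z) @ X  # (G, p)
    p = X.shape[1]
    ridge = 1e-10 * (np.trace(XtWX, axis1=1, axis2=2)[:, None, None] + 1.0)
    beta = np.linalg.solve(XtWX + ridge * np.eye(p)[None], XtWz[:, :, None])[:, :, 0]
    return beta, XtWX


def nb_glm_fit(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Vectorized IRLS fit of a log-link NB GLM with fixed per-transcript phi.

    Returns (beta, mu, XtWX, deviance, converged).
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))
    phi = np.asarray(phi, dtype=float)
    z0 = np.log(y + 0.5) - offset
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # (G, p)
    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    XtWX = None
    for _ in range(max_iter):
        eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset) + (y - mu) / mu
        beta, XtWX = _batched_wls(X, W, z)
        new_dev = _nb_deviance(y, np.exp(np.clip(offset + beta @ X.T, -30.0, 30.0)), phi)
        rel = np.abs(new_dev - dev) / (np.abs(new_dev) + 1.0)
        converged = rel < tol
        dev = new_dev
        if converged.all():
            break
    eta = np.clip(offset + beta @ X.T, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + phi[:, None] * mu)
    O = X[:, :, None] * X[:, None, :]
    XtWX = np.tensordot(W, O, axes=([1], [0]))
    return beta, mu, XtWX, dev, converged


# ---------------------------------------------------------------------------
# dispersion


@dataclass
class DispersionModel:
    """Common and tagwise NB dispersions with shrinkage toward the common value."""

    common: float
    tagwise: np.ndarray
    prior_df: float

    def __post_init__(self) -> None:
        self.tagwise = np.maximum(np.asarray(self.tagwise, dtype=float), 0.0)
        if self.common < 0:
            raise ValueError("dispersion must be >= 0")


_PHI_GRID = np.concatenate([[0.0], np.exp(np.linspace(np.log(1e-3), np.log(6.0), 36))])


def _offsets(cm: CountMatrix, norm: NormFactors | None) -> np.ndarray:
    eff = (norm or NormFactors.none(cm)).effective_library_sizes(cm)
    off = np.log(eff)
    return off - off.mean()


def estimate_dispersion(
    cm: CountMatrix,
    affected: np.ndarray,
    norm: NormFactors | None = None,
    pairs: list[tuple[int, int]] | None = None,
    prior_df: float = 10.0,
) -> DispersionModel:
    """Cox-Reid adjusted profile-likelihood dispersion estimation.

    The common dispersion maximizes the APL summed over transcripts; tagwise
    values are per-transcript APL maximizers shrunk toward the common value
    with weight ``prior_df`` against the residual degrees of freedom.
    """
    affected = np.asarray(affected, dtype=bool)
    if affected.sum() < 2 or (~affected).sum() < 2:
        raise DesignError("dispersion estimation needs >= 2 samples per group")
    y = cm.counts.astype(float)
    G, n = y.shape
    X, _ = design_matrix(affected, pairs)
    p = X.shape[1]
    off = _offsets(cm, norm)

    # fitted means at a provisional dispersion, then profile over phi
    phi_work = np.full(G, 0.1)
    for _ in range(2):
        _, mu, _, _, _ = nb_glm_fit(y, X, off, phi_work, max_iter=25)
        apl = np.empty((G, _PHI_GRID.size))
        O = X[:, :, None] * X[:, None, :]
        for j, phi in enumerate(_PHI_GRID):
            ll = _nb_loglik(y, mu, np.float64(phi)).sum(axis=1)
            W = mu / (1.0 + phi * mu)
            XtWX = np.tensordot(W, O, axes=([1], [0]))
            sign, logdet = np.linalg.slogdet(XtWX + 1e-12 * np.eye(p)[None])
            apl[:, j] = ll - 0.5 * logdet
        total = apl.sum(axis=0)
        j_best = int(np.argmax(total))
        common = float(_PHI_GRID[j_best])
        if 0 < j_best < _PHI_GRID.size - 1:
            # parabolic refinement on log-phi between neighbouring grid points
            xs = np.log(_PHI_GRID[j_best - 1 : j_best + 2])
            ys = total[j_best - 1 : j_best + 2]
            denom = (ys[0] - 2 * ys[1] + ys[2])
            if np.isfinite(xs).all() and denom < 0:
                shift = 0.5 * (ys[0] - ys[2]) / denom
                common = float(np.exp(xs[1] + np.clip(shift, -1.0, 1.0) * (xs[2] - xs[1])))
        phi_work = np.full(G, max(common, 1e-4))
    tag_ml = _PHI_GRID[np.argmax(apl, axis=1)]
    d = max(n - p, 1)
    tagwise = (d * tag_ml + prior_df * common) / (d + prior_df) if np.isfinite(prior_df) else np.full(G, common)
    return DispersionModel(common=common, tagwise=tagwise, prior_df=prior_df)


# ---------------------------------------------------------------------------
# exact NB test


def _exact_double_tail(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional NB double-tail p for one transcript.

    Group sums are NB(n_g * m, phi / n_g) under the null; the p-value sums the
    conditional probability of all splits no more probable than the observed
    one.  Large totals switch to a normal approximation of the conditional law.
    """
    t = s_a + s_b
    if t == 0:
        return 1.0
    n = n_a + n_b
    m = t / n
    m1, m2 = n_a * m, n_b * m
    if t <= _EXACT_ENUM_MAX:
        a = np.arange(t + 1)
        logf = _nb_loglik(a, np.full(a.shape, m1), np.float64(phi / n_a)) + _nb_loglik(
            t - a, np.full(a.shape, m2), np.float64(phi / n_b)
        )
        logf -= logf.max()
        f = np.exp(logf)
        total = f.sum()
        return float(min(1.0, f[f <= f[s_a] * (1.0 + 1e-12)].sum() / total))
    v1 = m1 + (phi / n_a) * m1**2
    v2 = m2 + (phi / n_b) * m2**2
    cond_var = v1 * v2 / (v1 + v2)
    z = (abs(s_a - m1) - 0.5) / np.sqrt(cond_var)
    return float(min(1.0, 2.0 * special.ndtr(-max(z, 0.0))))


def de_nb_exact(
    cm: CountMatrix,
    affected: np.ndarray,
    norm: NormFactors,
    disp: DispersionModel,
    pseudocount: float = 0.25,
    method_id: str = "nb_exact",
) -> pd.DataFrame:
    """Conditional NB exact test on group sums at equalized library sizes."""
    affected = np.asarray(affected, dtype=bool)
    eff = norm.effective_library_sizes(cm)
    geo = np.exp(np.mean(np.log(eff)))
    pseudo = cm.counts * (geo / eff)[None, :]
    s_a = np.rint(pseudo[:, affected].sum(axis=1)).astype(np.int64)
    s_b = np.rint(pseudo[:, ~affected].sum(axis=1)).astype(np.int64)
    n_a, n_b = int(affected.sum()), int((~affected).sum())
    p = np.array(
        [
            _exact_double_tail(int(a), int(b), n_a, n_b, float(phi))
            for a, b, phi in zip(s_a, s_b, disp.tagwise)
        ]
    )
    fc = fold_change(pseudo, affected, pseudocount)
    return _result_frame(method_id, cm, fc["log2fc"].to_numpy(), p)


# ---------------------------------------------------------------------------
# GLM tests


def de_nb_glm_lrt(
    cm: CountMatrix,
    affected: np.ndarray,
    norm: NormFactors,
    disp: DispersionModel,
    pairs: list[tuple[int, int]] | None = None,
    method_id: str = "nb_glm_lrt",
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test of the group coefficient (chi-square, 1 df)."""
    affected = np.asarray(affected, dtype=bool)
    y = cm.counts.astype(float)
    off = _offsets(cm, norm)
    X_full, g_idx = design_matrix(affected, pairs)
    X_null = np.delete(X_full, g_idx, axis=1)
    if X_null.shape[1] == 0:
        X_null = np.ones((y.shape[1], 1))
    beta, _, _, dev_full, conv_f = nb_glm_fit(y, X_full, off, disp.tagwise)
    _, _, _, dev_null, conv_n = nb_glm_fit(y, X_null, off, disp.tagwise)
    lrt = np.maximum(dev_null - dev_full, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    bad = ~(conv_f & conv_n)
    p[bad] = 1.0  # conservative for non-converged fits
    return _result_frame(method_id, cm, beta[:, g_idx] / _LN2, p, converged=~bad)


def de_nb_wald(
    cm: CountMatrix,
    affected: np.ndarray,
    norm: NormFactors,
    disp: DispersionModel,
    pairs: list[tuple[int, int]] | None = None,
    method_id: str = "nb_wald",
) -> pd.DataFrame:
    """NB Wald test: group coefficient over its standard error, standard normal."""
    affected = np.asarray(affected, dtype=bool)
    y = cm.counts.astype(float)
    off = _offsets(cm, norm)
    X, g_idx = design_matrix(affected, pairs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix has a zero-variance (rank-deficient) column")
    beta, _, XtWX, _, conv = nb_glm_fit(y, X, off, disp.tagwise)
    cov = np.linalg.inv(XtWX + 1e-10 * np.eye(X.shape[1])[None])
    se = np.sqrt(np.maximum(cov[:, g_idx, g_idx], 1e-300))
    z = beta[:, g_idx] / se
    p = 2.0 * special.ndtr(-np.abs(z))
    p[~conv] = 1.0
    return _result_frame(method_id, cm, beta[:, g_idx] / _LN2, p, converged=conv)


# ---------------------------------------------------------------------------
# DEGES normalization


def deges_normalize(
    cm: CountMatrix,
    affected: np.ndarray,
    iterations: int = 3,
    removal_fraction: float = 0.3,
    pairs: list[tuple[int, int]] | None = None,
    prior_df: float = 10.0,
) -> NormFactors:
    """DEGES: normalize, flag putative DEGs, drop them, renormalize.

    Each iteration estimates TMM factors, runs the exact NB test, removes the
    top ``removal_fraction`` of transcripts by raw p, and recomputes factors on
    the remainder.  With ``removal_fraction`` 0 this reduces to plain TMM.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    affected = np.asarray(affected, dtype=bool)
    factors = tmm_factors(cm)
    for _ in range(iterations):
        if removal_fraction <= 0:
            continue
        disp = estimate_dispersion(cm, affected, factors, pairs=None, prior_df=prior_df)
        res = de_nb_exact(cm, affected, factors, disp)
        n_remove = int(np.floor(removal_fraction * cm.n_transcripts))
        order = np.lexsort((cm.transcript_ids, res["p_raw"].to_numpy()))
        keep_idx = np.sort(order[n_remove:])
        if keep_idx.size < 50:
            raise DesignError("DEGES removal would leave fewer than 50 transcripts")
        sub = cm.subset_transcripts(np.isin(np.arange(cm.n_transcripts), keep_idx))
        sub_factors = tmm_factors(sub)
        # factors are computed against the reduced library sizes; rescale them
        # so that (full library) x factor preserves the reduced effective depth
        f = sub_factors.factors * sub.library_sizes() / cm.library_sizes()
        f = f / np.exp(np.mean(np.log(f)))
        factors = NormFactors(list(cm.sample_ids), f, "tmm", relative=True)
    return NormFactors(list(cm.sample_ids), factors.factors, "deges", relative=True)


# ---------------------------------------------------------------------------
# moderated t (log-CPM with mean-variance trend weights)


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to observed variances (log scale).

    Returns (d0, s0_squared); d0 may be ``inf`` when the variances are less
    spread than an F with df1 denominator df would imply.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df1 / 2.0)
    if evar > 0:
        df2 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(df2 / 2.0) - np.log(df2 / 2.0))
    else:
        df2, s0 = np.inf, np.exp(emean)
    return float(df2), float(s0)


def _log_cpm(cm: CountMatrix, norm: NormFactors | None = None) -> tuple[np.ndarray, np.ndarray]:
    """log2 counts per million with a library-size-scaled pseudocount.

    The pseudocount (0.5 at the average depth) is scaled per sample so that a
    zero count maps to the same log-CPM in deep and shallow libraries;
    otherwise every near-zero transcript inherits a spurious group effect
    whenever the groups differ in depth by chance.
    """
    lib = cm.library_sizes().astype(float) if norm is None else norm.effective_library_sizes(cm)
    prior = 0.5 * lib / lib.mean()
    return np.log2((cm.counts + prior[None, :]) / (lib + 2.0 * prior)[None, :] * 1e6), lib


def _voom_weights(logcpm: np.ndarray, fitted: np.ndarray, resid_sd: np.ndarray, lib: np.ndarray):
    """Precision weights from a lowess mean-variance trend (sqrt-sd scale)."""
    mean_logcount = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(np.maximum(resid_sd, 0.0))
    ok = np.isfinite(sy)
    if ok.sum() < 10 or np.allclose(sy[ok], sy[ok][0]):
        return np.ones_like(fitted)
    trend = lowess(sy[ok], mean_logcount[ok], frac=0.5, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-4)
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)
    return pred**-4


def de_moderated_t(
    cm: CountMatrix,
    affected: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    prior_df: float | None = None,
    trend_weights: bool = True,
    norm: NormFactors | None = None,
    method_id: str = "moderated_t",
) -> pd.DataFrame:
    """Moderated t on log2-CPM with lowess mean-variance precision weights.

    ``prior_df=None`` fits the empirical-Bayes prior by moment matching;
    ``prior_df=0`` disables moderation (ordinary t-test); a finite value is
    used as given with the prior variance set to the common value.
    ``norm`` supplies effective library sizes (e.g. TMM) so the CPM scale is
    robust to composition bias; raw column totals are used when omitted.
    Paired designs are analyzed as one-sample tests on within-pair differences.
    """
    affected = np.asarray(affected, dtype=bool)
    logcpm, lib = _log_cpm(cm, norm)
    G = logcpm.shape[0]

    if pairs is None:
        if affected.sum() < 2 or (~affected).sum() < 2:
            raise DesignError("moderated t needs >= 2 samples per group")
        X = np.column_stack([np.ones(logcpm.shape[1]), affected.astype(float)])
        pinv = np.linalg.pinv(X)
        beta = (pinv @ logcpm.T).T
        fitted = beta @ X.T
        d = logcpm.shape[1] - 2
        resid = logcpm - fitted
        s2_ols = (resid**2).sum(axis=1) / d
        if trend_weights:
            w = _voom_weights(logcpm, fitted, np.sqrt(s2_ols), lib)
            beta, XtWX = _batched_wls(X, w, logcpm)
            fitted = beta @ X.T
            resid = logcpm - fitted
            s2 = (w * resid**2).sum(axis=1) / d
            cov = np.linalg.inv(XtWX + 1e-12 * np.eye(2)[None])
            unscaled_se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
        else:
            s2 = s2_ols
            unscaled_se = np.full(G, np.sqrt(np.linalg.inv(X.T @ X)[1, 1]))
        effect = beta[:, 1]
    else:
        if len(pairs) < 3:
            raise DesignError("paired moderated t needs >= 3 pairs")
        aff_c = np.array([a for a, _ in pairs])
        un_c = np.array([u for _, u in pairs])
        diffs = logcpm[:, aff_c] - logcpm[:, un_c]
        npairs = diffs.shape[1]
        d = npairs - 1
        if trend_weights:
            mean_fit = np.tile(logcpm.mean(axis=1)[:, None], (1, logcpm.shape[1]))
            sd0 = diffs.std(axis=1, ddof=1)
            w_obs = _voom_weights(logcpm, mean_fit, sd0, lib)
            w = 1.0 / (1.0 / w_obs[:, aff_c] + 1.0 / w_obs[:, un_c])
        else:
            w = np.ones_like(diffs)
        wsum = w.sum(axis=1)
        effect = (w * diffs).sum(axis=1) / wsum
        s2 = (w * (diffs - effect[:, None]) ** 2).sum(axis=1) / d
        unscaled_se = np.sqrt(1.0 / wsum)

    if prior_df is None:
        d0, s0 = fit_f_dist(s2, d)
    elif prior_df == 0:
        d0, s0 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0

    if np.isinf(d0):
        s2_post = np.full(G, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / (np.sqrt(s2_post) * unscaled_se)
    # all-equal transcripts: zero variance and zero effect up to float noise
    degenerate = ~np.isfinite(tstat) | ((s2 < 1e-12) & (np.abs(effect) < 1e-6))
    tstat[degenerate] = 0.0
    if np.isinf(df_total):
        p = 2.0 * special.ndtr(-np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p[degenerate] = 1.0
    return _result_frame(method_id, cm, effect, p)


# ---------------------------------------------------------------------------
# compositional Monte-Carlo test


def de_clr_mc(
    cm: CountMatrix,
    affected: np.ndarray,
    n_mc: int = 128,
    seed: int = 0,
    method_id: str = "clr_mc",
) -> pd.DataFrame:
    """Dirichlet Monte-Carlo CLR test.

    Each instance draws per-sample compositions from Dirichlet(counts + 0.5),
    applies the centered log-ratio transform, and runs a Welch t per
    transcript; the reported p is the expectation over instances (conservative
    by construction), the effect the expected CLR difference in log2 units.
    """
    if n_mc < 16:
        raise ValueError("n_mc must be >= 16")
    affected = np.asarray(affected, dtype=bool)
    n_a, n_u = int(affected.sum()), int((~affected).sum())
    if n_a < 2 or n_u < 2:
        raise DesignError("Welch t needs >= 2 samples per group")
    rng = np.random.default_rng(seed)
    alpha = cm.counts + 0.5
    p_sum = np.zeros(cm.n_transcripts)
    eff_sum = np.zeros(cm.n_transcripts)
    for _ in range(n_mc):
        x = rng.gamma(alpha)
        logx = np.log(np.maximum(x, 1e-300))
        clr = logx - logx.mean(axis=0, keepdims=True)
        a, u = clr[:, affected], clr[:, ~affected]
        ma, mu_ = a.mean(axis=1), u.mean(axis=1)
        va, vu = a.var(axis=1, ddof=1), u.var(axis=1, ddof=1)
        se2 = va / n_a + vu / n_u
        t = (ma - mu_) / np.sqrt(np.maximum(se2, 1e-300))
        df = se2**2 / np.maximum(
            (va / n_a) ** 2 / (n_a - 1) + (vu / n_u) ** 2 / (n_u - 1), 1e-300
        )
        p_sum += 2.0 * stats.t.sf(np.abs(t), df)
        eff_sum += ma - mu_
    return _result_frame(method_id, cm, eff_sum / n_mc / _LN2, np.clip(p_sum / n_mc, 0.0, 1.0))


# ---------------------------------------------------------------------------
# battery orchestration


@dataclass(frozen=True)
class MethodSpec:
    method_id: str
    normalization: str  # tmm | median_of_ratios | deges | clr | log_cpm
    test: str  # nb_exact | nb_glm_lrt | nb_wald | moderated_t | mc_welch
    supports_paired: bool = True


DEFAULT_METHODS: dict[str, MethodSpec] = {
    "exact-tmm": MethodSpec("exact-tmm", "tmm", "nb_exact", supports_paired=False),
    "glm-lrt-tmm": MethodSpec("glm-lrt-tmm", "tmm", "nb_glm_lrt"),
    "exact-deges": MethodSpec("exact-deges", "deges", "nb_exact", supports_paired=False),
    "wald-mor": MethodSpec("wald-mor", "median_of_ratios", "nb_wald"),
    "mod-t": MethodSpec("mod-t", "log_cpm", "moderated_t"),
    "clr-mc": MethodSpec("clr-mc", "clr", "mc_welch", supports_paired=False),
}


def _result_frame(method_id: str, cm: CountMatrix, log2fc, p_raw, **extra) -> pd.DataFrame:
    p_raw = np.clip(np.asarray(p_raw, dtype=float), 0.0, 1.0)
    df = pd.DataFrame(
        {
            "method_id": method_id,
            "transcript_id": cm.transcript_ids,
            "log2fc": np.asarray(log2fc, dtype=float),
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


def run_battery(
    cm: CountMatrix,
    affected: np.ndarray,
    config: CohortConfig,
    pairs: list[tuple[int, int]] | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the configured battery; returns method_id -> DEResult frame.

    Normalization factors and dispersion models are computed once per
    normalization and shared across methods.
    """
    seed = config.seed if seed is None else seed
    specs = [DEFAULT_METHODS[m] for m in config.methods]
    norm_cache: dict[str, NormFactors] = {}
    disp_cache: dict[str, DispersionModel] = {}

    def get_norm(name: str) -> NormFactors:
        if name not in norm_cache:
            if name == "tmm":
                norm_cache[name] = tmm_factors(cm)
            elif name == "median_of_ratios":
                norm_cache[name] = median_of_ratios_factors(cm)
            elif name == "deges":
                norm_cache[name] = deges_normalize(cm, affected, prior_df=config.prior_df)
            else:
                norm_cache[name] = NormFactors.none(cm)
        return norm_cache[name]

    def get_disp(name: str, use_pairs) -> DispersionModel:
        key = f"{name}:{'paired' if use_pairs else 'unpaired'}"
        if key not in disp_cache:
            disp_cache[key] = estimate_dispersion(
                cm, affected, get_norm(name), pairs=use_pairs, prior_df=config.prior_df
            )
        return disp_cache[key]

    out: dict[str, pd.DataFrame] = {}
    for spec in specs:
        use_pairs = pairs if (pairs is not None and spec.supports_paired) else None
        if spec.test == "nb_exact":
            res = de_nb_exact(
                cm, affected, get_norm(spec.normalization),
                get_disp(spec.normalization, None), config.pseudocount, spec.method_id,
            )
        elif spec.test == "nb_glm_lrt":
            res = de_nb_glm_lrt(
                cm, affected, get_norm(spec.normalization),
                get_disp(spec.normalization, use_pairs), use_pairs, spec.method_id,
            )
        elif spec.test == "nb_wald":
            res = de_nb_wald(
                cm, affected, get_norm(spec.normalization),
                get_disp(spec.normalization, use_pairs), use_pairs, spec.method_id,
            )
        elif spec.test == "moderated_t":
            res = de_moderated_t(
                cm, affected, use_pairs, norm=get_norm("tmm"), method_id=spec.method_id
            )
        elif spec.test == "mc_welch":
            res = de_clr_mc(cm, affected, config.n_mc, seed=seed, method_id=spec.method_id)
        else:  # pragma: no cover - registry guards this
            raise ValueError(f"unknown test family {spec.test!r}")
        out[spec.method_id] = res
    return out
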