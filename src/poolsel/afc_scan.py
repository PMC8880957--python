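"""Per-SNP binomial-GLM allele-frequency-change scans.

The fitting engine is an iteratively-reweighted-least-squares (IRLS) binomial
logistic GLM for grouped count data, shared by both scan models:

* Model 1 — ancestor vs each evolved regime at the final generation, fit as a
  five-level factor with planned Wald contrasts ANC - regime.
* Model 2 — per-regime trajectory, alt counts regressed on numeric generation;
  the reported statistic is the Wald test of the generation slope.

Genome-wide significance uses a Bonferroni cut-off over the SNPs fit per model
(per regime for Model 2).  Because binomial GLM observations are collapsible
over shared covariate patterns, fits operate on per-cell totals, which also
makes the Model 2 scan fully vectorizable across SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from poolsel.counts_io import EVOLVED_REGIMES

logger = logging.getLogger(__name__)

MAX_ITER = 50
SCORE_TOL = 1e-8


@dataclass
class GlmFit:
    """A fitted binomial-logit GLM on grouped data."""

    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    n_obs: int
    deviance: float = np.nan
    adjusted: bool = False  # Haldane-Anscombe cell adjustment applied
    names: list = field(default_factory=list)

    def wald(self, contrast: np.ndarray) -> tuple[float, float, float, float]:
        """(estimate, se, z, two-sided p) for a linear contrast c'beta."""
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.coef)
        se = float(np.sqrt(c @ self.cov @ c))
        z = est / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return est, se, z, p


def _deviance(y: np.ndarray, n: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n * (1 - mu))), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def haldane_anscombe(y: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Add 0.5 successes and 0.5 failures to every informative cell when any
    cell is entirely 0 or entirely 1, keeping Wald statistics finite."""
    informative = n > 0
    degen = informative & ((y == 0) | (y == n))
    if degen.any():
        y = np.where(informative, y + 0.5, y)
        n = np.where(informative, n + 1.0, n)
        return y, n, True
    return y, n, False


def irls_binomial_fit(
    X: np.ndarray,
    successes: np.ndarray,
    totals: np.ndarray,
    adjust_separation: bool = True,
) -> GlmFit:
    """Fit a binomial-logit GLM by IRLS on grouped data.

    Rows with ``totals == 0`` carry zero weight.  Convergence is declared when
    the maximum absolute score falls below 1e-8 (within 50 iterations); the
    returned covariance is the inverse Fisher information at the optimum.  A
    step-halving guard keeps the deviance non-increasing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= successes <= totals")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    adjusted = False
    if adjust_separation:
        y, n, adjusted = haldane_anscombe(y, n)

    live = n > 0
    p0 = (y.sum() + 0.5) / (n.sum() + 1.0)
    beta = np.zeros(X.shape[1])
    beta[:] = 0.0
    # initialise intercept-like direction at the pooled logit via one LS step
    eta = np.full(len(y), np.log(p0 / (1 - p0)))
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(y[live], n[live], mu[live])
    converged = False
    for _ in range(MAX_ITER):
        w = n * mu * (1.0 - mu)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = eta + (y - n * mu) / np.where(w > 0, n * mu * (1.0 - mu), 1.0)
        W = w[live]
        Xl = X[live]
        XtWX = Xl.T @ (Xl * W[:, None])
        XtWz = Xl.T @ (W * z[live])
        beta_new = np.linalg.solve(XtWX, XtWz)
        # step-halving: deviance must not increase
        step = beta_new - beta
        for _half in range(20):
            eta_new = X @ (beta + step)
            mu_new = 1.0 / (1.0 + np.exp(-np.clip(eta_new, -500, 500)))
            dev_new = _deviance(y[live], n[live], mu_new[live])
            if dev_new <= dev + 1e-12:
                break
            step /= 2.0
        beta = beta + step
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        dev = _deviance(y[live], n[live], mu[live])
        score = X[live].T @ (y[live] - n[live] * mu[live])
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
    w = (n * mu * (1.0 - mu))[live]
    XtWX = X[live].T @ (X[live] * w[:, None])
    cov = np.linalg.inv(XtWX)
    return GlmFit(beta, cov, converged, int(live.sum()), dev, adjusted)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide Bonferroni cut-off alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# cell collapsing
# ---------------------------------------------------------------------------

def _collapse_by_generation(sites, meta: pd.DataFrame, regime: str):
    """Per-SNP alt/total count matrices collapsed to generation cells.

    Observations are the ancestor pools (generation 0) plus the given regime's
    replicate x timepoint samples; collapsing over samples sharing a
    generation is exact for the binomial GLM.
    """
    meta = meta.set_index("sample_id").loc[sites.samples].reset_index()
    use = (meta["regime"] == "ANC") | (meta["regime"] == regime)
    gens = np.sort(meta.loc[use, "generation"].unique())
    y = np.zeros((sites.n_sites, len(gens)))
    n = np.zeros_like(y)
    cov = sites.coverage()
    for gi, g in enumerate(gens):
        cols = np.flatnonzero(use.to_numpy() & (meta["generation"] == g).to_numpy())
        y[:, gi] = sites.alt_counts[:, cols].sum(axis=1)
        n[:, gi] = cov[:, cols].sum(axis=1)
    return gens.astype(float), y, n


def _batch_slope_fit(g: np.ndarray, y: np.ndarray, n: np.ndarray):
    """Vectorized IRLS for the two-parameter logit model eta = b0 + b1 * g,
    fit independently for every row of (y, n).

    Cells with n = 0 carry zero weight.  Returns (intercept, slope, se_slope,
    converged, adjusted) arrays.
    """
    m, K = y.shape
    y = y.astype(float).copy()
    n = n.astype(float).copy()
    live = n > 0
    degen = (live & ((y == 0) | (y == n))).any(axis=1)
    if degen.any():
        y[degen] = np.where(live[degen], y[degen] + 0.5, y[degen])
        n[degen] = np.where(live[degen], n[degen] + 1.0, n[degen])
    g = np.asarray(g, dtype=float)

    ysum = y.sum(axis=1)
    nsum = n.sum(axis=1)
    p0 = (ysum + 0.5) / (nsum + 1.0)
    b0 = np.log(p0 / (1.0 - p0))
    b1 = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    for _ in range(MAX_ITER):
        eta = b0[:, None] + b1[:, None] * g[None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.where(live, n * mu * (1.0 - mu), 0.0)
        resid = np.where(live, y - n * mu, 0.0)
        # score components
        s0 = resid.sum(axis=1)
        s1 = (resid * g[None, :]).sum(axis=1)
        newly = np.maximum(np.abs(s0), np.abs(s1)) < SCORE_TOL
        converged |= newly
        if converged.all():
            break
        # weighted LS normal equations (2x2 closed form)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = eta + resid / np.where(w > 0, w, 1.0)
        a = w.sum(axis=1)
        b = (w * g[None, :]).sum(axis=1)
        d = (w * g[None, :] ** 2).sum(axis=1)
        u = (w * z).sum(axis=1)
        v = (w * z * g[None, :]).sum(axis=1)
        det = a * d - b * b
        bad = det <= 0
        det = np.where(bad, 1.0, det)
        b0n = (d * u - b * v) / det
        b1n = (a * v - b * u) / det
        upd = ~converged & ~bad
        b0 = np.where(upd, b0n, b0)
        b1 = np.where(upd, b1n, b1)
    eta = b0[:, None] + b1[:, None] * g[None, :]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.where(live, n * mu * (1.0 - mu), 0.0)
    a = w.sum(axis=1)
    b = (w * g[None, :]).sum(axis=1)
    d = (w * g[None, :] ** 2).sum(axis=1)
    det = a * d - b * b
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(np.where(det > 0, a / det, np.nan))
    return b0, b1, se1, converged, degen


def model2_scan(
    sites,
    meta: pd.DataFrame,
    regime: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Model 2: per-SNP binomial GLM of alt counts on numeric generation for
    one regime (ancestor pools included at generation 0).

    Sites should already satisfy the per-regime presence filter (ancestor plus
    >= 9 occurrences).  SNPs with data at fewer than 3 distinct generations
    are skipped.  ``significant`` flags p < alpha / m with m = SNPs fit in
    this regime.
    """
    if regime not in EVOLVED_REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    gens, y, n = _collapse_by_generation(sites, meta, regime)
    enough = (n > 0).sum(axis=1) >= 3
    n_skipped = int((~enough).sum())
    if n_skipped:
        logger.info("model2_scan[%s]: skipped %d SNPs with < 3 generations", regime, n_skipped)
    b0, b1, se1, converged, adjusted = _batch_slope_fit(gens, y[enough], n[enough])
    with np.errstate(invalid="ignore"):
        z = b1 / se1
    p = 2.0 * stats.norm.sf(np.abs(z))
    m = int(enough.sum())
    thr = bonferroni_threshold(alpha, m) if m else np.nan
    out = pd.DataFrame(
        {
            "chrom": sites.chrom[enough],
            "pos": sites.pos[enough],
            "model": "model2",
            "regime": regime,
            "intercept": b0,
            "estimate": b1,
            "se": se1,
            "z": z,
            "p": p,
            "significant": p < thr,
            "converged": converged,
            "adjusted": adjusted,
        }
    )
    out.attrs["m"] = m
    out.attrs["bonferroni_threshold"] = thr
    return out


def model1_contrasts(
    sites,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    final_generation: int = 31,
) -> pd.DataFrame:
    """Model 1: five-level factor GLM (ANC + 4 regimes at the final
    generation) with planned Wald contrasts ANC - regime per SNP.

    Bonferroni m = number of SNPs fit; the four contrasts of a SNP share the
    same threshold (per-contrast counting is not multiplied in).
    """
    meta = meta.set_index("sample_id").loc[sites.samples].reset_index()
    is_anc = (meta["regime"] == "ANC").to_numpy()
    levels = ["ANC"] + list(EVOLVED_REGIMES)
    cols_by_level = {"ANC": np.flatnonzero(is_anc)}
    for r in EVOLVED_REGIMES:
        cols_by_level[r] = np.flatnonzero(
            (meta["regime"] == r).to_numpy() & (meta["generation"] == final_generation).to_numpy()
        )
    cov = sites.coverage()
    y = np.column_stack([sites.alt_counts[:, cols_by_level[l]].sum(axis=1) for l in levels]).astype(float)
    n = np.column_stack([cov[:, cols_by_level[l]].sum(axis=1) for l in levels]).astype(float)

    # indicator design: intercept (ANC) + one dummy per regime
    X = np.zeros((5, 5))
    X[:, 0] = 1.0
    for k in range(1, 5):
        X[k, k] = 1.0

    fit_mask = (n > 0).all(axis=1)
    m = int(fit_mask.sum())
    thr = bonferroni_threshold(alpha, m) if m else np.nan
    rows = []
    for i in np.flatnonzero(fit_mask):
        fit = irls_binomial_fit(X, y[i], n[i])
        for k, r in enumerate(EVOLVED_REGIMES, start=1):
            c = np.zeros(5)
            c[k] = -1.0  # ANC - regime = -beta_regime
            est, se, zz, p = fit.wald(c)
            rows.append(
                (sites.chrom[i], sites.pos[i], "model1", r, est, se, zz, p, p < thr, fit.converged, fit.adjusted)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "model", "regime", "estimate", "se", "z", "p",
            "significant", "converged", "adjusted",
        ],
    )
    out.attrs["m"] = m
    out.attrs["bonferroni_threshold"] = thr
    return out
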