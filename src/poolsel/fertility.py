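"""Competitive-fertility statistics.

One-sample equality-of-proportions tests against 0.5 (Yates-corrected chi2
with continuity-corrected Wilson score intervals, matching the R-ecosystem
convention), pooled-count helpers, the post-insemination contribution
fraction, fold changes relative to the ancestor, and planned GLM contrasts for
the evolved regimes with quasi-binomial overdispersion handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from poolsel.afc_scan import irls_binomial_fit
from poolsel.counts_io import ALL_REGIMES, EVOLVED_REGIMES

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class PropTestResult:
    chi2: float
    df: int
    p: float
    estimate: float
    ci_low: float
    ci_high: float


def prop_test_one_sample(
    x: int, n: int, p0: float = 0.5, continuity: bool = True, conf_level: float = 0.95
) -> PropTestResult:
    """One-sample equality-of-proportions chi-square test.

    With continuity (default): chi2 = (max(0, |x - n p0| - 0.5))^2 /
    (n p0 (1 - p0)), 1 df.  The confidence interval is the Wilson score
    interval with the same continuity correction applied to the estimate.
    """
    if not 0 <= x <= n or n < 1:
        raise ValueError("need 0 <= x <= n with n >= 1")
    e = n * p0
    yates = min(0.5, abs(x - e)) if continuity else 0.0
    chi2 = (abs(x - e) - yates) ** 2 / (n * p0 * (1.0 - p0))
    p = float(stats.chi2.sf(chi2, df=1))
    p_hat = x / n
    z = stats.norm.ppf((1.0 + conf_level) / 2.0)
    denom = 1.0 + z**2 / n
    pc = p_hat + yates / n
    if pc >= 1.0:
        hi = 1.0
    else:
        hi = (pc + z**2 / (2 * n) + z * np.sqrt(pc * (1 - pc) / n + z**2 / (4 * n**2))) / denom
    pc = p_hat - yates / n
    if pc <= 0.0:
        lo = 0.0
    else:
        lo = (pc + z**2 / (2 * n) - z * np.sqrt(pc * (1 - pc) / n + z**2 / (4 * n**2))) / denom
    return PropTestResult(float(chi2), 1, p, p_hat, max(0.0, float(lo)), min(1.0, float(hi)))


def pool_assays(assays: pd.DataFrame) -> tuple[int, int]:
    """Sum focal and total progeny counts across assays (one population x
    condition); mixing conditions is an error."""
    if len(assays) == 0:
        raise ValueError("no assays")
    if assays["condition"].nunique() > 1:
        raise ValueError("cannot pool assays across conditions")
    x = int(assays["n_focal"].sum())
    n = int((assays["n_focal"] + assays["n_competitor"]).sum())
    return x, n


def assay_proportions(assays: pd.DataFrame) -> pd.Series:
    tot = assays["n_focal"] + assays["n_competitor"]
    return assays["n_focal"] / tot


def contribution_fraction(mean_post_prop: float, mean_total_prop: float) -> float:
    """Fraction of total reproductive success attributable to post-insemination
    success: mean post proportion / mean total proportion, as a percentage."""
    if mean_total_prop <= 0:
        raise ValueError("mean total proportion must be positive")
    return 100.0 * mean_post_prop / mean_total_prop


def fold_change(replicate_means: np.ndarray, ancestor_mean: float) -> tuple[np.ndarray, float]:
    """Per-replicate fold changes relative to the ancestor and their regime
    mean.  Replicate means are each replicate's mean assay proportion."""
    if ancestor_mean <= 0:
        raise ValueError("ancestor mean must be positive")
    folds = np.asarray(replicate_means, dtype=float) / ancestor_mean
    return folds, float(folds.mean())


def regime_fold_changes(assays: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Aggregate assays -> replicate means -> folds vs ancestor -> regime mean.

    Populations are labelled either 'ANC' or '<regime>_R<rep>'.
    """
    sub = assays[assays["condition"] == condition].copy()
    sub["prop"] = assay_proportions(sub)
    anc = sub[sub["population"] == "ANC"]
    if len(anc) == 0:
        raise ValueError("no ancestor assays")
    anc_mean = float(anc["prop"].mean())
    rows = []
    for pop, grp in sub[sub["population"] != "ANC"].groupby("population"):
        regime = _regime_of(pop)
        rep_mean = float(grp["prop"].mean())
        rows.append((regime, pop, rep_mean, rep_mean / anc_mean))
    per_rep = pd.DataFrame(rows, columns=["regime", "population", "replicate_mean", "fold"])
    summary = per_rep.groupby("regime", as_index=False)["fold"].mean()
    summary = summary.rename(columns={"fold": "regime_mean_fold"})
    return per_rep.merge(summary, on="regime")


def _regime_of(population: str) -> str:
    if population in ALL_REGIMES:
        return population
    return population.rsplit("_R", 1)[0]


def evolved_glm_contrasts(assays: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Planned Wald contrasts on a binomial-logit GLM of assay counts with a
    population-level regime factor.

    Replicate-level overdispersion is absorbed by a quasi-binomial dispersion
    factor (Pearson chi2 / residual df) scaling the coefficient covariance.
    Two contrast families: (i) each evolved regime minus the ancestor; (ii)
    each directed-selection regime minus the WS-P&P baseline.
    """
    sub = assays if condition is None else assays[assays["condition"] == condition]
    if len(sub) == 0:
        raise ValueError("no assays")
    regime = sub["population"].map(_regime_of)
    levels = [r for r in ALL_REGIMES if r in set(regime)]
    if "ANC" not in levels or len(levels) < 2:
        raise ValueError("need ancestor plus at least one evolved regime")
    X = np.zeros((len(sub), len(levels)))
    X[:, 0] = 1.0
    for k, r in enumerate(levels[1:], start=1):
        X[:, k] = (regime == r).to_numpy(dtype=float)
    y = sub["n_focal"].to_numpy(dtype=float)
    n = (sub["n_focal"] + sub["n_competitor"]).to_numpy(dtype=float)
    fit = irls_binomial_fit(X, y, n)
    mu = 1.0 / (1.0 + np.exp(-(X @ fit.coef)))
    resid_df = len(sub) - len(levels)
    if resid_df > 0:
        pearson = float(np.sum((y - n * mu) ** 2 / (n * mu * (1 - mu))))
        phi = pearson / resid_df
    else:
        phi = 1.0
    cov = fit.cov * phi
    rows = []
    for k, r in enumerate(levels[1:], start=1):
        c = np.zeros(len(levels))
        c[k] = 1.0
        est = float(c @ fit.coef)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se
        rows.append(("vs_ancestor", r, est, se, z, 2 * stats.norm.sf(abs(z))))
    if "WS-P&P" in levels:
        kb = levels.index("WS-P&P")
        for r in EVOLVED_REGIMES:
            if r == "WS-P&P" or r not in levels:
                continue
            k = levels.index(r)
            c = np.zeros(len(levels))
            c[k], c[kb] = 1.0, -1.0
            est = float(c @ fit.coef)
            se = float(np.sqrt(c @ cov @ c))
            z = est / se
            rows.append(("vs_baseline", r, est, se, z, 2 * stats.norm.sf(abs(z))))
    out = pd.DataFrame(rows, columns=["family", "regime", "estimate", "se", "z", "p"])
    out.attrs["dispersion"] = phi
    return out
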