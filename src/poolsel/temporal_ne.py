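"""Temporal effective-population-size estimation from paired allele frequencies.

Implements the standardized temporal F statistic with two Plan II sampling
corrections: read-depth only ("waples_planII") and a two-stage pool-seq
correction combining read depth and pool size harmonically ("jonas_planII").
Also provides the regime ANOVA, the autosome-vs-X Welch comparison, and the
breeding-male bound from Ne = 4 Nm Nf / (Nm + Nf).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METHODS = ("waples_planII", "jonas_planII")


@dataclass
class NeEstimate:
    chromosome: str
    replicate: int
    regime: str
    method: str
    fc_bar: float
    n_loci: int
    ne: float  # may be +inf when drift signal is below sampling noise
    t: int


def fc_per_locus(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized temporal variance Fc = (x-y)^2 / ((x+y)/2 - xy).

    Loci with non-positive denominator (fixed for the same allele in both
    samples) are returned as NaN and must be excluded by callers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y) / 2.0 - x * y
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = (x - y) ** 2 / denom
    return np.where(denom > 0, fc, np.nan)


def effective_sample_size(read_depth: float, pool_individuals: float | None, method: str) -> float:
    """Per-stage effective sample size S~ in chromosome-equivalents.

    waples_planII: S~ = read depth (reads are the realized chromosome
    sample).  jonas_planII: harmonic two-stage combination
    1/S~ = 1/R + 1/(2 * N_pool), accounting for the finite pooled-individual
    stage beneath the read stage.

    The frequency sampling variance of a stage is p(1-p)/S~, so the per-stage
    term subtracted from Fc_bar is 1/S~ (equivalently 1/(2S) for S~ = 2S
    diploid individuals).
    """
    if method == "waples_planII":
        return float(read_depth)
    if method == "jonas_planII":
        if pool_individuals is None:
            raise ValueError("jonas_planII requires pool_individuals")
        return 1.0 / (1.0 / read_depth + 1.0 / (2.0 * pool_individuals))
    raise ValueError(f"unknown method {method!r}")


def estimate_ne(
    x: np.ndarray,
    y: np.ndarray,
    t: int,
    depth0: float,
    depth_t: float,
    method: str = "jonas_planII",
    pool_individuals: float | None = None,
    chromosome: str = "",
    replicate: int = 0,
    regime: str = "",
    weighting: str = "sum",
) -> NeEstimate:
    """Estimate Ne from paired frequencies at generations 0 and t.

    Ne = t / (2 * (Fc_bar - 1/S~0 - 1/S~t)) with S~ the per-stage effective
    sample size in chromosome-equivalents; a non-positive corrected Fc_bar
    yields Ne = +inf (drift signal below the sampling noise floor).

    ``weighting='sum'`` (default) aggregates Fc as the ratio of summed
    numerators to summed denominators across loci, which suppresses the
    upward ratio bias of the unweighted per-locus mean; ``weighting='mean'``
    gives the plain mean of per-locus Fc.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y) / 2.0 - x * y
    ok = denom > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("estimate_ne: excluded %d loci with non-positive denominator", n_excluded)
    if not ok.any():
        raise ValueError("no admissible loci")
    num = (x[ok] - y[ok]) ** 2
    den = denom[ok]
    if weighting == "sum":
        fc_bar = float(num.sum() / den.sum())
    elif weighting == "mean":
        fc_bar = float(np.mean(num / den))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    fc = num / den
    s0 = effective_sample_size(depth0, pool_individuals, method)
    st = effective_sample_size(depth_t, pool_individuals, method)
    corrected = fc_bar - 1.0 / s0 - 1.0 / st
    ne = t / (2.0 * corrected) if corrected > 0 else np.inf
    return NeEstimate(chromosome, replicate, regime, method, fc_bar, len(fc), ne, t)


def ne_by_chromosome(
    sites,
    meta: pd.DataFrame,
    pool_individuals: float,
    t: int = 31,
    final_generation: int = 31,
    methods: tuple = METHODS,
) -> pd.DataFrame:
    """Per chromosome x regime x replicate Ne from ancestor vs final generation.

    Ancestor pools (all G0 columns) are merged by summing read counts; the
    comparison uses the common SNP set covered in both merged ancestor and the
    evolved sample.  Read depths enter the corrections as per-comparison mean
    depths.
    """
    meta = meta.set_index("sample_id").loc[sites.samples].reset_index()
    anc_cols = np.flatnonzero((meta["regime"] == "ANC").to_numpy())
    if len(anc_cols) == 0:
        raise ValueError("no ancestor samples")
    anc_ref = sites.ref_counts[:, anc_cols].sum(axis=1)
    anc_alt = sites.alt_counts[:, anc_cols].sum(axis=1)
    anc_cov = anc_ref + anc_alt

    rows = []
    evolved = meta[(meta["regime"] != "ANC") & (meta["generation"] == final_generation)]
    for row in evolved.itertuples(index=False):
        j = sites.samples.index(row.sample_id)
        ev_ref = sites.ref_counts[:, j]
        ev_alt = sites.alt_counts[:, j]
        ev_cov = ev_ref + ev_alt
        common = (anc_cov >= 1) & (ev_cov >= 1)
        for chrom in pd.unique(sites.chrom):
            sel = common & (sites.chrom == chrom)
            if sel.sum() == 0:
                continue
            x = anc_alt[sel] / anc_cov[sel]
            y = ev_alt[sel] / ev_cov[sel]
            d0 = float(anc_cov[sel].mean())
            dt = float(ev_cov[sel].mean())
            for method in methods:
                est = estimate_ne(
                    x, y, t, d0, dt, method, pool_individuals,
                    chromosome=str(chrom), replicate=int(row.replicate), regime=row.regime,
                )
                rows.append(est.__dict__)
    return pd.DataFrame(rows)


def genome_wide_ne(estimates: pd.DataFrame) -> pd.DataFrame:
    """Mean finite Ne over chromosomes per regime x replicate x method."""
    df = estimates[np.isfinite(estimates["ne"])]
    return (
        df.groupby(["regime", "replicate", "method"], as_index=False)["ne"].mean()
    )


def regime_anova(estimates: pd.DataFrame, method: str = "waples_planII") -> tuple[float, int, float]:
    """One-way fixed-effects ANOVA of genome-wide Ne by regime.

    Returns (F, between-group df, p).
    """
    gw = genome_wide_ne(estimates)
    gw = gw[gw["method"] == method]
    groups = [g["ne"].to_numpy() for _, g in gw.groupby("regime")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 regimes with >= 2 values each")
    res = stats.f_oneway(*groups)
    return float(res.statistic), len(groups) - 1, float(res.pvalue)


def autosome_x_ttest(
    estimates: pd.DataFrame, x_chromosome: str = "X", method: str = "waples_planII"
) -> tuple[float, float, float, float]:
    """Welch t of autosomal vs X-chromosome Ne across replicates.

    Returns (t, p, mean autosomal Ne, mean X Ne).
    """
    df = estimates[(estimates["method"] == method) & np.isfinite(estimates["ne"])]
    is_x = df["chromosome"] == x_chromosome
    auto = df.loc[~is_x, "ne"].to_numpy()
    xne = df.loc[is_x, "ne"].to_numpy()
    if len(auto) < 2 or len(xne) < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(auto, xne, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(auto.mean()), float(xne.mean())


def breeding_males(ne: float, n_females: float = 2500.0) -> float:
    """Breeding males implied by Ne = 4 Nm Nf / (Nm + Nf) with all females
    reproducing: Nm = Ne * Nf / (4 Nf - Ne).  Defined for 0 < Ne < 4 Nf."""
    if not 0 < ne < 4 * n_females:
        raise ValueError(f"Ne must be in (0, {4 * n_females}) for the bound to exist")
    return ne * n_females / (4.0 * n_females - ne)
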