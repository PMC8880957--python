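"""Ancestral diversity statistics from pooled read counts.

Minor allele frequency, read-depth-corrected per-site heterozygosity (pi),
Watterson's theta in kb windows, and the arm/center and per-chromosome
comparisons used to characterise the ancestral SNP pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class DomainMap:
    """Arm/center domain intervals per chromosome (1-based, inclusive)."""

    domains: dict  # chrom -> list of (start, end, label)

    @classmethod
    def from_tsv(cls, path) -> "DomainMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "label": str})
        dm: dict = {}
        for row in df.itertuples(index=False):
            dm.setdefault(row.chrom, []).append((int(row.start), int(row.end), row.label))
        return cls(dm)

    @classmethod
    def from_dict(cls, d: dict) -> "DomainMap":
        return cls({c: [tuple(iv) for iv in ivs] for c, ivs in d.items()})

    def label_positions(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Domain label for each 1-based position ('' where unassigned)."""
        pos = np.asarray(pos)
        out = np.full(pos.shape, "", dtype=object)
        for start, end, label in self.domains.get(chrom, []):
            out[(pos >= start) & (pos <= end)] = label
        return out

    def is_arm(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        labels = self.label_positions(chrom, pos)
        return np.array([str(lb).startswith("arm") for lb in labels])


def site_maf(ref_count, alt_count) -> np.ndarray:
    """Minor allele frequency from read counts: min(p, 1-p) with p = alt/C.

    Elementwise on arrays; depth-0 sites yield NaN (and are logged).
    """
    ref_count = np.asarray(ref_count, dtype=float)
    alt_count = np.asarray(alt_count, dtype=float)
    cov = ref_count + alt_count
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(cov > 0, alt_count / cov, np.nan)
    n_bad = int(np.sum(cov == 0))
    if n_bad:
        logger.info("site_maf: %d zero-coverage sites skipped", n_bad)
    return np.minimum(p, 1.0 - p)


def site_pi(ref_count, alt_count) -> np.ndarray:
    """Read-depth-corrected per-site heterozygosity.

    pi = C/(C-1) * 2 p (1-p) with p = alt/C — the unbiased pooled-read
    estimator; undefined (NaN) for depth < 2.
    """
    ref_count = np.asarray(ref_count, dtype=float)
    alt_count = np.asarray(alt_count, dtype=float)
    cov = ref_count + alt_count
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_count / cov
        pi = cov / (cov - 1.0) * 2.0 * p * (1.0 - p)
    pi = np.where(cov >= 2, pi, np.nan)
    n_bad = int(np.sum(cov < 2))
    if n_bad:
        logger.info("site_pi: %d sites with depth < 2 skipped", n_bad)
    return pi


def harmonic_a(n: int) -> float:
    """Watterson's a(n) = sum_{i=1}^{n-1} 1/i."""
    if n < 2:
        return np.nan
    return float(np.sum(1.0 / np.arange(1, n)))


def theta_w_windows(
    chrom: np.ndarray,
    pos: np.ndarray,
    coverage: np.ndarray,
    window: int = 1000,
    stride: int | None = None,
    chrom_lengths: dict | None = None,
    n_eff: int | None = None,
) -> pd.DataFrame:
    """Watterson's theta per window of ``window`` bp.

    Windows tile each chromosome from position 1 (a smaller ``stride`` gives
    sliding windows).  Per window: S = number of SNPs, n_eff = round(mean
    total coverage of those SNPs) unless fixed via the ``n_eff`` argument,
    theta_w per bp = S / (a(n_eff) * window).  Windows with S = 0 report 0;
    windows where n_eff < 2 despite S > 0 are flagged NaN.
    """
    stride = stride or window
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    coverage = np.asarray(coverage, dtype=float)
    rows = []
    for c in pd.unique(chrom):
        sel = chrom == c
        cpos, ccov = pos[sel], coverage[sel]
        length = (chrom_lengths or {}).get(c, int(cpos.max()) if len(cpos) else window)
        start = 1
        while start <= length:
            end = start + window - 1
            in_w = (cpos >= start) & (cpos <= end)
            S = int(in_w.sum())
            if S == 0:
                rows.append((c, start, end, 0, 0, 0.0))
            else:
                ne = n_eff if n_eff is not None else int(round(ccov[in_w].mean()))
                a = harmonic_a(ne)
                theta = S / (a * window) if ne >= 2 else np.nan
                rows.append((c, start, end, S, ne, theta))
            start += stride
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "S", "n_eff", "theta_w_per_bp"]
    )


def ks_domain_test(values: np.ndarray, is_arm: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test of arm vs center distributions."""
    values = np.asarray(values, dtype=float)
    is_arm = np.asarray(is_arm, dtype=bool)
    arm = values[is_arm & np.isfinite(values)]
    center = values[~is_arm & np.isfinite(values)]
    if len(arm) < 2 or len(center) < 2:
        raise ValueError("need at least 2 values in each domain group")
    res = stats.ks_2samp(arm, center, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chrom_density_test(
    window_stats: pd.DataFrame, chromosome: str
) -> tuple[float, float]:
    """Welch two-sample t of per-window theta_w on ``chromosome`` vs the rest."""
    vals = window_stats["theta_w_per_bp"].to_numpy(dtype=float)
    grp = (window_stats["chrom"] == chromosome).to_numpy()
    a, b = vals[grp], vals[~grp]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 windows per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return np.nan, np.nan
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def diversity_summary(sites, domain_map: DomainMap | None = None) -> dict:
    """Genome-wide per-SNP summaries over pooled (summed) sample counts."""
    ref = sites.ref_counts.sum(axis=1)
    alt = sites.alt_counts.sum(axis=1)
    maf = site_maf(ref, alt)
    pi = site_pi(ref, alt)
    out = {
        "n_snps": sites.n_sites,
        "mean_maf": float(np.nanmean(maf)),
        "mean_pi": float(np.nanmean(pi)),
        "maf_min": float(np.nanmin(maf)),
        "maf_max": float(np.nanmax(maf)),
    }
    if domain_map is not None:
        is_arm = np.concatenate(
            [
                domain_map.is_arm(c, sites.pos[sites.chrom == c])
                for c in pd.unique(sites.chrom)
            ]
        )
        # reassemble in site order
        is_arm_full = np.zeros(sites.n_sites, dtype=bool)
        ofs = 0
        for c in pd.unique(sites.chrom):
            sel = sites.chrom == c
            k = int(sel.sum())
            is_arm_full[np.flatnonzero(sel)] = is_arm[ofs : ofs + k]
            ofs += k
        out["arm_fraction"] = float(is_arm_full.mean())
        out["mean_pi_arm"] = float(np.nanmean(pi[is_arm_full]))
        out["mean_pi_center"] = float(np.nanmean(pi[~is_arm_full]))
    return out
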