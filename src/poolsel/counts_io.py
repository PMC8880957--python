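"""Allele-count containers, readers/writers, and post-calling site filters.

The central container is :class:`SiteCounts`: per-site ref/alt read counts for
a panel of pooled samples, with 1-based coordinates.  Counts can be read from
a flat TSV dialect (``chrom pos ref alt  <sample>:ref <sample>:alt ...``) or
from a VCF carrying per-sample allelic depths (AD).  Filters implement the
standard post-variant-calling cleanup for pooled time-series data: repeat-mask
removal, coverage-tail trimming, and sample-presence requirements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four evolved selection regimes (within/between-strain crossed with
#: pre&post- vs post-insemination-only competition).
EVOLVED_REGIMES = ("WS-P&P", "WS-PO", "BS-P&P", "BS-PO")
ALL_REGIMES = ("ANC",) + EVOLVED_REGIMES

META_COLUMNS = ["sample_id", "regime", "replicate", "generation"]


class CountsFormatError(ValueError):
    """Raised for malformed count tables or VCFs without usable AD fields."""


@dataclass
class SiteCounts:
    """Per-SNP, per-sample ref/alt read counts with 1-based coordinates.

    Attributes
    ----------
    chrom, pos, ref, alt
        Arrays of length ``n_sites``; positions are 1-based and strictly
        increasing within each chromosome.
    samples
        Column (sample) identifiers, order preserved from input.
    ref_counts, alt_counts
        Integer matrices of shape ``(n_sites, n_samples)``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.samples = list(self.samples)
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        n = len(self.pos)
        if not (
            len(self.chrom) == len(self.ref) == len(self.alt) == n
            and self.ref_counts.shape == (n, len(self.samples))
            and self.alt_counts.shape == (n, len(self.samples))
        ):
            raise ValueError("inconsistent SiteCounts array shapes")
        if np.any(self.ref_counts < 0) or np.any(self.alt_counts < 0):
            raise ValueError("negative read counts")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def coverage(self) -> np.ndarray:
        """Per-site, per-sample total read depth (ref + alt)."""
        return self.ref_counts + self.alt_counts

    def total_coverage(self) -> np.ndarray:
        """Per-site depth summed over all samples."""
        return self.coverage().sum(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Per-site, per-sample alt read fraction; NaN where depth is 0."""
        cov = self.coverage().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.alt_counts / cov, np.nan)

    def subset_sites(self, keep: np.ndarray) -> "SiteCounts":
        """Return a copy restricted to sites where ``keep`` is True (or an
        integer index array)."""
        return SiteCounts(
            self.chrom[keep],
            self.pos[keep],
            self.ref[keep],
            self.alt[keep],
            self.samples,
            self.ref_counts[keep],
            self.alt_counts[keep],
        )

    def subset_samples(self, sample_ids: list[str]) -> "SiteCounts":
        idx = [self.samples.index(s) for s in sample_ids]
        return SiteCounts(
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            sample_ids,
            self.ref_counts[:, idx],
            self.alt_counts[:, idx],
        )

    def site_key(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays([self.chrom, self.pos], names=["chrom", "pos"])


@dataclass
class RegionSet:
    """Genomic intervals in BED convention: 0-based, half-open, merged."""

    intervals: dict = field(default_factory=dict)  # chrom -> (starts, ends) arrays

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        raw: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError(f"invalid BED interval {chrom}:{start}-{end}")
                raw.setdefault(chrom, []).append((start, end))
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RegionSet":
        merged = {}
        for chrom, ivs in raw.items():
            ivs = sorted(ivs)
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            starts = np.array([s for s, _ in out], dtype=np.int64)
            ends = np.array([e for _, e in out], dtype=np.int64)
            merged[chrom] = (starts, ends)
        return cls(merged)

    def contains(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions in the merged intervals of ``chrom``."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        if chrom not in self.intervals:
            return np.zeros(pos0.shape, dtype=bool)
        starts, ends = self.intervals[chrom]
        i = np.searchsorted(starts, pos0, side="right") - 1
        ok = i >= 0
        hit = np.zeros(pos0.shape, dtype=bool)
        hit[ok] = pos0[ok] < ends[i[ok]]
        return hit

    def chroms(self) -> set:
        return set(self.intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                starts, ends = self.intervals[chrom]
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_counts(sites: SiteCounts, path: str | Path) -> None:
    """Write the counts TSV dialect: one row per site, two columns per sample."""
    cols = {"chrom": sites.chrom, "pos": sites.pos, "ref": sites.ref, "alt": sites.alt}
    for j, s in enumerate(sites.samples):
        cols[f"{s}:ref"] = sites.ref_counts[:, j]
        cols[f"{s}:alt"] = sites.alt_counts[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _check_sorted_unique(chrom: np.ndarray, pos: np.ndarray) -> None:
    df = pd.DataFrame({"chrom": chrom, "pos": pos})
    for _, grp in df.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            bad = "duplicate" if np.any(np.diff(p) == 0) else "unsorted"
            raise CountsFormatError(f"{bad} positions within a chromosome")


def read_counts_tsv(path: str | Path) -> SiteCounts:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    fixed = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != fixed:
        raise CountsFormatError(f"counts TSV must start with columns {fixed}")
    samples: list[str] = []
    for col in df.columns[4:]:
        if col.endswith(":ref"):
            samples.append(col[:-4])
        elif not col.endswith(":alt"):
            raise CountsFormatError(f"unrecognized counts column {col!r}")
    refm = np.column_stack([df[f"{s}:ref"].to_numpy() for s in samples]) if samples else np.zeros((len(df), 0), dtype=int)
    altm = np.column_stack([df[f"{s}:alt"].to_numpy() for s in samples]) if samples else np.zeros((len(df), 0), dtype=int)
    sc = SiteCounts(
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(),
        df["ref"].to_numpy(dtype=object),
        df["alt"].to_numpy(dtype=object),
        samples,
        refm,
        altm,
    )
    _check_sorted_unique(sc.chrom, sc.pos)
    return sc


def read_counts_vcf(path: str | Path) -> tuple[SiteCounts, dict]:
    """Read diallelic SNPs with per-sample AD from a VCF.

    Indels and multi-allelic records are dropped; the returned dict reports
    how many records were dropped and why.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise CountsFormatError("VCF has no samples")
    chroms, poss, refs, alts, refrows, altrows = [], [], [], [], [], []
    dropped = {"multiallelic": 0, "indel": 0, "no_ad": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped["indel"] += 1
            continue
        ad = v.format("AD")
        if ad is None:
            dropped["no_ad"] += 1
            continue
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        refrows.append(ad[:, 0])
        altrows.append(ad[:, 1])
    if dropped["no_ad"] and not poss:
        raise CountsFormatError("VCF carries no AD (allelic depth) fields")
    n = len(poss)
    sc = SiteCounts(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        samples,
        np.vstack(refrows) if n else np.zeros((0, len(samples)), dtype=int),
        np.vstack(altrows) if n else np.zeros((0, len(samples)), dtype=int),
    )
    _check_sorted_unique(sc.chrom, sc.pos)
    for reason, k in dropped.items():
        if k:
            logger.info("read_counts_vcf: dropped %d records (%s)", k, reason)
    return sc, dropped


def read_counts(path: str | Path, format: str = "tsv", meta_path: str | Path | None = None):
    """Read allele counts (``format`` in {'tsv', 'vcf_ad'}); optionally join
    sample metadata by sample_id.

    Returns ``(SiteCounts, SampleMeta | None)``.
    """
    if format == "tsv":
        sites = read_counts_tsv(path)
    elif format == "vcf_ad":
        sites, _ = read_counts_vcf(path)
    else:
        raise ValueError(f"unknown counts format {format!r}")
    meta = None
    if meta_path is not None:
        meta = read_meta(meta_path)
        missing = set(sites.samples) - set(meta["sample_id"])
        if missing:
            raise CountsFormatError(f"metadata missing for samples: {sorted(missing)}")
    return sites, meta


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "regime": str})
    if list(meta.columns[:4]) != META_COLUMNS:
        raise CountsFormatError(f"metadata must have columns {META_COLUMNS}")
    bad = set(meta["regime"]) - set(ALL_REGIMES)
    if bad:
        raise CountsFormatError(f"unknown regimes {sorted(bad)}")
    anc = meta["regime"] == "ANC"
    if np.any(meta.loc[anc, "generation"] != 0):
        raise CountsFormatError("ancestor samples must have generation 0")
    return meta


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def mask_repeats(sites: SiteCounts, mask: RegionSet) -> SiteCounts:
    """Drop sites falling inside masked repeat regions.

    A site at 1-based position P is removed iff P-1 lies in a (0-based,
    half-open) mask interval on its chromosome.  Mask chromosomes absent from
    the data are ignored with a warning.
    """
    unknown = mask.chroms() - set(np.unique(sites.chrom.astype(str)))
    if unknown:
        logger.warning("mask_repeats: mask chromosomes not in data: %s", sorted(unknown))
    remove = np.zeros(sites.n_sites, dtype=bool)
    for chrom in np.unique(sites.chrom.astype(str)):
        sel = sites.chrom == chrom
        remove[sel] = mask.contains(chrom, sites.pos[sel] - 1)
    logger.info("mask_repeats: removed %d of %d sites", int(remove.sum()), sites.n_sites)
    return sites.subset_sites(~remove)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Type-1 (nearest-rank) quantile: the ceil(q*n)-th order statistic."""
    v = np.sort(np.asarray(values))
    n = len(v)
    if n == 0:
        raise ValueError("empty input")
    k = max(1, int(np.ceil(q * n)))
    return float(v[k - 1])


def filter_coverage_tails(
    sites: SiteCounts, lower_q: float = 0.05, upper_q: float = 0.95
) -> tuple[SiteCounts, tuple[float, float]]:
    """Remove sites in the tails of the total-coverage distribution.

    Thresholds are nearest-rank quantiles of per-site total coverage (summed
    over samples); sites with coverage <= lower or > upper are dropped.
    Returns the filtered sites and the (lower, upper) thresholds used.
    """
    if sites.n_sites == 0:
        raise ValueError("no sites to filter")
    cov = sites.total_coverage()
    if np.all(cov == cov[0]):
        logger.warning("filter_coverage_tails: degenerate all-equal coverages; nothing removed")
        return sites, (float(cov[0]), float(cov[0]))
    lo = nearest_rank_quantile(cov, lower_q)
    hi = nearest_rank_quantile(cov, upper_q)
    keep = (cov > lo) & (cov <= hi)
    logger.info(
        "filter_coverage_tails: thresholds (<=%g, >%g); removed %d of %d sites",
        lo, hi, int((~keep).sum()), sites.n_sites,
    )
    return sites.subset_sites(keep), (lo, hi)


def presence_mask(sites: SiteCounts, mode: str = "coverage") -> np.ndarray:
    """Boolean site x sample presence matrix.

    ``mode='coverage'``: present iff total depth >= 1 (default — the filters
    act on occurrence, not allele observation).  ``mode='alt'``: present iff
    at least one alt read.
    """
    if mode == "coverage":
        return sites.coverage() >= 1
    if mode == "alt":
        return sites.alt_counts >= 1
    raise ValueError(f"unknown presence mode {mode!r}")


def presence_filter(
    sites: SiteCounts,
    meta: pd.DataFrame,
    require_ancestor: bool = True,
    min_present: int = 10,
    scope: str = "all_evolved",
    regime: str | None = None,
    mode: str = "coverage",
) -> SiteCounts:
    """Require sites to be observed in the ancestor and in a minimum number of
    evolved samples.

    ``scope='all_evolved'`` counts presence over every evolved sample (all
    regimes, all generations > 0); ``scope='per_regime'`` counts only the
    samples of ``regime``.
    """
    meta = meta.set_index("sample_id").loc[sites.samples].reset_index()
    present = presence_mask(sites, mode)
    is_anc = (meta["regime"] == "ANC").to_numpy()
    if scope == "all_evolved":
        evolved_cols = ~is_anc
    elif scope == "per_regime":
        if regime is None:
            raise ValueError("per_regime scope requires a regime")
        evolved_cols = (meta["regime"] == regime).to_numpy() & ~is_anc
    else:
        raise ValueError(f"unknown scope {scope!r}")
    n_avail = int(evolved_cols.sum())
    if min_present > n_avail:
        raise ValueError(f"min_present={min_present} exceeds {n_avail} available samples")
    keep = present[:, evolved_cols].sum(axis=1) >= min_present
    if require_ancestor:
        if not is_anc.any():
            raise ValueError("require_ancestor set but no ancestor samples present")
        keep &= present[:, is_anc].any(axis=1)
    logger.info("presence_filter: retained %d of %d sites", int(keep.sum()), sites.n_sites)
    return sites.subset_sites(keep)
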