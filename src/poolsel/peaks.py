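"""Significance-peak calling and annotation.

Converts the positions of Bonferroni-significant SNPs into peaks (any run of
at least ``min_snps`` significant SNPs spanning at most 1 kb, maximal
overlapping runs merged), merges peaks falling within a single gene, classifies
peaks against a GFF3 annotation, computes cross-regime overlap tables, width
summaries, and arm/center enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Peak:
    chromosome: str
    start: int  # 1-based inclusive; span of member significant SNPs
    end: int
    n_sig_snps: int
    regimes: frozenset = frozenset()
    annotation_class: str | None = None
    gene_id: str | None = None

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class GeneAnnotation:
    """Gene intervals (1-based inclusive) with coding/pseudogene biotype."""

    genes: pd.DataFrame  # columns: chrom, start, end, gene_id, biotype

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="merge"
        )
        rows = []
        for ftype in ("gene", "pseudogene"):
            for feat in db.features_of_type(ftype):
                biotype = feat.attributes.get("biotype", [None])[0]
                if biotype is None:
                    biotype = "pseudogene" if ftype == "pseudogene" else "protein_coding"
                gid = feat.attributes.get("ID", [feat.id])[0]
                rows.append((feat.seqid, feat.start, feat.end, gid, biotype))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "biotype"])
        return cls(df.sort_values(["chrom", "start"]).reset_index(drop=True))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAnnotation":
        return cls(df.sort_values(["chrom", "start"]).reset_index(drop=True))

    def coding(self) -> pd.DataFrame:
        return self.genes[self.genes["biotype"] != "pseudogene"]

    def pseudo(self) -> pd.DataFrame:
        return self.genes[self.genes["biotype"] == "pseudogene"]


def call_peaks(
    positions: np.ndarray,
    chromosome: str = "",
    min_snps: int = 3,
    window: int = 1000,
    regime: str | None = None,
) -> list[Peak]:
    """Call peaks from sorted significant-SNP positions on one chromosome.

    Any set of >= ``min_snps`` significant SNPs whose positions span at most
    ``window`` bp qualifies; maximal overlapping qualifying sets are merged
    into a single peak covering [min member position, max member position].
    """
    pos = np.unique(np.asarray(positions, dtype=np.int64))
    k = min_snps
    if len(pos) < k:
        return []
    # qualifying index runs: k consecutive SNPs within the window span
    starts = np.flatnonzero(pos[k - 1 :] - pos[: len(pos) - k + 1] <= window)
    if len(starts) == 0:
        return []
    regimes = frozenset() if regime is None else frozenset([regime])
    peaks = []
    run_lo, run_hi = starts[0], starts[0] + k - 1
    for i in starts[1:]:
        if i <= run_hi:  # index windows share a SNP -> same peak
            run_hi = i + k - 1
        else:
            peaks.append(Peak(chromosome, int(pos[run_lo]), int(pos[run_hi]), run_hi - run_lo + 1, regimes))
            run_lo, run_hi = i, i + k - 1
    peaks.append(Peak(chromosome, int(pos[run_lo]), int(pos[run_hi]), run_hi - run_lo + 1, regimes))
    return peaks


def call_peaks_genome(
    scan_result: pd.DataFrame, min_snps: int = 3, window: int = 1000
) -> list[Peak]:
    """Call peaks per chromosome from a scan-result table (``significant``
    column), tagging peaks with the scan's regime."""
    sig = scan_result[scan_result["significant"]]
    peaks: list[Peak] = []
    for (chrom, regime), grp in sig.groupby(["chrom", "regime"], sort=True):
        peaks.extend(
            call_peaks(grp["pos"].to_numpy(), str(chrom), min_snps, window, regime=str(regime))
        )
    return peaks


def merge_within_genes(peaks: list[Peak], annotation: GeneAnnotation) -> list[Peak]:
    """Union peaks whose intervals fall entirely within the same gene.

    Peaks only partially overlapping a gene are left unmerged.
    """
    genes = annotation.genes
    assigned: dict[str, list[Peak]] = {}
    rest: list[Peak] = []
    for pk in peaks:
        g = genes[
            (genes["chrom"] == pk.chromosome)
            & (genes["start"] <= pk.start)
            & (genes["end"] >= pk.end)
        ]
        if len(g):
            assigned.setdefault(g.iloc[0]["gene_id"], []).append(pk)
        else:
            rest.append(pk)
    merged: list[Peak] = []
    for gid, group in assigned.items():
        if len(group) == 1:
            pk = group[0]
            merged.append(
                Peak(pk.chromosome, pk.start, pk.end, pk.n_sig_snps, pk.regimes, pk.annotation_class, gid)
            )
        else:
            merged.append(
                Peak(
                    group[0].chromosome,
                    min(p.start for p in group),
                    max(p.end for p in group),
                    sum(p.n_sig_snps for p in group),
                    frozenset().union(*(p.regimes for p in group)),
                    None,
                    gid,
                )
            )
    out = merged + rest
    out.sort(key=lambda p: (p.chromosome, p.start))
    return out


def _overlap_bp(pk: Peak, df: pd.DataFrame) -> tuple[int, str | None]:
    g = df[(df["chrom"] == pk.chromosome) & (df["start"] <= pk.end) & (df["end"] >= pk.start)]
    if not len(g):
        return 0, None
    ov = np.minimum(g["end"], pk.end) - np.maximum(g["start"], pk.start) + 1
    best = int(np.argmax(ov.to_numpy()))
    return int(ov.sum()), g.iloc[best]["gene_id"]


def classify_peaks(peaks: list[Peak], annotation: GeneAnnotation) -> list[Peak]:
    """Assign annotation classes: genic, pseudogenic, intergenic, or mixed.

    A peak overlapping both a coding gene and a pseudogene is mixed; a peak
    overlapping a single class is assigned that class when the overlap covers
    at least half the peak (majority-overlap), mixed otherwise.
    """
    coding = annotation.coding()
    pseudo = annotation.pseudo()
    out = []
    for pk in peaks:
        oc, gid_c = _overlap_bp(pk, coding)
        op, gid_p = _overlap_bp(pk, pseudo)
        if oc > 0 and op > 0:
            cls, gid = "mixed", gid_c
        elif oc > 0:
            cls = "genic" if oc >= 0.5 * pk.width else "mixed"
            gid = gid_c
        elif op > 0:
            cls = "pseudogenic" if op >= 0.5 * pk.width else "mixed"
            gid = gid_p
        else:
            cls, gid = "intergenic", None
        out.append(Peak(pk.chromosome, pk.start, pk.end, pk.n_sig_snps, pk.regimes, cls, gid))
    return out


def peak_overlap(peaksets: dict[str, list[Peak]]) -> pd.DataFrame:
    """Cross-regime overlap table (upset-style).

    Peaks from different regimes are the same peak iff their intervals overlap
    by >= 1 bp, with transitive union.  Returns counts per regime combination.
    """
    if len(peaksets) < 2:
        raise ValueError("need >= 2 peaksets")
    flat: list[tuple[str, Peak]] = [
        (regime, pk) for regime, pks in peaksets.items() for pk in pks
    ]
    n = len(flat)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if flat[i][1].overlaps(flat[j][1]):
                union(i, j)
    combos: dict[frozenset, int] = {}
    members: dict[int, set] = {}
    for i, (regime, _) in enumerate(flat):
        members.setdefault(find(i), set()).add(regime)
    for regs in members.values():
        key = frozenset(regs)
        combos[key] = combos.get(key, 0) + 1
    rows = [
        {"regimes": "+".join(sorted(k)), "n_regimes": len(k), "count": v}
        for k, v in combos.items()
    ]
    return pd.DataFrame(rows).sort_values(
        ["n_regimes", "regimes"], ascending=[False, True]
    ).reset_index(drop=True)


def width_stats(peaks: list[Peak]) -> tuple[float, float, float]:
    """(median, mean, max) of peak widths (end - start + 1)."""
    if not peaks:
        raise ValueError("no peaks")
    widths = np.array([p.width for p in peaks], dtype=float)
    return float(np.median(widths)), float(widths.mean()), float(widths.max())


def arm_center_enrichment(
    peaks: list[Peak], domain_map, expected_arm_fraction: float
) -> tuple[float, int, float]:
    """1-df goodness-of-fit chi-square of peak arm/center placement against
    the ancestral SNP arm fraction.  Peaks are assigned by midpoint."""
    if not 0 < expected_arm_fraction < 1:
        raise ValueError("expected fraction must be in (0,1)")
    if not peaks:
        raise ValueError("no peaks")
    obs_arm = 0
    for pk in peaks:
        mid = (pk.start + pk.end) // 2
        if domain_map.is_arm(pk.chromosome, np.array([mid]))[0]:
            obs_arm += 1
    n = len(peaks)
    e_arm = n * expected_arm_fraction
    e_cen = n * (1.0 - expected_arm_fraction)
    if min(e_arm, e_cen) < 1:
        import logging

        logging.getLogger(__name__).warning("arm_center_enrichment: expected cell < 1")
    chi2 = (obs_arm - e_arm) ** 2 / e_arm + ((n - obs_arm) - e_cen) ** 2 / e_cen
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chromosome for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "n_sig_snps": [p.n_sig_snps for p in peaks],
            "regimes": ["+".join(sorted(p.regimes)) for p in peaks],
            "annotation_class": [p.annotation_class for p in peaks],
            "gene_id": [p.gene_id for p in peaks],
        }
    )
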