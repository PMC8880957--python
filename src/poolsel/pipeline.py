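"""End-to-end pipeline orchestration.

Runs simulate -> filter -> diversity -> ne -> scan -> peaks -> fertility from a
single flat configuration, writing per-stage TSV outputs plus a JSON manifest
with seeds, record counts, and input digests.  Identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from poolsel import counts_io, diversity, fertility, peaks as peaks_mod, simdata, temporal_ne
from poolsel.afc_scan import model1_contrasts, model2_scan
from poolsel.counts_io import EVOLVED_REGIMES

logger = logging.getLogger("poolsel.pipeline")

STAGES = ["simulate", "filter", "diversity", "ne", "scan", "peaks", "fertility"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "poolsel_run"
    # simulation
    n_sites: int = 500
    chrom_lengths: dict = field(default_factory=lambda: {"I": 500_000, "II": 500_000})
    true_ne: int = 500
    pool_individuals: int = 2500
    n_replicates: int = 6
    selected_sites: list = field(default_factory=list)
    # filtering (thresholds follow the analysis defaults)
    coverage_lower_q: float = 0.05
    coverage_upper_q: float = 0.95
    model1_min_present: int = 10
    model2_min_present: int = 9
    # scan / peaks
    alpha: float = 0.05
    min_snps: int = 3
    peak_window: int = 1000
    # ne
    t: int = 31
    n_females: float = 2500.0
    # fertility
    fertility_true_probs: dict = field(
        default_factory=lambda: {"ANC": {"total": 0.445, "post": 0.041}}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        logger.info("stage=%s level=INFO message=done %s", stage, info)

    try:
        # simulate
        sim_cfg = simdata.SimConfig(
            seed=config.seed,
            chrom_lengths=config.chrom_lengths,
            n_sites=config.n_sites,
            true_ne=config.true_ne,
            pool_individuals=config.pool_individuals,
            n_replicates=config.n_replicates,
            selected_sites=list(config.selected_sites),
        )
        fert_cfg = simdata.FertilitySimConfig(seed=config.seed, true_siring_prob=config.fertility_true_probs)
        simdata.write_simulation(sim_cfg, outdir, fertility_config=fert_cfg)
        sites, meta = counts_io.read_counts(outdir / "counts.tsv", meta_path=outdir / "meta.tsv")
        record("simulate", n_sites=sites.n_sites, n_samples=sites.n_samples,
               counts_digest=_digest(outdir / "counts.tsv"))

        # filter
        n0 = sites.n_sites
        mask = counts_io.RegionSet.from_bed(outdir / "repeats.bed")
        sites = counts_io.mask_repeats(sites, mask)
        n_masked = n0 - sites.n_sites
        sites, thresholds = counts_io.filter_coverage_tails(
            sites, config.coverage_lower_q, config.coverage_upper_q
        )
        n_tails = n0 - n_masked - sites.n_sites
        counts_io.write_counts(sites, outdir / "counts.filtered.tsv")
        record("filter", input_sites=n0, masked=n_masked, coverage_tails=n_tails,
               retained=sites.n_sites, thresholds=list(thresholds))

        # diversity (on ancestor pools)
        anc_ids = meta.loc[meta["regime"] == "ANC", "sample_id"].tolist()
        anc = sites.subset_samples(anc_ids)
        dom = diversity.DomainMap.from_tsv(outdir / "domains.tsv")
        summary = diversity.diversity_summary(anc, dom)
        wins = diversity.theta_w_windows(
            anc.chrom, anc.pos, anc.total_coverage(), chrom_lengths=config.chrom_lengths
        )
        wins.to_csv(outdir / "theta_windows.tsv", sep="\t", index=False)
        record("diversity", **{k: summary[k] for k in ("n_snps", "mean_pi", "mean_maf")})

        # ne
        ne_df = temporal_ne.ne_by_chromosome(sites, meta, config.pool_individuals, t=config.t)
        ne_df.to_csv(outdir / "ne_estimates.tsv", sep="\t", index=False)
        record("ne", n_estimates=len(ne_df))

        # scan (Model 2 per regime + Model 1)
        scans = []
        for regime in EVOLVED_REGIMES:
            flt = counts_io.presence_filter(
                sites, meta, min_present=config.model2_min_present,
                scope="per_regime", regime=regime,
            )
            scans.append(model2_scan(flt, meta, regime, alpha=config.alpha))
        scan_df = pd.concat(scans, ignore_index=True)
        scan_df.to_csv(outdir / "scan_model2.tsv", sep="\t", index=False)
        m1_sites = counts_io.presence_filter(sites, meta, min_present=config.model1_min_present)
        m1 = model1_contrasts(m1_sites, meta, alpha=config.alpha)
        m1.to_csv(outdir / "scan_model1.tsv", sep="\t", index=False)
        record("scan", model2_snps=int(sum(s.attrs["m"] for s in scans)),
               model2_significant=int(scan_df["significant"].sum()), model1_snps=m1.attrs["m"])

        # peaks
        called = peaks_mod.call_peaks_genome(scan_df, config.min_snps, config.peak_window)
        ann = peaks_mod.GeneAnnotation.from_gff3(outdir / "genes.gff3")
        called = peaks_mod.merge_within_genes(called, ann)
        called = peaks_mod.classify_peaks(called, ann)
        peaks_mod.peaks_to_frame(called).to_csv(outdir / "peaks.tsv", sep="\t", index=False)
        record("peaks", n_peaks=len(called))

        # fertility
        assays = pd.read_csv(outdir / "assays.tsv", sep="\t")
        anc_post = assays[(assays["population"] == "ANC") & (assays["condition"] == "post")]
        x, n = fertility.pool_assays(anc_post)
        res = fertility.prop_test_one_sample(x, n)
        record("fertility", n_assays=len(assays), anc_post_chi2=res.chi2, anc_post_p=res.p)
    except Exception:
        manifest["failed"] = True
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
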