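"""Wright-Fisher experimental-evolution simulator with pool-seq sampling.

Generates ground-truthed synthetic data matching the structure of a four-regime
x six-replicate evolve-and-resequence design: an ancestral SNP pool with
arm-biased density and a low-skewed minor-allele-frequency spectrum, forward
Wright-Fisher trajectories with optional (regime-specific) selection, two-stage
pool-seq read counts (pooled individuals, then reads), and beta-binomial
competitive-fertility assay counts.

All randomness flows from a single seed through `numpy.random.SeedSequence`
spawning, so every emitted byte is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from poolsel.counts_io import (
    ALL_REGIMES,
    EVOLVED_REGIMES,
    SiteCounts,
    write_counts,
    write_meta,
)

SAMPLED_GENERATIONS = (0, 13, 22, 31)
# mean genome-wide depths by sampled generation, as realized in the design
DEFAULT_COVERAGE = {0: 162.0, 13: 24.0, 22: 26.0, 31: 50.0}


@dataclass
class SelectedSite:
    """A site under selection: coefficient ``s`` applied in ``regime`` (or in
    every evolved regime when ``regime`` is None)."""

    site: int
    s: float
    regime: str | None = None


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"I": 1_000_000, "II": 1_000_000})
    domain_map: dict | None = None  # chrom -> [(start, end, label)] 1-based inclusive
    n_sites: int = 1000
    arm_density_ratio: float = 5.0 / 3.0  # arm:center SNP density
    # defaults tuned so mean per-site 2p(1-p) across the spectrum is ~0.06
    maf_alpha: float = 0.3
    maf_beta: float = 8.5
    maf_min: float = 0.004
    true_ne: int = 500
    census: int = 5000
    n_replicates: int = 6
    sampled_generations: tuple = SAMPLED_GENERATIONS
    selected_sites: list = field(default_factory=list)  # of SelectedSite
    pool_individuals: int = 2500
    coverage_by_generation: dict = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    n_ancestor_pools: int = 3
    # site index -> fixed generation-0 frequency (e.g. to pin selected sites)
    freq0_overrides: dict = field(default_factory=dict)

    @property
    def regimes(self) -> tuple:
        return EVOLVED_REGIMES

    def __post_init__(self) -> None:
        if self.domain_map is None:
            self.domain_map = default_domain_map(self.chrom_lengths)
        if self.n_sites <= 0 or self.true_ne <= 0 or self.census <= 0:
            raise ValueError("counts must be positive")
        if self.pool_individuals < 1 or self.n_ancestor_pools < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        if self.maf_alpha <= 0 or self.maf_beta <= 0:
            raise ValueError("MAF shape parameters must be positive")
        gens = tuple(self.sampled_generations)
        if gens[0] != 0 or any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("sampled generations must be strictly increasing from 0")
        self.selected_sites = [
            s if isinstance(s, SelectedSite) else SelectedSite(*s) for s in self.selected_sites
        ]
        for sel in self.selected_sites:
            if not -1 < sel.s < 1:
                raise ValueError("|s| must be < 1")
        total_len = sum(self.chrom_lengths.values())
        if self.n_sites > total_len:
            raise ValueError("n_sites exceeds total genome length")
        for chrom, ivs in self.domain_map.items():
            for start, end, label in ivs:
                if end < start:
                    raise ValueError(f"zero-length domain {chrom}:{start}-{end}")


def default_domain_map(chrom_lengths: dict) -> dict:
    """Split each chromosome into equal arm_left / center / arm_right thirds."""
    dm = {}
    for chrom, length in chrom_lengths.items():
        third = length // 3
        dm[chrom] = [
            (1, third, "arm_left"),
            (third + 1, 2 * third, "center"),
            (2 * third + 1, length, "arm_right"),
        ]
    return dm


@dataclass
class TrueTrajectories:
    """Ground-truth allele frequencies for recovery tests.

    ``freq`` has shape (n_sites, n_regimes, n_replicates, n_generations) —
    for generation-0-only output the regime/replicate axes are length 1.
    """

    freq: np.ndarray
    regimes: tuple
    replicates: tuple
    generations: tuple
    selected: np.ndarray  # bool per site (in any regime)
    s_by_regime: np.ndarray | None = None  # (n_sites, n_regimes) coefficients

    def freq0(self) -> np.ndarray:
        return self.freq[:, 0, 0, 0]

    def to_frame(self, chrom: np.ndarray, pos: np.ndarray) -> pd.DataFrame:
        rows = []
        for ri, regime in enumerate(self.regimes):
            for pi, rep in enumerate(self.replicates):
                for gi, gen in enumerate(self.generations):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chrom": chrom,
                                "pos": pos,
                                "regime": regime,
                                "replicate": rep,
                                "generation": gen,
                                "true_freq": self.freq[:, ri, pi, gi],
                                "selected": self.selected,
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def draw_maf(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw minor allele frequencies: Beta(alpha, beta) folded to (0, 0.5],
    floored at ``maf_min``."""
    raw = rng.beta(config.maf_alpha, config.maf_beta, size=n)
    maf = np.minimum(raw, 1.0 - raw)
    return np.clip(maf, config.maf_min, 0.5)


def gen_ancestral_sites(config: SimConfig):
    """Generate ancestral SNP positions, true frequencies, and pooled counts.

    Site positions are drawn with the configured arm:center density ratio;
    true alt frequencies equal the drawn MAF (the alternate allele is treated
    as the minor, derived allele).  Returns ``(SiteCounts, TrueTrajectories)``
    with generation-0 frequencies only.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pos, rng_freq, rng_pool = [np.random.default_rng(s) for s in ss.spawn(3)]

    # choose domains weighted by length x relative density
    domains = []
    weights = []
    for chrom, ivs in config.domain_map.items():
        for start, end, label in ivs:
            density = config.arm_density_ratio if label.startswith("arm") else 1.0
            domains.append((chrom, start, end, label))
            weights.append((end - start + 1) * density)
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()

    # sample unique positions; resample collisions
    chosen: set = set()
    order: list = []
    while len(order) < config.n_sites:
        need = config.n_sites - len(order)
        dom_idx = rng_pos.choice(len(domains), size=need, p=weights)
        for di in dom_idx:
            chrom, start, end, _ = domains[di]
            p = int(rng_pos.integers(start, end + 1))
            if (chrom, p) not in chosen:
                chosen.add((chrom, p))
                order.append((chrom, p))
    order.sort()
    chroms = np.array([c for c, _ in order], dtype=object)
    pos = np.array([p for _, p in order], dtype=np.int64)

    freq0 = draw_maf(config, config.n_sites, rng_freq)
    for idx, f in config.freq0_overrides.items():
        freq0[idx] = f
    bases = np.array(list("ACGT"), dtype=object)
    ref_idx = rng_freq.integers(0, 4, size=config.n_sites)
    alt_shift = rng_freq.integers(1, 4, size=config.n_sites)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + alt_shift) % 4]

    cov_mean = config.coverage_by_generation[0]
    refm = np.zeros((config.n_sites, config.n_ancestor_pools), dtype=np.int64)
    altm = np.zeros_like(refm)
    samples = []
    for k in range(config.n_ancestor_pools):
        samples.append(f"ANC_P{k + 1}_G0")
        alt_c, ref_c = pool_seq_sample(
            freq0, config.pool_individuals, _draw_coverage(cov_mean, config.n_sites, rng_pool), rng_pool
        )
        refm[:, k] = ref_c
        altm[:, k] = alt_c

    counts = SiteCounts(chroms, pos, ref, alt, samples, refm, altm)
    truth = TrueTrajectories(
        freq0[:, None, None, None],
        ("ANC",),
        (0,),
        (0,),
        np.zeros(config.n_sites, dtype=bool),
    )
    return counts, truth


def _draw_coverage(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.poisson(mean, size=n)


def selection_update(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """One deterministic selection step: p' = p(1+s) / (1 + p s)."""
    return p * (1.0 + s) / (1.0 + p * s)


def simulate_trajectories(
    freq0: np.ndarray,
    config: SimConfig,
    s: np.ndarray | float = 0.0,
    rng: np.random.Generator | None = None,
    n_generations: int | None = None,
    sampled_generations: tuple | None = None,
) -> np.ndarray:
    """Simulate one Wright-Fisher lineage.

    Per generation a deterministic selection update is followed by binomial
    resampling of ``2 * true_ne`` allele copies (``true_ne=None``-like infinite
    limit is obtained by the deterministic path in callers).  Returns the
    frequency matrix at the sampled generations, shape
    ``(n_sites, len(sampled_generations))``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gens = tuple(sampled_generations or config.sampled_generations)
    n_gen = n_generations if n_generations is not None else gens[-1]
    s = np.broadcast_to(np.asarray(s, dtype=float), freq0.shape)
    p = np.asarray(freq0, dtype=float).copy()
    out = np.empty((len(p), len(gens)))
    gi = 0
    if gens[0] == 0:
        out[:, 0] = p
        gi = 1
    two_ne = 2 * config.true_ne
    for g in range(1, n_gen + 1):
        p = selection_update(p, s)
        p = rng.binomial(two_ne, p) / two_ne
        if gi < len(gens) and g == gens[gi]:
            out[:, gi] = p
            gi += 1
    return out


def pool_seq_sample(
    p_true: np.ndarray,
    pool_individuals: int,
    coverage: np.ndarray | int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage pool-seq sampling: individuals into the pool, then reads.

    q ~ Binomial(2*pool_individuals, p_true) / (2*pool_individuals), then
    alt ~ Binomial(coverage, q).  Returns ``(alt_count, ref_count)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_true = np.asarray(p_true, dtype=float)
    coverage = np.broadcast_to(np.asarray(coverage, dtype=np.int64), p_true.shape)
    two_n = 2 * pool_individuals
    q = rng.binomial(two_n, p_true) / two_n
    alt = rng.binomial(coverage, q)
    return alt, coverage - alt


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def _s_matrix(config: SimConfig) -> np.ndarray:
    """Per-site, per-regime selection coefficients from config.selected_sites."""
    s = np.zeros((config.n_sites, len(EVOLVED_REGIMES)))
    for sel in config.selected_sites:
        if sel.regime is None:
            s[sel.site, :] = sel.s
        else:
            s[sel.site, EVOLVED_REGIMES.index(sel.regime)] = sel.s
    return s


def gen_experiment(config: SimConfig):
    """Simulate the full design: ancestor pools plus every regime x replicate
    lineage sampled at the configured generations.

    Returns ``(SiteCounts, SampleMeta DataFrame, TrueTrajectories)``.  Sample
    columns: ``n_ancestor_pools`` ancestor pools at G0, then one column per
    (regime, replicate, evolved generation).
    """
    anc_counts, anc_truth = gen_ancestral_sites(config)
    freq0 = anc_truth.freq0()
    s_mat = _s_matrix(config)
    gens = tuple(config.sampled_generations)
    evolved_gens = [g for g in gens if g > 0]

    ss = np.random.SeedSequence((config.seed, 1))
    n_lineages = len(EVOLVED_REGIMES) * config.n_replicates
    lineage_seeds = ss.spawn(n_lineages)
    pool_rng = np.random.default_rng(ss.spawn(1)[0])

    freq = np.empty((config.n_sites, len(EVOLVED_REGIMES), config.n_replicates, len(gens)))
    cols_ref, cols_alt, meta_rows = [], [], []
    li = 0
    for ri, regime in enumerate(EVOLVED_REGIMES):
        for rep in range(1, config.n_replicates + 1):
            rng = np.random.default_rng(lineage_seeds[li])
            li += 1
            traj = simulate_trajectories(freq0, config, s_mat[:, ri], rng, sampled_generations=gens)
            freq[:, ri, rep - 1, :] = traj
            for gi, g in enumerate(gens):
                if g == 0:
                    continue
                cov = _draw_coverage(config.coverage_by_generation[g], config.n_sites, pool_rng)
                alt_c, ref_c = pool_seq_sample(traj[:, gi], config.pool_individuals, cov, pool_rng)
                cols_ref.append(ref_c)
                cols_alt.append(alt_c)
                meta_rows.append((f"{regime}_R{rep}_G{g}", regime, rep, g))

    samples = list(anc_counts.samples) + [m[0] for m in meta_rows]
    refm = np.column_stack([anc_counts.ref_counts] + cols_ref)
    altm = np.column_stack([anc_counts.alt_counts] + cols_alt)
    counts = SiteCounts(anc_counts.chrom, anc_counts.pos, anc_counts.ref, anc_counts.alt, samples, refm, altm)

    meta = pd.DataFrame(
        [(s, "ANC", 0, 0) for s in anc_counts.samples] + meta_rows,
        columns=["sample_id", "regime", "replicate", "generation"],
    )
    truth = TrueTrajectories(
        freq,
        EVOLVED_REGIMES,
        tuple(range(1, config.n_replicates + 1)),
        gens,
        s_mat.any(axis=1),
        s_by_regime=s_mat,
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# fertility assays
# ---------------------------------------------------------------------------

@dataclass
class FertilitySimConfig:
    seed: int = 0
    # population -> condition ('total'|'post') -> true siring probability
    true_siring_prob: dict = field(
        default_factory=lambda: {"ANC": {"total": 0.445, "post": 0.041}}
    )
    progeny_per_assay: int = 250
    n_assays: int = 3
    overdispersion_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.progeny_per_assay < 1 or self.n_assays < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        for pop, conds in self.true_siring_prob.items():
            for cond, p in conds.items():
                if not 0 < p < 1:
                    raise ValueError(f"probability out of (0,1) for {pop}/{cond}")


def gen_fertility_assays(config: FertilitySimConfig) -> pd.DataFrame:
    """Simulate competitive-fertility assay counts.

    Focal counts are Beta-Binomial(n, p, rho); rho = 0 degenerates to the
    plain binomial.  Returns a DataFrame with columns population, condition,
    assay, n_focal, n_competitor.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    rows = []
    for pop in sorted(config.true_siring_prob):
        for cond in sorted(config.true_siring_prob[pop]):
            p = config.true_siring_prob[pop][cond]
            for a in range(1, config.n_assays + 1):
                n = config.progeny_per_assay
                if config.overdispersion_rho > 0:
                    rho = config.overdispersion_rho
                    alpha = p * (1.0 - rho) / rho
                    beta = (1.0 - p) * (1.0 - rho) / rho
                    p_i = rng.beta(alpha, beta)
                else:
                    p_i = p
                x = int(rng.binomial(n, p_i))
                rows.append((pop, cond, a, x, n - x))
    return pd.DataFrame(rows, columns=["population", "condition", "assay", "n_focal", "n_competitor"])


# ---------------------------------------------------------------------------
# file emission (counts TSV, metadata, BED mask, toy GFF3, ground truth)
# ---------------------------------------------------------------------------

def write_simulation(
    config: SimConfig,
    outdir: str | Path,
    mask_intervals: dict | None = None,
    fertility_config: FertilitySimConfig | None = None,
) -> dict:
    """Run gen_experiment and write all artifacts to ``outdir``.

    Emits counts.tsv, meta.tsv, repeats.bed (possibly empty), genes.gff3 (a
    toy annotation tiling each chromosome), domains.tsv, truth.tsv and, when
    ``fertility_config`` is given, assays.tsv.  Returns a manifest dict.
    """
    from poolsel.counts_io import RegionSet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, meta, truth = gen_experiment(config)
    write_counts(counts, outdir / "counts.tsv")
    write_meta(meta, outdir / "meta.tsv")
    RegionSet.from_dict(mask_intervals or {}).to_bed(outdir / "repeats.bed")
    write_toy_gff3(config, outdir / "genes.gff3")
    dom_rows = [
        (chrom, start, end, label)
        for chrom, ivs in config.domain_map.items()
        for start, end, label in ivs
    ]
    pd.DataFrame(dom_rows, columns=["chrom", "start", "end", "label"]).to_csv(
        outdir / "domains.tsv", sep="\t", index=False
    )
    truth.to_frame(counts.chrom, counts.pos).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "n_sites": counts.n_sites,
        "n_samples": counts.n_samples,
        "files": ["counts.tsv", "meta.tsv", "repeats.bed", "genes.gff3", "domains.tsv", "truth.tsv"],
    }
    if fertility_config is not None:
        gen_fertility_assays(fertility_config).to_csv(outdir / "assays.tsv", sep="\t", index=False)
        manifest["files"].append("assays.tsv")
    return manifest


def write_toy_gff3(config: SimConfig, path: str | Path, gene_length: int = 5000, gap: int = 5000) -> None:
    """Write a deterministic toy GFF3: alternating coding genes and an
    occasional pseudogene tiling each chromosome."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in config.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
            start = 1
            k = 0
            while start + gene_length - 1 <= length:
                k += 1
                end = start + gene_length - 1
                biotype = "pseudogene" if k % 5 == 0 else "protein_coding"
                ftype = "pseudogene" if biotype == "pseudogene" else "gene"
                gid = f"{chrom}.g{k}"
                fh.write(
                    f"{chrom}\ttoy\t{ftype}\t{start}\t{end}\t.\t+\t.\t"
                    f"ID=gene:{gid};biotype={biotype};Name={gid}\n"
                )
                start = end + gap + 1
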