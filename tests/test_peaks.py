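import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolsel.diversity import DomainMap
from poolsel.peaks import (
    GeneAnnotation,
    Peak,
    arm_center_enrichment,
    call_peaks,
    call_peaks_genome,
    classify_peaks,
    merge_within_genes,
    peak_overlap,
    peaks_to_frame,
    width_stats,
)


def oracle_peaks(positions, min_snps=3, window=1000):
    """Independent brute-force peak caller: enumerate every candidate window
    anchored at a SNP, collect qualifying member sets, and merge any sets
    sharing a member until a fixpoint."""
    pos = sorted(set(int(p) for p in positions))
    sets = []
    for x in pos:
        members = frozenset(p for p in pos if x <= p <= x + window)
        if len(members) >= min_snps:
            sets.append(set(members))
    changed = True
    while changed:
        changed = False
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    sets[i] |= sets.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted((min(s), max(s), len(s)) for s in sets)


def called_tuples(positions, min_snps=3, window=1000):
    return sorted((p.start, p.end, p.n_sig_snps) for p in call_peaks(positions, min_snps=min_snps, window=window))


class TestCallPeaks:
    def test_sparse_no_peak(self):
        assert call_peaks([100, 2000, 5000]) == []

    def test_simple_triplet(self):
        (pk,) = call_peaks([100, 200, 900])
        assert (pk.start, pk.end, pk.n_sig_snps) == (100, 900, 3)

    def test_two_separate_peaks(self):
        pks = call_peaks([100, 200, 900, 2500, 2600, 2700])
        assert [(p.start, p.end) for p in pks] == [(100, 900), (2500, 2700)]

    def test_bridge_set_chains_runs(self):
        # {900, 1500, 1600} spans 700 bp, so it qualifies and chains the two
        # clusters into a single peak under the any-span-<=window rule
        (pk,) = call_peaks([100, 200, 900, 1500, 1600, 1700])
        assert (pk.start, pk.end, pk.n_sig_snps) == (100, 1700, 6)

    def test_chained_windows_merge(self):
        (pk,) = call_peaks([100, 200, 900, 1050])
        assert (pk.start, pk.end, pk.n_sig_snps) == (100, 1050, 4)

    def test_matches_oracle_examples(self):
        for positions in ([100, 2000, 5000], [100, 200, 900], [100, 200, 900, 1050],
                          [100, 200, 900, 1500, 1600, 1700], [0, 500, 1000, 1400]):
            assert called_tuples(positions) == oracle_peaks(positions)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(1, 20_000), min_size=0, max_size=80),
        st.sampled_from([3, 5]),
    )
    def test_matches_oracle_property(self, positions, min_snps):
        assert called_tuples(positions, min_snps) == oracle_peaks(positions, min_snps)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 10_000), min_size=0, max_size=60))
    def test_min5_subset_of_min3(self, positions):
        p3 = call_peaks(positions, min_snps=3)
        p5 = call_peaks(positions, min_snps=5)
        for pk5 in p5:
            assert any(p3k.start <= pk5.start and pk5.end <= p3k.end for p3k in p3)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 10_000), min_size=0, max_size=60))
    def test_conservation_and_membership(self, positions):
        uniq = np.unique(positions)
        pks = call_peaks(positions)
        assert sum(p.n_sig_snps for p in pks) <= len(uniq)
        for pk in pks:
            inside = uniq[(uniq >= pk.start) & (uniq <= pk.end)]
            assert len(inside) == pk.n_sig_snps


TOY_GENES = pd.DataFrame(
    {
        "chrom": ["I", "I", "I"],
        "start": [1000, 5000, 9000],
        "end": [2000, 6000, 9500],
        "gene_id": ["g1", "g2", "pseudo1"],
        "biotype": ["protein_coding", "protein_coding", "pseudogene"],
    }
)


class TestMergeClassify:
    def test_merge_two_peaks_in_gene(self):
        ann = GeneAnnotation.from_frame(TOY_GENES)
        pks = [Peak("I", 1100, 1200, 3), Peak("I", 1700, 1900, 4)]
        out = merge_within_genes(pks, ann)
        assert len(out) == 1
        assert (out[0].start, out[0].end, out[0].n_sig_snps, out[0].gene_id) == (1100, 1900, 7, "g1")

    def test_different_genes_unchanged(self):
        ann = GeneAnnotation.from_frame(TOY_GENES)
        pks = [Peak("I", 1100, 1200, 3), Peak("I", 5100, 5200, 3)]
        assert len(merge_within_genes(pks, ann)) == 2

    def test_boundary_overlap_not_merged(self):
        ann = GeneAnnotation.from_frame(TOY_GENES)
        pks = [Peak("I", 1100, 1200, 3), Peak("I", 1900, 2300, 3)]  # second straddles g1 end
        out = merge_within_genes(pks, ann)
        assert len(out) == 2

    def test_classification(self):
        ann = GeneAnnotation.from_frame(TOY_GENES)
        pks = [
            Peak("I", 1100, 1200, 3),   # inside coding
            Peak("I", 9100, 9400, 3),   # inside pseudogene
            Peak("I", 3000, 3500, 3),   # intergenic
            Peak("I", 5900, 9100, 3),   # overlaps coding and pseudogene
        ]
        out = classify_peaks(pks, ann)
        assert [p.annotation_class for p in out] == ["genic", "pseudogenic", "intergenic", "mixed"]

    def test_majority_overlap_rule(self):
        ann = GeneAnnotation.from_frame(TOY_GENES)
        mostly_in = classify_peaks([Peak("I", 1900, 2100, 3)], ann)[0]   # 101/201 bp in g1
        mostly_out = classify_peaks([Peak("I", 1950, 2600, 3)], ann)[0]  # 51/651 bp in g1
        assert mostly_in.annotation_class == "genic"
        assert mostly_out.annotation_class == "mixed"


class TestGff3:
    def test_parse_toy_gff3(self, tmp_path):
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "I\ttoy\tgene\t1000\t2000\t.\t+\t.\tID=gene:gA;biotype=protein_coding\n"
            "I\ttoy\tpseudogene\t9000\t9500\t.\t+\t.\tID=gene:pB;biotype=pseudogene\n"
        )
        ann = GeneAnnotation.from_gff3(gff)
        assert len(ann.genes) == 2
        assert len(ann.coding()) == 1 and len(ann.pseudo()) == 1
        assert ann.coding().iloc[0]["start"] == 1000


class TestOverlap:
    def test_identical_peaksets(self):
        pk = [Peak("I", 100, 200, 3)]
        table = peak_overlap({r: list(pk) for r in ("A", "B", "C", "D")})
        assert len(table) == 1
        assert table.iloc[0]["n_regimes"] == 4 and table.iloc[0]["count"] == 1

    def test_disjoint_peaksets(self):
        table = peak_overlap({
            "A": [Peak("I", 100, 200, 3)],
            "B": [Peak("I", 1000, 1100, 3)],
        })
        assert (table["n_regimes"] == 1).all() and table["count"].sum() == 2

    def test_three_way_transitive(self):
        table = peak_overlap({
            "A": [Peak("I", 100, 200, 3)],
            "B": [Peak("I", 150, 250, 3)],
            "C": [Peak("I", 180, 300, 3)],
            "D": [Peak("I", 5000, 5100, 3)],
        })
        top = table.iloc[0]
        assert top["regimes"] == "A+B+C" and top["count"] == 1
        assert table[table["regimes"] == "D"]["count"].iloc[0] == 1

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            peak_overlap({"A": []})


class TestWidthStats:
    def test_single_53bp(self):
        med, mean, mx = width_stats([Peak("I", 100, 152, 3)])
        assert med == mean == mx == 53

    def test_unit_widths(self):
        pks = [Peak("I", i, i, 3) for i in (10, 20, 30)]
        assert width_stats(pks) == (1, 1, 1)

    def test_mixed(self):
        pks = [Peak("I", 0, 9, 3), Peak("I", 100, 152, 3), Peak("I", 1000, 1999, 3)]
        med, mean, mx = width_stats(pks)
        assert med == 53 and mean == pytest.approx(354.3333, rel=1e-4) and mx == 1000

    def test_empty_error(self):
        with pytest.raises(ValueError):
            width_stats([])


DM = DomainMap.from_dict(
    {"I": [(1, 2500, "arm_left"), (2501, 7500, "center"), (7501, 10_000, "arm_right")]}
)


class TestEnrichment:
    def test_exact_match_zero(self):
        pks = [Peak("I", 10, 20, 3)] * 11 + [Peak("I", 5000, 5010, 3)] * 9
        chi2, df, p = arm_center_enrichment(pks, DM, 0.55)
        assert chi2 == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_hand_computation(self):
        pks = [Peak("I", 10, 20, 3)] * 30 + [Peak("I", 5000, 5010, 3)] * 10
        chi2, _, p = arm_center_enrichment(pks, DM, 0.55)
        assert chi2 == pytest.approx(64 / 22 + 64 / 18, rel=1e-9)
        assert p < 0.05

    def test_null_calibration_rejection_rate(self, rng):
        # uniform placement at the expected fraction: rejection rate at
        # alpha=.05 stays near nominal (chi2 on discrete counts)
        rej = 0
        n_sim = 200
        for _ in range(n_sim):
            arm = rng.random(100) < 0.5
            pks = [Peak("I", 10, 20, 3) if a else Peak("I", 5000, 5010, 3) for a in arm]
            _, _, p = arm_center_enrichment(pks, DM, 0.5)
            rej += p < 0.05
        assert rej / n_sim <= 0.09

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            arm_center_enrichment([Peak("I", 1, 2, 3)], DM, 1.5)


def test_call_peaks_genome_and_frame(small_experiment):
    from poolsel.afc_scan import model2_scan

    _, counts, meta, _ = small_experiment
    sc = model2_scan(counts, meta, "BS-PO")
    pks = call_peaks_genome(sc, min_snps=1, window=1000)
    df = peaks_to_frame(pks)
    assert set(df.columns) >= {"chrom", "start", "end", "n_sig_snps", "regimes"}
    assert (df["regimes"] == "BS-PO").all()
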