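import numpy as np
import pytest

import polytarget as pt
from polytarget.annotate import (
    CATEGORIES,
    assign_target_genes,
    classify_feature,
    classify_features,
    feature_distribution,
    tss_profile,
)
from polytarget.genome import GeneModel

from conftest import make_pair


def gene(gene_id="g1", chrom="c1", start=10_000, end=13_000, strand="+",
         with_features=True):
    kw = {}
    if with_features:
        if strand == "+":
            kw = dict(
                exons=((start, start + 1000), (start + 2000, end)),
                utr5=((start, start + 200),),
                utr3=((end - 200, end),),
            )
        else:
            kw = dict(
                exons=((start, start + 1000), (start + 2000, end)),
                utr5=((end - 200, end),),
                utr3=((start, start + 200),),
            )
    return GeneModel(gene_id, chrom, start, end, strand, **kw)


def oracle_category(summit, genes):
    """Independent per-gene window scan with explicit if-chains."""
    cands = []
    for g in genes:
        d = summit - g.start if g.strand == "+" else (g.end - 1) - summit
        if g.start <= summit < g.end:
            if any(a <= summit < b for a, b in g.utr5):
                cat = "five_prime_utr"
            elif any(a <= summit < b for a, b in g.utr3):
                cat = "three_prime_utr"
            elif any(a <= summit < b for a, b in g.exons):
                cat = "exon"
            else:
                cat = "intron"
        elif -1000 <= d <= -1:
            cat = "promoter_0_1kb"
        elif -2000 <= d <= -1001:
            cat = "promoter_1_2kb"
        elif -3000 <= d <= -2001:
            cat = "promoter_2_3kb"
        else:
            past = summit - (g.end - 1) if g.strand == "+" else g.start - summit
            if 1 <= past <= 3000:
                cat = "downstream_0_3kb"
            else:
                continue
        cands.append((CATEGORIES.index(cat), abs(d), g.gene_id, cat))
    if not cands:
        return "distal_intergenic", None
    cands.sort()
    return cands[0][3], cands[0][2]


class TestClassifyFeature:
    def test_summit_upstream_of_plus_tss_is_proximal_promoter(self):
        g = gene(start=10_000, strand="+")
        a = classify_feature(9_500, [g])
        assert a.category == "promoter_0_1kb"
        assert a.gene_id == "g1" and a.signed_tss_distance == -500

    def test_exonic_summit_without_promoter_context(self):
        g = gene(start=10_000, end=13_000, strand="+")
        a = classify_feature(10_500, [g])  # in exon 1, past the 5' UTR
        assert a.category == "exon"

    def test_utr_outranks_exon(self):
        g = gene(start=10_000, strand="+")
        assert classify_feature(10_100, [g]).category == "five_prime_utr"
        assert classify_feature(12_900, [g]).category == "three_prime_utr"

    def test_intronic_summit(self):
        g = gene(start=10_000, strand="+")
        assert classify_feature(11_500, [g]).category == "intron"

    def test_no_gene_in_range_is_distal(self):
        g = gene(start=10_000)
        a = classify_feature(50_000, [g])
        assert a.category == "distal_intergenic" and a.gene_id is None

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_random_peaks(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(30):
            start = int(rng.integers(0, 95_000))
            genes.append(
                gene(f"g{i:02d}", "c1", start, start + int(rng.integers(500, 4000)),
                     str(rng.choice(["+", "-"])))
            )
        for _ in range(200):
            summit = int(rng.integers(0, 100_000))
            got = classify_feature(summit, genes)
            cat, gid = oracle_category(summit, genes)
            assert got.category == cat
            if cat != "distal_intergenic":
                assert got.gene_id == gid

    def test_categories_partition_peak_set(self, small_genome, small_chip, small_cfg):
        r1, r2, _ = small_chip
        pairs = pt.overlap_replicates(pt.filter_peaks(r1), pt.filter_peaks(r2))
        assignments = classify_features(pairs, small_genome.genes)
        assert len(assignments) == len(pairs)
        assert sum(feature_distribution(assignments).values()) == len(pairs)


class TestTssProfile:
    def test_summits_at_tss_fill_central_bin(self):
        genes = [gene("g1", start=10_000, strand="+")]
        pairs = [make_pair(chrom="c1", s1=10_000, s2=10_000) for _ in range(5)]
        prof = tss_profile(pairs, genes)
        central = int(np.flatnonzero(prof.bin_edges == 0)[0])
        assert prof.counts[central] == 5 and prof.total_in_window == 5

    def test_no_gene_within_window(self):
        genes = [gene("g1", start=100_000, end=103_000)]
        pairs = [make_pair(chrom="c1", s1=5_000, s2=5_000)]
        prof = tss_profile(pairs, genes)
        assert prof.total_in_window == 0

    def test_gaussian_summits_mode_near_zero(self):
        rng = np.random.default_rng(8)
        genes = [gene(f"g{i}", start=20_000 * (i + 1),
                      end=20_000 * (i + 1) + 3000, strand="+")
                 for i in range(10)]
        pairs = []
        for _ in range(1000):
            g = genes[int(rng.integers(0, 10))]
            s = int(g.tss + rng.normal(0, 300))
            pairs.append(make_pair(chrom="c1", s1=s, s2=s))
        prof = tss_profile(pairs, genes, half_window=3000, bin_size=50)
        mode_bin = int(np.argmax(prof.counts))
        central = int(np.flatnonzero(prof.bin_edges == 0)[0])
        assert abs(mode_bin - central) <= 1

    def test_bin_size_must_divide_window(self):
        with pytest.raises(Exception, match="divide|positive"):
            tss_profile([], [], half_window=3000, bin_size=70)


def oracle_targets(pairs, genes, up=2000, down=100):
    out = {}
    for g in genes:
        for rp in pairs:
            if rp.chrom != g.chrom:
                continue
            d = rp.summit - g.tss if g.strand == "+" else g.tss - rp.summit
            if -up <= d <= down:
                out.setdefault(g.gene_id, set()).add(rp.name)
    return {k: sorted(v) for k, v in out.items()}


class TestAssignTargetGenes:
    def test_summit_within_upstream_window_assigned(self):
        g = gene("g1", start=10_000, strand="+")
        (pair,) = [make_pair(chrom="c1", s1=8_500, s2=8_500)]  # 1.5 kb upstream
        assert "g1" in assign_target_genes([pair], [g])

    def test_summit_past_downstream_edge_not_assigned(self):
        g = gene("g1", start=10_000, strand="+")
        pair = make_pair(chrom="c1", s1=10_150, s2=10_150)  # 150 bp downstream
        assert assign_target_genes([pair], [g]) == {}

    def test_empty_peaks_empty_mapping(self, small_genome):
        assert assign_target_genes([], small_genome.genes) == {}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_containment_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(100):
            start = int(rng.integers(3_000, 190_000))
            genes.append(GeneModel(f"g{i:03d}", "c1", start, start + 2000,
                                   str(rng.choice(["+", "-"]))))
        pairs = []
        for j in range(300):
            s = int(rng.integers(1_000, 195_000))
            pairs.append(make_pair(chrom="c1", s1=s, s2=s, name1=f"a{j}", name2=f"b{j}"))
        got = {
            k: sorted(rp.name for rp in v)
            for k, v in assign_target_genes(pairs, genes).items()
        }
        assert got == oracle_targets(pairs, genes)

    def test_shrinking_window_never_adds_targets(self, small_genome, small_chip):
        r1, r2, _ = small_chip
        pairs = pt.overlap_replicates(pt.filter_peaks(r1), pt.filter_peaks(r2))
        wide = set(assign_target_genes(pairs, small_genome.genes, up=2000, down=100))
        for up, down in [(1500, 100), (2000, 0), (1000, 50), (500, 0)]:
            narrow = set(
                assign_target_genes(pairs, small_genome.genes, up=up, down=down)
            )
            assert narrow <= wide

    def test_divergent_promoters_share_a_peak(self):
        # two TSSs facing away, 1 kb apart: one peak in between serves both
        g_plus = GeneModel("gp", "c1", 11_000, 13_000, "+")
        g_minus = GeneModel("gm", "c1", 8_000, 10_000, "-")
        pair = make_pair(chrom="c1", s1=10_500, s2=10_500)
        out = assign_target_genes([pair], [g_plus, g_minus])
        assert set(out) == {"gp", "gm"}
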