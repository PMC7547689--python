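from collections import Counter

import numpy as np
import pytest

from leafnet import synthetic as syn
from leafnet.peaks import fraction_in_open_chromatin, merge_peak_summits
from leafnet.types import GenomicInterval


class TestGenerateGenome:
    def test_gc_within_binomial_bound(self, small_genome):
        total = sum(len(s) for s in small_genome.sequences.values())
        gc = sum(s.count("G") + s.count("C")
                 for s in small_genome.sequences.values()) / total
        assert 0.48 <= gc <= 0.52

    def test_seeded_determinism(self):
        a = syn.generate_genome(n_chroms=1, chrom_length=100_000, n_genes=10, seed=7)
        b = syn.generate_genome(n_chroms=1, chrom_length=100_000, n_genes=10, seed=7)
        assert a.sequences == b.sequences
        assert a.genes == b.genes
        assert a.open_chromatin == b.open_chromatin

    def test_gene_count_and_strands(self, small_genome):
        assert len(small_genome.genes) == 200
        strands = {g.strand for g in small_genome.genes}
        assert strands == {"+", "-"}

    def test_genes_do_not_overlap(self, small_genome):
        by_chrom = {}
        for g in small_genome.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_invalid_gc_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_genome(gc=1.5)

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_genome(n_chroms=1, chrom_length=100_000, n_genes=50)


class TestPlantLandscape:
    def test_motifs_distinct_and_planted(self, small_genome, small_truth):
        canon = {syn.canonical_kmer(m) for m in small_truth.tf_motifs.values()}
        assert len(canon) == len(small_truth.tf_motifs)
        for tf, gene in small_truth.true_edges:
            promoter = small_truth.gene_promoters[gene]
            seq = small_genome.fetch(promoter)
            motif = small_truth.tf_motifs[tf]
            assert motif in seq or syn.reverse_complement(motif) in seq

    def test_indegree_tail_refit(self):
        genome = syn.generate_genome(n_chroms=2, chrom_length=2_000_000,
                                     n_genes=400, seed=3, promoter_size=1000)
        truth = syn.plant_regulatory_landscape(
            genome, n_tfs=100, degree_exponent=2.5, seed=3
        )
        degrees = Counter(g for _, g in truth.true_edges)
        from leafnet.topology import fit_power_law

        fit = fit_power_law(list(degrees.values()), n_bootstrap=0, seed=0)
        assert 2.0 <= fit.alpha <= 3.0

    def test_module_bias(self, small_truth):
        intra = sum(
            small_truth.module_assignment[tf] == small_truth.module_assignment[g]
            for tf, g in small_truth.true_edges
        )
        assert intra / len(small_truth.true_edges) > 0.8

    def test_motif_exhaustion_error(self, small_genome):
        with pytest.raises(ValueError):
            syn.plant_regulatory_landscape(small_genome, n_tfs=4**7)

    def test_degree_exponent_validation(self, small_genome):
        with pytest.raises(ValueError):
            syn.plant_regulatory_landscape(small_genome, degree_exponent=0.9)


class TestGeneratePeaks:
    def test_open_fraction_recovered(self, small_genome, small_truth, small_peaks):
        fractions = [
            fraction_in_open_chromatin(ps, small_genome.open_chromatin)
            for ps in small_peaks.values()
            if len(ps)
        ]
        assert abs(np.mean(fractions) - 0.74) <= 0.05

    def test_zero_jitter_summit_in_motif(self, small_genome, small_truth):
        peaks = syn.generate_peaks(
            small_genome, small_truth, summit_jitter=0, seed=2,
            plant_cobinding=False, decoy_ratio=0.0, open_fraction=1.0,
        )
        for tf, ps in peaks.items():
            motif = small_truth.tf_motifs[tf]
            for p in ps:
                window = small_genome.sequences[p.chrom][p.summit - 6 : p.summit + 7]
                assert motif in window or syn.reverse_complement(motif) in window

    def test_seeded_determinism(self, small_genome, small_truth):
        a = syn.generate_peaks(small_genome, small_truth, seed=5)
        b = syn.generate_peaks(small_genome, small_truth, seed=5)
        for tf in a:
            assert [(p.chrom, p.summit, p.signal) for p in a[tf]] == [
                (p.chrom, p.summit, p.signal) for p in b[tf]
            ]

    def test_unreachable_open_fraction_error(self, small_genome, small_truth):
        with pytest.raises(ValueError):
            syn.generate_peaks(
                small_genome, small_truth, open_fraction=0.1, decoy_ratio=0.5,
            )


class TestGenerateVariants:
    def test_null_planting_flat(self, small_genome):
        loci = [GenomicInterval("chr1", 100_000 * i, 100_000 * i + 400)
                for i in range(1, 9)]
        var = syn.generate_variants(
            small_genome, loci, base_rate=0.01,
            summit_depletion=1.0, hit_fold=1.0, seed=4,
        )
        # rate recovered and hits at base probability everywhere
        total_bp = sum(len(s) for s in small_genome.sequences.values())
        assert abs(len(var) / total_bp - 0.01) < 0.001
        hits = sum(1 for _, _, h in var.records if h)
        assert abs(hits / len(var) - 0.1) < 0.01

    def test_summit_depletion_halves_center(self, small_genome):
        summits = [("chr1", 50_000 * i) for i in range(2, 19)]
        loci = []
        var = syn.generate_variants(
            small_genome, loci, base_rate=0.02, summit_depletion=0.5,
            seed=4, summits=summits,
        )
        near = far = 0
        for chrom, pos, _ in var.records:
            if chrom != "chr1":
                continue
            d = min(abs(pos - s) for _, s in summits)
            if d <= 100:
                near += 1
            elif 300 <= d <= 3000:
                far += 1
        ratio = (near / (len(summits) * 201)) / (far / (len(summits) * 5402))
        assert abs(ratio - 0.5) < 0.12

    def test_hit_fold_recovered(self, small_genome):
        loci = [GenomicInterval("chr1", 10_000 * i, 10_000 * i + 2000)
                for i in range(1, 50)]
        var = syn.generate_variants(
            small_genome, loci, base_rate=0.02, hit_fold=2.0, seed=9,
        )
        in_hits = in_tot = out_hits = out_tot = 0
        for chrom, pos, h in var.records:
            inside = chrom == "chr1" and any(
                iv.start <= pos < iv.end for iv in loci
            )
            if inside:
                in_tot += 1
                in_hits += bool(h)
            else:
                out_tot += 1
                out_hits += bool(h)
        fold = (in_hits / in_tot) / (out_hits / out_tot)
        assert abs(fold - 2.0) < 0.25

    def test_parameter_validation(self, small_genome):
        with pytest.raises(ValueError):
            syn.generate_variants(small_genome, [], base_rate=0.5)
        with pytest.raises(ValueError):
            syn.generate_variants(small_genome, [], summit_depletion=0.0)


class TestDinucleotideShuffle:
    def test_composition_preserved(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        shuffled = syn.dinucleotide_shuffle(seq, rng)
        assert Counter(zip(seq[:-1], seq[1:])) == Counter(
            zip(shuffled[:-1], shuffled[1:])
        )
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_actually_shuffles(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        assert syn.dinucleotide_shuffle(seq, rng) != seq


class TestSecondSpecies:
    def test_rate_one_identical(self, small_genome, small_truth):
        sp2, synteny = syn.generate_second_species(
            small_genome, small_truth, conservation_rate=1.0, seed=6
        )
        assert sp2.sequences == small_genome.sequences
        assert len(synteny.pairs) == len(small_genome.genes)

    def test_rate_zero_destroys_motifs(self, small_genome, small_truth):
        sp2, _ = syn.generate_second_species(
            small_genome, small_truth, conservation_rate=0.0, seed=6
        )
        surviving = 0
        for tf, gene in small_truth.true_edges:
            promoter = small_truth.gene_promoters[gene]
            seq = sp2.fetch(promoter)
            motif = small_truth.tf_motifs[tf]
            if motif in seq or syn.reverse_complement(motif) in seq:
                surviving += 1
        assert surviving / len(small_truth.true_edges) < 0.1

    def test_rate_half_binomial_bounds(self, small_genome, small_truth):
        flags = syn.edge_conservation_flags(small_truth, 0.5, seed=6)
        n = len(flags)
        conserved = sum(flags.values())
        sd = (n * 0.25) ** 0.5
        assert abs(conserved - n / 2) <= 2.5 * sd

    def test_synteny_one_to_one(self, small_genome, small_truth):
        _, synteny = syn.generate_second_species(
            small_genome, small_truth, conservation_rate=0.5, seed=6
        )
        sources = [a for a, _ in synteny.pairs]
        assert len(set(sources)) == len(sources)


class TestMotifDataset:
    def test_labels_balanced(self):
        seqs, labels, sites = syn.synthesize_motif_dataset("GATCGTA", n_pos=50)
        assert (labels == 1).sum() == (labels == 0).sum() == 50

    def test_planted_sites_contain_motif(self):
        seqs, labels, sites = syn.synthesize_motif_dataset(
            "GATCGTA", n_pos=30, plant_rate=1.0, n_sites=2, seed=1
        )
        for seq, site_list in zip(seqs[:30], sites[:30]):
            assert len(site_list) == 2
            for s in site_list:
                assert seq[s : s + 7] == "GATCGTA"

    def test_negatives_have_no_sites(self):
        _, labels, sites = syn.synthesize_motif_dataset("GATCGTA", n_pos=20, seed=2)
        for lbl, s in zip(labels, sites):
            if lbl == 0:
                assert s == []


class TestColocMatrixSynthesis:
    def test_planted_group_all_or_none(self):
        partners = [f"T{i}" for i in range(10)]
        M = syn.synthesize_coloc_matrix(partners, partners[:4], n_rows=200, seed=0)
        cols = [M.partners.index(p) for p in partners[:4]]
        present = M.matrix[:, cols] > 0
        assert np.all(present.all(axis=1) | (~present).any(axis=1))
        row_on = present.all(axis=1)
        assert np.all(present.sum(axis=1)[~row_on] == 0)

    def test_unknown_partner_error(self):
        with pytest.raises(ValueError):
            syn.synthesize_coloc_matrix(["A", "B"], ["C"])
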