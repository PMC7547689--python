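"""End-to-end benchmarks on synthetic data with planted ground truth.

Each function generates its inputs from a seed, runs the relevant analysis
stage, and measures recovery of the planted structure. The acceptance test
suite asserts on these numbers; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np

from . import coloc, conservation as cons, enrich, seqmodel as sm, synthetic as syn
from . import tip, topology as topo
from .peaks import merge_peak_summits

DESK_SCALE = dict(n_chroms=2, chrom_length=1_000_000, gc=0.5, n_genes=200)


def tip_benchmark(seed: int = 0) -> dict:
    """Precision/recall of planted-edge recovery at FDR 5% (20 TFs, 200 genes)."""
    genome = syn.generate_genome(seed=seed, **DESK_SCALE)
    truth = syn.plant_regulatory_landscape(
        genome, n_tfs=20, seed=seed, target_fraction=0.5
    )
    peaksets = syn.generate_peaks(genome, truth, seed=seed, plant_cobinding=False)
    edge_lists = {}
    for tf, ps in peaksets.items():
        if not len(ps):
            continue
        _, edges = tip.infer_targets(ps, genome.genes, fdr=0.05)
        edge_lists[tf] = edges
    network = tip.assemble_network(edge_lists)
    called = {(t, g) for t, g, _ in network.edges}
    tp = len(called & truth.true_edges)
    return {
        "precision": tp / len(called) if called else 0.0,
        "recall": tp / len(truth.true_edges),
        "n_called": len(called),
        "n_true": len(truth.true_edges),
    }


def seqmodel_benchmark(
    seed: int = 0,
    n_tfs: int = 20,
    n_pos: int = 200,
    n_occlusion_seqs: int = 3,
) -> dict:
    """Planted 7-mer recovery: CV accuracy, top-1% rank, occlusion localization."""
    rng = np.random.default_rng(seed)
    accuracies, in_top1, occl_fracs = [], [], []
    exact_occlusion = True
    for t in range(n_tfs):
        motif = "".join(rng.choice(syn.BASES, size=7))
        seqs, labels, _ = syn.synthesize_motif_dataset(
            motif, n_pos=n_pos, n_sites=3, plant_rate=0.9, seed=seed + 1000 + t
        )
        model = sm.train_kmer_model(seqs, labels, tf=f"tf{t}", seed=seed)
        accuracies.append(model.cv_accuracy)
        in_top1.append(sm.canonical_kmer(motif) in model.top_kmers(1.0))

        eval_seqs, _, eval_sites = syn.synthesize_motif_dataset(
            motif, n_pos=n_occlusion_seqs, n_sites=3, plant_rate=1.0,
            seed=seed + 2000 + t,
        )
        for seq, sites in zip(eval_seqs[:n_occlusion_seqs],
                              eval_sites[:n_occlusion_seqs]):
            track = sm.occlusion_map(model, seq)
            n_top = len(seq) // 10
            top_positions = np.argsort(track.occlusion)[::-1][:n_top]
            motif_positions = {p for s in sites for p in range(s, s + 7)}
            occl_fracs.append(
                float(np.mean([p in motif_positions for p in top_positions]))
            )
        # spot-check exact agreement with brute-force recomputation
        check_seq = eval_seqs[0][:60]
        base = sm.score_sequence(model, check_seq)
        track = sm.occlusion_map(model, check_seq)
        for i in range(len(check_seq)):
            masked = check_seq[:i] + "N" + check_seq[i + 1 :]
            if track.occlusion[i] != base - sm.score_sequence(model, masked):
                exact_occlusion = False
    return {
        "mean_cv_accuracy": float(np.mean(accuracies)),
        "fraction_tfs_planted_kmer_top1pct": float(np.mean(in_top1)),
        "occlusion_top_decile_in_motif": float(np.mean(occl_fracs)),
        "occlusion_exact_match": exact_occlusion,
        "n_tfs": n_tfs,
    }


def coloc_benchmark(
    seed: int = 0,
    n_contexts: int = 10,
    n_partners: int = 19,
    n_planted: int = 5,
    n_rows: int = 600,
) -> dict:
    """Planted partner-dependency detection: AUROC, RI top rank, DI sign."""
    partners = [f"P{i:02d}" for i in range(n_partners)]
    planted = partners[:n_planted]
    aurocs, top_is_planted = [], []
    for c in range(n_contexts):
        matrix = syn.synthesize_coloc_matrix(
            partners, planted, n_rows=n_rows, seed=seed + c
        )
        ensemble, ri = coloc.context_importance(matrix, seed=seed + c)
        aurocs.append(ensemble.auroc)
        top_partner = max(ri, key=lambda p: ri[p])
        top_is_planted.append(ri[top_partner] == 100.0 and top_partner in planted)
    di_matrix = syn.synthesize_coloc_matrix(
        partners, planted, n_rows=600, proximal_only=partners[n_planted],
        seed=seed + 500,
    )
    di = coloc.differential_importance(di_matrix, seed=seed + 501)
    return {
        "mean_auroc": float(np.mean(aurocs)),
        "contexts_with_planted_ri_100": int(np.sum(top_is_planted)),
        "n_contexts": n_contexts,
        "di_proximal_partner": float(di[partners[n_planted]]) if di else float("nan"),
    }


def topology_benchmark(
    seed: int = 0,
    n_runs: int = 10,
    n: int = 10_000,
    alpha: float = 2.5,
    xmin: int = 5,
    n_bootstrap: int = 200,
    n_null_graphs: int = 1000,
) -> dict:
    """Power-law recovery across seeded runs plus modularity vs rewired null."""
    alpha_ok = null_retained = 0
    alphas = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        sample = topo.sample_discrete_powerlaw(rng, alpha, xmin, n)
        fit = topo.fit_power_law(sample, n_bootstrap=n_bootstrap, seed=seed + r)
        alphas.append(fit.alpha)
        alpha_ok += abs(fit.alpha - alpha) <= 0.1
        null_retained += fit.ks_p > 0.05

    rng = np.random.default_rng(seed)
    import networkx as nx

    n_nodes = 60
    G = nx.DiGraph()
    G.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            p = 0.3 if (i < n_nodes // 2) == (j < n_nodes // 2) else 0.01
            if rng.random() < p:
                G.add_edge(i, j)
    result = topo.modularity_significance(G, n_graphs=n_null_graphs, seed=seed)
    degrees_preserved = True
    H = G.copy()
    nx.directed_edge_swap(H, nswap=10 * H.number_of_edges(),
                          max_tries=1000 * H.number_of_edges(), seed=seed)
    if sorted(d for _, d in H.in_degree()) != sorted(d for _, d in G.in_degree()):
        degrees_preserved = False
    if sorted(d for _, d in H.out_degree()) != sorted(d for _, d in G.out_degree()):
        degrees_preserved = False
    return {
        "mean_alpha": float(np.mean(alphas)),
        "alpha_within_tolerance_runs": int(alpha_ok),
        "null_retained_runs": int(null_retained),
        "n_runs": n_runs,
        "observed_Q": result.Q,
        "max_null_Q": float(result.null_Q.max()),
        "modularity_p": float(result.p),
        "degree_sequences_preserved": degrees_preserved,
    }


def enrichment_benchmark(
    seed: int = 0,
    n_coverage_sims: int = 100,
    n_trials: int = 5000,
    planted_fold: float = 2.0,
) -> dict:
    """Conjugacy, credible-interval coverage, and summit-depletion recovery."""
    rng = np.random.default_rng(seed)
    conjugacy_exact = True
    for _ in range(50):
        n1 = int(rng.integers(1, 1000))
        k1 = int(rng.integers(0, n1 + 1))
        r = enrich.betabinom_enrichment(k1, n1, 1, 10, n_draws=1000, seed=0)
        if r.posterior_region != (1 + k1, 1 + n1 - k1):
            conjugacy_exact = False

    p_ctrl = 0.05
    covered = 0
    for s in range(n_coverage_sims):
        local = np.random.default_rng(seed + s)
        k1 = int(local.binomial(n_trials, p_ctrl * planted_fold))
        k2 = int(local.binomial(n_trials, p_ctrl))
        r = enrich.betabinom_enrichment(
            k1, n_trials, k2, n_trials, n_draws=20_000, seed=seed + s
        )
        covered += r.ci_low <= planted_fold <= r.ci_high

    genome = syn.generate_genome(seed=seed, **DESK_SCALE)
    truth = syn.plant_regulatory_landscape(
        genome, n_tfs=20, seed=seed, target_fraction=0.5
    )
    peaksets = syn.generate_peaks(genome, truth, seed=seed)
    loci = [l.interval for l in merge_peak_summits(list(peaksets.values()))]
    summits = [(iv.chrom, iv.midpoint) for iv in loci]
    variants = syn.generate_variants(
        genome, loci, base_rate=0.05, summit_depletion=0.5, seed=seed,
        summits=summits,
    )
    d, m = enrich.snp_density_profile(
        variants, summits, genome.chrom_sizes, smooth=1
    )
    central = float(m[np.abs(d) <= 50].mean())
    flank = float(m[np.abs(d) >= 500].mean())
    return {
        "conjugacy_exact": conjugacy_exact,
        "ci_coverage_count": int(covered),
        "n_coverage_sims": n_coverage_sims,
        "depletion_ratio": central / flank,
    }


def conservation_benchmark(
    seed: int = 0,
    threshold: float = 0.5,
    scan_window: int = 200,
    scan_stride: int = 100,
    assign_window: int = 1500,
    n_fpr_replicates: int = 3,
    model_C: float = 50.0,
    model_n_pos: int = 250,
) -> dict:
    """Edge conservation at rates 1 and 0, measured FPR, threshold monotonicity."""
    genome = syn.generate_genome(seed=seed, **DESK_SCALE)
    truth = syn.plant_regulatory_landscape(
        genome, n_tfs=20, seed=seed, target_fraction=0.5
    )
    models = {}
    for i, (tf, motif) in enumerate(sorted(truth.tf_motifs.items())):
        seqs, labels, _ = syn.synthesize_motif_dataset(
            motif, n_pos=model_n_pos, n_sites=3, seed=seed + 3000 + i
        )
        models[tf] = sm.train_kmer_model(seqs, labels, tf=tf, seed=seed, C=model_C)
    network = tip.RegulatoryNetwork(
        tf_ids=set(truth.tf_motifs),
        edges=[(tf, g, 1.0) for tf, g in sorted(truth.true_edges)],
    )

    def assess(rate: float, species_seed: int):
        sp2, synteny = syn.generate_second_species(
            genome, truth, conservation_rate=rate, seed=species_seed
        )
        assigned = cons.assign_open_chromatin_to_genes(
            sp2.open_chromatin, sp2.genes, window=assign_window
        )
        regions = {g: [sp2.fetch(iv) for iv in ivs] for g, ivs in assigned.items()}
        calls = cons.predict_edge_conservation(
            network, models, synteny, regions, threshold=threshold,
            scan_window=scan_window, scan_stride=scan_stride,
        )
        summary = cons.conservation_summary(network, calls)
        return summary, synteny, regions

    summary1, synteny1, regions1 = assess(1.0, seed)
    summary0, _, _ = assess(0.0, seed)
    fractions = {1.0: summary1.fraction_conserved, 0.0: summary0.fraction_conserved}

    # measured model FPR: conserved fraction on independent replicates of the
    # fully shuffled (rate-0) species - the same assessment protocol applied
    # to sequence with no planted signal
    fpr_hits = fpr_total = 0
    for r in range(n_fpr_replicates):
        s, _, _ = assess(0.0, seed + 101 + r)
        fpr_hits += s.n_conserved
        fpr_total += s.n_assessable

    # monotonicity across thresholds at rate 1
    monotone = True
    prev = 1.1
    for thr in (0.3, 0.5, 0.7, 0.9):
        calls = cons.predict_edge_conservation(
            network, models, synteny1, regions1, threshold=thr,
            scan_window=scan_window, scan_stride=scan_stride,
        )
        frac = cons.conservation_summary(network, calls).fraction_conserved
        if frac > prev + 1e-12:
            monotone = False
        prev = frac

    return {
        "fraction_conserved_rate1": fractions[1.0],
        "fraction_conserved_rate0": fractions[0.0],
        "measured_fpr": fpr_hits / fpr_total if fpr_total else float("nan"),
        "n_fpr_assessments": fpr_total,
        "threshold_monotone": monotone,
    }
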