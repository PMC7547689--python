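"""Synthetic genomes, peak sets, variants and a second species with planted
ground truth.

The generators produce data with the statistical structure the downstream
analyses assume: per-TF peaks concentrated in open chromatin, planted 7-mer
sequence preferences, heavy-tailed in-degree target structure with modules,
partner-TF co-binding dependencies, SNP depletion at summits with planted
hit enrichment, and a second species with a tunable conserved fraction of
regulatory sequence.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .types import (
    GeneModel,
    GenomeBundle,
    GenomicInterval,
    Peak,
    PeakSet,
    SyntenyMap,
    TruthSet,
    VariantSet,
)

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_GENE_LENGTH = 2000
DEFAULT_PROMOTER = 500
MOTIF_K = 7


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def generate_genome(
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    gc: float = 0.5,
    n_genes: int = 200,
    seed: int = 0,
    gene_length: int = DEFAULT_GENE_LENGTH,
    promoter_size: int = DEFAULT_PROMOTER,
    distal_fraction: float = 0.2,
) -> GenomeBundle:
    """Random genome with non-overlapping genes and open-chromatin windows.

    Bases are i.i.d. at the requested GC. Genes are placed on a regular grid
    of slots, alternating strand; each TSS gets one upstream open-chromatin
    window of ``promoter_size`` bp, plus ``distal_fraction`` (per gene) of
    distal windows far from genes.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T

    sequences = {
        f"chr{i + 1}": "".join(
            rng.choice(BASES, size=chrom_length, p=probs)
        )
        for i in range(n_chroms)
    }

    footprint = gene_length + 2 * promoter_size
    genes_per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        genes_per_chrom[i] += 1
    genes: list[GeneModel] = []
    open_chromatin: list[GenomicInterval] = []
    gene_idx = 0
    for ci, chrom in enumerate(sorted(sequences)):
        count = genes_per_chrom[ci]
        if count == 0:
            continue
        slot = chrom_length // count
        if slot < 2 * footprint:
            raise ValueError(
                f"cannot place {count} genes of footprint {footprint} bp "
                f"on a {chrom_length} bp chromosome"
            )
        for k in range(count):
            slot_start = k * slot
            # random offset within the slot so inter-TSS spacing varies;
            # a regular grid would alias neighbours into one profile bin
            lo = promoter_size
            hi = slot - gene_length - promoter_size
            g0 = slot_start + int(rng.integers(lo, hi))
            strand = "+" if gene_idx % 2 == 0 else "-"
            gene = GeneModel(
                gene_id=f"g{gene_idx:04d}",
                chrom=chrom,
                start=g0,
                end=g0 + gene_length,
                strand=strand,
            )
            genes.append(gene)
            if strand == "+":
                promoter = GenomicInterval(chrom, g0 - promoter_size, g0)
            else:
                promoter = GenomicInterval(
                    chrom, g0 + gene_length, g0 + gene_length + promoter_size
                )
            open_chromatin.append(promoter)
            if rng.random() < distal_fraction:
                # distal window wherever the slot has clearance from the gene
                region_lo = g0 - promoter_size
                region_hi = g0 + gene_length + promoter_size
                if region_lo - slot_start >= promoter_size + 100:
                    d0 = slot_start + 50
                elif slot_start + slot - region_hi >= promoter_size + 100:
                    d0 = region_hi + 50
                else:
                    d0 = None
                if d0 is not None:
                    open_chromatin.append(
                        GenomicInterval(chrom, d0, d0 + promoter_size)
                    )
            gene_idx += 1

    open_chromatin.sort(key=lambda iv: (iv.chrom, iv.start))
    return GenomeBundle(
        sequences=sequences, genes=genes, open_chromatin=open_chromatin
    )


def promoter_of(genome: GenomeBundle, gene: GeneModel,
                max_dist: int = 1000) -> GenomicInterval | None:
    """Open-chromatin window nearest the gene's TSS (within ``max_dist``)."""
    best, best_d = None, max_dist + 1
    for iv in genome.open_chromatin:
        if iv.chrom != gene.chrom:
            continue
        if iv.start <= gene.tss < iv.end:
            d = 0
        else:
            d = min(abs(iv.start - gene.tss), abs(iv.end - 1 - gene.tss))
        if d < best_d:
            best, best_d = iv, d
    return best


def sample_discrete_powerlaw(
    rng: np.random.Generator, alpha: float, xmin: int, size: int
) -> np.ndarray:
    """Discrete power-law deviates by the rounding approximation.

    x = floor((xmin - 1/2) (1 - u)^(-1/(alpha-1)) + 1/2).
    """
    u = rng.random(size)
    return np.floor((xmin - 0.5) * (1 - u) ** (-1.0 / (alpha - 1.0)) + 0.5).astype(
        np.int64
    )


def plant_regulatory_landscape(
    genome: GenomeBundle,
    n_tfs: int = 20,
    degree_exponent: float = 2.5,
    n_modules: int = 2,
    within_module_bias: float = 0.9,
    seed: int = 0,
    cobind_partners_per_tf: int = 2,
    cobind_probability: float = 0.85,
    target_fraction: float = 1.0,
) -> TruthSet:
    """Plant TFs, motifs, a heavy-tailed edge structure, and co-binding.

    The first ``n_tfs`` genes become TF-coding genes (their ids double as TF
    ids). Gene in-degrees follow a discrete power law; regulators are drawn
    preferentially from the gene's own module. Each TF's distinct 7-mer is
    written into the promoter open chromatin of all its true targets.
    """
    if n_tfs < 2:
        raise ValueError("need at least 2 TFs")
    if degree_exponent <= 1:
        raise ValueError("degree_exponent must exceed 1")
    if n_tfs > 4 ** MOTIF_K // 2:
        raise ValueError("motif alphabet exhausted: too many TFs for 7-mers")
    if n_tfs > len(genome.genes):
        raise ValueError("more TFs than genes")
    rng = np.random.default_rng(seed)

    tf_ids = [g.gene_id for g in genome.genes[:n_tfs]]
    gene_by_id = {g.gene_id: g for g in genome.genes}

    # distinct canonical 7-mers, also pairwise distinct from reverse complements
    motifs: dict[str, str] = {}
    used: set[str] = set()
    for tf in tf_ids:
        while True:
            kmer = "".join(rng.choice(BASES, size=MOTIF_K))
            if canonical_kmer(kmer) not in used:
                used.add(canonical_kmer(kmer))
                motifs[tf] = kmer
                break

    module_assignment = {
        g.gene_id: i % n_modules for i, g in enumerate(genome.genes)
    }

    tf_modules: dict[int, list[str]] = defaultdict(list)
    for tf in tf_ids:
        tf_modules[module_assignment[tf]].append(tf)

    in_degrees = np.minimum(
        sample_discrete_powerlaw(rng, degree_exponent, 1, len(genome.genes)), n_tfs
    )
    # thinning targets keeps each TF's regulon a small fraction of genes,
    # which the TIP z-score needs to separate signal from background
    if target_fraction < 1.0:
        in_degrees[rng.random(len(genome.genes)) >= target_fraction] = 0
    true_edges: set[tuple[str, str]] = set()
    for gene, d in zip(genome.genes, in_degrees):
        own = module_assignment[gene.gene_id]
        chosen: set[str] = set()
        while len(chosen) < d:
            if rng.random() < within_module_bias and tf_modules[own]:
                pool = tf_modules[own]
            else:
                pool = tf_ids
            chosen.add(pool[rng.integers(len(pool))])
        for tf in chosen:
            true_edges.add((tf, gene.gene_id))

    # promoters of every true target, and motif planting: each TF always
    # sits at the same strand-aware distance from the TSS, so its binding
    # profile is sharp and TF motifs never collide within a promoter
    gene_promoters: dict[str, GenomicInterval] = {}
    target_genes = {g for _, g in true_edges}
    mutable = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    for g_id in sorted(target_genes):
        gene = gene_by_id[g_id]
        promoter = promoter_of(genome, gene)
        if promoter is None:
            raise ValueError(f"gene {g_id} has no promoter open chromatin")
        gene_promoters[g_id] = promoter
        for tf in (t for t, g in true_edges if g == g_id):
            chrom, starts = _motif_sites_for(gene, tf_ids, tf, len(promoter))
            for m0 in starts:
                mutable[chrom][m0 : m0 + MOTIF_K] = bytes(motifs[tf], "ascii")
    genome.sequences = {c: bts.decode("ascii") for c, bts in mutable.items()}

    cobind: dict[str, list[tuple[str, float]]] = {}
    for tf in tf_ids:
        own = module_assignment[tf]
        candidates = [t for t in tf_modules[own] if t != tf] or [
            t for t in tf_ids if t != tf
        ]
        k = min(cobind_partners_per_tf, len(candidates))
        picked = list(rng.choice(candidates, size=k, replace=False))
        cobind[tf] = [(p, cobind_probability) for p in picked]

    return TruthSet(
        tf_motifs=motifs,
        true_edges=true_edges,
        module_assignment=module_assignment,
        cobind_partners=cobind,
        planted_enrichment=1.0,
        conservation_rate=1.0,
        gene_promoters=gene_promoters,
    )


def _motif_sites_for(
    gene: GeneModel, tf_ids: list[str], tf: str, promoter_size: int
) -> tuple[str, list[int]]:
    """Starts of ``tf``'s motif copies in ``gene``'s promoter.

    Each TF gets a fixed slot ``10 + spacing * tf_rank`` bp upstream of the
    TSS on the gene's strand, so distinct TFs occupy distinct,
    non-overlapping offsets in every promoter and each TF's binding profile
    is sharp. Slots wide enough hold up to 3 tandem copies (8 bp apart),
    mimicking the multi-occurrence composition of real binding regions.
    """
    spacing = (promoter_size - 20) // max(len(tf_ids), 1)
    if spacing < MOTIF_K:
        raise ValueError("promoter too small for this many TF motif slots")
    n_copies = max(1, min(3, spacing // (MOTIF_K + 1)))
    d = 10 + spacing * sorted(tf_ids).index(tf)
    if gene.strand == "+":
        anchor = gene.tss - d - MOTIF_K // 2
        starts = [anchor - (MOTIF_K + 1) * i for i in range(n_copies)]
    else:
        anchor = gene.tss + d - MOTIF_K // 2
        starts = [anchor + (MOTIF_K + 1) * i for i in range(n_copies)]
    return gene.chrom, sorted(starts)


def _motif_sites(truth: TruthSet, tf: str, gene_id: str,
                 gene_by_id: dict[str, GeneModel]) -> tuple[str, list[int]]:
    """Recover the planted motif locations of an edge from the truth set."""
    tf_ids = sorted(truth.tf_motifs)
    gene = gene_by_id[gene_id]
    promoter = truth.gene_promoters[gene_id]
    return _motif_sites_for(gene, tf_ids, tf, len(promoter))


def generate_peaks(
    genome: GenomeBundle,
    truth: TruthSet,
    open_fraction: float = 0.74,
    summit_jitter: int = 10,
    seed: int = 0,
    peak_width: int = 200,
    decoy_ratio: float = 1.0,
    plant_cobinding: bool = True,
    planted_signal: float = 8.0,
    planted_signal_scale: float = 1.0,
) -> dict[str, PeakSet]:
    """Per-TF peak sets: planted peaks on motif sites plus decoys.

    Planted peaks are centered (within ``summit_jitter``) on the planted
    motif occurrence of each true target and carry shifted-exponential
    signal so they rank high. Decoys are split between open chromatin and
    background so the measured per-TF open-chromatin overlap equals
    ``open_fraction``. With ``plant_cobinding``, partner TFs additionally
    receive peaks co-located with the focus TF's planted peaks.
    """
    if not 0.0 <= open_fraction <= 1.0:
        raise ValueError("open_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sizes = genome.chrom_sizes
    half = peak_width // 2

    open_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in genome.open_chromatin:
        open_by_chrom[iv.chrom].append(iv)

    def clamp(chrom: str, pos: int) -> int:
        return int(min(max(pos, half + 1), sizes[chrom] - half - 2))

    def make_peak(tf: str, chrom: str, summit: int, signal: float) -> Peak:
        summit = clamp(chrom, summit)
        return Peak(
            chrom=chrom,
            start=summit - half,
            end=summit + half,
            summit=summit,
            signal=float(signal),
            tf=tf,
        )

    peaks_by_tf: dict[str, list[Peak]] = {tf: [] for tf in truth.tf_motifs}
    gene_by_id = {g.gene_id: g for g in genome.genes}

    for tf in sorted(truth.tf_motifs):
        targets = sorted(g for t, g in truth.true_edges if t == tf)
        for g_id in targets:
            chrom, starts = _motif_sites(truth, tf, g_id, gene_by_id)
            m0 = starts[len(starts) // 2]  # summit on the middle copy
            center = m0 + MOTIF_K // 2
            jitter = int(rng.integers(-summit_jitter, summit_jitter + 1)) if summit_jitter else 0
            signal = planted_signal + rng.exponential(planted_signal_scale)
            peaks_by_tf[tf].append(make_peak(tf, chrom, center + jitter, signal))

    # decoys tune the per-TF open-chromatin overlap to open_fraction
    all_open = genome.open_chromatin
    open_lookup = {
        c: np.array([(iv.start, iv.end) for iv in ivs], dtype=np.int64)
        for c, ivs in open_by_chrom.items()
    }

    def in_open(chrom: str, pos: int) -> bool:
        arr = open_lookup.get(chrom)
        if arr is None or not arr.size:
            return False
        i = np.searchsorted(arr[:, 0], pos, side="right")
        return bool(i > 0 and np.any(arr[:i, 1] > pos))

    chroms = sorted(sizes)
    for tf in sorted(peaks_by_tf):
        n_planted = len(peaks_by_tf[tf])
        if n_planted == 0:
            continue
        in_open0 = sum(in_open(p.chrom, p.summit) for p in peaks_by_tf[tf])
        n_total = int(round(n_planted * (1.0 + decoy_ratio)))
        n_decoy_open = int(round(open_fraction * n_total)) - in_open0
        n_decoy_out = n_total - n_planted - max(n_decoy_open, 0)
        if n_decoy_open < 0 or n_decoy_out < 0:
            raise ValueError(
                f"open_fraction={open_fraction} unreachable for {tf} at "
                f"decoy_ratio={decoy_ratio}"
            )
        for _ in range(n_decoy_open):
            iv = all_open[rng.integers(len(all_open))]
            summit = int(rng.integers(iv.start, iv.end))
            peaks_by_tf[tf].append(
                make_peak(tf, iv.chrom, summit, rng.exponential(1.0))
            )
        placed = 0
        while placed < n_decoy_out:
            chrom = chroms[rng.integers(len(chroms))]
            summit = int(rng.integers(half + 1, sizes[chrom] - half - 1))
            if in_open(chrom, summit):
                continue
            peaks_by_tf[tf].append(
                make_peak(tf, chrom, summit, rng.exponential(1.0))
            )
            placed += 1

    if plant_cobinding:
        # co-binding is all-or-none per focus peak: one shared deviate
        # switches the whole partner group, giving the bimodal joint pattern
        # that column permutation destroys
        for focus, partners in sorted(truth.cobind_partners.items()):
            for peak in list(peaks_by_tf[focus]):
                u = rng.random()
                for partner, prob in partners:
                    if u < prob:
                        offset = int(rng.integers(-half // 2, half // 2 + 1))
                        signal = 4.0 + rng.exponential(2.0)
                        peaks_by_tf[partner].append(
                            make_peak(partner, peak.chrom, peak.summit + offset, signal)
                        )

    return {tf: PeakSet(tf=tf, peaks=pk) for tf, pk in peaks_by_tf.items()}


def generate_variants(
    genome: GenomeBundle,
    loci: list[GenomicInterval],
    base_rate: float = 0.01,
    summit_depletion: float = 1.0,
    hit_fold: float = 1.0,
    seed: int = 0,
    summits: list[tuple[str, int]] | None = None,
    hit_base_rate: float = 0.1,
    depletion_halfwidth: int = 100,
) -> VariantSet:
    """I.i.d. SNPs with optional summit depletion and planted hit enrichment.

    SNPs land i.i.d. at ``base_rate`` per bp, then are thinned to a fraction
    ``summit_depletion`` within +/- ``depletion_halfwidth`` of each summit.
    Each surviving SNP is labeled a hit with probability ``hit_base_rate``
    outside ``loci`` and ``hit_fold`` times that inside.
    """
    if not base_rate < 0.1:
        raise ValueError("base_rate must be small (< 0.1)")
    if summit_depletion <= 0 or hit_fold <= 0:
        raise ValueError("factors must be positive")
    if hit_fold * hit_base_rate > 1.0:
        raise ValueError("hit_fold * hit_base_rate exceeds 1")
    rng = np.random.default_rng(seed)
    if summits is None:
        summits = [(iv.chrom, iv.midpoint) for iv in loci]
    summits_by_chrom: dict[str, np.ndarray] = {
        c: np.sort(np.array([p for cc, p in summits if cc == c], dtype=np.int64))
        for c in genome.sequences
    }
    loci_by_chrom: dict[str, np.ndarray] = defaultdict(lambda: np.empty((0, 2), np.int64))
    grouped: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in loci:
        grouped[iv.chrom].append((iv.start, iv.end))
    for c, pairs in grouped.items():
        loci_by_chrom[c] = np.array(sorted(pairs), dtype=np.int64)

    records: list[tuple[str, int, bool | None]] = []
    for chrom in sorted(genome.sequences):
        length = len(genome.sequences[chrom])
        pos = np.flatnonzero(rng.random(length) < base_rate)
        s = summits_by_chrom.get(chrom, np.empty(0, np.int64))
        if s.size and summit_depletion < 1.0:
            idx = np.searchsorted(s, pos)
            left = np.abs(pos - s[np.clip(idx - 1, 0, s.size - 1)])
            right = np.abs(s[np.clip(idx, 0, s.size - 1)] - pos)
            near = np.minimum(left, right) <= depletion_halfwidth
            keep = ~near | (rng.random(pos.size) < summit_depletion)
            pos = pos[keep]
        arr = loci_by_chrom[chrom]
        if arr.size:
            i = np.searchsorted(arr[:, 0], pos, side="right")
            inside = np.zeros(pos.size, dtype=bool)
            nz = i > 0
            max_end = np.maximum.accumulate(arr[:, 1])
            inside[nz] = max_end[i[nz] - 1] > pos[nz]
        else:
            inside = np.zeros(pos.size, dtype=bool)
        p_hit = np.where(inside, hit_base_rate * hit_fold, hit_base_rate)
        hits = rng.random(pos.size) < p_hit
        records.extend(
            (chrom, int(p), bool(h)) for p, h in zip(pos, hits)
        )
    return VariantSet(records=records)


def synthesize_motif_dataset(
    motif: str,
    n_pos: int = 200,
    length: int = 200,
    plant_rate: float = 0.9,
    n_sites: int = 1,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[list[str], np.ndarray, list[list[int]]]:
    """Labeled sequences for sequence-model benchmarks.

    Positives are i.i.d. background with ``n_sites`` copies of ``motif``
    planted at random non-overlapping offsets (each positive is planted with
    probability ``plant_rate``); negatives are pure background of the same
    composition. Returns (sequences, labels, per-sequence site starts).
    """
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    k = len(motif)

    def background() -> str:
        return "".join(rng.choice(BASES, size=length, p=probs))

    sequences: list[str] = []
    labels: list[int] = []
    sites: list[list[int]] = []
    for _ in range(n_pos):
        seq = background()
        placed: list[int] = []
        if rng.random() < plant_rate:
            attempts = 0
            while len(placed) < n_sites and attempts < 100:
                attempts += 1
                start = int(rng.integers(0, length - k + 1))
                if any(abs(start - p) < k for p in placed):
                    continue
                seq = seq[:start] + motif + seq[start + k:]
                placed.append(start)
        sequences.append(seq)
        labels.append(1)
        sites.append(sorted(placed))
    for _ in range(n_pos):
        sequences.append(background())
        labels.append(0)
        sites.append([])
    return sequences, np.array(labels), sites


def synthesize_coloc_matrix(
    partners: list[str],
    planted: list[str],
    n_rows: int = 300,
    on_prob: float = 0.5,
    background_prob: float = 0.3,
    proximal_fraction: float = 0.5,
    proximal_only: str | None = None,
    seed: int = 0,
):
    """Focus-context co-localization matrix with a planted partner dependency.

    Each row is 'co-bound' with probability ``on_prob``: all ``planted``
    partners are then present together (normalized ranks in (0.2, 1]),
    otherwise all absent - the all-or-none joint pattern that independent
    column permutation destroys. Remaining partners are present
    independently at ``background_prob``. ``proximal_only`` names a partner
    that joins the dependency group only in proximal rows (for DI checks).

    Returns a :class:`leafnet.coloc.ColocMatrix`.
    """
    from .coloc import ColocMatrix

    rng = np.random.default_rng(seed)
    missing = [p for p in planted if p not in partners]
    if missing or (proximal_only is not None and proximal_only not in partners):
        raise ValueError("planted partners must be listed in partners")
    col = {p: j for j, p in enumerate(partners)}
    X = np.zeros((n_rows, len(partners)))
    row_class = []
    for i in range(n_rows):
        prox = rng.random() < proximal_fraction
        row_class.append("proximal" if prox else "distal")
        group = list(planted)
        if proximal_only is not None and prox and proximal_only not in group:
            group.append(proximal_only)
        on = rng.random() < on_prob
        for p in partners:
            if p in group:
                if on:
                    X[i, col[p]] = 0.2 + 0.8 * rng.random()
            elif p != proximal_only:
                if rng.random() < background_prob:
                    X[i, col[p]] = rng.random()
            else:  # proximal_only partner in distal rows: background presence
                if rng.random() < background_prob:
                    X[i, col[p]] = rng.random()
    return ColocMatrix(
        focus="synthetic", partners=list(partners), matrix=X, row_class=row_class
    )


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the dinucleotide composition exactly.

    Altschul-Erickson: sample one outgoing 'last edge' per vertex forming an
    arborescence into the terminal base, randomize the remaining successor
    lists, and read off the Eulerian walk.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq[:-1], seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    vertices = [a for a in edges if a != last]

    def is_arborescence(chosen: dict[str, str]) -> bool:
        for a in vertices:
            cur, hops = a, 0
            while cur != last:
                cur = chosen.get(cur)
                hops += 1
                if cur is None or hops > len(chosen) + 1:
                    return False
        return True

    chosen: dict[str, str] = {}
    for _ in range(10_000):  # tiny alphabet: succeeds almost immediately
        chosen = {a: edges[a][rng.integers(len(edges[a]))] for a in vertices}
        if is_arborescence(chosen):
            break
    else:
        raise RuntimeError("failed to sample an Eulerian edge ordering")

    ordered: dict[str, list[str]] = {}
    for a, succ in edges.items():
        succ = list(succ)
        if a in chosen:
            succ.remove(chosen[a])
        order = rng.permutation(len(succ))
        ordered[a] = [succ[i] for i in order]
        if a in chosen:
            ordered[a].append(chosen[a])

    out = [seq[0]]
    counters = {a: 0 for a in ordered}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def generate_second_species(
    genome: GenomeBundle,
    truth: TruthSet,
    conservation_rate: float = 0.5,
    seed: int = 0,
) -> tuple[GenomeBundle, SyntenyMap]:
    """Second species: per-edge conserved or dinucleotide-shuffled promoters.

    Every true edge is independently conserved with probability
    ``conservation_rate``. A target gene's promoter is copied verbatim when
    all its edges are conserved; otherwise the promoter is dinucleotide-
    shuffled and the motifs of conserved edges are re-planted at their
    original offsets. Genes map one-to-one into the second species.
    """
    if not 0.0 <= conservation_rate <= 1.0:
        raise ValueError("conservation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edge_conserved = {
        edge: bool(rng.random() < conservation_rate)
        for edge in sorted(truth.true_edges)
    }
    mutable = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}
    gene_by_id = {g.gene_id: g for g in genome.genes}

    edges_of_gene: dict[str, list[str]] = defaultdict(list)
    for tf, g in sorted(truth.true_edges):
        edges_of_gene[g].append(tf)
    for g_id, tfs in sorted(edges_of_gene.items()):
        promoter = truth.gene_promoters[g_id]
        if all(edge_conserved[(tf, g_id)] for tf in tfs):
            continue
        original = genome.sequences[promoter.chrom][promoter.start : promoter.end]
        shuffled = dinucleotide_shuffle(original, rng)
        mutable[promoter.chrom][promoter.start : promoter.end] = bytes(
            shuffled, "ascii"
        )
        for tf in tfs:
            if edge_conserved[(tf, g_id)]:
                chrom, starts = _motif_sites(truth, tf, g_id, gene_by_id)
                for m0 in starts:
                    mutable[chrom][m0 : m0 + MOTIF_K] = bytes(
                        truth.tf_motifs[tf], "ascii"
                    )

    species2 = GenomeBundle(
        sequences={c: bts.decode("ascii") for c, bts in mutable.items()},
        genes=[
            GeneModel(
                gene_id=f"{g.gene_id}_sp2",
                chrom=g.chrom,
                start=g.start,
                end=g.end,
                strand=g.strand,
            )
            for g in genome.genes
        ],
        open_chromatin=list(genome.open_chromatin),
    )
    synteny = SyntenyMap(
        pairs=[(g.gene_id, f"{g.gene_id}_sp2") for g in genome.genes]
    )
    return species2, synteny


def edge_conservation_flags(
    truth: TruthSet, conservation_rate: float, seed: int
) -> dict[tuple[str, str], bool]:
    """Re-derive the per-edge conservation decisions of ``generate_second_species``."""
    rng = np.random.default_rng(seed)
    return {
        edge: bool(rng.random() < conservation_rate)
        for edge in sorted(truth.true_edges)
    }
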