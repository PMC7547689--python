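"""Probabilistic TF->target inference from binding profiles (TIP-style),
FDR edge calling, network assembly, pathway-regulator ranking, and generic
term enrichment.

For each TF, an average profile of peak signal around gene start sites is
built, each gene's binding is weighted by that profile, and the resulting
scores are converted to z-scores and one-sided normal p-values. Edges pass
at Benjamini-Hochberg FDR 5% and carry -log10(p) weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import GeneModel, PeakSet


@dataclass
class BindingProfile:
    """Mean binding profile over ``2W/b`` bins around the TSS (sums to 1)."""

    tf: str
    bin_weights: np.ndarray
    window: int
    bin_size: int


@dataclass
class TargetScore:
    gene: str
    score: float
    z: float
    p: float
    q: float = float("nan")


@dataclass
class RegulatoryNetwork:
    """Directed TF -> gene graph with -log10(p) edge weights."""

    tf_ids: set[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return {t for t, _, _ in self.edges} | {g for _, g, _ in self.edges}

    def node_type(self, node: str) -> str:
        return "TF" if node in self.tf_ids else "gene"

    def in_degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for _, g, _ in self.edges:
            deg[g] = deg.get(g, 0) + 1
        return deg


def gene_signal_matrix(
    peakset: PeakSet,
    genes: list[GeneModel],
    window: int = 10_000,
    bin_size: int = 100,
) -> np.ndarray:
    """Genes x bins matrix of summed peak signal around each TSS.

    Bins span ``[-window, +window)`` in strand-oriented coordinates
    (negative = upstream of the TSS); a peak contributes its signal to the
    single bin containing its summit.
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin_size")
    n_bins = 2 * window // bin_size
    X = np.zeros((len(genes), n_bins))
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for p in peakset.peaks:
        by_chrom.setdefault(p.chrom, []).append((p.summit, p.signal))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for gi, gene in enumerate(genes):
        entries = by_chrom.get(gene.chrom)
        if not entries:
            continue
        positions = np.array([s for s, _ in entries])
        signals = np.array([v for _, v in entries])
        lo = np.searchsorted(positions, gene.tss - window, side="left")
        hi = np.searchsorted(positions, gene.tss + window, side="left")
        for summit, signal in zip(positions[lo:hi], signals[lo:hi]):
            rel = summit - gene.tss
            if gene.strand == "-":
                rel = -rel
            b = (rel + window) // bin_size
            if 0 <= b < n_bins:
                X[gi, b] += signal
    return X


def build_binding_profile(
    signal_matrix: np.ndarray,
    tf: str = "",
    window: int = 10_000,
    bin_size: int = 100,
) -> BindingProfile:
    """Column means normalized to sum to one."""
    if np.any(signal_matrix < 0):
        raise ValueError("signal matrix must be non-negative")
    col_means = signal_matrix.mean(axis=0)
    total = col_means.sum()
    if total == 0:
        raise ValueError("all-zero signal matrix: no binding to profile")
    return BindingProfile(
        tf=tf, bin_weights=col_means / total, window=window, bin_size=bin_size
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def score_targets(
    signal_matrix: np.ndarray,
    profile: BindingProfile,
    gene_ids: list[str],
) -> list[TargetScore]:
    """Profile-weighted gene scores with z, one-sided p and BH q."""
    if signal_matrix.shape[1] != profile.bin_weights.size:
        raise ValueError("signal matrix and profile shapes disagree")
    raw = signal_matrix @ profile.bin_weights
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across genes: cannot standardize")
    z = (raw - raw.mean()) / sd
    p = stats.norm.sf(z)
    q = benjamini_hochberg(p)
    return [
        TargetScore(gene=g, score=float(s), z=float(zz), p=float(pp), q=float(qq))
        for g, s, zz, pp, qq in zip(gene_ids, raw, z, p, q)
    ]


MIN_P = 1e-300  # floor before -log10 so weights stay finite


def call_targets(
    scores: list[TargetScore], tf: str, fdr: float = 0.05
) -> list[tuple[str, str, float]]:
    """Edges ``(tf, gene, -log10 p)`` for genes with q <= fdr (inclusive)."""
    return [
        (tf, s.gene, float(-np.log10(max(s.p, MIN_P))))
        for s in scores
        if s.q <= fdr
    ]


def infer_targets(
    peakset: PeakSet,
    genes: list[GeneModel],
    window: int = 10_000,
    bin_size: int = 100,
    fdr: float = 0.05,
) -> tuple[list[TargetScore], list[tuple[str, str, float]]]:
    """Full per-TF pipeline: matrix -> profile -> scores -> called edges."""
    X = gene_signal_matrix(peakset, genes, window, bin_size)
    profile = build_binding_profile(X, tf=peakset.tf, window=window, bin_size=bin_size)
    scores = score_targets(X, profile, [g.gene_id for g in genes])
    return scores, call_targets(scores, peakset.tf, fdr)


def assemble_network(
    edge_lists: dict[str, list[tuple[str, str, float]]]
) -> RegulatoryNetwork:
    """Union of per-TF edge lists into one directed graph."""
    if not edge_lists:
        raise ValueError("no edge lists supplied")
    edges: list[tuple[str, str, float]] = []
    for tf in sorted(edge_lists):
        edges.extend(edge_lists[tf])
    return RegulatoryNetwork(tf_ids=set(edge_lists), edges=edges)


def rank_pathway_regulators(
    network: RegulatoryNetwork, pathway_genes: set[str]
) -> list[tuple[str, float]]:
    """TFs ranked by summed edge weight into the pathway genes."""
    if not pathway_genes:
        raise ValueError("empty pathway gene set")
    sums = {tf: 0.0 for tf in network.tf_ids}
    for tf, gene, w in network.edges:
        if gene in pathway_genes:
            sums[tf] += w
    return sorted(sums.items(), key=lambda kv: (-kv[1], kv[0]))


def term_enrichment(
    query_genes: set[str],
    background: set[str],
    annotation: dict[str, set[str]],
) -> dict[str, tuple[float, float, float]]:
    """Per-term two-sided Fisher exact with BH adjustment.

    Returns term -> (odds ratio, p, q). Query must be a subset of background.
    """
    if not query_genes:
        raise ValueError("empty query gene set")
    if not query_genes <= background:
        raise ValueError("query genes must be a subset of the background")
    terms = sorted(annotation)
    pvals = []
    odds = []
    for term in terms:
        members = annotation[term] & background
        a = len(query_genes & members)
        b = len(query_genes - members)
        c = len(members - query_genes)
        d = len(background - query_genes - members)
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        pvals.append(p)
        odds.append(orr)
    qvals = benjamini_hochberg(np.array(pvals)) if terms else np.array([])
    return {
        t: (float(o), float(p), float(q))
        for t, o, p, q in zip(terms, odds, pvals, qvals)
    }


def write_edges_tsv(network: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tgene\tweight\n")
        for tf, gene, w in network.edges:
            fh.write(f"{tf}\t{gene}\t{w:.6g}\n")


def read_edges_tsv(path, tf_ids: set[str] | None = None) -> RegulatoryNetwork:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    edges = [
        (str(r.tf), str(r.gene), float(r.weight)) for r in df.itertuples(index=False)
    ]
    return RegulatoryNetwork(
        tf_ids=tf_ids if tf_ids is not None else {t for t, _, _ in edges},
        edges=edges,
    )
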