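"""Cross-species edge-conservation inference.

A maize-style TF sequence model is applied to the syntenic open-chromatin
regions of a second species; an edge is conserved when any syntenic region
scores at or above the probability threshold. Summaries contrast TF-to-TF
versus TF-to-non-TF edge conservation with a two-sided Fisher exact test,
and per-TF model match counts are correlated across species.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqmodel import SequenceModel, score_sequence
from .tip import RegulatoryNetwork
from .types import GeneModel, GenomeBundle, GenomicInterval, SyntenyMap


def assign_open_chromatin_to_genes(
    open_chromatin: list[GenomicInterval],
    genes: list[GeneModel],
    window: int = 10_000,
) -> dict[str, list[GenomicInterval]]:
    """Assign each region to every gene whose TSS is within ``window`` of it.

    Distance is measured from the TSS to the nearest covered base (0 when
    the TSS lies inside the region); regions may serve multiple genes.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    assigned: dict[str, list[GenomicInterval]] = defaultdict(list)
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in open_chromatin:
        by_chrom[iv.chrom].append(iv)
    for gene in genes:
        for iv in by_chrom.get(gene.chrom, []):
            if iv.start <= gene.tss < iv.end:
                d = 0
            else:
                d = min(abs(iv.start - gene.tss), abs(iv.end - 1 - gene.tss))
            if d <= window:
                assigned[gene.gene_id].append(iv)
    return dict(assigned)


def score_region(
    model: SequenceModel,
    sequence: str,
    scan_window: int | None = None,
    stride: int = 50,
) -> float:
    """Model probability for a region; long regions are scanned in windows.

    With ``scan_window`` set, the region is tiled in overlapping windows of
    that size and the maximum window probability is returned, so a region
    much longer than the model's training sequences is not penalized by
    dilution of its informative k-mers.
    """
    if scan_window is None or len(sequence) <= scan_window:
        return score_sequence(model, sequence)
    best = 0.0
    for start in range(0, len(sequence) - scan_window + 1, stride):
        best = max(best, score_sequence(model, sequence[start : start + scan_window]))
    return best


@dataclass
class ConservationCall:
    tf: str
    source_gene: str
    status: str  # 'conserved' | 'not-conserved' | 'not-assessable'
    best_probability: float = float("nan")


def predict_edge_conservation(
    network: RegulatoryNetwork,
    models: dict[str, SequenceModel],
    synteny: SyntenyMap,
    species_regions: dict[str, list[str]],
    threshold: float = 0.5,
    scan_window: int | None = None,
    scan_stride: int = 50,
) -> list[ConservationCall]:
    """Score each edge's syntenic open-chromatin sequences with the TF model.

    ``species_regions`` maps second-species gene ids to their assigned
    open-chromatin sequences. An edge with no synteny partner or no regions
    is not assessable.
    """
    missing = sorted({tf for tf, _, _ in network.edges} - set(models))
    if missing:
        raise ValueError(f"missing sequence models for TFs: {missing}")
    partner_of = dict(synteny.pairs)
    calls = []
    for tf, gene, _ in network.edges:
        partner = partner_of.get(gene)
        regions = species_regions.get(partner, []) if partner else []
        if not partner or not regions:
            calls.append(ConservationCall(tf=tf, source_gene=gene,
                                          status="not-assessable"))
            continue
        best = max(
            score_region(models[tf], seq, scan_window=scan_window,
                         stride=scan_stride)
            for seq in regions
        )
        status = "conserved" if best >= threshold else "not-conserved"
        calls.append(
            ConservationCall(tf=tf, source_gene=gene, status=status,
                             best_probability=float(best))
        )
    return calls


@dataclass
class ConservationSummary:
    fraction_conserved: float
    n_assessable: int
    n_conserved: int
    fraction_tf_to_tf: float | None
    fraction_tf_to_gene: float | None
    fisher_odds: float | None
    fisher_p: float | None


def conservation_summary(
    network: RegulatoryNetwork, calls: list[ConservationCall]
) -> ConservationSummary:
    """Conserved fractions over assessable edges, split by target type, with
    a two-sided Fisher exact TF-to-TF vs TF-to-non-TF contrast."""
    assessable = [c for c in calls if c.status != "not-assessable"]
    if not assessable:
        raise ValueError("no assessable edges")
    conserved = [c for c in assessable if c.status == "conserved"]
    tt = [c for c in assessable if c.source_gene in network.tf_ids]
    tg = [c for c in assessable if c.source_gene not in network.tf_ids]
    frac_tt = (
        sum(c.status == "conserved" for c in tt) / len(tt) if tt else None
    )
    frac_tg = (
        sum(c.status == "conserved" for c in tg) / len(tg) if tg else None
    )
    odds = p = None
    if tt and tg:
        a = sum(c.status == "conserved" for c in tt)
        b = len(tt) - a
        c_ = sum(c.status == "conserved" for c in tg)
        d = len(tg) - c_
        if (a + b) and (c_ + d) and not (b == 0 and d == 0) and not (a == 0 and c_ == 0):
            odds, p = stats.fisher_exact([[a, b], [c_, d]], alternative="two-sided")
            odds, p = float(odds), float(p)
        else:
            warnings.warn("degenerate TF-to-TF contrast table; contrast skipped")
    else:
        warnings.warn("an edge-type stratum is empty; contrast skipped")
    return ConservationSummary(
        fraction_conserved=len(conserved) / len(assessable),
        n_assessable=len(assessable),
        n_conserved=len(conserved),
        fraction_tf_to_tf=frac_tt,
        fraction_tf_to_gene=frac_tg,
        fisher_odds=odds,
        fisher_p=p,
    )


def count_model_matches(
    models: dict[str, SequenceModel],
    species_sequences: dict[str, list[str]],
    threshold: float = 0.5,
    scan_window: int | None = None,
) -> tuple[dict[str, dict[str, int]], dict[tuple[str, str], float | None]]:
    """Per-TF per-species counts of regions scoring >= threshold, plus the
    Spearman correlation of the counts between each species pair.

    A correlation is None (not assessable) when either count vector is
    constant.
    """
    if len(models) < 3:
        raise ValueError("need >= 3 TFs for a rank correlation")
    counts: dict[str, dict[str, int]] = {}
    for species, seqs in species_sequences.items():
        per_tf = {}
        for tf, model in sorted(models.items()):
            per_tf[tf] = int(
                sum(
                    score_region(model, s, scan_window=scan_window) >= threshold
                    for s in seqs
                )
            )
        counts[species] = per_tf
    tfs = sorted(models)
    correlations: dict[tuple[str, str], float | None] = {}
    species_names = sorted(counts)
    for i, s1 in enumerate(species_names):
        for s2 in species_names[i + 1 :]:
            x = np.array([counts[s1][tf] for tf in tfs])
            y = np.array([counts[s2][tf] for tf in tfs])
            if np.all(x == x[0]) or np.all(y == y[0]):
                correlations[(s1, s2)] = None
            else:
                correlations[(s1, s2)] = float(stats.spearmanr(x, y).statistic)
    return counts, correlations
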