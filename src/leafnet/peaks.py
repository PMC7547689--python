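"""Peak-set operations: QC filtering, summit merging, occupancy, overlap
permutation testing and distance-to-gene classification.

Membership of a peak in a region is decided by its summit throughout
(single-point rule); summit merging follows ``bedtools merge -d`` semantics
with summits treated as 1-bp features.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .types import GeneModel, GenomicInterval, Locus, Peak, PeakSet, QCRecord


def qc_filter(
    records: list[QCRecord],
    min_pearson: float = 0.8,
    min_nsc: float = 1.05,
    min_rsc: float = 0.8,
) -> list[str]:
    """Return TF ids whose metrics meet every threshold (inclusive)."""
    if not records:
        raise ValueError("no QC records supplied")
    return [
        r.tf
        for r in records
        if r.replicate_pearson >= min_pearson and r.nsc >= min_nsc and r.rsc >= min_rsc
    ]


def _summit_in_any(chrom: str, pos: int, by_chrom: dict[str, np.ndarray]) -> bool:
    """Membership of a point in sorted, non-overlapping-agnostic intervals."""
    arr = by_chrom.get(chrom)
    if arr is None or arr.size == 0:
        return False
    starts, ends = arr[:, 0], arr[:, 1]
    i = np.searchsorted(starts, pos, side="right")
    return bool(np.any(ends[:i] > pos))


def _intervals_by_chrom(intervals: list[GenomicInterval]) -> dict[str, np.ndarray]:
    grouped: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        grouped[iv.chrom].append((iv.start, iv.end))
    return {
        chrom: np.array(sorted(pairs), dtype=np.int64)
        for chrom, pairs in grouped.items()
    }


def subtract_intervals(
    peakset: PeakSet, exclude: list[GenomicInterval]
) -> PeakSet:
    """Drop peaks whose summit falls inside any excluded interval."""
    by_chrom = _intervals_by_chrom(exclude)
    kept = [
        p for p in peakset.peaks if not _summit_in_any(p.chrom, p.summit, by_chrom)
    ]
    return PeakSet(tf=peakset.tf, peaks=kept)


def merge_peak_summits(
    peaksets: list[PeakSet], gap: int = 300
) -> list[Locus]:
    """Merge summits across TFs into loci; inter-summit gap <= ``gap`` joins."""
    summits: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for ps in peaksets:
        for p in ps.peaks:
            summits[p.chrom].append((p.summit, ps.tf))
    loci: list[Locus] = []
    for chrom in sorted(summits):
        entries = sorted(summits[chrom])
        cluster_pos = [entries[0][0]]
        cluster_tfs = {entries[0][1]}
        for pos, tf in entries[1:]:
            # inter-summit distance = position difference; <= gap joins
            if pos - cluster_pos[-1] <= gap:
                cluster_pos.append(pos)
                cluster_tfs.add(tf)
            else:
                loci.append(
                    Locus(
                        interval=GenomicInterval(
                            chrom, cluster_pos[0], cluster_pos[-1] + 1
                        ),
                        member_tfs=frozenset(cluster_tfs),
                    )
                )
                cluster_pos = [pos]
                cluster_tfs = {tf}
        loci.append(
            Locus(
                interval=GenomicInterval(chrom, cluster_pos[0], cluster_pos[-1] + 1),
                member_tfs=frozenset(cluster_tfs),
            )
        )
    return loci


def occupancy_table(
    loci: list[Locus], top_percent: float = 5.0
) -> tuple[list[int], list[Locus]]:
    """Per-locus distinct-TF occupancy and the high-occupancy subset.

    The subset contains loci whose occupancy reaches the
    ``100 - top_percent`` percentile of the occupancy distribution; ties at
    the threshold are included.
    """
    if not loci:
        raise ValueError("no loci supplied")
    occ = [locus.occupancy for locus in loci]
    threshold = float(np.percentile(occ, 100.0 - top_percent))
    high = [locus for locus in loci if locus.occupancy >= threshold]
    return occ, high


def _overlap_count(
    query: dict[str, np.ndarray], reference: dict[str, np.ndarray]
) -> int:
    """Number of query intervals overlapping >= 1 reference interval."""
    total = 0
    for chrom, q in query.items():
        r = reference.get(chrom)
        if r is None or r.size == 0:
            continue
        r_starts = r[:, 0]
        r_ends = r[:, 1]
        order = np.argsort(r_starts)
        r_starts, r_ends = r_starts[order], r_ends[order]
        max_end = np.maximum.accumulate(r_ends)
        # query overlaps some reference iff exists ref with start < q_end
        # and end > q_start
        idx = np.searchsorted(r_starts, q[:, 1], side="left")
        has = np.zeros(len(q), dtype=bool)
        nz = idx > 0
        has[nz] = max_end[idx[nz] - 1] > q[nz, 0]
        total += int(has.sum())
    return total


def overlap_permutation_test(
    query: list[GenomicInterval],
    reference: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Per-chromosome randomization test for query/reference association.

    Query intervals are repositioned uniformly within their own chromosome
    (lengths preserved); the evaluation function is the number of query
    intervals overlapping the reference set.

    Returns ``(observed, p, z)`` with ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if not query or not reference:
        raise ValueError("degenerate test: empty query or reference set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    q_by = _intervals_by_chrom(query)
    r_by = _intervals_by_chrom(reference)
    observed = _overlap_count(q_by, r_by)
    null = np.empty(n_perm, dtype=np.int64)
    lengths = {c: arr[:, 1] - arr[:, 0] for c, arr in q_by.items()}
    for i in range(n_perm):
        perm: dict[str, np.ndarray] = {}
        for chrom, arr in q_by.items():
            ln = lengths[chrom]
            room = chrom_sizes[chrom] - ln
            if np.any(room < 0):
                raise ValueError(f"interval longer than chromosome {chrom}")
            starts = rng.integers(0, room + 1)
            perm[chrom] = np.column_stack([starts, starts + ln])
        null[i] = _overlap_count(perm, r_by)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    sd = float(null.std())
    z = (observed - float(null.mean())) / sd if sd > 0 else float("inf")
    return observed, p, z


@dataclass(frozen=True)
class GeneDistance:
    distance: int
    label: str  # 'genic' | 'proximal' | 'distal'


def distance_to_gene(
    loci: list[Locus],
    genes: list[GeneModel],
    proximal_cutoff: int = 2000,
) -> list[GeneDistance]:
    """Distance from each locus to the nearest gene and its class.

    A locus overlapping a gene body is genic (distance 0; counted with
    proximal when stratifying). Otherwise the distance is to the nearest
    gene boundary, classed proximal (< cutoff) or distal (>= cutoff).
    """
    if not genes:
        raise ValueError("no genes supplied")
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    results = []
    for locus in loci:
        iv = locus.interval
        best = None
        for g in by_chrom.get(iv.chrom, []):
            if iv.start < g.end and g.start < iv.end:
                best = 0
                break
            # distance between closest covered bases of locus and gene
            d = max(g.start - (iv.end - 1), iv.start - (g.end - 1))
            best = d if best is None else min(best, d)
        if best is None:
            results.append(GeneDistance(distance=-1, label="distal"))
            continue
        if best == 0:
            results.append(GeneDistance(distance=0, label="genic"))
        elif best < proximal_cutoff:
            results.append(GeneDistance(distance=best, label="proximal"))
        else:
            results.append(GeneDistance(distance=best, label="distal"))
    return results


def fraction_in_open_chromatin(
    peakset: PeakSet, open_chromatin: list[GenomicInterval]
) -> float:
    """Fraction of peaks whose summit lies inside an open-chromatin interval."""
    if not peakset.peaks:
        raise ValueError("empty peak set")
    by_chrom = _intervals_by_chrom(open_chromatin)
    inside = sum(
        _summit_in_any(p.chrom, p.summit, by_chrom) for p in peakset.peaks
    )
    return inside / len(peakset.peaks)
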