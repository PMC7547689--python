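"""Sequence-diversity profiles around summits and beta-binomial enrichment
of labeled variants in TF-binding regions versus matched controls.

Enrichment uses conjugate Beta(1,1) posteriors on hit frequencies in region
and control; the fold is the median of ratios of independent posterior
draws with a percentile 2.5-97.5 interval.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .peaks import distance_to_gene
from .tip import benjamini_hochberg
from .types import GeneModel, GenomicInterval, Locus, VariantSet


def snp_density_profile(
    variants: VariantSet,
    summits: list[tuple[str, int]],
    chrom_sizes: dict[str, int],
    bin_size: int = 100,
    max_dist: int = 1000,
    smooth: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean SNP count per distance-to-summit, smoothed.

    The genome is tiled in non-overlapping ``bin_size`` windows; each bin's
    SNP count is attributed to the signed distance between the bin midpoint
    and the nearest summit (clipped to ``+-max_dist``); counts at each
    distance are averaged and smoothed with a ``smooth``-position moving
    average. Returns (distances, smoothed mean counts).
    """
    if not summits:
        raise ValueError("no summits supplied")
    summits_by_chrom: dict[str, np.ndarray] = defaultdict(lambda: np.empty(0, np.int64))
    tmp: dict[str, list[int]] = defaultdict(list)
    for c, p in summits:
        tmp[c].append(p)
    for c, ps in tmp.items():
        summits_by_chrom[c] = np.sort(np.array(ps, dtype=np.int64))

    dist_counts: dict[int, list[int]] = defaultdict(list)
    for chrom, size in chrom_sizes.items():
        s = summits_by_chrom[chrom]
        if s.size == 0:
            continue
        positions = np.array(variants.positions(chrom), dtype=np.int64)
        n_bins = size // bin_size
        edges = np.arange(0, (n_bins + 1) * bin_size, bin_size)
        counts = np.histogram(positions, bins=edges)[0]
        mids = edges[:-1] + bin_size // 2
        idx = np.searchsorted(s, mids)
        left = mids - s[np.clip(idx - 1, 0, s.size - 1)]
        right = s[np.clip(idx, 0, s.size - 1)] - mids
        signed = np.where(np.abs(left) <= np.abs(right), -left, right)
        # signed distance: negative = summit upstream of midpoint
        for d, c in zip(signed, counts):
            if abs(int(d)) <= max_dist:
                dist_counts[int(d)].append(int(c))
    distances = np.array(sorted(dist_counts))
    means = np.array([np.mean(dist_counts[d]) for d in distances])
    if smooth > 1 and means.size:
        kernel = np.ones(min(smooth, means.size))
        # normalize by actual window overlap so edges are not zero-padded down
        means = np.convolve(means, kernel, mode="same") / np.convolve(
            np.ones_like(means), kernel, mode="same"
        )
    return distances, means


@dataclass
class ControlPlacement:
    locus: GenomicInterval
    controls: list[GenomicInterval]
    flagged: bool  # one-sided or skipped


def build_control_regions(
    tf_loci: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    min_gap: int = 5000,
) -> list[ControlPlacement]:
    """Matched controls: per locus of length L, two L/2 flanks placed at the
    nearest admissible positions >= ``min_gap`` from any TF locus, never
    overlapping loci or previously placed controls. Loci that can only be
    matched on one side (or not at all) are flagged.
    """
    loci_by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in tf_loci:
        loci_by_chrom[iv.chrom].append(iv)
    placed: dict[str, list[GenomicInterval]] = defaultdict(list)

    def conflicts(iv: GenomicInterval) -> bool:
        if iv.start < 0 or iv.end > chrom_sizes[iv.chrom]:
            return True
        for other in loci_by_chrom[iv.chrom]:
            # must stay >= min_gap away from every TF locus
            if iv.start < other.end + min_gap and other.start - min_gap < iv.end:
                return True
        return any(iv.overlaps(o) for o in placed[iv.chrom])

    results = []
    for locus in sorted(tf_loci, key=lambda iv: (iv.chrom, iv.start)):
        half = max(len(locus) // 2, 1)
        controls = []
        # upstream: slide left from the nearest admissible offset
        candidate_starts_up = range(locus.start - min_gap - half, -1, -half)
        for s in candidate_starts_up:
            iv = GenomicInterval(locus.chrom, s, s + half)
            if not conflicts(iv):
                controls.append(iv)
                placed[locus.chrom].append(iv)
                break
        n_up = len(controls)
        candidate_starts_down = range(
            locus.end + min_gap, chrom_sizes[locus.chrom] - half + 1, half
        )
        for s in candidate_starts_down:
            iv = GenomicInterval(locus.chrom, s, s + half)
            if not conflicts(iv):
                controls.append(iv)
                placed[locus.chrom].append(iv)
                break
        results.append(
            ControlPlacement(
                locus=locus, controls=controls,
                flagged=(len(controls) < 2 or n_up == 0),
            )
        )
    return results


@dataclass
class EnrichmentResult:
    fold: float
    ci_low: float
    ci_high: float
    counts: tuple[int, int, int, int]  # k1, n1, k2, n2
    prior: tuple[float, float] = (1.0, 1.0)

    @property
    def posterior_region(self) -> tuple[float, float]:
        k1, n1, _, _ = self.counts
        a, b = self.prior
        return (a + k1, b + n1 - k1)

    @property
    def posterior_control(self) -> tuple[float, float]:
        _, _, k2, n2 = self.counts
        a, b = self.prior
        return (a + k2, b + n2 - k2)


def betabinom_enrichment(
    hits_region: int,
    total_region: int,
    hits_control: int,
    total_control: int,
    prior: tuple[float, float] = (1.0, 1.0),
    n_draws: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Posterior fold enrichment of hit frequency in region vs control.

    Posteriors are Beta(a + k, b + n - k); the fold is the median of ratios
    of independent draws and the CI their 2.5/97.5 percentiles.
    """
    if total_region <= 0 or total_control <= 0:
        raise ValueError("totals must be positive")
    if hits_region > total_region or hits_control > total_control:
        raise ValueError("hits cannot exceed totals")
    if n_draws < 1000:
        raise ValueError("n_draws < 1000 gives unstable percentiles")
    a, b = prior
    rng = np.random.default_rng(seed)
    region = rng.beta(a + hits_region, b + total_region - hits_region, size=n_draws)
    control = rng.beta(a + hits_control, b + total_control - hits_control, size=n_draws)
    ratio = region / control
    lo, med, hi = np.percentile(ratio, [2.5, 50.0, 97.5])
    return EnrichmentResult(
        fold=float(med), ci_low=float(lo), ci_high=float(hi),
        counts=(hits_region, total_region, hits_control, total_control),
        prior=prior,
    )


def _count_hits(
    variants: VariantSet, intervals: list[GenomicInterval]
) -> tuple[int, int]:
    """(labeled hits, total variants) inside the intervals (point-in-interval)."""
    by_chrom: dict[str, np.ndarray] = {}
    grouped: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        grouped[iv.chrom].append((iv.start, iv.end))
    for c, pairs in grouped.items():
        by_chrom[c] = np.array(sorted(pairs), dtype=np.int64)
    k = n = 0
    for chrom, pos, is_hit in variants.records:
        arr = by_chrom.get(chrom)
        if arr is None:
            continue
        i = np.searchsorted(arr[:, 0], pos, side="right")
        if i > 0 and np.any(arr[:i, 1] > pos):
            n += 1
            if is_hit:
                k += 1
    return k, n


def enrichment_from_regions(
    variants: VariantSet,
    regions: list[GenomicInterval],
    controls: list[GenomicInterval],
    n_draws: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    k1, n1 = _count_hits(variants, regions)
    k2, n2 = _count_hits(variants, controls)
    return betabinom_enrichment(k1, n1, k2, n2, n_draws=n_draws, seed=seed)


def stratified_enrichment(
    variants: VariantSet,
    tf_loci: list[GenomicInterval],
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    cutoff: int = 2000,
    min_gap: int = 5000,
    n_draws: int = 100_000,
    seed: int = 0,
) -> dict[str, EnrichmentResult | None]:
    """Enrichment per stratum (proximal incl. genic, distal, combined).

    Controls are matched per locus and inherit its stratum. Strata with no
    variants in region or control come back as None (not assessable).
    """
    loci = [Locus(interval=iv, member_tfs=frozenset({"_"})) for iv in tf_loci]
    dists = distance_to_gene(loci, genes, cutoff)
    strata = {
        "proximal": [iv for iv, d in zip(tf_loci, dists)
                     if d.label in ("proximal", "genic")],
        "distal": [iv for iv, d in zip(tf_loci, dists) if d.label == "distal"],
        "combined": list(tf_loci),
    }
    placements = build_control_regions(tf_loci, chrom_sizes, min_gap)
    control_of = {pl.locus: pl.controls for pl in placements}
    results: dict[str, EnrichmentResult | None] = {}
    for name, stratum_loci in strata.items():
        controls = [c for iv in stratum_loci for c in control_of.get(iv, [])]
        if not stratum_loci or not controls:
            results[name] = None
            continue
        k1, n1 = _count_hits(variants, stratum_loci)
        k2, n2 = _count_hits(variants, controls)
        if n1 == 0 or n2 == 0:
            results[name] = None
            continue
        results[name] = betabinom_enrichment(
            k1, n1, k2, n2, n_draws=n_draws, seed=seed
        )
    return results


def call_gwas_hits(pvalues: np.ndarray, fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg hit labels at the given FDR (inclusive)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return benjamini_hochberg(p) <= fdr
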