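"""Core domain types shared across the toolkit.

All genomic coordinates are 0-based, half-open ``[start, end)``. BED-family
formats map directly; GFF3 is converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A ``[start, end)`` interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid gene span {self.start}-{self.end}")

    @property
    def tss(self) -> int:
        """5' boundary: ``start`` on '+', ``end - 1`` on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record: interval, absolute summit, and signal."""

    chrom: str
    start: int
    end: int
    summit: int
    signal: float
    tf: str

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start},{self.end}) for {self.tf}"
            )
        if not self.signal >= 0:  # also rejects NaN
            raise ValueError(f"signal must be >= 0 and not NaN, got {self.signal}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """All reproducible peaks of one TF, kept sorted by (chrom, start)."""

    tf: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def summits(self) -> list[tuple[str, int]]:
        return [(p.chrom, p.summit) for p in self.peaks]


@dataclass
class Locus:
    """A merged TF-binding locus with the set of contributing TFs."""

    interval: GenomicInterval
    member_tfs: frozenset[str]

    @property
    def occupancy(self) -> int:
        return len(self.member_tfs)


@dataclass(frozen=True)
class QCRecord:
    """Replicate-level ChIP quality metrics for one TF."""

    tf: str
    replicate_pearson: float
    nsc: float
    rsc: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.replicate_pearson <= 1.0:
            raise ValueError("replicate_pearson must lie in [-1, 1]")


@dataclass
class GenomeBundle:
    """A genome with annotation: sequences, genes, open chromatin."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    open_chromatin: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sizes = self.chrom_sizes
        for g in self.genes:
            if g.chrom not in sizes or g.end > sizes[g.chrom]:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
        prev: GenomicInterval | None = None
        for iv in self.open_chromatin:
            if iv.chrom not in sizes or iv.end > sizes[iv.chrom]:
                raise ValueError(f"open-chromatin interval {iv} outside bounds")
            if prev is not None and prev.chrom == iv.chrom:
                if iv.start < prev.end:
                    raise ValueError("open-chromatin intervals overlap or are unsorted")
            if prev is not None and (iv.chrom, iv.start) < (prev.chrom, prev.start):
                raise ValueError("open-chromatin intervals are unsorted")
            prev = iv

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, iv: GenomicInterval) -> str:
        return self.sequences[iv.chrom][iv.start : iv.end]


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside a synthetic genome."""

    tf_motifs: dict[str, str]
    true_edges: set[tuple[str, str]]
    module_assignment: dict[str, int]
    cobind_partners: dict[str, list[tuple[str, float]]]
    planted_enrichment: float
    conservation_rate: float
    # promoter open-chromatin interval of each gene (motif placement site)
    gene_promoters: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for focus, partners in self.cobind_partners.items():
            for partner, prob in partners:
                if not 0.0 <= prob <= 1.0:
                    raise ValueError(
                        f"co-occurrence probability {prob} for {focus}->{partner}"
                    )


@dataclass
class VariantSet:
    """Sorted point variants with optional hit labels."""

    records: list[tuple[str, int, bool | None]]

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r[0], r[1]))

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, chrom: str) -> list[int]:
        return [pos for c, pos, _ in self.records if c == chrom]


@dataclass
class SyntenyMap:
    """One-to-one gene correspondence between two species."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        sources = [a for a, _ in self.pairs]
        targets = [b for _, b in self.pairs]
        if len(set(sources)) != len(sources) or len(set(targets)) != len(targets):
            raise ValueError("synteny map must be one-to-one")

    def partner_of(self, source_gene: str) -> str | None:
        return dict(self.pairs).get(source_gene)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
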