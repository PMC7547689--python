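"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA via Biopython; the tabular formats (BED6, narrowPeak, GFF3, variant and
synteny TSV) via pandas. GFF3 coordinates are converted between 1-based
closed (on disk) and 0-based half-open (in memory).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    GeneModel,
    GenomeBundle,
    GenomicInterval,
    Peak,
    PeakSet,
    QCRecord,
    SyntenyMap,
    TruthSet,
    VariantSet,
)

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "leafnet") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            # 0-based half-open -> 1-based closed
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
        dtype={"chrom": str},
    )
    df = df[df["type"] == "gene"]
    genes = []
    for row in df.itertuples():
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        genes.append(
            GeneModel(
                gene_id=attrs.get("ID", f"{row.chrom}:{row.start}"),
                chrom=str(row.chrom),
                start=int(row.start) - 1,
                end=int(row.end),
                strand=str(row.strand),
            )
        )
    return genes


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion_{i}\t0\t.\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    return [
        GenomicInterval(str(r[0]), int(r[1]), int(r[2]))
        for r in df.itertuples(index=False)
    ]


def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset.peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{peakset.tf}_peak_{i}\t0\t.\t"
                f"{p.signal:.6g}\t-1\t-1\t{p.summit - p.start}\n"
            )


def read_narrowpeak(path: str | Path, tf: str | None = None) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                     dtype={"chrom": str})
    if tf is None:
        tf = Path(path).stem.split(".")[0]
    peaks = [
        Peak(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            summit=int(r.start) + int(r.peak),
            signal=float(r.signalValue),
            tf=tf,
        )
        for r in df.itertuples(index=False)
    ]
    return PeakSet(tf=tf, peaks=peaks)


def write_variants(variants: VariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tis_hit\n")
        for chrom, pos, is_hit in variants.records:
            label = "" if is_hit is None else str(int(is_hit))
            fh.write(f"{chrom}\t{pos}\t{label}\n")


def read_variants(path: str | Path) -> VariantSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for r in df.itertuples(index=False):
        is_hit = None
        if "is_hit" in df.columns and not pd.isna(r.is_hit):
            is_hit = bool(int(r.is_hit))
        records.append((str(r.chrom), int(r.pos), is_hit))
    return VariantSet(records=records)


def write_synteny(synteny: SyntenyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\n")
        for a, b in synteny.pairs:
            fh.write(f"{a}\t{b}\n")


def read_synteny(path: str | Path) -> SyntenyMap:
    df = pd.read_csv(path, sep="\t")
    return SyntenyMap(pairs=[(str(a), str(b)) for a, b in df.itertuples(index=False)])


def read_qc_table(path: str | Path) -> list[QCRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        QCRecord(tf=str(r.tf), replicate_pearson=float(r.replicate_pearson),
                 nsc=float(r.nsc), rsc=float(r.rsc))
        for r in df.itertuples(index=False)
    ]


def write_truth(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "tf_motifs": truth.tf_motifs,
        "true_edges": sorted(list(e) for e in truth.true_edges),
        "module_assignment": truth.module_assignment,
        "cobind_partners": {
            tf: [[p, prob] for p, prob in partners]
            for tf, partners in truth.cobind_partners.items()
        },
        "planted_enrichment": truth.planted_enrichment,
        "conservation_rate": truth.conservation_rate,
        "gene_promoters": {
            g: [iv.chrom, iv.start, iv.end] for g, iv in truth.gene_promoters.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    return TruthSet(
        tf_motifs=payload["tf_motifs"],
        true_edges={tuple(e) for e in payload["true_edges"]},
        module_assignment={k: int(v) for k, v in payload["module_assignment"].items()},
        cobind_partners={
            tf: [(p, float(prob)) for p, prob in partners]
            for tf, partners in payload["cobind_partners"].items()
        },
        planted_enrichment=float(payload["planted_enrichment"]),
        conservation_rate=float(payload["conservation_rate"]),
        gene_promoters={
            g: GenomicInterval(c, int(s), int(e))
            for g, (c, s, e) in payload["gene_promoters"].items()
        },
    )


def write_genome_bundle(bundle: GenomeBundle, outdir: str | Path,
                        prefix: str = "genome") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.sequences, outdir / f"{prefix}.fa")
    write_gff3(bundle.genes, outdir / f"{prefix}.gff3")
    write_bed(bundle.open_chromatin, outdir / f"{prefix}.open_chromatin.bed")


def read_genome_bundle(outdir: str | Path, prefix: str = "genome") -> GenomeBundle:
    outdir = Path(outdir)
    return GenomeBundle(
        sequences=read_fasta(outdir / f"{prefix}.fa"),
        genes=read_gff3(outdir / f"{prefix}.gff3"),
        open_chromatin=read_bed(outdir / f"{prefix}.open_chromatin.bed"),
    )


def write_pwms_meme(pwms: list, path: str | Path) -> None:
    """Write PWMs in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            width = pwm.matrix.shape[1]
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {width}\n")
            for col in pwm.matrix.T:
                fh.write(" ".join(f"{x:.10f}" for x in col) + "\n")
            fh.write("\n")


def read_pwms_meme(path: str | Path) -> list:
    """Read a MEME minimal motif file into PWM objects."""
    from .seqmodel import PWM

    import re

    pwms = []
    name = None
    rows: list[list[float]] = []
    expecting = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            if m is None:
                raise ValueError(f"malformed matrix header: {line!r}")
            expecting = int(m.group(1))
            rows = []
        elif expecting and line:
            rows.append([float(x) for x in line.split()])
            if len(rows) == expecting:
                matrix = np.array(rows).T  # 4 x width
                family = name.split("_")[0] if name else "unknown"
                pwms.append(PWM(matrix=matrix, name=name or "motif", family=family))
                expecting = 0
    return pwms
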