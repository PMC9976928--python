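"""Readers and writers for the plain-text interchange formats used by the pipeline.

Genomes are FASTA, homology hits are BLAST tabular (outfmt 6), insertion sites and
chromatin states are BED, gene models and all stage reports are TSV.  Coordinates are
0-based half-open in memory; BLAST tabular input is 1-based inclusive and converted on
read, BED is emitted 0-based half-open as the format requires.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import HomologyHit
from .insertions import GeneModel, InsertionSite, StateSegment

log = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-contig) FASTA into a dict of uppercase sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_blast_tab(path: str | Path) -> list[HomologyHit]:
    """Parse BLAST outfmt-6 hits against a genome (subject = genomic contig).

    Subject coordinates are 1-based inclusive; sstart > send marks a minus-strand hit.
    Malformed records are rejected individually with a logged reason.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                log.warning("line %d: expected 12 columns, got %d; skipped", lineno, len(fields))
                continue
            try:
                sstart, send = int(fields[8]), int(fields[9])
                strand = "+" if sstart <= send else "-"
                lo, hi = min(sstart, send), max(sstart, send)
                hit = HomologyHit(
                    query_id=fields[0],
                    chrom=fields[1],
                    start=lo - 1,
                    end=hi,
                    strand=strand,
                    percent_identity=float(fields[2]),
                    evalue=float(fields[10]),
                    aligned_length=int(fields[3]),
                )
            except ValueError as exc:
                log.warning("line %d: %s; skipped", lineno, exc)
                continue
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Emit hits back to outfmt-6 (fields we do not track are written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                sstart, send = h.start + 1, h.end
            else:
                sstart, send = h.end, h.start + 1
            fh.write("\t".join(map(str, [
                h.query_id, h.chrom, h.percent_identity, h.aligned_length, 0, 0,
                1, h.aligned_length, sstart, send, h.evalue, 0,
            ])) + "\n")


def read_sites_bed(path: str | Path) -> list[InsertionSite]:
    """BED6 insertion sites; the name column carries the sample label."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            chrom, start = f[0], int(f[1])
            label = f[3] if len(f) > 3 else "sites"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else None
            sites.append(InsertionSite(chrom=chrom, position=start, strand=strand,
                                       sample_label=label))
    return sites


def write_sites_bed(sites: Iterable[InsertionSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            strand = s.strand or "."
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 2}\t{s.sample_label}\t0\t{strand}\n")


def read_states_bed(path: str | Path) -> list[StateSegment]:
    """BED4 chromatin-state segmentation; column 4 is the state label."""
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            segs.append(StateSegment(chrom=f[0], start=int(f[1]), end=int(f[2]), state=f[3]))
    return segs


def write_states_bed(segments: Iterable[StateSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\n")


GENE_COLUMNS = ["chrom", "start", "end", "strand", "name",
                "expression", "exon_starts", "exon_ends"]


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Minimal gene-model TSV: chrom, start, end, strand, name, expression,
    exon_starts, exon_ends (comma-separated, optional)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "name": str})
    genes = []
    for row in df.itertuples(index=False):
        exons = None
        es = getattr(row, "exon_starts", None)
        ee = getattr(row, "exon_ends", None)
        if isinstance(es, str) and es:
            starts = [int(x) for x in es.rstrip(",").split(",")]
            ends = [int(x) for x in str(ee).rstrip(",").split(",")]
            exons = list(zip(starts, ends))
        expr = getattr(row, "expression", None)
        genes.append(GeneModel(chrom=row.chrom, start=int(row.start), end=int(row.end),
                               strand=row.strand, name=row.name,
                               expression=None if pd.isna(expr) else float(expr),
                               exons=exons))
    return genes


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "chrom": g.chrom, "start": g.start, "end": g.end, "strand": g.strand,
            "name": g.name, "expression": g.expression if g.expression is not None else "",
            "exon_starts": ",".join(str(s) for s, _ in g.exons) if g.exons else "",
            "exon_ends": ",".join(str(e) for _, e in g.exons) if g.exons else "",
        })
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)
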