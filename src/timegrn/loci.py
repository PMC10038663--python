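"""CTCF-bounded regulatory locus assignment and sequence extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

from timegrn.chromatin import IndexedSite, Peak

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (0-based half-open, converted from GTF)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty gene interval for {self.gene_id}")


@dataclass(frozen=True)
class RegulatoryLocus:
    """The CTCF-bounded window owning a gene's candidate sites."""

    gene_id: str
    chrom: str
    start: int
    end: int
    upstream_peak: str | None = None  # None -> capped at max_search
    downstream_peak: str | None = None


def read_gtf_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read gene features from a GTF (1-based inclusive -> half-open)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "gene":
            continue
        attrs = {}
        for chunk in fields[8].strip().split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            key, _, value = chunk.partition(" ")
            attrs[key] = value.strip().strip('"')
        gene_id = attrs.get("gene_id")
        if gene_id is None:
            raise ValueError(f"GTF gene record without gene_id: {line!r}")
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chrom=fields[0],
                start=int(fields[3]) - 1,
                end=int(fields[4]),
                strand=fields[6],
            )
        )
    return genes


def read_ctcf_bed(path: str | Path) -> list[Peak]:
    """Read a CTCF BED with signalValue in column 7."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 7:
        raise ValueError("CTCF BED needs >= 7 columns (signalValue in col 7)")
    return [
        Peak(
            chrom=str(row[0]),
            start=int(row[1]),
            end=int(row[2]),
            name=str(row[3]),
            signal=float(row[6]),
        )
        for row in df.itertuples(index=False, name=None)
    ]


def build_locus(
    gene: GeneAnnotation,
    ctcf: Sequence[Peak],
    max_search: int = 500_000,
) -> RegulatoryLocus:
    """Bound a gene's regulatory window by its strongest flanking CTCF peaks.

    On each side, the CTCF peak with maximal signalValue overlapping the
    search window (up to ``max_search`` bp beyond the gene body) is
    chosen; the locus runs from the upstream peak's start to the
    downstream peak's end.  Ties are broken by proximity to the gene,
    then by coordinate.  A side with no peak is capped at the gene
    boundary +/- ``max_search`` (floored at 0).
    """
    chrom_peaks = [p for p in ctcf if p.chrom == gene.chrom]

    up_lo = max(0, gene.start - max_search)
    candidates_up = [p for p in chrom_peaks if p.end > up_lo and p.start < gene.start]
    candidates_down = [
        p for p in chrom_peaks if p.start < gene.end + max_search and p.end > gene.end
    ]

    upstream = downstream = None
    if candidates_up:
        upstream = min(
            candidates_up,
            key=lambda p: (-p.signal, gene.start - p.end, p.start),
        )
    if candidates_down:
        downstream = min(
            candidates_down,
            key=lambda p: (-p.signal, p.start - gene.end, p.start),
        )

    start = upstream.start if upstream else max(0, gene.start - max_search)
    end = downstream.end if downstream else gene.end + max_search
    # the locus always contains the gene body
    start = min(start, gene.start)
    end = max(end, gene.end)
    return RegulatoryLocus(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=start,
        end=end,
        upstream_peak=upstream.name if upstream else None,
        downstream_peak=downstream.name if downstream else None,
    )


def sites_in_locus(
    locus: RegulatoryLocus,
    sites: Iterable[IndexedSite],
) -> list[IndexedSite]:
    """Sites overlapping the locus by >= 1 bp (multi-ownership allowed)."""
    return [
        s
        for s in sites
        if s.chrom == locus.chrom and s.start < locus.end and locus.start < s.end
    ]


def extract_sequences(
    sites: Iterable[IndexedSite],
    genome_fasta: str | Path,
) -> dict[str, str]:
    """Uppercase forward-strand sequences keyed by site id.

    Raises on intervals outside chromosome bounds or on chromosomes
    absent from the FASTA.
    """
    fasta = Fasta(str(genome_fasta))
    out: dict[str, str] = {}
    for s in sites:
        if s.chrom not in fasta:
            raise KeyError(f"chromosome {s.chrom} absent from {genome_fasta}")
        contig_len = len(fasta[s.chrom])
        if s.start < 0 or s.end > contig_len:
            raise ValueError(
                f"interval {s.chrom}:{s.start}-{s.end} outside contig (len {contig_len})"
            )
        out[s.site_id or f"{s.chrom}:{s.start}-{s.end}"] = str(
            fasta[s.chrom][s.start:s.end]
        ).upper()
    return out


def loci_to_bed(loci: Sequence[RegulatoryLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "name": l.gene_id,
                "upstream_peak": l.upstream_peak or ".",
                "downstream_peak": l.downstream_peak or ".",
            }
            for l in loci
        ]
    )
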