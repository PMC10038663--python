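"""PWM loading, log-odds scoring and double-strand site scanning.

Scores follow the classic log-likelihood-ratio convention: for each
position the matrix frequency (with a total pseudocount apportioned by
background) is compared to a uniform background, in log base 2, and the
per-position contributions summed.  Windows scoring strictly above the
threshold (default 10) on either strand are reported as hits and mapped
back to genomic coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from timegrn.chromatin import IndexedSite

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degenerate nucleotide codes -> allowed bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """A motif as an L x 4 count matrix with scoring metadata."""

    motif_id: str
    counts: np.ndarray  # (L, 4) float, column order ACGT
    tf_genes: tuple[str, ...] = ()
    pseudocount: float = 0.1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an L x 4 matrix")
        if np.any(self.counts < 0):
            raise ValueError("negative matrix entries")
        self.background = np.asarray(self.background, dtype=float)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Pseudocount-corrected column frequencies (rows sum to 1)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + self.pseudocount * self.background) / (
            totals + self.pseudocount
        )

    @property
    def score_matrix(self) -> np.ndarray:
        """(L, 5) log2 odds; the 5th column scores N (and any other
        ambiguity) as 0."""
        lods = np.log2(self.frequencies / self.background)
        return np.hstack([lods, np.zeros((len(self), 1))])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.score_matrix[:, :4].max(axis=1).sum())


def log_odds_score(pwm: PositionWeightMatrix, kmer: str) -> float:
    """Log2-odds score of one window (length must equal the motif's)."""
    if len(kmer) != len(pwm):
        raise ValueError(f"kmer length {len(kmer)} != motif length {len(pwm)}")
    m = pwm.score_matrix
    return float(sum(m[i, _BASE_INDEX.get(b, 4)] for i, b in enumerate(kmer.upper())))


def consensus_to_pwm(
    motif_id: str,
    consensus: str,
    tf_genes: tuple[str, ...] = (),
    weight: float = 1000.0,
) -> PositionWeightMatrix:
    """High-information PWM from a (possibly degenerate) consensus string."""
    counts = np.zeros((len(consensus), 4))
    for i, code in enumerate(consensus.upper()):
        bases = IUPAC.get(code)
        if bases is None:
            raise ValueError(f"invalid consensus character {code!r}")
        for b in bases:
            counts[i, _BASE_INDEX[b]] = weight / len(bases)
    return PositionWeightMatrix(motif_id=motif_id, counts=counts, tf_genes=tf_genes)


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM match inside a regulatory site."""

    motif_id: str
    site_id: str
    strand: str  # '+' or '-'
    offset: int  # 0-based, forward-strand coordinates within the site
    score: float
    matched: str  # motif-oriented sequence (revcomp of the window on '-')
    genomic_start: int = -1  # 0-based half-open, forward strand
    genomic_end: int = -1


def scan_sequence(
    sequence: str,
    pwm: PositionWeightMatrix,
    threshold: float = 10.0,
    site_id: str = "",
) -> list[MotifHit]:
    """All windows on both strands scoring strictly above ``threshold``.

    Minus-strand hits are reported at their forward-strand offset.
    Sequences shorter than the motif yield an empty list.
    """
    seq = sequence.upper()
    L = len(pwm)
    n = len(seq) - L + 1
    if n <= 0:
        return []
    codes = np.fromiter(
        (_BASE_INDEX.get(b, 4) for b in seq), dtype=np.intp, count=len(seq)
    )
    m_fwd = pwm.score_matrix
    # minus strand: score the reverse complement of each window without
    # materializing it -- reverse the matrix rows and complement columns.
    m_rev = m_fwd[::-1][:, [3, 2, 1, 0, 4]]

    fwd = np.zeros(n)
    rev = np.zeros(n)
    for j in range(L):
        fwd += m_fwd[j, codes[j : j + n]]
        rev += m_rev[j, codes[j : j + n]]

    hits = []
    for off in np.nonzero(fwd > threshold)[0]:
        window = seq[off : off + L]
        hits.append(
            MotifHit(pwm.motif_id, site_id, "+", int(off), float(fwd[off]), window)
        )
    for off in np.nonzero(rev > threshold)[0]:
        window = seq[off : off + L]
        hits.append(
            MotifHit(
                pwm.motif_id, site_id, "-", int(off), float(rev[off]),
                reverse_complement(window),
            )
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# spec name for the same operation
scan_site = scan_sequence


def hits_for_gene(
    sites: Sequence[IndexedSite],
    sequences: Mapping[str, str],
    library: Sequence[PositionWeightMatrix],
    grn_genes: Iterable[str],
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Table of (site_id, tf_gene, hit...) for motifs mapping into the GRN.

    Only motifs whose TF symbol maps (case-insensitively) into
    ``grn_genes`` contribute; identical (motif, offset, strand) hits are
    deduplicated.  Hit coordinates are lifted to the genome via each
    site's interval.
    """
    gene_by_lower = {g.lower(): g for g in grn_genes}
    rows = []
    for site in sites:
        seq = sequences[site.site_id]
        seen: set[tuple[str, int, str]] = set()
        for pwm in library:
            mapped = [
                gene_by_lower[tf.lower()]
                for tf in pwm.tf_genes
                if tf.lower() in gene_by_lower
            ]
            if not mapped:
                continue
            for hit in scan_sequence(seq, pwm, threshold=threshold, site_id=site.site_id):
                key = (hit.motif_id, hit.offset, hit.strand)
                if key in seen:
                    continue
                seen.add(key)
                for tf_gene in mapped:
                    rows.append(
                        {
                            "site_id": site.site_id,
                            "tf_gene": tf_gene,
                            "motif_id": hit.motif_id,
                            "strand": hit.strand,
                            "offset": hit.offset,
                            "score": hit.score,
                            "matched": hit.matched,
                            "chrom": site.chrom,
                            "genomic_start": site.start + hit.offset,
                            "genomic_end": site.start + hit.offset + len(hit.matched),
                            "chip_time": site.chip_time,
                            "site_index": site.index,
                            "site_category": site.category,
                        }
                    )
    columns = [
        "site_id", "tf_gene", "motif_id", "strand", "offset", "score", "matched",
        "chrom", "genomic_start", "genomic_end", "chip_time", "site_index",
        "site_category",
    ]
    return pd.DataFrame(rows, columns=columns)


# --- motif library I/O -----------------------------------------------------

_MEME_HEADER = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25
"""


def write_meme(pwms: Sequence[PositionWeightMatrix], path: str | Path) -> None:
    """Write a library in MEME minimal motif format.

    The TF gene symbol(s) are carried in the alternate-name field
    (dimers joined with ``::``).
    """
    chunks = [_MEME_HEADER]
    for pwm in pwms:
        alt = "::".join(pwm.tf_genes)
        nsites = max(int(round(pwm.counts.sum(axis=1).max())), 1)
        freqs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
        lines = [f"\nMOTIF {pwm.motif_id} {alt}".rstrip()]
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= {nsites} E= 0"
        )
        for row in freqs:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        chunks.append("\n".join(lines) + "\n")
    Path(path).write_text("".join(chunks))


def _read_meme(path: Path) -> list[PositionWeightMatrix]:
    # Exact reader for the minimal subset written by write_meme; kept
    # in-house because available parsers round probabilities to integer
    # counts, which distorts log-odds scores.
    text = path.read_text()
    pwms = []
    pattern = re.compile(
        r"MOTIF\s+(\S+)(?:[ \t]+(\S+))?\s*\n"
        r"letter-probability matrix:[^\n]*?w=\s*(\d+)[^\n]*?nsites=\s*(\d+)[^\n]*\n"
        r"((?:\s*[\d.eE+-]+[ \t]+[\d.eE+-]+[ \t]+[\d.eE+-]+[ \t]+[\d.eE+-]+\s*\n)+)",
    )
    for m in pattern.finditer(text):
        motif_id, alt, w, nsites = m.group(1), m.group(2), int(m.group(3)), int(m.group(4))
        rows = [
            [float(v) for v in line.split()]
            for line in m.group(5).strip().splitlines()
        ]
        freqs = np.asarray(rows, dtype=float)
        if freqs.shape != (w, 4):
            raise ValueError(f"malformed matrix for motif {motif_id} in {path}")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=5e-3):
            raise ValueError(f"motif {motif_id} rows do not sum to 1")
        tf_genes = tuple(alt.split("::")) if alt else ()
        pwms.append(
            PositionWeightMatrix(
                motif_id=motif_id, counts=freqs * nsites, tf_genes=tf_genes
            )
        )
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def _read_jaspar(path: Path) -> list[PositionWeightMatrix]:
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
        name = getattr(m, "name", None) or ""
        motif_id = getattr(m, "matrix_id", None) or name
        tf_genes = tuple(name.split("::")) if name else ()
        pwms.append(
            PositionWeightMatrix(motif_id=str(motif_id), counts=counts, tf_genes=tf_genes)
        )
    return pwms


def load_motifs(
    paths: Iterable[str | Path],
    grn_genes: Iterable[str] | None = None,
) -> list[PositionWeightMatrix]:
    """Load a PWM library from MEME minimal and/or JASPAR pfm files.

    When ``grn_genes`` is given, motifs whose TF symbols do not map into
    the set (case-insensitively) are kept but logged; they never
    contribute network edges downstream.
    """
    pwms: list[PositionWeightMatrix] = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in {".meme", ".txt"}:
            pwms.extend(_read_meme(p))
        elif p.suffix.lower() in {".pfm", ".jaspar"}:
            pwms.extend(_read_jaspar(p))
        else:
            raise ValueError(f"unrecognized motif file extension: {p}")
    if grn_genes is not None:
        lowered = {g.lower() for g in grn_genes}
        for pwm in pwms:
            if not any(tf.lower() in lowered for tf in pwm.tf_genes):
                log.warning(
                    "motif %s (TFs %s) has no GRN gene mapping; kept but inert",
                    pwm.motif_id, ",".join(pwm.tf_genes) or "-",
                )
    log.info("loaded %d motifs", len(pwms))
    return pwms


def hits_to_fimo_tsv(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hits in FIMO-like TSV columns."""
    out = pd.DataFrame(
        {
            "motif_id": hits["motif_id"],
            "sequence_name": hits["site_id"],
            "start": hits["offset"] + 1,  # FIMO is 1-based inclusive
            "stop": hits["genomic_end"] - hits["genomic_start"] + hits["offset"],
            "strand": hits["strand"],
            "score": hits["score"],
            "matched_sequence": hits["matched"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
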