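"""H3K27 chromatin-state indexing of regulatory sites.

Peaks enriched for H3K27ac or H3K27me3 in induced/uninduced tissue are
filtered, merged into a unique site set (bedtools ``merge -d`` semantics)
and every site's joint mark pattern across the two conditions is
classified into one of 16 indices grouped into four categories:
activation (1-3), repression (4-6), poised (7-12), no change (13-16).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

ACTIVATION = "activation"
REPRESSION = "repression"
POISED = "poised"
NO_CHANGE = "no_change"

#: Indices used per selection mode.
MODE_INDICES = {
    "activation_only": frozenset({1, 2, 3, 7}),
    "activation_and_repression": frozenset(range(1, 8)),
    "all_changing": frozenset(range(1, 11)),
}

#: Per-tissue mark statuses.
_STATUSES = ("none", "ac_only", "me3_only", "both")

#: Canonical (uninduced status, induced status) -> index.  The numbering
#: within each category is configurable; this table keeps index 7 as the
#: activation-like poised class (me3-marked chromatin gaining acetylation)
#: and indices 1-10 as the "changing" set.
DEFAULT_INDEX_TABLE: dict[tuple[str, str], int] = {
    ("none", "ac_only"): 1,
    ("me3_only", "ac_only"): 2,
    ("me3_only", "none"): 3,
    ("ac_only", "none"): 4,
    ("ac_only", "me3_only"): 5,
    ("none", "me3_only"): 6,
    ("me3_only", "both"): 7,
    ("none", "both"): 8,
    ("ac_only", "both"): 9,
    ("both", "ac_only"): 10,
    ("both", "none"): 11,
    ("both", "me3_only"): 12,
    ("none", "none"): 13,
    ("ac_only", "ac_only"): 14,
    ("me3_only", "me3_only"): 15,
    ("both", "both"): 16,
}


def index_category(index: int) -> str:
    """Category of an index per the 1-3 / 4-6 / 7-12 / 13-16 grouping."""
    if 1 <= index <= 3:
        return ACTIVATION
    if 4 <= index <= 6:
        return REPRESSION
    if 7 <= index <= 12:
        return POISED
    if 13 <= index <= 16:
        return NO_CHANGE
    raise ValueError(f"index out of range 1-16: {index}")


@dataclass(frozen=True)
class Peak:
    """A mark-enriched interval (BED convention: 0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    signal: float = 0.0
    p_score: float = 0.0  # -log10 p-value
    q_score: float = 0.0  # -log10 q-value
    fold_change: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class MarkState:
    """The four mark/condition booleans of a site at one ChIP time."""

    ac_induced: bool
    me3_induced: bool
    ac_uninduced: bool
    me3_uninduced: bool

    def status(self, condition: str) -> str:
        if condition == "induced":
            ac, me3 = self.ac_induced, self.me3_induced
        elif condition == "uninduced":
            ac, me3 = self.ac_uninduced, self.me3_uninduced
        else:
            raise ValueError(f"unknown condition {condition!r}")
        if ac and me3:
            return "both"
        if ac:
            return "ac_only"
        if me3:
            return "me3_only"
        return "none"


@dataclass(frozen=True)
class MergedSite:
    """Output of interval merging: a unique site with source membership."""

    chrom: str
    start: int
    end: int
    count: int
    sources: tuple[str, ...]


@dataclass(frozen=True)
class IndexedSite:
    """A classified regulatory site at one ChIP time point."""

    chrom: str
    start: int
    end: int
    chip_time: int
    index: int
    category: str
    site_id: str = ""
    source_peaks: tuple[str, ...] = ()

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def filter_enriched(
    peaks: Iterable[Peak],
    min_p_score: float = 5.0,
    min_fold_change: float = 1.2,
    min_q_score: float = 3.0,
) -> list[Peak]:
    """Keep peaks passing the enrichment filter (strict inequalities).

    Defaults encode p-value < 1e-5 (p_score > 5), fold change > 1.2 and
    q-score > 3.
    """
    peaks = list(peaks)
    kept = [
        p
        for p in peaks
        if p.p_score > min_p_score
        and p.fold_change > min_fold_change
        and p.q_score > min_q_score
    ]
    log.info("filter_enriched: %d in -> %d retained", len(peaks), len(kept))
    return kept


def merge_intervals(
    *interval_lists: Iterable[Peak],
    gap: int = 100,
) -> list[MergedSite]:
    """Merge intervals with bedtools ``merge -d <gap>`` semantics.

    After sorting, intervals whose separation is <= ``gap`` bp are merged
    transitively (per chromosome).  Each merged site records the number
    of source intervals and their collapsed names, mirroring
    ``-c 1,4 -o count,collapse``.
    """
    pool: list[Peak] = [p for lst in interval_lists for p in lst]
    by_chrom: dict[str, list[Peak]] = {}
    for p in pool:
        by_chrom.setdefault(p.chrom, []).append(p)

    out: list[MergedSite] = []
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end = peaks[0].start, peaks[0].end
        cur_sources = [peaks[0].name]
        for p in peaks[1:]:
            if p.start - cur_end <= gap:
                cur_end = max(cur_end, p.end)
                cur_sources.append(p.name)
            else:
                out.append(MergedSite(chrom, cur_start, cur_end, len(cur_sources), tuple(cur_sources)))
                cur_start, cur_end = p.start, p.end
                cur_sources = [p.name]
        out.append(MergedSite(chrom, cur_start, cur_end, len(cur_sources), tuple(cur_sources)))
    return out


def classify_index(
    state: MarkState,
    index_table: Mapping[tuple[str, str], int] = DEFAULT_INDEX_TABLE,
) -> tuple[int, str]:
    """Map a site's joint H3K27 pattern to its (index, category).

    Total on all 16 joint states.  Category follows from the pattern:
    identical per-tissue statuses -> no change; a "both" status in
    exactly one tissue (or in either tissue of a differing pair) ->
    poised; otherwise the induced tissue strictly gaining activity
    (gains ac and/or loses me3) -> activation, the reverse -> repression.
    """
    s_un = state.status("uninduced")
    s_in = state.status("induced")
    index = index_table[(s_un, s_in)]
    return index, index_category(index)


def mark_state_at(
    site: tuple[str, int, int],
    peak_sets: Mapping[tuple[str, str], Sequence[Peak]],
) -> MarkState:
    """Assign the four mark booleans of ``site`` by >= 1 bp peak overlap.

    ``peak_sets`` maps (mark, condition) with mark in {"ac", "me3"} and
    condition in {"induced", "uninduced"} to pre-filtered peak lists.
    A chromosome absent from a peak set simply yields False.
    """
    chrom, start, end = site

    def overlaps(key: tuple[str, str]) -> bool:
        for p in peak_sets.get(key, ()):
            if p.chrom == chrom and p.start < end and start < p.end:
                return True
        return False

    seen_chroms = {p.chrom for peaks in peak_sets.values() for p in peaks}
    if seen_chroms and chrom not in seen_chroms:
        log.warning("site chromosome %s absent from all peak sets", chrom)

    return MarkState(
        ac_induced=overlaps(("ac", "induced")),
        me3_induced=overlaps(("me3", "induced")),
        ac_uninduced=overlaps(("ac", "uninduced")),
        me3_uninduced=overlaps(("me3", "uninduced")),
    )


def index_sites(
    peak_sets: Mapping[tuple[str, str], Sequence[Peak]],
    chip_time: int,
    gap: int = 100,
    index_table: Mapping[tuple[str, str], int] = DEFAULT_INDEX_TABLE,
) -> list[IndexedSite]:
    """Merge the four filtered peak sets of one ChIP time into unique
    sites and classify each one."""
    merged = merge_intervals(*peak_sets.values(), gap=gap)
    sites = []
    for i, m in enumerate(merged):
        state = mark_state_at((m.chrom, m.start, m.end), peak_sets)
        index, category = classify_index(state, index_table)
        sites.append(
            IndexedSite(
                chrom=m.chrom,
                start=m.start,
                end=m.end,
                chip_time=chip_time,
                index=index,
                category=category,
                site_id=f"{m.chrom}:{m.start}-{m.end}@{chip_time}h",
                source_peaks=m.sources,
            )
        )
    log.info("index_sites(%dh): %d merged sites", chip_time, len(sites))
    return sites


def sites_for_network(
    indexed_sites: Iterable[IndexedSite],
    mode: str = "activation_only",
) -> list[IndexedSite]:
    """Select the index subset entering network construction.

    ``activation_only`` -> indices {1,2,3,7}; ``activation_and_repression``
    -> {1..7}; ``all_changing`` -> {1..10}.
    """
    try:
        wanted = MODE_INDICES[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(MODE_INDICES)}")
    return [s for s in indexed_sites if s.index in wanted]


# --- broadPeak-like I/O ----------------------------------------------------

PEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "foldChange",
]


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a MACS2 broadPeak-like TSV with an extra fold-change column."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < len(PEAK_COLUMNS):
        missing = PEAK_COLUMNS[df.shape[1]:]
        raise ValueError(f"peak file {path} missing columns: {missing}")
    df.columns = PEAK_COLUMNS + list(df.columns[len(PEAK_COLUMNS):])
    return [
        Peak(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            name=str(r.name),
            signal=float(r.signalValue),
            p_score=float(r.pValue),
            q_score=float(r.qValue),
            fold_change=float(r.foldChange),
        )
        for r in df.itertuples(index=False)
    ]


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    rows = [
        [p.chrom, p.start, p.end, p.name, 0, ".", p.signal, p.p_score, p.q_score, p.fold_change]
        for p in peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def sites_to_frame(sites: Sequence[IndexedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "site_id": s.site_id,
                "chip_time": s.chip_time,
                "index": s.index,
                "category": s.category,
                "source_peaks": ",".join(s.source_peaks),
            }
            for s in sites
        ],
        columns=["chrom", "start", "end", "site_id", "chip_time", "index", "category", "source_peaks"],
    )


def frame_to_sites(df: pd.DataFrame) -> list[IndexedSite]:
    out = []
    for r in df.to_dict("records"):
        src = str(r["source_peaks"]) if not pd.isna(r["source_peaks"]) else ""
        out.append(
            IndexedSite(
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                chip_time=int(r["chip_time"]),
                index=int(r["index"]),
                category=str(r["category"]),
                site_id=str(r["site_id"]),
                source_peaks=tuple(src.split(",")) if src else (),
            )
        )
    return out
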