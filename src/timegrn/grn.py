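"""Signed, time-resolved network assembly from expression calls and
motif-bearing chromatin sites.

At each network time point, every candidate target whose direction call
is nonzero collects the regulators hitting the selected-category sites
of its locus at the matching ChIP epoch.  A regulator must itself carry
a nonzero direction at the same time point or the immediately preceding
one; matching directions give a positive edge, opposing directions a
negative one (the rule is reversed at repression-category sites, where
an unexpressed regulator yields no edge at all).  Duplicate edges
arising from multiple supporting sites are collapsed, and genes with no
interactions anywhere are pruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from timegrn.chromatin import (
    ACTIVATION,
    MODE_INDICES,
    POISED,
    REPRESSION,
    IndexedSite,
    merge_intervals,
    Peak,
)
from timegrn.config import TIME_POINTS
from timegrn.expression import DOWN, NONE, UP

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: Network time point -> ChIP epoch.  5 h chromatin serves 0-5 h (the
#: 0 h mapping is a fallback to the nearest available epoch), 9 h serves
#: 7-9 h, 12 h serves 12 h.
CHIP_EPOCH = {0: 5, 1: 5, 3: 5, 5: 5, 7: 9, 9: 9, 12: 12}


def chip_epoch(t: int) -> int:
    """ChIP time point whose sites inform the network at hour ``t``."""
    try:
        return CHIP_EPOCH[t]
    except KeyError:
        raise ValueError(f"unknown network time point {t!r}") from None


@dataclass(frozen=True)
class InteractionEdge:
    """One signed regulator -> target interaction at one time point."""

    regulator: str
    target: str
    sign: str  # positive | negative
    time: int
    sites: tuple[str, ...] = ()
    site_category: str = ACTIVATION


@dataclass
class TimedGrn:
    """Edge sets per time point plus the node direction profile."""

    profile: pd.DataFrame  # gene x TIME_POINTS directions
    edges: list[InteractionEdge] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted(self.profile.index)

    def edges_at(self, t: int) -> list[InteractionEdge]:
        return [e for e in self.edges if e.time == t]

    def graph_at(self, t: int) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.genes)
        for e in self.edges_at(t):
            g.add_edge(e.regulator, e.target, sign=e.sign)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": e.regulator,
                "target": e.target,
                "sign": e.sign,
                "time": e.time,
                "sites": ";".join(e.sites),
                "site_category": e.site_category,
            }
            for e in sorted(
                self.edges, key=lambda e: (e.time, e.regulator, e.target, e.sign)
            )
        ]
        return pd.DataFrame(
            rows, columns=["regulator", "target", "sign", "time", "sites", "site_category"]
        )


def edge_sign(
    regulator_direction: str,
    target_direction: str,
    site_category: str,
) -> str | None:
    """Sign of a putative interaction, or None when no edge is modelled.

    At activation-category sites co-regulation gives a positive and
    opposition a negative interaction; at repression-category sites the
    rule is reversed.  No edge is modelled when either direction is
    ``none``.
    """
    if regulator_direction == NONE or target_direction == NONE:
        return None
    same = regulator_direction == target_direction
    if site_category == ACTIVATION or site_category == POISED:
        return POSITIVE if same else NEGATIVE
    if site_category == REPRESSION:
        return NEGATIVE if same else POSITIVE
    return None


def _effective_direction(profile: pd.DataFrame, gene: str, t: int) -> str:
    """Direction at ``t``, falling back to the immediately preceding
    time point ("simultaneously or just before")."""
    d = profile.loc[gene, t]
    if d != NONE:
        return d
    idx = TIME_POINTS.index(t)
    if idx == 0:
        return NONE
    return profile.loc[gene, TIME_POINTS[idx - 1]]


def infer_edges_at(
    t: int,
    profile: pd.DataFrame,
    site_hits: pd.DataFrame,
    loci_by_gene: Mapping[str, Sequence[str]],
    mode: str = "activation_only",
) -> list[InteractionEdge]:
    """Raw (pre-dedup) edges at one network time point.

    ``site_hits`` is the motif-hit table (site_id, tf_gene, chip_time,
    site_index, site_category, ...); ``loci_by_gene`` maps each candidate
    gene to the site ids inside its locus.  Only hits at the matching
    ChIP epoch in the selected index subset contribute.
    """
    epoch = chip_epoch(t)
    wanted = MODE_INDICES[mode]
    edges: list[InteractionEdge] = []
    if site_hits.empty:
        return edges
    hits = site_hits[
        (site_hits["chip_time"] == epoch) & (site_hits["site_index"].isin(wanted))
    ]
    for target in sorted(loci_by_gene):
        if target not in profile.index:
            continue
        t_dir = profile.loc[target, t]
        if t_dir == NONE:
            continue
        target_sites = set(loci_by_gene[target])
        sub = hits[hits["site_id"].isin(target_sites)]
        for row in sub.itertuples(index=False):
            regulator = row.tf_gene
            if regulator not in profile.index:
                continue
            r_dir = _effective_direction(profile, regulator, t)
            if r_dir == NONE:
                continue
            sign = edge_sign(r_dir, t_dir, row.site_category)
            if sign is None:
                continue
            edges.append(
                InteractionEdge(
                    regulator=regulator,
                    target=target,
                    sign=sign,
                    time=t,
                    sites=(row.site_id,),
                    site_category=row.site_category,
                )
            )
    return edges


def dedup_edges(edges: Iterable[InteractionEdge]) -> list[InteractionEdge]:
    """Unique edges on (regulator, target, sign, time); site ids unioned."""
    grouped: dict[tuple, dict] = {}
    for e in edges:
        key = (e.regulator, e.target, e.sign, e.time)
        if key not in grouped:
            grouped[key] = {"sites": set(e.sites), "category": e.site_category}
        else:
            grouped[key]["sites"].update(e.sites)
    return [
        InteractionEdge(
            regulator=k[0], target=k[1], sign=k[2], time=k[3],
            sites=tuple(sorted(v["sites"])), site_category=v["category"],
        )
        for k, v in sorted(grouped.items())
    ]


def prune_isolated(grn: TimedGrn) -> tuple[TimedGrn, list[str]]:
    """Drop genes with neither input nor output interactions anywhere."""
    connected = {e.regulator for e in grn.edges} | {e.target for e in grn.edges}
    removed = sorted(set(grn.profile.index) - connected)
    pruned = TimedGrn(profile=grn.profile.drop(index=removed), edges=list(grn.edges))
    if removed:
        log.info("prune_isolated: removed %d genes: %s", len(removed), ",".join(removed))
    return pruned, removed


def build_grn(
    profile: pd.DataFrame,
    site_hits: pd.DataFrame,
    loci_by_gene: Mapping[str, Sequence[str]],
    mode: str = "activation_only",
    time_points: Sequence[int] = TIME_POINTS,
) -> tuple[TimedGrn, list[str]]:
    """Assemble, deduplicate and prune the full timed network."""
    raw: list[InteractionEdge] = []
    for t in time_points:
        raw.extend(infer_edges_at(t, profile, site_hits, loci_by_gene, mode=mode))
    grn = TimedGrn(profile=profile, edges=dedup_edges(raw))
    log.info("build_grn: %d raw -> %d unique edges", len(raw), len(grn.edges))
    return prune_isolated(grn)


# --- site-resolved subnetwork ----------------------------------------------


@dataclass
class SubnetworkNode:
    """A merged regulatory site treated as an independent component."""

    node_id: str
    chrom: str
    start: int
    end: int
    #: chip time -> (index, category) of the constituent site(s)
    states: dict[int, tuple[int, str]] = field(default_factory=dict)
    member_sites: tuple[str, ...] = ()


@dataclass
class Subnetwork:
    target: str
    nodes: list[SubnetworkNode]
    #: TF -> site-node edges, tagged with time and sign
    edges: list[dict]


def build_subnetwork(
    target: str,
    profile: pd.DataFrame,
    sites: Sequence[IndexedSite],
    site_hits: pd.DataFrame,
    locus_site_ids: Sequence[str],
    merge_gap: int = 500,
    time_points: Sequence[int] = TIME_POINTS,
) -> Subnetwork:
    """Site-resolved network of one target gene.

    Sites of indices 1-7 from all ChIP epochs inside the target's locus
    are merged across time (bedtools semantics, 500 bp default gap);
    each merged site becomes one node that receives TF edges at the
    times its per-epoch state supports, with the activation/repression
    sign rules applied per constituent state.
    """
    wanted = MODE_INDICES["activation_and_repression"]
    pool = [
        s
        for s in sites
        if s.site_id in set(locus_site_ids) and s.index in wanted
    ]
    as_peaks = [
        Peak(chrom=s.chrom, start=s.start, end=s.end, name=s.site_id) for s in pool
    ]
    by_id = {s.site_id: s for s in pool}
    merged = merge_intervals(as_peaks, gap=merge_gap) if as_peaks else []

    nodes = []
    for i, m in enumerate(merged, start=1):
        states = {}
        for sid in m.sources:
            s = by_id[sid]
            states[s.chip_time] = (s.index, s.category)
        nodes.append(
            SubnetworkNode(
                node_id=f"{target}_site{i}",
                chrom=m.chrom,
                start=m.start,
                end=m.end,
                states=states,
                member_sites=tuple(sorted(set(m.sources))),
            )
        )

    edges = []
    if not site_hits.empty:
        for node in nodes:
            member = set(node.member_sites)
            sub = site_hits[site_hits["site_id"].isin(member)]
            for t in time_points:
                epoch = chip_epoch(t)
                if epoch not in node.states:
                    continue
                _, category = node.states[epoch]
                t_dir = profile.loc[target, t] if target in profile.index else NONE
                if t_dir == NONE:
                    continue
                for row in sub[sub["chip_time"] == epoch].itertuples(index=False):
                    regulator = row.tf_gene
                    if regulator not in profile.index:
                        continue
                    r_dir = _effective_direction(profile, regulator, t)
                    if r_dir == NONE:
                        continue
                    sign = edge_sign(r_dir, t_dir, category)
                    if sign is None:
                        continue
                    edges.append(
                        {
                            "regulator": regulator,
                            "site_node": node.node_id,
                            "sign": sign,
                            "time": t,
                            "category": category,
                        }
                    )
    # dedup (regulator, site_node, sign, time)
    seen = set()
    unique = []
    for e in sorted(edges, key=lambda d: (d["time"], d["regulator"], d["site_node"], d["sign"])):
        key = (e["regulator"], e["site_node"], e["sign"], e["time"])
        if key not in seen:
            seen.add(key)
            unique.append(e)
    return Subnetwork(target=target, nodes=nodes, edges=unique)


def edges_from_frame(df: pd.DataFrame) -> list[InteractionEdge]:
    edges = []
    for r in df.to_dict("records"):
        sites = str(r.get("sites", "")) if not pd.isna(r.get("sites", "")) else ""
        edges.append(
            InteractionEdge(
                regulator=str(r["regulator"]),
                target=str(r["target"]),
                sign=str(r["sign"]),
                time=int(r["time"]),
                sites=tuple(sites.split(";")) if sites else (),
                site_category=str(r.get("site_category", ACTIVATION)),
            )
        )
    return edges
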