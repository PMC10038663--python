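"""Per-gene, per-time direction calls from two expression platforms.

RNA-seq FPKM tables are classified with abundance-gated fold-change
rules (including the special time-zero rule), nCounter assays are
normalized (positive-control and housekeeping lane factors, background
subtraction) and tested for differential expression, and the two call
sets are consolidated into one integrated time-course profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from timegrn.config import NANO_TIMES, RNASEQ_TIMES, TIME_POINTS

log = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"

_EPS = 1e-12


def _ratio(num: float, den: float) -> float:
    """Fold change with a +inf convention for a zero denominator."""
    if den == 0:
        return math.inf
    return num / den


def classify_fpkm(
    fpkm_induced: float,
    fpkm_uninduced: float,
    up_fc: float = 1.5,
    down_fc: float = 0.5,
    min_fpkm: float = 10.0,
) -> str:
    """Direction call for one gene at one time point from FPKM values.

    ``up`` requires induced abundance above ``min_fpkm`` and fold change
    (induced/uninduced) above ``up_fc``; ``down`` requires uninduced
    abundance above ``min_fpkm`` and fold change below ``down_fc``.
    A zero uninduced value makes the fold change +inf (up path only).
    """
    if fpkm_induced < 0 or fpkm_uninduced < 0:
        raise ValueError("FPKM values must be non-negative")
    fc = _ratio(fpkm_induced, fpkm_uninduced)
    if fpkm_induced > min_fpkm and fc > up_fc:
        return UP
    if fpkm_uninduced > min_fpkm and fc < down_fc:
        return DOWN
    return NONE


def classify_time_zero(
    unind_0h: float,
    ind_5h: float,
    unind_5h: float,
    min_fpkm: float = 10.0,
    up_fc: float = 1.5,
) -> str:
    """Direction call at 0 h (only ``up`` is defined at this time).

    A gene is up at 0 h when the 0 h uninduced FPKM exceeds the
    abundance gate, its fold change against the 5 h induced tissue
    exceeds ``up_fc``, and the 5 h uninduced FPKM both exceeds the gate
    and exceeds the 5 h induced value.
    """
    if min(unind_0h, ind_5h, unind_5h) < 0:
        raise ValueError("FPKM values must be non-negative")
    if (
        unind_0h > min_fpkm
        and _ratio(unind_0h, ind_5h) > up_fc
        and unind_5h > min_fpkm
        and unind_5h > ind_5h
    ):
        return UP
    return NONE


@dataclass(frozen=True)
class DeseqRow:
    """One row of an upstream differential-expression table."""

    gene_id: str
    log2_fc: float
    p_value: float
    induced_base_mean: float
    uninduced_base_mean: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def select_candidates(row: DeseqRow) -> str:
    """Classify a DE row as up-candidate, down-candidate or rejected.

    Up-candidates need log2 FC >= 1.2, p < 0.05 and induced base mean
    >= 45; down-candidates need log2 FC <= -1.2, p < 0.05 and uninduced
    base mean >= 200.
    """
    if row.log2_fc >= 1.2 and row.p_value < 0.05 and row.induced_base_mean >= 45:
        return "up-candidate"
    if row.log2_fc <= -1.2 and row.p_value < 0.05 and row.uninduced_base_mean >= 200:
        return "down-candidate"
    return "rejected"


# --- nCounter normalization -------------------------------------------------

ENDOGENOUS = "endogenous"
POSITIVE = "positive"
NEGATIVE = "negative"
HOUSEKEEPING = "housekeeping"

PROBE_CLASSES = (ENDOGENOUS, POSITIVE, NEGATIVE, HOUSEKEEPING)


@dataclass
class NanoStringAssay:
    """One nCounter lane: raw probe counts plus QC metadata."""

    assay_id: str
    counts: dict[str, float]
    probe_classes: dict[str, str]
    fields_of_view: int = 600
    binding_density: float = 1.0
    meta: dict = field(default_factory=dict)

    def probes(self, probe_class: str) -> list[str]:
        return sorted(p for p, c in self.probe_classes.items() if c == probe_class)

    def qc_pass(self) -> bool:
        return self.fields_of_view == 600 and 0.05 <= self.binding_density <= 2.25


def _geomean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("geometric mean undefined for non-positive counts")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass
class NormalizationResult:
    """Normalized endogenous counts and per-lane factors/diagnostics."""

    counts: pd.DataFrame  # endogenous probes x assays
    plnf: dict[str, float]
    lsnf: dict[str, float]
    background: dict[str, float]
    excluded: list[str]


def nanostring_normalize(assays: Sequence[NanoStringAssay]) -> NormalizationResult:
    """Normalize nCounter lanes and background-subtract endogenous counts.

    Per passing lane *a*: PLNF_a = (mean over lanes of the geometric mean
    of the six positive probes) / positive geomean of *a*; negative,
    endogenous and housekeeping counts are scaled by PLNF_a.  LSNF_a is
    computed identically from housekeeping geomeans of the PLNF-scaled
    data and applied on top.  Background (per lane mean + 2 SD of the
    normalized negative probes) is subtracted from endogenous counts,
    negatives are clipped to 0, and zeros are replaced with 1.

    Lanes failing QC (fields of view != 600 or binding density outside
    [0.05, 2.25]) are excluded with a log record.
    """
    passing = []
    excluded = []
    for a in assays:
        if a.qc_pass():
            passing.append(a)
        else:
            excluded.append(a.assay_id)
            log.warning(
                "assay %s failed QC (fov=%s, density=%s); excluded",
                a.assay_id, a.fields_of_view, a.binding_density,
            )
    if not passing:
        raise ValueError("no assay passed QC")
    for a in passing:
        for cls in (POSITIVE, NEGATIVE, HOUSEKEEPING):
            if not a.probes(cls):
                raise ValueError(f"assay {a.assay_id} lacks {cls} probes")

    pos_geo = {a.assay_id: _geomean([a.counts[p] for p in a.probes(POSITIVE)]) for a in passing}
    mean_pos = float(np.mean(list(pos_geo.values())))
    plnf = {aid: mean_pos / g for aid, g in pos_geo.items()}

    hk_geo = {
        a.assay_id: _geomean([a.counts[p] * plnf[a.assay_id] for p in a.probes(HOUSEKEEPING)])
        for a in passing
    }
    mean_hk = float(np.mean(list(hk_geo.values())))
    lsnf = {aid: mean_hk / g for aid, g in hk_geo.items()}

    background = {}
    endo_cols = {}
    endo_probes = sorted({p for a in passing for p in a.probes(ENDOGENOUS)})
    for a in passing:
        f = plnf[a.assay_id] * lsnf[a.assay_id]
        neg = np.array([a.counts[p] for p in a.probes(NEGATIVE)], dtype=float) * f
        bg = float(neg.mean() + 2.0 * neg.std(ddof=1))
        background[a.assay_id] = bg
        col = []
        for p in endo_probes:
            v = a.counts[p] * f - bg
            v = max(v, 0.0)
            col.append(1.0 if v == 0.0 else v)
        endo_cols[a.assay_id] = col

    counts = pd.DataFrame(endo_cols, index=endo_probes)
    return NormalizationResult(counts=counts, plnf=plnf, lsnf=lsnf, background=background, excluded=excluded)


def nanostring_de(
    norm_induced: Sequence[float],
    norm_uninduced: Sequence[float],
    up_fc: float = 1.2,
    down_fc: float = 0.8,
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """(FC, p, direction) from normalized replicate counts.

    FC = mean(induced)/mean(uninduced) (+inf on a zero denominator).
    The p-value is a two-tailed equal-variance (pooled) t-test on the
    replicate counts.  A zero pooled variance yields p = 0 for unequal
    means and direction ``none`` for equal means.
    """
    ind = np.asarray(norm_induced, dtype=float)
    unind = np.asarray(norm_uninduced, dtype=float)
    if len(ind) < 2 or len(unind) < 2:
        raise ValueError("need >= 2 replicates per side")
    fc = _ratio(float(ind.mean()), float(unind.mean()))

    if ind.var(ddof=1) < _EPS and unind.var(ddof=1) < _EPS:
        p = 1.0 if math.isclose(ind.mean(), unind.mean(), rel_tol=1e-9, abs_tol=1e-12) else 0.0
    else:
        p = float(stats.ttest_ind(ind, unind, equal_var=True).pvalue)

    if fc >= up_fc and p <= alpha:
        return fc, p, UP
    if fc <= down_fc and p <= alpha:
        return fc, p, DOWN
    return fc, p, NONE


# --- platform tables -> calls ----------------------------------------------


def rnaseq_calls(
    fpkm: pd.DataFrame,
    min_fpkm: float = 10.0,
    up_fc: float = 1.5,
    down_fc: float = 0.5,
) -> pd.DataFrame:
    """Direction calls (gene x {0,5,9,12} h) from an FPKM table.

    ``fpkm`` columns follow the ``<condition>_<time>`` contract, e.g.
    ``induced_5``/``uninduced_5``; rows are gene ids.  The 0 h call uses
    the time-zero rule, later calls the plain fold-change rule.
    """
    out = {}
    for gene, row in fpkm.iterrows():
        calls = {
            0: classify_time_zero(
                row["uninduced_0"], row["induced_5"], row["uninduced_5"],
                min_fpkm=min_fpkm, up_fc=up_fc,
            )
        }
        for t in RNASEQ_TIMES[1:]:
            calls[t] = classify_fpkm(
                row[f"induced_{t}"], row[f"uninduced_{t}"],
                up_fc=up_fc, down_fc=down_fc, min_fpkm=min_fpkm,
            )
        out[gene] = calls
    return pd.DataFrame.from_dict(out, orient="index").reindex(columns=list(RNASEQ_TIMES))


def nanostring_calls(
    assays: Sequence[NanoStringAssay],
    up_fc: float = 1.2,
    down_fc: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Direction calls (gene x {1,3,5,7,9,12} h) from nCounter lanes.

    Lane metadata must carry ``time`` (hours), ``condition`` and
    ``replicate``; endogenous probe ids are gene ids.  All lanes are
    normalized together, then each time point is tested induced vs
    uninduced across replicates.
    """
    norm = nanostring_normalize(assays)
    meta = {a.assay_id: a.meta for a in assays if a.assay_id in norm.counts.columns}
    times = sorted({int(m["time"]) for m in meta.values()})
    out = {}
    for gene in norm.counts.index:
        calls = {}
        for t in times:
            ind_cols = [aid for aid, m in meta.items() if int(m["time"]) == t and m["condition"] == "induced"]
            un_cols = [aid for aid, m in meta.items() if int(m["time"]) == t and m["condition"] == "uninduced"]
            if len(ind_cols) < 2 or len(un_cols) < 2:
                calls[t] = NONE
                continue
            _, _, direction = nanostring_de(
                norm.counts.loc[gene, ind_cols].to_numpy(),
                norm.counts.loc[gene, un_cols].to_numpy(),
                up_fc=up_fc, down_fc=down_fc, alpha=alpha,
            )
            calls[t] = direction
        out[gene] = calls
    return pd.DataFrame.from_dict(out, orient="index").reindex(columns=times)


@dataclass
class IntegrationResult:
    profile: pd.DataFrame  # gene x TIME_POINTS, values in {up, down, none}
    dropped: dict[str, str]  # gene -> reason


def integrate_platforms(
    rnaseq: pd.DataFrame,
    nanostring: pd.DataFrame,
    shared_times: Sequence[int] = (5, 9, 12),
) -> IntegrationResult:
    """Consolidate the two platforms into one integrated profile.

    A gene is retained iff no shared time point carries contradictory
    nonzero directions (up vs down).  The retained profile takes the
    RNA-seq calls at 0/5/9/12 h and the nCounter calls at 1/3/7 h.
    Genes absent from either platform are dropped with a reason.
    """
    profile_rows = {}
    dropped: dict[str, str] = {}
    for gene in sorted(set(rnaseq.index) | set(nanostring.index)):
        if gene not in rnaseq.index:
            dropped[gene] = "missing from RNA-seq calls"
            continue
        if gene not in nanostring.index:
            dropped[gene] = "missing from nCounter calls"
            continue
        conflict = None
        for t in shared_times:
            a, b = rnaseq.loc[gene, t], nanostring.loc[gene, t]
            if {a, b} == {UP, DOWN}:
                conflict = t
                break
        if conflict is not None:
            dropped[gene] = f"contradictory directions at {conflict} h"
            continue
        row = {}
        for t in TIME_POINTS:
            if t in RNASEQ_TIMES:
                row[t] = rnaseq.loc[gene, t]
            else:
                row[t] = nanostring.loc[gene, t] if t in nanostring.columns else NONE
        profile_rows[gene] = row
    profile = pd.DataFrame.from_dict(profile_rows, orient="index").reindex(columns=list(TIME_POINTS))
    profile.index.name = "gene_id"
    log.info(
        "integrate_platforms: %d genes retained, %d dropped", len(profile), len(dropped)
    )
    return IntegrationResult(profile=profile, dropped=dropped)


# --- nCounter table I/O ----------------------------------------------------

NANO_COLUMNS = [
    "assay_id", "probe_id", "probe_class", "count",
    "time", "condition", "replicate", "fields_of_view", "binding_density",
]


def read_nanostring(path) -> list[NanoStringAssay]:
    """Read long-format nCounter lanes (one row per probe per lane)."""
    df = pd.read_csv(path)
    missing = set(NANO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"nCounter table missing columns: {sorted(missing)}")
    assays = []
    for aid, grp in df.groupby("assay_id", sort=True):
        first = grp.iloc[0]
        assays.append(
            NanoStringAssay(
                assay_id=str(aid),
                counts={
                    str(p): float(c) for p, c in zip(grp["probe_id"], grp["count"])
                },
                probe_classes={
                    str(p): str(c) for p, c in zip(grp["probe_id"], grp["probe_class"])
                },
                fields_of_view=int(first["fields_of_view"]),
                binding_density=float(first["binding_density"]),
                meta={
                    "time": int(first["time"]),
                    "condition": str(first["condition"]),
                    "replicate": int(first["replicate"]),
                },
            )
        )
    return assays


def write_nanostring(assays: Sequence[NanoStringAssay], path) -> None:
    rows = []
    for a in assays:
        for probe in sorted(a.counts):
            rows.append(
                {
                    "assay_id": a.assay_id,
                    "probe_id": probe,
                    "probe_class": a.probe_classes[probe],
                    "count": a.counts[probe],
                    "time": a.meta.get("time", 0),
                    "condition": a.meta.get("condition", ""),
                    "replicate": a.meta.get("replicate", 0),
                    "fields_of_view": a.fields_of_view,
                    "binding_density": a.binding_density,
                }
            )
    pd.DataFrame(rows, columns=NANO_COLUMNS).to_csv(path, index=False)
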