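"""Synthetic scenario generator with a planted ground-truth network.

Produces a small genome, gene annotation, CTCF peaks, per-mark/condition
peak tables, an FPKM table, replicate nCounter lanes with lane effects,
and a motif library -- all mutually consistent, so that running the full
pipeline at zero noise recovers exactly the planted edge set.

Design: genes occupy equally spaced non-overlapping slots, each flanked
by its own CTCF peaks; regulatory sites sit between gene body and the
downstream CTCF peak; planted motif instances are exact consensus
copies of sharp PWMs (count 1000 for the consensus base), so only exact
matches clear the score-10 cutoff and chance hits are vanishingly rare
(and explicitly checked for).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from timegrn.chromatin import Peak, write_peaks
from timegrn.expression import (
    DOWN,
    NONE,
    UP,
    NanoStringAssay,
    write_nanostring,
)
from timegrn.loci import GeneAnnotation
from timegrn.motifs import PositionWeightMatrix, reverse_complement, write_meme

log = logging.getLogger(__name__)

# local copy of the network-time -> ChIP-epoch map, so the planted truth
# is stated independently of the pipeline implementation
_EPOCH = {0: 5, 1: 5, 3: 5, 5: 5, 7: 9, 9: 9, 12: 12}

_SITE_LEN = 60
_SITE_SPACING = 600


class SizingError(ValueError):
    """The requested genome cannot hold all loci without overlap."""


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic scenario; the seed fully determines output."""

    n_genes: int = 20
    genome_length: int | None = None  # auto-sized when None
    time_points: tuple[int, ...] = (0, 1, 3, 5, 7, 9, 12)
    chip_times: tuple[int, ...] = (5, 9, 12)
    n_planted_edges: int = 30  # planted (regulator, target, epoch) supports
    motif_length: int = 12
    noise_sd: float = 0.0  # lognormal sd on expression values
    lane_scale_range: tuple[float, float] = (0.7, 1.4)
    gc: float = 0.5
    seed: int = 0
    n_decoy_genes: int = 2  # expressed genes with no interactions
    decoy_motifs: bool = False  # plant an unmapped decoy motif in every site
    include_time_zero: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 6 <= self.motif_length <= 12:
            # 2L must exceed the score-10 cutoff while a single mismatch
            # (penalty ~15.3 for count-1000 columns) must stay below it
            raise ValueError("motif_length must be in [6, 12]")
        lo, hi = self.lane_scale_range
        if not 0 < lo <= hi:
            raise ValueError("lane_scale_range must be a positive interval")


@dataclass
class PlantedSupport:
    """One planted (regulator, target) support: a motif in a site."""

    regulator: str
    target: str
    epoch: int
    site_id: str
    motif_id: str
    offset: int
    strand: str


@dataclass
class GroundTruth:
    """Everything the pipeline is expected to recover."""

    profile: pd.DataFrame  # intended gene x time directions
    supports: list[PlantedSupport]
    #: the expected final edge set: (regulator, target, sign, time)
    edges: set[tuple[str, str, str, int]]
    #: site_id -> (epoch, (ac_ind, me3_ind, ac_unind, me3_unind))
    site_states: dict[str, tuple[int, tuple[bool, bool, bool, bool]]]


@dataclass
class Scenario:
    """In-memory bundle of all generated inputs plus the ground truth."""

    config: ScenarioConfig
    genome: str
    chrom: str
    genes: list[GeneAnnotation]
    ctcf: list[Peak]
    peak_tables: dict[tuple[str, str, int], list[Peak]]  # (mark, cond, time)
    fpkm: pd.DataFrame
    nanostring: list[NanoStringAssay]
    pwms: list[PositionWeightMatrix]
    ground_truth: GroundTruth
    max_search: int  # locus search window suited to the layout

    def write(self, out_dir: str | Path) -> Path:
        """Write the bundle as plain-text files (deterministic bytes)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        with open(out / "genome.fa", "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.genome), 60):
                fh.write(self.genome[i : i + 60] + "\n")

        with open(out / "genes.gtf", "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\ttimegrn_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

        with open(out / "ctcf.bed", "w") as fh:
            for p in self.ctcf:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t{p.signal}\n"
                )

        for (mark, cond, t), peaks in sorted(self.peak_tables.items()):
            write_peaks(peaks, out / f"peaks_{mark}_{cond}_{t}h.tsv")

        fpkm = self.fpkm.copy()
        fpkm.index.name = "gene_id"
        fpkm.to_csv(out / "fpkm.csv")

        write_nanostring(self.nanostring, out / "nanostring.csv")
        write_meme(self.pwms, out / "motifs.meme")

        gt = self.ground_truth
        prof = gt.profile.copy()
        prof.index.name = "gene_id"
        prof.to_csv(out / "truth_profile.csv")
        pd.DataFrame(
            sorted(gt.edges),
            columns=["regulator", "target", "sign", "time"],
        ).to_csv(out / "truth_edges.csv", index=False)
        pd.DataFrame(
            [
                {
                    "regulator": s.regulator,
                    "target": s.target,
                    "epoch": s.epoch,
                    "site_id": s.site_id,
                    "motif_id": s.motif_id,
                    "offset": s.offset,
                    "strand": s.strand,
                }
                for s in gt.supports
            ]
        ).to_csv(out / "truth_supports.csv", index=False)

        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self.config).items()
        }
        cfg["max_search"] = self.max_search
        cfg["chrom"] = self.chrom
        (out / "scenario.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
        return out


def plant_motif(
    sequence: str,
    pwm: PositionWeightMatrix,
    offset: int,
    strand: str = "+",
) -> str:
    """Overwrite a window of ``sequence`` with the PWM consensus.

    The planted window scores the PWM maximum on the requested strand;
    the rest of the sequence is untouched.
    """
    consensus = pwm.consensus
    if offset < 0 or offset + len(consensus) > len(sequence):
        raise ValueError(
            f"offset {offset} + motif length {len(consensus)} exceeds sequence "
            f"length {len(sequence)}"
        )
    insert = consensus if strand == "+" else reverse_complement(consensus)
    return sequence[:offset] + insert + sequence[offset + len(insert):]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def _profiles(cfg: ScenarioConfig) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """Intended direction profiles plus (tf, target, decoy) gene lists."""
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    decoys = genes[cfg.n_genes - cfg.n_decoy_genes :] if cfg.n_decoy_genes else []
    active = genes[: cfg.n_genes - len(decoys)]
    n_tfs = max(3, len(active) // 3)
    tfs = active[:n_tfs]

    onsets: dict[str, tuple[int, str]] = {}
    zero_genes: list[str] = []
    if cfg.include_time_zero and len(active) >= 4:
        # one TF and one non-TF with the time-zero pattern (up at 0 h,
        # down from 1 h on)
        zero_genes = [tfs[0], active[n_tfs]]
    tf_onset_cycle = [1, 3, 5]
    target_onset_cycle = [1, 3, 5, 7, 9, 12]
    i_tf = i_tg = 0
    for g in active:
        if g in zero_genes:
            onsets[g] = (0, "zero")
        elif g in tfs:
            onsets[g] = (tf_onset_cycle[i_tf % len(tf_onset_cycle)], UP if i_tf % 4 else DOWN)
            i_tf += 1
        else:
            onsets[g] = (
                target_onset_cycle[i_tg % len(target_onset_cycle)],
                UP if i_tg % 3 else DOWN,
            )
            i_tg += 1
    for g in decoys:
        onsets[g] = (5, UP)

    rows = {}
    for g in genes:
        onset, kind = onsets[g]
        row = {}
        for t in cfg.time_points:
            if kind == "zero":
                row[t] = UP if t == 0 else DOWN
            elif t == 0:
                row[t] = NONE
            else:
                row[t] = kind if t >= onset else NONE
        rows[g] = row
    profile = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(cfg.time_points)
    )
    profile.index.name = "gene_id"
    return profile, tfs, active, decoys


def _pick_supports(
    cfg: ScenarioConfig,
    profile: pd.DataFrame,
    tfs: list[str],
    active: list[str],
    rng: np.random.Generator,
) -> list[tuple[str, str, int]]:
    """Choose (regulator, target, epoch) triples that each yield >=1 edge."""

    def times_for(reg: str, tgt: str, epoch: int) -> list[int]:
        out = []
        for t in cfg.time_points:
            if _EPOCH[t] != epoch:
                continue
            if profile.loc[tgt, t] == NONE:
                continue
            if _effective(profile, reg, t, cfg.time_points) == NONE:
                continue
            out.append(t)
        return out

    combos = [
        (r, tg, e)
        for e in cfg.chip_times
        for tg in active
        for r in tfs
        if r != tg and times_for(r, tg, e)
    ]
    if len(combos) < cfg.n_planted_edges:
        raise ValueError(
            f"cannot plant {cfg.n_planted_edges} supports; only {len(combos)} "
            "valid (regulator, target, epoch) combinations exist"
        )
    order = [combos[i] for i in rng.permutation(len(combos))]

    # guarantee a 0 h edge when the scenario carries time-zero genes
    zero_pairs = [c for c in combos if 0 in times_for(*c)]
    chosen: list[tuple[str, str, int]] = zero_pairs[:1]
    for c in order:
        if len(chosen) >= cfg.n_planted_edges:
            break
        if c not in chosen:
            chosen.append(c)
    return sorted(chosen)


def _effective(profile: pd.DataFrame, gene: str, t: int, time_points: Sequence[int]) -> str:
    d = profile.loc[gene, t]
    if d != NONE:
        return d
    idx = list(time_points).index(t)
    if idx == 0:
        return NONE
    return profile.loc[gene, time_points[idx - 1]]


def _make_pwms(
    cfg: ScenarioConfig,
    tfs: list[str],
    rng: np.random.Generator,
) -> tuple[dict[str, PositionWeightMatrix], PositionWeightMatrix | None]:
    """Sharp, mutually distant PWMs (one per TF, plus an optional decoy)."""
    L = cfg.motif_length
    consensi: list[str] = []

    def far_enough(cand: str) -> bool:
        if cand == reverse_complement(cand):
            return False
        for other in consensi:
            for ref in (other, reverse_complement(other)):
                if sum(a != b for a, b in zip(cand, ref)) < 3:
                    return False
        return True

    needed = len(tfs) + (1 if cfg.decoy_motifs else 0)
    while len(consensi) < needed:
        cand = _random_seq(rng, L, 0.5)
        if far_enough(cand):
            consensi.append(cand)

    def sharp(motif_id: str, consensus: str, tf: tuple[str, ...]) -> PositionWeightMatrix:
        counts = np.zeros((L, 4))
        for i, b in enumerate(consensus):
            counts[i, "ACGT".index(b)] = 1000.0
        return PositionWeightMatrix(motif_id=motif_id, counts=counts, tf_genes=tf)

    pwms = {
        tf: sharp(f"M{i:03d}", consensi[i], (tf,)) for i, tf in enumerate(tfs)
    }
    decoy = (
        sharp("M_DECOY", consensi[-1], ("DECOYTF",)) if cfg.decoy_motifs else None
    )
    return pwms, decoy


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full bundle; identical configs give identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"

    profile, tfs, active, decoys = _profiles(cfg)
    supports_rti = _pick_supports(cfg, profile, tfs, active, rng)
    pwms_by_tf, decoy_pwm = _make_pwms(cfg, tfs, rng)

    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    planted_per_gene: dict[str, list[tuple[str, int]]] = {g: [] for g in genes}
    for r, tg, e in supports_rti:
        planted_per_gene[tg].append((r, e))

    # --- layout -------------------------------------------------------------
    max_sites = max(len(v) for v in planted_per_gene.values()) + 1  # + no-change site
    sites_span = max_sites * _SITE_SPACING + _SITE_LEN
    required_slot = 3000 + sites_span + 500 + 200 + 800
    slot = (
        cfg.genome_length // cfg.n_genes
        if cfg.genome_length
        else int(math.ceil(required_slot / 1000.0)) * 1000
    )
    if slot < required_slot:
        raise SizingError(
            f"genome_length {cfg.genome_length} gives {slot} bp per gene but the "
            f"layout needs {required_slot} bp (gene body, {max_sites} sites at "
            f"{_SITE_SPACING} bp spacing, flanking CTCF peaks)"
        )
    genome_length = cfg.genome_length or slot * cfg.n_genes

    genome = list(_random_seq(rng, genome_length, cfg.gc))

    gene_ann: list[GeneAnnotation] = []
    ctcf: list[Peak] = []
    site_coords: dict[str, tuple[int, int]] = {}  # site_id -> interval
    site_states: dict[str, tuple[int, tuple[bool, bool, bool, bool]]] = {}
    supports: list[PlantedSupport] = []
    peak_tables: dict[tuple[str, str, int], list[Peak]] = {
        (mark, cond, t): []
        for mark in ("H3K27ac", "H3K27me3")
        for cond in ("induced", "uninduced")
        for t in cfg.chip_times
    }

    for gi, g in enumerate(genes):
        base = gi * slot
        up_ctcf = Peak(chrom, base + 1000, base + 1200, name=f"CTCF_{g}_up", signal=10.0)
        gene_iv = (base + 2000, base + 2400)
        gene_ann.append(GeneAnnotation(g, chrom, *gene_iv))
        ctcf.append(up_ctcf)

        next_site = base + 3000
        # planted activation sites (one per support)
        for si, (reg, epoch) in enumerate(sorted(planted_per_gene[g])):
            s_start, s_end = next_site, next_site + _SITE_LEN
            next_site += _SITE_SPACING
            site_id = f"{chrom}:{s_start}-{s_end}@{epoch}h"
            site_coords[site_id] = (s_start, s_end)
            site_states[site_id] = (epoch, (True, False, False, False))  # index 1
            peak_tables[("H3K27ac", "induced", epoch)].append(
                Peak(chrom, s_start, s_end, name=f"ac_ind_{g}_{si}",
                     signal=5.0, p_score=6.0, q_score=4.0, fold_change=2.0)
            )
            pwm = pwms_by_tf[reg]
            strand = "+" if (si + gi) % 2 == 0 else "-"
            offset = 10
            seq = "".join(genome[s_start:s_end])
            seq = plant_motif(seq, pwm, offset, strand)
            if decoy_pwm is not None:
                seq = plant_motif(seq, decoy_pwm, 30 + cfg.motif_length - 12, "+")
            genome[s_start:s_end] = list(seq)
            supports.append(
                PlantedSupport(
                    regulator=reg, target=g, epoch=epoch, site_id=site_id,
                    motif_id=pwm.motif_id, offset=offset, strand=strand,
                )
            )

        # one no-change site per gene (acetylated in both conditions, 5 h)
        s_start, s_end = next_site, next_site + _SITE_LEN
        next_site += _SITE_SPACING
        nc_id = f"{chrom}:{s_start}-{s_end}@5h"
        site_coords[nc_id] = (s_start, s_end)
        site_states[nc_id] = (5, (True, False, True, False))  # index 14
        for cond in ("induced", "uninduced"):
            peak_tables[("H3K27ac", cond, 5)].append(
                Peak(chrom, s_start, s_end, name=f"ac_{cond}_nc_{g}",
                     signal=5.0, p_score=6.0, q_score=4.0, fold_change=2.0)
            )

        down_start = next_site + 500
        ctcf.append(
            Peak(chrom, down_start, down_start + 200, name=f"CTCF_{g}_down", signal=10.0)
        )

    # sub-threshold peaks that the enrichment filter must remove
    for t in cfg.chip_times:
        peak_tables[("H3K27ac", "induced", t)].append(
            Peak(chrom, 1500, 1560, name=f"weak_{t}h",
                 signal=1.0, p_score=2.0, q_score=1.0, fold_change=1.0)
        )

    genome_str = "".join(genome)
    _check_no_spurious_hits(genome_str, site_coords, site_states, supports,
                            pwms_by_tf, decoy_pwm)

    # --- expression ---------------------------------------------------------
    fpkm = _fpkm_table(cfg, profile, rng)
    nanostring = _nanostring_assays(cfg, profile, rng)

    # --- ground-truth edge closure -----------------------------------------
    edges: set[tuple[str, str, str, int]] = set()
    for sup in supports:
        for t in cfg.time_points:
            if _EPOCH[t] != sup.epoch:
                continue
            d_t = profile.loc[sup.target, t]
            if d_t == NONE:
                continue
            d_r = _effective(profile, sup.regulator, t, cfg.time_points)
            if d_r == NONE:
                continue
            sign = "positive" if d_r == d_t else "negative"
            edges.add((sup.regulator, sup.target, sign, t))

    pwm_list = sorted(pwms_by_tf.values(), key=lambda p: p.motif_id)
    if decoy_pwm is not None:
        pwm_list.append(decoy_pwm)

    truth = GroundTruth(
        profile=profile, supports=supports, edges=edges, site_states=site_states
    )
    return Scenario(
        config=cfg,
        genome=genome_str,
        chrom=chrom,
        genes=gene_ann,
        ctcf=ctcf,
        peak_tables=peak_tables,
        fpkm=fpkm,
        nanostring=nanostring,
        pwms=pwm_list,
        ground_truth=truth,
        max_search=slot,
    )


def _check_no_spurious_hits(
    genome: str,
    site_coords: dict[str, tuple[int, int]],
    site_states: dict[str, tuple[int, tuple[bool, bool, bool, bool]]],
    supports: list[PlantedSupport],
    pwms_by_tf: dict[str, PositionWeightMatrix],
    decoy_pwm: PositionWeightMatrix | None,
) -> None:
    """Assert planted consensus strings occur in sites only where planted.

    With count-1000 columns only exact consensus copies clear the score
    cutoff, so literal string search is a sufficient spuriousness check.
    """
    planted = {(s.site_id, pwms_by_tf[s.regulator].motif_id): s for s in supports}
    all_pwms = list(pwms_by_tf.values()) + ([decoy_pwm] if decoy_pwm else [])
    for site_id, (start, end) in site_coords.items():
        seq = genome[start:end]
        for pwm in all_pwms:
            cons = pwm.consensus
            n_hits = sum(
                seq.count(pat) for pat in {cons, reverse_complement(cons)}
            )
            expected = 1 if (site_id, pwm.motif_id) in planted else 0
            if pwm is decoy_pwm and decoy_pwm is not None and site_id in {
                s.site_id for s in supports
            }:
                expected = 1
            if n_hits != expected:
                raise RuntimeError(
                    f"spurious motif occurrence: {pwm.motif_id} x{n_hits} in "
                    f"{site_id} (expected {expected}); re-seed the scenario"
                )


def _fpkm_table(
    cfg: ScenarioConfig, profile: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    high, low = 30.0, 5.0
    cols = {}
    for t in (0, 5, 9, 12):
        ind, unind = [], []
        for g in profile.index:
            d0 = profile.loc[g, 0]
            d = profile.loc[g, t]
            if d0 == UP:  # time-zero pattern: on in uninduced, off in induced
                iv = high if t == 0 else low
                uv = high
            elif d == UP:
                iv, uv = high, low
            elif d == DOWN:
                iv, uv = low, high
            else:
                iv, uv = low, low
            ind.append(iv)
            unind.append(uv)
        cols[f"induced_{t}"] = ind
        cols[f"uninduced_{t}"] = unind
    df = pd.DataFrame(cols, index=list(profile.index))
    if cfg.noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=cfg.noise_sd, size=df.shape)
        df = df * noise
    return df.round(4)


_POSITIVE_MEANS = {
    "POS_A": 2400.0, "POS_B": 1200.0, "POS_C": 600.0,
    "POS_D": 300.0, "POS_E": 150.0, "POS_F": 75.0,
}
_NEGATIVE_MEANS = {f"NEG_{c}": 4.0 for c in "ABCDEFGH"}
_HK_MEANS = {"HK_ACTB": 800.0, "HK_GAPDH": 400.0}


def _nanostring_assays(
    cfg: ScenarioConfig, profile: pd.DataFrame, rng: np.random.Generator
) -> list[NanoStringAssay]:
    """Triplicate lanes per (time, condition) with per-lane scale effects."""
    high, low = 600.0, 100.0
    nano_times = [t for t in cfg.time_points if t != 0]
    assays = []
    lo, hi = cfg.lane_scale_range
    for t in nano_times:
        for cond in ("induced", "uninduced"):
            for rep in (1, 2, 3):
                lam = float(rng.uniform(lo, hi))
                counts: dict[str, float] = {}
                classes: dict[str, str] = {}
                for probe, mean in {**_POSITIVE_MEANS, **_NEGATIVE_MEANS, **_HK_MEANS}.items():
                    val = mean * lam
                    if cfg.noise_sd > 0:
                        val = float(rng.poisson(max(val, 0.0)))
                    counts[probe] = round(val, 6)
                    classes[probe] = (
                        "positive" if probe.startswith("POS")
                        else "negative" if probe.startswith("NEG")
                        else "housekeeping"
                    )
                for g in profile.index:
                    d = profile.loc[g, t]
                    if d == UP:
                        mean = high if cond == "induced" else low
                    elif d == DOWN:
                        mean = low if cond == "induced" else high
                    else:
                        mean = low
                    val = mean * lam
                    if cfg.noise_sd > 0:
                        val *= float(rng.lognormal(0.0, cfg.noise_sd))
                        val = float(rng.poisson(max(val, 0.0)))
                    counts[g] = round(val, 6)
                    classes[g] = "endogenous"
                assays.append(
                    NanoStringAssay(
                        assay_id=f"{cond}_{t}h_r{rep}",
                        counts=counts,
                        probe_classes=classes,
                        fields_of_view=600,
                        binding_density=1.0,
                        meta={"time": t, "condition": cond, "replicate": rep},
                    )
                )
    return assays
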