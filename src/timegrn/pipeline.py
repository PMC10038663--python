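"""End-to-end orchestration over a scenario directory.

Each stage reads/writes the plain-text interchange formats so the CLI
subcommands can be chained; :func:`run_pipeline` wires them in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from timegrn import chromatin, expression, grn, loci as loci_mod, motifs as motifs_mod
from timegrn.config import PipelineConfig
from timegrn.grn import TimedGrn

log = logging.getLogger(__name__)

MARKS = {"ac": "H3K27ac", "me3": "H3K27me3"}
CONDITIONS = ("induced", "uninduced")


@dataclass
class PipelineResult:
    profile: pd.DataFrame
    dropped_genes: dict[str, str]
    sites: list[chromatin.IndexedSite]
    loci: list[loci_mod.RegulatoryLocus]
    loci_sites: dict[str, list[str]]  # gene -> site ids in its locus
    hits: pd.DataFrame
    grn: TimedGrn
    pruned: list[str]


def _scenario_meta(scenario_dir: Path) -> dict:
    meta_path = scenario_dir / "scenario.yaml"
    if meta_path.exists():
        return yaml.safe_load(meta_path.read_text()) or {}
    return {}


def chip_times(scenario_dir: str | Path) -> list[int]:
    meta = _scenario_meta(Path(scenario_dir))
    return [int(t) for t in meta.get("chip_times", (5, 9, 12))]


def load_peak_sets(
    scenario_dir: str | Path, chip_time: int, config: PipelineConfig
) -> dict[tuple[str, str], list[chromatin.Peak]]:
    """Filtered peak sets keyed by (mark, condition) for one ChIP time."""
    scenario_dir = Path(scenario_dir)
    sets = {}
    for short, mark in MARKS.items():
        for cond in CONDITIONS:
            path = scenario_dir / f"peaks_{mark}_{cond}_{chip_time}h.tsv"
            peaks = chromatin.read_peaks(path) if path.exists() else []
            sets[(short, cond)] = chromatin.filter_enriched(
                peaks,
                min_p_score=config.peak_p_score,
                min_fold_change=config.peak_fc,
                min_q_score=config.peak_q_score,
            )
    return sets


def stage_expression(
    scenario_dir: str | Path, config: PipelineConfig
) -> expression.IntegrationResult:
    scenario_dir = Path(scenario_dir)
    fpkm = pd.read_csv(scenario_dir / "fpkm.csv", index_col="gene_id")
    rna = expression.rnaseq_calls(
        fpkm, min_fpkm=config.min_fpkm, up_fc=config.up_fc, down_fc=config.down_fc
    )
    assays = expression.read_nanostring(scenario_dir / "nanostring.csv")
    nano = expression.nanostring_calls(
        assays, up_fc=config.nano_up, down_fc=config.nano_down, alpha=config.nano_p
    )
    return expression.integrate_platforms(rna, nano)


def stage_chromatin(
    scenario_dir: str | Path, config: PipelineConfig
) -> list[chromatin.IndexedSite]:
    sites: list[chromatin.IndexedSite] = []
    for t in chip_times(scenario_dir):
        peak_sets = load_peak_sets(scenario_dir, t, config)
        sites.extend(chromatin.index_sites(peak_sets, t, gap=config.merge_gap))
    return sites


def stage_loci(
    scenario_dir: str | Path,
    sites: list[chromatin.IndexedSite],
    config: PipelineConfig,
    genes: list[str] | None = None,
) -> tuple[list[loci_mod.RegulatoryLocus], dict[str, list[str]]]:
    scenario_dir = Path(scenario_dir)
    annotations = loci_mod.read_gtf_genes(scenario_dir / "genes.gtf")
    if genes is not None:
        wanted = set(genes)
        annotations = [g for g in annotations if g.gene_id in wanted]
    ctcf = loci_mod.read_ctcf_bed(scenario_dir / "ctcf.bed")
    meta = _scenario_meta(scenario_dir)
    max_search = int(meta.get("max_search", config.max_search))
    built = [loci_mod.build_locus(g, ctcf, max_search=max_search) for g in annotations]
    owned = {
        l.gene_id: sorted(s.site_id for s in loci_mod.sites_in_locus(l, sites))
        for l in built
    }
    return built, owned


def stage_scan(
    scenario_dir: str | Path,
    sites: list[chromatin.IndexedSite],
    loci_sites: dict[str, list[str]],
    grn_genes: list[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    scenario_dir = Path(scenario_dir)
    owned_ids = {sid for ids in loci_sites.values() for sid in ids}
    owned_sites = [s for s in sites if s.site_id in owned_ids]
    sequences = loci_mod.extract_sequences(owned_sites, scenario_dir / "genome.fa")
    library = motifs_mod.load_motifs([scenario_dir / "motifs.meme"], grn_genes=grn_genes)
    return motifs_mod.hits_for_gene(
        owned_sites, sequences, library, grn_genes, threshold=config.score_threshold
    )


def run_pipeline(
    scenario_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """expression -> chromatin -> loci -> motifs -> edges -> dedup -> prune."""
    config = config or PipelineConfig()
    integration = stage_expression(scenario_dir, config)
    profile = integration.profile
    sites = stage_chromatin(scenario_dir, config)
    built, owned = stage_loci(scenario_dir, sites, config, genes=list(profile.index))
    hits = stage_scan(scenario_dir, sites, owned, list(profile.index), config)
    network, pruned = grn.build_grn(profile, hits, owned, mode=config.site_mode)
    return PipelineResult(
        profile=profile,
        dropped_genes=integration.dropped,
        sites=sites,
        loci=built,
        loci_sites=owned,
        hits=hits,
        grn=network,
        pruned=pruned,
    )
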