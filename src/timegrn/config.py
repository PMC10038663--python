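"""Pipeline thresholds and their YAML (de)serialization."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Network time points (hours after induction).
TIME_POINTS = (0, 1, 3, 5, 7, 9, 12)

#: Time points covered by chromatin (ChIP) data.
CHIP_TIMES = (5, 9, 12)

#: Time points with RNA-seq coverage.
RNASEQ_TIMES = (0, 5, 9, 12)

#: Time points with nCounter coverage.
NANO_TIMES = (1, 3, 5, 7, 9, 12)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the GRN pipeline.

    Defaults reproduce the published rules: FPKM abundance gate of 10
    with fold-change cutoffs 1.5/0.5, nCounter cutoffs 1.2/0.8 at
    p <= 0.05, peak enrichment filter (p < 1e-5, FC > 1.2, q-score > 3),
    100 bp site merging, 500 kb CTCF search window, motif log-odds
    score > 10 and 500 bp cross-time merging for subnetworks.
    """

    min_fpkm: float = 10.0
    up_fc: float = 1.5
    down_fc: float = 0.5
    nano_up: float = 1.2
    nano_down: float = 0.8
    nano_p: float = 0.05
    peak_p_score: float = 5.0  # -log10 p; "p < 1e-5"
    peak_q_score: float = 3.0
    peak_fc: float = 1.2
    merge_gap: int = 100
    subnetwork_gap: int = 500
    max_search: int = 500_000
    score_threshold: float = 10.0
    core_quantile: float = 0.9
    site_mode: str = "activation_only"
    #: count sign-distinct parallel edges separately in outdegree
    outdegree_parallel: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
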