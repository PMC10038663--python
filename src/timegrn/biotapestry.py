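"""Minimal BioTapestry-style exports with a bundled round-trip parser.

Two artifacts are written: a Model Hierarchy CSV enumerating model,
region, node and link rows (signs encoded as enhance/repress) and a
Time Expression XML file encoding per-gene per-hour expression states.
The dialect is a documented minimal subset -- the testable contract is
round-trip fidelity through the parsers shipped here, not bit-exact
compatibility with the external GUI's importer.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path

import pandas as pd

from timegrn.config import TIME_POINTS
from timegrn.expression import NONE
from timegrn.grn import InteractionEdge, TimedGrn

_SIGN_TO_CSV = {"positive": "enhance", "negative": "repress"}
_CSV_TO_SIGN = {v: k for k, v in _SIGN_TO_CSV.items()}

MODEL_ID = "root"
REGION_ID = "network"


def write_model_csv(grn: TimedGrn, path: str | Path) -> None:
    """Model Hierarchy CSV: model/region/node/link rows.

    Columns: row_type, model, region, source, target, sign, time.
    Unused cells are left empty.  Deterministic ordering.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row_type", "model", "region", "source", "target", "sign", "time"])
        w.writerow(["model", MODEL_ID, "", "", "", "", ""])
        w.writerow(["region", MODEL_ID, REGION_ID, "", "", "", ""])
        for gene in grn.genes:
            w.writerow(["node", MODEL_ID, REGION_ID, "", gene, "", ""])
        for e in sorted(
            grn.edges, key=lambda e: (e.time, e.regulator, e.target, e.sign)
        ):
            w.writerow(
                ["link", MODEL_ID, REGION_ID, e.regulator, e.target,
                 _SIGN_TO_CSV[e.sign], e.time]
            )


def write_time_expression_xml(grn: TimedGrn, path: str | Path) -> None:
    """Time Expression XML: per-gene expression state at each hour."""
    root = ET.Element("TimeExpression", units="h")
    for gene in grn.genes:
        g = ET.SubElement(root, "gene", name=gene)
        for t in TIME_POINTS:
            state = grn.profile.loc[gene, t]
            ET.SubElement(g, "expr", time=str(t), state=str(state))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a") as fh:
        fh.write("\n")


def parse_model_csv(path: str | Path) -> tuple[list[str], list[InteractionEdge]]:
    """Round-trip parser for :func:`write_model_csv` output."""
    nodes: list[str] = []
    edges: list[InteractionEdge] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            kind = row["row_type"]
            if kind == "node":
                nodes.append(row["target"])
            elif kind == "link":
                edges.append(
                    InteractionEdge(
                        regulator=row["source"],
                        target=row["target"],
                        sign=_CSV_TO_SIGN[row["sign"]],
                        time=int(row["time"]),
                    )
                )
            elif kind not in {"model", "region"}:
                raise ValueError(f"unknown row type {kind!r} in {path}")
    return nodes, edges


def parse_time_expression_xml(path: str | Path) -> pd.DataFrame:
    """Round-trip parser for :func:`write_time_expression_xml` output."""
    root = ET.parse(path).getroot()
    rows = {}
    for g in root.findall("gene"):
        rows[g.get("name")] = {
            int(e.get("time")): e.get("state") for e in g.findall("expr")
        }
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(TIME_POINTS))
    if df.empty:
        df = pd.DataFrame(columns=list(TIME_POINTS))
    df.index.name = "gene_id"
    return df


def export_biotapestry(grn: TimedGrn, out_dir: str | Path) -> tuple[Path, Path]:
    """Write both artifacts into ``out_dir``; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "model_hierarchy.csv"
    xml_path = out_dir / "time_expression.xml"
    write_model_csv(grn, csv_path)
    write_time_expression_xml(grn, xml_path)
    return csv_path, xml_path


def export_bed(
    track_rows: pd.DataFrame,
    path: str | Path,
    track_name: str,
) -> None:
    """Write a browser BED track (0-based half-open, deterministic order).

    ``track_rows`` must carry chrom/start/end plus optional name, score
    and strand columns.  An empty input yields a header-only file.
    """
    df = track_rows.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df = df[["chrom", "start", "end", "name", "score", "strand"]]
    df = df.sort_values(["chrom", "start", "end", "name"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for row in df.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED track written by :func:`export_bed`."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#", "browser")):
            continue
        f = line.split("\t")
        rows.append(
            {
                "chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                "name": f[3] if len(f) > 3 else ".",
                "score": f[4] if len(f) > 4 else 0,
                "strand": f[5] if len(f) > 5 else ".",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
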