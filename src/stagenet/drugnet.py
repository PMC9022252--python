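"""Drug -> target -> PPI network assembly with per-stage annotations.

Combines a drug-target table with a high-confidence PPI snapshot
(score >= 0.9 by default) restricted to target genes that are in the
master DEG list, and annotates every gene node with its per-stage gene
weight (sum of incident |PCC| edge weights in the stage-specific network)
and per-stage log2 fold-change versus normal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import FormatError, ScoredEdgeList
from .networks import Network, gene_weights

__all__ = ["DrugTargetTable", "build_drug_network", "write_drug_network"]


@dataclass
class DrugTargetTable:
    """Rows of (drug, target gene); duplicate pairs are rejected."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            dup = next(p for p in self.pairs if self.pairs.count(p) > 1)
            raise FormatError(f"duplicate drug-target pair {dup}")

    @classmethod
    def read(cls, path) -> "DrugTargetTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("drug", "gene"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        return cls(list(zip(df["drug"], df["gene"])))

    @property
    def drugs(self) -> list[str]:
        return sorted({d for d, _ in self.pairs})

    @property
    def targets(self) -> list[str]:
        return sorted({g for _, g in self.pairs})


def build_drug_network(
    targets: DrugTargetTable,
    ppi: ScoredEdgeList,
    stage_nets: list[Network],
    fc_maps: dict[str, dict[str, float]],
    master,
    ppi_score_min: float = 0.9,
    pathway_sets: dict[str, set[str]] | None = None,
) -> nx.Graph:
    """Assemble the annotated drug-target-PPI graph.

    Target genes outside the master DEG list are dropped (warned). Drugs
    whose targets are all dropped remain as flagged degree-0 nodes. PPI
    edges require score >= ``ppi_score_min`` and both endpoints retained.
    ``fc_maps`` maps stage -> gene -> log2fc versus normal.
    """
    master = set(master)
    g = nx.Graph(ppi_score_min=float(ppi_score_min))
    kept: set[str] = set()
    dropped: set[str] = set()
    for gene in targets.targets:
        if gene in master:
            kept.add(gene)
        else:
            dropped.add(gene)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} target gene(s) outside the master DEG "
            f"list: {sorted(dropped)[:5]}..."
        )
    weight_maps = {net.stage: gene_weights(net) for net in stage_nets}
    for drug in targets.drugs:
        g.add_node(drug, kind="drug")
    for gene in sorted(kept):
        attrs: dict[str, float | str] = {"kind": "gene"}
        for stage, wmap in weight_maps.items():
            attrs[f"weight_{stage}"] = float(wmap.get(gene, 0.0))
        for stage, fmap in fc_maps.items():
            attrs[f"log2fc_{stage}"] = float(fmap.get(gene, 0.0))
        if pathway_sets:
            member = sorted(n for n, s in pathway_sets.items() if gene in s)
            attrs["pathways"] = ";".join(member)
        g.add_node(gene, **attrs)
    for drug, gene in sorted(set(targets.pairs)):
        if gene in kept:
            g.add_edge(drug, gene, kind="drug-target")
    for (a, b), score in sorted(ppi.scores.items()):
        if score >= ppi_score_min and a in kept and b in kept:
            g.add_edge(a, b, kind="ppi", score=float(score))
    for drug in targets.drugs:
        g.nodes[drug]["all_targets_dropped"] = g.degree(drug) == 0
    return g


def write_drug_network(graph: nx.Graph, out_dir) -> None:
    """GraphML plus a JSON summary of the assembled network."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, out / "drug_target_ppi.graphml")
    drugs = [n for n, d in graph.nodes(data=True) if d.get("kind") == "drug"]
    genes = [n for n, d in graph.nodes(data=True) if d.get("kind") == "gene"]
    summary = {
        "n_drugs": len(drugs),
        "n_target_genes": len(genes),
        "n_drug_target_edges": sum(
            1 for _, _, d in graph.edges(data=True) if d.get("kind") == "drug-target"
        ),
        "n_ppi_edges": sum(
            1 for _, _, d in graph.edges(data=True) if d.get("kind") == "ppi"
        ),
        "degree_zero_drugs": sorted(
            d for d in drugs if graph.nodes[d].get("all_targets_dropped")
        ),
    }
    (out / "drug_target_ppi.json").write_text(json.dumps(summary, indent=1))
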