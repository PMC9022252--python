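"""End-to-end orchestration of the stage-network analysis.

Each stage reads its inputs from (and writes its outputs to) fixed file
names under a run directory, so stages are individually invokable and
resumable. Every stage writes a JSON manifest recording parameters, input
checksums and the seeds used. All randomness flows from one top-level
seed via ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import differential as diff
from . import drugnet as dn
from . import io as snio
from . import networks as nets
from . import simulate as sim
from . import trends as tr
from .enrichment import enrich_networks
from .constants import DEFAULTS, NEIGHBOR_COMPARISONS, STAGES, comparison_label

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat, YAML-loadable pipeline configuration (defaults = the standard
    analysis setup recorded in :data:`stagenet.constants.DEFAULTS`)."""

    # inputs (unset paths default to the simulate stage's outputs)
    expression: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    ppi: str | None = None
    drug_targets: str | None = None
    key_genes: list[str] = field(default_factory=list)
    # parameters
    alpha_deg: float = DEFAULTS["alpha_deg"]
    p_edge: float = DEFAULTS["p_edge"]
    n_perm: int = DEFAULTS["n_perm"]
    stem_profiles: int = DEFAULTS["stem_profiles"]
    stem_max_change: int = DEFAULTS["stem_max_change"]
    ppi_score_subnet: float = DEFAULTS["ppi_score_subnet"]
    ppi_score_drug: float = DEFAULTS["ppi_score_drug"]
    max_neighbors: int = DEFAULTS["max_neighbors"]
    outlier_k: float = DEFAULTS["outlier_k"]
    weighted: bool = True
    sim_n_genes: int = 200
    sim_n_blocks: int = 4
    sim_genes_per_block: int = 40
    sim_block_rho: float = 0.9
    sim_n_outliers: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage_name: str) -> int:
        """Stable per-stage seed derived from the top-level seed."""
        h = hashlib.sha256(f"{self.seed}:{stage_name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _resolve(cfg: PipelineConfig, out: Path, attr: str, default_name: str) -> Path:
    val = getattr(cfg, attr)
    path = Path(val) if val else out / "dataset" / default_name
    if not path.exists():
        raise PipelineError(f"input file for {attr!r} not found: {path}")
    return path


# ---------------------------------------------------------------------------
# stages


def run_simulate(cfg: PipelineConfig, out: Path) -> sim.Dataset:
    simcfg = sim.SimulationConfig(
        n_genes=cfg.sim_n_genes,
        n_blocks=cfg.sim_n_blocks,
        genes_per_block=cfg.sim_genes_per_block,
        block_rho=cfg.sim_block_rho,
        n_outliers=cfg.sim_n_outliers,
        seed=cfg.stage_seed("simulate"),
    )
    ds = sim.generate_dataset(simcfg)
    sim.write_dataset(ds, out / "dataset")
    _write_manifest(out, "simulate", {"config": asdict(simcfg)}, [])
    return ds


def run_preprocess(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    expr_path = _resolve(cfg, out, "expression", "expression.tsv")
    meta_path = _resolve(cfg, out, "metadata", "samples.tsv")
    annot_path = _resolve(cfg, out, "annotation", "probes.tsv")
    matrix = snio.read_expression(expr_path)
    stage_of = snio.read_metadata(meta_path)
    snio.check_metadata_covers(matrix, stage_of)
    gene_of = snio.read_annotation(annot_path)
    outliers = snio.detect_outlier_samples(matrix, k=cfg.outlier_k)
    if outliers:
        logger.info("removing %d outlier sample(s): %s", len(outliers), sorted(outliers))
        matrix = matrix.drop(columns=sorted(outliers))
        stage_of = stage_of.drop(index=sorted(outliers))
    genes = snio.collapse_probes(matrix, gene_of)
    genes.to_csv(out / "gene_matrix.tsv", sep="\t")
    snio.write_metadata(stage_of, out / "samples_clean.tsv")
    (out / "outliers.json").write_text(json.dumps(sorted(outliers)))
    _write_manifest(
        out, "preprocess", {"outlier_k": cfg.outlier_k},
        [expr_path, meta_path, annot_path],
    )
    return genes


def _load_gene_matrix(out: Path) -> tuple[pd.DataFrame, pd.Series]:
    path = out / "gene_matrix.tsv"
    if not path.exists():
        raise PipelineError(f"run the preprocess stage first ({path} missing)")
    return snio.read_expression(path), snio.read_metadata(out / "samples_clean.tsv")


def run_deg(cfg: PipelineConfig, out: Path) -> list[str]:
    genes, stage_of = _load_gene_matrix(out)
    table = diff.differential_table(genes, stage_of)
    table.to_csv(out / "differential.tsv", sep="\t", index=False)
    master = diff.master_deg_list(table, alpha=cfg.alpha_deg)
    (out / "master_degs.txt").write_text("\n".join(master) + "\n")
    # per-stage log2fc vs normal, used to annotate subnetwork/drug nodes
    vs_normal = diff.differential_table(
        genes, stage_of, comparisons=[(s, "normal") for s in STAGES[1:]]
    )
    vs_normal.to_csv(out / "differential_vs_normal.tsv", sep="\t", index=False)
    _write_manifest(out, "deg", {"alpha_deg": cfg.alpha_deg}, [out / "gene_matrix.tsv"])
    return master


def _load_master(out: Path) -> list[str]:
    path = out / "master_degs.txt"
    if not path.exists():
        raise PipelineError(f"run the deg stage first ({path} missing)")
    return path.read_text().split()


def run_network(cfg: PipelineConfig, out: Path) -> dict[str, nets.Network]:
    genes, stage_of = _load_gene_matrix(out)
    master = _load_master(out)
    sub = genes.loc[[g for g in master if g in genes.index]]
    netdir = out / "networks"
    netdir.mkdir(exist_ok=True)
    specific: dict[str, nets.Network] = {}
    for s in STAGES:
        cols = [c for c in sub.columns if stage_of.get(c) == s]
        if len(cols) < 3:
            raise PipelineError(f"stage {s!r} has fewer than 3 samples")
        net = nets.build_stage_network(
            sub[cols], stage=s, p=cfg.p_edge, weighted=cfg.weighted
        )
        specific[s] = net
        net.write_tsv(netdir / f"stage_{s}.tsv")
        net.write_graphml(netdir / f"stage_{s}.graphml")
    summary = {}
    for s, net in specific.items():
        unique = nets.stage_unique_network(
            net, [o for t, o in specific.items() if t != s]
        )
        unique.write_tsv(netdir / f"stage_{s}_unique.tsv")
        summary[s] = {
            "n_samples": int(sum(stage_of == s)),
            "r_th": net.r_th,
            "n_edges": net.n_edges,
            "n_unique_edges": unique.n_edges,
        }
    (out / "networks_summary.json").write_text(json.dumps(summary, indent=1))
    _write_manifest(
        out, "network", {"p_edge": cfg.p_edge, "weighted": cfg.weighted},
        [out / "gene_matrix.tsv", out / "master_degs.txt"],
    )
    return specific


def _load_network(out: Path, stage: str, r_th: float | None = None) -> nets.Network:
    path = out / "networks" / f"stage_{stage}.tsv"
    if not path.exists():
        raise PipelineError(f"run the network stage first ({path} missing)")
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    summary = json.loads((out / "networks_summary.json").read_text())
    edges = {
        (a, b) if a <= b else (b, a): float(w)
        for a, b, w in zip(df["gene_a"], df["gene_b"], df["weight"])
    }
    nodes = set(df["gene_a"]) | set(df["gene_b"])
    return nets.Network(
        stage=stage, nodes=nodes, edges=edges,
        r_th=float(summary[stage]["r_th"]), weighted=True,
    )


def run_communities(cfg: PipelineConfig, out: Path) -> dict[str, comm.Partition]:
    commdir = out / "communities"
    commdir.mkdir(exist_ok=True)
    parts: dict[str, comm.Partition] = {}
    summary = {}
    for s in STAGES:
        net = _load_network(out, s)
        part = comm.louvain(net, seed=cfg.stage_seed(f"louvain:{s}"))
        parts[s] = part
        pd.DataFrame(
            {"gene": sorted(part.assignment),
             "community": [part.assignment[g] for g in sorted(part.assignment)]}
        ).to_csv(commdir / f"stage_{s}.tsv", sep="\t", index=False)
        summary[s] = {"n_communities": part.n_communities(), "modularity": part.q}
    (out / "communities_summary.json").write_text(json.dumps(summary, indent=1))
    _write_manifest(out, "communities", {"seed": cfg.seed}, [])
    return parts


def _load_partition(out: Path, stage: str) -> comm.Partition:
    path = out / "communities" / f"stage_{stage}.tsv"
    if not path.exists():
        raise PipelineError(f"run the communities stage first ({path} missing)")
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return comm.Partition(dict(zip(df["gene"], df["community"].astype(int))), float("nan"))


def run_compare(
    cfg: PipelineConfig, out: Path,
    permutation_pairs: tuple[tuple[str, str], ...] = (("I", "II"), ("II", "III")),
) -> pd.DataFrame:
    parts = {s: _load_partition(out, s) for s in STAGES}
    mat = pd.DataFrame(np.nan, index=list(STAGES), columns=list(STAGES))
    for i, s in enumerate(STAGES):
        for t in STAGES[i:]:
            common = set(parts[s].assignment) & set(parts[t].assignment)
            val = comm.nmi(parts[s].restrict(common), parts[t].restrict(common)) if common else np.nan
            mat.loc[s, t] = val
            mat.loc[t, s] = val
    mat.to_csv(out / "nmi_matrix.tsv", sep="\t")
    results = {}
    for a, b in permutation_pairs:
        res = comm.nmi_permutation_test(
            _load_network(out, a), _load_network(out, b),
            n_perm=cfg.n_perm, seed=cfg.stage_seed(f"perm:{a}:{b}"),
        )
        results[f"{a}_vs_{b}"] = {
            "observed_nmi": res.observed_nmi,
            "p_value": res.p_value,
            "n_perm": cfg.n_perm,
            "null_mean": float(res.null_nmis.mean()),
            "null_q95": float(np.quantile(res.null_nmis, 0.95)),
        }
    (out / "nmi_permutation.json").write_text(json.dumps(results, indent=1))
    _write_manifest(out, "compare", {"n_perm": cfg.n_perm}, [])
    return mat


def run_enrich(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    if not cfg.gene_sets:
        raise PipelineError("enrich stage needs a gene_sets GMT path in the config")
    sets = snio.read_gmt(cfg.gene_sets)
    master = _load_master(out)
    specific = {s: _load_network(out, s) for s in STAGES}
    networks = []
    for s, net in specific.items():
        networks.append(net)
        unique = nets.stage_unique_network(
            net, [o for t, o in specific.items() if t != s]
        )
        unique.stage = f"{s}_unique"
        networks.append(unique)
    table = enrich_networks(networks, sets, master, alpha=cfg.alpha_deg)
    table.to_csv(out / "enrichment_edges.tsv", sep="\t", index=False)
    _write_manifest(out, "enrich", {"alpha": cfg.alpha_deg}, [Path(cfg.gene_sets)])
    return table


def run_trends(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    genes, stage_of = _load_gene_matrix(out)
    medians = tr.stage_medians(genes, stage_of)
    universe = tr.enumerate_profiles(t=len(STAGES), c=cfg.stem_max_change)
    profiles = tr.select_profiles(universe, m=cfg.stem_profiles)
    assignments = tr.assign_genes(medians, profiles)
    table = pd.DataFrame(
        {
            "gene": [a.gene for a in assignments],
            "profile": [str(a.profile) for a in assignments],
            "score": [a.score for a in assignments],
        }
    )
    table.to_csv(out / "trend_assignments.tsv", sep="\t", index=False)
    _write_manifest(
        out, "trends",
        {"stem_profiles": cfg.stem_profiles, "stem_max_change": cfg.stem_max_change},
        [out / "gene_matrix.tsv"],
    )
    return table


def run_biomarkers(cfg: PipelineConfig, out: Path) -> dict[str, list[str]]:
    genes, stage_of = _load_gene_matrix(out)
    result = {
        s: diff.stage_specific_biomarkers(genes, stage_of, s, alpha=cfg.alpha_deg)
        for s in STAGES[1:]
    }
    (out / "stage_specific_biomarkers.json").write_text(json.dumps(result, indent=1))
    _write_manifest(out, "biomarkers", {"alpha_deg": cfg.alpha_deg}, [])
    return result


def _fc_maps(out: Path) -> dict[str, dict[str, float]]:
    path = out / "differential_vs_normal.tsv"
    if not path.exists():
        raise PipelineError(f"run the deg stage first ({path} missing)")
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    maps: dict[str, dict[str, float]] = {}
    for s in STAGES[1:]:
        lab = comparison_label(s, "normal")
        sub = df[df["comparison"] == lab]
        maps[s] = dict(zip(sub["gene"], sub["log2fc"]))
    return maps


def run_subnet(cfg: PipelineConfig, out: Path) -> None:
    if not cfg.key_genes:
        raise PipelineError("subnet stage needs key_genes in the config")
    if not cfg.ppi:
        raise PipelineError("subnet stage needs a ppi edge-list path in the config")
    ppi = snio.read_edges(cfg.ppi)
    master = _load_master(out)
    fc = _fc_maps(out)
    subdir = out / "subnetworks"
    subdir.mkdir(exist_ok=True)
    for s in STAGES[1:]:
        net = _load_network(out, s)
        sub = nets.extract_key_subnetwork(
            cfg.key_genes, ppi, master, net,
            score_min=cfg.ppi_score_subnet, max_neighbors=cfg.max_neighbors,
        )
        sub.write_graphml(subdir / f"stage_{s}_key_subnetwork.graphml",
                          node_log2fc=fc.get(s))
        sub.write_tsv(subdir / f"stage_{s}_key_subnetwork.tsv")
    _write_manifest(
        out, "subnet",
        {"score_min": cfg.ppi_score_subnet, "max_neighbors": cfg.max_neighbors,
         "key_genes": list(cfg.key_genes)},
        [Path(cfg.ppi)],
    )


def run_drugnet(cfg: PipelineConfig, out: Path) -> None:
    if not cfg.drug_targets or not cfg.ppi:
        raise PipelineError("drugnet stage needs drug_targets and ppi paths")
    table = dn.DrugTargetTable.read(cfg.drug_targets)
    ppi = snio.read_edges(cfg.ppi)
    master = _load_master(out)
    stage_nets = [_load_network(out, s) for s in STAGES[1:]]
    pathway_sets = snio.read_gmt(cfg.gene_sets) if cfg.gene_sets else None
    graph = dn.build_drug_network(
        table, ppi, stage_nets, _fc_maps(out), master,
        ppi_score_min=cfg.ppi_score_drug, pathway_sets=pathway_sets,
    )
    dn.write_drug_network(graph, out)
    _write_manifest(
        out, "drugnet", {"ppi_score_min": cfg.ppi_score_drug},
        [Path(cfg.drug_targets), Path(cfg.ppi)],
    )


#: stage name -> runner, in execution order
STAGE_RUNNERS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "deg": run_deg,
    "network": run_network,
    "communities": run_communities,
    "compare": run_compare,
    "enrich": run_enrich,
    "trends": run_trends,
    "biomarkers": run_biomarkers,
    "subnet": run_subnet,
    "drugnet": run_drugnet,
}


def run_all(cfg: PipelineConfig, out, skip_missing_inputs: bool = True) -> dict:
    """Run every stage in order; optional stages without configured inputs
    (enrich/subnet/drugnet) are skipped when ``skip_missing_inputs``.

    Returns a run manifest naming completed and skipped stages.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    completed, skipped = [], []
    for name, runner in STAGE_RUNNERS.items():
        if name == "simulate" and cfg.expression:
            skipped.append(name)  # real data supplied; nothing to simulate
            continue
        optional = (
            (name == "enrich" and not cfg.gene_sets)
            or (name == "subnet" and not (cfg.key_genes and cfg.ppi))
            or (name == "drugnet" and not (cfg.drug_targets and cfg.ppi))
        )
        if optional and skip_missing_inputs:
            skipped.append(name)
            continue
        try:
            runner(cfg, out)
        except Exception as exc:
            manifest = {"completed": completed, "skipped": skipped,
                        "failed": name, "error": str(exc)}
            (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        completed.append(name)
    manifest = {"completed": completed, "skipped": skipped, "failed": None,
                "seed": cfg.seed}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
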