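"""Stage-structured synthetic expression data with known ground truth.

The generator emulates the structure of a staged tumor microarray cohort:
five stage groups with unequal sample counts, genes measured by one to
three probes, planted within-stage correlation blocks, differential
expression between neighboring stages, monotone/step trend genes, and a
few globally shifted outlier samples.

Correlation blocks use a one-factor model: for a gene in block ``b`` of a
stage, the unit-variance signal is ``sqrt(rho) * f_b + sqrt(1 - rho) * eps``
with ``f_b`` a per-stage, per-block latent factor shared by the block and
``eps`` independent noise, so the expected pairwise correlation inside a
block is exactly ``rho``. Differential-expression shifts are cumulative
from the test stage onward, so a shift planted for one neighboring-stage
comparison changes the group-mean difference of that comparison only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as snio
from .constants import NEIGHBOR_COMPARISONS, REFERENCE_SAMPLES_PER_STAGE, STAGES, comparison_label

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Dataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

#: Cumulative stage offsets (in units of ``de_effect``) per trend pattern.
TREND_SHAPES: dict[str, tuple[int, ...]] = {
    "monotone-up": (0, 1, 2, 3, 4),
    "step-up": (0, 1, 1, 1, 1),
    "monotone-down": (0, -1, -2, -3, -4),
    "step-down": (0, -1, -1, -1, -1),
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the reference cohort the pipeline targets: 126 patients
    over five stage groups, ~55k probes for ~20k genes scaled down to a
    desk-size problem, strong block correlation and clear planted effects.
    """

    n_genes: int = 200
    #: probability of a gene being measured by 1, 2 or 3 probes
    n_probes_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    samples_per_stage: dict[str, int] = field(
        default_factory=lambda: dict(REFERENCE_SAMPLES_PER_STAGE)
    )
    n_blocks: int = 4
    genes_per_block: int = 40
    block_rho: float = 0.9
    #: fraction of genes shifted per neighboring-stage comparison
    de_fraction: float = 0.1
    de_effect: float = 2.0
    trend_genes: dict[str, int] = field(
        default_factory=lambda: {"monotone-up": 5, "step-up": 5,
                                 "monotone-down": 5, "step-down": 5}
    )
    noise_sd: float = 0.5
    n_outliers: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        if self.n_blocks < 0:
            raise ConfigurationError("n_blocks must be >= 0")
        if self.genes_per_block < 0:
            raise ConfigurationError("genes_per_block must be >= 0")
        if self.n_outliers < 0:
            raise ConfigurationError("n_outliers must be >= 0")
        if not 0.0 <= self.block_rho < 1.0:
            raise ConfigurationError("block_rho must be in [0, 1)")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if self.n_blocks * self.genes_per_block > self.n_genes:
            raise ConfigurationError(
                "n_blocks * genes_per_block exceeds n_genes"
            )
        if any(c < 0 for c in self.samples_per_stage.values()):
            raise ConfigurationError("samples_per_stage counts must be >= 0")
        if any(s not in STAGES for s in self.samples_per_stage):
            raise ConfigurationError("samples_per_stage has an unknown stage")
        probs = self.n_probes_per_gene
        if any(k not in (1, 2, 3) for k in probs) or any(v < 0 for v in probs.values()):
            raise ConfigurationError("n_probes_per_gene must weight {1,2,3} >= 0")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("n_probes_per_gene weights must sum to 1")
        if sum(self.trend_genes.values()) > self.n_genes:
            raise ConfigurationError("trend_genes exceed n_genes")
        if any(t not in TREND_SHAPES for t in self.trend_genes):
            raise ConfigurationError(
                f"trend_genes patterns must be among {sorted(TREND_SHAPES)}"
            )


@dataclass
class GroundTruth:
    """What was planted, keyed exactly like the generated matrix."""

    block_membership: dict[str, dict[str, int]]
    de_genes: dict[str, set[str]]
    trend_assignment: dict[str, str]
    outlier_samples: set[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "block_membership": {
                    s: dict(sorted(m.items())) for s, m in self.block_membership.items()
                },
                "de_genes": {c: sorted(g) for c, g in self.de_genes.items()},
                "trend_assignment": dict(sorted(self.trend_assignment.items())),
                "outlier_samples": sorted(self.outlier_samples),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            block_membership={
                s: {g: int(b) for g, b in m.items()}
                for s, m in d["block_membership"].items()
            },
            de_genes={c: set(g) for c, g in d["de_genes"].items()},
            trend_assignment=dict(d["trend_assignment"]),
            outlier_samples=set(d["outlier_samples"]),
        )


@dataclass
class Dataset:
    expression: pd.DataFrame           # probes x samples
    stage_of: pd.Series                # sample -> stage
    gene_of: dict[str, str | None]     # probe -> gene
    truth: GroundTruth


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(max(n - 1, 0))))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Draw one cohort. Identical config (incl. seed) -> identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    stages = [s for s in STAGES if config.samples_per_stage.get(s, 0) > 0]

    # --- gene roles -------------------------------------------------------
    block_of: dict[str, int] = {}
    idx = 0
    for b in range(config.n_blocks):
        for _ in range(config.genes_per_block):
            block_of[genes[idx]] = b
            idx += 1

    # trend genes drawn from the non-block remainder when possible
    free = [g for g in genes if g not in block_of]
    pool = free if len(free) >= sum(config.trend_genes.values()) else list(genes)
    pool = list(pool)
    trend_assignment: dict[str, str] = {}
    for pattern in sorted(config.trend_genes):
        count = config.trend_genes[pattern]
        chosen = rng.choice(len(pool), size=count, replace=False)
        for j in sorted(chosen, reverse=True):
            trend_assignment[pool[j]] = pattern
            pool.pop(j)

    # per-comparison DE genes (may include block genes; never trend genes)
    de_pool = [g for g in genes if g not in trend_assignment]
    n_de = int(round(config.de_fraction * config.n_genes))
    de_genes: dict[str, set[str]] = {}
    signs: dict[tuple[str, str], float] = {}
    for test, ref in NEIGHBOR_COMPARISONS:
        label = comparison_label(test, ref)
        if test not in stages or ref not in stages or n_de == 0 or not de_pool:
            de_genes[label] = set()
            continue
        take = min(n_de, len(de_pool))
        chosen = rng.choice(len(de_pool), size=take, replace=False)
        de_genes[label] = {de_pool[j] for j in chosen}
        for g in de_genes[label]:
            signs[(label, g)] = float(rng.choice([-1.0, 1.0]))

    # cumulative per-stage mean offsets
    offset = pd.DataFrame(0.0, index=genes, columns=list(STAGES))
    for ci, (test, ref) in enumerate(NEIGHBOR_COMPARISONS):
        label = comparison_label(test, ref)
        later = list(STAGES)[ci + 1:]  # test stage onward
        for g in de_genes.get(label, ()):
            offset.loc[g, later] += signs[(label, g)] * config.de_effect
    for g, pattern in trend_assignment.items():
        shape = TREND_SHAPES[pattern]
        for s, v in zip(STAGES, shape):
            offset.loc[g, s] += v * config.de_effect

    baseline = rng.normal(8.0, 1.5, size=config.n_genes)

    # --- per-stage gene-level signals ------------------------------------
    sample_ids: list[str] = []
    stage_labels: list[str] = []
    cols: list[np.ndarray] = []
    rho = config.block_rho
    for s in stages:
        n_s = config.samples_per_stage[s]
        factors = rng.normal(size=(config.n_blocks, n_s))
        eps = rng.normal(size=(config.n_genes, n_s))
        z = eps.copy()
        for gi, g in enumerate(genes):
            b = block_of.get(g)
            if b is not None and rho > 0:
                z[gi] = np.sqrt(rho) * factors[b] + np.sqrt(1.0 - rho) * eps[gi]
        vals = (
            baseline[:, None]
            + offset[s].to_numpy()[:, None]
            + config.noise_sd * z
        )
        cols.append(vals)
        sample_ids += [f"S_{s}_{i:03d}" for i in range(n_s)]
        stage_labels += [s] * n_s

    # outliers: normal-stage profile plus a large global shift
    outliers: set[str] = set()
    if config.n_outliers:
        out_stage = "normal" if "normal" in stages else stages[0]
        eps = rng.normal(size=(config.n_genes, config.n_outliers))
        vals = (
            baseline[:, None]
            + offset[out_stage].to_numpy()[:, None]
            + config.noise_sd * eps
            + 10.0 * config.noise_sd
        )
        cols.append(vals)
        for i in range(config.n_outliers):
            sid = f"S_outlier_{i:03d}"
            sample_ids.append(sid)
            stage_labels.append(out_stage)
            outliers.add(sid)

    gene_matrix = np.concatenate(cols, axis=1) if cols else np.empty((config.n_genes, 0))

    # --- probe level ------------------------------------------------------
    probe_counts = rng.choice(
        sorted(config.n_probes_per_gene),
        size=config.n_genes,
        p=[config.n_probes_per_gene[k] for k in sorted(config.n_probes_per_gene)],
    ) if config.n_genes else np.array([], dtype=int)
    probe_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    gene_of: dict[str, str | None] = {}
    probe_noise_sd = config.noise_sd / 2.0  # keeps probes faithful to the gene signal
    for gi, g in enumerate(genes):
        for p in range(int(probe_counts[gi])):
            pid = f"{g}_p{p}"
            shift = rng.normal(0.0, 0.25)  # probe-specific affinity offset
            noise = rng.normal(0.0, probe_noise_sd, size=gene_matrix.shape[1])
            probe_rows.append(gene_matrix[gi] + shift + noise)
            probe_ids.append(pid)
            gene_of[pid] = g

    expression = pd.DataFrame(
        np.asarray(probe_rows) if probe_rows else np.empty((0, len(sample_ids))),
        index=pd.Index(probe_ids, name="feature_id"),
        columns=sample_ids,
    )
    stage_of = pd.Series(stage_labels, index=sample_ids, name="stage")
    truth = GroundTruth(
        block_membership={s: dict(block_of) for s in stages},
        de_genes=de_genes,
        trend_assignment=trend_assignment,
        outlier_samples=outliers,
    )
    return Dataset(expression, stage_of, gene_of, truth)


_FILES = {
    "expression": "expression.tsv",
    "metadata": "samples.tsv",
    "annotation": "probes.tsv",
    "truth": "ground_truth.json",
}


def write_dataset(dataset: Dataset, out_dir) -> dict:
    """Write the four dataset files and return a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snio.write_expression(dataset.expression, out / _FILES["expression"])
    snio.write_metadata(dataset.stage_of, out / _FILES["metadata"])
    snio.write_annotation(dataset.gene_of, out / _FILES["annotation"])
    (out / _FILES["truth"]).write_text(dataset.truth.to_json())
    manifest = {"files": {}}
    for key, name in _FILES.items():
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest["files"][name] = {"role": key, "sha256": digest}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_dataset(out_dir) -> Dataset:
    out = Path(out_dir)
    return Dataset(
        expression=snio.read_expression(out / _FILES["expression"]),
        stage_of=snio.read_metadata(out / _FILES["metadata"]),
        gene_of=snio.read_annotation(out / _FILES["annotation"]),
        truth=GroundTruth.from_json((out / _FILES["truth"]).read_text()),
    )
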