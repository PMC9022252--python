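"""Readers and writers for the pipeline's plain-text formats.

Conventions
-----------
* Expression matrix: TSV, header row, first column the feature (probe or
  gene) id, remaining columns one per sample; values are log2 intensities.
  In memory it is a :class:`pandas.DataFrame` (features x samples).
* Sample metadata: TSV with columns ``sample_id`` and ``stage``; in memory
  a :class:`pandas.Series` mapping sample id -> stage label.
* Probe annotation: TSV with columns ``probe_id`` and ``gene_id``; an empty
  gene field, the literal ``NA``, or a probe listed with several distinct
  genes marks the probe unmapped/ambiguous (stored as ``None``).
* Gene sets: GMT (set name, description, then member genes, tab-separated).
* Scored edges: TSV with columns ``gene_a``, ``gene_b``, ``score``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .constants import STAGES

__all__ = [
    "FormatError",
    "ScoredEdgeList",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "read_edges",
    "write_edges",
    "drop_unmapped_probes",
    "collapse_probes",
    "detect_outlier_samples",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ScoredEdgeList:
    """Undirected scored gene-gene interactions (e.g. a STRING snapshot).

    Edges are keyed by the sorted gene pair; duplicate pairs collapse to the
    maximum score, self-pairs are rejected at construction.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "ScoredEdgeList":
        scores: dict[tuple[str, str], float] = {}
        for a, b, s in records:
            if a == b:
                warnings.warn(f"dropping self-interaction {a!r}")
                continue
            key = (a, b) if a <= b else (b, a)
            s = float(s)
            if not 0.0 <= s <= 1.0:
                raise FormatError(f"score {s} for pair {key} outside [0, 1]")
            if key not in scores or s > scores[key]:
                scores[key] = s
        return cls(scores)

    def partners_of(self, gene: str) -> dict[str, float]:
        """Interaction partners of ``gene`` with their scores."""
        out: dict[str, float] = {}
        for (a, b), s in self.scores.items():
            if a == gene:
                out[b] = s
            elif b == gene:
                out[a] = s
        return out

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "feature_id"
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "feature_id"
    # 17 significant digits round-trip float64 exactly
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "stage"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad = df.loc[~df["stage"].isin(STAGES)]
    if len(bad):
        line = bad.index[0] + 2  # 1-based, after header
        raise FormatError(
            f"{path}:{line}: unknown stage label {bad['stage'].iloc[0]!r} "
            f"(expected one of {', '.join(STAGES)})"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return pd.Series(df["stage"].values, index=df["sample_id"].values, name="stage")


def write_metadata(stage_of: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": stage_of.index, "stage": stage_of.values}).to_csv(
        path, sep="\t", index=False
    )


def check_metadata_covers(matrix: pd.DataFrame, stage_of: pd.Series) -> None:
    """Every sample in the matrix must carry a stage label."""
    missing = [s for s in matrix.columns if s not in stage_of.index]
    if missing:
        raise FormatError(f"samples without stage labels: {missing[:5]}")


# ---------------------------------------------------------------------------
# probe annotation


def read_annotation(path) -> dict[str, str | None]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    gene_of: dict[str, str | None] = {}
    for probe, gene in zip(df["probe_id"], df["gene_id"]):
        gene = gene.strip()
        mapped: str | None = None if gene in ("", "NA", "---") else gene
        if probe in gene_of and gene_of[probe] != mapped:
            gene_of[probe] = None  # multiple distinct genes -> ambiguous
        else:
            gene_of[probe] = mapped
    return gene_of


def write_annotation(gene_of: dict[str, str | None], path) -> None:
    pd.DataFrame(
        {
            "probe_id": list(gene_of),
            "gene_id": ["" if g is None else g for g in gene_of.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def drop_unmapped_probes(
    matrix: pd.DataFrame, gene_of: dict[str, str | None]
) -> pd.DataFrame:
    """Keep only probes with exactly one gene id; preserve row order.

    Probes absent from the annotation count as unmapped. Idempotent.
    """
    keep = [p for p in matrix.index if gene_of.get(p) is not None]
    if not keep:
        warnings.warn("no probes with a unique gene id remain")
    return matrix.loc[keep]


def collapse_probes(
    matrix: pd.DataFrame, gene_of: dict[str, str | None]
) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by per-gene median."""
    mapped = drop_unmapped_probes(matrix, gene_of)
    genes = pd.Index([gene_of[p] for p in mapped.index], name="feature_id")
    return mapped.groupby(genes, sort=True).median()


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> dict[str, set[str]]:
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# scored edge lists


def read_edges(path) -> ScoredEdgeList:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return ScoredEdgeList.from_records(
        zip(df["gene_a"], df["gene_b"], df["score"].astype(float))
    )


def write_edges(edges: ScoredEdgeList, path) -> None:
    rows = sorted(edges.scores.items())
    pd.DataFrame(
        {
            "gene_a": [k[0] for k, _ in rows],
            "gene_b": [k[1] for k, _ in rows],
            "score": [s for _, s in rows],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# outlier samples


def detect_outlier_samples(matrix: pd.DataFrame, k: float = 5.0) -> set[str]:
    """Flag samples far from the bulk in PC1-PC2 of the standardized matrix.

    Genes are standardized across samples, samples are projected onto the
    first two principal components, and a sample is flagged when the robust
    z-score of its Euclidean distance from the component-space centroid —
    ``(d - median(d)) / (1.4826 * MAD(d))`` — exceeds ``k``. A deterministic
    stand-in for the visual PCA/t-SNE inspection used when curating cohorts
    by hand; on homogeneous data the default ``k = 5`` flags essentially
    nothing, while a sample shifted globally by many noise SDs is caught.
    """
    if matrix.shape[1] < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    if math.isinf(k):
        return set()
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    n_comp = min(2, min(z.shape) - 1) or 1
    proj = PCA(n_components=n_comp, svd_solver="full").fit_transform(z)
    dist = np.linalg.norm(proj - proj.mean(axis=0), axis=1)
    med = float(np.median(dist))
    mad = float(np.median(np.abs(dist - med)))
    if mad == 0.0:
        return set()
    z_robust = (dist - med) / (1.4826 * mad)
    return {s for s, zr in zip(matrix.columns, z_robust) if zr > k}
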