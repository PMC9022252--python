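"""Differential expression between stage groups.

Probe-level two-sided Welch t-tests on log2 intensities, gene-level
aggregation of multi-probe p-values by geometric mean, the master DEG list
(union of the four neighboring-stage comparisons), and stage-specific
biomarkers (intersection of one stage's comparisons against every other
group).

Gene calls use raw p-values at ``alpha`` (default 0.05); BH-adjusted
q-values are reported alongside for transparency but never used to filter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import NEIGHBOR_COMPARISONS, STAGES, comparison_label

__all__ = [
    "probe_test",
    "aggregate_gene_p",
    "differential_table",
    "master_deg_list",
    "stage_specific_biomarkers",
]


def probe_test(values_test, values_ref) -> tuple[float, float]:
    """Welch two-sample t-test on log2 values.

    Returns ``(p_value, log2fc)`` with ``log2fc = mean(test) - mean(ref)``.
    Degenerate variance: both groups constant and equal -> p = 1; constant
    but different -> p set to the smallest positive float with a warning.
    """
    x = np.asarray(values_test, dtype=float)
    y = np.asarray(values_ref, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("probe_test needs at least 2 samples per group")
    log2fc = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if log2fc == 0.0:
            return 1.0, 0.0
        warnings.warn("zero within-group variance with unequal means")
        return float(np.finfo(float).tiny), log2fc
    p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return p, log2fc


def aggregate_gene_p(probe_ps) -> float:
    """Geometric mean of a gene's probe-level p-values."""
    ps = np.asarray(list(probe_ps), dtype=float)
    if ps.size == 0:
        raise ValueError("aggregate_gene_p needs at least one p-value")
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.exp(np.mean(np.log(ps))))


def _gene_level(
    matrix: pd.DataFrame,
    stage_of: pd.Series,
    test: str,
    ref: str,
    gene_of: dict[str, str | None] | None,
) -> pd.DataFrame:
    test_cols = [s for s in matrix.columns if stage_of.get(s) == test]
    ref_cols = [s for s in matrix.columns if stage_of.get(s) == ref]
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise ValueError(
            f"comparison {test} vs {ref}: need >= 2 samples per group "
            f"(got {len(test_cols)}/{len(ref_cols)})"
        )
    xt = matrix[test_cols].to_numpy(dtype=float)
    xr = matrix[ref_cols].to_numpy(dtype=float)
    ps = np.empty(matrix.shape[0])
    fcs = np.empty(matrix.shape[0])
    for i in range(matrix.shape[0]):
        ps[i], fcs[i] = probe_test(xt[i], xr[i])
    probe_df = pd.DataFrame(
        {"p_value": ps, "log2fc": fcs}, index=matrix.index
    )
    if gene_of is None:
        out = probe_df.copy()
        out["n_probes"] = 1
        out.index.name = "gene"
        return out
    probe_df["gene"] = [gene_of.get(p) for p in probe_df.index]
    probe_df = probe_df.dropna(subset=["gene"])
    grouped = probe_df.groupby("gene")
    out = pd.DataFrame(
        {
            "p_value": grouped["p_value"].apply(lambda s: aggregate_gene_p(s.values)),
            "log2fc": grouped["log2fc"].mean(),  # arithmetic mean on log scale
            "n_probes": grouped.size(),
        }
    )
    out.index.name = "gene"
    return out


def differential_table(
    matrix: pd.DataFrame,
    stage_of: pd.Series,
    comparisons=NEIGHBOR_COMPARISONS,
    gene_of: dict[str, str | None] | None = None,
) -> pd.DataFrame:
    """Gene-level differential results for a list of comparisons.

    If ``gene_of`` is given the matrix is treated as probe-level and
    aggregated (geometric-mean p, mean log2fc); otherwise features are
    genes. Returns a tidy frame with columns gene, comparison, p_value,
    q_value (BH within comparison), log2fc, n_probes.
    """
    frames = []
    for test, ref in comparisons:
        res = _gene_level(matrix, stage_of, test, ref, gene_of).reset_index()
        res.insert(1, "comparison", comparison_label(test, ref))
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    return out[["gene", "comparison", "p_value", "q_value", "log2fc", "n_probes"]]


def master_deg_list(results: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Union of genes with p <= alpha in any neighboring-stage comparison.

    ``results`` is the frame from :func:`differential_table`; all four
    neighboring comparisons must be present. Lexicographically sorted.
    """
    have = set(results["comparison"].unique())
    for test, ref in NEIGHBOR_COMPARISONS:
        label = comparison_label(test, ref)
        if label not in have:
            raise ValueError(f"missing comparison {label}")
    hits = results.loc[results["p_value"] <= alpha, "gene"]
    return sorted(set(hits))


def stage_specific_biomarkers(
    matrix: pd.DataFrame,
    stage_of: pd.Series,
    stage: str,
    alpha: float = 0.05,
    gene_of: dict[str, str | None] | None = None,
) -> list[str]:
    """Genes significant against *every* other group for one tumor stage.

    The given stage is compared with each of the other four groups (the
    other three tumor stages and normal); a biomarker must reach
    p <= alpha in all four comparisons.
    """
    if stage not in STAGES[1:]:
        raise ValueError(f"stage must be one of {STAGES[1:]}, got {stage!r}")
    others = [s for s in STAGES if s != stage]
    present = set(stage_of.values)
    missing = [s for s in [stage, *others] if s not in present]
    if missing:
        raise ValueError(f"missing stage group(s): {missing}")
    hit_sets = []
    for other in others:
        res = _gene_level(matrix, stage_of, stage, other, gene_of)
        hit_sets.append(set(res.index[res["p_value"] <= alpha]))
    common = set.intersection(*hit_sets)
    return sorted(common)
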