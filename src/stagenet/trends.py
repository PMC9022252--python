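"""Trend-profile mining over stage medians (short-series expression style).

Each gene is summarized by its per-stage median expression ordered
normal, I, II, III, IV. Candidate model profiles are integer templates of
length 5 starting at 0 with successive changes bounded by ±c; a diverse
subset of m profiles is chosen by greedy max-min correlation distance,
and each gene is assigned to the selected profile most correlated with
its median vector. Defaults (m = 60 profiles, c = 1) match the standard
short-time-series setup for five ordered groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .constants import STAGES

__all__ = [
    "ModelProfile",
    "TrendAssignment",
    "stage_medians",
    "enumerate_profiles",
    "select_profiles",
    "assign_genes",
    "is_monotone_nondecreasing",
    "is_monotone_nonincreasing",
]


@dataclass(frozen=True, order=True)
class ModelProfile:
    """Integer trend template; ``values[0] == 0``, steps bounded by ±c."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.values or self.values[0] != 0:
            raise ValueError("profile must start at 0")

    @property
    def is_constant(self) -> bool:
        return len(set(self.values)) == 1

    def __str__(self) -> str:
        return ",".join(str(v) for v in self.values)


@dataclass(frozen=True)
class TrendAssignment:
    gene: str
    profile: ModelProfile
    score: float


def stage_medians(matrix: pd.DataFrame, stage_of: pd.Series) -> pd.DataFrame:
    """Per-gene median expression per stage, columns ordered normal..IV."""
    cols = {}
    for s in STAGES:
        samples = [c for c in matrix.columns if stage_of.get(c) == s]
        if not samples:
            raise ValueError(f"stage {s!r} has no samples")
        cols[s] = matrix[samples].median(axis=1)
    return pd.DataFrame(cols)[list(STAGES)]


def enumerate_profiles(t: int = 5, c: int = 1) -> list[ModelProfile]:
    """All (2c+1)^(t-1) profiles, lexicographic in the difference vector."""
    if t < 2 or c < 1:
        raise ValueError("need t >= 2 and c >= 1")
    out = []
    for diffs in product(range(-c, c + 1), repeat=t - 1):
        vals = [0]
        for d in diffs:
            vals.append(vals[-1] + d)
        out.append(ModelProfile(tuple(vals)))
    return out


def _profile_corr(p: np.ndarray, q: np.ndarray) -> float:
    """Pearson correlation with conventions for constant vectors:
    constant-vs-constant -> 1, constant-vs-non-constant -> 0."""
    sp, sq = p.std(), q.std()
    if sp == 0.0 and sq == 0.0:
        return 1.0
    if sp == 0.0 or sq == 0.0:
        return 0.0
    return float(np.corrcoef(p, q)[0, 1])


def select_profiles(universe, m: int = 60) -> list[ModelProfile]:
    """Greedy max-min diverse subset of the profile universe.

    Seeded with the all-zero profile; repeatedly adds the candidate whose
    minimum distance ``1 - corr`` to the selected set is largest, ties
    broken lexicographically. Deterministic.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    universe = sorted(set(universe))
    if m >= len(universe):
        return universe
    t = len(universe[0].values)
    zero = ModelProfile((0,) * t)
    selected = [zero if zero in universe else universe[0]]
    arrays = {p: np.array(p.values, dtype=float) for p in universe}
    min_dist = {
        p: 1.0 - _profile_corr(arrays[p], arrays[selected[0]]) for p in universe
    }
    while len(selected) < m:
        best = None
        best_d = -1.0
        for p in universe:
            if p in selected:
                continue
            d = min_dist[p]
            if d > best_d or (d == best_d and (best is None or p < best)):
                best, best_d = p, d
        selected.append(best)
        for p in universe:
            d = 1.0 - _profile_corr(arrays[p], arrays[best])
            if d < min_dist[p]:
                min_dist[p] = d
    return selected


def assign_genes(medians: pd.DataFrame, profiles) -> list[TrendAssignment]:
    """Assign each gene to the best-correlated profile.

    Zero-variance median vectors go to the all-zero (or lexicographically
    smallest) profile with score 0; correlation ties break toward the
    lexicographically smallest profile.
    """
    profiles = sorted(set(profiles))
    if not profiles:
        raise ValueError("profiles must be non-empty")
    t = len(profiles[0].values)
    zero = ModelProfile((0,) * t)
    fallback = zero if zero in profiles else profiles[0]
    arrays = [np.array(p.values, dtype=float) for p in profiles]
    out = []
    for gene, vec in medians.iterrows():
        v = vec.to_numpy(dtype=float)
        if v.std() == 0.0:
            out.append(TrendAssignment(str(gene), fallback, 0.0))
            continue
        best_p, best_s = None, -np.inf
        for p, arr in zip(profiles, arrays):
            s = _profile_corr(v, arr)
            if s > best_s:  # profiles sorted: first max wins ties
                best_p, best_s = p, s
        out.append(TrendAssignment(str(gene), best_p, best_s))
    return out


def is_monotone_nondecreasing(profile: ModelProfile) -> bool:
    v = profile.values
    return all(b >= a for a, b in zip(v, v[1:]))


def is_monotone_nonincreasing(profile: ModelProfile) -> bool:
    v = profile.values
    return all(b <= a for a, b in zip(v, v[1:]))
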