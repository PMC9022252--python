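"""Shared vocabulary and frozen default parameters of the pipeline.

The stage vocabulary is closed: ``normal`` plus tumor stages I-IV. All
pipeline defaults are collected in :data:`DEFAULTS` so that tests and the
CLI assert against a single frozen table rather than scattered literals.
"""

from __future__ import annotations

#: Ordered disease-stage labels (the "time" axis of trend profiles).
STAGES: tuple[str, ...] = ("normal", "I", "II", "III", "IV")

#: Neighboring-stage comparisons as (test_group, reference_group) pairs.
NEIGHBOR_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("I", "normal"),
    ("II", "I"),
    ("III", "II"),
    ("IV", "III"),
)

#: Default analysis parameters.
DEFAULTS: dict[str, float | int] = {
    "alpha_deg": 0.05,        # raw p cutoff for DEG calls
    "p_edge": 0.001,          # correlation-test p cutoff for network edges
    "n_perm": 1000,           # permutation replicates for the NMI null
    "stem_profiles": 60,      # model profiles kept by the trend miner
    "stem_max_change": 1,     # max unit change between successive stages
    "ppi_score_subnet": 0.4,  # PPI score floor for key-gene neighborhoods
    "ppi_score_drug": 0.9,    # PPI score floor for the drug-target network
    "max_neighbors": 20,      # PPI partner cap per key gene
    "outlier_k": 5.0,         # MAD multiplier for PCA outlier flagging
}

#: Per-stage patient counts of the reference cohort the synthetic generator
#: emulates (normal counted after removal of two outlier samples).
REFERENCE_SAMPLES_PER_STAGE: dict[str, int] = {
    "normal": 22,
    "I": 13,
    "II": 37,
    "III": 34,
    "IV": 20,
}


def comparison_label(test: str, ref: str) -> str:
    """Canonical string form of a comparison, e.g. ``'II_vs_I'``."""
    return f"{test}_vs_{ref}"
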