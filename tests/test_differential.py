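"""Welch tests, geometric-mean aggregation, DEG lists and biomarkers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagenet.constants import STAGES, comparison_label
from stagenet.differential import (
    aggregate_gene_p,
    differential_table,
    master_deg_list,
    probe_test,
    stage_specific_biomarkers,
)


class TestProbeTest:
    def test_identical_groups_give_p_one_and_zero_fc(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        p, fc = probe_test(x, x)
        assert p == pytest.approx(1.0)
        assert fc == 0.0

    def test_zero_variance_equal_means(self):
        p, fc = probe_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0 and fc == 0.0

    def test_zero_variance_forced_shift(self):
        with pytest.warns(UserWarning, match="zero within-group variance"):
            p, fc = probe_test([3.0, 3.0], [1.0, 1.0])
        assert fc == 2.0
        assert 0.0 < p < 1e-300

    def test_requires_two_samples_per_group(self):
        with pytest.raises(ValueError, match="2 samples"):
            probe_test([1.0], [1.0, 2.0])

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(1.0, 2.0, size=5)
            p1, fc1 = probe_test(x, y)
            p2, fc2 = probe_test(y, x)
            assert p1 == pytest.approx(p2, rel=1e-12)
            assert fc1 == pytest.approx(-fc2, rel=1e-12)

    def test_power_on_planted_shift(self):
        """Shift 2.0, sd 0.5, n = 13 vs 22: rejection rate >= 0.99."""
        rng = np.random.default_rng(1)
        reject = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.normal(2.0, 0.5, size=13)
            y = rng.normal(0.0, 0.5, size=22)
            p, _ = probe_test(x, y)
            reject += p <= 0.05
        assert reject / n_sim >= 0.99


class TestAggregateGeneP:
    @pytest.mark.parametrize(
        "ps, expected",
        [([0.05], 0.05), ([0.01, 0.04], 0.02), ([0.3, 0.3, 0.3], 0.3)],
    )
    def test_geometric_mean(self, ps, expected):
        assert aggregate_gene_p(ps) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            aggregate_gene_p([0.5, 0.0])
        with pytest.raises(ValueError):
            aggregate_gene_p([])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=8))
    def test_bounded_by_min_and_max(self, ps):
        agg = aggregate_gene_p(ps)
        assert min(ps) - 1e-15 <= agg <= max(ps) + 1e-15


def _stage_series(counts):
    samples, stages = [], []
    for s, n in counts.items():
        for i in range(n):
            samples.append(f"{s}{i}")
            stages.append(s)
    return pd.Series(stages, index=samples)


def _matrix(stage_of, gene_specs, rng, noise_sd=0.5):
    """gene_specs: gene -> stage -> mean offset."""
    rows = {}
    for gene, offsets in gene_specs.items():
        vals = [
            8.0 + offsets.get(stage_of[s], 0.0) + rng.normal(0, noise_sd)
            for s in stage_of.index
        ]
        rows[gene] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=stage_of.index)


COUNTS = {"normal": 10, "I": 8, "II": 10, "III": 9, "IV": 8}


def test_master_list_is_union_of_disjoint_planted_sets():
    """Large effects: master list equals the union of planted DE sets."""
    rng = np.random.default_rng(2)
    stage_of = _stage_series(COUNTS)
    specs = {}
    planted = {}
    later = {"I": ["I", "II", "III", "IV"], "II": ["II", "III", "IV"],
             "III": ["III", "IV"], "IV": ["IV"]}
    for i, test_stage in enumerate(["I", "II", "III", "IV"]):
        g = f"de_{test_stage}"
        specs[g] = {s: 3.0 for s in later[test_stage]}  # effect/sd = 6
        planted[g] = test_stage
    m = _matrix(stage_of, specs, rng)
    table = differential_table(m, stage_of)
    master = master_deg_list(table, alpha=0.05)
    assert set(master) == set(planted)
    # each planted gene significant exactly in its own comparison
    for g, stg in planted.items():
        sub = table[(table.gene == g) & (table.p_value <= 0.05)]
        assert list(sub.comparison) == [
            comparison_label(stg, STAGES[STAGES.index(stg) - 1])
        ]


def test_master_list_requires_all_four_comparisons():
    rng = np.random.default_rng(3)
    stage_of = _stage_series(COUNTS)
    m = _matrix(stage_of, {"g1": {}}, rng)
    table = differential_table(m, stage_of, comparisons=[("I", "normal")])
    with pytest.raises(ValueError, match="II_vs_I"):
        master_deg_list(table)


def test_null_calibration_at_five_percent():
    """No planted effects: fraction with p <= 0.05 is 0.05 +/- 0.01."""
    rng = np.random.default_rng(4)
    stage_of = _stage_series({"II": 37, "III": 34})
    x = rng.normal(8.0, 0.5, size=(10_000, len(stage_of)))
    m = pd.DataFrame(x, index=[f"g{i}" for i in range(10_000)],
                     columns=stage_of.index)
    table = differential_table(m, stage_of, comparisons=[("III", "II")])
    frac = float((table.p_value <= 0.05).mean())
    assert abs(frac - 0.05) <= 0.01


def test_multi_probe_gene_aggregation():
    rng = np.random.default_rng(5)
    stage_of = _stage_series({"normal": 12, "I": 12})
    m = _matrix(stage_of, {"p_a": {"I": 2.0}, "p_b": {"I": 2.0}, "p_c": {}}, rng)
    gene_of = {"p_a": "gX", "p_b": "gX", "p_c": "gY"}
    table = differential_table(m, stage_of, comparisons=[("I", "normal")],
                               gene_of=gene_of)
    row = table[table.gene == "gX"].iloc[0]
    assert row.n_probes == 2
    pa, fa = probe_test(m.loc["p_a", stage_of == "I"], m.loc["p_a", stage_of == "normal"])
    pb, fb = probe_test(m.loc["p_b", stage_of == "I"], m.loc["p_b", stage_of == "normal"])
    assert row.p_value == pytest.approx(aggregate_gene_p([pa, pb]), rel=1e-12)
    assert row.log2fc == pytest.approx((fa + fb) / 2, rel=1e-12)


class TestStageSpecificBiomarkers:
    def test_gene_shifted_only_in_stage_iv(self):
        rng = np.random.default_rng(6)
        stage_of = _stage_series(COUNTS)
        specs = {"marker": {"IV": 3.0}}
        specs.update({f"null_{i}": {} for i in range(10)})
        m = _matrix(stage_of, specs, rng)
        assert stage_specific_biomarkers(m, stage_of, "IV") == ["marker"]
        assert "marker" not in stage_specific_biomarkers(m, stage_of, "II")

    def test_alpha_one_returns_everything(self):
        rng = np.random.default_rng(7)
        stage_of = _stage_series(COUNTS)
        m = _matrix(stage_of, {f"g{i}": {} for i in range(5)}, rng)
        assert stage_specific_biomarkers(m, stage_of, "I", alpha=1.0) == sorted(
            m.index
        )

    def test_missing_group_is_an_error(self):
        rng = np.random.default_rng(8)
        stage_of = _stage_series({"normal": 5, "I": 5, "II": 5, "III": 5})
        m = _matrix(stage_of, {"g": {}}, rng)
        with pytest.raises(ValueError, match="IV"):
            stage_specific_biomarkers(m, stage_of, "I")
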