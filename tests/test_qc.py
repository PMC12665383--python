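"""QC metrics, the MAD rule, normalization, and HVG selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import sparse

from scmr.errors import ConfigurationError, InputError
from scmr.qc import (
    QCRule,
    apply_qc_filter,
    compute_qc_metrics,
    default_qc_rules,
    find_variable_genes,
    log_normalize,
    mad_upper_bound,
)
from scmr.synthetic import SCSimConfig, simulate_sc_counts


def mad_bound_oracle(values, n_mads, scale):
    """Sort-based brute-force MAD bound."""
    v = sorted(float(x) for x in values)
    n = len(v)
    med = (v[(n - 1) // 2] + v[n // 2]) / 2
    dev = sorted(abs(x - med) for x in v)
    mad = (dev[(n - 1) // 2] + dev[n // 2]) / 2
    return med + n_mads * scale * mad


class TestMetrics:
    def test_percent_mt_simple(self):
        counts = np.array([[10], [90]])
        m = compute_qc_metrics(counts, ["MT-CO1", "GAPDH"], ["c1"])
        assert m.loc["c1", "percent_mt"] == pytest.approx(10.0)
        assert m.loc["c1", "n_count"] == 100
        assert m.loc["c1", "n_feature"] == 2

    def test_all_zero_cell_flagged_by_definition(self):
        counts = np.array([[0, 3], [0, 1]])
        m = compute_qc_metrics(counts, ["MT-CO1", "B"], ["dead", "ok"])
        assert m.loc["dead", "n_feature"] == 0
        assert m.loc["dead", "percent_mt"] == 0.0

    def test_n_feature_counts_nonzero_per_column(self):
        counts = np.array([[1, 0, 2], [0, 0, 5], [3, 0, 1]])
        m = compute_qc_metrics(counts, ["A", "B", "C"])
        assert m["n_feature"].tolist() == [2, 0, 3]

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(InputError):
            compute_qc_metrics(np.ones((2, 2)), ["A", "A"])


class TestMADBound:
    def test_hand_computed_example(self):
        values = list(range(1, 10)) + [100]
        # median 5.5, MAD 2.5 -> bound 13.0
        assert mad_upper_bound(values, 3, 1.0) == pytest.approx(13.0, abs=1e-12)
        assert sum(v > 13.0 for v in values) == 1

    def test_constant_vector(self):
        assert mad_upper_bound([4.2] * 7, 3, 1.4826) == pytest.approx(4.2)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            mad_upper_bound([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60),
           st.floats(0.5, 5.0), st.sampled_from([1.0, 1.4826]))
    def test_matches_bruteforce_oracle(self, values, n_mads, scale):
        assert mad_upper_bound(values, n_mads, scale) == pytest.approx(
            mad_bound_oracle(values, n_mads, scale), abs=1e-9, rel=1e-12)


class TestFilter:
    def _metrics(self):
        return pd.DataFrame({
            "n_feature": [200, 201, 500, 450],
            "percent_mt": [3.0, 2.0, 80.0, 2.5],
        }, index=["a", "b", "c", "d"])

    def test_boundary_cell_removed_under_strict_lower_bound(self):
        rules = [QCRule("n_feature", lower=200, upper_mad=False)]
        res = apply_qc_filter(self._metrics(), rules)
        assert "a" not in res.kept and "b" in res.kept

    def test_no_rules_keeps_everything(self):
        res = apply_qc_filter(self._metrics(), [])
        assert res.kept == ["a", "b", "c", "d"]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_qc_filter(self._metrics(), [QCRule("banana")])

    def test_frozen_thresholds_reproduce_kept_set(self):
        metrics = self._metrics()
        rules = [QCRule("n_feature", lower=150, upper_mad=True),
                 QCRule("percent_mt", upper_mad=True)]
        first = apply_qc_filter(metrics, rules)
        again = apply_qc_filter(metrics.loc[first.kept], rules,
                                thresholds=first.thresholds)
        assert again.kept == first.kept

    def test_planted_outliers_all_removed_and_most_cells_kept(self):
        cfg = SCSimConfig(n_cells_per_group=600, mito_fraction_outliers=10,
                          seed=13)
        data, meta, _ = simulate_sc_counts(cfg)
        metrics = compute_qc_metrics(data)
        res = apply_qc_filter(metrics, default_qc_rules())
        kept = set(res.kept)
        outliers = set(meta.loc[meta["planted_outlier"], "barcode"])
        normal = set(meta["barcode"]) - outliers
        assert kept & outliers == set()
        assert len(kept & normal) / len(normal) >= 0.99


class TestNormalize:
    def test_closed_form_entry(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 5
        counts[1, 0] = 4995
        out = log_normalize(counts, scale=10_000)
        assert out[0, 0] == pytest.approx(math.log(11.0), abs=1e-12)

    def test_zero_stays_zero_and_sparse_preserved(self):
        counts = sparse.csr_matrix(np.array([[0.0, 2.0], [5.0, 3.0]]))
        out = log_normalize(counts)
        assert sparse.issparse(out)
        assert out[0, 0] == 0.0

    def test_depth_invariance(self, rng):
        counts = rng.poisson(5.0, (30, 4)).astype(float) + 1
        doubled = counts.copy()
        doubled[:, 2] *= 2
        np.testing.assert_allclose(log_normalize(counts), log_normalize(doubled),
                                   atol=1e-12)

    def test_zero_total_column_rejected(self):
        with pytest.raises(InputError):
            log_normalize(np.array([[0.0, 1.0], [0.0, 2.0]]))

    def test_preserves_within_cell_ranking(self, rng):
        counts = rng.poisson(10.0, (50, 3)).astype(float)
        counts[:, 0] += 1  # keep totals positive
        out = log_normalize(counts)
        for j in range(3):
            order_in = np.argsort(counts[:, j], kind="mergesort")
            order_out = np.argsort(out[:, j], kind="mergesort")
            np.testing.assert_array_equal(order_in, order_out)


class TestHVG:
    def test_single_high_variance_gene(self):
        mat = np.zeros((3, 4))
        mat[1] = [0, 4, 0, 4]
        assert find_variable_genes(mat, ["A", "B", "C"], 1) == ["B"]

    def test_k_equals_n_genes_is_stable(self):
        mat = np.random.default_rng(0).normal(size=(4, 5))
        got = find_variable_genes(mat, list("DCBA"), 4)
        assert sorted(got) == ["A", "B", "C", "D"]
        assert got == find_variable_genes(mat, list("DCBA"), 4)

    def test_lexicographic_tie_break(self):
        mat = np.array([[0.0, 2.0], [0.0, 2.0], [0.0, 0.0]])
        assert find_variable_genes(mat, ["ZZZ", "AAA", "MMM"], 1) == ["AAA"]

    def test_k_too_large_rejected(self):
        with pytest.raises(InputError):
            find_variable_genes(np.ones((2, 2)), ["A", "B"], 3)
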