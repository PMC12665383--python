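"""Marker calling, fold changes, and the FCscore ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scmr.contribution import (
    bulk_fold_change,
    fcscore,
    find_cluster_markers,
    proportion_fold_change,
)
from scmr.errors import InputError


class TestMarkers:
    def test_exact_small_sample_p_excludes_marginal_gene(self):
        # (5,6,7) vs (0,0,0): exact two-sided rank-sum p = 0.10 > 0.05
        mat = np.array([[5.0, 6.0, 7.0, 0.0, 0.0, 0.0]])
        clusters = np.array(["A", "A", "A", "B", "B", "B"])
        table = find_cluster_markers(mat, ["g1"], clusters, return_all=True)
        row = table[(table["gene"] == "g1") & (table["cluster"] == "A")].iloc[0]
        assert row["pval"] == pytest.approx(0.1)
        called = find_cluster_markers(mat, ["g1"], clusters)
        assert len(called[called["cluster"] == "A"]) == 0

    def test_flat_gene_has_zero_logfc(self):
        mat = np.vstack([np.full(8, 2.0), np.r_[np.full(4, 5.0), np.zeros(4)]])
        clusters = np.array(["A"] * 4 + ["B"] * 4)
        table = find_cluster_markers(mat, ["flat", "marker"], clusters,
                                     return_all=True)
        flat = table[table["gene"] == "flat"]
        assert np.allclose(flat["log2fc"], 0.0)

    def test_logfc_threshold_is_strict(self):
        # construct a gene whose expression-scale fold change is exactly
        # 1.5 (log2 = 0.585 after rounding); a strictly greater threshold
        # of log2(1.5) must exclude it
        hi = np.log1p(np.full(20, 3.0))
        lo = np.log1p(np.full(20, 2.0))
        mat = np.concatenate([hi, lo])[None, :]
        clusters = np.array(["A"] * 20 + ["B"] * 20)
        called = find_cluster_markers(mat, ["g"], clusters,
                                      logfc_min=float(np.log2(1.5)), eps=0.0)
        assert len(called[called["cluster"] == "A"]) == 0

    def test_single_cluster_rejected(self):
        with pytest.raises(InputError):
            find_cluster_markers(np.ones((2, 4)), ["a", "b"],
                                 np.array(["A"] * 4))


class TestFoldChanges:
    def _bulk(self):
        bulk = pd.DataFrame(
            {"s1": [8.0, 5.0], "s2": [8.0, 5.0], "s3": [2.0, 5.0], "s4": [2.0, 5.0]},
            index=["up", "flat"])
        groups = pd.Series(["case", "case", "control", "control"],
                           index=["s1", "s2", "s3", "s4"])
        return bulk, groups

    def test_mean_ratio(self):
        bulk, groups = self._bulk()
        fc = bulk_fold_change(bulk, groups, ["up", "flat"], eps=1e-12)
        assert fc["up"] == pytest.approx(4.0)
        assert fc["flat"] == pytest.approx(1.0)

    def test_pseudocount_symmetry_on_zero_means(self):
        bulk = pd.DataFrame(np.zeros((1, 4)), index=["zero"],
                            columns=["s1", "s2", "s3", "s4"])
        groups = pd.Series(["case", "case", "control", "control"],
                           index=bulk.columns)
        fc = bulk_fold_change(bulk, groups, ["zero"], eps=0.01)
        assert fc["zero"] == pytest.approx(1.0)

    def test_missing_gene_is_nan(self):
        bulk, groups = self._bulk()
        fc = bulk_fold_change(bulk, groups, ["up", "absent"])
        assert np.isnan(fc["absent"])

    def test_proportion_ratio(self):
        meta = pd.DataFrame({
            "cluster": ["X"] * 2 + ["Y"] * 8 + ["X"] * 1 + ["Y"] * 9,
            "group": ["case"] * 10 + ["control"] * 10,
        })
        fc = proportion_fold_change(meta)
        assert fc["X"] == pytest.approx(2.0)

    def test_continuity_correction_for_absent_cluster(self):
        meta = pd.DataFrame({
            "cluster": ["X"] * 5 + ["Y"] * 5 + ["Y"] * 10,
            "group": ["case"] * 10 + ["control"] * 10,
        })
        fc = proportion_fold_change(meta)
        assert np.isfinite(fc["X"]) and fc["X"] > 0

    def test_empty_group_rejected(self):
        meta = pd.DataFrame({"cluster": ["X"], "group": ["case"]})
        with pytest.raises(InputError):
            proportion_fold_change(meta)


class TestFCscore:
    def _markers(self):
        return pd.DataFrame({
            "gene": ["g1", "g2", "g3"],
            "cluster": ["A", "A", "B"],
            "log2fc": [1.0, 1.0, 1.0],
            "pval": [0.001] * 3,
            "padj": [0.01] * 3,
        })

    def test_known_scores(self):
        fcexp = pd.Series({"g1": 4.0, "g2": 2.0, "g3": 1.0})
        fcprop = pd.Series({"A": 1.0, "B": 1.0})
        res = fcscore(self._markers(), fcexp, fcprop)
        per = res.per_gene.set_index("gene")["fcscore"]
        assert per["g1"] == pytest.approx(2.0)   # sqrt(4 * 1)
        assert per["g3"] == pytest.approx(1.0)   # identity case
        # FCexp=2, FCprop=2 -> also 2.0
        res2 = fcscore(self._markers(), pd.Series({"g1": 2.0, "g2": 2.0, "g3": 1.0}),
                       pd.Series({"A": 2.0, "B": 1.0}))
        assert res2.per_gene.set_index("gene")["fcscore"]["g1"] == pytest.approx(2.0)

    @given(st.lists(st.tuples(st.floats(0.05, 50), st.floats(0.05, 20)),
                    min_size=1, max_size=12))
    def test_square_identity(self, pairs):
        markers = pd.DataFrame({
            "gene": [f"g{i}" for i in range(len(pairs))],
            "cluster": ["A"] * len(pairs),
        })
        fcexp = pd.Series({f"g{i}": e for i, (e, _) in enumerate(pairs)})
        fcprop = pd.Series({"A": pairs[0][1]})
        res = fcscore(markers, fcexp, fcprop)
        err = (res.per_gene["fcscore"] ** 2
               - res.per_gene["fcexp"] * res.per_gene["fcprop"]).abs().max()
        assert err < 1e-12

    def test_missing_fcexp_excluded_and_counted(self):
        fcexp = pd.Series({"g1": 4.0, "g2": np.nan, "g3": 1.0})
        fcprop = pd.Series({"A": 1.0, "B": 1.0})
        res = fcscore(self._markers(), fcexp, fcprop)
        a = res.clusters.set_index("cluster")
        assert a.loc["A", "n_markers"] == 2 and a.loc["A", "n_scored"] == 1
        assert res.missing_genes == ["g2"]
        assert a.loc["A", "mean_fcscore"] == pytest.approx(2.0)

    def test_cluster_without_scoreable_markers_ranked_last_flagged(self):
        fcexp = pd.Series({"g1": 4.0, "g2": 4.0, "g3": np.nan})
        fcprop = pd.Series({"A": 1.0, "B": 1.0})
        res = fcscore(self._markers(), fcexp, fcprop)
        last = res.clusters.iloc[-1]
        assert last["cluster"] == "B" and last["flagged"]

    def test_missing_fcprop_rejected(self):
        with pytest.raises(InputError):
            fcscore(self._markers(), pd.Series({"g1": 1.0}), pd.Series({"A": 1.0}))
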