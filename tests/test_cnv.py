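"""Expression-CNV inference, calibration, subclone calling and differential
copy number."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonetraj import (
    CellMeta,
    CNVMatrix,
    ExpressionMatrix,
    call_subclones,
    classify_malignancy,
    cnv_level,
    differential_cnv,
    infer_cnv,
    normalize_e,
    sample_reference,
)
from clonetraj.cnv import moving_average


class TestSampleReference:
    def meta(self, n_opc=500):
        table = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n_opc + 50)],
            "sample_id": "s1",
            "condition": "primary",
        })
        table["cell_type"] = ["OPC"] * n_opc + ["Mic"] * 50
        return CellMeta(table)

    def test_exact_n_distinct_ids(self):
        ref = sample_reference(self.meta(), "OPC", n=300, rng_seed=0)
        assert len(ref) == 300 and len(set(ref)) == 300

    def test_clamped_with_warning_when_short(self):
        with pytest.warns(UserWarning, match="taking all"):
            ref = sample_reference(self.meta(n_opc=100), "OPC", n=300)
        assert len(ref) == 100

    def test_deterministic_under_seed(self):
        a = sample_reference(self.meta(), "OPC", n=300, rng_seed=3)
        b = sample_reference(self.meta(), "OPC", n=300, rng_seed=3)
        assert a == b

    def test_unknown_type_raises(self):
        with pytest.raises(ValueError, match="no cells"):
            sample_reference(self.meta(), "Tcell")


class TestMovingAverage:
    def brute_force(self, x, window):
        h = window // 2
        out = np.empty_like(x, dtype=float)
        for i in range(len(x)):
            lo, hi = max(0, i - h), min(len(x), i + h + 1)
            out[i] = x[lo:hi].mean(axis=0)
        return out

    def test_matches_bruteforce_on_toy_chromosome(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 4))
        for window in (3, 7, 101):
            np.testing.assert_allclose(
                moving_average(x, window), self.brute_force(x, window),
                atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=40), st.integers(0, 10))
    def test_matches_bruteforce_property(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 2))
        np.testing.assert_allclose(
            moving_average(x, 7), self.brute_force(x, 7), atol=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 3))
        np.testing.assert_allclose(moving_average(x + 2.5, 7),
                                   moving_average(x, 7) + 2.5, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average(np.zeros((5, 1)), 4)


class TestInferCNV:
    def test_reference_only_input_calibrates_to_one(self, default_cohort,
                                                    e_default):
        _, genes, _, truth = default_cohort
        normal = list(truth.loc[~truth["true_malignant"], "cell_id"])
        e_norm = e_default.subset(cells=normal)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cnv = infer_cnv(e_norm, genes, normal[:150])
        assert np.abs(cnv.values - 1).mean() < 0.05

    def test_reference_mean_calibrated(self, cnv_bundle):
        cnv = cnv_bundle["cnv"]
        ref_cols = cnv.cell_index(cnv.reference_cell_ids)
        assert 0.95 <= cnv.values[:, ref_cols].mean() <= 1.05

    def test_planted_gain_sign_recovered_in_carriers(self, default_cohort,
                                                     cnv_bundle):
        _, _, _, truth = default_cohort
        cnv = cnv_bundle["cnv"]
        gid = {g: i for i, g in enumerate(cnv.gene_ids)}
        seg = [gid[f"G{i:05d}"] for i in range(200) if f"G{i:05d}" in gid]
        carriers = list(truth.loc[
            truth["true_subclone"].eq("subclone1").fillna(False), "cell_id"])
        others = list(truth.loc[
            truth["true_subclone"].eq("subclone2").fillna(False), "cell_id"])
        seg_mean_car = cnv.values[np.ix_(seg, cnv.cell_index(carriers))].mean(axis=0)
        seg_mean_oth = cnv.values[np.ix_(seg, cnv.cell_index(others))].mean()
        assert (seg_mean_car > seg_mean_oth).mean() >= 0.99

    def test_tiny_chromosome_passes_through_unsmoothed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(10, 40)) + 1
        e = normalize_e(ExpressionMatrix(counts, [f"g{i}" for i in range(10)],
                                         [f"c{i}" for i in range(40)]))
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)],
            "chromosome": ["chr1"] * 8 + ["chr2"] * 2,
            "start": list(range(8)) + [0, 1],
            "end": [x + 1 for x in list(range(8)) + [0, 1]],
        })
        with pytest.warns(UserWarning, match="unsmoothed"):
            infer_cnv(e, ann, [f"c{i}" for i in range(20)], window=3,
                      expr_cutoff=0, min_cells_per_gene=1)

    def test_count_range_filter_drops_cells(self, ):
        rng = np.random.default_rng(0)
        counts = rng.poisson(30.0, size=(20, 30)) + 1
        counts[:, 0] = 0
        counts[0, 0] = 5  # 5 total counts < 500 -> dropped
        m = ExpressionMatrix(counts, [f"g{i}" for i in range(20)],
                             [f"c{i}" for i in range(30)])
        e = normalize_e(m)
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)],
            "chromosome": "chr1",
            "start": range(20),
            "end": range(1, 21),
        })
        with pytest.warns(UserWarning, match="count"):
            cnv = infer_cnv(e, ann, [f"c{i}" for i in range(10, 30)], window=3,
                            expr_cutoff=0, min_cells_per_gene=1, counts=m)
        assert "c0" not in cnv.cell_ids


class TestCnvLevel:
    def toy_cnv(self, values, counts=None):
        g = [f"g{i}" for i in range(values.shape[0])]
        c = [f"c{i}" for i in range(values.shape[1])]
        cnv = CNVMatrix(values, g, c, [], window_size=3)
        if counts is None:
            return cnv, None
        return cnv, ExpressionMatrix(counts, g, c)

    def test_all_normal_cell_is_exactly_zero(self):
        cnv, _ = self.toy_cnv(np.ones((5, 3)))
        assert (cnv_level(cnv) == 0).all()

    def test_single_expressed_gene_at_two_gives_one(self):
        values = np.ones((3, 1)); values[1, 0] = 2.0
        counts = np.zeros((3, 1), dtype=int); counts[1, 0] = 7
        cnv, cmat = self.toy_cnv(values, counts)
        assert cnv_level(cnv, counts=cmat).iloc[0] == pytest.approx(1.0)

    def test_additive_over_disjoint_gene_sets_and_order_invariant(self):
        rng = np.random.default_rng(0)
        values = np.clip(1 + rng.normal(0, 0.2, size=(10, 4)), 0, 2)
        cnv, _ = self.toy_cnv(values)
        top, _ = self.toy_cnv(values[:5])
        bottom, _ = self.toy_cnv(values[5:])
        np.testing.assert_allclose(
            cnv_level(cnv).to_numpy(),
            cnv_level(top).to_numpy() + cnv_level(bottom).to_numpy())
        perm = rng.permutation(10)
        shuffled, _ = self.toy_cnv(values[perm])
        np.testing.assert_allclose(cnv_level(cnv).to_numpy(),
                                   cnv_level(shuffled).to_numpy())

    def test_malignant_cells_separate_from_normal(self, default_cohort,
                                                  cnv_bundle):
        from sklearn.metrics import roc_auc_score

        truth = default_cohort.truth.set_index("cell_id")
        levels = cnv_bundle["levels"]
        auroc = roc_auc_score(
            truth["true_malignant"].reindex(levels.index).to_numpy(),
            levels.to_numpy())
        assert auroc >= 0.95


class TestSubclones:
    def test_planted_subclones_recovered(self, default_cohort, cnv_bundle):
        from sklearn.metrics import adjusted_rand_score

        truth = default_cohort.truth.set_index("cell_id")
        sub = cnv_bundle["subclones"]
        ari = adjusted_rand_score(
            truth.loc[sub.labels.index, "true_subclone"].to_numpy(),
            sub.labels.to_numpy())
        assert sub.k == 2
        assert ari >= 0.9

    def test_no_planted_cnv_flags_low_confidence(self, default_cohort,
                                                 e_default):
        _, genes, _, truth = default_cohort
        normal = list(truth.loc[~truth["true_malignant"], "cell_id"])
        e_norm = e_default.subset(cells=normal)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cnv = infer_cnv(e_norm, genes, normal[:150])
            sub = call_subclones(cnv, cells=normal[150:])
        assert sub.low_confidence

    def test_duplicated_cells_get_identical_labels(self):
        rng = np.random.default_rng(0)
        base = np.clip(1 + rng.normal(0, 0.1, size=(50, 20)), 0, 2)
        base[:25, 10:] = np.clip(base[:25, 10:] + 0.5, 0, 2)
        values = np.hstack([base, base])  # duplicate every cell
        cnv = CNVMatrix(values, [f"g{i}" for i in range(50)],
                        [f"c{i}" for i in range(40)], [], 3)
        sub = call_subclones(cnv, k=2)
        labels = sub.labels.to_numpy()
        assert np.array_equal(labels[:20], labels[20:])

    def test_identical_profiles_single_cluster(self):
        cnv = CNVMatrix(np.ones((10, 8)), [f"g{i}" for i in range(10)],
                        [f"c{i}" for i in range(8)], [], 3)
        with pytest.warns(UserWarning, match="identical"):
            sub = call_subclones(cnv)
        assert sub.k == 1 and sub.labels.nunique() == 1


class TestMalignancy:
    def test_accuracy_on_default_cohort(self, default_cohort, cnv_bundle):
        truth = default_cohort.truth.set_index("cell_id")
        levels = cnv_bundle["levels"]
        clusters = truth["true_type"].reindex(levels.index)
        call = classify_malignancy(levels, clusters,
                                   cnv_bundle["reference"])
        acc = (call == truth["true_malignant"].reindex(call.index)).mean()
        assert acc >= 0.98

    def test_reference_cells_never_malignant(self, default_cohort, cnv_bundle):
        truth = default_cohort.truth.set_index("cell_id")
        levels = cnv_bundle["levels"]
        call = classify_malignancy(levels,
                                   truth["true_type"].reindex(levels.index),
                                   cnv_bundle["reference"])
        assert not call.loc[cnv_bundle["reference"]].any()

    def test_unimodal_levels_trigger_warning_path(self):
        rng = np.random.default_rng(0)
        levels = pd.Series(rng.normal(5, 0.01, size=100),
                           index=[f"c{i}" for i in range(100)])
        clusters = pd.Series(np.repeat([0, 1], 50), index=levels.index)
        with pytest.warns(UserWarning, match="unimodal|unreliable"):
            call = classify_malignancy(levels, clusters)
        assert call.isin([True, False]).all()


class TestDifferentialCNV:
    def test_planted_segment_dominates_significant_set(self, default_cohort,
                                                       cnv_bundle):
        truth = default_cohort.truth
        cnv = cnv_bundle["cnv"]
        s1 = list(truth.loc[truth["true_subclone"].eq("subclone1")
                            .fillna(False), "cell_id"])
        s2 = list(truth.loc[truth["true_subclone"].eq("subclone2")
                            .fillna(False), "cell_id"])
        table = differential_cnv(cnv, s1, s2)
        sig_up = table[table["significant"] & (table["delta_mean_proxy"] > 0)]
        # genes with higher copy proxy in subclone1: its own chr1 gain plus
        # subclone2's chr2 loss seen from the other side
        on_planted = sig_up["gene_id"].str.slice(1).astype(int) < 400
        assert on_planted.mean() >= 0.95

    def test_same_group_twice_all_zero_delta(self, cnv_bundle):
        cnv = cnv_bundle["cnv"]
        cells = cnv.cell_ids[:20]
        table = differential_cnv(cnv, cells, cells)
        assert (table["delta_mean_proxy"] == 0).all()

    def test_mann_whitney_matches_enumeration_for_4v4(self):
        from itertools import combinations
        from scipy.stats import rankdata

        rng = np.random.default_rng(0)
        values = np.clip(1 + rng.normal(0, 0.3, size=(6, 8)), 0, 2)
        cnv = CNVMatrix(values, [f"g{i}" for i in range(6)],
                        [f"c{i}" for i in range(8)], [], 3)
        table = differential_cnv(cnv, cnv.cell_ids[:4], cnv.cell_ids[4:])
        for gi in range(6):
            ranks = rankdata(values[gi])
            obs = ranks[:4].sum()
            sums = np.array([ranks[list(c)].sum()
                             for c in combinations(range(8), 4)])
            p_exact = min(1.0, 2 * min((sums <= obs).mean(),
                                       (sums >= obs).mean()))
            assert table["p_value"].iloc[gi] == pytest.approx(p_exact,
                                                              abs=1e-12)

    def test_constant_gene_gets_p_one(self):
        values = np.ones((2, 8))
        values[1] = np.linspace(0.5, 1.5, 8)
        cnv = CNVMatrix(values, ["flat", "var"], [f"c{i}" for i in range(8)],
                        [], 3)
        table = differential_cnv(cnv, cnv.cell_ids[:4], cnv.cell_ids[4:])
        assert table.loc[table["gene_id"] == "flat", "p_value"].iloc[0] == 1.0
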