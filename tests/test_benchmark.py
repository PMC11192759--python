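"""Benchmark metrics, entity-exclusive splits, ML baseline pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netavatar.benchmark import (
    BenchmarkDataset,
    balanced_accuracy,
    ic50_correlation,
    make_splits,
    roc_auc,
    run_baselines,
)
from netavatar.dose_response import DoseResponseCurve, IC50Fit, make_dose_grid
from netavatar.errors import SplitError, UndefinedMetricError
from netavatar.pharmacology import TargetProfile


def vectors_with_rates(tpr_frac, tnr_frac, n_pos=100, n_neg=100):
    """Construct score vectors achieving exact TPR/TNR at threshold 0.5."""
    k_tp = round(tpr_frac * n_pos)
    k_tn = round(tnr_frac * n_neg)
    pred = np.concatenate(
        [
            np.ones(k_tp),
            np.zeros(n_pos - k_tp),  # false negatives
            np.zeros(k_tn),
            np.ones(n_neg - k_tn),  # false positives
        ]
    )
    ref = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    return pred, ref


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "tpr,tnr,expected_ba",
        [(0.37, 0.78, 0.575), (0.46, 0.78, 0.62), (1.0, 1.0, 1.0)],
    )
    def test_from_sensitivity_specificity_pairs(self, tpr, tnr, expected_ba):
        pred, ref = vectors_with_rates(tpr, tnr)
        m = balanced_accuracy(pred, ref, 0.5, 0.5)
        assert m.TPR == pytest.approx(tpr)
        assert m.TNR == pytest.approx(tnr)
        assert m.BA == pytest.approx(expected_ba)

    def test_threshold_is_inclusive(self):
        m = balanced_accuracy([20.0, 19.999], [30.0, 29.0], 20.0, 30.0)
        assert m.TPR == 1.0 and m.TNR == 1.0

    def test_single_class_reference_rejected(self):
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy([1.0, 0.0], [1.0, 1.0], 0.5, 0.5)

    def test_invariant_under_class_swap(self):
        rng = np.random.default_rng(0)
        pred = rng.uniform(0, 1, 50)
        ref = rng.uniform(0, 1, 50)
        m = balanced_accuracy(pred, ref, 0.5, 0.5)
        # swap classes: negate both scores around the thresholds
        m_swapped = balanced_accuracy(1 - pred, 1 - ref, 0.5 + 1e-12, 0.5 + 1e-12)
        assert m_swapped.BA == pytest.approx(m.BA)
        assert (m_swapped.TPR, m_swapped.TNR) == (
            pytest.approx(m.TNR),
            pytest.approx(m.TPR),
        )


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_perfect_inversion(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1]) == 0.0

    def test_hand_counted_concordant_pairs(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))
        assert roc_auc(scores, labels) == pytest.approx(3 / 4)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_rank_statistic_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            return
        assert roc_auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [1, 1])


class TestIC50Correlation:
    def curves(self, values):
        return [
            DoseResponseCurve(
                drug=f"d{i}",
                cell_line="CL",
                doses_nM=np.array([1.0]),
                viability=np.array([1.0]),
                ic50=IC50Fit(ic50_nM=v, censored=not np.isfinite(v)),
            )
            for i, v in enumerate(values)
        ]

    def test_identical_vectors_r_one(self):
        curves = self.curves([10.0, 100.0, 1000.0])
        ref = {("CL", f"d{i}"): v for i, v in enumerate([10.0, 100.0, 1000.0])}
        r, censored = ic50_correlation(curves, ref)
        assert r == pytest.approx(1.0)
        assert censored == 0

    def test_anti_ordered_r_minus_one(self):
        curves = self.curves([10.0, 100.0, 1000.0])
        ref = {("CL", f"d{i}"): v for i, v in enumerate([1000.0, 100.0, 10.0])}
        assert ic50_correlation(curves, ref)[0] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        pred = {k: v for k, v in zip("abcde", [10.0, 30.0, 100.0, 300.0, 5000.0])}
        ref = {k: v for k, v in zip("abcde", [20.0, 25.0, 80.0, 900.0, 2000.0])}
        x, y = np.log10(list(pred.values())), np.log10(list(ref.values()))
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert ic50_correlation(pred, ref)[0] == pytest.approx(manual)

    def test_censored_excluded_and_counted(self):
        curves = self.curves([10.0, 100.0, 1000.0, np.inf])
        ref = {("CL", f"d{i}"): 10.0 ** (i + 1) for i in range(4)}
        r, censored = ic50_correlation(curves, ref)
        assert censored == 1

    def test_insufficient_overlap_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ic50_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def toy_rows(n_cells=4, n_drugs=2, doses=(0.0, 10.0, 100.0, 1000.0)):
    rows = [
        (f"CL{c}", f"d{d}", dose, 0.0)
        for c in range(n_cells)
        for d in range(n_drugs)
        for dose in doses
    ]
    return pd.DataFrame(rows, columns=["cell_line", "drug", "dose_nM", "killrate"])


class TestSplits:
    def test_cex_holds_out_whole_cell_lines(self):
        rows = toy_rows(4, 2)
        train, test = make_splits(rows, "CEX", test_fraction=0.5, seed=0)
        train_cells = set(rows.iloc[train].cell_line)
        test_cells = set(rows.iloc[test].cell_line)
        assert train_cells.isdisjoint(test_cells)
        assert len(test_cells) == 2
        assert len(train) + len(test) == len(rows)

    def test_dex_empty_drug_intersection(self):
        rows = toy_rows(3, 4)
        train, test = make_splits(rows, "DEX", test_fraction=0.25, seed=1)
        assert set(rows.iloc[train].drug).isdisjoint(set(rows.iloc[test].drug))

    def test_aex_two_by_two_by_hand(self):
        rows = toy_rows(2, 2)
        train, test = make_splits(rows, "AEX", test_fraction=0.5, seed=0)
        train_rows, test_rows = rows.iloc[train], rows.iloc[test]
        assert len(set(test_rows.cell_line)) == 1 and len(set(test_rows.drug)) == 1
        assert set(train_rows.cell_line).isdisjoint(set(test_rows.cell_line))
        assert set(train_rows.drug).isdisjoint(set(test_rows.drug))
        # mixed rows dropped: 4 dose points per (cell, drug) block
        assert len(train_rows) == len(test_rows) == 4

    def test_infeasible_aex_rejected(self):
        with pytest.raises(SplitError):
            make_splits(toy_rows(1, 1), "AEX", test_fraction=0.5, seed=0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_all_strategies_entity_disjoint_on_random_datasets(self, seed):
        rng = np.random.default_rng(seed)
        rows = toy_rows(int(rng.integers(3, 7)), int(rng.integers(3, 6)))
        for strategy in ("CEX", "DEX", "AEX"):
            train, test = make_splits(rows, strategy, test_fraction=0.3, seed=seed)
            tr, te = rows.iloc[train], rows.iloc[test]
            assert len(te) > 0 and len(tr) > 0
            if strategy in ("CEX", "AEX"):
                assert set(tr.cell_line).isdisjoint(set(te.cell_line))
            if strategy in ("DEX", "AEX"):
                assert set(tr.drug).isdisjoint(set(te.drug))


def linear_dataset(seed=0, n_cells=8, n_drugs=4):
    """Killrate is an exact linear-in-features construct (inhibition-driven)."""
    rng = np.random.default_rng(seed)
    nodes = [f"T{k}" for k in range(n_drugs)]
    profiles = {
        f"d{k}": TargetProfile(drug=f"d{k}", targets={nodes[k]: 100.0})
        for k in range(n_drugs)
    }
    genes = [f"g{j}" for j in range(3)]
    expression = pd.DataFrame(
        rng.uniform(0.5, 2.0, (n_cells, len(genes))),
        index=[f"CL{i}" for i in range(n_cells)],
        columns=genes,
    )
    sens = {f"CL{i}": rng.uniform(0.3, 0.9) for i in range(n_cells)}
    doses = make_dose_grid(8)
    rows = []
    for cell in expression.index:
        for drug in profiles:
            for dose in doses:
                inhib = dose / (dose + 100.0)
                rows.append((cell, drug, dose, sens[cell] * inhib))
    mono = pd.DataFrame(rows, columns=["cell_line", "drug", "dose_nM", "killrate"])
    return BenchmarkDataset(
        monotherapy=mono, expression=expression, profiles=profiles, feature_nodes=nodes
    )


class TestBaselines:
    def test_ridge_recovers_linear_killrate_structure(self):
        ds = linear_dataset()
        summary = run_baselines(ds, strategy="CEX", models=("ridge",), n_splits=2)
        assert summary.loc[summary.model == "ridge", "killrate_pearson_r"].iloc[0] > 0.95

    def test_all_three_model_families_train(self):
        ds = linear_dataset()
        summary = run_baselines(
            ds, strategy="DEX", models=("ridge", "nn", "gbt"), n_splits=1
        )
        assert set(summary.model) == {"ridge", "nn", "gbt"}
        assert np.isfinite(summary["killrate_pearson_r"]).all()

    def test_shuffled_reference_synergy_ba_near_chance(self):
        rng = np.random.default_rng(1)
        ds = linear_dataset()
        combos = [
            (c, "d0", "d1") for c in ds.expression.index
        ]
        ds.reference_synergy = pd.DataFrame(
            {
                "cell_line": [c for c, _, _ in combos],
                "drugA": [a for _, a, _ in combos],
                "drugB": [b for _, _, b in combos],
                "synergy": rng.permutation([15.0, 45.0] * (len(combos) // 2)),
            }
        )
        summary = run_baselines(ds, strategy="CEX", models=("ridge",), n_splits=3)
        ba = summary["BA"].iloc[0]
        assert abs(ba - 0.5) < 0.2  # chance level within Monte-Carlo error
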