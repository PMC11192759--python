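"""Benchmarking synergy and monotherapy predictions against references.

Metrics follow standard screening practice: predictions and reference
synergy scores are dichotomized at stated thresholds (>= threshold is
synergistic; the simulator's 0-1 Bliss scale is multiplied by 100 at
this boundary so a 0.2 score lines up with a reference threshold of 20),
yielding TPR/TNR and balanced accuracy BA = (TPR + TNR) / 2; ranking
quality uses the Mann-Whitney AUC with midranked ties; monotherapy
potency agreement uses Pearson correlation on log10 IC50.

Three standard ML baselines (ridge regression, a small fully-connected
network, gradient-boosted trees) are trained to regress monotherapy
killrates from cell-line expression concatenated with per-node
dose-dependent target-inhibition features, then asked to predict full
combination grids whose synergy is scored by the same Bliss machinery —
so the baselines see exactly the feature space available to the
mechanistic model, but no combination data during training.

Train/test splitting is exclusive by cell line (CEX), by drug (DEX) or
by both (AEX); AEX drops rows mixing held-in and held-out entities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .dose_response import DoseResponseCurve, fit_ic50, make_dose_grid
from .errors import (
    InputError,
    SplitError,
    TrainingError,
    UndefinedMetricError,
)
from .pharmacology import TargetProfile, target_inhibition
from .synergy import bliss_excess_grid

PRESENTATION_SCALE = 100.0  # 0-1 Bliss scale -> 0-100 at the benchmarking boundary
SPLIT_STRATEGIES = ("CEX", "DEX", "AEX")
BASELINE_MODELS = ("ridge", "nn", "gbt")


@dataclass
class BenchmarkMetrics:
    TPR: float = np.nan
    TNR: float = np.nan
    BA: float = np.nan
    AUC: float = np.nan
    pearson_r: float = np.nan


@dataclass
class BenchmarkDataset:
    """Monotherapy rows plus feature blocks for the ML baselines.

    ``monotherapy`` needs columns cell_line, drug, dose_nM, killrate.
    ``expression`` is a cell_line x gene DataFrame; ``profiles`` maps drug
    -> TargetProfile; ``feature_nodes`` fixes the node order of the
    inhibition feature block.
    """

    monotherapy: pd.DataFrame
    expression: pd.DataFrame
    profiles: dict[str, TargetProfile]
    feature_nodes: list[str]
    reference_synergy: pd.DataFrame | None = None  # cell_line, drugA, drugB, synergy

    def __post_init__(self) -> None:
        required = {"cell_line", "drug", "dose_nM", "killrate"}
        if not required.issubset(self.monotherapy.columns):
            raise InputError(f"monotherapy table must have columns {sorted(required)}")

    def inhibition_vector(self, doses_by_drug: Mapping[str, float]) -> np.ndarray:
        """Combined per-node inhibition for a set of (drug, dose) exposures."""
        inhib = np.zeros(len(self.feature_nodes))
        for drug, dose in doses_by_drug.items():
            prof = self.profiles[drug]
            for k, node in enumerate(self.feature_nodes):
                if node in prof.targets:
                    i = target_inhibition(dose, prof.targets[node])
                    inhib[k] = 1.0 - (1.0 - inhib[k]) * (1.0 - i)
        return inhib

    def features(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        rows = self.monotherapy if rows is None else rows
        feats = np.empty((len(rows), self.expression.shape[1] + len(self.feature_nodes)))
        for k, r in enumerate(rows.itertuples(index=False)):
            expr = self.expression.loc[r.cell_line].to_numpy()
            inhib = self.inhibition_vector({r.drug: r.dose_nM})
            feats[k] = np.concatenate([expr, inhib])
        return feats


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(
    predicted_scores: Sequence[float],
    reference_scores: Sequence[float],
    threshold_pred: float,
    threshold_ref: float,
) -> BenchmarkMetrics:
    """Dichotomize both score vectors and report TPR/TNR/BA.

    Scores at or above their threshold count as synergistic.
    """
    pred = np.asarray(predicted_scores, dtype=float)
    ref = np.asarray(reference_scores, dtype=float)
    if pred.shape != ref.shape:
        raise InputError("prediction and reference vectors differ in length")
    pred_pos = pred >= threshold_pred
    ref_pos = ref >= threshold_ref
    n_pos, n_neg = int(ref_pos.sum()), int((~ref_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("reference contains a single class after dichotomization")
    tpr = float(np.sum(pred_pos & ref_pos) / n_pos)
    tnr = float(np.sum(~pred_pos & ~ref_pos) / n_neg)
    return BenchmarkMetrics(TPR=tpr, TNR=tnr, BA=(tpr + tnr) / 2.0)


def roc_auc(predicted_scores: Sequence[float], reference_labels: Sequence[int]) -> float:
    """AUC via the Mann-Whitney rank statistic with midranked ties."""
    scores = np.asarray(predicted_scores, dtype=float)
    labels = np.asarray(reference_labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("need both classes for AUC")
    ranks = rankdata(scores)  # midranks for ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ic50_correlation(
    predicted_curves: Sequence[DoseResponseCurve] | Mapping[tuple, float],
    reference_ic50s: Mapping,
) -> tuple[float, int]:
    """Pearson r on log10 IC50 over the key overlap.

    Censored or non-finite predictions are excluded; returns (r,
    n_censored_excluded).  Requires at least 3 overlapping finite pairs.
    """
    if isinstance(predicted_curves, Mapping):
        predicted = dict(predicted_curves)
    else:
        predicted = {}
        for c in predicted_curves:
            predicted[(c.cell_line, c.drug)] = (
                np.inf if c.ic50.censored else c.ic50.ic50_nM
            )
    xs, ys, censored = [], [], 0
    for key in sorted(set(predicted) & set(reference_ic50s)):
        p, r = predicted[key], reference_ic50s[key]
        if not np.isfinite(p) or not np.isfinite(r) or p <= 0 or r <= 0:
            censored += 1
            continue
        xs.append(np.log10(p))
        ys.append(np.log10(r))
    if len(xs) < 3:
        raise UndefinedMetricError(
            f"only {len(xs)} finite overlapping IC50 pairs (need >= 3)"
        )
    r, _ = pearsonr(xs, ys)
    return float(r), censored


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def make_splits(
    dataset: BenchmarkDataset | pd.DataFrame,
    strategy: str,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Entity-exclusive train/test split over monotherapy rows.

    CEX holds out whole cell lines, DEX whole drugs, AEX both (rows mixing
    held-in and held-out entities are dropped).  Returns positional row
    indices into the monotherapy table.
    """
    rows = dataset.monotherapy if isinstance(dataset, BenchmarkDataset) else dataset
    if strategy not in SPLIT_STRATEGIES:
        raise SplitError(f"unknown strategy {strategy!r}")
    if len(rows) == 0:
        raise SplitError("empty dataset")
    rng = np.random.default_rng(seed)

    def hold_out(values: np.ndarray) -> set:
        uniq = np.sort(np.unique(values))
        n_test = max(1, int(round(test_fraction * len(uniq))))
        if n_test >= len(uniq):
            raise SplitError(
                f"cannot hold out {n_test} of {len(uniq)} entities at "
                f"test_fraction={test_fraction}"
            )
        return set(rng.choice(uniq, size=n_test, replace=False))

    cells = rows["cell_line"].to_numpy()
    drugs = rows["drug"].to_numpy()
    if strategy == "CEX":
        held = hold_out(cells)
        test = np.isin(cells, list(held))
        train = ~test
    elif strategy == "DEX":
        held = hold_out(drugs)
        test = np.isin(drugs, list(held))
        train = ~test
    else:  # AEX
        held_c = hold_out(cells)
        held_d = hold_out(drugs)
        in_c, in_d = np.isin(cells, list(held_c)), np.isin(drugs, list(held_d))
        test = in_c & in_d
        train = ~in_c & ~in_d
        if not test.any() or not train.any():
            raise SplitError("AEX split infeasible: too few entities")
    return np.where(train)[0], np.where(test)[0]


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def _make_model(name: str, seed: int):
    if name == "ridge":
        from sklearn.linear_model import Ridge

        return Ridge(alpha=1.0)
    if name == "nn":
        from sklearn.neural_network import MLPRegressor

        return MLPRegressor(
            hidden_layer_sizes=(64, 64),
            early_stopping=True,
            max_iter=500,
            random_state=seed,
        )
    if name == "gbt":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            n_estimators=200,
            random_state=seed,
            deterministic=True,
            verbose=-1,
            min_child_samples=5,
        )
    raise InputError(f"unknown baseline model {name!r}")


def predict_combination_synergy(
    model,
    dataset: BenchmarkDataset,
    cell_line: str,
    drugA: str,
    drugB: str,
    doses: np.ndarray | None = None,
) -> float:
    """Predicted Bliss-max synergy for one combination from a killrate model.

    The model predicts the full dose matrix plus the two marginals; the
    Bliss machinery then scores the grid exactly as for the simulator.
    """
    doses = make_dose_grid() if doses is None else doses
    expr = dataset.expression.loc[cell_line].to_numpy()
    feats = []
    for da in doses:
        for db in doses:
            inhib = dataset.inhibition_vector({drugA: float(da), drugB: float(db)})
            feats.append(np.concatenate([expr, inhib]))
    pred = np.clip(model.predict(np.asarray(feats)), 0.0, 1.0)
    kab = pred.reshape(len(doses), len(doses))
    excess = bliss_excess_grid(kab[:, 0], kab[0, :], kab)
    return float(np.maximum(excess, 0.0).max())


def run_baselines(
    dataset: BenchmarkDataset,
    strategy: str = "CEX",
    models: Sequence[str] = BASELINE_MODELS,
    n_splits: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    synergy_threshold_pred: float = 20.0,
    synergy_threshold_ref: float = 30.0,
) -> pd.DataFrame:
    """Train the standard ML baselines and score them per split.

    Each model regresses monotherapy killrate on expression + inhibition
    features.  Per split it reports the killrate Pearson r on held-out
    monotherapy rows, log-IC50 correlation of refitted curves, and —
    when the dataset carries reference synergy — BA/AUC of Bliss-scored
    predicted combination grids (scaled x100 at this boundary).
    Metrics are averaged over ``n_splits`` random splits.
    """
    rows = dataset.monotherapy.reset_index(drop=True)
    X = dataset.features(rows)
    y = rows["killrate"].to_numpy()
    if X.shape[0] == 0 or np.allclose(X.std(axis=0), 0):
        raise TrainingError("degenerate feature matrix (no rows or zero variance)")

    records = []
    for split_idx in range(n_splits):
        train_idx, test_idx = make_splits(
            rows, strategy, test_fraction=test_fraction, seed=seed + split_idx
        )
        for name in models:
            model = _make_model(name, seed=seed + split_idx)
            try:
                model.fit(X[train_idx], y[train_idx])
            except Exception as exc:  # noqa: BLE001 - surfaced as TrainingError
                raise TrainingError(f"{name} failed to train: {exc}") from exc
            pred = np.clip(model.predict(X[test_idx]), 0.0, 1.0)
            truth = y[test_idx]
            r_kill = np.nan
            if len(np.unique(truth)) > 1 and len(np.unique(pred)) > 1:
                r_kill = float(pearsonr(pred, truth)[0])

            # per-(cell, drug) IC50 refits on the held-out monotherapy curves
            test_rows = rows.iloc[test_idx].assign(pred=pred)
            pred_ic50, ref_ic50 = {}, {}
            for (cell, drug), sub in test_rows.groupby(["cell_line", "drug"]):
                if len(sub) < 4:
                    continue
                fit_p = fit_ic50(sub["dose_nM"], 1.0 - sub["pred"])
                fit_r = fit_ic50(sub["dose_nM"], 1.0 - sub["killrate"])
                if not fit_p.censored and not fit_r.censored:
                    pred_ic50[(cell, drug)] = fit_p.ic50_nM
                    ref_ic50[(cell, drug)] = fit_r.ic50_nM
            try:
                r_ic50, _ = ic50_correlation(pred_ic50, ref_ic50)
            except UndefinedMetricError:
                r_ic50 = np.nan

            ba = auc = np.nan
            if dataset.reference_synergy is not None and len(dataset.reference_synergy):
                ref = dataset.reference_synergy
                preds = [
                    PRESENTATION_SCALE
                    * predict_combination_synergy(
                        model, dataset, r.cell_line, r.drugA, r.drugB
                    )
                    for r in ref.itertuples(index=False)
                ]
                refs = ref["synergy"].to_numpy(dtype=float)
                try:
                    m = balanced_accuracy(
                        preds, refs, synergy_threshold_pred, synergy_threshold_ref
                    )
                    ba = m.BA
                    auc = roc_auc(preds, refs >= synergy_threshold_ref)
                except UndefinedMetricError:
                    pass
            records.append(
                {
                    "model": name,
                    "split": split_idx,
                    "strategy": strategy,
                    "killrate_pearson_r": r_kill,
                    "ic50_pearson_r": r_ic50,
                    "BA": ba,
                    "AUC": auc,
                }
            )
    df = pd.DataFrame(records)
    summary = (
        df.groupby("model", sort=True)[["killrate_pearson_r", "ic50_pearson_r", "BA", "AUC"]]
        .mean()
        .reset_index()
    )
    summary["strategy"] = strategy
    summary["n_splits"] = n_splits
    return summary
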