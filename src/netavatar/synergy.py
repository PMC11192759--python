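"""16x16 combination screens and modified Bliss-independence scoring.

Under Bliss independence two drugs with single-agent killrates kA and kB
are expected to kill kA + kB - kA*kB of the cells; synergy is the excess
of the observed combination killrate over that expectation.  Negative
excess (antagonism) is clamped to zero before scoring — only synergy is
quantified.  Two summary scores are kept per grid: the maximum clamped
excess over the whole dose matrix (``bliss_score``) and the maximum
restricted to dose pairs where both members stay below their respective
monotherapy IC50s (``bliss_max_ic50``), the clinically interesting
sub-IC50 regime.

Grids are quality-controlled against dose-response principles: a
marginal viability that *rises* with dose by more than a tolerance
indicates a broken curve and disqualifies the grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .conditioning import CellLineAvatar
from .dose_response import make_dose_grid
from .engine import SimulationConfig, run_ensemble
from .errors import DegenerateInputError, InputError, NativeDeadError
from .pharmacology import TargetProfile

QC_MONOTONICITY_TOL = 0.1
SYNERGY_CATEGORY_LABELS = ("non", "moderate", "strong")


@dataclass
class CombinationGrid:
    """Killrate surface for one drug pair on one cell line.

    ``killrate_AB[i, j]`` is the killrate at dose ``doses_A[i]`` of drug A
    and ``doses_B[j]`` of drug B; row/column 0 are the monotherapy
    marginals.
    """

    drugA: str
    drugB: str
    cell_line: str
    doses_A: np.ndarray
    doses_B: np.ndarray
    killrate_AB: np.ndarray

    @property
    def killrate_A(self) -> np.ndarray:
        return self.killrate_AB[:, 0]

    @property
    def killrate_B(self) -> np.ndarray:
        return self.killrate_AB[0, :]

    @property
    def viability(self) -> np.ndarray:
        return 1.0 - self.killrate_AB

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(
            np.arange(len(self.doses_A)), np.arange(len(self.doses_B)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "cell_line": self.cell_line,
                "drugA": self.drugA,
                "drugB": self.drugB,
                "dose_A": self.doses_A[ii.ravel()],
                "dose_B": self.doses_B[jj.ravel()],
                "killrate": self.killrate_AB.ravel(),
            }
        )


@dataclass
class SynergyResult:
    drugA: str
    drugB: str
    cell_line: str
    bliss_excess: np.ndarray
    bliss_score: float
    bliss_max_ic50: float
    argmax_doses: tuple[float, float]
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)


@dataclass
class SynergyCategories:
    thresholds: tuple[float, float]  # t1 < t2: non < t1 <= moderate <= t2 < strong
    labels: list[str]
    centroids: tuple[float, float, float]


def bliss_excess_grid(
    killrate_A: Sequence[float],
    killrate_B: Sequence[float],
    killrate_AB: np.ndarray,
) -> np.ndarray:
    """Observed minus Bliss-expected killrate, unclamped.

    excess[i, j] = kAB[i, j] - (kA[i] + kB[j] - kA[i] * kB[j]).
    """
    ka = np.asarray(killrate_A, dtype=float)
    kb = np.asarray(killrate_B, dtype=float)
    kab = np.asarray(killrate_AB, dtype=float)
    if kab.shape != (len(ka), len(kb)):
        raise InputError(
            f"killrate_AB shape {kab.shape} does not match marginals "
            f"({len(ka)}, {len(kb)})"
        )
    for name, arr in (("killrate_A", ka), ("killrate_B", kb), ("killrate_AB", kab)):
        if np.any((arr < 0) | (arr > 1)):
            raise InputError(f"{name} outside [0, 1]")
    expected = ka[:, None] + kb[None, :] - ka[:, None] * kb[None, :]
    return kab - expected


def qc_grid(grid: CombinationGrid, tol: float = QC_MONOTONICITY_TOL) -> tuple[bool, list[str]]:
    """Check dose-response principles on both marginals.

    Fails when a marginal viability increases with dose by more than
    ``tol`` anywhere, or when any matrix entry is non-finite.
    """
    reasons: list[str] = []
    if not np.all(np.isfinite(grid.killrate_AB)):
        reasons.append("non-finite killrate entries")
    for name, marg in ((grid.drugA, 1.0 - grid.killrate_A), (grid.drugB, 1.0 - grid.killrate_B)):
        jumps = np.diff(marg)
        worst = jumps.max() if len(jumps) else 0.0
        if worst > tol:
            reasons.append(
                f"drug {name}: marginal viability rises by {worst:.3f} (> {tol}) with dose"
            )
    return (not reasons, reasons)


def max_synergy(
    grid: CombinationGrid,
    ic50_A: float = np.inf,
    ic50_B: float = np.inf,
    qc_tol: float = QC_MONOTONICITY_TOL,
    force: bool = False,
) -> SynergyResult:
    """Score a combination grid: clamped Bliss maxima and argmax doses.

    ``bliss_score`` is the maximum clamped excess over all cells;
    ``bliss_max_ic50`` restricts the search to cells with dose_A < ic50_A
    and dose_B < ic50_B (censored IC50s pass everything).  Ties resolve
    to the first cell in row-major order.
    """
    ok, reasons = qc_grid(grid, tol=qc_tol)
    if not ok and not force:
        return SynergyResult(
            drugA=grid.drugA,
            drugB=grid.drugB,
            cell_line=grid.cell_line,
            bliss_excess=np.full_like(grid.killrate_AB, np.nan),
            bliss_score=np.nan,
            bliss_max_ic50=np.nan,
            argmax_doses=(np.nan, np.nan),
            qc_pass=False,
            qc_reasons=reasons,
        )
    excess = bliss_excess_grid(grid.killrate_A, grid.killrate_B, grid.killrate_AB)
    clamped = np.maximum(excess, 0.0)
    flat_argmax = int(np.argmax(clamped))  # first maximum in row-major order
    i, j = np.unravel_index(flat_argmax, clamped.shape)
    sub = (grid.doses_A[:, None] < ic50_A) & (grid.doses_B[None, :] < ic50_B)
    max_sub = float(clamped[sub].max()) if np.any(sub) else 0.0
    return SynergyResult(
        drugA=grid.drugA,
        drugB=grid.drugB,
        cell_line=grid.cell_line,
        bliss_excess=excess,
        bliss_score=float(clamped.max()),
        bliss_max_ic50=max_sub,
        argmax_doses=(float(grid.doses_A[i]), float(grid.doses_B[j])),
        qc_pass=ok,
        qc_reasons=reasons,
    )


def combination_screen(
    avatar: CellLineAvatar,
    profileA: TargetProfile,
    profileB: TargetProfile,
    doses_A: Sequence[float] | None = None,
    doses_B: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
) -> CombinationGrid:
    """Simulate the full dose matrix for one drug pair on one avatar.

    Killrates are 1 - survival normalized to the untreated (0, 0) corner
    with the same seed, so the corner killrate is exactly 0.
    """
    doses_A = make_dose_grid() if doses_A is None else np.asarray(doses_A, dtype=float)
    doses_B = make_dose_grid() if doses_B is None else np.asarray(doses_B, dtype=float)
    config = config or SimulationConfig()
    base = run_ensemble(avatar, (), config)
    s0 = base.survival_fraction
    if s0 == 0:
        raise NativeDeadError(f"cell line {avatar.cell_line!r} is natively dead")
    kill = np.empty((len(doses_A), len(doses_B)))
    for i, da in enumerate(doses_A):
        for j, db in enumerate(doses_B):
            if da == 0 and db == 0:
                kill[i, j] = 0.0
                continue
            treatment = []
            if da > 0:
                treatment.append((profileA, float(da)))
            if db > 0:
                treatment.append((profileB, float(db)))
            res = run_ensemble(avatar, treatment, config)
            kill[i, j] = 1.0 - min(res.survival_fraction / s0, 1.0)
    return CombinationGrid(
        drugA=profileA.drug,
        drugB=profileB.drug,
        cell_line=avatar.cell_line,
        doses_A=doses_A,
        doses_B=doses_B,
        killrate_AB=kill,
    )


def discretize_synergy(
    scores: Sequence[float], seed: int = 0, n_restarts: int = 100
) -> tuple[SynergyCategories, list[str]]:
    """1-D k-means (k=3) discretization into non/moderate/strong synergy.

    Clusters are ordered by centroid; each threshold is the midpoint of
    the gap between adjacent clusters (max of the lower cluster averaged
    with min of the upper).  Deterministic for a given seed.
    """
    arr = np.asarray(scores, dtype=float)
    if len(np.unique(arr)) < 3:
        raise DegenerateInputError("need at least 3 distinct synergy scores for k=3")
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(arr.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    rank_of = {int(orig): rank for rank, orig in enumerate(order)}
    ranks = np.array([rank_of[int(l)] for l in raw_labels])
    centroids = tuple(float(c) for c in np.sort(km.cluster_centers_.ravel()))
    t1 = (arr[ranks == 0].max() + arr[ranks == 1].min()) / 2.0
    t2 = (arr[ranks == 1].max() + arr[ranks == 2].min()) / 2.0
    labels = [SYNERGY_CATEGORY_LABELS[r] for r in ranks]
    return SynergyCategories(thresholds=(float(t1), float(t2)), labels=labels, centroids=centroids), labels


def enumerate_combinations(
    ddr_drugs: Sequence[str], nonddr_drugs: Sequence[str]
) -> list[tuple[str, str]]:
    """Ordered (anchor, partner) pairs: each DDR drug against every other drug.

    Anchors run over the DDR panel; partners over DDR + non-DDR minus the
    anchor itself, so the count is |DDR| * (|DDR| - 1 + |non-DDR|).
    """
    ddr = list(ddr_drugs)
    non = list(nonddr_drugs)
    if len(set(ddr)) != len(ddr) or len(set(non)) != len(non):
        raise InputError("duplicate drugs within a panel")
    if set(ddr) & set(non):
        raise InputError(f"panels overlap: {sorted(set(ddr) & set(non))}")
    return [(d, p) for d in ddr for p in itertools.chain(ddr, non) if p != d]


# ---------------------------------------------------------------------------
# MoA x indication reporting helpers
# ---------------------------------------------------------------------------

def aggregate_by_moa(
    results: pd.DataFrame,
    group_cols: Sequence[str] = ("moa_pair",),
    score_col: str = "bliss_score",
    killrate_col: str = "killrate",
) -> pd.DataFrame:
    """Mean synergy and killrate per MoA group (reporting helper)."""
    agg = {score_col: "mean"}
    if killrate_col in results.columns:
        agg[killrate_col] = "mean"
    out = results.groupby(list(group_cols), sort=True).agg(agg)
    return out.rename(columns={score_col: "mean_synergy", killrate_col: "mean_killrate"})


def pairwise_group_tests(
    results: pd.DataFrame,
    group_col: str = "moa_pair",
    score_col: str = "bliss_score",
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum between groups with Benjamini-Hochberg."""
    groups = sorted(results[group_col].unique())
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        x = results.loc[results[group_col] == g1, score_col].to_numpy()
        y = results.loc[results[group_col] == g2, score_col].to_numpy()
        if len(x) == 0 or len(y) == 0:
            continue
        stat, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"group_1": g1, "group_2": g2, "statistic": stat, "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
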