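"""In silico biomarker screening by systematic node perturbation.

A perturbation mimics an extrinsic molecular alteration using the
field's shorthand codes: ``0.0`` knocks a node out (loss-of-function,
activity pinned to 0), ``1.0`` keeps it constitutively active
(gain-of-function, activity pinned to 1), ``mc5.0`` overexpresses it
(concentration x 5) and ``mc0.3`` underexpresses it (concentration x
0.3).  For every (perturbation, cell line) the monotherapy screens and
the combination grid are rerun and compared with the baseline:

* ``synergy_shift``  — perturbed minus baseline Bliss score;
* ``killrate_shift`` — combination killrate change at the synergy-argmax
  dose pair (baseline argmax; perturbed argmax when the baseline grid
  shows no synergy);
* ``delta_log_ic50`` — per-drug monotherapy potency shift.

A *combination-specific* biomarker shifts synergy without moving either
monotherapy IC50 (|delta log10 IC50| below a tolerance, default 0.2).
Two exclusion filters guard against artifacts: pairs whose baseline
synergy argmax sits above either monotherapy IC50 are not analyzed, and
triplets where survival drops significantly while synergy collapses to a
non-synergistic state are discarded as suspected model artifacts.
Effects are significant at p < 0.001 (two-sided Wilcoxon rank-sum on
replicate-level survival at the argmax doses; an across-cell-line mode
pools per-cell-line scores instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .conditioning import CellLineAvatar
from .dose_response import monotherapy_screen
from .engine import SimulationConfig, run_ensemble
from .errors import InputError, NativeDeadError, UnknownNodeError
from .pharmacology import TargetProfile
from .synergy import combination_screen, max_synergy

logger = logging.getLogger(__name__)

PERTURBATION_KINDS = ("lof", "gof", "overexpress", "underexpress")
#: shorthand codes used in perturbation tables and figure labels
KIND_CODES = {"0.0": "lof", "1.0": "gof", "mc5.0": "overexpress", "mc0.3": "underexpress"}
CODE_OF_KIND = {v: k for k, v in KIND_CODES.items()}

SIGNIFICANCE_LEVEL = 0.001
IC50_SHIFT_TOL_LOG10 = 0.2
NON_SYNERGY_THRESHOLD = 0.2


@dataclass(frozen=True)
class Perturbation:
    node: str
    kind: str  # lof | gof | overexpress | underexpress (codes accepted)

    def __post_init__(self) -> None:
        kind = KIND_CODES.get(self.kind, self.kind)
        if kind not in PERTURBATION_KINDS:
            raise InputError(f"unknown perturbation kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)

    @property
    def code(self) -> str:
        return CODE_OF_KIND[self.kind]


@dataclass
class BiomarkerEffect:
    perturbation: Perturbation
    combination: tuple[str, str]
    cell_line: str
    synergy_shift: float
    killrate_shift: float
    delta_log_ic50_A: float
    delta_log_ic50_B: float
    p_value: float
    effect_class: str = "none"  # sensitivity | resistance | none
    scope: str = "none"  # combination_specific | monotherapy_specific_A/B | none


def apply_perturbation(avatar: CellLineAvatar, p: Perturbation) -> CellLineAvatar:
    """Return a perturbed copy of the avatar; the original is untouched."""
    if p.node not in avatar.network.nodes:
        raise UnknownNodeError(f"unknown node id {p.node!r}")
    out = avatar.copy()
    node = out.network.nodes[p.node]
    if p.kind == "lof":
        node.activity_max = 0.0
        node.activity_min = 0.0
        node.base_activity = 0.0
    elif p.kind == "gof":
        node.activity_min = 1.0
        node.activity_max = 1.0
        node.base_activity = 1.0
    elif p.kind == "overexpress":
        node.base_concentration *= 5.0
    elif p.kind == "underexpress":
        node.base_concentration *= 0.3
    return out


def test_significance(
    baseline_values: Sequence[float], perturbed_values: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a biomarker effect.

    Uses the exact null distribution when both samples have n <= 25 and
    carry no ties, and the tie-corrected normal approximation otherwise.
    Identical constant samples give p = 1 by convention.
    """
    x = np.asarray(baseline_values, dtype=float)
    y = np.asarray(perturbed_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    _, p = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(p)


test_significance.__test__ = False  # not a pytest case despite the field-standard name


def classify_biomarker(
    effect: BiomarkerEffect,
    significance_level: float = SIGNIFICANCE_LEVEL,
    ic50_shift_tol: float = IC50_SHIFT_TOL_LOG10,
) -> BiomarkerEffect:
    """Assign sensitivity/resistance class and specificity scope in place."""
    significant = effect.p_value < significance_level
    shift = effect.synergy_shift if effect.synergy_shift != 0 else effect.killrate_shift
    if not significant or shift == 0:
        effect.effect_class = "none"
        effect.scope = "none"
        return effect
    effect.effect_class = "sensitivity" if shift > 0 else "resistance"
    a_shifted = abs(effect.delta_log_ic50_A) >= ic50_shift_tol
    b_shifted = abs(effect.delta_log_ic50_B) >= ic50_shift_tol
    if not a_shifted and not b_shifted:
        effect.scope = "combination_specific"
    elif a_shifted and not b_shifted:
        effect.scope = "monotherapy_specific_A"
    elif b_shifted and not a_shifted:
        effect.scope = "monotherapy_specific_B"
    else:
        effect.scope = "none"  # both monotherapies moved: not specific
    return effect


def _delta_log_ic50(base, pert, grid_top: float) -> float:
    """Censoring-aware log10 IC50 shift (censored side evaluated at grid top)."""
    if base.censored and pert.censored:
        return 0.0
    b = grid_top if base.censored else base.ic50_nM
    p = grid_top if pert.censored else pert.ic50_nM
    return float(np.log10(p) - np.log10(b))


def _survival_at(avatar, profA, doseA, profB, doseB, config) -> np.ndarray:
    treatment = []
    if doseA > 0:
        treatment.append((profA, doseA))
    if doseB > 0:
        treatment.append((profB, doseB))
    return run_ensemble(avatar, treatment, config).verdicts.astype(float)


def screen_biomarkers(
    avatar: CellLineAvatar,
    profileA: TargetProfile,
    profileB: TargetProfile,
    perturbations: Iterable[Perturbation],
    config: SimulationConfig | None = None,
    doses: Sequence[float] | None = None,
    significance_level: float = SIGNIFICANCE_LEVEL,
    ic50_shift_tol: float = IC50_SHIFT_TOL_LOG10,
    non_synergy_threshold: float = NON_SYNERGY_THRESHOLD,
) -> list[BiomarkerEffect]:
    """Perturb nodes one at a time and measure synergy/killrate/IC50 shifts.

    Runs baseline monotherapy + combination screens once, then reruns the
    full portfolio under each perturbation.  Returns only effects that
    survive the two exclusion filters (sub-IC50 synergy argmax; no
    kill-up/synergy-collapse artifacts); each is significance-tested and
    classified.  Natively dead perturbed avatars are skipped with a log
    entry (the perturbation itself is lethal, not a response biomarker).
    """
    config = config or SimulationConfig()
    curveA = monotherapy_screen(avatar, profileA, doses, config)
    curveB = monotherapy_screen(avatar, profileB, doses, config)
    grid = combination_screen(avatar, profileA, profileB, doses, doses, config)
    base_syn = max_synergy(grid, curveA.ic50.ic50_nM, curveB.ic50.ic50_nM)
    grid_top = float(grid.doses_A.max())

    # exclusion filter 1: only analyze pairs whose synergy argmax is sub-IC50
    if base_syn.bliss_score > 0:
        da, db = base_syn.argmax_doses
        if not (da < curveA.ic50.ic50_nM and db < curveB.ic50.ic50_nM):
            logger.info(
                "%s: baseline synergy argmax at supra-IC50 doses; pair excluded",
                avatar.cell_line,
            )
            return []

    effects: list[BiomarkerEffect] = []
    for p in perturbations:
        pert_avatar = apply_perturbation(avatar, p)
        try:
            p_curveA = monotherapy_screen(pert_avatar, profileA, doses, config)
            p_curveB = monotherapy_screen(pert_avatar, profileB, doses, config)
            p_grid = combination_screen(pert_avatar, profileA, profileB, doses, doses, config)
        except NativeDeadError:
            logger.info("perturbation %s %s is natively lethal; skipped", p.node, p.code)
            continue
        p_syn = max_synergy(p_grid, p_curveA.ic50.ic50_nM, p_curveB.ic50.ic50_nM)
        if not (base_syn.qc_pass and p_syn.qc_pass):
            logger.info("perturbation %s %s failed grid QC; skipped", p.node, p.code)
            continue

        synergy_shift = float(p_syn.bliss_score - base_syn.bliss_score)
        # killrate shift at the argmax of whichever grid carries the synergy
        if base_syn.bliss_score > 0:
            da, db = base_syn.argmax_doses
        else:
            da, db = p_syn.argmax_doses
        ia = int(np.argmin(np.abs(grid.doses_A - da)))
        ib = int(np.argmin(np.abs(grid.doses_B - db)))
        killrate_shift = float(p_grid.killrate_AB[ia, ib] - grid.killrate_AB[ia, ib])

        base_surv = _survival_at(avatar, profileA, da, profileB, db, config)
        pert_surv = _survival_at(pert_avatar, profileA, da, profileB, db, config)
        p_value = test_significance(base_surv, pert_surv)

        # exclusion filter 2: significant extra kill + synergy collapsing to
        # non-synergistic is a suspected model artifact
        if (
            killrate_shift > 0
            and p_value < significance_level
            and base_syn.bliss_score >= non_synergy_threshold
            and p_syn.bliss_score < non_synergy_threshold
        ):
            logger.info(
                "perturbation %s %s: kill-up with synergy collapse; excluded as artifact",
                p.node,
                p.code,
            )
            continue

        effect = BiomarkerEffect(
            perturbation=p,
            combination=(profileA.drug, profileB.drug),
            cell_line=avatar.cell_line,
            synergy_shift=synergy_shift,
            killrate_shift=killrate_shift,
            delta_log_ic50_A=_delta_log_ic50(curveA.ic50, p_curveA.ic50, grid_top),
            delta_log_ic50_B=_delta_log_ic50(curveB.ic50, p_curveB.ic50, grid_top),
            p_value=p_value,
        )
        classify_biomarker(effect, significance_level, ic50_shift_tol)
        effects.append(effect)
    return effects


def test_significance_across_cell_lines(
    baseline_by_line: Sequence[float], perturbed_by_line: Sequence[float]
) -> float:
    """Across-cell-line mode: rank-sum on per-cell-line summary scores."""
    return test_significance(baseline_by_line, perturbed_by_line)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_perturbation_table(path) -> list[Perturbation]:
    """TSV with columns node, kind (codes 0.0 / 1.0 / mc5.0 / mc0.3)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"node", "kind"}.issubset(df.columns):
        raise InputError("perturbation table must have columns node, kind")
    return [Perturbation(node=r.node, kind=r.kind) for r in df.itertuples(index=False)]


def effects_to_frame(effects: Sequence[BiomarkerEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [e.perturbation.node for e in effects],
            "kind": [e.perturbation.code for e in effects],
            "drugA": [e.combination[0] for e in effects],
            "drugB": [e.combination[1] for e in effects],
            "cell_line": [e.cell_line for e in effects],
            "synergy_shift": [e.synergy_shift for e in effects],
            "killrate_shift": [e.killrate_shift for e in effects],
            "delta_log_ic50_A": [e.delta_log_ic50_A for e in effects],
            "delta_log_ic50_B": [e.delta_log_ic50_B for e in effects],
            "p_value": [e.p_value for e in effects],
            "class": [e.effect_class for e in effects],
            "scope": [e.scope for e in effects],
        }
    )
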