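"""Compound -> target bioactivity curation and dose -> activity-cap mapping.

Bioactivity records follow the ChEMBL export shape.  After filtering
(human, binding assays, confidence > 5, exact-relation values at or below
10,000 nM) each drug's profile maps network node ids to its best (lowest)
affinity per target.

A drug at dose ``d`` occupies a fraction ``d^h / (d^h + K^h)`` of its
target (one-site occupancy; Hill coefficient ``h`` defaults to 1), and
the occupied fraction is removed from the target's achievable maximum
activity: ``activity_max := min(activity_max, 1 - occupancy)``.  Several
drugs hitting the same node combine by taking the lowest resulting cap.
All doses and affinities are in nM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conditioning import CellLineAvatar
from .errors import InputError

logger = logging.getLogger(__name__)

MAX_EFFECTIVE_AFFINITY_NM = 10_000.0
MIN_CONFIDENCE_EXCLUSIVE = 5

MOA_GROUPS = (
    "DDR",
    "TK/RTK",
    "PIK3/AKT/MTOR",
    "ERK",
    "NFKB",
    "JAK/STAT",
    "EM/TM",
    "CSNK",
    "other",
)


@dataclass(frozen=True)
class BioactivityRecord:
    drug: str
    target: str
    affinity_nM: float
    relation: str = "="
    assay_type: str = "binding"
    confidence: int = 9
    organism: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if not self.affinity_nM > 0:
            raise InputError(f"{self.drug}->{self.target}: affinity must be > 0")


@dataclass
class TargetProfile:
    """One drug's filtered target map (node id -> affinity in nM)."""

    drug: str
    targets: dict[str, float] = field(default_factory=dict)
    moa_group: str = "other"

    def primary_target(self) -> str:
        """Strongest binder: numerically lowest affinity, ties by node id."""
        if not self.targets:
            raise InputError(f"drug {self.drug}: empty target profile")
        return min(self.targets, key=lambda t: (self.targets[t], t))


def filter_bioactivity(records: Iterable[BioactivityRecord]) -> list[BioactivityRecord]:
    """Apply the curation filters and collapse duplicates to minimum affinity.

    Keeps records that are human, binding-assay, confidence strictly above
    5, exact relation '=', and affinity at or below 10,000 nM (higher
    values are considered ineffective; '>'-censored values unreliable).
    Output order is sorted by (drug, target) — filtering has set semantics.
    """
    best: dict[tuple[str, str], BioactivityRecord] = {}
    for rec in records:
        if rec.organism != "Homo sapiens":
            continue
        if rec.confidence <= MIN_CONFIDENCE_EXCLUSIVE:
            continue
        if rec.assay_type != "binding":
            continue
        if rec.relation != "=":
            continue
        if rec.affinity_nM > MAX_EFFECTIVE_AFFINITY_NM:
            continue
        key = (rec.drug, rec.target)
        if key not in best or rec.affinity_nM < best[key].affinity_nM:
            best[key] = rec
    if not best:
        logger.warning("bioactivity filtering removed every record")
    return [best[k] for k in sorted(best)]


def build_target_profiles(
    records: Iterable[BioactivityRecord],
    pathway_map: Mapping[str, str] | None = None,
) -> dict[str, TargetProfile]:
    """Filter records and assemble one TargetProfile per drug."""
    profiles: dict[str, TargetProfile] = {}
    for rec in filter_bioactivity(records):
        prof = profiles.setdefault(rec.drug, TargetProfile(drug=rec.drug))
        prof.targets[rec.target] = min(
            prof.targets.get(rec.target, np.inf), rec.affinity_nM
        )
    if pathway_map is not None:
        for prof in profiles.values():
            prof.moa_group = classify_moa(prof, pathway_map)
    return profiles


def target_inhibition(dose_nM: float, affinity_nM: float, hill: float = 1.0) -> float:
    """Fractional target occupancy at a given dose (one-site model).

    Strictly increasing in dose, 0 at dose 0, exactly 0.5 at dose equal
    to the affinity, and approaching 1 asymptotically.
    """
    if dose_nM < 0:
        raise InputError(f"negative dose {dose_nM}")
    if not affinity_nM > 0:
        raise InputError(f"non-positive affinity {affinity_nM}")
    if dose_nM == 0:
        return 0.0
    dh = dose_nM**hill
    return float(dh / (dh + affinity_nM**hill))


def classify_moa(profile: TargetProfile, pathway_map: Mapping[str, str]) -> str:
    """MoA group = pathway of the strongest-affinity (primary) target."""
    primary = profile.primary_target()
    group = pathway_map.get(primary)
    if group is None:
        logger.warning(
            "drug %s: primary target %s missing from pathway map; MoA 'other'",
            profile.drug,
            primary,
        )
        return "other"
    return group


def apply_treatment(
    avatar: CellLineAvatar,
    treatment: Sequence[tuple[TargetProfile, float]],
    hill: float = 1.0,
) -> CellLineAvatar:
    """Return an avatar copy with drug-induced activity caps applied.

    Every (profile, dose) pair lowers the activity_max of each of the
    drug's network targets by its occupancy; multiple drugs on one node
    take the minimum cap.  If a cap falls below an existing activity_min
    (e.g. a gain-of-function pin), the pharmacological cap dominates and
    the lower bound is pulled down with it.
    """
    treated = avatar.copy()
    for profile, dose in treatment:
        if dose < 0:
            raise InputError(f"negative dose {dose} for drug {profile.drug}")
        for target, affinity in profile.targets.items():
            node = treated.network.nodes.get(target)
            if node is None:
                continue  # off-network target: silently inert
            cap = 1.0 - target_inhibition(dose, affinity, hill=hill)
            if cap < node.activity_max:
                node.activity_max = cap
            if node.activity_min > node.activity_max:
                node.activity_min = node.activity_max
            node.base_activity = min(
                max(node.base_activity, node.activity_min), node.activity_max
            )
    return treated


# ---------------------------------------------------------------------------
# TSV interfaces (ChEMBL-style export)
# ---------------------------------------------------------------------------

def read_bioactivity_table(path: str | Path) -> list[BioactivityRecord]:
    """Read a TSV mirroring ChEMBL export columns."""
    return bioactivity_records_from_frame(pd.read_csv(path, sep="\t"))


def bioactivity_records_from_frame(df: pd.DataFrame) -> list[BioactivityRecord]:
    required = {
        "drug",
        "target",
        "standard_value",
        "standard_relation",
        "assay_type",
        "confidence_score",
        "organism",
    }
    if not required.issubset(df.columns):
        raise InputError(f"bioactivity table must have columns {sorted(required)}")
    return [
        BioactivityRecord(
            drug=str(r.drug),
            target=str(r.target),
            affinity_nM=float(r.standard_value),
            relation=str(r.standard_relation),
            assay_type=str(r.assay_type),
            confidence=int(r.confidence_score),
            organism=str(r.organism),
        )
        for r in df.itertuples(index=False)
    ]


def read_pathway_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV node id -> pathway/MoA group."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "pathway"])
    return dict(zip(df["node"].astype(str), df["pathway"].astype(str)))
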