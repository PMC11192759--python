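"""Condition the generic network into a cell-line-specific avatar.

Two omics layers specialise the network:

* expression fold-changes (cell line vs. a healthy-tissue baseline)
  multiply each node's base concentration, so relative protein abundance
  scales the node's influence on its neighbours;
* pathogenic mutations cap the activity bounds — loss-of-function pins
  the activity to 0 (``activity_max = 0``), gain-of-function pins it to 1
  (``activity_min = 1``) — for the entire simulation.

Variant annotation (liftover, VEP, ClinVar, dbNSFP) is out of scope: the
mutation table must already carry the consequence class and a
pathogenicity boolean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, MutationConflictError
from .network import SignalingNetwork

logger = logging.getLogger(__name__)

CONSEQUENCES = ("missense", "frameshift", "stop_gain", "splice", "inframe", "other")
#: consequence classes that are clearly protein-truncating, hence
#: loss-of-function even on an oncogene
TRUNCATING = frozenset({"frameshift", "stop_gain"})


@dataclass
class ExpressionProfile:
    """Per-cell-line fold-changes vs. baseline; missing nodes default to 1."""

    cell_line: str
    fold_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.fold_changes.items() if not v > 0}
        if bad:
            raise InputError(f"non-positive fold-changes: {bad}")

    def get(self, node_id: str) -> float:
        return self.fold_changes.get(node_id, 1.0)


@dataclass
class MutationRecord:
    cell_line: str
    node: str
    consequence: str = "missense"
    pathogenic: bool = False


@dataclass
class CellLineAvatar:
    """A cell-line-specific network instance ready for simulation.

    ``network`` is a deep copy of the generic network whose
    ``base_concentration`` fields already carry the expression scaling
    and whose activity bounds carry the mutation caps.
    """

    cell_line: str
    network: SignalingNetwork
    indication: str = ""
    applied_mutations: list[tuple[str, str]] = field(default_factory=list)

    def copy(self) -> "CellLineAvatar":
        return CellLineAvatar(
            cell_line=self.cell_line,
            network=self.network.copy(),
            indication=self.indication,
            applied_mutations=list(self.applied_mutations),
        )


def compute_fold_change(
    cell_expression: Mapping[str, float],
    baseline_expression: Mapping[str, Sequence[float]],
    epsilon: float = 1.0,
) -> dict[str, float]:
    """Fold-change = (cell + eps) / (mean(baseline) + eps) per shared gene.

    ``epsilon`` is a pseudocount guarding against zero baselines (healthy
    tissues frequently do not express a gene at all).
    """
    shared = set(cell_expression) & set(baseline_expression)
    if not shared:
        raise InputError("no genes shared between cell and baseline expression")
    out = {}
    for gene in sorted(shared):
        base = float(np.mean(baseline_expression[gene]))
        out[gene] = (float(cell_expression[gene]) + epsilon) / (base + epsilon)
    return out


def map_variant_effect(record: MutationRecord, role: str) -> str:
    """Classify a mutation as gain_of_function / loss_of_function / none.

    Pathogenic hits on tumor suppressors are loss-of-function; pathogenic
    hits on oncogenes are gain-of-function unless the consequence is
    clearly truncating (frameshift, stop gain), which destroys the protein
    regardless of the gene's usual direction.
    """
    if not record.pathogenic:
        return "none"
    if role == "tumor_suppressor":
        return "loss_of_function"
    if role == "oncogene":
        if record.consequence in TRUNCATING:
            return "loss_of_function"
        return "gain_of_function"
    logger.info(
        "pathogenic mutation on neutral node %s ignored (no direction)", record.node
    )
    return "none"


def build_avatar(
    net: SignalingNetwork,
    expr: ExpressionProfile | None,
    muts: Iterable[MutationRecord] = (),
    indication: str = "",
    on_conflict: str = "error",
) -> CellLineAvatar:
    """Apply expression scaling and mutation caps to a network copy.

    Effective concentration = base_concentration x fold_change.
    Loss-of-function sets ``activity_max = 0`` (base activity clamped down);
    gain-of-function sets ``activity_min = 1`` (base activity clamped up).
    Opposite-direction mutations on one node raise
    :class:`MutationConflictError` unless ``on_conflict="skip"``.
    """
    avatar_net = net.copy()
    cell_line = expr.cell_line if expr is not None else ""
    if expr is not None:
        for nid, node in avatar_net.nodes.items():
            node.base_concentration = node.base_concentration * expr.get(nid)

    effects: dict[str, str] = {}
    applied: list[tuple[str, str]] = []
    for rec in muts:
        if expr is not None and rec.cell_line != expr.cell_line:
            raise InputError(
                f"mutation record for {rec.cell_line!r} does not match "
                f"expression profile {expr.cell_line!r}"
            )
        cell_line = cell_line or rec.cell_line
        if rec.node not in avatar_net.nodes:
            logger.warning("mutation on unmapped node %s skipped", rec.node)
            continue
        effect = map_variant_effect(rec, avatar_net.nodes[rec.node].role)
        if effect == "none":
            continue
        prev = effects.get(rec.node)
        if prev is not None and prev != effect:
            if on_conflict == "skip":
                logger.warning("conflicting GoF+LoF on node %s; both skipped", rec.node)
                effects[rec.node] = "conflict"
                continue
            raise MutationConflictError(
                f"node {rec.node}: conflicting gain- and loss-of-function mutations"
            )
        effects[rec.node] = effect

    for nid, effect in effects.items():
        node = avatar_net.nodes[nid]
        if effect == "loss_of_function":
            node.activity_max = 0.0
            node.activity_min = 0.0
            node.base_activity = 0.0
            applied.append((nid, "loss_of_function"))
        elif effect == "gain_of_function":
            node.activity_min = 1.0
            node.activity_max = 1.0
            node.base_activity = 1.0
            applied.append((nid, "gain_of_function"))

    return CellLineAvatar(
        cell_line=cell_line,
        network=avatar_net,
        indication=indication,
        applied_mutations=applied,
    )


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> dict[str, ExpressionProfile]:
    """Read a TSV with columns cell_line, gene_id, fold_change."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_line", "gene_id", "fold_change"}
    if not required.issubset(df.columns):
        raise InputError(f"expression table must have columns {sorted(required)}")
    out: dict[str, ExpressionProfile] = {}
    for cell, sub in df.groupby("cell_line", sort=True):
        fc = {}
        for gene, value in zip(sub["gene_id"], sub["fold_change"]):
            node = alias_map.get(gene, gene) if alias_map else gene
            fc[str(node)] = float(value)
        out[str(cell)] = ExpressionProfile(cell_line=str(cell), fold_changes=fc)
    return out


def read_mutation_table(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> dict[str, list[MutationRecord]]:
    """Read a TSV with columns cell_line, gene_id, consequence, pathogenic."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_line", "gene_id", "consequence", "pathogenic"}
    if not required.issubset(df.columns):
        raise InputError(f"mutation table must have columns {sorted(required)}")
    out: dict[str, list[MutationRecord]] = {}
    for row in df.itertuples(index=False):
        gene = str(row.gene_id)
        node = alias_map.get(gene, gene) if alias_map else gene
        rec = MutationRecord(
            cell_line=str(row.cell_line),
            node=node,
            consequence=str(row.consequence),
            pathogenic=bool(row.pathogenic)
            if isinstance(row.pathogenic, (bool, np.bool_))
            else str(row.pathogenic).strip().lower() in {"true", "1", "yes"},
        )
        out.setdefault(rec.cell_line, []).append(rec)
    return out


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV alias -> node id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "node"])
    return dict(zip(df["alias"].astype(str), df["node"].astype(str)))
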