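"""Self-contained synthetic fixtures with known ground truth.

The generator emits small signaling networks (parallel growth pathways
feeding cell-cycle and apoptosis readouts), matched expression/mutation
panels, and a ChEMBL-shaped bioactivity table, so every screening
workflow is testable without any external download.  Everything is a
pure, seeded function of a :class:`FixtureSpec`.

Topology
--------
Each of ``n_pathways`` pathways is a receptor (constitutively active)
driving a kinase chain into the readouts.  Weights and biases are chosen
so a chain transmits its receptor state essentially unattenuated:
edge weight 16 with unit concentration gives an effective input of ~8
per active upstream node against a bias of -4, i.e. nodes sit close to
0 or 1.

* ``survival_logic="OR"`` — redundant pathways: the cell cycle fires if
  *any* pathway is on, so only dual-pathway inhibition kills and
  cross-pathway drug pairs are synergistic by construction.
* ``survival_logic="AND"`` — conjunctive pathways: every pathway is
  required, so blocking any one kills (monotherapy lethality, no
  combination synergy).

A ``BACKUP`` node (no inputs) feeds the readouts strongly enough that,
when active, it keeps the cell alive even under dual blockade.  With its
default low base activity it is silent and its gain-of-function is the
planted *resistance* biomarker (synergy collapses, monotherapies
untouched); generated with ``backup_base`` high, its loss-of-function is
the planted *sensitivity* biomarker.  Disconnected decoy nodes must
never surface in any screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InputError
from .network import EdgeSpec, NodeSpec, SignalingNetwork, save_network

CHAIN_WEIGHT = 16.0  # effective input 8 per fully active upstream node (chat=0.5)
EFFECTIVE_PER_PATHWAY = 8.0
OR_BIAS = -4.0
BACKUP_CC_WEIGHT = 10.0  # effective +5 on cell cycle when BACKUP is fully on
BACKUP_APOP_WEIGHT = 12.0  # effective -6 on apoptosis
RECEPTOR_BASE = 0.95
CHAIN_BASE = float(expit(OR_BIAS))
DRUG_AFFINITY_NM = 100.0


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system (a pure function of these)."""

    seed: int = 0
    n_pathways: int = 2
    nodes_per_pathway: int = 3
    survival_logic: str = "OR"  # OR: redundant pathways; AND: all required
    planted_biomarkers: list[tuple[str, str, int]] | None = None  # (node, code, sign)
    noise_sd: float = 0.05
    n_cell_lines: int = 3
    n_drugs: int = 4  # extra decoy-targeting drugs beyond the core panel
    n_decoys: int = 3
    backup_base: float = 0.02
    expr_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise InputError("need at least one pathway")
        if self.survival_logic not in ("OR", "AND"):
            raise InputError(f"unknown survival_logic {self.survival_logic!r}")
        if self.planted_biomarkers is None:
            if self.backup_base >= 0.5:
                self.planted_biomarkers = [("BACKUP", "0.0", +1)]
            else:
                self.planted_biomarkers = [("BACKUP", "1.0", -1)]


def _receptor(k: int) -> str:
    return f"R{k}"


def _chain_node(k: int, j: int) -> str:
    return f"P{k}N{j}"


def make_toy_network(spec: FixtureSpec) -> tuple[SignalingNetwork, dict]:
    """Build the fixture network and its ground-truth metadata."""
    net = SignalingNetwork()
    n_p = spec.n_pathways

    for k in range(1, n_p + 1):
        module = f"pathway_{k}"
        net.add_node(
            NodeSpec(
                id=_receptor(k),
                base_activity=RECEPTOR_BASE,
                role="oncogene",
                module=module,
            )
        )
        for j in range(1, spec.nodes_per_pathway + 1):
            net.add_node(
                NodeSpec(
                    id=_chain_node(k, j),
                    base_activity=CHAIN_BASE,
                    role="oncogene",
                    module=module,
                )
            )
            src = _receptor(k) if j == 1 else _chain_node(k, j - 1)
            net.add_edge(EdgeSpec(source=src, target=_chain_node(k, j), sign=1, weight=CHAIN_WEIGHT))

    # readout biases: OR fires on any pathway, AND requires every pathway
    if spec.survival_logic == "OR":
        cc_bias = OR_BIAS
        apop_bias = -OR_BIAS
    else:
        cc_bias = -(EFFECTIVE_PER_PATHWAY * n_p - 4.0)
        apop_bias = EFFECTIVE_PER_PATHWAY * (n_p - 1) + 4.0
    net.add_node(
        NodeSpec(
            id="CELL_CYCLE",
            base_activity=float(expit(cc_bias)),
            readout="cell_cycle",
            module="readout",
        )
    )
    net.add_node(
        NodeSpec(
            id="APOPTOSIS",
            base_activity=float(expit(apop_bias)),
            readout="apoptosis",
            module="readout",
        )
    )
    for k in range(1, n_p + 1):
        terminal = _chain_node(k, spec.nodes_per_pathway)
        net.add_edge(EdgeSpec(source=terminal, target="CELL_CYCLE", sign=1, weight=CHAIN_WEIGHT))
        net.add_edge(EdgeSpec(source=terminal, target="APOPTOSIS", sign=-1, weight=CHAIN_WEIGHT))

    # survival backup: silent at the default low base activity
    net.add_node(
        NodeSpec(id="BACKUP", base_activity=spec.backup_base, role="oncogene", module="backup")
    )
    net.add_edge(EdgeSpec(source="BACKUP", target="CELL_CYCLE", sign=1, weight=BACKUP_CC_WEIGHT))
    net.add_edge(EdgeSpec(source="BACKUP", target="APOPTOSIS", sign=-1, weight=BACKUP_APOP_WEIGHT))

    # a weak tumor suppressor (mutation-panel material) and disconnected decoys
    net.add_node(
        NodeSpec(id="TSG", base_activity=0.1, role="tumor_suppressor", module="guard")
    )
    net.add_edge(EdgeSpec(source="TSG", target="CELL_CYCLE", sign=-1, weight=0.5))
    for d in range(1, spec.n_decoys + 1):
        net.add_node(NodeSpec(id=f"DECOY{d}", base_activity=0.5, module="decoy"))

    drugs = _drug_panel_layout(spec)
    if spec.survival_logic == "OR" and spec.backup_base < 0.5:
        synergistic = [
            [f"anti_R{a}", f"anti_R{b}"]
            for a in range(1, n_p + 1)
            for b in range(a + 1, n_p + 1)
        ]
        mono_lethal: list[str] = []
    elif spec.survival_logic == "OR":
        synergistic = []  # the active backup keeps dual blockade alive
        mono_lethal = []
    else:
        synergistic = []
        mono_lethal = [f"anti_R{k}" for k in range(1, n_p + 1)]

    meta = {
        "seed": spec.seed,
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "survival_logic": spec.survival_logic,
        "synergistic_pairs": synergistic,
        "same_pathway_pairs": [["anti_R1", "anti_P1"]],
        "monotherapy_lethal_drugs": mono_lethal,
        "planted_biomarkers": [
            {"node": n, "kind": c, "expected_sign": s} for n, c, s in spec.planted_biomarkers
        ],
        "decoy_nodes": [f"DECOY{d}" for d in range(1, spec.n_decoys + 1)],
        "ddr_drugs": drugs["ddr"],
        "nonddr_drugs": drugs["nonddr"],
        "native_dead_cell_lines": ["CL3"] if spec.n_cell_lines >= 3 else [],
        "n_planted_bad_bioactivity": 5,
    }
    return net, meta


def _drug_panel_layout(spec: FixtureSpec) -> dict:
    ddr = ["anti_R1", "anti_P1"]
    nonddr = [f"anti_R{k}" for k in range(2, spec.n_pathways + 1)]
    nonddr += ["multi", "inert"]
    nonddr += [f"extra{i}" for i in range(1, spec.n_drugs + 1)]
    return {"ddr": ddr, "nonddr": nonddr}


def make_drug_panel(spec: FixtureSpec) -> pd.DataFrame:
    """ChEMBL-shaped bioactivity table with planted filter violations.

    Includes one record designed to be removed by each curation filter
    (confidence 5, relation '>', affinity 12,000 nM, non-human organism,
    functional assay) plus a duplicate that must collapse to the minimum.
    """
    rows = []

    def good(drug, target, nm):
        rows.append((drug, target, nm, "=", "binding", 8, "Homo sapiens"))

    for k in range(1, spec.n_pathways + 1):
        good(f"anti_R{k}", _receptor(k), DRUG_AFFINITY_NM)
    good("anti_P1", _chain_node(1, 1), DRUG_AFFINITY_NM)
    # multi-target drug with an affinity tie (MoA tie-break material)
    good("multi", _receptor(1), 10.0)
    if spec.n_pathways >= 2:
        good("multi", _receptor(2), 10.0)
    good("inert", "NOT_IN_NETWORK", 50.0)
    affinities = np.geomspace(1.0, 10_000.0, max(spec.n_drugs, 1))
    for i in range(1, spec.n_drugs + 1):
        target = f"DECOY{(i - 1) % spec.n_decoys + 1}"
        good(f"extra{i}", target, float(affinities[i - 1]))
    # duplicate record: must collapse to the 100 nM minimum
    good("anti_R1", _receptor(1), 250.0)

    # planted-bad records, one per filter
    rows.append(("anti_R1", _receptor(1), 5.0, "=", "binding", 5, "Homo sapiens"))
    rows.append(("anti_R1", _receptor(1), 5.0, ">", "binding", 8, "Homo sapiens"))
    rows.append(("anti_R1", _receptor(1), 12_000.0, "=", "binding", 8, "Homo sapiens"))
    rows.append(("anti_R1", _receptor(1), 5.0, "=", "binding", 8, "Mus musculus"))
    rows.append(("anti_R1", _receptor(1), 5.0, "=", "functional", 8, "Homo sapiens"))

    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "target",
            "standard_value",
            "standard_relation",
            "assay_type",
            "confidence_score",
            "organism",
        ],
    )


def make_pathway_map(spec: FixtureSpec) -> dict[str, str]:
    """Node -> MoA pathway labels (pathway 1 plays the DDR role)."""
    groups = ["DDR", "TK/RTK", "PIK3/AKT/MTOR", "ERK", "NFKB", "JAK/STAT", "EM/TM", "CSNK"]
    out: dict[str, str] = {}
    for k in range(1, spec.n_pathways + 1):
        group = groups[(k - 1) % len(groups)]
        out[_receptor(k)] = group
        for j in range(1, spec.nodes_per_pathway + 1):
            out[_chain_node(k, j)] = group
    for d in range(1, spec.n_decoys + 1):
        out[f"DECOY{d}"] = "EM/TM"
    out["BACKUP"] = "other"
    return out


def make_avatar_panel(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression and mutation tables for ``n_cell_lines`` synthetic lines.

    Fold-changes are log-normal with median 1 (sigma ``expr_sigma``).
    CL2 carries a pathogenic missense in the tumor suppressor TSG
    (loss-of-function); CL3 carries truncating mutations in every
    receptor, making it natively dead.
    """
    net, _ = make_toy_network(spec)
    rng = np.random.default_rng(spec.seed)
    node_ids = net.node_ids
    expr_rows = []
    for i in range(1, spec.n_cell_lines + 1):
        cell = f"CL{i}"
        if spec.expr_sigma > 0:
            fc = np.exp(rng.normal(0.0, spec.expr_sigma, len(node_ids)))
        else:
            fc = np.ones(len(node_ids))
        for nid, f in zip(node_ids, fc):
            expr_rows.append((cell, nid, float(f)))
    expression = pd.DataFrame(expr_rows, columns=["cell_line", "gene_id", "fold_change"])

    mut_rows = []
    if spec.n_cell_lines >= 2:
        mut_rows.append(("CL2", "TSG", "missense", True))
        mut_rows.append(("CL2", _receptor(min(2, spec.n_pathways)), "missense", False))
    if spec.n_cell_lines >= 3:
        for k in range(1, spec.n_pathways + 1):
            mut_rows.append(("CL3", _receptor(k), "frameshift", True))
        if spec.backup_base >= 0.5:  # the backup would rescue CL3 otherwise
            mut_rows.append(("CL3", "BACKUP", "frameshift", True))
    mutations = pd.DataFrame(
        mut_rows, columns=["cell_line", "gene_id", "consequence", "pathogenic"]
    )
    return expression, mutations


def write_bundle(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write the complete fixture bundle to a directory; returns metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, meta = make_toy_network(spec)
    save_network(net, outdir / "network.json")
    expression, mutations = make_avatar_panel(spec)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    make_drug_panel(spec).to_csv(outdir / "bioactivity.tsv", sep="\t", index=False)
    pathway_map = make_pathway_map(spec)
    pd.DataFrame(sorted(pathway_map.items())).to_csv(
        outdir / "pathways.tsv", sep="\t", index=False, header=False
    )
    (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=1) + "\n")
    return meta


def load_bundle_avatars(bundle_dir: str | Path):
    """Convenience loader: bundle directory -> dict of CellLineAvatar."""
    from .conditioning import build_avatar, read_expression_table, read_mutation_table
    from .network import load_network

    bundle_dir = Path(bundle_dir)
    net = load_network(bundle_dir / "network.json")
    profiles = read_expression_table(bundle_dir / "expression.tsv")
    mutations = read_mutation_table(bundle_dir / "mutations.tsv")
    return {
        cell: build_avatar(net, prof, mutations.get(cell, []))
        for cell, prof in profiles.items()
    }
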