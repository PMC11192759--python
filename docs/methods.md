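# Methods

## The model

`netavatar` simulates drug response of cancer cell lines on a signed,
weighted, directed signaling network. Each node `i` (a protein or a
logical process node such as "DNA repair") carries two state variables:

* an **activity** `a_i(t) ∈ [activity_min_i, activity_max_i] ⊆ [0, 1]`
  that evolves during simulation, and
* a **concentration** `c_i > 0` that is fixed during a run and scales
  the node's influence on its neighbours.

Dynamics are discrete-time, continuous-valued and synchronous. One step:

```
input_j  = bias_j + Σ_i  sign_ij · w_ij · a_i(t) · ĉ_i
a_j(t+1) = clamp( σ(input_j), activity_min_j, activity_max_j )
```

with `σ` the logistic function, `ĉ_i = c_i / (1 + c_i)` and
`bias_j = logit(base_activity_j)` (logit clamped to ±logit(1e-9)).

Rationale for this gate function: it is continuous-valued, honours the
sign/weight semantics of the edges, saturates inside [0, 1], and makes
an input-free node sit exactly at its base activity (`σ(logit(b)) = b`),
so hand-set base values double as the untreated operating point. The
saturating transform `ĉ` bounds the influence of expression
fold-changes: doubling an already-abundant protein changes its effective
weight much less than doubling a scarce one. Concentrations do not
evolve — the model has no synthesis/degradation kinetics. The update
rule is isolated behind a single internal function (`engine._step_batch`)
so alternatives (e.g. normalized-Hill gates) can be swapped without
touching the screening layers. Asynchronous update schemes are out of
scope.

## Cell-line conditioning

An avatar is the generic network specialised to one cell line:

* **Expression**: fold-change of each gene vs. a healthy-tissue baseline
  multiplies the node's base concentration. Fold-changes are computed as
  `(cell + ε) / (mean(baseline) + ε)` with pseudocount `ε = 1`
  (configurable); baselines of zero occur in real tissue panels.
* **Mutations**: pathogenic calls cap the activity bounds. Pathogenic
  hits on tumor suppressors are loss-of-function (`activity_max := 0`);
  pathogenic hits on oncogenes are gain-of-function
  (`activity_min := 1`) unless the consequence is clearly truncating
  (frameshift, stop gain), which is loss-of-function regardless of the
  gene's usual direction. Variant annotation itself (liftover, effect
  prediction, pathogenicity databases) is not part of this package; the
  mutation table must already carry the consequence class and the
  pathogenicity boolean. Opposite-direction mutations on one node raise
  an error by default rather than silently picking a winner.

## Pharmacology

Bioactivity records follow the ChEMBL export shape and are curated with
set semantics: human, binding assays only, confidence strictly above 5,
exact-relation (`=`) values at or below 10,000 nM; duplicates collapse
to the lowest affinity. A drug at dose `d` occupies
`d^h / (d^h + K^h)` of a target with affinity `K` (one-site occupancy;
Hill coefficient `h = 1` by default) and the occupied fraction is
removed from the target's achievable activity:
`activity_max := min(activity_max, 1 − occupancy)`. Several drugs on one
node combine by the minimum cap. When a cap falls below a
gain-of-function pin, the pharmacological cap dominates and the lower
bound follows it down (clinical kinase inhibitors do inhibit
constitutively active mutants); this is a deliberate tie-break the
source biology leaves open. A drug's mechanism-of-action group is the
pathway of its strongest-affinity target, ties broken by node id.

## Simulation protocol and readout

Heterogeneity enters only through initial conditions: activities and
concentrations start at base values × `exp(N(0, noise_sd))`, clamped to
bounds, with `noise_sd = 0.05` by default. Each replicate draws from its
own child stream of the run seed, so replicate `r` is invariant to the
ensemble size and every result is bit-reproducible. A replicate reaches

* a **fixed point** when the largest activity change in one step falls
  below `attractor_tol = 1e-6`;
* a **limit cycle** when a state rounded to 6 decimals recurs within the
  last `cycle_detection_window = 20` steps.

Runs last at most 300 steps (the screening default). Phenotype readouts
are the mean activities of the cell-cycle and apoptosis readout nodes at
the attractor (averaged over one period for cycles). A replicate is
**alive** iff its cell-cycle score is at least 0.60 **and** its
apoptosis score is at most 0.20, both bounds inclusive — apoptosis
always vetoes proliferation. Ensemble survival is the alive fraction
over replicates (100 by default).

## Dose-response and synergy

The screening grid is 16 doses: 0 plus 15 log-spaced points from 1 nM to
10,000 nM. Log-uniform coverage is the pharmacological norm; both the
spacing and the grid size are configurable. Viability at each dose is
survival normalized to the untreated, same-seed ensemble (removing
noise-floor bias), and `killrate = 1 − viability`. IC50 is defined at
**absolute** viability 0.5 on a four-parameter logistic fitted on log10
dose (dose 0 enters at a 0.1 nM floor); curves that never cross 0.5
within the grid are right-censored at > 10,000 nM. The absolute-IC50
convention (rather than half-max-effect) is switchable at the fit level.

Combination grids are 16×16 killrate matrices whose row/column 0 are the
monotherapy marginals. Bliss excess is
`k_AB − (k_A + k_B − k_A·k_B)`; negative excess (antagonism) is clamped
to zero before scoring — only synergy is quantified. Two summaries per
grid: `bliss_score`, the maximum clamped excess over all 256 cells, and
`bliss_max_ic50`, the maximum over cells where both doses are strictly
below the respective monotherapy IC50s (censored IC50s exclude nothing).
Grid QC enforces dose-response principles: a marginal viability that
rises with dose by more than τ = 0.1 anywhere, or any non-finite entry,
disqualifies the grid. τ and the monotonicity criterion are this
package's operationalisation of "dose-response principles".

Synergy scores are discretized into non/moderate/strong by 1-D k-means
(k = 3, k-means++ with 100 restarts, fixed seed); the two thresholds are
midpoints of the gaps between adjacent sorted clusters. The thresholds
are data outcomes, not constants. Combination panels are enumerated as
ordered (anchor, partner) pairs with anchors over the DDR panel, so a
12-DDR/46-non-DDR library yields 12·(11+46) = 684 combinations.

## Biomarker screening

Perturbations use the field's shorthand: `0.0` knock-out
(`activity_max := 0`), `1.0` constitutive activation
(`activity_min := 1`), `mc5.0` overexpression (concentration × 5),
`mc0.3` underexpression (× 0.3). For each (perturbation, cell line) the
monotherapy screens and the combination grid are rerun and compared with
the baseline. Reported quantities: synergy shift (perturbed − baseline
Bliss score), killrate shift at the synergy-argmax dose pair, and
per-drug Δlog10 IC50. Two exclusion filters guard against artifacts:
pairs whose baseline synergy peak sits at supra-IC50 doses are not
analyzed (no dose-sparing potential), and triplets where survival drops
significantly while synergy collapses below the non-synergy threshold
(0.2) are discarded as suspected model artifacts.

Significance uses the two-sided Wilcoxon rank-sum test at p < 0.001 —
exact null when both samples have n ≤ 25 without ties, tie-corrected
normal approximation otherwise; identical constant samples give p = 1 by
convention. The default unit of replication is the per-replicate
survival indicator at the argmax dose pair (an across-cell-line mode on
per-cell-line summary scores is also provided; which unit real boxplots
use is ambiguous in practice, so both exist and the replicate-level mode
is the documented default). A biomarker is *combination-specific* when
it shifts synergy without moving either monotherapy IC50 by 0.2 log10
units or more (tolerance configurable). Censored IC50s are compared as:
both censored → no shift; one censored → the censored side is evaluated
at the grid top (10,000 nM). The killrate shift is measured at the
baseline synergy argmax, falling back to the perturbed argmax when the
baseline grid shows no synergy (so emergent synergy is measured where it
lives). Protein complexes are ordinary nodes; perturbing one perturbs
only that node.

## Benchmarking

Predicted and reference synergy are dichotomized at stated thresholds
(≥ threshold is synergistic; the internal 0-1 Bliss scale is multiplied
by 100 only at this boundary, so 0.2 lines up with a reference threshold
of 20). Reported: TPR, TNR, BA = (TPR+TNR)/2, Mann-Whitney AUC with
midranked ties, and Pearson r on log10 IC50 over the key overlap with
censored values excluded and counted. Baselines — ridge regression, a
2×64 fully-connected network with early stopping, and gradient-boosted
trees — regress monotherapy killrate on cell-line expression
concatenated with per-node dose-dependent target-inhibition features,
then predict full combination grids that the same Bliss machinery
scores; they therefore see the feature space of the mechanistic model
but never a combination during training. Train/test splits are
entity-exclusive by cell line (CEX), drug (DEX) or both (AEX; rows
mixing held-in and held-out entities are dropped), averaged over 10
random splits by default. The NN hyperparameters are fixed in code;
nothing in this package tunes them.

## Synthetic fixtures: what they emulate and what they do not

The fixture generator (`netavatar.fixtures`) is first-class, tested
code. It emits networks of `n_pathways` parallel receptor→kinase-chain
pathways feeding the two readouts, with weights (16) and biases (−4 per
missing pathway-equivalent) chosen so chains transmit their receptor
state essentially unattenuated and nodes sit near 0 or 1 — the network
computes a crisp OR (redundant pathways: only dual blockade kills;
cross-pathway drug pairs synergistic by construction) or AND (every
pathway required: monotherapy lethality) over pathway states. A
`BACKUP` survival node rescues dual blockade when active: its
gain-of-function is the planted combination-specific *resistance*
biomarker in the default bundle, and in the backup-active variant its
knock-out is the planted *sensitivity* biomarker. Disconnected decoy
nodes must never surface. The avatar panel uses log-normal fold-changes
(median 1, σ = 0.2), a pathogenic tumor-suppressor missense on cell line
CL2, and truncating receptor knockouts making CL3 natively dead. The
drug panel spans 1-10,000 nM affinities and plants one record per
curation filter that must be removed.

Defaults (2 pathways × 3 chain nodes, 3 cell lines, noise 0.05, 100
replicates) are the study conditions for all shipped tests and for
`scripts/acceptance.py`; they were chosen so brute-force oracles (path
enumeration, exact rank-sum enumeration, exhaustive 1-D partitions)
remain feasible. What the fixtures deliberately do **not** emulate:
realistic human pathway topology, graded partial redundancy, feedback
loops (except the dedicated oscillator tests), transcriptional
regulation, or the scale (thousands of nodes) of curated interactomes.
Passing tests therefore demonstrate that the machinery is correct on
systems with known ground truth, not that a particular biological
prediction is right.

## Numerical choices and degenerate inputs

* Logit clamp at 1e-9 keeps biases finite for base activities of 0/1.
* Attractor rounding for cycle detection: 6 decimals.
* Viability is clipped at 1 after normalization (noise can push a
  treated ensemble marginally above its untreated baseline).
* 4PL fitting bounds: top ∈ [0, 1.5], bottom ∈ [0, 1], slope ∈
  [0.05, 20], log10-midpoint ∈ [−4, 9]; non-convergence reports a
  censored fit rather than failing a screen.
* K-means discretization needs ≥ 3 distinct scores; fewer is an error.
* Argmax ties on synergy grids resolve to the first cell in row-major
  order; MoA affinity ties resolve lexicographically; shortest-path ties
  resolve to the lexicographically smallest node sequence.
* Metrics that are undefined (single-class references, < 3 IC50
  overlaps) raise typed errors instead of returning NaN.

## Known limitations

* Edge weights are fixed scalars; no dose- or context-dependent wiring.
* Concentrations are static during a run; no synthesis/degradation.
* Only the activity cap responds to drugs; target concentration is
  untouched (whether real systems scale both is an open question).
* Bliss is the only synergy model (no Loewe/ZIP/HSA) and antagonism is
  deliberately not quantified.
* The manual, biologist-driven calibration loop that real deployments
  of such simulators rely on is out of scope; base parameters here are
  either fixture constructions or user inputs.
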