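# Methods

## Scope and model

The package maps a protein's gating-pathway residue segment onto a
grid-like noncovalent interaction network and evaluates an empirical
thermal model on it. The pipeline has four stages — structure IO,
interaction detection, network/grid analysis, thermodynamics — plus a
synthetic-data module that makes every stage testable without structure
downloads, and a CLI that strings them together.

### Coordinate model

Structures are parsed with gemmi. Author residue numbering is used
throughout (`auth_seq_id` in mmCIF; the residue-number column in PDB),
because pathway landmarks (e.g. F330, L719 in rat TRPV2) are quoted in
author numbering. Only the first model of multi-model files is read;
alternate locations keep the highest-occupancy conformer, ties broken
by first encountered — deterministic and standard. Waters and
non-amino-acid heteroatoms are dropped; non-standard amino acids are
kept and flagged. Pathway selection records unmodelled positions inside
the segment as explicit gaps rather than dropping them: a disordered
loop still separates engaged residues along the chain.

### Interaction detection

Six side-chain interaction classes are detected from distances, ring
centroids/normals (least-squares plane via SVD) and angles. Defaults,
all editable through a YAML criteria file:

| class | window (defaults) |
|---|---|
| hydrogen bond | donor–acceptor heavy atoms ≤ 3.5 Å, antecedent–donor–acceptor angle ≥ 120° |
| salt bridge | charged-group N–O ≤ 4.0 Å |
| π–π | centroids ≤ 5.5 Å parallel (inter-normal ≤ 30°) or ≤ 6.0 Å T-shaped (≥ 60°) |
| cation-π | charge centre to centroid ≤ 6.0 Å, off-axis ≤ 45° |
| CH-π | sp³ carbon to centroid ≤ 4.5 Å |
| lone-pair-π | O/N carrier to centroid ≤ 4.0 Å, off-axis ≤ 45° |

These follow widely used literature geometry for residue contact
analysis; any other calibration (e.g. a published supplementary cutoff
table) can be restored by editing the YAML and re-running, and detected
tables are written as TSV so external tables can be diffed and
re-imported.

Choices worth noting:

- **Histidine** is treated both as aromatic and as a possible cation
  (charge centre = ring centroid); protonation states are not inferred.
- **Tryptophan** contributes both rings; the closer centroid wins.
- A pair qualifying as both salt bridge and hydrogen bond is recorded
  once, as a salt bridge (one bridge per pair).
- **CH-π donors** are an explicit per-residue carbon table excluding
  carbons in charged groups, bonded to heteroatoms, or aromatic — this
  prevents a cation-π or stacking pose from double-counting as CH-π.
  Cationic nitrogens are likewise excluded from lone-pair-π carriers
  (a protonated amine has no lone pair).
- Backbone donors/acceptors are off for intra-pathway detection and on
  for intersubunit detection by default (switchable): reported
  intersubunit H-bonds can involve backbone NH groups, while the
  intra-pathway analysis is a side-chain network.
- Intersubunit detection deduplicates the symmetric copies of a
  homo-oligomer to one record per residue pair-class; intersubunit
  records never count toward the intra-pathway N.
- Detection has no randomness; output is sorted by residue pair and
  type. Because only internal distances and angles are used, the result
  is rigid-motion invariant, and enlarging any distance cutoff can only
  add detections.

Default energy equivalents per type (basic H-bonds, ~1 kcal/mol each):
H-bond 1.0, salt bridge 2.0, π–π 2.0, cation-π 2.0, CH-π 1.0,
lone-pair-π 1.0. These are a per-type convenience only: published
per-bridge n values are assigned ad hoc per bridge (a single H-bond can
count as 2 basic H-bonds), so reproducing a printed table goes through
the pair- and grid-level override mechanism, and the bare-table
regression (`table1`, `StateSummary`) takes printed n directly.

### Network and grids

Engaged residues become nodes; consecutive engaged residues get a
sequence edge weighted by the count of intervening free residues
(author-number difference − 1, so unmodelled gaps count as free by
default — they participate in no interaction; a switch restricts the
count to modelled residues). Interactions add zero-weight edges.
Parallel edges are real (sequence + interaction between adjacent
engaged residues, or two interaction types on one pair) and close
2-cycles of size 0, the smallest grids.

- **Per-edge grid size** (shortest round path): weight of the shortest
  path between the edge's endpoints with the edge removed, computed by
  Dijkstra on the edge-deleted graph (equivalent to the all-pairs
  formulation; Dijkstra is the standard choice for sparse graphs). An
  edge whose endpoints disconnect on removal has no round path and
  reports the acyclic marker (`None`) — unreachable in practice for a
  connected pathway, where every interaction closes a loop through the
  chain and the number of independent cycles equals N.
- **Total S**: total weight of a minimum-weight cycle basis, computed
  with Horton's algorithm — candidate cycles from every shortest-path
  tree crossed with every edge, screened for simplicity, then selected
  greedily by weight under GF(2) independence (bitmask Gaussian
  elimination). Edge weights are made unique by adding 2^j (edge index
  j) on a 2^m scale, which makes shortest paths unique, the Horton set
  complete, and the greedy selection exact; true weights are recovered
  afterwards. Extra parallel edges are first subdivided with virtual
  nodes so both algorithms run on a simple graph; virtual nodes are
  stripped from reported cycles. Operationalising S as the minimum
  basis weight (rather than the sum of per-edge minima) avoids double
  counting shared grids and matches a mesh's independent faces.
- Ties among equal-weight cycles are broken by the perturbation (a
  deterministic lexicographic-like order); reported cycles start at
  their smallest node and proceed toward the smaller neighbour.
- Each grid's **controlled bridge(s)** are its lowest-energy member
  interaction(s), ties reported together; the grid's n is their energy
  sum unless a grid-level override pins the printed value.
- The **verification oracle** enumerates every simple cycle
  (networkx `simple_cycles` on the subdivided graph) and derives exact
  per-edge minima and a matroid-greedy minimum basis — an independent
  route used by the test suite and the `oracle` CLI subcommand, guarded
  to ≤ 15 interaction edges.

### Thermodynamics

All closed-form, no fitting — the constants are the model's fixed
empirical calibration:

- Tᵢ = S/N (undefined for N = 0; 0 for an acyclic network).
- Tₘ(°C) = 34 + (n−2)·10 + (20−s)·2: anchor Tₘ(2, 20) = 34 °C, −2 °C per
  free residue, +10 °C per basic H-bond.
- Ω₁₀ = ((S_c−S_o)·E/2)^(N_c/N_o), E defaulting to 1 kcal/mol. The
  defining expression is typeset ambiguously in the source literature;
  the exponential reading is adopted because the literal product gives
  ~27 where ~155 is printed, while the exponent form reproduces every
  printed transition within ~1.2%. Full-precision values are reported
  (e.g. 156.32 where 154.6 is printed; the residual traces to rounding
  of the exponent N_c/N_o upstream), and regressions compare at 1.5%
  relative tolerance. A transition with S_c ≤ S_o has no
  activation-direction change and raises.
- Q₁₀ = (X₂/X₁)^(10/(T₂−T₁)), temperatures in Kelvin.
- ΔH = (broken_intra + broken_inter − formed) × subunits × E.

## Synthetic data

The geometry generator poses idealised rigid side-chain groups
(Arg/Lys/Asp/Phe/Ser/Ala — enough chemistry for all six classes) at
known distances/angles, each satisfying its default window with ≥ 0.2 Å
/ 5° margin, alongside decoys that violate every window by a wide
margin (≥ 3 Å beyond the largest cutoff, or 35° off-axis). Pose pairs
sit 30 Å apart so no cross-pose contact can form, and atom clashes
< 0.8 Å raise a pose-conflict error. The network generator samples
planted interaction pairs over a small engaged pool and attaches ground
truth computed by the exhaustive oracle at generation time — expected
values are never hand-entered. Both are byte-reproducible under a fixed
seed.

What the fixtures deliberately do not emulate: real rotamer
distributions, cryo-EM noise, B-factors, missing side-chain density,
crowded environments where several windows almost overlap. Passing
tests therefore demonstrate the geometric logic and the graph
computations exactly, but not detection robustness on noisy
experimental coordinates — on real structures the criteria calibration
dominates, which is why the criteria file is the unit of
reproducibility. Full-structure reproduction of published N/S totals
additionally requires the deposited models (the optional
`fetch_structure` helper caches them locally; the analysis core never
touches the network).

## Problem sizes and determinism

Regression tests run the graph core against the oracle on 100 seeded
random networks of up to 12 interaction edges over 60-residue pathways
(well inside the oracle's ≤ 15-edge guard), which keeps exhaustive
enumeration exact and the whole comparison under a minute; the
acceptance script repeats a 25-network self-check. All randomness flows
through explicit integer seeds (numpy `default_rng`); detection and
graph analysis are themselves fully deterministic, so identical inputs
give byte-identical reports.

## Known limitations

- No protonation-state or tautomer inference; His is considered both
  aromatic and cationic, which can over-detect at low pH specificity.
- No water-mediated bridges, no protein–lipid contact scoring (lipids
  enter only as state labels), no backbone-mediated intra-pathway
  contacts by default.
- The per-chain "consensus" across a homotetramer is a median of N and
  S, not a symmetry-aware merge.
- The Tₘ and Ω₁₀ constants are taken as fixed; the package does not
  refit them.
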