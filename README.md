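# thermoring

Thermoring analysis of temperature-gated ion channels: from atomic
coordinates to gating thermodynamics.

Thermosensitive TRP channels (TRPV1–4) open in response to heat, with
sharply defined activation thresholds and temperature sensitivities
(Q₁₀ values up to >100 for rat TRPV2). The *thermoring* model explains
these numbers structurally: the side-chain noncovalent interactions
(H-bonds, salt bridges, π–π, cation-π, CH-π and lone-pair-π contacts)
along a channel's gating pathway form a grid-like mesh network, and the
closed *round paths* ("grids", or thermorings) of that network gauge how
much thermal motion each interaction can absorb before it melts. This
package implements that analysis as a tested, reusable pipeline for
anyone studying residue interaction networks and their thermal stability
in ion channels or other proteins.

## The model

For a pathway segment (e.g. F330–L719 of rat TRPV2), residues engaged in
at least one noncovalent interaction become network nodes; consecutive
engaged residues are joined by sequence edges weighted by the number of
intervening *free* residues, and each interaction adds a zero-weight
edge. On this network:

- each interaction's **grid size** *s* is the weight of the shortest
  round path (cycle) closing over it — the minimal number of free
  residues whose motion controls that bridge;
- the state's totals are **N** (interactions) and **S** (total weight of
  a minimum-weight cycle basis), giving the systematic thermal
  instability **Tᵢ = S/N**;
- the melting threshold of a grid's least-stable bridge is
  **Tₘ(°C) = 34 + (n−2)·10 + (20−s)·2**, with *n* the bridge energy in
  basic-H-bond equivalents (~1 kcal/mol each);
- a closed→open transition has structural thermosensitivity
  **Ω₁₀ = ((S_c−S_o)·E/2)^(N_c/N_o)**, to be compared with the
  functional **Q₁₀ = (X₂/X₁)^(10/(T₂−T₁))**;
- activation enthalpy is the net per-subunit loss of noncovalent
  bridges × subunits × E.

## Worked example

Evaluate the model on the published per-state totals of rat TRPV2
(closed state 3 → open transition):

```python
>>> from thermoring import thermal_instability, melting_threshold, \
...     structural_thermosensitivity
>>> round(thermal_instability(67, 99), 2)       # N=67, S=99
1.48
>>> melting_threshold(2.0, 12)                  # biggest grid: n=2, s=12
50.0
>>> round(structural_thermosensitivity(99, 71, 67, 35), 2)
156.32
```

Tᵢ = 1.48 marks a comparatively stable closed state; the 50 °C melting
threshold of its biggest 12-residue grid matches the channel's 48–52 °C
activation threshold; and Ω₁₀ ≈ 156 reproduces the channel's very high
functional Q₁₀ (≈155) for the first heat activation.

The same pipeline runs from coordinates. On the bundled synthetic
fixture (six posed interaction geometries):

```sh
thermoring fixtures --outdir fixtures
thermoring analyze fixtures/poses.pdb --chain A --segment 1-100 --out state
thermoring table1 values.tsv --transition closed3:open
```

`analyze` writes `state.json` (N, S, Tᵢ, every grid with its size and
controlled bridge, Tₘ of the biggest grid) and `state.grids.tsv`;
`table1` recomputes the Tᵢ/Tₘ/Ω₁₀ columns from a bare per-state TSV
(columns `state N S n s`) with no structure input. `compare` derives
transition metrics from two `analyze` reports, and `oracle` cross-checks
the grid algorithms against exhaustive cycle enumeration on random
planted networks.

## Layout

- `thermoring.structure` — mmCIF/PDB IO (gemmi), pathway selection
- `thermoring.interactions` — geometric interaction detection, criteria
  as YAML, TSV interaction tables
- `thermoring.network` — mesh construction, shortest round paths,
  minimum-weight cycle basis (Horton)
- `thermoring.oracle` — exhaustive cycle-enumeration verification oracle
- `thermoring.thermo` — Tᵢ, Tₘ, Ω₁₀, Q₁₀, activation enthalpy
- `thermoring.synthetic` — planted-geometry and planted-network fixtures
- `thermoring.report` / `thermoring.cli` — state and transition reports,
  `thermoring` command-line tool

See `docs/methods.md` for the methods note (assumptions, parameter
defaults, numerical choices, limitations).
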