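"""State and transition reports: the pipeline driver plus JSON/TSV output.

A *state report* runs the full chain — pathway selection, interaction
detection, network construction, grid enumeration, thermodynamics — for
one structure and gating state.  A *transition report* compares two state
reports sharing the same pathway bounds.  Reports are plain dicts with a
``schema_version`` key so they round-trip through JSON and re-import.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import thermo
from .interactions import (GeometricCriteria, InteractionSet,
                           assign_energy_equivalents, detect_interactions,
                           detect_intersubunit)
from .network import ThermoringNetwork, enumerate_grids, summarize
from .structure import StructureModel, select_pathway

SCHEMA_VERSION = 1


def _grid_dict(grid) -> dict:
    return {
        "label": grid.label,
        "size_s": grid.size_s,
        "cycle": grid.cycle,
        "controlled": [list(e.pair) for e in grid.controlled],
        "controlled_types": [e.itype for e in grid.controlled],
        "n_equiv": grid.n_equiv,
    }


def analyze_chain(
    model: StructureModel,
    chain_id: str,
    start: int,
    end: int,
    criteria: GeometricCriteria | None = None,
    pair_overrides: dict | None = None,
    grid_overrides: dict | None = None,
) -> dict:
    """Full thermoring analysis of one chain's pathway segment."""
    criteria = criteria or GeometricCriteria()
    selection = select_pathway(model, chain_id, start, end)
    iset = detect_interactions(selection, criteria)
    if pair_overrides or grid_overrides:
        iset = assign_energy_equivalents(iset, pair_overrides, grid_overrides)
    net = ThermoringNetwork.from_interactions(iset, selection)
    grids = enumerate_grids(net)
    summary = summarize(net, grids)
    n, s = summary.n_interactions, summary.total_grid_sizes
    biggest = summary.biggest_grid
    report = {
        "chain_id": chain_id,
        "pathway": {"start": start, "end": end,
                    "gaps": selection.gaps},
        "n_interactions": n,
        "total_grid_sizes": s,
        "thermal_instability": round(thermo.thermal_instability(n, s), 2)
        if n else None,
        "grids": [_grid_dict(g) for g in summary.grids],
        "biggest_grid": _grid_dict(biggest) if biggest else None,
        "smallest_grids": [g.label for g in summary.smallest_grids],
        "per_edge_grid_sizes": {
            f"{e.pair[0]}-{e.pair[1]}:{e.itype}": size
            for e, size in summary.per_edge_sizes.items()
        },
        "melting_threshold_C": round(
            thermo.melting_threshold(biggest.n_equiv, biggest.size_s), 1)
        if biggest and biggest.n_equiv > 0 else None,
    }
    return report


def build_state_report(
    model: StructureModel,
    start: int,
    end: int,
    chain_id: str | None = None,
    criteria: GeometricCriteria | None = None,
    include_intersubunit: bool = False,
    pair_overrides: dict | None = None,
    grid_overrides: dict | None = None,
) -> dict:
    """Per-state report; with no chain given, analyses every chain and adds
    a consensus (median N and S across subunits)."""
    criteria = criteria or GeometricCriteria()
    chain_ids = [chain_id] if chain_id else [c.chain_id for c in model.chains]
    per_chain = [
        analyze_chain(model, cid, start, end, criteria,
                      pair_overrides, grid_overrides)
        for cid in chain_ids
    ]
    headline = per_chain[0]
    report = {
        "schema_version": SCHEMA_VERSION,
        "structure_id": model.structure_id,
        "pathway": {"start": start, "end": end},
        "chains": per_chain,
        "n_interactions": headline["n_interactions"],
        "total_grid_sizes": headline["total_grid_sizes"],
        "thermal_instability": headline["thermal_instability"],
        "biggest_grid": headline["biggest_grid"],
        "melting_threshold_C": headline["melting_threshold_C"],
        "consensus": {
            "n_interactions": int(statistics.median(
                c["n_interactions"] for c in per_chain)),
            "total_grid_sizes": int(statistics.median(
                c["total_grid_sizes"] for c in per_chain)),
        },
        "provenance": {"criteria": asdict(criteria)},
    }
    if include_intersubunit:
        inter = detect_intersubunit(model, criteria)
        report["intersubunit"] = [
            {"pair": list(ia.pair), "type": ia.itype.value,
             "distance_A": round(ia.distance, 3)}
            for ia in inter.interactions
        ]
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")


def read_report_json(path: str | Path) -> dict:
    report = json.loads(Path(path).read_text())
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema in {path}")
    return report


def write_grids_tsv(report: dict, path: str | Path) -> None:
    """Grid table of a state report (headline chain) as TSV."""
    grids = report.get("grids")
    if grids is None and report.get("chains"):
        grids = report["chains"][0]["grids"]
    rows = [
        {
            "label": g["label"],
            "size_s": g["size_s"],
            "cycle": "-".join(map(str, g["cycle"])),
            "controlled": ";".join(f"{a}-{b}" for a, b in g["controlled"]),
            "n_equiv": g["n_equiv"],
        }
        for g in grids or []
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_transition_report(
    report_closed: dict,
    report_open: dict,
    energy: float = thermo.DEFAULT_ENERGY_KCAL,
    measured_q10: float | None = None,
    broken_inter: int = 0,
    formed_inter: int = 0,
    subunits: int = 4,
) -> dict:
    """Transition metrics between two state reports (closed first).

    Raises when the two reports were computed over different pathway
    bounds.  Delta H counts the intra-pathway interaction loss plus any
    supplied intersubunit bookkeeping.
    """
    pa, pb = report_closed["pathway"], report_open["pathway"]
    if (pa["start"], pa["end"]) != (pb["start"], pb["end"]):
        raise ValueError("reports cover different pathway bounds")
    s_c = report_closed["total_grid_sizes"]
    s_o = report_open["total_grid_sizes"]
    n_c = report_closed["n_interactions"]
    n_o = report_open["n_interactions"]
    omega = thermo.structural_thermosensitivity(s_c, s_o, n_c, n_o, energy)
    broken_intra = max(n_c - n_o, 0)
    delta_h = thermo.activation_enthalpy(
        broken_intra, broken_inter, formed_inter, subunits, energy)
    return {
        "schema_version": SCHEMA_VERSION,
        "from_state": report_closed["structure_id"],
        "to_state": report_open["structure_id"],
        "delta_n": n_c - n_o,
        "delta_s": s_c - s_o,
        "omega_10": round(omega, 2),
        "delta_h_kcal_mol": delta_h,
        "measured_q10": measured_q10,
        "energy_kcal": energy,
    }


def table_regression(states: pd.DataFrame,
                     transitions: list[tuple[str, str]] | None = None,
                     energy: float = thermo.DEFAULT_ENERGY_KCAL) -> dict:
    """Recompute T_i, T_m and transition Omega_10 from bare printed
    quadruples (state, N, S, n, s) with no structure input.

    ``states`` needs columns state, N, S and optionally n, s.  Output is
    keyed by state id, so row order never matters.
    """
    out: dict = {"states": {}, "transitions": {}}
    summaries: dict[str, thermo.StateSummary] = {}
    for _, row in states.iterrows():
        sid = str(row["state"])
        summary = thermo.StateSummary(
            state_id=sid,
            n_interactions=int(row["N"]),
            total_grid_sizes=int(row["S"]),
            biggest_grid_size=float(row["s"]) if "s" in row and
            pd.notna(row.get("s")) else None,
            biggest_grid_n=float(row["n"]) if "n" in row and
            pd.notna(row.get("n")) else None,
        )
        summaries[sid] = summary
        out["states"][sid] = {
            "N": summary.n_interactions,
            "S": summary.total_grid_sizes,
            "T_i": round(summary.t_i, 2),
            "T_m_C": round(summary.t_m, 1) if summary.t_m is not None
            else None,
        }
    for frm, to in transitions or []:
        if frm not in summaries or to not in summaries:
            raise KeyError(f"transition {frm}->{to} names unknown states")
        tm = thermo.compare_states(summaries[frm], summaries[to], energy)
        out["transitions"][f"{frm}->{to}"] = {
            "delta_N": tm.delta_n,
            "delta_S": tm.delta_s,
            "omega_10": round(tm.omega_10, 2),
        }
    return out
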