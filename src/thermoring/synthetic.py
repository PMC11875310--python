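"""Synthetic fixtures: planted interaction geometries and planted networks.

Two generators make every stage of the pipeline testable without any
structure download:

* :func:`generate_network_fixture` draws an abstract pathway network with
  planted interaction pairs; its ground truth (per-edge shortest round
  paths and minimum-basis total S) is computed by the exhaustive oracle at
  generation time, never hand-entered.

* :func:`generate_structure_fixture` writes a single-chain coordinate
  model in which idealised side-chain groups are posed at known
  interaction geometries (one pose per interaction class, each satisfying
  the default criteria with >= 0.2 A / 5 deg margin) together with decoy
  pairs that violate every criterion by a wide margin.  Detection must
  recover exactly the poses and none of the decoys.

Fixture residues are limited to Arg/Lys/Asp/Phe/Ser/Ala: enough chemistry
for all six interaction classes with minimal atom-placement logic.  Side
chains are placed as idealised rigid groups; no rotamer library, no
B-factors, no attempt to imitate cryo-EM noise.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .network import ThermoringNetwork
from .oracle import MAX_INTERACTION_EDGES, brute_force_grid_oracle
from .structure import AtomRecord, Chain, Residue, StructureModel

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])


# --------------------------------------------------------------------------
# Abstract network fixtures.

@dataclass
class NetworkBlueprint:
    """Ground truth attached to a generated network fixture."""

    seed: int
    n_residues: int
    planted_interactions: list[tuple[int, int]]
    expected_per_edge_sizes: dict[str, int | None]
    expected_s: int
    expected_basis_sizes: list[int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True,
                                         indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkBlueprint":
        data = json.loads(Path(path).read_text())
        data["planted_interactions"] = [tuple(p) for p in
                                        data["planted_interactions"]]
        return cls(**data)


def _pair_key(pair: tuple[int, int]) -> str:
    a, b = sorted(pair)
    return f"{a}-{b}"


def generate_network_fixture(
    seed: int,
    n_residues: int = 60,
    n_interactions: int = 8,
) -> tuple[ThermoringNetwork, NetworkBlueprint]:
    """Random planted pathway network with oracle-computed ground truth.

    Reproducible under a fixed seed.  ``n_interactions`` is capped by the
    oracle guard; an infeasible request (more pairs than the residue pool
    supports) raises.
    """
    if n_interactions > MAX_INTERACTION_EDGES:
        raise ValueError(f"n_interactions capped at {MAX_INTERACTION_EDGES}")
    if n_interactions < 1:
        raise ValueError("need at least one interaction")
    rng = np.random.default_rng(seed)
    # engaged pool small enough to share residues and close cycles
    m_min = max(3, math.ceil((1 + math.sqrt(1 + 8 * n_interactions)) / 2))
    if m_min > n_residues:
        raise ValueError(
            f"{n_interactions} interactions infeasible on {n_residues} "
            "residues")
    m_max = min(n_residues, n_interactions + 3)
    m = int(rng.integers(m_min, max(m_min, m_max) + 1))
    engaged = sorted(rng.choice(np.arange(1, n_residues + 1), size=m,
                                replace=False).tolist())
    all_pairs = list(itertools.combinations(engaged, 2))
    idx = rng.choice(len(all_pairs), size=n_interactions, replace=False)
    pairs = sorted(all_pairs[i] for i in sorted(idx))
    net = ThermoringNetwork.from_pairs(pairs)
    oracle = brute_force_grid_oracle(net)
    per_edge = {_pair_key(ref.pair): size
                for ref, size in oracle.per_edge_sizes.items()}
    blueprint = NetworkBlueprint(
        seed=seed,
        n_residues=n_residues,
        planted_interactions=pairs,
        expected_per_edge_sizes=per_edge,
        expected_s=oracle.total_s,
        expected_basis_sizes=oracle.basis_sizes,
    )
    return net, blueprint


def grid12_replica() -> tuple[ThermoringNetwork, tuple[int, int]]:
    """The pre-S1/VSLD interface thermoring: engaged residues F362, R369,
    F462, D469 with bridges 362-462 (pi) and 369-469 (H-bond); the round
    path F362 -> R369 -> D469 -> F462 -> F362 holds 12 free residues, so
    the 369-469 bridge is controlled by a 12-residue grid."""
    net = ThermoringNetwork.from_pairs([(362, 462), (369, 469)])
    return net, (369, 469)


# --------------------------------------------------------------------------
# Coordinate fixtures with posed interaction geometries.

@dataclass
class GeometryBlueprint:
    """Planted poses (must be detected) and decoys (must not be)."""

    seed: int = 0
    poses: list[dict] = field(default_factory=list)
    decoys: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True,
                                         indent=1) + "\n")


def _atoms(spec: dict[str, np.ndarray]) -> list[AtomRecord]:
    out = []
    for name, pos in spec.items():
        element = "".join(c for c in name if c.isalpha())[0]
        out.append(AtomRecord(name=name, element=element,
                              position=np.asarray(pos, float)))
    return out


def _backbone(anchor: np.ndarray, away: np.ndarray) -> dict[str, np.ndarray]:
    """Minimal backbone placed 'away' from the business end."""
    away = away / np.linalg.norm(away)
    side = np.cross(away, Z)
    if np.linalg.norm(side) < 1e-6:
        side = np.cross(away, X)
    side = side / np.linalg.norm(side)
    ca = anchor + 1.5 * away
    return {
        "CA": ca,
        "N": ca + 1.45 * side,
        "C": ca - 1.45 * side + 0.4 * away,
        "O": ca - 1.45 * side + 1.6 * away,
    }


def _ser(chain: str, seq: int, og: np.ndarray, cb_dir: np.ndarray) -> Residue:
    cb_dir = cb_dir / np.linalg.norm(cb_dir)
    cb = og + 1.42 * cb_dir
    spec = {"OG": og, "CB": cb}
    spec.update(_backbone(cb, cb_dir))
    return Residue(chain, seq, "SER", atoms=_atoms(spec))


def _ala(chain: str, seq: int, cb: np.ndarray, out_dir: np.ndarray) -> Residue:
    out_dir = out_dir / np.linalg.norm(out_dir)
    spec = {"CB": cb}
    spec.update(_backbone(cb, out_dir))
    return Residue(chain, seq, "ALA", atoms=_atoms(spec))


def _arg(chain: str, seq: int, cz: np.ndarray, tail_dir: np.ndarray) -> Residue:
    """Guanidinium in the plane spanned by tail_dir and its normal-in-plane."""
    tail_dir = tail_dir / np.linalg.norm(tail_dir)
    perp = np.cross(Z, tail_dir)
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(X, tail_dir)
    perp = perp / np.linalg.norm(perp)
    spec = {
        "CZ": cz,
        "NH1": cz - 0.65 * tail_dir + 1.1 * perp,
        "NH2": cz - 0.65 * tail_dir - 1.1 * perp,
        "NE": cz + 1.35 * tail_dir,
        "CD": cz + 2.85 * tail_dir,
        "CG": cz + 4.3 * tail_dir + 0.5 * perp,
        "CB": cz + 5.7 * tail_dir,
    }
    spec.update(_backbone(spec["CB"], tail_dir))
    return Residue(chain, seq, "ARG", atoms=_atoms(spec))


def _asp(chain: str, seq: int, od1: np.ndarray, tail_dir: np.ndarray) -> Residue:
    tail_dir = tail_dir / np.linalg.norm(tail_dir)
    perp = np.cross(Z, tail_dir)
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(X, tail_dir)
    perp = perp / np.linalg.norm(perp)
    cg = od1 + 1.1 * tail_dir + 0.6 * perp
    spec = {
        "OD1": od1,
        "CG": cg,
        "OD2": cg + 1.0 * tail_dir - 0.75 * perp,
        "CB": cg + 1.5 * tail_dir + 0.6 * perp,
    }
    spec.update(_backbone(spec["CB"], tail_dir))
    return Residue(chain, seq, "ASP", atoms=_atoms(spec))


def _lys(chain: str, seq: int, nz: np.ndarray, tail_dir: np.ndarray) -> Residue:
    tail_dir = tail_dir / np.linalg.norm(tail_dir)
    perp = np.cross(Z, tail_dir)
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(X, tail_dir)
    perp = perp / np.linalg.norm(perp)
    spec = {
        "NZ": nz,
        "CE": nz + 1.5 * tail_dir,
        "CD": nz + 2.6 * tail_dir + 1.1 * perp,
        "CG": nz + 4.0 * tail_dir + 1.4 * perp,
        "CB": nz + 5.3 * tail_dir + 2.0 * perp,
    }
    spec.update(_backbone(spec["CB"], tail_dir))
    return Residue(chain, seq, "LYS", atoms=_atoms(spec))


def _phe(chain: str, seq: int, center: np.ndarray, normal: np.ndarray,
         cb_angle_deg: float = 0.0) -> Residue:
    """Benzene ring of radius 1.39 A centred at *center*, plane
    perpendicular to *normal*; CB placed radially outward from CG."""
    normal = normal / np.linalg.norm(normal)
    e1 = np.cross(normal, Z)
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(normal, X)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rot = math.radians(cb_angle_deg)
    e1, e2 = (math.cos(rot) * e1 + math.sin(rot) * e2,
              -math.sin(rot) * e1 + math.cos(rot) * e2)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    spec = {}
    for i, name in enumerate(names):
        ang = math.radians(60.0 * i)
        spec[name] = center + 1.39 * (math.cos(ang) * e1 + math.sin(ang) * e2)
    cb = center + 2.9 * e1
    spec["CB"] = cb
    spec.update(_backbone(cb, e1))
    return Residue(chain, seq, "PHE", atoms=_atoms(spec))


def default_geometry_blueprint(seed: int = 0) -> GeometryBlueprint:
    """Six poses covering every interaction class, plus matched decoys."""
    bp = GeometryBlueprint(seed=seed)
    bp.poses = [
        {"itype": "hydrogen_bond", "res_a": "SER", "res_b": "SER",
         "distance": 2.8},
        {"itype": "salt_bridge", "res_a": "ARG", "res_b": "ASP",
         "distance": 2.9},
        {"itype": "pi_pi", "res_a": "PHE", "res_b": "PHE", "distance": 3.8},
        {"itype": "cation_pi", "res_a": "LYS", "res_b": "PHE",
         "distance": 4.2},
        {"itype": "ch_pi", "res_a": "ALA", "res_b": "PHE", "distance": 3.6},
        {"itype": "lone_pair_pi", "res_a": "SER", "res_b": "PHE",
         "distance": 3.2},
    ]
    bp.decoys = [
        {"itype": "hydrogen_bond", "res_a": "SER", "res_b": "SER",
         "distance": 9.0},
        {"itype": "salt_bridge", "res_a": "ARG", "res_b": "ASP",
         "distance": 9.0},
        {"itype": "pi_pi", "res_a": "PHE", "res_b": "PHE", "distance": 10.0},
        {"itype": "cation_pi", "res_a": "LYS", "res_b": "PHE",
         "distance": 9.0},
        {"itype": "ch_pi", "res_a": "ALA", "res_b": "PHE", "distance": 9.0},
        {"itype": "lone_pair_pi", "res_a": "SER", "res_b": "PHE",
         "distance": 9.0},
        # angle decoy: cation well inside the distance cutoff but 80 deg
        # off the ring axis (limit 45 deg)
        {"itype": "cation_pi", "res_a": "LYS", "res_b": "PHE",
         "distance": 4.5, "offaxis_deg": 80.0},
    ]
    return bp


def _build_pose(itype: str, base: np.ndarray, seq_a: int, seq_b: int,
                distance: float, offaxis_deg: float = 0.0,
                chain: str = "A") -> tuple[Residue, Residue]:
    d = distance
    if itype == "hydrogen_bond":
        # donor OG at base, antecedent CB along -x, acceptor 30 deg off +x
        acc = base + d * np.array([math.cos(math.radians(30)),
                                   math.sin(math.radians(30)), 0.0])
        return (_ser(chain, seq_a, base, -X),
                _ser(chain, seq_b, acc, X))
    if itype == "salt_bridge":
        arg = _arg(chain, seq_a, base, -X)
        nh1 = arg.atom("NH1").position
        return arg, _asp(chain, seq_b, nh1 + d * X, X)
    if itype == "pi_pi":
        return (_phe(chain, seq_a, base, Z),
                _phe(chain, seq_b, base + d * Z, Z, cb_angle_deg=180.0))
    if itype == "cation_pi":
        theta = math.radians(offaxis_deg)
        site = base + d * (math.sin(theta) * X + math.cos(theta) * Z)
        return (_phe(chain, seq_b, base, Z),
                _lys(chain, seq_a, site, Z))
    if itype == "ch_pi":
        return (_phe(chain, seq_b, base, Z),
                _ala(chain, seq_a, base + d * Z, Z))
    if itype == "lone_pair_pi":
        return (_phe(chain, seq_b, base, Z),
                _ser(chain, seq_a, base + d * Z, Z))
    raise ValueError(f"unknown pose type {itype!r}")


def generate_structure_fixture(
    blueprint: GeometryBlueprint | None = None,
    path: str | Path | None = None,
) -> StructureModel:
    """Single-chain PDB-writable model realising the blueprint's poses.

    Pose pairs are spaced 30 A apart so no cross-pose contact can form.
    Raises when two placed atoms clash (< 0.8 A), which would indicate a
    pose conflicting with covalent geometry.
    """
    bp = blueprint or default_geometry_blueprint()
    residues: list[Residue] = []
    seq = 1
    row = 0
    for pose in bp.poses + bp.decoys:
        base = np.array([0.0, 30.0 * row, 0.0])
        ra, rb = _build_pose(pose["itype"], base, seq, seq + 1,
                             pose["distance"],
                             pose.get("offaxis_deg", 0.0))
        residues.extend([ra, rb])
        seq += 2
        row += 1
    coords = [(r.seq_number, a.name, a.position)
              for r in residues for a in r.atoms]
    for i, (si, ni, pi) in enumerate(coords):
        for sj, nj, pj in coords[i + 1:]:
            if si != sj and np.linalg.norm(pi - pj) < 0.8:
                raise ValueError(
                    f"pose conflict: atom {ni} of residue {si} clashes "
                    f"with {nj} of residue {sj}")
    model = StructureModel(structure_id="synthetic-poses",
                           chains=[Chain("A", residues)])
    if path is not None:
        from .structure import write_pdb
        write_pdb(model, path)
    return model


def generate_intersubunit_fixture(separation: float = 4.2) -> StructureModel:
    """Two-chain model with one planted inter-chain cation-pi pose; with
    *separation* beyond the cutoffs (> 12 A) the chains make no contact."""
    ring_center = np.zeros(3)
    phe = _phe("A", 10, ring_center, Z)
    lys = _lys("B", 20, ring_center + separation * Z, Z)
    return StructureModel(
        structure_id="synthetic-intersubunit",
        chains=[Chain("A", [phe]), Chain("B", [lys])],
        assembly_size=2,
    )
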