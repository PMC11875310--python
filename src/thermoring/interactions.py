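"""Detection of side-chain noncovalent interactions.

Six interaction classes are recognised between residue side chains:
hydrogen bonds, salt bridges, pi-pi stacking, cation-pi, CH-pi and
lone-pair-pi contacts.  Geometry windows live in :class:`GeometricCriteria`
and can be loaded from / dumped to a YAML file, so a differently calibrated
cutoff table can be swapped in without code changes.

Detection is purely geometric and deterministic: it uses only interatomic
distances, ring centroids/normals and angles, so the detected set is
invariant under any rigid motion of the coordinates, and the output is
sorted by residue numbers and type.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .structure import PathwaySelection, Residue, StructureModel

logger = logging.getLogger(__name__)


class InteractionType(str, enum.Enum):
    hydrogen_bond = "hydrogen_bond"
    salt_bridge = "salt_bridge"
    pi_pi = "pi_pi"
    cation_pi = "cation_pi"
    ch_pi = "ch_pi"
    lone_pair_pi = "lone_pair_pi"


# --------------------------------------------------------------------------
# Chemistry tables.  Side-chain atoms only; backbone donors/acceptors are
# admitted solely where a criteria switch allows them (see detect_intersubunit).

SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    # donor atom -> bonded heavy-atom antecedent (for the donor angle)
    "ARG": {"NE": "CZ", "NH1": "CZ", "NH2": "CZ"},
    "LYS": {"NZ": "CE"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "CYS": {"SG": "CB"},
}

SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "HIS": ["ND1", "NE2"],
}

#: Nitrogens of positively chargeable groups (His counted as a possible
#: cation; protonation is not inferred).
CATIONIC_NITROGENS: dict[str, list[str]] = {
    "ARG": ["NE", "NH1", "NH2"],
    "LYS": ["NZ"],
    "HIS": ["ND1", "NE2"],
}

ANIONIC_OXYGENS: dict[str, list[str]] = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
}

#: Aromatic ring atom sets.  Trp has two rings; the closer centroid is used.
AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [
        ["CG", "CD1", "NE1", "CE2", "CD2"],
        ["CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
    ],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

#: sp3 carbons admitted as CH-pi donors.  Carbons bonded to charged groups,
#: heteroatoms or aromatic rings are excluded so a cation-pi or stacking pose
#: never double-counts as CH-pi.
CH_PI_DONOR_CARBONS: dict[str, list[str]] = {
    "ALA": ["CB"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG"],
    "PRO": ["CB", "CG"],
    "THR": ["CG2"],
    "LYS": ["CB", "CG", "CD"],
    "ARG": ["CB", "CG"],
    "GLU": ["CB", "CG"],
    "GLN": ["CB", "CG"],
    "ASP": ["CB"],
    "ASN": ["CB"],
}

#: Side-chain O/N lone-pair carriers for lone-pair-pi contacts.  Cationic
#: nitrogens are excluded (a protonated amine has no lone pair to donate).
LONE_PAIR_CARRIERS: dict[str, list[str]] = {
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1", "ND2"],
    "GLN": ["OE1", "NE2"],
    "MET": ["SD"],
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Default basic-H-bond equivalents per interaction type (overridable; the
#: printed per-bridge n values of a reference table always win via overrides).
DEFAULT_ENERGY_EQUIV: dict[InteractionType, float] = {
    InteractionType.hydrogen_bond: 1.0,
    InteractionType.salt_bridge: 2.0,
    InteractionType.pi_pi: 2.0,
    InteractionType.cation_pi: 2.0,
    InteractionType.ch_pi: 1.0,
    InteractionType.lone_pair_pi: 1.0,
}


@dataclass
class GeometricCriteria:
    """Geometry windows per interaction class (distances in Å, angles in °).

    Defaults follow widely used literature geometry for side-chain contact
    analysis; the exact calibration used for any particular published table
    can be restored by editing a YAML dump of this object.
    """

    hbond_max_distance: float = 3.5
    hbond_min_donor_angle: float = 120.0
    salt_bridge_max_distance: float = 4.0
    pi_pi_max_parallel_distance: float = 5.5
    pi_pi_max_tshaped_distance: float = 6.0
    pi_pi_parallel_max_angle: float = 30.0
    pi_pi_tshaped_min_angle: float = 60.0
    cation_pi_max_distance: float = 6.0
    cation_pi_max_offaxis_angle: float = 45.0
    ch_pi_max_distance: float = 4.5
    lone_pair_pi_max_distance: float = 4.0
    lone_pair_pi_max_offaxis_angle: float = 45.0
    #: admit backbone N-H donors / C=O acceptors for intra-pathway pairs
    intra_include_backbone: bool = False
    #: admit backbone donors/acceptors for intersubunit pairs (the literature
    #: reports e.g. a side-chain-to-backbone-NH intersubunit H-bond)
    intersubunit_include_backbone: bool = True
    #: candidate pairs farther than this (minimum heavy-atom distance) are
    #: skipped before any geometry is measured
    prefilter_distance: float = 8.0

    @property
    def max_cutoff(self) -> float:
        return max(
            self.hbond_max_distance,
            self.salt_bridge_max_distance,
            self.pi_pi_max_tshaped_distance,
            self.cation_pi_max_distance,
            self.ch_pi_max_distance,
            self.lone_pair_pi_max_distance,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeometricCriteria":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown criteria keys: {sorted(unknown)}")
        return cls(**data)


class ResidueRef(NamedTuple):
    """Lightweight reference to a residue: (chain, author number, name)."""

    chain_id: str
    seq_number: int
    res_name: str


@dataclass(frozen=True)
class Interaction:
    """A typed residue-pair noncovalent contact with its geometry metrics."""

    partner_a: ResidueRef
    partner_b: ResidueRef
    itype: InteractionType
    distance: float
    angles: tuple[tuple[str, float], ...] = ()
    energy_equiv: float = 1.0
    intersubunit: bool = False

    def __post_init__(self) -> None:
        if self.partner_a == self.partner_b:
            raise ValueError("an interaction needs two distinct residues")
        if self.energy_equiv <= 0:
            raise ValueError("energy_equiv must be positive")

    @property
    def pair(self) -> tuple[int, int]:
        """Unordered residue-number pair, sorted."""
        return tuple(sorted((self.partner_a.seq_number, self.partner_b.seq_number)))

    @property
    def sort_key(self):
        return (*self.pair, self.itype.value, self.partner_a.chain_id,
                self.partner_b.chain_id)


@dataclass
class InteractionSet:
    """Detected interactions plus the criteria that produced them."""

    interactions: list[Interaction]
    criteria: GeometricCriteria
    pathway: PathwaySelection | None = None
    #: grid-level energy overrides, keyed by frozenset of residue-number pairs
    grid_energy_overrides: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for ia in self.interactions:
            key = (frozenset(ia.pair), ia.itype, ia.intersubunit)
            if key in seen:
                raise ValueError(f"duplicate interaction {key}")
            seen.add(key)
        self.interactions.sort(key=lambda ia: ia.sort_key)

    @property
    def n_interactions(self) -> int:
        """N of the thermoring model: intra-pathway, intra-subunit count."""
        return sum(1 for ia in self.interactions if not ia.intersubunit)

    def intra(self) -> list[Interaction]:
        return [ia for ia in self.interactions if not ia.intersubunit]

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for ia in self.interactions:
            a, b = ia.partner_a, ia.partner_b
            key_angle = ia.angles[0][1] if ia.angles else math.nan
            rows.append(
                dict(
                    chain_a=a.chain_id, res_a=a.seq_number, name_a=a.res_name,
                    chain_b=b.chain_id, res_b=b.seq_number, name_b=b.res_name,
                    type=ia.itype.value,
                    distance_A=round(ia.distance, 3),
                    key_angle_deg=round(key_angle, 1) if ia.angles else "",
                    energy_equiv=ia.energy_equiv,
                    intersubunit=int(ia.intersubunit),
                )
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 criteria: GeometricCriteria | None = None) -> "InteractionSet":
        df = pd.read_csv(path, sep="\t")
        interactions = []
        for _, row in df.iterrows():
            interactions.append(
                Interaction(
                    partner_a=ResidueRef(str(row.chain_a), int(row.res_a),
                                         str(row.name_a)),
                    partner_b=ResidueRef(str(row.chain_b), int(row.res_b),
                                         str(row.name_b)),
                    itype=InteractionType(row.type),
                    distance=float(row.distance_A),
                    energy_equiv=float(row.energy_equiv),
                    intersubunit=bool(row.intersubunit),
                )
            )
        return cls(interactions=interactions,
                   criteria=criteria or GeometricCriteria())


# --------------------------------------------------------------------------
# Geometry helpers.

def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _vec_angle(v1: np.ndarray, v2: np.ndarray, fold: bool = True) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return min(ang, 180.0 - ang) if fold else ang


def ring_planes(res: Residue) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid, unit normal) for each aromatic ring of *res*."""
    planes = []
    for ring in AROMATIC_RINGS.get(res.res_name, []):
        coords = res.coords(ring)
        if coords is None:
            continue
        centroid = coords.mean(axis=0)
        centered = coords - centroid
        # least-squares plane normal = singular vector of smallest variance
        _, _, vt = np.linalg.svd(centered)
        planes.append((centroid, vt[2] / np.linalg.norm(vt[2])))
    return planes


def _sidechain_atoms(res: Residue, include_backbone: bool) -> list:
    if include_backbone:
        return list(res.atoms)
    return [a for a in res.atoms if a.name not in BACKBONE_ATOMS]


def _donor_sites(res: Residue, include_backbone: bool):
    """Yield (donor atom, antecedent atom | None)."""
    for name, antecedent in SIDECHAIN_DONORS.get(res.res_name, {}).items():
        d = res.atom(name)
        if d is not None:
            yield d, res.atom(antecedent)
    if include_backbone and res.res_name != "PRO":
        d = res.atom("N")
        if d is not None:
            yield d, res.atom("CA")


def _acceptor_sites(res: Residue, include_backbone: bool):
    for name in SIDECHAIN_ACCEPTORS.get(res.res_name, []):
        a = res.atom(name)
        if a is not None:
            yield a
    if include_backbone:
        a = res.atom("O")
        if a is not None:
            yield a


def _cation_center(res: Residue) -> np.ndarray | None:
    """Charge-group centre: mean of the cationic nitrogens, or the His ring
    centroid (imidazolium charge is delocalised over the ring)."""
    if res.res_name == "HIS":
        planes = ring_planes(res)
        return planes[0][0] if planes else None
    names = CATIONIC_NITROGENS.get(res.res_name)
    if not names:
        return None
    coords = res.coords(names)
    return None if coords is None else coords.mean(axis=0)


# --------------------------------------------------------------------------
# Per-type detectors.  Each returns None or (distance, angles tuple).

def _check_hbond(donor_res: Residue, acceptor_res: Residue,
                 c: GeometricCriteria, include_backbone: bool):
    best = None
    for donor, antecedent in _donor_sites(donor_res, include_backbone):
        for acceptor in _acceptor_sites(acceptor_res, include_backbone):
            d = float(np.linalg.norm(donor.position - acceptor.position))
            if d > c.hbond_max_distance or d < 1.5:
                continue
            if antecedent is not None:
                ang = _angle(antecedent.position, donor.position,
                             acceptor.position)
                if ang < c.hbond_min_donor_angle:
                    continue
            else:
                ang = math.nan
            if best is None or d < best[0]:
                best = (d, (("donor_angle", round(ang, 2)),))
    return best


def _check_salt_bridge(res_a: Residue, res_b: Residue, c: GeometricCriteria):
    for cat, ani in ((res_a, res_b), (res_b, res_a)):
        n_names = CATIONIC_NITROGENS.get(cat.res_name)
        o_names = ANIONIC_OXYGENS.get(ani.res_name)
        if not n_names or not o_names:
            continue
        ncoords, ocoords = cat.coords(n_names), ani.coords(o_names)
        if ncoords is None or ocoords is None:
            continue
        dists = np.linalg.norm(ncoords[:, None, :] - ocoords[None, :, :], axis=2)
        d = float(dists.min())
        if d <= c.salt_bridge_max_distance:
            return d, ()
    return None


def _check_pi_pi(res_a: Residue, res_b: Residue, c: GeometricCriteria):
    best = None
    for cen_a, norm_a in ring_planes(res_a):
        for cen_b, norm_b in ring_planes(res_b):
            d = float(np.linalg.norm(cen_a - cen_b))
            theta = _vec_angle(norm_a, norm_b)
            ok = (theta <= c.pi_pi_parallel_max_angle
                  and d <= c.pi_pi_max_parallel_distance) or (
                 theta >= c.pi_pi_tshaped_min_angle
                 and d <= c.pi_pi_max_tshaped_distance)
            if ok and (best is None or d < best[0]):
                best = (d, (("interplanar_angle", round(theta, 2)),))
    return best


def _check_cation_pi(res_a: Residue, res_b: Residue, c: GeometricCriteria):
    best = None
    for cat, aro in ((res_a, res_b), (res_b, res_a)):
        center = _cation_center(cat)
        if center is None:
            continue
        for centroid, normal in ring_planes(aro):
            d = float(np.linalg.norm(center - centroid))
            if d > c.cation_pi_max_distance or d < 2.0:
                continue
            offaxis = _vec_angle(normal, center - centroid)
            if offaxis > c.cation_pi_max_offaxis_angle:
                continue
            if best is None or d < best[0]:
                best = (d, (("offaxis_angle", round(offaxis, 2)),))
    return best


def _check_ch_pi(res_a: Residue, res_b: Residue, c: GeometricCriteria):
    best = None
    for don, aro in ((res_a, res_b), (res_b, res_a)):
        carbons = CH_PI_DONOR_CARBONS.get(don.res_name, [])
        if not carbons:
            continue
        for centroid, _ in ring_planes(aro):
            for cname in carbons:
                atom = don.atom(cname)
                if atom is None:
                    continue
                d = float(np.linalg.norm(atom.position - centroid))
                if 2.0 <= d <= c.ch_pi_max_distance and (
                        best is None or d < best[0]):
                    best = (d, ())
    return best


def _check_lone_pair_pi(res_a: Residue, res_b: Residue, c: GeometricCriteria):
    best = None
    for don, aro in ((res_a, res_b), (res_b, res_a)):
        carriers = LONE_PAIR_CARRIERS.get(don.res_name, [])
        if not carriers:
            continue
        for centroid, normal in ring_planes(aro):
            for name in carriers:
                atom = don.atom(name)
                if atom is None:
                    continue
                d = float(np.linalg.norm(atom.position - centroid))
                if not 2.0 <= d <= c.lone_pair_pi_max_distance:
                    continue
                offaxis = _vec_angle(normal, atom.position - centroid)
                if offaxis > c.lone_pair_pi_max_offaxis_angle:
                    continue
                if best is None or d < best[0]:
                    best = (d, (("offaxis_angle", round(offaxis, 2)),))
    return best


def _detect_pair(res_a: Residue, res_b: Residue, c: GeometricCriteria,
                 include_backbone: bool,
                 intersubunit: bool) -> list[Interaction]:
    """All interaction records for one unordered residue pair."""
    found: dict[InteractionType, tuple] = {}
    hit = _check_salt_bridge(res_a, res_b, c)
    if hit:
        found[InteractionType.salt_bridge] = hit
    hb = (_check_hbond(res_a, res_b, c, include_backbone)
          or _check_hbond(res_b, res_a, c, include_backbone))
    # a pair qualifying as both salt bridge and H-bond is one bridge
    if hb and InteractionType.salt_bridge not in found:
        found[InteractionType.hydrogen_bond] = hb
    for itype, checker in (
        (InteractionType.pi_pi, _check_pi_pi),
        (InteractionType.cation_pi, _check_cation_pi),
        (InteractionType.ch_pi, _check_ch_pi),
        (InteractionType.lone_pair_pi, _check_lone_pair_pi),
    ):
        hit = checker(res_a, res_b, c)
        if hit:
            found[itype] = hit

    ref_a = ResidueRef(res_a.chain_id, res_a.seq_number, res_a.res_name)
    ref_b = ResidueRef(res_b.chain_id, res_b.seq_number, res_b.res_name)
    if (ref_b.seq_number, ref_b.chain_id) < (ref_a.seq_number, ref_a.chain_id):
        ref_a, ref_b = ref_b, ref_a
    return [
        Interaction(
            partner_a=ref_a, partner_b=ref_b, itype=itype,
            distance=dist, angles=angles,
            energy_equiv=DEFAULT_ENERGY_EQUIV[itype],
            intersubunit=intersubunit,
        )
        for itype, (dist, angles) in found.items()
    ]


def _min_heavy_distance(res_a: Residue, res_b: Residue) -> float:
    ca = np.vstack([a.position for a in res_a.atoms])
    cb = np.vstack([a.position for a in res_b.atoms])
    return float(np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2).min())


def detect_interactions(
    selection: PathwaySelection,
    criteria: GeometricCriteria | None = None,
) -> InteractionSet:
    """Detect intra-subunit noncovalent interactions within a pathway.

    Candidate pairs with missing side-chain atoms are skipped with a logged
    warning, never a crash.  Output order is deterministic (residue numbers,
    then type).
    """
    c = criteria or GeometricCriteria()
    residues = selection.residues
    out: list[Interaction] = []
    for i, ra in enumerate(residues):
        for rb in residues[i + 1:]:
            if not ra.atoms or not rb.atoms:
                logger.warning("pair %s-%s skipped: missing atoms",
                               ra.label, rb.label)
                continue
            if _min_heavy_distance(ra, rb) > c.prefilter_distance:
                continue
            try:
                out.extend(
                    _detect_pair(ra, rb, c, c.intra_include_backbone, False))
            except ValueError as exc:
                logger.warning("pair %s-%s skipped: %s", ra.label, rb.label, exc)
    return InteractionSet(interactions=out, criteria=c, pathway=selection)


def detect_intersubunit(
    model: StructureModel,
    criteria: GeometricCriteria | None = None,
) -> InteractionSet:
    """Detect interactions whose partners lie on different chains.

    Symmetric copies across a homo-oligomer are deduplicated to one record
    per unique residue pair-class (pair of author numbers + type).  A
    single-chain model yields an empty set with a warning.
    """
    c = criteria or GeometricCriteria()
    if model.assembly_size < 2 or len(model.chains) < 2:
        logger.warning("%s: single chain, no intersubunit interactions",
                       model.structure_id)
        return InteractionSet(interactions=[], criteria=c)
    seen: dict[tuple, Interaction] = {}
    for i, chain_a in enumerate(model.chains):
        for chain_b in model.chains[i + 1:]:
            for ra in chain_a.residues:
                for rb in chain_b.residues:
                    if not ra.atoms or not rb.atoms:
                        continue
                    if _min_heavy_distance(ra, rb) > c.prefilter_distance:
                        continue
                    for ia in _detect_pair(
                            ra, rb, c, c.intersubunit_include_backbone, True):
                        key = (ia.pair, ia.itype)
                        if key not in seen:
                            seen[key] = ia
    return InteractionSet(interactions=list(seen.values()), criteria=c)


def assign_energy_equivalents(
    iset: InteractionSet,
    pair_overrides: dict[tuple[int, int], float] | None = None,
    grid_overrides: dict[Iterable[tuple[int, int]], float] | None = None,
) -> InteractionSet:
    """Attach basic-H-bond energy equivalents.

    ``pair_overrides`` maps an unordered residue-number pair to its n value;
    ``grid_overrides`` maps a collection of pairs (a grid's controlled
    bridges) to the grid-level total n, consulted when a grid's melting
    threshold is computed.  Overrides naming unknown pairs raise.
    """
    pair_overrides = {tuple(sorted(k)): v
                      for k, v in (pair_overrides or {}).items()}
    known = {ia.pair for ia in iset.interactions}
    unknown = set(pair_overrides) - known
    if unknown:
        raise ValueError(f"overrides reference unknown pairs: {sorted(unknown)}")
    new = [
        replace(ia, energy_equiv=pair_overrides.get(ia.pair, ia.energy_equiv))
        for ia in iset.interactions
    ]
    grid_ov = {}
    for pairs, total in (grid_overrides or {}).items():
        key = frozenset(tuple(sorted(p)) for p in pairs)
        missing = key - known
        if missing:
            raise ValueError(f"grid override references unknown pairs: "
                             f"{sorted(missing)}")
        grid_ov[key] = total
    return InteractionSet(interactions=new, criteria=iset.criteria,
                          pathway=iset.pathway, grid_energy_overrides=grid_ov)
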