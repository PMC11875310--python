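"""Atomic structure input/output and gating-pathway selection.

Structures are read with gemmi (mmCIF or PDB) into a light, uniform
coordinate model.  Residue numbering throughout is *author* numbering
(``auth_seq_id`` in mmCIF, columns 23-26 in PDB), because that is the
numbering in which gating-pathway landmarks such as F330 and L719 are
quoted in the literature.  Only the first model of multi-model files is
used; for alternate locations the highest-occupancy conformer is kept
(ties broken by first encountered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class AtomRecord:
    """One atom: name, element symbol, position (Å), occupancy, alt-loc tag."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A residue with author numbering and its atoms."""

    chain_id: str
    seq_number: int
    res_name: str
    insertion_code: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    @property
    def label(self) -> str:
        """Single-letter-free label such as ``ARG369``."""
        return f"{self.res_name}{self.seq_number}{self.insertion_code}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names: list[str]) -> np.ndarray | None:
        """Stacked coordinates for *names*; None if any atom is missing."""
        rows = []
        for n in names:
            a = self.atom(n)
            if a is None:
                return None
            rows.append(a.position)
        return np.vstack(rows)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_number: int) -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number:
                return r
        return None


@dataclass
class StructureModel:
    """Parsed chains/residues/atoms: the raw substrate of the analysis."""

    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    assembly_size: int = 1

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("a structure model needs at least one chain")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.structure_id}")


@dataclass
class PathwaySelection:
    """Ordered residue segment [start, end] on one chain, with explicit gaps.

    ``gaps`` lists author positions inside the segment that have no modelled
    residue (e.g. a disordered pore turret).  Gap residues participate in no
    interaction but still separate engaged residues along the sequence, so
    they are never silently dropped.
    """

    chain_id: str
    start: int
    end: int
    residues: list[Residue] = field(default_factory=list)
    gaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("pathway start must be below end")
        nums = [r.seq_number for r in self.residues]
        if nums != sorted(nums) or len(set(nums)) != len(nums):
            raise ValueError("pathway residues must be strictly increasing")

    def residue(self, seq_number: int) -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number:
                return r
        return None

    def __contains__(self, seq_number: int) -> bool:
        return self.start <= seq_number <= self.end


def _keep_best_altloc(res: gemmi.Residue) -> list[AtomRecord]:
    """Collapse alternate locations: highest occupancy, tie -> first seen."""
    best: dict[str, AtomRecord] = {}
    for atom in res:
        rec = AtomRecord(
            name=atom.name,
            element=atom.element.name,
            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            occupancy=atom.occ,
            alt_loc=atom.altloc if atom.altloc else "",
        )
        prev = best.get(atom.name)
        if prev is None or rec.occupancy > prev.occupancy:
            best[atom.name] = rec
    return list(best.values())


def load_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read an mmCIF or PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Coordinate file.
    format
        ``"mmcif"``, ``"pdb"`` or ``"auto"`` (extension/content sniffing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no model in file")
    if len(st) > 1:
        logger.warning("%s: %d models, using the first only", path.name, len(st))
    model = st[0]

    chains: list[Chain] = []
    for ch in model:
        residues = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and (info.is_water() or not info.is_amino_acid()):
                continue
            if res.name not in STANDARD_AA:
                logger.debug("non-standard residue %s %s kept", res.name, res.seqid)
            residues.append(
                Residue(
                    chain_id=ch.name,
                    seq_number=res.seqid.num,
                    res_name=res.name,
                    insertion_code=res.seqid.icode.strip(),
                    atoms=_keep_best_altloc(res),
                )
            )
        if residues:
            chains.append(Chain(chain_id=ch.name, residues=residues))
    if not chains:
        raise ValueError(f"{path}: empty model (no amino-acid residues)")
    return StructureModel(
        structure_id=st.name or path.stem,
        chains=chains,
        assembly_size=len(chains),
    )


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.res_name
            gr.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model in PDB format (coordinates to 3 decimals)."""
    to_gemmi(model).write_pdb(str(path))


def write_mmcif(model: StructureModel, path: str | Path) -> None:
    """Write the model in mmCIF format."""
    to_gemmi(model).make_mmcif_document().write_file(str(path))


def select_pathway(
    model: StructureModel, chain_id: str, start: int, end: int
) -> PathwaySelection:
    """Restrict a chain to the residue segment [start, end].

    Unmodelled positions inside the segment are recorded in ``gaps``.
    Raises ``KeyError`` for an absent chain and ``ValueError`` for an
    empty selection or a reversed segment.
    """
    if start >= end:
        raise ValueError("start must be below end")
    chain = model.chain(chain_id)
    picked = sorted(
        (r for r in chain.residues if start <= r.seq_number <= end),
        key=lambda r: (r.seq_number, r.insertion_code),
    )
    if not picked:
        raise ValueError(
            f"no residues of chain {chain_id} fall inside [{start}, {end}]"
        )
    present = {r.seq_number for r in picked}
    gaps = [n for n in range(start, end + 1) if n not in present]
    return PathwaySelection(
        chain_id=chain_id, start=start, end=end, residues=picked, gaps=gaps
    )


def fetch_structure(accession: str, cache_dir: str | Path) -> Path:
    """Download a deposited mmCIF by accession into *cache_dir* (optional
    convenience; the analysis core never touches the network).  Returns the
    cached path; reuses an existing file."""
    import urllib.request

    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{accession.lower()}.cif"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{accession.upper()}.cif"
    urllib.request.urlretrieve(url, dest)  # noqa: S310 - https to a fixed host
    return dest
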