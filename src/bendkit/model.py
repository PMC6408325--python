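"""Macromolecular coordinate model and PDB/mmCIF input-output.

The in-memory representation is a lightweight chain → residue → atom
hierarchy (:class:`StructureModel`) that every geometric stage of the
toolkit consumes.  File parsing and writing are delegated to gemmi; this
module fixes the policies the rest of the pipeline relies on: first model
only, highest-occupancy altloc conformer, waters retained but flagged
hetero, and a bundled van der Waals radius table so surface-area and clash
results are reproducible across installations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyModelError,
    FormatError,
    ParseError,
    SelectionError,
)

#: Van der Waals radii in Å.  Fixed bundled table (Bondi-style values for the
#: common elements) so SASA and clash counts do not depend on an external
#: library version.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "ZN": 1.39,
    "MN": 1.61,
    "FE": 1.56,
    "SE": 1.90,
}

#: The 20 standard amino acids plus common variants treated as protein.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}


def vdw_radius(element: str) -> Optional[float]:
    """Return the bundled van der Waals radius for *element*, or None."""
    return VDW_RADII.get(element.upper())


@dataclass
class AtomRecord:
    """A single atom: label, element, position and bookkeeping flags."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    vdw_radius: Optional[float] = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if self.vdw_radius is None:
            self.vdw_radius = vdw_radius(self.element)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ResidueRecord:
    """One residue: author number, optional insertion code, and its atoms."""

    seq_id: int
    comp_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def is_water(self) -> bool:
        return self.comp_id in ("HOH", "WAT", "DOD")

    @property
    def is_protein(self) -> bool:
        return self.comp_id in STANDARD_AA

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.comp_id, "X")


@dataclass
class StructureModel:
    """Hierarchical coordinates: ordered chains of residues of atoms."""

    id: str
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    source_format: str = "synthetic"

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def protein_chain_ids(self) -> list[str]:
        """Chains with at least one standard amino-acid residue."""
        return [
            cid
            for cid, residues in self.chains.items()
            if any(r.is_protein for r in residues)
        ]

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of the protein residues of a chain."""
        if chain_id not in self.chains:
            raise SelectionError(f"no chain {chain_id!r} in model {self.id!r}")
        return "".join(r.one_letter for r in self.chains[chain_id] if r.is_protein)

    def iter_atoms(
        self, chain_ids: Optional[Iterable[str]] = None, heavy_only: bool = True
    ) -> Iterator[tuple[str, ResidueRecord, AtomRecord]]:
        ids = self.chain_ids() if chain_ids is None else list(chain_ids)
        for cid in ids:
            if cid not in self.chains:
                raise SelectionError(f"no chain {cid!r} in model {self.id!r}")
            for res in self.chains[cid]:
                for atom in res.atoms:
                    if heavy_only and atom.is_hydrogen:
                        continue
                    yield cid, res, atom

    def validate(self) -> None:
        if not self.chains:
            raise EmptyModelError(f"model {self.id!r} has no chains")
        if not any(self.chains.values()):
            raise EmptyModelError(f"model {self.id!r} has no residues")


# ---------------------------------------------------------------------------
# Reading


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif (atom.occupancy, _altloc_key(atom.altloc)) > (
            prev.occupancy,
            _altloc_key(prev.altloc),
        ):
            by_name[atom.name] = atom
    for atom in by_name.values():
        atom.altloc = ""
    return [by_name[name] for name in order]


def _altloc_key(altloc: str) -> float:
    # earlier letters win ties, so invert the ordinal
    return -ord(altloc) if altloc else 0.0


def _detect_format(path: str, format: str) -> str:
    if format != "auto":
        return format
    lower = path.lower()
    if lower.endswith((".cif", ".mmcif", ".cif.gz")):
        return "mmcif"
    return "pdb"


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first deposited model of multi-model files is kept; altlocs are
    resolved to the highest-occupancy conformer; waters are retained but
    flagged hetero.

    Parameters
    ----------
    path:
        Coordinate file.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (inferred from the extension).

    Raises
    ------
    ParseError
        If the file cannot be parsed under the named standard.
    EmptyModelError
        If no protein chain survives parsing.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
        else:
            raise ParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")

    model = StructureModel(id=st.name or os.path.basename(path), chains={},
                           source_format=fmt)
    gm = st[0]  # first model only
    for chain in gm:
        residues: list[ResidueRecord] = []
        for res in chain:
            atoms = [
                AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    altloc=atom.altloc if atom.altloc != "\x00" else "",
                    is_hetero=res.het_flag == "H" or res.name not in STANDARD_AA,
                )
                for atom in res
            ]
            atoms = _resolve_altlocs(atoms)
            residues.append(
                ResidueRecord(
                    seq_id=res.seqid.num,
                    comp_id=res.name,
                    atoms=atoms,
                    insertion_code=(res.seqid.icode or "").strip(),
                )
            )
        if residues:
            model.chains[chain.name] = residues
    if not model.protein_chain_ids():
        raise EmptyModelError(f"{path}: no protein chains found")
    return model


# ---------------------------------------------------------------------------
# Writing


def write_structure(model: StructureModel, path: str | os.PathLike,
                    format: str = "pdb") -> None:
    """Write *model* to a PDB file.

    The emitted file re-reads to an atom-wise identical model (names,
    numbers, coordinates to 3 decimals).
    """
    if format != "pdb":
        raise FormatError(f"unsupported output format {format!r}")
    for cid in model.chains:
        if len(cid) > 2:
            raise FormatError(f"chain id {cid!r} too long for PDB output")
    model.validate()
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.comp_id
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "H" if res.is_water or not res.is_protein else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            chain.add_residue(gres)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(os.fspath(path))


# ---------------------------------------------------------------------------
# Selection


def select_atoms(
    model: StructureModel,
    chain_ids: Optional[Sequence[str]] = None,
    residue_ranges: Optional[Sequence[tuple[int, int]]] = None,
    atom_names: Optional[Sequence[str]] = None,
    heavy_only: bool = True,
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Select atom coordinates with provenance labels.

    Returns an ``(n, 3)`` coordinate array and a parallel list of
    ``(chain_id, residue seq_id, atom name)`` labels.  Order is deterministic:
    chains in the requested order, then residue number, then atom name.
    An empty selection is allowed and returns empty arrays.
    """
    ids = model.chain_ids() if chain_ids is None else list(chain_ids)
    for cid in ids:
        if cid not in model.chains:
            raise SelectionError(f"no chain {cid!r} in model {model.id!r}")
    names = set(atom_names) if atom_names is not None else None
    coords: list[np.ndarray] = []
    labels: list[tuple[str, int, str]] = []
    for cid in ids:
        residues = sorted(
            model.chains[cid], key=lambda r: (r.seq_id, r.insertion_code)
        )
        for res in residues:
            if residue_ranges is not None and not any(
                lo <= res.seq_id <= hi for lo, hi in residue_ranges
            ):
                continue
            for atom in sorted(res.atoms, key=lambda a: a.name):
                if heavy_only and atom.is_hydrogen:
                    continue
                if names is not None and atom.name not in names:
                    continue
                coords.append(atom.coord)
                labels.append((cid, res.seq_id, atom.name))
    if coords:
        return np.vstack(coords), labels
    return np.empty((0, 3)), labels
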