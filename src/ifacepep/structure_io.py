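"""Reading and writing of protein structures in PDB format.

The pipeline works on multimeric assemblies (e.g. an alpha/beta-tubulin
dimer sliced from a microtubule lattice model) and on small peptide
fragments excised from them.  PDB is the mandatory dialect; parsing is
delegated to :mod:`gemmi` and the result is converted into light domain
containers (:class:`Atom`, :class:`Residue`, :class:`AssemblyModel`) that
the downstream stages consume.

Author residue numbering is preserved everywhere; the only renumbering
happens in :func:`write_fragment`, which emits candidate peptides as
single-chain PDB files numbered from 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

try:  # Biopython >= 1.80
    from Bio.PDB.Polypeptide import protein_letters_3to1
except ImportError:  # pragma: no cover
    from Bio.Data.SCOPData import protein_letters_3to1

__all__ = [
    "Atom",
    "Residue",
    "AssemblyModel",
    "StructureParseError",
    "read_structure",
    "write_fragment",
    "write_assembly",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_fasta",
    "to_one_letter",
]

#: residue names always treated as hetero groups even when written as ATOM
_HETERO_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "NA", "CL", "K", "MG", "CA2", "ZN",
     "GTP", "GDP", "ATP", "ADP", "SO4", "PO4"}
)


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be parsed into an assembly."""


@dataclass
class Atom:
    """A single atom of a structure model (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue identified by author numbering within its chain."""

    chain_id: str
    resnum: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    @property
    def label(self) -> str:
        """Human-readable identifier, e.g. ``A.Val258``."""
        three = self.resname.capitalize()
        return f"{self.chain_id}.{three}{self.resnum}{self.icode.strip()}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        heavy = self.heavy_atoms()
        if not heavy:
            raise ValueError(f"residue {self.label} has no heavy atoms")
        return np.array([a.coords for a in heavy])

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.label} has no atom {name!r}")


@dataclass
class AssemblyModel:
    """One model of a (possibly multimeric) structure.

    ``chains`` maps chain id to the ordered residue list; polymer residues
    are kept sorted by (resnum, icode).  Hetero groups (waters, ions,
    nucleotides such as GTP/GDP) carry ``is_hetero=True``.
    """

    model_id: int
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def residues(self, include_hetero: bool = True) -> Iterator[Residue]:
        for residues in self.chains.values():
            for res in residues:
                if include_hetero or not res.is_hetero:
                    yield res

    def polymer_residues(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in model")
        return [r for r in self.chains[chain_id] if not r.is_hetero]

    def residue(self, chain_id: str, resnum: int, icode: str = "") -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.resnum == resnum and res.icode == icode:
                return res
        raise KeyError(f"residue {chain_id}:{resnum}{icode} not in model")

    def atoms(self) -> list[Atom]:
        """Flat atom list; its order defines trajectory atom indexing."""
        return [a for res in self.residues() for a in res.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()])

    def atom_residues(self) -> list[Residue]:
        """Owning residue for each entry of :meth:`atoms` (same order)."""
        return [res for res in self.residues() for _ in res.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.key in seen:
                raise ValueError(f"duplicate residue key {res.key}")
            if not res.atoms:
                raise ValueError(f"residue {res.label} has no atoms")
            seen.add(res.key)


# ---------------------------------------------------------------------------
# reading


def _validate_pdb_text(path: Path) -> None:
    # gemmi is permissive; fail loudly on mangled ATOM records, naming the line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise StructureParseError(
                            f"{path}: malformed coordinate field on line {lineno}: {line.rstrip()!r}"
                        ) from None
            elif line.startswith(("ATOM", "HETATM")):
                raise StructureParseError(
                    f"{path}: truncated ATOM/HETATM record on line {lineno}"
                )


def _is_hetero(resname: str, het_flag: str) -> bool:
    if resname.strip().upper() in _HETERO_RESNAMES:
        return True
    if het_flag == "H":
        return True
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        return False
    return het_flag == "H"


def _resolve_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    if policy not in ("highest-occupancy", "first", "all"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    if policy == "all":
        return atoms
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            resolved.append(group[0])
        elif policy == "first":
            resolved.append(group[0])
        else:  # highest occupancy; ties broken toward altloc "A" (then alphabetical)
            resolved.append(min(group, key=lambda a: (-a.occupancy, a.altloc or "~")))
    return resolved


def read_structure(
    path: str | Path,
    model_select: int = 1,
    altloc_policy: str = "highest-occupancy",
) -> AssemblyModel:
    """Read one model of a PDB file into an :class:`AssemblyModel`.

    Parameters
    ----------
    path:
        PDB file (``.pdb``; ``.cif`` also accepted via gemmi).
    model_select:
        1-based model number to extract (PDB ``MODEL`` record numbering).
    altloc_policy:
        ``"highest-occupancy"`` (default; ties resolved toward altloc A),
        ``"first"``, or ``"all"`` (keep every alternate location).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".pdb", ".ent", ""):
        _validate_pdb_text(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    model = None
    for m in st:
        if m.num == model_select:
            model = m
            break
    if model is None:
        raise ValueError(f"{path}: model {model_select} not present")
    assembly = _convert_model(model, altloc_policy)
    if assembly.n_atoms == 0:
        raise StructureParseError(f"{path}: model {model_select} contains no atoms")
    assembly.validate()
    return assembly


def _convert_model(model: gemmi.Model, altloc_policy: str) -> AssemblyModel:
    assembly = AssemblyModel(model_id=model.num)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            atoms = [
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms, altloc_policy)
            residues.append(
                Residue(
                    chain_id=chain.name,
                    resnum=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    resname=res.name,
                    atoms=atoms,
                    is_hetero=_is_hetero(res.name, res.het_flag),
                )
            )
        # author numbering preserved; polymer part kept sorted for contiguity logic
        polymer = sorted(
            (r for r in residues if not r.is_hetero), key=lambda r: (r.resnum, r.icode)
        )
        hetero = [r for r in residues if r.is_hetero]
        assembly.chains[chain.name] = polymer + hetero
    return assembly


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(assembly: AssemblyModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "ifacepep"
    model = gemmi.Model(assembly.model_id)
    for chain_id, residues in assembly.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.seqid = gemmi.SeqId(res.resnum, res.icode or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\x00"
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_assembly(assembly: AssemblyModel, path: str | Path) -> None:
    """Write an assembly as a single-model PDB file."""
    _to_gemmi(assembly).write_pdb(str(path))


def write_fragment(candidate, path: str | Path) -> None:
    """Write a peptide candidate as a single-chain PDB, renumbered from 1.

    The sequence and coordinates are those of the source segment; chain id
    is ``"P"`` and residues are numbered 1..n, which is what downstream
    docking/simulation tools expect for an isolated peptide.
    """
    residues = getattr(candidate, "residues", None)
    if not residues:
        raise ValueError("candidate has no residues/coordinates to write")
    frag = AssemblyModel(model_id=1)
    frag.chains["P"] = [
        Residue(
            chain_id="P",
            resnum=i + 1,
            icode="",
            resname=res.resname,
            atoms=[
                Atom(a.serial, a.name, a.element, a.coords.copy(), a.occupancy, a.altloc)
                for a in res.atoms
            ],
            is_hetero=False,
        )
        for i, res in enumerate(residues)
    ]
    write_assembly(frag, path)


def write_trajectory_pdb(
    topology: AssemblyModel, frames: np.ndarray, path: str | Path
) -> None:
    """Write frame coordinates over a fixed topology as a multi-model PDB."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != topology.n_atoms:
        raise ValueError("frames must be (n_frames, n_atoms, 3) matching the topology")
    st = gemmi.Structure()
    st.name = "ifacepep-traj"
    template = _to_gemmi(topology)[0]
    for f, frame in enumerate(frames, start=1):
        model = template.clone()
        model.num = f
        i = 0
        for chain in model:
            for res in chain:
                for atom in res:
                    atom.pos = gemmi.Position(*frame[i])
                    i += 1
        st.add_model(model)
    st.write_pdb(str(path))


def read_trajectory_pdb(path: str | Path) -> tuple[AssemblyModel, np.ndarray]:
    """Read a multi-model PDB as (topology from model 1, frames array)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    topology = _convert_model(st[0], "all")
    n_atoms = topology.n_atoms
    frames = np.empty((len(st), n_atoms, 3))
    for f, model in enumerate(st):
        i = 0
        for chain in model:
            for res in chain:
                for atom in res:
                    frames[f, i] = (atom.pos.x, atom.pos.y, atom.pos.z)
                    i += 1
        if i != n_atoms:
            raise StructureParseError(f"{path}: model {model.num} atom count mismatch")
    return topology, frames


def write_fasta(candidates: Iterable, path: str | Path) -> None:
    """Write candidate sequences to a FASTA file (ids as headers)."""
    with open(path, "w") as fh:
        for cand in candidates:
            fh.write(f">{cand.id} {cand.source_chain}:{cand.start}-{cand.end}\n")
            seq = cand.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def to_one_letter(resname: str) -> str:
    """Map a 3-letter residue code to its one-letter code (unknown -> 'X')."""
    code = protein_letters_3to1.get(resname.strip().upper(), "X")
    return code if len(code) == 1 and code.isalpha() else "X"
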