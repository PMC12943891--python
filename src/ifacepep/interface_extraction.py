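"""Interface mapping and contiguous peptide-candidate extraction.

Stage 1 of the pipeline: residues of one chain lying within a distance
cutoff (default 6 A, minimum heavy-atom distance) of another chain are
marked as interface residues, and maximal contiguous stretches of them
become peptide candidates.  Each candidate is then duplicated into two
terminal variants: free termini (NH2-/-COOH, charged at pH 7) and capped
termini (acetyl / N-methylamide, neutral).

Formal charges follow fixed pKa rules at pH 7: Asp/Glu -1, Arg/Lys +1,
His neutral, free N-terminus +1, free C-terminus -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AssemblyModel, Residue, to_one_letter

__all__ = [
    "InterfaceContact",
    "PeptideCandidate",
    "min_heavy_atom_distance",
    "find_interface_residues",
    "contiguous_segments",
    "extract_candidates",
    "make_terminal_variants",
    "neutralizing_counterions",
    "sidechain_charge",
]

ResidueKey = tuple[str, int, str]

#: side-chain formal charges at pH 7 (fixed pKa; His treated neutral)
_SIDECHAIN_CHARGE = {"D": -1, "E": -1, "R": +1, "K": +1}


@dataclass(frozen=True)
class InterfaceContact:
    """A residue pair from different chains within the interface cutoff."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float
    chain_pair: tuple[str, str]
    interface_label: str = ""

    def __post_init__(self) -> None:
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")
        if self.residue_a[0] == self.residue_b[0]:
            raise ValueError("contact residues must come from different chains")


@dataclass
class PeptideCandidate:
    """A contiguous interfacial segment proposed as a peptide."""

    id: str
    source_chain: str
    start: int
    end: int
    sequence: str
    residues: list[Residue] = field(default_factory=list)
    terminal_variant: str = "free"
    interface_label: str = ""
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if self.terminal_variant not in ("free", "capped"):
            raise ValueError(f"unknown terminal variant {self.terminal_variant!r}")
        if self.residues and len(self.sequence) != len(self.residues):
            raise ValueError("sequence length must match residue count")

    def __len__(self) -> int:
        return len(self.sequence)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for res in self.residues for a in res.atoms])


def min_heavy_atom_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs (Angstrom)."""
    return float(cdist(res_a.heavy_coords(), res_b.heavy_coords()).min())


def find_interface_residues(
    assembly: AssemblyModel,
    chain_pair: tuple[str, str],
    cutoff: float = 6.0,
    include_hetero: bool = False,
    interface_label: str = "",
) -> list[InterfaceContact]:
    """All residue pairs across ``chain_pair`` with min heavy-atom distance <= cutoff.

    Hetero groups (waters, ions, nucleotides) are excluded by default.
    The result is symmetric in the chain order: ``(A, B)`` and ``(B, A)``
    yield the same contact set (pairs are reported with ``residue_a`` from
    the first chain given).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca, cb = chain_pair
    for c in (ca, cb):
        if c not in assembly.chains:
            raise KeyError(f"chain {c!r} not in assembly")

    def _chain_arrays(chain_id: str):
        coords, res_idx, residues = [], [], []
        pool = (
            assembly.chains[chain_id]
            if include_hetero
            else assembly.polymer_residues(chain_id)
        )
        for i, res in enumerate(pool):
            heavy = res.heavy_atoms()
            if not heavy:
                continue
            residues.append(res)
            for a in heavy:
                coords.append(a.coords)
                res_idx.append(len(residues) - 1)
        return np.array(coords), np.array(res_idx), residues

    xa, ia, ra = _chain_arrays(ca)
    xb, ib, rb = _chain_arrays(cb)
    if len(xa) == 0 or len(xb) == 0:
        return []
    d = cdist(xa, xb)
    # reduce atom-pair distances to residue-pair minima
    nmin = np.full((len(ra), len(rb)), np.inf)
    np.minimum.at(nmin, (ia[:, None], ib[None, :]), d)
    contacts = []
    for i, j in zip(*np.nonzero(nmin <= cutoff)):
        contacts.append(
            InterfaceContact(
                residue_a=ra[i].key,
                residue_b=rb[j].key,
                min_distance=float(nmin[i, j]),
                chain_pair=(ca, cb),
                interface_label=interface_label,
            )
        )
    return contacts


def contiguous_segments(
    interface_residues: Iterable[ResidueKey],
    min_len: int = 6,
    max_gap: int = 0,
    present: dict[str, set[int]] | None = None,
) -> list[tuple[str, int, int]]:
    """Maximal contiguous runs of interface residues per chain.

    Consecutive members of a run differ in author resnum by at most
    ``max_gap + 1``; runs shorter than ``min_len`` are dropped.  When
    ``present`` gives the residue numbers actually present in the model per
    chain, a gap can only be bridged if every intermediate residue exists
    (a chain break always terminates a run).  Insertion codes are not
    bridged.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_chain: dict[str, set[int]] = {}
    for chain_id, resnum, icode in interface_residues:
        if icode:
            continue  # icode residues participate only as isolated positions
        by_chain.setdefault(chain_id, set()).add(resnum)
    segments = []
    for chain_id in sorted(by_chain):
        nums = sorted(by_chain[chain_id])
        start = prev = nums[0]
        for n in nums[1:]:
            bridgeable = n - prev <= max_gap + 1
            if bridgeable and present is not None:
                have = present.get(chain_id, set())
                bridgeable = all(m in have for m in range(prev + 1, n))
            if bridgeable:
                prev = n
            else:
                if prev - start + 1 >= min_len:
                    segments.append((chain_id, start, prev))
                start = prev = n
        if prev - start + 1 >= min_len:
            segments.append((chain_id, start, prev))
    return segments


def extract_candidates(
    assembly: AssemblyModel,
    segments: Sequence[tuple[str, int, int]],
    interface_label: str = "",
    id_prefix: str = "P",
) -> list[PeptideCandidate]:
    """One candidate per segment; ids P1..Pn in chain-then-resnum order."""
    ordered = sorted(segments)
    candidates = []
    for k, (chain_id, start, end) in enumerate(ordered, start=1):
        residues = []
        for resnum in range(start, end + 1):
            try:
                res = assembly.residue(chain_id, resnum)
            except KeyError:
                raise KeyError(
                    f"segment {chain_id}:{start}-{end} references absent residue {resnum}"
                ) from None
            residues.append(res)
        sequence = "".join(to_one_letter(r.resname) for r in residues)
        candidates.append(
            PeptideCandidate(
                id=f"{id_prefix}{k}",
                source_chain=chain_id,
                start=start,
                end=end,
                sequence=sequence,
                residues=residues,
                terminal_variant="free",
                interface_label=interface_label,
                formal_charge=peptide_formal_charge(sequence, "free"),
            )
        )
    return candidates


def sidechain_charge(sequence: str) -> int:
    """Sum of side-chain formal charges at pH 7."""
    return sum(_SIDECHAIN_CHARGE.get(aa, 0) for aa in sequence.upper())


def peptide_formal_charge(sequence: str, terminal_variant: str) -> int:
    """Net formal charge: side chains plus termini (+1/-1 if free, 0/0 if capped)."""
    charge = sidechain_charge(sequence)
    if terminal_variant == "free":
        charge += 1 - 1  # NH3+ and COO- cancel
    return charge


def make_terminal_variants(
    candidate: PeptideCandidate,
) -> tuple[PeptideCandidate, PeptideCandidate]:
    """Free-termini and capped (Ace/NMe) variants of a candidate.

    The two variants share sequence and coordinates; they differ only in
    the terminal tag and the formal charge implied by it.
    """
    if len(candidate) == 0:
        raise ValueError("cannot make variants of an empty candidate")
    free = replace(
        candidate,
        terminal_variant="free",
        formal_charge=peptide_formal_charge(candidate.sequence, "free"),
    )
    capped = replace(
        candidate,
        terminal_variant="capped",
        formal_charge=peptide_formal_charge(candidate.sequence, "capped"),
    )
    return free, capped


def neutralizing_counterions(net_charge: int) -> tuple[int, int]:
    """(n_Na, n_Cl) needed to neutralize a system of the given net charge."""
    return (max(0, -net_charge), max(0, net_charge))
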