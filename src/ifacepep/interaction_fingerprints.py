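"""Geometric interaction fingerprints over trajectory frames.

For each frame, peptide-receptor interactions (hydrogen bonds,
hydrophobic, van der Waals, ionic, pi-stacking) are detected from purely
geometric criteria and collapsed to residue-level keys
``(receptor residue, peptide residue, type)``.  Over a trajectory this
yields a boolean timeline per key and its *persistence* — the fraction of
frames in which the interaction is present, the quantity usually quoted
as contact frequency (e.g. "hydrophobic contact, ~99% of frames").

Hydrogen bonds are evaluated in donor-H-acceptor angle mode when
hydrogens are present; :func:`hbond_heavy_fallback` provides a
distance-only donor-acceptor criterion for hydrogen-free (e.g.
cryo-EM-derived) frames and flags its keys as heavy-atom mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AssemblyModel, Residue
from .trajectory_analysis import TrajectoryEnsemble

__all__ = [
    "InteractionCriteria",
    "FingerprintTimeline",
    "InteractionContext",
    "detect_frame_interactions",
    "hbond_heavy_fallback",
    "build_timeline",
    "BONDI_RADII",
]

ResidueKey = tuple[str, int, str]
Key = tuple[ResidueKey, ResidueKey, str]

#: Bondi van der Waals radii (Angstrom)
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

# Apolar carbons per residue: carbons bonded only to C/H/S in the standard
# amino-acid templates (used for the hydrophobic criterion).
APOLAR_CARBONS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset({"CB"}),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "MET": frozenset({"CB", "CG", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG"}),
    "SER": frozenset(),
    "THR": frozenset({"CG2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}

#: positively / negatively charged side-chain heavy atoms (pH 7)
CATIONIC_ATOMS = {
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "LYS": {"NZ"},
}
ANIONIC_ATOMS = {
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
}

#: aromatic ring atom names per residue (TRP contributes two rings)
AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}

_COVALENT_HX_MAX = 1.25  # A; N/O-H covalent bond detection cutoff


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for interaction detection (all overridable)."""

    hbond_da_max: float = 3.5  # donor-acceptor heavy distance, A
    hbond_dha_min: float = 130.0  # donor-H-acceptor angle, degrees
    hydrophobic_cc_max: float = 4.5  # apolar carbon-carbon distance, A
    vdw_tolerance: float = 0.5  # added to Bondi radii sum, A
    ionic_max: float = 4.5  # charged-group heavy-atom distance, A
    pistack_centroid_max: float = 5.5  # ring centroid distance, A
    pistack_angle_max: float = 40.0  # ring-plane angle, degrees

    def __post_init__(self) -> None:
        for name in ("hbond_da_max", "hydrophobic_cc_max", "vdw_tolerance",
                     "ionic_max", "pistack_centroid_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_dha_min", "pistack_angle_max"):
            if not 0 < getattr(self, name) <= 180:
                raise ValueError(f"{name} must be in (0, 180]")


@dataclass
class FingerprintTimeline:
    """Per-key boolean presence over frames, with persistence fractions."""

    keys: list[Key]
    presence: np.ndarray  # (n_keys, n_frames) bool
    persistence: np.ndarray  # (n_keys,), row means of presence

    def __post_init__(self) -> None:
        if self.presence.shape[0] != len(self.keys):
            raise ValueError("presence rows must match keys")
        expected = self.presence.mean(axis=1) if self.presence.size else np.empty(0)
        if not np.allclose(self.persistence, expected):
            raise ValueError("persistence must equal row means of presence")

    def as_dict(self) -> dict[Key, float]:
        return dict(zip(self.keys, self.persistence.tolist()))


class InteractionContext:
    """Atom classifications for a fixed topology, precomputed once.

    Donor/acceptor/apolar/charged/ring classification is template-driven
    for the 20 standard residues; for non-standard residues (synthetic
    fixtures) apolar carbons are inferred geometrically from the reference
    coordinates (a carbon bonded only to C/H/S) and donors/acceptors fall
    back to element rules (N/O acceptors; N/O with a covalently bound H as
    donors).
    """

    def __init__(
        self,
        topology: AssemblyModel,
        receptor_sel: np.ndarray,
        peptide_sel: np.ndarray,
        reference: np.ndarray | None = None,
    ) -> None:
        receptor_sel = np.asarray(receptor_sel, dtype=int)
        peptide_sel = np.asarray(peptide_sel, dtype=int)
        if np.intersect1d(receptor_sel, peptide_sel).size:
            raise ValueError("receptor and peptide selections overlap")
        self.topology = topology
        self.receptor_sel = receptor_sel
        self.peptide_sel = peptide_sel
        atoms = topology.atoms()
        residues = topology.atom_residues()
        self.elements = np.array([a.element.upper() for a in atoms])
        self.names = [a.name for a in atoms]
        self.res_keys = [r.key for r in residues]
        self.resnames = [r.resname.upper() for r in residues]
        coords = topology.coords() if reference is None else np.asarray(reference)

        n = len(atoms)
        side = np.full(n, -1, dtype=int)  # 0 receptor, 1 peptide
        side[receptor_sel] = 0
        side[peptide_sel] = 1
        self.side = side

        in_scope = side >= 0
        is_h = np.array([a.is_hydrogen for a in atoms])
        # covalent H attachment by geometry (template-free; works for any topology)
        self.h_parent = np.full(n, -1, dtype=int)
        heavy_idx = np.nonzero(in_scope & ~is_h)[0]
        h_idx = np.nonzero(in_scope & is_h)[0]
        if len(h_idx) and len(heavy_idx):
            d = cdist(coords[h_idx], coords[heavy_idx])
            nearest = d.argmin(axis=1)
            ok = d[np.arange(len(h_idx)), nearest] <= _COVALENT_HX_MAX
            self.h_parent[h_idx[ok]] = heavy_idx[nearest[ok]]

        self.acceptors = np.nonzero(in_scope & np.isin(self.elements, ("N", "O")))[0]
        donor_set = set(self.h_parent[self.h_parent >= 0]) & set(self.acceptors)
        self.donors = np.array(sorted(donor_set), dtype=int)
        self.donor_hydrogens = {
            d: np.nonzero(self.h_parent == d)[0] for d in self.donors
        }

        self.apolar = self._classify_apolar(coords, in_scope, is_h)
        self.vdw_heavy = np.nonzero(in_scope & ~is_h)[0]
        self.vdw_radii = np.array(
            [BONDI_RADII.get(e, 1.7) for e in self.elements[self.vdw_heavy]]
        )
        self.cationic = self._charged_atoms(CATIONIC_ATOMS, in_scope)
        self.anionic = self._charged_atoms(ANIONIC_ATOMS, in_scope)
        self.rings = self._find_rings(in_scope)

    def _classify_apolar(self, coords, in_scope, is_h) -> np.ndarray:
        apolar = []
        geom_candidates = []
        for i in np.nonzero(in_scope & (self.elements == "C"))[0]:
            template = APOLAR_CARBONS.get(self.resnames[i])
            if template is not None:
                if self.names[i] in template:
                    apolar.append(i)
            else:
                geom_candidates.append(i)
        if geom_candidates:
            heavy = np.nonzero(~is_h)[0]
            d = cdist(coords[geom_candidates], coords[heavy])
            for row, i in enumerate(geom_candidates):
                bonded = heavy[(d[row] < 1.9) & (d[row] > 1e-6)]
                if all(self.elements[j] in ("C", "H", "S") for j in bonded):
                    apolar.append(i)
        return np.array(sorted(apolar), dtype=int)

    def _charged_atoms(self, table, in_scope) -> np.ndarray:
        out = [
            i
            for i in np.nonzero(in_scope)[0]
            if self.names[i] in table.get(self.resnames[i], ())
        ]
        return np.array(out, dtype=int)

    def _find_rings(self, in_scope):
        rings = []  # (atom index tuple, side, residue key)
        seen = set()
        for i in np.nonzero(in_scope)[0]:
            rk = self.res_keys[i]
            if rk in seen:
                continue
            seen.add(rk)
            for names in AROMATIC_RINGS.get(self.resnames[i], ()):
                members = [
                    j
                    for j in np.nonzero(in_scope)[0]
                    if self.res_keys[j] == rk and self.names[j] in names
                ]
                if len(members) == len(names):
                    rings.append((tuple(members), self.side[members[0]], rk))
        return rings


def _cross_pairs(ctx, idx_a, idx_b, coords, cutoff):
    """Pairs (i, j) with i receptor-side, j peptide-side, within cutoff."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        return []
    d = cdist(coords[idx_a], coords[idx_b])
    pairs = []
    for ai, bj in zip(*np.nonzero(d <= cutoff)):
        i, j = idx_a[ai], idx_b[bj]
        if ctx.side[i] == ctx.side[j]:
            continue
        pairs.append((i, j) if ctx.side[i] == 0 else (j, i))
    return pairs


def detect_frame_interactions(
    frame: np.ndarray,
    ctx: InteractionContext,
    criteria: InteractionCriteria | None = None,
    hbond_mode: str = "angle",
) -> set[Key]:
    """Residue-level interaction keys present in one frame.

    ``hbond_mode``: ``"angle"`` requires an explicit donor hydrogen and a
    donor-H-acceptor angle above threshold; ``"heavy"`` uses the
    donor-acceptor distance only (keys typed ``"hbond_heavy"``).
    Atom-level hits are collapsed to one key per
    (receptor residue, peptide residue, type).
    """
    if criteria is None:
        criteria = InteractionCriteria()
    coords = np.asarray(frame, dtype=float)
    keys: set[Key] = set()

    def add(i: int, j: int, itype: str) -> None:
        keys.add((ctx.res_keys[i], ctx.res_keys[j], itype))

    # hydrogen bonds (donors on either side)
    for i, j in _cross_pairs(ctx, ctx.donors, ctx.acceptors, coords, criteria.hbond_da_max):
        for donor, acceptor in ((i, j), (j, i)):
            if donor not in ctx.donor_hydrogens:
                continue
            r = np.linalg.norm(coords[donor] - coords[acceptor])
            if r > criteria.hbond_da_max or acceptor == donor:
                continue
            if hbond_mode == "heavy":
                add(i, j, "hbond_heavy")
                continue
            for h in ctx.donor_hydrogens[donor]:
                v1 = coords[donor] - coords[h]
                v2 = coords[acceptor] - coords[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= criteria.hbond_dha_min:
                    add(i, j, "hbond")
                    break

    for i, j in _cross_pairs(ctx, ctx.apolar, ctx.apolar, coords, criteria.hydrophobic_cc_max):
        add(i, j, "hydrophobic")

    if len(ctx.vdw_heavy):
        d = cdist(coords[ctx.vdw_heavy], coords[ctx.vdw_heavy])
        limit = ctx.vdw_radii[:, None] + ctx.vdw_radii[None, :] + criteria.vdw_tolerance
        for ai, bj in zip(*np.nonzero(d <= limit)):
            i, j = ctx.vdw_heavy[ai], ctx.vdw_heavy[bj]
            if ctx.side[i] == 0 and ctx.side[j] == 1:
                add(i, j, "vdw")

    for i, j in _cross_pairs(ctx, ctx.cationic, ctx.anionic, coords, criteria.ionic_max):
        add(i, j, "ionic")

    for (atoms_a, side_a, rk_a) in ctx.rings:
        for (atoms_b, side_b, rk_b) in ctx.rings:
            if not (side_a == 0 and side_b == 1):
                continue
            ca = coords[list(atoms_a)].mean(axis=0)
            cb = coords[list(atoms_b)].mean(axis=0)
            if np.linalg.norm(ca - cb) > criteria.pistack_centroid_max:
                continue
            na = _ring_normal(coords[list(atoms_a)])
            nb = _ring_normal(coords[list(atoms_b)])
            ang = np.degrees(np.arccos(np.clip(abs(np.dot(na, nb)), 0.0, 1.0)))
            if ang <= criteria.pistack_angle_max:
                keys.add((rk_a, rk_b, "pistack"))
    return keys


def _ring_normal(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def hbond_heavy_fallback(
    frame: np.ndarray,
    ctx: InteractionContext,
    da_max: float = 3.5,
) -> set[Key]:
    """Distance-only hydrogen bonds for hydrogen-free frames.

    Any cross N/O...N/O pair within ``da_max`` is reported, typed
    ``"hbond_heavy"`` to flag heavy-atom mode in output.
    """
    coords = np.asarray(frame, dtype=float)
    keys: set[Key] = set()
    polar = ctx.acceptors  # N/O heavy atoms on both sides
    for i, j in _cross_pairs(ctx, polar, polar, coords, da_max):
        keys.add((ctx.res_keys[i], ctx.res_keys[j], "hbond_heavy"))
    return keys


def build_timeline(
    traj: TrajectoryEnsemble,
    receptor_sel: np.ndarray,
    peptide_sel: np.ndarray,
    criteria: InteractionCriteria | None = None,
    hbond_mode: str = "angle",
    types: Sequence[str] | None = None,
) -> FingerprintTimeline:
    """Interaction timeline and persistence over a whole trajectory.

    ``types`` optionally restricts the reported interaction types.  Keys
    are sorted for deterministic output; presence[k][t] is True iff key k
    was detected in frame t and persistence is its row mean.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    ctx = InteractionContext(traj.topology, receptor_sel, peptide_sel,
                             reference=traj.frames[0])
    per_frame = []
    all_keys: set[Key] = set()
    for frame in traj.frames:
        keys = detect_frame_interactions(frame, ctx, criteria, hbond_mode)
        if types is not None:
            keys = {k for k in keys if k[2] in types}
        per_frame.append(keys)
        all_keys |= keys
    keys_sorted = sorted(all_keys)
    presence = np.zeros((len(keys_sorted), traj.n_frames), dtype=bool)
    index = {k: i for i, k in enumerate(keys_sorted)}
    for t, keys in enumerate(per_frame):
        for k in keys:
            presence[index[k], t] = True
    persistence = presence.mean(axis=1) if keys_sorted else np.empty(0)
    return FingerprintTimeline(keys=keys_sorted, presence=presence, persistence=persistence)
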