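"""Single-trajectory MM-GBSA binding free energy with per-residue decomposition.

The binding free energy of a peptide-receptor complex is estimated per
frame as

    dG = E_vdw(cross) + E_elec(cross)
       + [G_GB(complex) - G_GB(receptor) - G_GB(ligand)]
       + gamma * [SASA(complex) - SASA(receptor) - SASA(ligand)] + beta

with receptor and ligand conformations sliced from the complex frames
(single-trajectory scheme), so internal bonded/LJ/Coulomb terms cancel
exactly and only cross-molecule MM terms and the solvation differences
are computed.

The polar term uses the Onufriev-Bashford-Case generalized Born model
(GB-OBC II, the "igb = 5" parameterization): effective radii from
pairwise Hawkins-Cramer-Truhlar descreening with a tanh correction
(alpha, beta, gamma = 1.0, 0.8, 4.85; intrinsic-radius offset 0.09 A),
and salt screening via a Debye-Hueckel factor with the conventional 0.73
scaling of kappa.  The nonpolar term is gamma_SASA * SASA with
Shrake-Rupley numeric surface areas (probe 1.4 A).

Atom parameters (partial charges, LJ, GB radii/screens, SASA radii) are
consumed from a structured per-atom table; no force-field typing is done
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import constants as sc
from scipy.spatial.distance import cdist, squareform

from .structure_io import AssemblyModel

__all__ = [
    "AtomParams",
    "ParamSet",
    "GBSASettings",
    "EnergyBreakdown",
    "BindingEstimate",
    "born_radii_obc2",
    "gb_polar_energy",
    "sasa",
    "intermolecular_mm",
    "mmgbsa_frame",
    "mmgbsa_trajectory",
    "per_residue_decomposition",
    "aggregate_frames",
    "debye_kappa",
    "generic_params",
    "read_params",
    "write_params",
    "KE_KCAL",
]

#: Coulomb constant in kcal*A/(mol*e^2) (Amber convention)
KE_KCAL = 332.0636


@dataclass(frozen=True)
class AtomParams:
    """Per-atom nonbonded and solvation parameters."""

    partial_charge: float  # e
    lj_rmin_half: float  # A
    lj_epsilon: float  # kcal/mol
    gb_radius: float  # intrinsic Born radius, A
    gb_screen: float  # HCT screening scale, dimensionless
    sasa_radius: float  # A

    def __post_init__(self) -> None:
        if self.gb_radius <= 0 or self.sasa_radius <= 0 or self.lj_rmin_half <= 0:
            raise ValueError("radii must be positive")
        if self.lj_epsilon < 0:
            raise ValueError("LJ epsilon must be >= 0")


class ParamSet:
    """Column arrays of :class:`AtomParams` for a fixed atom order."""

    def __init__(self, params: Sequence[AtomParams]):
        self.charges = np.array([p.partial_charge for p in params])
        self.rmin_half = np.array([p.lj_rmin_half for p in params])
        self.epsilon = np.array([p.lj_epsilon for p in params])
        self.gb_radius = np.array([p.gb_radius for p in params])
        self.gb_screen = np.array([p.gb_screen for p in params])
        self.sasa_radius = np.array([p.sasa_radius for p in params])

    def __len__(self) -> int:
        return len(self.charges)

    def subset(self, idx: np.ndarray) -> "ParamSet":
        out = ParamSet.__new__(ParamSet)
        for name in ("charges", "rmin_half", "epsilon", "gb_radius",
                     "gb_screen", "sasa_radius"):
            setattr(out, name, getattr(self, name)[idx])
        return out


@dataclass(frozen=True)
class GBSASettings:
    """Model constants (Amber igb=5 workflow defaults)."""

    eps_in: float = 1.0
    eps_out: float = 78.5
    salt_molar: float = 0.15
    offset: float = 0.09  # intrinsic-radius offset, A
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    kappa_scale: float = 0.73
    gamma_sasa: float = 0.0072  # kcal/(mol*A^2)
    beta_offset: float = 0.0  # kcal/mol
    probe: float = 1.4  # A
    sasa_points: int = 960
    temperature: float = 298.15  # K


@dataclass
class EnergyBreakdown:
    """MM-GBSA components for one frame (kcal/mol)."""

    e_vdw: float
    e_elec: float
    g_gb: float
    g_np: float
    total: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        s = self.e_vdw + self.e_elec + self.g_gb + self.g_np
        if abs(self.total - s) > 1e-9:
            raise ValueError("total must equal the sum of components")


@dataclass
class BindingEstimate:
    """Mean binding free energy over selected frames with naive SEM."""

    dg_mean: float
    dg_sem: float
    n_frames: int
    component_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dg_sem < 0:
            raise ValueError("SEM must be >= 0")


# ---------------------------------------------------------------------------
# generalized Born (OBC-II)


def _hct_integral(r: float, s: float, rho: float) -> float:
    """Pairwise descreening integral: (1/4pi) * int |x|^-4 dV over the
    scaled neighbor sphere (radius s at distance r), excluding |x| < rho."""
    if rho >= r + s:
        return 0.0
    L = max(abs(r - s), rho)
    U = r + s
    term = 0.5 * (
        1.0 / L
        - 1.0 / U
        + 0.25 * (r - s * s / r) * (1.0 / U**2 - 1.0 / L**2)
        + 0.5 / r * math.log(L / U)
    )
    if rho < s - r:  # atom center engulfed by the neighbor's scaled sphere
        term += 1.0 / rho - 1.0 / L
    return term


def born_radii_obc2(
    coords: np.ndarray, params: ParamSet, settings: GBSASettings | None = None
) -> np.ndarray:
    """Effective Born radii via HCT descreening with the OBC-II tanh correction.

    With reduced radius rho_i = gb_radius_i - offset and descreening sum
    I_i over neighbors (scaled radii s_j = screen_j * rho_j):

        psi_i = rho_i * I_i
        1/R_i = 1/rho_i - tanh(alpha*psi - beta*psi^2 + gamma*psi^3) / gb_radius_i
    """
    if settings is None:
        settings = GBSASettings()
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    rho = params.gb_radius - settings.offset
    if np.any(rho <= 0):
        raise ValueError("all intrinsic GB radii must exceed the offset")
    scaled = params.gb_screen * rho
    descreen = np.zeros(n)
    if n > 1:
        d = cdist(coords, coords)
        for i in range(n):
            acc = 0.0
            for j in range(n):
                if j != i:
                    acc += _hct_integral(d[i, j], scaled[j], rho[i])
            descreen[i] = acc
    psi = rho * descreen
    a, b, g = settings.obc_alpha, settings.obc_beta, settings.obc_gamma
    inv_r = 1.0 / rho - np.tanh(a * psi - b * psi**2 + g * psi**3) / params.gb_radius
    return 1.0 / inv_r


def debye_kappa(
    salt_molar: float, temperature: float = 298.15, eps_out: float = 78.5
) -> float:
    """Debye screening parameter kappa in 1/Angstrom for a 1:1 salt."""
    if salt_molar < 0:
        raise ValueError("salt concentration must be >= 0")
    if salt_molar == 0:
        return 0.0
    ionic = salt_molar * 1000 * sc.N_A  # ions of each sign per m^3 -> number density
    kappa_sq = (
        2 * ionic * sc.e**2 / (sc.epsilon_0 * eps_out * sc.k * temperature)
    )  # 1/m^2
    return math.sqrt(kappa_sq) * 1e-10  # 1/A


def gb_polar_energy(
    coords: np.ndarray,
    radii: np.ndarray,
    charges: np.ndarray,
    settings: GBSASettings | None = None,
    return_pairs: bool = False,
):
    """GB polar solvation energy (kcal/mol), optionally with per-pair terms.

    dG = -ke/2 * sum_{i,j} q_i q_j (1/eps_in - exp(-kappa'*f)/eps_out) / f,
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))), summed over all
    pairs including i=j (self terms), with kappa' = kappa_scale * kappa.
    ``return_pairs`` yields the full symmetric (n, n) matrix of summands
    (self terms on the diagonal), used for per-residue decomposition.
    """
    if settings is None:
        settings = GBSASettings()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("effective radii must be positive")
    kappa = settings.kappa_scale * debye_kappa(
        settings.salt_molar, settings.temperature, settings.eps_out
    )
    r2 = cdist(coords, coords) ** 2
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    dielectric = 1.0 / settings.eps_in - np.exp(-kappa * f) / settings.eps_out
    pair = -0.5 * KE_KCAL * (charges[:, None] * charges[None, :]) * dielectric / f
    energy = float(pair.sum())
    if return_pairs:
        return energy, pair
    return energy


# ---------------------------------------------------------------------------
# nonpolar term (Shrake-Rupley SASA)


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal-axes frame of a coordinate set.

    Axis signs are fixed by the coordinate skewness along each axis (a
    rotation-covariant rule), so the frame co-rotates exactly with the
    molecule.  Perfectly symmetric configurations (zero skewness) keep
    the eigensolver's sign.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(2):
        skew = float(np.sum((centered @ vecs[:, k]) ** 3))
        if skew < 0:
            vecs[:, k] = -vecs[:, k]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return vecs


def sasa(
    coords: np.ndarray,
    sasa_radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    For each atom, test points on the expanded sphere (radius + probe);
    the accessible fraction times the expanded-sphere area is its SASA.
    The quadrature lattice is oriented along the molecule's principal
    axes (or an explicitly supplied ``orientation`` frame), which makes
    the numeric areas invariant under rigid motion; passing one shared
    frame for complex and separated states makes their quadrature errors
    cancel exactly in the binding difference.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    coords = np.asarray(coords, dtype=float)
    if orientation is None and len(coords) > 1:
        orientation = _principal_frame(coords)
    if orientation is not None:
        coords = (coords - coords.mean(axis=0)) @ orientation
    radii = np.asarray(sasa_radii, dtype=float) + probe
    n = len(coords)
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            dij = np.linalg.norm(coords[i] - coords[j])
            if dij >= radii[i] + radii[j]:
                continue
            accessible &= (
                np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
                >= radii[j] ** 2
            )
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return areas


# ---------------------------------------------------------------------------
# molecular-mechanics cross terms


def intermolecular_mm(
    coords: np.ndarray,
    params: ParamSet,
    receptor_sel: np.ndarray,
    ligand_sel: np.ndarray,
    settings: GBSASettings | None = None,
    return_pairs: bool = False,
):
    """Cross receptor-ligand vdW and Coulomb energies (kcal/mol), no cutoff.

    e_elec = ke/eps_in * sum q_i q_j / r_ij over cross pairs;
    e_vdw uses the 12-6 potential eps_ij [(rmin_ij/r)^12 - 2 (rmin_ij/r)^6]
    with geometric-mean epsilon and summed rmin halves.
    """
    if settings is None:
        settings = GBSASettings()
    receptor_sel = np.asarray(receptor_sel, dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    if np.intersect1d(receptor_sel, ligand_sel).size:
        raise ValueError("receptor and ligand selections must be disjoint")
    coords = np.asarray(coords, dtype=float)
    r = cdist(coords[receptor_sel], coords[ligand_sel])
    if np.any(r == 0):
        raise ValueError("zero-distance cross pair")
    qq = params.charges[receptor_sel][:, None] * params.charges[ligand_sel][None, :]
    elec = KE_KCAL / settings.eps_in * qq / r
    eps_ij = np.sqrt(
        params.epsilon[receptor_sel][:, None] * params.epsilon[ligand_sel][None, :]
    )
    rmin_ij = params.rmin_half[receptor_sel][:, None] + params.rmin_half[ligand_sel][None, :]
    ratio6 = (rmin_ij / r) ** 6
    vdw = eps_ij * (ratio6**2 - 2.0 * ratio6)
    if return_pairs:
        return float(vdw.sum()), float(elec.sum()), vdw, elec
    return float(vdw.sum()), float(elec.sum())


# ---------------------------------------------------------------------------
# per-frame MM-GBSA


@dataclass
class FrameDetail:
    """Per-pair and per-atom terms retained for decomposition."""

    breakdown: EnergyBreakdown
    mm_vdw_pairs: np.ndarray  # (n_rec, n_lig)
    mm_elec_pairs: np.ndarray  # (n_rec, n_lig)
    gb_pair_delta: np.ndarray  # (n, n) complex-minus-separated GB summands
    sasa_delta: np.ndarray  # (n,) per-atom SASA change * gamma


def mmgbsa_frame(
    frame: np.ndarray,
    params: ParamSet,
    receptor_sel: np.ndarray,
    ligand_sel: np.ndarray,
    settings: GBSASettings | None = None,
    frame_index: int = 0,
    keep_detail: bool = False,
):
    """Single-trajectory MM-GBSA binding energy for one complex frame.

    ``receptor_sel`` and ``ligand_sel`` must partition the solute atoms.
    Effective Born radii are recomputed for complex, receptor and ligand
    states.  Returns an :class:`EnergyBreakdown`, or a
    :class:`FrameDetail` when ``keep_detail`` (needed for per-residue
    decomposition).
    """
    if settings is None:
        settings = GBSASettings()
    frame = np.asarray(frame, dtype=float)
    receptor_sel = np.asarray(receptor_sel, dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    n = len(frame)
    combined = np.concatenate([receptor_sel, ligand_sel])
    if len(np.unique(combined)) != n or len(combined) != n:
        raise ValueError("selections must partition the solute atoms")
    if len(params) != n:
        raise ValueError(f"parameter table covers {len(params)} atoms, frame has {n}")

    e_vdw, e_elec, vdw_pairs, elec_pairs = intermolecular_mm(
        frame, params, receptor_sel, ligand_sel, settings, return_pairs=True
    )

    # GB: complex and separated states (radii recomputed per state)
    radii_c = born_radii_obc2(frame, params, settings)
    g_c, pairs_c = gb_polar_energy(frame, radii_c, params.charges, settings, True)
    gb_delta = pairs_c.copy()
    g_sep = 0.0
    for sel in (receptor_sel, ligand_sel):
        sub = params.subset(sel)
        radii_s = born_radii_obc2(frame[sel], sub, settings)
        g_s, pairs_s = gb_polar_energy(frame[sel], radii_s, sub.charges, settings, True)
        g_sep += g_s
        gb_delta[np.ix_(sel, sel)] -= pairs_s
    g_gb = g_c - g_sep

    # SASA: complex and separated states in one shared quadrature frame
    orient = _principal_frame(frame)
    sasa_c = sasa(frame, params.sasa_radius, settings.probe, settings.sasa_points, orient)
    sasa_delta = sasa_c.copy()
    for sel in (receptor_sel, ligand_sel):
        sasa_delta[sel] -= sasa(
            frame[sel], params.sasa_radius[sel], settings.probe,
            settings.sasa_points, orient,
        )
    g_np = settings.gamma_sasa * float(sasa_delta.sum()) + settings.beta_offset

    total = e_vdw + e_elec + g_gb + g_np
    breakdown = EnergyBreakdown(e_vdw, e_elec, g_gb, g_np, total, frame_index)
    if not keep_detail:
        return breakdown
    return FrameDetail(
        breakdown=breakdown,
        mm_vdw_pairs=vdw_pairs,
        mm_elec_pairs=elec_pairs,
        gb_pair_delta=gb_delta,
        sasa_delta=settings.gamma_sasa * sasa_delta,
    )


def mmgbsa_trajectory(
    frames: np.ndarray,
    params: ParamSet,
    receptor_sel: np.ndarray,
    ligand_sel: np.ndarray,
    settings: GBSASettings | None = None,
    keep_detail: bool = False,
) -> list:
    """Apply :func:`mmgbsa_frame` to every frame of a trajectory."""
    return [
        mmgbsa_frame(f, params, receptor_sel, ligand_sel, settings, i, keep_detail)
        for i, f in enumerate(np.asarray(frames, dtype=float))
    ]


# ---------------------------------------------------------------------------
# per-residue decomposition


def per_residue_decomposition(
    details: "FrameDetail | Sequence[FrameDetail]",
    topology: AssemblyModel,
    receptor_sel: np.ndarray,
    ligand_sel: np.ndarray,
):
    """Per-residue MM-GBSA decomposition table (pandas DataFrame).

    Pairwise terms (cross vdW/elec and GB pair-term changes) are split
    half/half between the two participating residues; self terms (GB
    diagonal, SASA change) belong to their own residue.  This makes the
    residue totals sum exactly to the frame binding energy.  Averages and
    the naive SEM are taken over the supplied frames.

    Columns mirror the usual decomposition-table schema:
    residue, vdw, elec, polar_solv, nonpolar_solv, total, sem.
    """
    import pandas as pd

    if not isinstance(details, (list, tuple)):
        details = [details]
    receptor_sel = np.asarray(receptor_sel, dtype=int)
    ligand_sel = np.asarray(ligand_sel, dtype=int)
    atom_res = topology.atom_residues()
    # residue index per atom, residue labels in topology order
    labels: list[str] = []
    res_index = np.empty(topology.n_atoms, dtype=int)
    seen: dict[tuple, int] = {}
    for i, res in enumerate(atom_res):
        if res.key not in seen:
            seen[res.key] = len(labels)
            labels.append(res.label)
        res_index[i] = seen[res.key]
    n_res = len(labels)

    per_frame = np.zeros((len(details), n_res, 4))  # vdw, elec, gb, np
    for t, det in enumerate(details):
        acc = per_frame[t]
        rr = res_index[receptor_sel]
        rl = res_index[ligand_sel]
        for comp, pairs in ((0, det.mm_vdw_pairs), (1, det.mm_elec_pairs)):
            half = 0.5 * pairs
            np.add.at(acc[:, comp], rr, half.sum(axis=1))
            np.add.at(acc[:, comp], rl, half.sum(axis=0))
        gb = det.gb_pair_delta
        half = 0.5 * (gb + gb.T)  # symmetric; row sums give the half-share + self
        np.add.at(acc[:, 2], res_index, half.sum(axis=1))
        np.add.at(acc[:, 3], res_index, det.sasa_delta)

    mean = per_frame.mean(axis=0)
    totals = per_frame.sum(axis=2)  # (frames, residues)
    sem = (
        totals.std(axis=0, ddof=1) / math.sqrt(len(details))
        if len(details) > 1
        else np.zeros(n_res)
    )
    return pd.DataFrame(
        {
            "residue": labels,
            "vdw": mean[:, 0],
            "elec": mean[:, 1],
            "polar_solv": mean[:, 2],
            "nonpolar_solv": mean[:, 3],
            "total": mean.sum(axis=1),
            "sem": sem,
        }
    )


def aggregate_frames(
    dg_series: Sequence[float] | np.ndarray,
    frame_selection: str | slice | None = None,
    components: Sequence[EnergyBreakdown] | None = None,
) -> BindingEstimate:
    """Mean and naive SEM of per-frame dG over a frame selection.

    ``frame_selection`` may be ``None`` (all frames), a slice, or a string
    ``"last:f"`` with f in (0, 1] selecting the trailing fraction of
    frames (e.g. ``"last:0.5"`` - the convention used when scoring is
    restricted to the equilibrated tail of a trajectory).
    """
    dg = np.asarray(dg_series, dtype=float)
    idx = np.arange(len(dg))
    if isinstance(frame_selection, str):
        tag, _, value = frame_selection.partition(":")
        if tag != "last" or not value:
            raise ValueError(f"unsupported frame selection {frame_selection!r}")
        f = float(value)
        if not 0 < f <= 1:
            raise ValueError("last-fraction must be in (0, 1]")
        idx = idx[len(dg) - int(round(f * len(dg))):]
    elif isinstance(frame_selection, slice):
        idx = idx[frame_selection]
    if len(idx) == 0:
        raise ValueError("empty frame selection")
    if len(idx) < 2:
        raise ValueError("need >= 2 frames for a SEM")
    sel = dg[idx]
    comp_means: dict[str, float] = {}
    if components is not None:
        comp = [components[i] for i in idx]
        comp_means = {
            "e_vdw": float(np.mean([c.e_vdw for c in comp])),
            "e_elec": float(np.mean([c.e_elec for c in comp])),
            "g_gb": float(np.mean([c.g_gb for c in comp])),
            "g_np": float(np.mean([c.g_np for c in comp])),
        }
    return BindingEstimate(
        dg_mean=float(sel.mean()),
        dg_sem=float(sel.std(ddof=1) / math.sqrt(len(sel))),
        n_frames=len(sel),
        component_means=comp_means,
    )


# ---------------------------------------------------------------------------
# parameter tables


#: generic element defaults: (rmin/2, epsilon, gb_radius, gb_screen, sasa_radius)
_ELEMENT_DEFAULTS = {
    "H": (0.60, 0.0157, 1.20, 0.85, 1.20),
    "C": (1.908, 0.1094, 1.70, 0.72, 1.70),
    "N": (1.824, 0.17, 1.55, 0.79, 1.55),
    "O": (1.6612, 0.21, 1.50, 0.85, 1.52),
    "S": (2.0, 0.25, 1.80, 0.96, 1.80),
    "P": (2.1, 0.20, 1.85, 0.86, 1.80),
}

#: simple sidechain charge placements for the generic parameter set
_GENERIC_CHARGED = {
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("LYS", "NZ"): 1.0,
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
}


def generic_params(topology: AssemblyModel, charges: np.ndarray | None = None) -> ParamSet:
    """Element-based generic parameters for test/demo systems.

    LJ and radii come from element defaults; partial charges are zero
    except for charged side-chain groups (or taken from ``charges`` when
    given).  This is a synthetic parameter set for fixtures, not a force
    field.
    """
    atoms = topology.atoms()
    residues = topology.atom_residues()
    params = []
    for i, (atom, res) in enumerate(zip(atoms, residues)):
        elem = atom.element.upper()
        rmin, eps, gbr, screen, sasar = _ELEMENT_DEFAULTS.get(
            elem, _ELEMENT_DEFAULTS["C"]
        )
        if charges is not None:
            q = float(charges[i])
        else:
            q = _GENERIC_CHARGED.get((res.resname.upper(), atom.name), 0.0)
        params.append(AtomParams(q, rmin, eps, gbr, screen, sasar))
    return ParamSet(params)


_PARAM_COLUMNS = (
    "chain resnum resname atom charge rmin_half epsilon gb_radius gb_screen sasa_radius"
).split()


def write_params(
    topology: AssemblyModel, params: ParamSet, path: str | Path
) -> None:
    """Write an extended PQR-like whitespace parameter table."""
    atoms = topology.atoms()
    residues = topology.atom_residues()
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(_PARAM_COLUMNS) + "\n")
        for i, (atom, res) in enumerate(zip(atoms, residues)):
            fh.write(
                f"{res.chain_id}\t{res.resnum}\t{res.resname}\t{atom.name}\t"
                f"{params.charges[i]:.6f}\t{params.rmin_half[i]:.4f}\t"
                f"{params.epsilon[i]:.4f}\t{params.gb_radius[i]:.4f}\t"
                f"{params.gb_screen[i]:.4f}\t{params.sasa_radius[i]:.4f}\n"
            )


def read_params(path: str | Path, topology: AssemblyModel | None = None) -> ParamSet:
    """Read a parameter table written by :func:`write_params`.

    When a topology is given, row order and atom identities are checked
    against it; a missing or extra atom raises an error naming the atom.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(_PARAM_COLUMNS):
                raise ValueError(f"{path}: bad parameter row: {line!r}")
            rows.append(parts)
    params = [
        AtomParams(*[float(x) for x in parts[4:]]) for parts in rows
    ]
    if topology is not None:
        atoms = topology.atoms()
        residues = topology.atom_residues()
        if len(atoms) != len(rows):
            raise ValueError(
                f"parameter table has {len(rows)} atoms, topology {len(atoms)}"
            )
        for parts, atom, res in zip(rows, atoms, residues):
            if parts[3] != atom.name or parts[2] != res.resname:
                raise ValueError(
                    f"parameter mismatch for atom {res.label}:{atom.name} "
                    f"(table row {parts[2]} {parts[3]})"
                )
    return ParamSet(params)
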