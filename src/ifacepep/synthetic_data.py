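"""Seeded generators of synthetic inputs for every pipeline stage.

Real inputs to this kind of study are a cryo-EM lattice model, microsecond
MD trajectories and plate/cytometer readouts; none can be regenerated at
desk scale.  These generators instead produce small inputs that carry the
*statistical and geometric structure* each analysis stage assumes, with
machine-readable ground truth attached, so every stage is testable
end-to-end with no downloads:

* two-chain assemblies with planted contiguous interface segments at
  controlled distances (interface extraction);
* trajectories fluctuating harmonically around a reference along
  prescribed orthonormal covariance modes (RMSF / essential dynamics);
* scripted contact on/off patterns (fingerprint persistence);
* 4PL dose-response tables with known parameters and noise (IC50 fits);
* two-channel cytometry event clouds from labelled mixtures (gating).

All generators take a mandatory seed and use a single private RNG stream;
the same seed and parameters reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .assay_analysis import CytometryEvents, four_pl
from .structure_io import Atom, AssemblyModel, Residue
from .trajectory_analysis import TrajectoryEnsemble

__all__ = [
    "make_toy_assembly",
    "make_contact_pair",
    "make_synthetic_trajectory",
    "make_contact_script",
    "make_dose_response",
    "make_cytometry",
    "AMINO_ACIDS",
]

AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

_RESIDUE_STEP = 7.5  # A between residue centers along the chain axis
_CONTACT_SPACING = 5.0  # A between planted partner residues (must stay < 6)
_FAR_SPACING = 20.0  # A for non-interface residues (must stay > 8)
_JITTER = 0.4  # A max displacement of side atoms around the residue center


def _dummy_residue(
    chain_id: str, resnum: int, resname: str, center: np.ndarray, rng: np.random.Generator
) -> Residue:
    """A 4-heavy-atom dummy residue: CA at the center plus 3 side atoms."""
    atoms = [Atom(serial=1, name="CA", element="C", coords=center.copy())]
    for k in range(3):
        offset = rng.uniform(-1.0, 1.0, size=3)
        offset *= _JITTER / max(np.linalg.norm(offset), 1e-9) * rng.uniform(0.3, 1.0)
        atoms.append(
            Atom(serial=k + 2, name=f"C{k + 1}", element="C", coords=center + offset)
        )
    return Residue(
        chain_id=chain_id, resnum=resnum, icode="", resname=resname, atoms=atoms
    )


def make_toy_assembly(
    n_residues: int = 30,
    planted_segments: Sequence[tuple[int, int]] = ((10, 17),),
    spacing: float = _CONTACT_SPACING,
    seed: int = 0,
    n_chains: int = 2,
) -> tuple[AssemblyModel, list[tuple[str, int, int]]]:
    """Two parallel chains with planted interfacial segments.

    Chains A and B run along x with residue centers ``_RESIDUE_STEP``
    apart.  At the planted residue ranges the two chains approach to
    ``spacing`` (< 6 A, so every planted pair is an interface contact);
    everywhere else they are ``_FAR_SPACING`` apart (> 8 A, never a
    contact).  Additional chains, if requested, are placed far away and
    contact nothing.  Returns the assembly and the ground-truth segment
    list [(chain, start, end), ...] covering both interface chains.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing + 2 * _JITTER >= 6.0:
        raise ValueError(f"spacing {spacing} cannot guarantee contacts under 6 A")
    lateral = (_RESIDUE_STEP**2 + spacing**2) ** 0.5 - 2 * _JITTER
    if lateral <= 8.0:
        raise ValueError("residue step too small: adjacent columns would leak contacts")
    segs = sorted(planted_segments)
    for (s, e) in segs:
        if not 1 <= s <= e <= n_residues:
            raise ValueError(f"planted segment {(s, e)} outside 1..{n_residues}")
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        if s2 - e1 < 2:
            raise ValueError("planted segments must be separated by >= 2 residues")
    planted = {r for (s, e) in segs for r in range(s, e + 1)}

    rng = np.random.default_rng(seed)
    assembly = AssemblyModel(model_id=1)
    chain_ids = [chr(ord("A") + i) for i in range(n_chains)]
    for ci, chain_id in enumerate(chain_ids):
        residues = []
        for r in range(1, n_residues + 1):
            x = r * _RESIDUE_STEP
            if ci == 0:
                center = np.array([x, 0.0, 0.0])
            elif ci == 1:
                y = spacing if r in planted else _FAR_SPACING
                center = np.array([x, y, 0.0])
            else:
                center = np.array([x, 0.0, 50.0 * ci])
            resname = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
            residues.append(_dummy_residue(chain_id, r, resname, center, rng))
        assembly.chains[chain_id] = residues
    truth = [(c, s, e) for c in chain_ids[:2] for (s, e) in segs]
    return assembly, sorted(truth)


def make_contact_pair(distance: float, resname: str = "GLY") -> AssemblyModel:
    """Two single-residue chains whose min heavy-atom distance is exactly
    ``distance`` — for cutoff boundary checks."""
    assembly = AssemblyModel(model_id=1)
    a = Residue("A", 1, "", resname, [Atom(1, "CA", "C", np.zeros(3))])
    b = Residue("B", 1, "", resname, [Atom(1, "CA", "C", np.array([distance, 0.0, 0.0]))])
    assembly.chains["A"] = [a]
    assembly.chains["B"] = [b]
    return assembly


def make_synthetic_trajectory(
    reference: np.ndarray,
    modes: Sequence[tuple[np.ndarray, float]],
    n_frames: int,
    seed: int,
    topology: AssemblyModel | None = None,
) -> TrajectoryEnsemble:
    """Harmonic fluctuation around a reference along orthonormal modes.

    ``modes`` is a list of (3N-direction, variance in A^2); frame t is
    reference + sum_k a_k(t) * mode_k with a_k ~ N(0, variance_k).  No
    rigid-body drift is added, so frames are already "fit".  When no
    topology is supplied a chain of one-CA pseudo-residues is created.
    """
    reference = np.asarray(reference, dtype=float)
    n_atoms = reference.shape[0]
    dirs = np.array([np.asarray(d, dtype=float).ravel() for d, _ in modes])
    variances = np.array([v for _, v in modes], dtype=float)
    if dirs.shape[1] != 3 * n_atoms:
        raise ValueError("mode directions must have length 3 * n_atoms")
    gram = dirs @ dirs.T
    if not np.allclose(gram, np.eye(len(dirs)), atol=1e-8):
        raise ValueError("mode directions must be orthonormal")
    if np.any(variances < 0):
        raise ValueError("mode variances must be >= 0")
    rng = np.random.default_rng(seed)
    amplitudes = rng.normal(0.0, np.sqrt(variances), size=(n_frames, len(dirs)))
    frames = reference.ravel()[None, :] + amplitudes @ dirs
    frames = frames.reshape(n_frames, n_atoms, 3)
    if topology is None:
        topology = _pseudo_topology(reference)
    return TrajectoryEnsemble(topology=topology, frames=frames)


def _pseudo_topology(reference: np.ndarray) -> AssemblyModel:
    topology = AssemblyModel(model_id=1)
    topology.chains["A"] = [
        Residue("A", i + 1, "", "GLY", [Atom(i + 1, "CA", "C", xyz.copy())])
        for i, xyz in enumerate(np.asarray(reference, dtype=float))
    ]
    return topology


def make_contact_script(
    fractions: Sequence[float],
    n_frames: int,
    seed: int,
    contact_distance: float = 3.0,
    apart_distance: float = 12.0,
) -> tuple[TrajectoryEnsemble, dict]:
    """Scripted on/off contacts with exactly known persistence.

    One receptor/peptide residue pair per requested fraction, laid out 30 A
    apart so pairs cannot cross-talk.  Pair k is in contact
    (``contact_distance``, hydrophobic range) in exactly
    ``round(fraction_k * n_frames)`` randomly chosen frames and far apart
    (``apart_distance``) otherwise.  Returns the trajectory and the
    planted persistence per fingerprint key
    ``((chain R res), (chain P res), "hydrophobic")``.
    """
    fractions = list(fractions)
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    topology = AssemblyModel(model_id=1)
    rec, pep = [], []
    for k in range(len(fractions)):
        x = 30.0 * k
        rec.append(Residue("R", k + 1, "", "DUM",
                           [Atom(1, "CA", "C", np.array([x, 0.0, 0.0]))]))
        pep.append(Residue("P", k + 1, "", "DUM",
                           [Atom(1, "CA", "C", np.array([x, apart_distance, 0.0]))]))
    topology.chains["R"] = rec
    topology.chains["P"] = pep

    frames = np.repeat(topology.coords()[None, :, :], n_frames, axis=0)
    expected = {}
    n_rec = len(rec)
    for k, fraction in enumerate(fractions):
        n_on = int(round(fraction * n_frames))
        on_frames = rng.choice(n_frames, size=n_on, replace=False)
        pep_atom = n_rec + k  # peptide atoms follow receptor atoms in flat order
        frames[on_frames, pep_atom, 1] = contact_distance
        key = (("R", k + 1, ""), ("P", k + 1, ""), "hydrophobic")
        expected[key] = n_on / n_frames
    traj = TrajectoryEnsemble(topology=topology, frames=frames)
    return traj, expected


def make_dose_response(
    params: tuple[float, float, float, float] = (0.0, 100.0, 10.0, 1.5),
    doses: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_doses: int = 6,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Seeded 4PL dose-response table with known ground truth.

    Default doses are log-spaced two decades around the true IC50 (the
    usual six-point curve design).  Gaussian response noise with the given
    SD is added.  Returns (doses, responses, truth dict).
    """
    bottom, top, ic50, hill = params
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if doses is None:
        doses = np.logspace(np.log10(ic50) - 1.25, np.log10(ic50) + 1.25, n_doses)
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    responses = four_pl(doses, bottom, top, ic50, hill)
    if noise_sd > 0:
        responses = responses + rng.normal(0.0, noise_sd, size=len(doses))
    truth = {"bottom": bottom, "top": top, "ic50": ic50, "hill": hill}
    return doses, responses, truth


def _apportion(fractions: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to n, largest-remainder apportionment."""
    raw = [f * n for f in fractions]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_cytometry(
    fractions: tuple[float, float, float, float] = (0.6, 0.2, 0.15, 0.05),
    n_events: int = 10_000,
    seed: int = 0,
    av_thr: float = 100.0,
    pi_thr: float = 100.0,
    separation: float = 40.0,
    cluster_sd: float = 8.0,
) -> tuple[CytometryEvents, dict[str, Fraction]]:
    """Two-channel event clouds from a labelled four-population mixture.

    ``fractions`` order: (normal, early apoptosis, late apoptosis,
    necrosis).  Cluster centers sit ``separation`` away from the gate
    thresholds on the appropriate side; with the default 5-sigma
    separation the planted quadrant fractions are recovered exactly.
    Counts are apportioned by largest remainder so they sum to n_events.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be >= 0")
    rng = np.random.default_rng(seed)
    # quadrant sign pattern (av_positive, pi_positive)
    signs = {"normal": (-1, -1), "early_apoptosis": (+1, -1),
             "late_apoptosis": (+1, +1), "necrosis": (-1, +1)}
    names = list(signs)
    counts = _apportion(fractions, n_events)
    av, pi = [], []
    for name, count in zip(names, counts):
        sa, sp = signs[name]
        av.append(rng.normal(av_thr + sa * separation, cluster_sd, size=count))
        pi.append(rng.normal(pi_thr + sp * separation, cluster_sd, size=count))
    events = CytometryEvents(
        av_intensity=np.concatenate(av),
        pi_intensity=np.concatenate(pi),
        av_thr=av_thr,
        pi_thr=pi_thr,
    )
    truth = {name: Fraction(c, n_events) for name, c in zip(names, counts)}
    return events, truth
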