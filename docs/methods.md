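# Methods

This note documents the models implemented in `ifacepep`, their
assumptions, the defaults and why they were chosen, the numerical choices
that matter, and what the synthetic-data generators do and do not emulate.

## Interface mapping and candidate extraction

A residue pair across two chains is an interface contact when the minimum
distance over all heavy-atom pairs is at most the cutoff (default 6 Å).
Heavy atoms only: the motivating inputs are cryo-EM-derived models whose
hydrogens are absent or unreliable, and a hydrogen-inclusive criterion
would make the contact set depend on a protonation step outside this
package's scope. Alternative operationalizations (Cβ–Cβ distance,
buried-surface area) exist; minimum heavy-atom distance is the most common
reading of a "within X Å of the interface" rule and is the one implemented.

Contiguous segments are maximal runs of interface residues in author
numbering where consecutive members differ by at most `max_gap + 1`
(default `max_gap = 0`, i.e. strictly consecutive). A gap is only
bridgeable when every intermediate residue exists in the model — a chain
break (missing residues) always terminates a run, because a peptide
synthesized from the sequence could not span coordinates the model does
not have. Runs shorter than `min_len` (default 6, the shortest candidate
length worth synthesizing in this context) are dropped. Both parameters
are exposed on the CLI; no single setting is claimed to reproduce any
particular published candidate set exactly, since the original extraction
parameters are not recorded.

Interface labels ("lateral", "longitudinal") are user-supplied annotations
of chain pairs, not inferred from geometry: which lattice contact a chain
pair represents is knowledge about the assembly, not derivable from a
single dimer's coordinates.

Terminal variants: each candidate exists with free termini (protonated
N-terminus +1, deprotonated C-terminus −1 at pH 7) and with
acetyl/N-methylamide caps (both neutral). Formal charges use fixed pKa
rules at pH 7 — Asp/Glu −1, Arg/Lys +1, His neutral — with no titration;
this is the standard bookkeeping used to choose neutralizing counterions
(`n_Na = max(0, −q)`, `n_Cl = max(0, q)`).

## Single-trajectory MM-GBSA

Per complex frame,

ΔG = [E_vdw + E_elec]_cross + [G_GB(C) − G_GB(R) − G_GB(L)] + γ·[SASA(C) − SASA(R) − SASA(L)] + β

where receptor (R) and ligand (L) conformations are sliced from the
complex (C) frame. In this single-trajectory scheme all internal bonded,
LJ and Coulomb terms cancel exactly in the difference, so only the
cross-molecule MM terms and the solvation differences are computed. The
scheme ignores conformational relaxation of the separated species and all
entropy terms; it is a ranking tool, not an absolute affinity predictor.

**Electrostatics.** Cross Coulomb with ε_in = 1 and k_e = 332.0636
kcal·Å/(mol·e²); 12-6 Lennard-Jones with geometric-mean ε and summed
r_min/2. No distance cutoffs anywhere: systems are desk-scale and O(N²) is
accepted.

**Generalized Born (OBC-II).** Effective radii from pairwise
Hawkins–Cramer–Truhlar descreening: for atom i with reduced radius
ρ̃ = ρ − offset (offset 0.09 Å) and neighbors with scaled radii
s_j = S_j·ρ̃_j, the descreening sum I_i uses the closed-form integral of
r⁻⁴ over each neighbor sphere (the engulfed-atom correction included),
verified in the tests against 2-D numerical quadrature. Then
Ψ = ρ̃·I and 1/R = 1/ρ̃ − tanh(αΨ − βΨ² + γΨ³)/ρ with α, β, γ =
1.0, 0.8, 4.85. The polar energy sums
−k_e/2 · q_iq_j (1/ε_in − e^{−κ′f}/ε_out)/f over all pairs including
self terms, with f_GB = √(r² + R_iR_j·e^{−r²/4R_iR_j}), ε_out = 78.5, and
κ′ = 0.73·κ where κ is the Debye parameter computed from physical
constants at 298.15 K (κ ≈ 0.127 Å⁻¹ at 0.15 M 1:1 salt; default salt
0.15 M). All constants live in `GBSASettings` and can be overridden.

A note on salt: screening makes the GB reaction-field term itself *larger*
in magnitude (e^{−κf} shrinks, so the dielectric factor grows), while the
physically screened quantity is the combined charge–charge interaction,
vacuum Coulomb plus GB cross term, which decays toward
−k_e q_iq_j e^{−κr}/(ε_out r) at long range. The test suite asserts
monotone weakening of that combined pair interaction, and the asymptotic
screened-Coulomb limit, rather than a monotonicity the GB term alone does
not have.

**Nonpolar term.** γ·SASA + β with γ = 0.0072 kcal/(mol·Å²) and β = 0,
Shrake–Rupley areas with probe 1.4 Å and 960 quasi-uniform points per atom
(golden-spiral lattice). Two numerical choices matter here:

* the point lattice is oriented along the molecule's principal axes (axis
  signs fixed by coordinate skewness, a rotation-covariant rule; the third
  axis completes a right-handed frame), which makes the numeric areas
  exactly invariant under rigid motion of the input — a space-fixed
  lattice would leave an orientation-dependent quadrature residue of
  order 0.01 kcal/mol in the nonpolar term. Perfectly symmetric
  configurations with zero skewness retain the eigensolver's sign and may
  lose this exact invariance; this does not occur for generic structures.
* the complex and both separated states are evaluated in one shared frame
  (the complex's), so the per-atom quadrature error cancels exactly in the
  binding difference; a non-interacting ligand contributes ΔG = 0 to
  machine precision.

**Per-residue decomposition.** Every pairwise summand — cross vdW, cross
Coulomb, and the change in each GB pair term between complex and separated
states — is split half/half between its two residues; per-atom terms (GB
self energies, SASA changes) belong to their owning residue. This is the
symmetric convention used by standard decomposition tools, and it is the
only assignment under which the residue totals sum identically to the
frame ΔG (an assignment of full pair terms to both partners would
double-count them). Row components always sum to the row total; both
identities are enforced in the tests at 1e-9/1e-6 kcal/mol.

**Aggregation.** Mean over selected frames with the naive SEM
(s/√n over frames). Frame selections support `last:f` (trailing fraction),
matching the convention of scoring only the equilibrated tail of a
production run. Frame-level SEM understates the uncertainty of correlated
MD frames; replicate-level spread should be preferred when replicates
exist (the ranking stage accepts one record per replicate for exactly this
reason).

**Parameters.** Atom parameters (partial charge, LJ r_min/2 and ε, GB
intrinsic radius and screen, SASA radius) are consumed from a whitespace
table (extended PQR-like); no force-field typing is performed. The bundled
`generic_params` assigns element-based radii/LJ and places unit charges
only on Arg/Lys/Asp/Glu charged groups — a synthetic parameter set for
tests and demos, not a force field.

## Trajectory analysis

Superposition is Kabsch (SVD with determinant correction, always a proper
rotation); collinear or sub-3-atom selections are rejected. RMSF is the
per-atom RMS deviation from the time-average position after optional
superposition on frame 0, averaged over the selected atoms of each
residue (Cα by default, giving one value per residue). Essential dynamics
diagonalizes the 3N×3N covariance of selected coordinates, mass-unweighted
(the common default for Cα PCA), normalized by 1/n_frames; eigenvalues are
sorted descending, variance fractions are λ_i/Σλ, and each eigenvector's
first nonzero component is made positive so output is deterministic.
Frames are assumed pre-superposed (rotation/translation removed); `fit=True`
superposes on frame 0 internally. Whether to analyze the full assembly or
one subunit is a selection choice left to the caller.

## Interaction fingerprints

Residue-level keys (receptor residue, peptide residue, type) are detected
per frame from geometric criteria; atom-level hits collapse to one boolean
per key per frame. Defaults, all overridable:

| type | criterion |
|---|---|
| hydrogen bond | D–A ≤ 3.5 Å and D–H–A ≥ 130° (explicit H required) |
| hydrogen bond, heavy mode | D–A ≤ 3.5 Å only; keys flagged `hbond_heavy` |
| hydrophobic | apolar C···apolar C ≤ 4.5 Å (C bonded only to C/H/S) |
| van der Waals | d ≤ r_Bondi,i + r_Bondi,j + 0.5 Å |
| ionic | charged-group heavy atoms ≤ 4.5 Å |
| π-stacking | ring centroids ≤ 5.5 Å and plane angle ≤ 40° (or ≥ 140°) |

Apolar-carbon membership for the 20 standard residues comes from a bundled
template table; non-standard residues fall back to geometric inference
(carbon whose bonded neighbors, by a 1.9 Å covalent cutoff, are all
C/H/S). Donors are N/O heavy atoms with a covalently attached hydrogen
(H assignment by nearest heavy atom within 1.25 Å); acceptors are all N/O.
Water bridges, cation–π and halogen bonds are out of scope. Persistence is
the row mean of the presence matrix; tightening any threshold can only
remove detections, so persistence is monotone in the criteria (tested).
Published persistence percentages from long production runs depend on the
exact parameterization used there and are not reproduced here.

## Ranking

Within each terminal-variant family a peptide's rank key is its minimum
mean ΔG over replicates/conformers ("best replicate"), matching the
convention of advancing a peptide if any replicate binds well; a
mean-over-replicates key is available. Ties break lexicographically by
peptide id, making selection deterministic and row-order invariant.

## Assay post-processing

The 4PL model is fitted by least squares in log₁₀-dose space,
initialization from the response extremes and the dose nearest
half-maximum, Hill slope bounded to [0.1, 10], non-convergence reported as
`fit_ok=False`. Fitting in log-dose makes the fit scale-equivariant
(doses × c ⇒ IC₅₀ × c). Censored IC₅₀ values (">c") propagate through the
selectivity index as exact lower bounds, never imputed; a censored
denominator is rejected as uninformative. Quadrant gating uses
boundary-inclusive thresholds (≥ threshold counts positive — some
convention is needed and ties are measure-zero in real data) and exact
rational fractions on counts, so the four fractions sum to 1 identically.

One published consistency issue is worth recording: a reported selectivity
index of 0.12 for the positive-control compound is consistent with its
tumor IC₅₀ expressed in nM and non-tumor IC₅₀ in µM being divided without
unit conversion (7.4/63.4 ≈ 0.117), while the stated formula with
consistent units gives ≈ 117. The implementation requires consistent units
and takes no position; that value is not used anywhere.

## Synthetic data: what it does and does not show

The generators emulate only the *statistical structure* each analysis
assumes: planted interface segments at controlled distances (partner
residues at 5 Å with ≤ 0.4 Å atom jitter, everything else beyond 8 Å, so
the 6 Å criterion separates them with margin); harmonic, mode-structured
fluctuations with no rigid-body drift; contacts toggled between 3 Å and
12 Å in an exactly counted subset of frames; noiseless-to-noisy 4PL
curves; well-separated Gaussian event clouds with largest-remainder count
apportionment. They contain no force-field realism, no anharmonicity or
correlated solvent effects, no frame-to-frame autocorrelation, no plate or
spillover artifacts. Passing tests therefore demonstrate correctness of
the *algorithms* under their stated assumptions — exact recovery of
planted truth, agreement with closed forms and independent oracles — not
predictive accuracy on real structures, trajectories or assays. Problem
sizes used by the test suite and acceptance script (tens of residues,
4-atom dummy residues, 10³–5·10³ frames, 200 fit replicates) were chosen
as the smallest sizes at which the statistical checks are stable.

## Pipeline

The demo pipeline chains the stages on synthetic inputs, with the external
docking/MD stages replaced by constructed complexes (candidate fragment
plus the facing partner-chain segment at a controlled approach distance;
the closest approach is the planted best binder) and harmonic
trajectories. Every output table carries the package version, seed and a
hash of the scientific configuration (paths excluded), so identical-seed
re-runs are byte-identical and mismatched configurations are detectable.
Stage parameters are validated up front; unknown configuration keys are
rejected before any stage runs.

## Known limitations

* O(N²) energies and O(N²·points) SASA limit systems to a few thousand
  atoms; the package targets peptide-scale complexes, not full assemblies.
* GB self-consistency is with the OBC-II parameterization only; no PB
  reference, no normal-mode or quasi-harmonic entropy.
* The heavy-atom hydrogen-bond fallback cannot distinguish donor from
  acceptor orientation and will over-count polar contacts relative to the
  angle-aware mode.
* Multi-model PDB is the only mandatory trajectory dialect; binary formats
  are out of scope.
* Exact reproduction of any published candidate set from a specific
  lattice model is best-effort: it depends on extraction parameters the
  original workflow did not record.
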