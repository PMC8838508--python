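# Methods

This note documents the models, conventions, and numerical choices behind
`azidyn`, and what the synthetic generators do and do not emulate.

## Superposition, RMSD, RMSF

Each frame is superposed onto the reference by a single-pass Kabsch fit on
the analysis selection (SVD of the weighted covariance; the sign of the
smallest singular vector is flipped when the optimal orthogonal matrix
would be a reflection, so the returned rotation is always proper).  A
covariance whose smallest singular value is numerically zero — all selected
points collinear — is rejected rather than silently resolved, because the
rotation is then not unique.  No iterative "core-finding" re-superposition
is performed.

RMSD is per-frame, mass-unweighted, over the Cα selection.  RMSF is
computed about the **trajectory mean** position after superposition onto
the reference structure: the superposition target (X-ray reference) and the
fluctuation reference (mean structure) are deliberately distinct, which is
the standard pipeline for fluctuation analysis.  RMSF is computed over the
whole trajectory, not block-averaged.

Closed forms used in validation: isotropic per-coordinate Gaussian noise of
scale σ gives RMSF = σ√3, and the post-fit RMSD of a rigid frame with such
noise approaches σ√3·√(1 − O(1/n)) for n atoms (the fit absorbs six degrees
of freedom).

## Cross-correlation maps

The map element is the normalized covariance of Cartesian displacement
3-vectors about their single-pass trajectory means,
C_ij = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^1/2.  Numerical overshoot beyond
|C| = 1 (at the 1e-16 level) is clipped; a site with zero displacement
variance is an error naming the residue, not a NaN.

Difference maps use the convention ΔC = C(modified) − C(wild type), stored
in the output header, so coupling gained upon labelling is positive.
Display thresholding is **strict**: an entry survives only if |value| is
greater than the cutoff (default 0.25), so a value exactly at the cutoff is
masked.  Masking is display-only and never alters surviving values.  The
0.25 default reflects the working convention that smaller changes in a
correlation coefficient are insignificant at practically attainable
sampling; differences beyond 0.75 are not expected for this kind of
modification.

Feature blocks are 8-connected components of the surviving cells of the
upper triangle (the matrix is symmetric; labelling both triangles would
duplicate every feature as its mirror image).  Positive and negative
survivors are labelled separately, since a feature's sign is part of its
identity; components are reported as bounding residue ranges with the
extremal |ΔC|, sorted descending.

## The harmonic azide label

Energy convention is CHARMM-style, E = k(x − x₀)² with **no ½ factor**, so
the published constants are used verbatim and the Newtonian spring constant
of a bond is 2k.  Defaults: rₑ = 1.14 Å, k_b = 877.413 kcal/mol/Å² for each
N−N bond; θₑ = 180°, k_θ = 46.706 kcal/mol/rad² for the bend.

The Cartesian angle gradient carries a 1/sin θ factor that is singular at
the linear equilibrium; the implementation evaluates the regular product
(θ − θₑ)/sin θ with a series expansion near θ = π, so forces are finite and
smooth exactly where the molecule spends its time.

Normal modes come from an analytic Hessian at the collinear geometry: each
bond contributes 2k_b êêᵀ along the chain axis, and the linear bend
contributes 2k_θ c cᵀ per transverse direction with
c = (p/r₁₂, −(1/r₁₂ + 1/r₂₃)p, p/r₂₃).  Mass-weighted eigenvalues are
converted to cm⁻¹ through a single conversion constant (units Å, fs, amu,
kcal/mol internally; k_B = 0.0019872041 kcal/mol/K).  A linear triatomic
has exactly five zero modes; eigenvalues below 1e-8 of the spectral radius
are reported as exact zeros.  For equal masses the stretch eigenvalues are
{κ/m, 3κ/m} (κ = 2k_b), hence the √3 frequency ratio used as an internal
consistency check; with nitrogen masses the asymmetric stretch lands at
2105 cm⁻¹, i.e. in the experimentally relevant azide window.

## Langevin dynamics of the label

The integrator is the BAOAB splitting of Langevin dynamics, chosen for its
near-exact configurational sampling of harmonic systems; with zero friction
it reduces to velocity Verlet.  The hot loop is scalarized (9 coordinates in
plain float arithmetic) because per-step array dispatch dominates the cost
for a 3-atom system; a 10⁶-step run takes ~10 s on one core.

Parameters that matter: timestep (default 0.25 fs, refused above one tenth
of the fastest normal-mode period, ~1.6 fs here), friction (1/ps; 1–5/ps
gives well-mixed sampling without visibly broadening the stretch band), and
temperature (default 300 K).  Label partial charges default to a CO₂-like
pattern (−0.4, +0.8, −0.4 e) that makes the asymmetric stretch and bend
IR-active and the symmetric stretch dark; these are documented test values,
not physical azide charges.

Two diagnostics are exposed: total energy at saved frames and the mean
kinetic energy per degree of freedom.  Energy "drift" is measured as the
difference between the mean total energy over the last and first 10% of a
zero-friction run, normalized by the initial energy — the instantaneous
velocity-Verlet energy oscillates at O((ωΔt)²) with zero secular trend, so
windowed means are the meaningful measure.  Velocity-Verlet dispersion also
shifts the observed oscillation frequency by (ωΔt)²/24 (+0.9 cm⁻¹ at
0.25 fs for the asymmetric stretch), which is why spectral-peak checks
carry a ~2 cm⁻¹ allowance.

## Synthetic ensembles with planted correlations

Site displacements are zero-mean multivariate normal with a prescribed
correlation matrix R applied through its symmetric matrix square root,
independently and identically to x, y, and z; the expectation of the
correlation map is then exactly R, and sampling error shrinks as
n_frames^(−1/2).  Planted structure is expressed as latent-factor clusters
(all pairs within a site set share ρ): a cross-group-only block of
correlation ρ is not a valid correlation matrix once ρ·n exceeds 1, so
cluster membership is the planting mechanism, and the result is validated
for positive semi-definiteness regardless.  The reference geometry is an
α-helix-like Cα trace (2.3 Å radius, 1.5 Å rise, 100° twist), non-collinear
so the ensemble can be superposed.

What the generators do **not** emulate: solvent and friction-mediated
time correlation between frames (frames are exchangeable), anharmonicity
and conformational substates, secondary-structure signal in the correlation
maps, and electrostatic embedding of the label.  Passing tests therefore
demonstrate the correctness of the estimators and transforms, not the
biophysics of any particular protein; on real trajectories the same code
paths apply unchanged but sampling error must be judged against the
trajectory's own correlation time.

## Spectroscopy

The dipole autocorrelation C(τ) = ⟨μ(t)·μ(t+τ)⟩ is estimated by FFT with
**biased** normalization (divide by N), which keeps the estimator positive
semi-definite and |C(τ)| ≤ C(0).  The static mean dipole is removed first;
otherwise the zero-frequency term dwarfs the far-infrared region.  Default
maximum lag is one quarter of the series (variance control); both the lag
and the ×4 zero-padding are configurable.

The "filter" applied before the transform is the classic three-term
Blackman window (coefficients 0.42, 0.5, 0.08, i.e. exact α = 0.16),
applied to the one-sided ACF — the conventional placement in MD-IR
workflows.  The windowed ACF is extended to an even signal and FFT'd; the
intensity is the real part multiplied per-bin by the harmonic quantum
correction x/(1 − e^(−x)), x = hcν̃/(k_B T), with the removable singularity
at ν̃ = 0 handled explicitly (factor → 1).  No additional ω² prefactor is
applied.  The wavenumber grid spacing is 1/(c·N·Δt) for FFT length N, so
doubling the simulated time halves the spacing.  Output is unnormalized; a
`--normalize max` option exists on the CLI.  Window sidelobes can produce
tiny negative intensity ripple; it is left untouched rather than clipped.

Peak metrics: the band argmax is refined by three-point parabolic
interpolation and the FWHM by linear interpolation of the half-maximum
crossings; an isolated single-bin peak reports one grid spacing as its
width by convention.

## Structure and trajectory I/O

PDB parsing is fixed-column (wwPDB 3.3): first MODEL only, altLoc blank or
'A' only, occupancy/B-factor ignored, malformed records reported with their
line number.  Residue numbering is 1-based as in crystallographic practice;
frame indexing is 0-based.  The required trajectory dialect is multi-frame
XYZ (text, bit-exact round trips, no downloads in tests); binary DCD is not
implemented.  Atom masses are assigned from the element; the two-character
PDB charge column is parsed when present.  The Cα selector requires the
residue to be a standard amino acid, so ligand "CA" (calcium) atoms are not
picked up.

## Pipeline and reproducibility

Every generator is a pure function of its spec including the seed; no stage
reads a clock or global entropy source.  `run_pipeline` executes stages in
dependency order, logs parameters at stage boundaries, aborts on the first
error naming the stage, and writes a manifest with SHA-256 hashes of all
outputs — identical configs produce hash-identical artifacts.

Validation problem sizes: planted-correlation recovery uses 30 sites ×
10⁵ frames (max-norm error ≤ 0.02 with the n^(−1/2) scaling verified over a
4000→64000-frame seed ladder), difference-map recovery 20 sites × 10⁵
frames, equipartition 10⁶ Langevin steps (3% tolerance ≈ 3 standard errors
at friction 5/ps), and spectral checks 2¹⁷ integration steps (grid spacing
0.51 cm⁻¹).

## Known limitations

* The label force field is strictly harmonic: no anharmonic frequency
  shifts, no environment-induced band shifts, no coupling to a protein.
  Site-discrimination of real azide labels arises from exactly those
  effects and is outside this package's scope.
* Thermal (finite-temperature) label spectra sample the curvilinear
  anharmonicity of the bond/angle coordinates and peak a few cm⁻¹ away
  from the harmonic normal mode; the harmonic-limit checks use
  small-amplitude zero-friction runs for that reason.
* The correlated-ensemble generator has no time correlation, so quantities
  that depend on dynamics within a trajectory (relaxation times, spectral
  densities of protein motion) cannot be validated against it.
* PDB writing is limited to what the tests need; the package is not a
  general structure editor.
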