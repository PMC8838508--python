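# azidyn

Trajectory analysis for proteins carrying site-specific vibrational probes,
built around the azide (−N3) label attached to alanine residues.  Azide is a
popular infrared reporter: it absorbs near 2100 cm⁻¹, a transparent window
of the protein spectrum, and both its band position and the protein's
internal dynamics change with the attachment site.  `azidyn` provides the
full analysis chain used to quantify those changes from molecular-dynamics
trajectories, plus seeded synthetic generators so every stage can be
validated against known ground truth.

## What it computes

**Superposition and fluctuations.**  Optimal rigid-body superposition by the
Kabsch algorithm (SVD of the weighted covariance, with reflection
correction), per-frame RMSD to a reference structure, and per-residue RMSF
about the trajectory mean, on a Cα selection.

**Dynamical cross-correlation maps (DCCM).**  For Cα displacement vectors
Δrᵢ about their trajectory means,

    C_ij = ⟨Δr_i · Δr_j⟩ / (⟨Δr_i²⟩ ⟨Δr_j²⟩)^1/2,

so C_ij = +1 for fully correlated and −1 for fully anticorrelated motion.
Difference maps ΔC = C(modified) − C(wild type) localize labelling-induced
changes; entries with |ΔC| ≤ 0.25 are masked as insignificant and contiguous
super-threshold regions are reported as feature blocks with residue ranges,
sign, and extremal |ΔC|.

**The harmonic label force field.**  Each N−N bond is a harmonic oscillator
(rₑ = 1.14 Å, k = 877.413 kcal/mol/Å²) and the N−N−N bend is harmonic about
a linear equilibrium (θₑ = 180°, k = 46.706 kcal/mol/rad²), in the CHARMM
convention E = k(x − x₀)² without the ½ factor.  With nitrogen masses these
constants place the asymmetric stretch at 2105 cm⁻¹.  Analytic gradients,
an analytic mass-weighted Hessian, and normal modes are provided; a BAOAB
Langevin integrator drives the label to generate dipole time series.

**IR spectra.**  The spectrum is the Fourier transform of the dipole
autocorrelation C(t) = ⟨μ(0)·μ(t)⟩, tapered with the classic Blackman
window, multiplied by the harmonic quantum correction βħω/(1 − e^(−βħω)),
with peak positions and FWHMs extracted by parabolic/linear interpolation.

## Worked example

```python
import numpy as np
from azidyn import *

# synthetic ensembles: the "modified" protein gains a correlated cluster
# spanning residues 20-27 and 60-65 (latent-factor correlation 0.55)
cluster = list(range(19, 27)) + list(range(59, 65))
R_mod = block_correlation_matrix(80, [(cluster, 0.55)])
wt = compute_dccm(generate_correlated_trajectory(
    CorrelatedEnsembleSpec(n_sites=80, correlation=np.eye(80),
                           n_frames=20000, seed=1)), label="WT")
mod = compute_dccm(generate_correlated_trajectory(
    CorrelatedEnsembleSpec(n_sites=80, correlation=R_mod,
                           n_frames=20000, seed=2)), label="labelled")
delta = compute_delta_dccm(mod, wt)
masked, survivors = threshold_mask(delta, cutoff=0.25)
print(f"survivors above |dC| = 0.25: {survivors} of {80*79//2} pairs")
for b in extract_feature_blocks(delta)[:2]:
    print(f"feature: rows {b.row_range}, cols {b.col_range}, "
          f"sign {b.sign:+d}, max |dC| = {b.extremal_value:.3f}")

# the label's vibrations: normal modes vs the spectrum of a Langevin run
nm = normal_modes(np.array([14.007]*3), LabelForceField())
print(f"label normal modes (cm^-1): bend {nm.frequencies[5]:.1f}, "
      f"sym {nm.frequencies[7]:.1f}, asym {nm.frequencies[8]:.1f}")
res = simulate_triatomic(
    TriatomicSpec(temperature=0.0, friction=0.0, n_steps=2**16),
    initial_displacement=np.array([[1,0,0],[-1,0,0],[1,0,0]]) * 0.005)
spec = ir_spectrum(dipole_acf(res.dipole), SpectrumParams(temperature=300.0))
peak, fwhm = peak_metrics(spec, (1800, 2400))
print(f"dipole spectrum peak: {peak:.1f} cm^-1 (FWHM {fwhm:.1f} cm^-1)")
```

Output:

```
survivors above |dC| = 0.25: 91 of 3160 pairs
feature: rows (20, 27), cols (60, 65), sign +1, max |dC| = 0.564
feature: rows (60, 64), cols (61, 65), sign +1, max |dC| = 0.559
label normal modes (cm^-1): bend 602.6, sym 1215.5, asym 2105.2
dipole spectrum peak: 2106.1 cm^-1 (FWHM 9.7 cm^-1)
```

The planted cluster is recovered as a feature block with the correct
residue ranges and sign (the second block is the cluster's internal
near-diagonal part), and the dipole spectrum of the simulated label peaks
within a wavenumber of the asymmetric-stretch normal mode — the residual
0.9 cm⁻¹ is velocity-Verlet dispersion at the 0.25 fs timestep.

A command-line interface mirrors the library (`azidyn rmsf`, `rmsd`,
`dccm`, `ddccm`, `irspectrum`, `synth corr`, `synth triatomic`, `run`);
`azidyn run --config run.yaml` executes the whole chain and writes a
manifest with content hashes of every artifact.

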