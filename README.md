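# dimerframe

Conformational-plasticity analysis of H2A-H2B histone dimers and
nucleosome core particles, built around the dimer's own two-fold
pseudosymmetry.

The H2A-H2B dimer — two histone folds (α1, α2, α3 helices) interlocked in
a handshake — is not rigid: its long α2-helices bend, and that bending
changes how the dimer grips nucleosomal DNA at its L1L2 binding sites.
`dimerframe` is a toolkit for quantifying this plasticity in molecular
dynamics ensembles and in surveys of experimental structures:

* **Dimer reference frame (DRF)** — the C2 pseudosymmetry axis of the
  handshake (found by superposing one fold onto the other and extracting
  the rotation axis) becomes the X axis; Y maximizes the α2 Cα
  projections perpendicular to it; Z = X × Y.  A nucleosome frame (NRF)
  is built analogously from the DNA superhelical and dyad axes.
* **Bending metrics** — the α2-α2 angle θ (between the first→last Cα
  vectors of the two α2-helices), terminal-Cα helix amplitudes, maximal
  pairwise RMSD, per-atom RMSF over trajectories, RMSV across aligned
  experimental structures, and RMSF = √(3B/8π²) from B-factors.
* **PCA modes** — eigen-decomposition of aligned Cα fluctuations,
  eigenvector comparison across simulations via inner products,
  trajectory projections, and the Pearson correlation between θ and the
  leading bending mode (sign-canonicalized).
* **Secondary structure & H-bonds** — a Kabsch–Sander (DSSP-style)
  helix/turn assigner with geometric H-bond detection and Fisher exact
  association tests between H-bond and turn states.
* **DNA unwrapping** — base-pair center paths from C1′ midpoints and the
  unwrapped-end length: the longest terminal run of base pairs all more
  than 7 Å from every base pair of the wrapped reference.
* **Structure survey** — chain mapping onto canonical histone sequences,
  grouping into free dimer / dimer complex / free NCP / NCP complex,
  nucleosomal-DNA sequence classification, and a resolution filter.
* **Synthetic generators** — every input the pipeline consumes (ideal
  helices with full backbones, C2-symmetric dimers at a requested bending
  angle, ensembles with planted PCA spectra, superhelical DNA paths with
  planted unwrapped ends, coupled H-bond/turn state series) can be
  generated with known ground truth, so the entire analysis is testable
  without any external data.

## Worked example

Generate a bending-dominated synthetic trajectory of a free dimer and run
the mode analysis:

```python
from dimerframe.synthetic import synthetic_dimer, bending_ensemble
from dimerframe.modes import pca_modes, project_trajectory, angle_mode_correlation
from dimerframe.plasticity import alpha2_angle_series
from dimerframe.stats import kde_mode, spread

dimer = synthetic_dimer(angle=144.3)
ens = bending_ensemble(dimer, preset="free_dimer_modes", n_frames=20000, seed=1)
dec = pca_modes(ens)
theta = alpha2_angle_series(ens, dimer)
proj = project_trajectory(ens, dec.eigenvectors[:, 0], dec.mean_conformation)
r, _ = angle_mode_correlation(theta, proj)

print(f"mode 1 variance fraction: {dec.variance_fractions[0]:.3f}")
print(f"modes 1+2 cumulative:     {dec.variance_fractions[:2].sum():.3f}")
print(f"angle mode: {kde_mode(theta):.2f} deg, spread: {spread(theta):.2f} deg")
print(f"angle-mode Pearson r:     {r:.3f}")
```

```
mode 1 variance fraction: 0.236
modes 1+2 cumulative:     0.346
angle mode: 144.43 deg, spread: 1.38 deg
angle-mode Pearson r:     -0.957
```

The `free_dimer_modes` preset plants a covariance whose first mode (the
symmetric α2 bending along the pseudosymmetry axis) carries 24% of the
variance and whose first two modes carry 35%; PCA recovers both within
sampling error.  The bending angle θ is a geometric collective variable
for the first mode: its per-frame values correlate strongly and
negatively with the mode projection (bending lowers θ).  The KDE mode
and spread recover the construction angle and the planted width.

The same analysis runs on any multi-model PDB through the CLI:

```sh
dimerframe synth free_dimer_modes --n-frames 200 --seed 1 --out traj.pdb
dimerframe analyze traj.pdb --out report/
dimerframe drf traj.pdb
dimerframe classify file1.pdb file2.pdb --out groups.tsv
```

`analyze` writes per-frame angles and mode projections, eigenvalue
tables, amplitude and RMSF profiles and the angle KDE / free-energy
profile as TSV; `drf` prints the reference frame as YAML.

## Layout

```
src/dimerframe/
  core.py          shared containers (DimerModel, ensembles, frames)
  structure_io.py  PDB/mmCIF reading, chain mapping, survey classification
  frames.py        Kabsch superposition, pseudosymmetry axis, DRF/NRF
  plasticity.py    α2-α2 angle, amplitudes, RMSD/RMSF/RMSV, projections
  modes.py         PCA modes, inner products, projections, correlation
  ss_hbonds.py     H-bond detection, Kabsch–Sander subset, Fisher test
  dna.py           base-pair centers, unwrapped-length metric
  stats.py         Gaussian KDE, mode, spread, Boltzmann ΔG
  synthetic.py     generators with planted ground truth (presets in data/)
  pipeline.py      end-to-end ensemble analysis and structure survey
  cli.py           `dimerframe` command-line interface
```

See `docs/methods.md` for the model definitions, numerical choices and
known limitations.
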