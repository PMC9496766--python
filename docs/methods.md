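# Methods

## The system and the question

The H2A-H2B histone dimer is one of the two dimer types of the nucleosome
core particle (NCP), where ~147 bp of DNA wrap a histone octamer.  Each
dimer is built from two copies of the histone fold — three α-helices (α1,
α2, α3) — interdigitated in a "handshake" whose core is approximately
two-fold (C2) pseudosymmetric.  The package quantifies the conformational
plasticity of this core: how the two long α2-helices bend, how that bending
decomposes into collective modes, how it differs between the free dimer,
the DNA-bound dimer and the nucleosome-embedded dimer, and how it couples
to local secondary-structure transitions and to nucleosomal DNA
unwrapping.

## The dimer reference frame (DRF)

All comparisons between conformations happen in a common frame derived
from the dimer's own pseudosymmetry:

* **X axis** — the C2 pseudosymmetry axis.  It is found by superposing the
  Cα atoms of one histone fold onto their structural equivalents in the
  other fold (Kabsch least-squares superposition, proper rotation
  enforced) and extracting the rotation axis.  For an exactly symmetric
  dimer the rotation angle is 180° and the fit RMSD zero; on real
  structures the angle stays close to 180° and the fit RMSD measures the
  deviation from perfect symmetry.  The fold equivalence table defaults to
  pairing α1↔α1, α2↔α2, α3↔α3 position by position; an explicit table can
  be supplied.
* **Y axis** — the direction perpendicular to X along which the α2-helix
  Cα atoms extend the furthest.  Two criteria are implemented: maximal
  mean absolute projection (default) and maximal projection variance; on
  dimer-like geometries they agree to well under a degree, because both
  are dominated by the α2 span.  The maximizer is located by a dense
  3600-point angular grid scan followed by bounded scalar refinement.
* **Z axis** — X × Y.
* **Origin** — centroid of the histone-fold α-helix Cα atoms.
* **Sign conventions** — the mathematical frame is defined only up to
  ±X, ±Y.  We orient X so the first chain's α2 N→C vector has non-negative
  X component, and Y so the second chain's α2 centroid has positive Y.
  This makes frames reproducible across runs and equivariant under rigid
  motion of the input (tested).

The nucleosome reference frame (NRF) is built from the DNA instead: Z is
the best-fit superhelical (cylinder) axis of the base-pair-center path —
initialized from the smallest principal axis and refined by least-squares
on the radial spread — Y points from the axis through the central (dyad)
base pair, and X = Y × Z.  This is a deliberately simplified cylinder-fit
construction that captures the axis semantics (superhelical + dyad axes)
without reproducing any particular published NRF algorithm in full.

## Plasticity metrics

* **α2-α2 angle** — angle between the vectors joining the first and last
  Cα of each chain's α2-helix, both taken N→C.  Near-antiparallel helices
  give values around 140–150°; bending that brings the two L1L2
  DNA-binding sites together lowers the angle.
* **Helix amplitude** — maximum distance between positions of a terminal
  Cα across all frame pairs of a DRF-aligned ensemble (an O(T²) quantity
  computed via `pdist`).  The alternative "maximum excursion from the
  first frame" is exposed as an option.
* **Max pairwise RMSD / RMSF / RMSV** — once an ensemble is aligned
  (Kabsch on the fold-helix Cα selection, flagged on the object), all
  pairwise RMSDs are plain coordinate RMSDs with *no* second superposition
  round; RMSF is the per-atom fluctuation about the ensemble mean, and
  RMSV is the identical quantity computed across a set of aligned
  experimental structures, restricted to residues present in all of them.
  Crystallographic B-factors convert to fluctuation estimates via
  RMSF = √(3B/8π²).

## PCA bending modes

PCA runs on the flattened 3N Cα coordinates of an aligned ensemble, via
SVD of the centered data matrix (covariance normalization 1/(T−1), no mass
weighting — the selection is Cα-only).  A warning is emitted when T ≤ 3N.
Eigenvector sign is arbitrary; for the signed angle–mode correlation the
projection series is canonicalized so that it decreases as the α2-α2 angle
increases, which fixes the reported Pearson correlation to the negative
branch.  Mode similarity across ensembles uses absolute inner products of
eigenvectors (1 codirectional, 0 orthogonal).

## Secondary structure and hydrogen bonds

Individual hydrogen bonds use the geometric criterion: donor-acceptor
distance ≤ 3.0 Å and donor-H-acceptor angle ≥ 120°.  Secondary structure
uses the Kabsch–Sander electrostatic model
(E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
E < −0.5) on backbone N/Cα/C/O, with amide hydrogens reconstructed 1.01 Å
from N along the bisector of the N←C(i−1) and N←O(i−1) directions whenever
the input carries no hydrogens (crystal structures).  Only the
helix/turn subset of the class taxonomy is implemented — H (α), G (3₁₀),
I (π), T (H-bonded turn), a minimal E from the bridge/ladder rules, else
'-' — with priority H > E > G > I > T; residues flanking a chain break
(C–N distance > 2.5 Å or non-consecutive numbering) stay unassigned.
This subset is exactly what the α-helix ↔ H-bonded-turn transition
analysis at the H2A α2 N-end needs.  The association between an H-bond
state series and a turn state series is tested with the two-sided Fisher
exact test on the 2×2 contingency table.

## DNA unwrapping

Base-pair centers are midpoints of paired C1′ atoms (pairing i ↔ N+1−i
for equal-length complementary strands, nearest-C1′ fallback with
overhangs dropped).  The C1′ midpoint sits within ~1 Å of a full
base-pair reference point for Watson–Crick geometry — negligible against
the 7 Å cutoff.  A terminal DNA segment is unwrapped when *every* base
pair in it lies more than 7 Å from *all* base-pair centers of the wrapped
reference; the "all reference centers" clause means DNA that slid along
the superhelical path is not counted, and runs are counted strictly from
each terminus inward, so interior excursions never contribute.

## Distribution statistics

Angle distributions are estimated with Gaussian-kernel KDE (Scott's-rule
bandwidth by default; the bandwidth actually used is recorded on the
estimate).  The distribution mode is the grid argmax refined by local
quadratic interpolation, ties breaking toward the smaller value.  Angles
are treated as plain scalars — observed α2-α2 angles live far from the
0°/180° wrap, so circular statistics would change nothing.  Free-energy
profiles are Boltzmann inversions ΔG(θ) = −kT·ln[p(θ)/p(θ_mode)], zero at
the mode, masked (NaN) where the density falls below 10⁻⁶ of its maximum;
kT = 0.593 kcal/mol at 300 K converts to kcal/mol.  In the Gaussian limit
ΔG approaches (θ−μ)²/2σ², which the tests verify to 0.1 kT within ±2σ.

## Synthetic generators: what they emulate, and what they do not

The generators produce inputs carrying exactly the statistical and
geometric structure the analysis assumes, so each stage is validated by
planted-parameter recovery:

* `ideal_helix` / `ideal_helix_backbone` — parametric Cα helices (1.5 Å
  rise, 100°/residue, 2.3 Å radius) and full-backbone helices built by
  internal-coordinate chain extension at (φ, ψ) = (−57°, −47°) with
  canonical peptide geometry, used as the secondary-structure fixture.
* `synthetic_dimer` — two chains of α1/α2/α3 ideal-helix pieces, exact C2
  images about a planted x-axis, with each α2 first→last-Cα chord at half
  the requested angle from the axis so the α2-α2 angle equals the request
  exactly.  The angle presets for the different contexts are: free dimer
  144.3° (σ 2.0°), nucleosome-embedded 145.9° (σ 1.5°) — the free-dimer
  mode sits 1.6° below it and the measured sliding-associated bending of
  142.9° sits 3° below it — DNA-bound 145.8° (σ 2.1°), H2A.Z nucleosome
  149.7° (the +3.8° variant shift); the extreme sampled conformations are
  154° (DNA-bound) and 138° (free), a > 16° span.
* `bending_ensemble` — Gaussian ensembles with planted covariance: mode 1
  bends both α2 C-terminal halves along the pseudosymmetry axis through a
  piecewise-linear hinge at mid-helix (the simplest field consistent with
  simultaneous bending of the two longest helices), mode 2 bends them
  perpendicular; the `free_dimer_modes` preset plants variance fractions
  (0.24, 0.11) with the remaining 65% isotropic over the orthogonal
  complement, total variance 10 Å².
* `arc_excursion_ensemble` — one terminal Cα sweeps a 60° circular arc
  whose end-to-end chord equals the planted amplitude (preset 4.5 Å for
  the free-dimer H2A α2 C-end) while every other atom is static; random
  rigid motions are applied per frame.  Alignment on the static-atom
  selection inverts those motions exactly, so the planted chord survives
  alignment to machine precision.  Aligning on a selection including the
  moving atom would smear ~0.1 Å of the motion into the fitted transform;
  the static-selection choice is what makes an exact-recovery check
  meaningful.
* `synthetic_ncp_dna` — 147 bp superhelical center path (radius 41.9 Å,
  pitch 25.9 Å, 3.4 Å arc per bp) with requested terminal segments
  replaced by straight tangent continuations displaced 15 Å outward; the
  construction verifies the every-bp-beyond-cutoff condition and refuses
  infeasible requests.
* `correlated_state_series` — paired Bernoulli series with requested
  marginals and odds ratio (joint cell solved from the 2×2 association
  identity), emulating H-bond/turn coupling.
* `angle_sample_pair` — two preset angle samples generated from a single
  standard-normal draw (common random numbers).  Comparing the KDE modes
  of two *independent* n = 5000 samples would carry ≈0.27° of sampling
  noise in the mode difference — larger than the 1.6° shift's recovery
  tolerance — whereas the paired design cancels the shared sampling error
  and leaves ≈0.06°.  Pairing is the natural design here because the two
  presets model the same system in two contexts.

All generators are deterministic under their seed (NumPy `default_rng`).

What the generators do **not** emulate: force-field physics, anharmonic
and multimodal conformational distributions, sequence-dependent DNA
elasticity, histone tails, solvent, or correlated noise between modes.
Passing recovery tests therefore demonstrates that the *analysis
machinery* is correct and calibrated — not that any particular biological
system behaves Gaussianly.  In particular the free-energy quadratic check
validates the Boltzmann-inversion implementation, and real bending
distributions may (and do) have non-Gaussian tails.

## Problem sizes and numerical choices

Recovery analyses use 20,000-frame ensembles for PCA fractions and
angle-mode correlation (sampling error on a 24% fraction ≈ 0.3 points),
5,000-sample pairs for the mode shift, 200 frames for the amplitude arc,
and 147 bp DNA paths — sizes at which every planted quantity is resolved
well inside its tolerance while the whole suite runs in minutes on one
CPU.  Degenerate inputs are rejected rather than guessed at: fewer than
3 points or collinear point sets for superposition, fewer than 20
equivalent Cα pairs for the symmetry axis, fewer than 20 bp for the
superhelix fit, zero-variance series for correlation/KDE, constant series
for the Fisher test.  KDE grids use 2001 points over the data ± 3
bandwidths; the DRF angular grid uses 3600 points plus refinement;
`le`/boundary comparisons in hydrogen-bond criteria are inclusive.

## Known limitations

* The fold equivalence table is a fixed α-helix pairing, not a structural
  alignment; strongly diverged folds would need an explicit table.
* The NRF is a cylinder-axis approximation; it does not reproduce any
  specific published nucleosome-frame algorithm beyond axis semantics.
* Base-pair centers are C1′ midpoints, not full base-pair reference
  frames; twist/roll/slide step parameters are out of scope, as is
  twist-defect detection.
* The secondary-structure assigner implements the helix/turn/bridge
  subset only; full β-sheet topology, bends and κ-classes are not
  assigned.
* Chain mapping classifies local files only; no remote database queries.
* The bundled α-satellite reference sequences are reconstructed
  palindromic approximations (marked as such in the FASTA headers); DNA
  classification of real files is by best-match identity and tolerates
  this.
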