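# Generator presets encoding the study conditions for synthetic ensembles.
#
# Angle presets: Gaussian parameters (degrees) of the α2-α2 bending-angle
# distribution in each simulation context.  The nucleosome-embedded dimer is
# the most constrained (smallest σ); the free dimer's most probable angle is
# 1.6° below the nucleosome-embedded one; the DNA-bound dimer's mode is
# almost identical to the nucleosome-embedded one; the H2A.Z nucleosome mode
# is shifted 3.8° above the canonical nucleosome.
angle_presets:
  angle_free_dimer: {mean: 144.3, std: 2.0}
  angle_ncp: {mean: 145.9, std: 1.5}
  angle_dna_bound: {mean: 145.8, std: 2.1}
  angle_h2az_ncp: {mean: 149.7, std: 1.5}

# Extreme sampled conformations of the bending coordinate (degrees): the
# largest angle reached by the DNA-bound dimer and the smallest reached by
# the free dimer, spanning the accessible bending range (> 16°).
extreme_conformations:
  angle_max_dna_bound: 154.0
  angle_min_free: 138.0

# PCA mode presets: variance fractions carried by the two leading collective
# bending modes of the free dimer (mode 1 along the pseudosymmetry axis,
# mode 2 perpendicular); the remainder is isotropic thermal noise.
mode_presets:
  free_dimer_modes:
    fractions: [0.24, 0.11]
    total_variance: 10.0   # Å², summed over all Cα coordinates

# Helix-amplitude presets (Å): maximal excursion of α2 C-terminal Cα atoms.
amplitude_presets:
  free_dimer_h2a_amp: 4.5
  free_dimer_h2b_amp: 6.8
  ncp_h2a_amp: 4.2

# DNA superhelix geometry of the wrapped nucleosomal path.
dna:
  n_bp: 147
  radius: 41.9     # Å
  pitch: 25.9      # Å per superhelical turn
  rise: 3.4        # Å arc length per base pair
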