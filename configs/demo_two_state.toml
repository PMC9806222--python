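# Shipped synthetic two-state demo: a "reference" state with weak
# inter-domain anti-correlation vs a "perturbed" state with strong
# anti-correlation, each sampling two conformational substates.
# Values shown are the package defaults; any key may be overridden.

[run]
output_dir = "results/demo"
seed = 11
temperature = 300.0

[ensemble]
n_residues = 48            # two chains: receptor (A) + binder (B)
receptor_residues = 32
n_frames = 400             # per state
amplitude = 0.5            # Å RMS fluctuation per axis
intra_correlation = 0.6
inter_correlation_state_a = -0.2
inter_correlation_state_b = -0.5
deformation = 8.0          # Å hinge displacement between the two substates
substate_weight = 0.5

[network]
contact_cutoff = 6.0       # Å; Cα-only synthetic chains need a looser cutoff
persistence_threshold = 0.75
min_community_size = 3

[dccm]
mask_threshold = 0.4
anti_cutoff = -0.4

[pca]
bins = 16
basin_depth = 0.5          # kcal/mol

[solvation]
shell_radius = 2.35        # Å, first-shell peak position
shell_occupancy = 7
box = 24.0
bulk_density = 0.0334      # Å^-3, bulk water number density
jitter = 0.05
n_frames = 50
coordination_cutoff = 3.0

[cluster]
cutoff = 1.2               # Å, between substate spread and separation
stride = 5

[gbsa]
gamma = 0.0072             # kcal/(mol Å²)
b = 0.0
solvent_dielectric = 78.5
solute_dielectric = 1.0
n_points = 240
n_frames = 10
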