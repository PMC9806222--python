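"""Physical constants and package-wide defaults (kcal/mol, Å, K units)."""

# Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 0.0019872

# Coulomb conversion constant in kcal mol^-1 Å e^-2
K_COULOMB = 332.06

# Simulation/analysis temperature default (K)
DEFAULT_TEMPERATURE = 300.0

# Dynamic-network defaults: residue pairs in contact within this heavy-atom
# cutoff for strictly more than this fraction of frames become edges
CONTACT_CUTOFF = 4.5          # Å
PERSISTENCE_THRESHOLD = 0.75  # fraction of frames

# Correlation magnitude below which DCCM heatmap entries are blanked
DCCM_DISPLAY_MASK = 0.4

# Nonpolar solvation: dG_nonpolar = GAMMA_SASA * dSASA + B_SASA
GAMMA_SASA = 0.0072  # kcal mol^-1 Å^-2
B_SASA = 0.0         # kcal mol^-1

# Implicit-solvent dielectrics
SOLUTE_DIELECTRIC = 1.0
SOLVENT_DIELECTRIC = 78.5

# Shrake-Rupley defaults
SASA_PROBE = 1.4     # Å
SASA_POINTS = 960

# Solvation-shell defaults
RDF_BIN_WIDTH = 0.05       # Å
RDF_R_MAX = 8.0            # Å
COORDINATION_CUTOFF = 3.0  # Å, Ca-O first minimum region

# Ca2+ Lennard-Jones parameters recorded from the force-field database the
# trajectories were produced with (metadata only; not used in toy systems)
CA_RSTAR = 1.79     # Å
CA_EPSILON = 0.0140  # kcal/mol

# Residue names treated as water
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "T3P", "SOL", "SPC", "H2O"})

# Standard amino-acid residue names (protein selector / backbone detection)
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HID HIE HIP ILE LEU LYS MET PHE
    PRO SER THR TRP TYR VAL""".split()
)
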