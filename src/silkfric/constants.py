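"""Physical constants and geometric defaults shared across the package.

Internal unit conventions: lengths in nm for structures, SI (m, s, N) for
dynamics and friction coefficients, forces reported in pN where noted.
"""

# Boltzmann constant
K_B = 1.380649e-23  # J/K
T_DEFAULT = 300.0  # K, simulation temperature
KT_300 = K_B * T_DEFAULT  # J  (= 4.141 pN nm)

# beta-strand geometry defaults (nm); crystal blocks are 2-5 nm on a side
RISE_PER_RESIDUE = 0.35     # backbone rise along the strand axis
STRAND_SPACING = 0.48       # inter-strand distance within a beta-sheet
SHEET_SPACING = 0.53        # inter-sheet stacking distance

# Bondi van der Waals radii (nm) for the coarse heavy-atom representation
VDW_RADII = {
    "N": 0.155,
    "CA": 0.170,
    "C": 0.170,
    "O": 0.152,
    "CB": 0.170,
}

# water probe radius recommended for SASA
PROBE_RADIUS = 0.14  # nm

# dragline silk sequences (Araneus diadematus MA gland)
POLYALA_SEQUENCE = "AAAAAAAA"
AMORPHOUS_SEQUENCE = "GPGGYGPGSQGPSGPGGYGPGGPG"

# per-residue water friction coefficient, close to bulk-water experiment
XI_WATER_PER_RESIDUE = 1.0e-12  # Ns/m

# harmonic pulling spring
SPRING_K_PN_PER_NM = 830.0          # pN/nm
SPRING_K_SI = SPRING_K_PN_PER_NM * 1e-12 / 1e-9  # N/m

PN = 1e-12   # N per pN
NM = 1e-9    # m per nm
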