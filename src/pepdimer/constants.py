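"""Physical constants used throughout the package.

All energies are kJ/mol, temperatures K, distances nm, masses Da.
"""

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314e-3

#: Gas constant, J mol^-1 K^-1 (for callers working in J).
R_J = 8.314

#: Proton mass, Da (charge carrier for positive-mode ESI).
PROTON_MASS = 1.00728

#: Monoisotopic mass of water, Da (added once per peptide chain).
WATER_MONO = 18.0105646863

#: Mass correction for C-terminal amidation (-OH +NH2), Da.
AMIDE_CORRECTION = -0.98402

#: Monoisotopic mass of trimethylamine N-oxide (C3H9NO), Da.
TMAO_MONO = 75.068414

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23
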