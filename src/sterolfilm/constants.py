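"""Physical constants shared across the package (SI unless noted)."""

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.31446261815324

#: AT-cut quartz density, kg m^-3.
QUARTZ_DENSITY = 2648.0

#: AT-cut quartz shear modulus, Pa.
QUARTZ_SHEAR_MODULUS = 2.947e10

#: Molar concentration of water, mol L^-1, used for mole-fraction standard state.
WATER_MOLARITY = 55.5

#: Sterol long-axis length, nm (cholesterol C3..C17 extent plus tail rise).
STEROL_LENGTH_NM = 1.71

#: Sterol ring-system width, nm.
STEROL_WIDTH_NM = 0.65

#: Upright sterol cross-sectional area at the interface, nm^2.
STEROL_CROSS_SECTION_NM2 = 0.38
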