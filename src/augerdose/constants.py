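"""Physical constants and liquid-water material data (CGS-ish mix, documented per symbol)."""

# electron rest energy
MC2_EV = 510_998.95  # eV
# classical electron radius
RE_CM = 2.817_940_326e-13  # cm
# fine-structure constant
ALPHA = 1.0 / 137.035_999

# liquid water, density 1 g/cm^3
WATER_DENSITY_KG_M3 = 1000.0
WATER_N_MOLECULES_CM3 = 3.3428e22
WATER_N_ELECTRONS_CM3 = 10 * WATER_N_MOLECULES_CM3
WATER_I_EV = 78.0  # mean excitation energy (ICRU-90 value for liquid water)

EV_TO_J = 1.602_176_634e-19
KEV_TO_J = 1.602_176_634e-16
MEV_TO_J = 1.602_176_634e-13

# tracking cutoff: sub-excitation electrons are deposited locally below this
CUTOFF_EV = 7.4

UM_TO_CM = 1e-4
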