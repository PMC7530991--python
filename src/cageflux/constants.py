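"""Physical constants shared across the package.

Values are kept in the unit system the stopped-flow literature uses:
lengths in nm (geometry) or μm s⁻¹ (permeabilities), osmolarities in
Osm L⁻¹, molar volume of water in L mol⁻¹.
"""

from scipy.constants import Avogadro

#: Molar volume of water, L mol⁻¹ (not temperature-corrected).
V_W_L_PER_MOL: float = 0.018

#: Molar volume of water, m³ mol⁻¹.
V_W_M3_PER_MOL: float = V_W_L_PER_MOL * 1e-3

#: Water molecules per cm³ of liquid water: N_A / (18 cm³ mol⁻¹).
WATERS_PER_CM3: float = Avogadro / 18.0  # ≈ 3.346e22

#: Default lipid-bilayer thickness, nm.
BILAYER_THICKNESS_NM: float = 5.0

#: Cross-sectional area of one lipid headgroup, nm².
LIPID_AREA_NM2: float = 0.35
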