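"""Electron bookkeeping for a peptide-doped anionic membrane.

The absolute scale of a bilayer electron-density profile comes from plain
counting: every molecule in the unit cell contributes its electrons, and
the composition-weighted sum per lipid fixes the normalization.
"""

from memdiff.composition import (
    ABETA_1_42_SEQUENCE,
    MembraneComposition,
    electrons_of_formula,
    leaflet_electron_budget,
    molar_mass_of_formula,
    peptide_formula,
    registry_species,
)

# species come with formula-derived electron counts
for name in ("DMPC", "DMPS", "cholesterol", "melatonin"):
    sp = registry_species(name)
    print(f"{name:12s} {sp.formula}  {sp.electrons} e-  "
          f"{molar_mass_of_formula(sp.formula):.1f} g/mol")

# peptides are condensed from their one-letter sequence
f = peptide_formula(ABETA_1_42_SEQUENCE)
print(f"\nAbeta(1-42)  {f}  {electrons_of_formula(f)} e-")

# the leaflet budget for a 97:3 DMPC:DMPS membrane with 7 waters per lipid
comp = MembraneComposition(
    lipid_fractions=((registry_species("DMPC"), 0.97),
                     (registry_species("DMPS"), 0.03)),
    waters_per_lipid=7.0,
)
print(f"\nleaflet budget (97:3 + 7 waters): "
      f"{leaflet_electron_budget(comp):.2f} e- per lipid")
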