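"""Membrane composition bookkeeping for the two reference bilayers.

SM1 is the two-lipid POPC/POPE membrane; SM2 adds cholesterol and a
trace of cardiolipin.  Mass (%W) and molar (%mol) fractions follow the
published totals; internal inconsistencies in the printed table are
flagged, not silently resolved.
"""

import poremap as pm
from poremap.composition import SM1, SM2

for comp in (SM1, SM2):
    print(f"== {comp.name} ==")
    print(comp.table().round(1).to_string(index=False))
    for issue in comp.consistency_report():
        print(f"  note: {issue}")
    print()

ratio = pm.lipid_protein_molar_ratio(mass_ratio=3.0, mean_lipid_mass=745.0,
                                     protein_mass=34_766.0)
print(f"3:1 (w:w) lipid:protein reconstitution -> {ratio:.0f}:1 molar ratio")
print("(~140 lipids per channel, enough for roughly two annular shells)")
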