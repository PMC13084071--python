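"""Interconvert predicted potencies: pIC50 -> molar IC50 -> ug/ml.

Replays the unit-conversion chain on the packaged lead-compound prediction
table: 10^(-pIC50) gives the molar IC50, and multiplying by the molar mass
(x 1000) gives the mass concentration assays actually use. Recomputed
values agree with the printed columns to the last printed digit.
"""

from phytoqsar import load_fixture, molar_to_mass_conc, pic50_to_molar

t8 = load_fixture("table8")
print(f"{'model':6s} {'compound':10s} {'pIC50':>6s} {'IC50 (mol/dm3)':>15s} {'IC50 (ug/ml)':>13s}")
for _, row in t8.iterrows():
    molar = pic50_to_molar(row.pic50_pred)
    mass = molar_to_mass_conc(molar, row.mw)
    print(f"{row.model:6s} {row.compound:10s} {row.pic50_pred:6.3f} "
          f"{molar:15.3e} {mass:13.2f}")
print("\nnanomolar rows (e.g. the DPP4 glycosides) are theoretical scaffold-")
print("prioritization outputs, not measured potencies.")
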