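"""Tabulate the Al_i-pH toxicity surface for a family of gibbsite constants.

For each solubility constant the script reports the largest pH at which
cationic inorganic aluminum still reaches the 50 μg/L roach-mortality
limit: with the default log K_Al = 8.1 this crossing sits below pH 4.8,
which is why pH itself can proxy aluminum toxicity in these waters.
"""

from borealacid import al_toxicity_curve

table, crossings = al_toxicity_curve()

print("log_KAl   pH where Al_i last reaches 50 ug/L")
for kal, ph in crossings.items():
    print(f"  {kal:4.1f}    {ph:.2f}")

print()
sub = table[(table.log_KAl == 8.1) & (table.pH.round(2).isin([4.5, 5.0, 5.5, 6.0]))]
print("default-constant curve (log_KAl = 8.1):")
for _, row in sub.iterrows():
    print(f"  pH {row.pH:.1f}: Al_i = {row.al_i_mass:8.2f} ug/L")
print()
print("A larger solubility constant dissolves more aluminum at a given pH")
print("and shifts the toxic crossing upward; the curve itself always falls")
print("monotonically with pH.")
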