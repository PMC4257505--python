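"""Solve the charge balance of a single lake-water sample.

Builds a sulfate-impacted, humic composition, solves for pH, and prints
the speciation.  Concentrations are charge equivalents in μeq/L; the
cationic inorganic aluminum pool is also given as μg/L because 50 μg/L is
the conventional toxicity limit for roach.
"""

from borealacid import IonComposition, solve_pH

comp = IonComposition(
    ca=60, mg=20, na=40, k=8, nh4=2,     # base cations, μeq/L
    so4=140, cl=35, no3=6, f=1,          # strong acid anions, μeq/L
    toc=9.0,                             # mg C/L
)

result = solve_pH(comp)

print(f"solved pH:            {result.pH:.3f}")
print(f"charge residual:      {result.residual:+.2e} μeq/L")
print(f"bicarbonate:          {result.hco3:.2f} μeq/L")
print(f"organic anion charge: {result.oa_charge:.1f} μeq/L")
print(f"cationic Al charge:   {result.al3 + result.aloh2 + result.aloh2p:.2f} μeq/L")
print(f"inorganic Al (Al_i):  {result.al_i_mass:.1f} μg/L")
print()
print("The lake's acid anions far exceed its base cations, so the balance")
print("is closed by protons and dissolved aluminum while bicarbonate is")
print("suppressed: a solved pH this far below 5.5, with Al_i an order of")
print("magnitude above the 50 μg/L limit, cannot support roach.")
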