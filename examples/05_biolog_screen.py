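"""Screen two strains for differential respiration across many environments.

Phenotype-microarray wells report respiration as kinetic dye-reduction
curves; each well is summarised by its average curve height h, and a strain
pair is called differential in a well when the mean heights differ by more
than 3 replicate standard deviations of each strain.  The generator plants
10 gains and 3 losses of function among 96 wells; the screen recovers them.
"""

from epiland.biolog import screen_from_table, screen_summary
from epiland.synthetic import simulate_biolog

curves = simulate_biolog(seed=7, n_wells=96, n_gains=10, n_losses=3)
calls = screen_from_table(curves, strain_evolved="evolved", strain_ancestor="ancestor")
s = screen_summary(calls)

print(f"{s['n_environments']} environments screened")
print(f"differential: {s['differential']} "
      f"({s['gains']} gains of function, {s['losses']} losses of function)")
print("gain environments:", ", ".join(s["gain_environments"][:5]), "...")

# A gain of function means the evolved strain respires more than its
# ancestor in that environment; losses indicate catabolic functions decayed
# during adaptation elsewhere.
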